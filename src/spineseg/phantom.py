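"""Seeded sagittal lumbar-spine phantoms with paired segmentation masks.

Each phantom is a 2D grayscale "sagittal slice": a gently curved vertical
column of bright rounded-rectangle vertebral bodies, darker elliptical
intervertebral discs between consecutive vertebrae, and a thin dark
spinal-canal stripe posterior to the column, over a noisy low-intensity
background.  The intensity ordering (bright bone marrow, mid-intensity
discs, dark canal) mimics T1-weighted contrast.  Masks are defined on the
crisp pre-blur geometry, so ground truth is exact while the rendered image
has soft edges.

All geometry defaults are expressed as fractions of the image size, so the
same configuration scales from the 128-pixel working resolution down to
reduced test sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .preprocess import (IDENTITY_4CLASS, SlicePair, encode_masks,
                         save_cache)

BACKGROUND, VERTEBRA, DISC, CANAL = 0, 1, 2, 3


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, contrast and noise of one phantom.

    Pixel quantities default to ``None`` and are derived from ``size``;
    pass explicit pixel values to override.  ``seed`` fully determines the
    sample.
    """

    size: int = 128
    n_vertebrae: int = 6
    vertebra_height: float | None = None  # pixels; default 0.68 * span/n
    vertebra_width: float | None = None  # pixels; default 0.22 * size
    disc_height: float | None = None  # pixels; default 0.55 * gap
    canal_width: float | None = None  # pixels; default 0.055 * size
    jitter: float = 0.08  # fractional size jitter per structure
    column_curvature: float = 0.15  # max lateral bow, fraction of width margin
    vertebra_intensity: float = 0.75
    disc_intensity: float = 0.45
    canal_intensity: float = 0.25
    background_intensity: float = 0.10
    noise_sigma: float = 0.03
    blur_sigma: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.n_vertebrae < 2:
            raise ValueError("n_vertebrae must be >= 2")
        for name in ("vertebra_intensity", "disc_intensity",
                     "canal_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.size < 16:
            raise ValueError("size must be >= 16")

    # derived geometry (pixels)

    @property
    def _margin(self) -> float:
        return 0.08 * self.size

    @property
    def _unit(self) -> float:
        return (self.size - 2 * self._margin) / self.n_vertebrae

    @property
    def vert_h(self) -> float:
        return self.vertebra_height or 0.68 * self._unit

    @property
    def vert_w(self) -> float:
        return self.vertebra_width or 0.22 * self.size

    @property
    def gap(self) -> float:
        return self._unit - self.vert_h

    @property
    def disc_h(self) -> float:
        return self.disc_height or 0.55 * self.gap

    @property
    def canal_w(self) -> float:
        return self.canal_width or 0.055 * self.size

    def validate_geometry(self) -> None:
        if self.vert_h >= self._unit:
            raise ValueError("vertebra_height leaves no room for discs")
        if self.disc_h >= self.gap:
            raise ValueError("disc_height exceeds the inter-vertebral gap")
        # column + canal must fit laterally even at maximum bow
        needed = self.vert_w / 2 + 0.10 * self.size + self.canal_w
        if 0.30 * self.size + needed > self.size:
            raise ValueError("column geometry overflows the image")


@dataclass
class PhantomSample:
    image: np.ndarray  # (S, S) float in [0, 1]
    mask4: np.ndarray  # (S, S) int labels {0..3}
    config: PhantomConfig
    seed: int

    @property
    def mask2(self) -> np.ndarray:
        return (self.mask4 > 0).astype(np.int64)


def generate_phantom(cfg: PhantomConfig) -> PhantomSample:
    """Render one phantom, fully determined by ``cfg`` (incl. its seed)."""
    cfg.validate_geometry()
    rng = np.random.default_rng(cfg.seed)
    s = cfg.size
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    mask = np.zeros((s, s), dtype=np.int64)

    # column center line: lateral quadratic bow around mid-height
    cx0 = (0.38 + 0.08 * rng.random()) * s
    bow = cfg.column_curvature * (2 * rng.random() - 1) * 0.1 * s
    y0, y1 = cfg._margin, s - cfg._margin

    def center_x(y):
        t = (y - (y0 + y1) / 2) / ((y1 - y0) / 2)
        return cx0 + bow * t * t

    # vertebral bodies (rounded rectangles), top to bottom
    centers = []
    for i in range(cfg.n_vertebrae):
        cy = y0 + (i + 0.5) * cfg._unit
        h = cfg.vert_h * (1 + cfg.jitter * (2 * rng.random() - 1))
        w = cfg.vert_w * (1 + cfg.jitter * (2 * rng.random() - 1))
        h = min(h, 0.96 * cfg._unit)
        cx = center_x(cy)
        centers.append((cy, cx))
        r = 0.25 * min(h, w)
        dy = np.abs(yy - cy) - (h / 2 - r)
        dx = np.abs(xx - cx) - (w / 2 - r)
        dist = np.hypot(np.maximum(dx, 0), np.maximum(dy, 0))
        inside = (dist <= r) & (np.abs(yy - cy) <= h / 2) & (np.abs(xx - cx) <= w / 2)
        mask[inside] = VERTEBRA

    # discs: ellipses centered between consecutive vertebrae, never
    # overwriting vertebra pixels (keeps them strictly between bodies)
    for (cy_a, cx_a), (cy_b, cx_b) in zip(centers[:-1], centers[1:]):
        cy = (cy_a + cy_b) / 2
        cx = (cx_a + cx_b) / 2
        h = cfg.disc_h * (1 + cfg.jitter * (2 * rng.random() - 1))
        h = min(h, 0.9 * cfg.gap)
        w = 0.85 * cfg.vert_w
        ell = ((yy - cy) / (h / 2)) ** 2 + ((xx - cx) / (w / 2)) ** 2 <= 1.0
        mask[ell & (mask == BACKGROUND)] = DISC

    # spinal canal: thin stripe following the column on its posterior side
    y_top = centers[0][0] - cfg.vert_h / 2
    y_bot = centers[-1][0] + cfg.vert_h / 2
    offset = cfg.vert_w / 2 + 0.045 * s
    canal_cx = center_x(yy) + offset
    stripe = ((np.abs(xx - canal_cx) <= cfg.canal_w / 2)
              & (yy >= y_top) & (yy <= y_bot))
    mask[stripe & (mask == BACKGROUND)] = CANAL

    intensities = np.array([cfg.background_intensity, cfg.vertebra_intensity,
                            cfg.disc_intensity, cfg.canal_intensity])
    image = intensities[mask]
    if cfg.blur_sigma > 0:
        image = gaussian_filter(image, cfg.blur_sigma)
    if cfg.noise_sigma > 0:
        image = image + rng.normal(0.0, cfg.noise_sigma, image.shape)
    image = np.clip(image, 0.0, 1.0)
    return PhantomSample(image=image.astype(np.float64), mask4=mask,
                         config=cfg, seed=cfg.seed)


def phantom_to_slice_pair(sample: PhantomSample, n_classes: int = 2
                          ) -> SlicePair:
    """Convert a phantom to the cache/training representation."""
    size = sample.config.size
    mask, bott = encode_masks(sample.mask4, IDENTITY_4CLASS, n_classes,
                              bottleneck_size=size // 16)
    return SlicePair(
        image=sample.image.astype(np.float32), mask_onehot=mask,
        bottleneck_onehot=bott,
        provenance={"source_id": f"phantom-{sample.seed}",
                    "series_tag": "t1_phantom", "seed": int(sample.seed)})


def generate_dataset(cfg: PhantomConfig, n: int, seed: int,
                     n_classes: int = 2,
                     cache_dir: str | Path | None = None
                     ) -> list[SlicePair]:
    """n phantoms with per-sample seeds spawned from a master seed.

    The result uses the same cache layout as the MRI preprocessing
    pipeline, so training consumes either source identically.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]
    pairs = [phantom_to_slice_pair(
        generate_phantom(replace(cfg, seed=s)), n_classes)
        for s in child_seeds]
    if cache_dir is not None:
        save_cache(pairs, cache_dir)
    return pairs


# 4-color palette for PNG mask previews (background, vertebra, disc, canal)
MASK_PALETTE = np.array([[0, 0, 0], [255, 210, 60], [80, 170, 255],
                         [235, 80, 80]], dtype=np.uint8)


def export_png(sample: PhantomSample, image_path: str | Path,
               mask_path: str | Path | None = None) -> None:
    import imageio.v3 as iio
    iio.imwrite(str(image_path),
                np.floor(sample.image * 255 + 0.5).astype(np.uint8))
    if mask_path is not None:
        iio.imwrite(str(mask_path), MASK_PALETTE[sample.mask4])
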