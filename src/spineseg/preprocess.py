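"""Deterministic conversion of labeled MRI volumes into training slices.

The pipeline is: keep T1-weighted series, take the central sagittal slice,
rescale intensities to 8-bit [0, 255], resize to a square working size
(bilinear for the image, nearest-neighbor for the labels), normalize to
[0, 1], and one-hot encode the mask at full resolution and at the 16x
downsampled bottleneck resolution used for auxiliary supervision.

Volumes are read with SimpleITK (MetaImage) or nibabel (NIfTI); slice
pairs are cached as .npy arrays with a JSON index so phantom data and real
data share one on-disk layout.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize


@dataclass
class VolumeRecord:
    """A 3D image volume with a same-shaped integer label volume."""

    voxels: np.ndarray  # (slice, row, col)
    labels: np.ndarray
    series_tag: str = ""
    source_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.labels = np.asarray(self.labels)
        if self.voxels.shape != self.labels.shape:
            raise ValueError(
                f"voxels {self.voxels.shape} and labels {self.labels.shape} "
                "must be shape-identical")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative integers")


@dataclass
class LabelMap:
    """Mapping from raw mask codes to class indices.

    For binary work the rule is simply nonzero -> foreground; for
    multiclass a total mapping {raw code: class index} must be supplied
    (class indices 0=background, 1=vertebra, 2=disc, 3=canal).
    """

    mapping: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.mapping.get(0, 0) != 0:
            raise ValueError("background (raw code 0) must map to class 0")

    def apply(self, labels: np.ndarray, n_classes: int) -> np.ndarray:
        labels = np.asarray(labels)
        if n_classes == 2:
            return (labels > 0).astype(np.int64)
        codes = np.unique(labels)
        missing = [int(c) for c in codes if c != 0 and int(c) not in self.mapping]
        if missing:
            raise ValueError(f"unmapped raw label codes: {missing}")
        out = np.zeros(labels.shape, dtype=np.int64)
        for code, cls in self.mapping.items():
            if not 0 <= cls < n_classes:
                raise ValueError(f"class index {cls} outside [0, {n_classes})")
            out[labels == code] = cls
        return out


IDENTITY_4CLASS = LabelMap({0: 0, 1: 1, 2: 2, 3: 3})


@dataclass
class SlicePair:
    """A preprocessed training example."""

    image: np.ndarray  # (S, S) in [0, 1]
    mask_onehot: np.ndarray  # (S, S, C)
    bottleneck_onehot: np.ndarray  # (S/16, S/16, C)
    provenance: dict = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return self.mask_onehot.shape[-1]

    @property
    def labels(self) -> np.ndarray:
        return self.mask_onehot.argmax(axis=-1)


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def select_t1(records: list[VolumeRecord],
              pattern: str = "t1") -> list[VolumeRecord]:
    """Keep records whose series tag matches ``pattern`` (case-insensitive
    regex search; the default matches any tag containing 't1')."""
    rx = re.compile(pattern, re.IGNORECASE)
    kept = [r for r in records if rx.search(r.series_tag)]
    if not kept:
        warnings.warn(f"no records matched T1 pattern {pattern!r}")
    return kept


def central_slice(volume: VolumeRecord) -> tuple[np.ndarray, np.ndarray]:
    """The floor(depth/2) slice of both voxels and labels."""
    depth = volume.voxels.shape[0]
    if depth < 1:
        raise ValueError("empty volume")
    i = depth // 2
    return volume.voxels[i], volume.labels[i]


def rescale_to_8bit(image: np.ndarray) -> np.ndarray:
    """Min-max rescale to integers in [0, 255] (round half up).

    A constant image maps to all zeros.
    """
    x = np.asarray(image, dtype=np.float64)
    if not np.isfinite(x).all():
        raise ValueError("image contains NaN or Inf")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(x.shape, dtype=np.uint8)
    scaled = 255.0 * (x - lo) / (hi - lo)
    return np.floor(scaled + 0.5).astype(np.uint8)


def nearest_resize_labels(labels: np.ndarray, out_shape: tuple[int, int]
                          ) -> np.ndarray:
    """Nearest-neighbor label resize by pixel-center index mapping.

    Output pixel i samples source index floor((i + 0.5) * in/out); no new
    label values can appear.
    """
    labels = np.asarray(labels)
    h, w = labels.shape
    oh, ow = out_shape
    rows = np.minimum((np.floor((np.arange(oh) + 0.5) * h / oh)).astype(int), h - 1)
    cols = np.minimum((np.floor((np.arange(ow) + 0.5) * w / ow)).astype(int), w - 1)
    return labels[np.ix_(rows, cols)]


def resize_pair(image: np.ndarray, labels: np.ndarray,
                size: int = 128) -> tuple[np.ndarray, np.ndarray]:
    """Resize to size x size: bilinear image (then /255 into [0,1]),
    nearest-neighbor labels."""
    if size <= 0:
        raise ValueError("size must be positive")
    img = _sk_resize(np.asarray(image, dtype=np.float64), (size, size),
                     order=1, anti_aliasing=False, preserve_range=True)
    img = np.clip(img / 255.0, 0.0, 1.0)
    lab = nearest_resize_labels(labels, (size, size))
    return img, lab


def one_hot(class_map: np.ndarray, n_classes: int) -> np.ndarray:
    eye = np.eye(n_classes, dtype=np.float32)
    return eye[np.asarray(class_map, dtype=np.int64)]


def encode_masks(labels: np.ndarray, label_map: LabelMap, n_classes: int,
                 bottleneck_size: int | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """One-hot mask at full resolution plus the downsampled bottleneck
    target (nearest-neighbor on the class-index map, then one-hot)."""
    class_map = label_map.apply(labels, n_classes)
    if bottleneck_size is None:
        bottleneck_size = class_map.shape[0] // 16
    small = nearest_resize_labels(class_map, (bottleneck_size, bottleneck_size))
    return one_hot(class_map, n_classes), one_hot(small, n_classes)


def build_dataset(records: list[VolumeRecord], label_map: LabelMap,
                  n_classes: int = 2, size: int = 128,
                  t1_pattern: str = "t1",
                  cache_dir: str | Path | None = None) -> list[SlicePair]:
    """Full pipeline over a list of volumes; optionally persists a cache."""
    if not records:
        raise ValueError("no input records")
    pairs: list[SlicePair] = []
    for rec in select_t1(records, t1_pattern):
        try:
            img, lab = central_slice(rec)
            img8 = rescale_to_8bit(img)
            img01, lab = resize_pair(img8, lab, size)
            mask, bott = encode_masks(lab, label_map, n_classes, size // 16)
        except ValueError as exc:
            raise ValueError(
                f"record {rec.source_id or rec.series_tag!r}: {exc}") from exc
        pairs.append(SlicePair(
            image=img01.astype(np.float32), mask_onehot=mask,
            bottleneck_onehot=bott,
            provenance={"source_id": rec.source_id,
                        "series_tag": rec.series_tag,
                        "slice_index": rec.voxels.shape[0] // 2}))
    if cache_dir is not None:
        save_cache(pairs, cache_dir)
    return pairs


# ---------------------------------------------------------------------------
# on-disk cache (shared with the phantom generator)
# ---------------------------------------------------------------------------

def save_cache(pairs: list[SlicePair], cache_dir: str | Path) -> None:
    """Write stacked .npy arrays plus a JSON index."""
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    np.save(cache_dir / "images.npy",
            np.stack([p.image for p in pairs]).astype(np.float32))
    np.save(cache_dir / "masks.npy",
            np.stack([p.mask_onehot for p in pairs]).astype(np.float32))
    np.save(cache_dir / "bottleneck.npy",
            np.stack([p.bottleneck_onehot for p in pairs]).astype(np.float32))
    index = {
        "n_items": len(pairs),
        "image_size": int(pairs[0].image.shape[0]),
        "n_classes": int(pairs[0].n_classes),
        "bottleneck_size": int(pairs[0].bottleneck_onehot.shape[0]),
        "provenance": [p.provenance for p in pairs],
    }
    (cache_dir / "index.json").write_text(json.dumps(index, indent=2))


def load_cache(cache_dir: str | Path) -> list[SlicePair]:
    cache_dir = Path(cache_dir)
    index = json.loads((cache_dir / "index.json").read_text())
    images = np.load(cache_dir / "images.npy")
    masks = np.load(cache_dir / "masks.npy")
    bott = np.load(cache_dir / "bottleneck.npy")
    return [SlicePair(images[i], masks[i], bott[i],
                      provenance=index["provenance"][i])
            for i in range(index["n_items"])]


# ---------------------------------------------------------------------------
# volume readers
# ---------------------------------------------------------------------------

def read_volume(image_path: str | Path, label_path: str | Path,
                series_tag: str | None = None) -> VolumeRecord:
    """Read an image/label volume pair from MetaImage or NIfTI files.

    The series tag defaults to the image file stem, which for conventional
    naming (e.g. ``patient12_t1.mha``) carries the modality.
    """
    image_path, label_path = Path(image_path), Path(label_path)
    voxels = _read_array(image_path)
    labels = _read_array(label_path).astype(np.int64)
    tag = series_tag if series_tag is not None else image_path.stem
    return VolumeRecord(voxels, labels, series_tag=tag,
                        source_id=image_path.stem)


def _read_array(path: Path) -> np.ndarray:
    name = path.name.lower()
    if name.endswith((".mha", ".mhd")):
        import SimpleITK as sitk
        return sitk.GetArrayFromImage(sitk.ReadImage(str(path)))
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        arr = np.asanyarray(nib.load(str(path)).dataobj)
        # nibabel is (x, y, z); put the slice axis first like SimpleITK
        return np.transpose(arr, (2, 1, 0)) if arr.ndim == 3 else arr
    raise ValueError(f"unsupported volume format: {path.name}")
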