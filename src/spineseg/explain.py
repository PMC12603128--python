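"""Grad-CAM heatmaps for the segmentation network.

Adaptation of Grad-CAM to a dense softmax head: the class score is the
spatial sum of the chosen class's final softmax channel; channel weights
are the global-average-pooled gradients of that score with respect to the
target layer's activations; the map is the ReLU of the weighted activation
sum, bilinearly upsampled to the input resolution and min-max normalized
to [0, 1] (an all-zero map stays all-zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .arch import LayerGraph

DEFAULT_LAYER = "dec4b_bn"  # last decoder activation before the 1x1 head


@dataclass
class HeatMap:
    values: np.ndarray  # (H, W) in [0, 1], input resolution
    layer: str
    class_index: int


def conv_layer_names(model: LayerGraph) -> list[str]:
    """Nodes whose output is a convolutional activation map."""
    return [n.name for n in model.nodes.values()
            if isinstance(n.layer, (nn.Conv2D, nn.TransposedConv2x2,
                                    nn.BatchNorm))]


def gradcam(model: LayerGraph, image: np.ndarray,
            layer: str | None = None, class_index: int = 1) -> HeatMap:
    """Class-discriminative heatmap over ``image`` at ``layer``."""
    if layer is None:
        layer = DEFAULT_LAYER if DEFAULT_LAYER in model.nodes else \
            conv_layer_names(model)[-1]
    if layer not in model.nodes:
        raise ValueError(
            f"unknown layer {layer!r}; convolutional layers: "
            f"{conv_layer_names(model)}")
    n_classes = model.config.n_classes
    if not 0 <= class_index < n_classes:
        raise ValueError(f"class_index {class_index} outside [0, {n_classes})")

    x = np.asarray(image, dtype=nn.DTYPE)
    if x.ndim == 2:
        x = x[None, :, :, None]
    out = model.forward(x, training=False)
    final = out["final"]
    # score = sum over pixels of the class channel -> seed gradient is a
    # one-hot channel indicator
    seed = np.zeros_like(final)
    seed[..., class_index] = 1.0
    captured = model.backward({"final": seed}, capture={layer})
    grads = captured[layer][0]  # (h, w, c)
    acts = model.activations()[layer][0]

    weights = grads.mean(axis=(0, 1))
    cam = np.maximum((acts * weights).sum(axis=-1), 0.0)
    size = model.config.input_size
    cam = _sk_resize(cam.astype(np.float64), (size, size), order=1,
                     anti_aliasing=False, preserve_range=True)
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return HeatMap(values=cam, layer=layer, class_index=class_index)


def save_heatmap_png(heatmap: HeatMap, image: np.ndarray,
                     out_path: str | Path, alpha: float = 0.5) -> None:
    """Write an overlay PNG: grayscale image blended with a hot colormap."""
    import imageio.v3 as iio
    img = np.asarray(image, dtype=float)
    img = (img - img.min()) / (np.ptp(img) or 1.0)
    h = heatmap.values
    # simple "hot" ramp: black -> red -> yellow -> white
    r = np.clip(3 * h, 0, 1)
    g = np.clip(3 * h - 1, 0, 1)
    b = np.clip(3 * h - 2, 0, 1)
    overlay = (1 - alpha) * img[..., None] + alpha * np.stack([r, g, b], axis=-1)
    iio.imwrite(str(out_path),
                np.floor(np.clip(overlay, 0, 1) * 255 + 0.5).astype(np.uint8))
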