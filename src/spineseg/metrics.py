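"""Evaluation suite: confusion-based pixel metrics and boundary distances.

Pixel metrics (mIoU, accuracy, precision, recall, F1) all derive from a
single additive per-class confusion accumulator, so pooling across a test
set is exact.  Boundary metrics are the Hausdorff distance and the average
symmetric surface distance (ASSD) between 4-connected boundary point sets,
in pixel units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


class EmptyBoundaryError(ValueError):
    """A boundary distance was requested for an empty point set."""


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest TP/FP/FN/TN counts; additive across images."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.tp)

    @property
    def total_pixels(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])

    @classmethod
    def zeros(cls, n_classes: int) -> "ConfusionCounts":
        z = lambda: np.zeros(n_classes, dtype=np.int64)
        return cls(z(), z(), z(), z())

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        if self.n_classes != other.n_classes:
            raise ValueError("class count mismatch")
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def confusion(pred_labels: np.ndarray, true_labels: np.ndarray,
              n_classes: int) -> ConfusionCounts:
    """Per-class confusion counts from integer label maps of equal shape."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    for name, arr in (("pred", pred), ("true", true)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} labels outside [0, {n_classes})")
    # joint histogram: rows = truth, cols = prediction
    joint = np.bincount(true.ravel() * n_classes + pred.ravel(),
                        minlength=n_classes * n_classes
                        ).reshape(n_classes, n_classes)
    tp = np.diag(joint).astype(np.int64)
    fp = joint.sum(axis=0) - tp
    fn = joint.sum(axis=1) - tp
    tn = joint.sum() - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def scalar_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """mIoU, accuracy, precision, recall and F1 from pooled counts.

    IoU of a class absent from both maps is defined as 1.  For two classes,
    precision/recall/F1 are the foreground-class values; for more, the
    macro average over classes.  Per-class ratios with an empty denominator
    are set to 0 (no predictions / no positives).
    """
    if counts.total_pixels == 0:
        raise ValueError("no pixels evaluated")
    tp = counts.tp.astype(float)
    fp = counts.fp.astype(float)
    fn = counts.fn.astype(float)
    denom = tp + fp + fn
    iou = np.where(denom > 0, tp / np.where(denom > 0, denom, 1), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec_c = np.where(tp + fp > 0, tp / np.where(tp + fp > 0, tp + fp, 1), 0.0)
        rec_c = np.where(tp + fn > 0, tp / np.where(tp + fn > 0, tp + fn, 1), 0.0)
    if counts.n_classes == 2:
        precision, recall = float(prec_c[1]), float(rec_c[1])
    else:
        precision, recall = float(prec_c.mean()), float(rec_c.mean())
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return {
        "miou": float(iou.mean()),
        "accuracy": float(tp.sum() / counts.total_pixels),
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


# ---------------------------------------------------------------------------
# boundary metrics
# ---------------------------------------------------------------------------

def extract_boundary(mask: np.ndarray) -> np.ndarray:
    """Coordinates of foreground pixels with a background 4-neighbor.

    Off-image counts as background, so pixels on the array edge are
    boundary whenever they are foreground.  Returns an (n, 2) int array of
    (row, col) points.
    """
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2D")
    padded = np.pad(m, 1, constant_values=False)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1]
                & padded[1:-1, :-2] & padded[1:-1, 2:])
    boundary = m & ~interior
    return np.argwhere(boundary)


def hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets, in pixels."""
    a, b = _as_points(a), _as_points(b)
    d = cdist(a, b)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def assd(a: np.ndarray, b: np.ndarray) -> float:
    """Average symmetric surface distance between two point sets."""
    a, b = _as_points(a), _as_points(b)
    d = cdist(a, b)
    return float((d.min(axis=1).sum() + d.min(axis=0).sum()) / (len(a) + len(b)))


def _as_points(points: np.ndarray) -> np.ndarray:
    p = np.asarray(points, dtype=float)
    if p.size == 0:
        raise EmptyBoundaryError("boundary point set is empty")
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    return p


def boundary_distances(pred_mask: np.ndarray, true_mask: np.ndarray
                       ) -> tuple[float, float] | None:
    """(HD, ASSD) between the boundaries of two binary masks.

    Returns None (with a warning) when either mask has no boundary, so a
    caller aggregating over images can skip it.
    """
    a = extract_boundary(pred_mask)
    b = extract_boundary(true_mask)
    if len(a) == 0 or len(b) == 0:
        warnings.warn("empty boundary; skipping HD/ASSD for this image")
        return None
    return hausdorff(a, b), assd(a, b)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

_COLUMNS = ["miou", "accuracy", "precision", "recall", "f1"]
_HEADERS = ["mIoU", "Accuracy", "Precision", "Recall", "F1-score"]


def metrics_table(rows: dict[str, dict[str, float]]) -> str:
    """Aligned text table of metric dicts keyed by row label."""
    label_w = max(12, max((len(k) for k in rows), default=0) + 2)
    lines = ["".join([f"{'':<{label_w}}"] + [f"{h:>11}" for h in _HEADERS])]
    for label, m in rows.items():
        cells = [f"{m[c]:>11.4f}" for c in _COLUMNS]
        lines.append(f"{label:<{label_w}}" + "".join(cells))
    return "\n".join(lines)


def metrics_json(metrics: dict[str, float]) -> str:
    return json.dumps({k: round(float(v), 6) for k, v in metrics.items()},
                      indent=2)
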