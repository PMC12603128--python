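"""Dual-output training, evaluation, and multi-seed stability harness.

Training minimizes ``w_final * L(final head) + w_bottleneck * L(bottleneck
head)`` with the same loss at both heads (the auxiliary 8x8 head is a
supervision signal only; inference uses the final head alone).  The
optimizer is Adam; every stochastic element — weight initialization,
shuffling, dropout, splitting — flows through explicit seeds.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import arch, metrics as metrics_mod
from .losses import LOSS_GRADS, LossConfig
from .preprocess import SlicePair


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 2
    epochs: int = 50
    loss_name: str = "dice"
    # (final head, bottleneck head) loss weights
    output_loss_weights: tuple[float, float] = (1.0, 1.0)
    train_fraction: float = 0.8
    val_fraction: float = 0.2  # of the training pool
    seed: int = 0
    model: arch.ModelConfig = field(default_factory=arch.ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.loss_name not in LOSS_GRADS:
            raise ValueError(f"unknown loss {self.loss_name!r}")

    def with_(self, **kw) -> "TrainConfig":
        return replace(self, **kw)


@dataclass
class RunMetrics:
    train_loss: list[float]
    val_loss: list[float]
    test_metrics: dict[str, float] = field(default_factory=dict)
    seed: int = 0


@dataclass
class StabilityReport:
    """Per-run metric table with mean and sample (n-1) std per metric."""

    rows: list[dict[str, float]]
    mean: dict[str, float] = field(default_factory=dict)
    std: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_rows(cls, rows: list[dict[str, float]]) -> "StabilityReport":
        keys = rows[0].keys()
        mean = {k: float(np.mean([r[k] for r in rows])) for k in keys}
        std = {k: float(np.std([r[k] for r in rows], ddof=1)) for k in keys}
        return cls(rows=list(rows), mean=mean, std=std)


def split_dataset(n_items: int, train_fraction: float = 0.8,
                  val_fraction: float = 0.2, seed: int = 0,
                  val_seed: int | None = None
                  ) -> tuple[list[int], list[int], list[int]]:
    """Disjoint, exhaustive (train, val, test) index lists.

    The test set (round((1 - train_fraction) * n)) is fixed by ``seed``;
    the validation set (round(val_fraction * pool)) is carved from the
    remaining pool by ``val_seed`` (defaults to ``seed``), so repeated
    stability runs can keep train/test fixed while re-sampling validation.
    """
    if n_items < 3:
        raise ValueError("need at least 3 items to split")
    n_test = round((1.0 - train_fraction) * n_items)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_items)
    test = sorted(int(i) for i in perm[:n_test])
    pool = [int(i) for i in perm[n_test:]]
    n_val = round(val_fraction * len(pool))
    if n_val == 0 or n_val == len(pool) or n_test == 0:
        raise ValueError("split fractions produce an empty subset")
    vrng = np.random.default_rng(seed if val_seed is None else val_seed)
    vperm = vrng.permutation(len(pool))
    val = sorted(pool[i] for i in vperm[:n_val])
    train = sorted(pool[i] for i in vperm[n_val:])
    return train, val, test


def _stack(pairs: list[SlicePair], idx) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    imgs = np.stack([pairs[i].image for i in idx])[..., None]
    masks = np.stack([pairs[i].mask_onehot for i in idx])
    botts = np.stack([pairs[i].bottleneck_onehot for i in idx])
    return imgs.astype(np.float32), masks, botts


def _batch_loss(model: arch.LayerGraph, loss_grad, weights, x, y_full, y_bott,
                training: bool):
    """Forward (+grads when training): returns (loss value, seed grads)."""
    out = model.forward(x, training=training)
    w_final, w_bott = weights
    value, grads = 0.0, {}
    v, g = loss_grad(y_full, out["final"])
    value += w_final * v
    grads["final"] = w_final * g
    if "bottleneck" in out and w_bott != 0.0:
        vb, gb = loss_grad(y_bott, out["bottleneck"])
        value += w_bott * vb
        grads["bottleneck"] = w_bott * gb
    return value, grads


def fit(train_cfg: TrainConfig, data: list[SlicePair],
        split: tuple[list[int], list[int], list[int]] | None = None
        ) -> tuple[arch.LayerGraph, RunMetrics, tuple[list[int], list[int], list[int]]]:
    """Train a model on ``data``; returns (model, metrics, index split).

    By default the (train, val, test) split is derived from the config
    seed so one seed reproduces the whole run; pass ``split`` to pin it
    externally (the stability harness does, to keep test fixed across
    runs).  The test indices are returned untouched for downstream
    evaluation.
    """
    if not data:
        raise ValueError("no training data")
    mc = train_cfg.model
    if data[0].n_classes != mc.n_classes:
        raise ValueError(
            f"model has {mc.n_classes} classes but data has "
            f"{data[0].n_classes}")
    if data[0].image.shape[0] != mc.input_size:
        raise ValueError(
            f"model input_size {mc.input_size} does not match data size "
            f"{data[0].image.shape[0]}")

    tr_idx, va_idx, te_idx = split if split is not None else split_dataset(
        len(data), train_cfg.train_fraction, train_cfg.val_fraction,
        seed=train_cfg.seed)
    model = arch.build_model(mc, seed=train_cfg.seed)
    rng = np.random.default_rng(train_cfg.seed + 1)
    model.set_dropout_rng(np.random.default_rng(train_cfg.seed + 2))
    opt = arch.nn.Adam(model.params(), lr=train_cfg.learning_rate)
    loss_grad = LOSS_GRADS[train_cfg.loss_name]

    def lg(y_true, y_pred):
        return loss_grad(y_true, y_pred, train_cfg.loss)

    x_va, y_va, b_va = _stack(data, va_idx)
    history_tr, history_va = [], []
    bs = train_cfg.batch_size
    for _ in range(train_cfg.epochs):
        order = rng.permutation(len(tr_idx))
        epoch_losses = []
        for start in range(0, len(order), bs):
            batch = [tr_idx[i] for i in order[start:start + bs]]
            x, y, b = _stack(data, batch)
            value, grads = _batch_loss(model, lg, train_cfg.output_loss_weights,
                                       x, y, b, training=True)
            model.backward(grads)
            opt.step()
            epoch_losses.append(value)
        history_tr.append(float(np.mean(epoch_losses)))
        v_val, _ = _batch_loss(model, lg, train_cfg.output_loss_weights,
                               x_va, y_va, b_va, training=False)
        history_va.append(float(v_val))
    return model, RunMetrics(history_tr, history_va, seed=train_cfg.seed), \
        (tr_idx, va_idx, te_idx)


def evaluate_model(model: arch.LayerGraph, test: list[SlicePair],
                   with_boundary: bool = False,
                   batch_size: int = 8) -> dict[str, float]:
    """Pooled-confusion metrics of the final head's argmax predictions.

    With ``with_boundary``, adds the mean per-image Hausdorff distance and
    ASSD of the binary foreground (images with an empty boundary on either
    side are skipped).
    """
    if not test:
        raise ValueError("empty test set")
    n_classes = test[0].n_classes
    counts = metrics_mod.ConfusionCounts.zeros(n_classes)
    hds, assds = [], []
    for start in range(0, len(test), batch_size):
        chunk = test[start:start + batch_size]
        x, y, _ = _stack(chunk, range(len(chunk)))
        pred = model.forward(x, training=False)["final"].argmax(axis=-1)
        true = y.argmax(axis=-1)
        for i in range(len(chunk)):
            counts = counts + metrics_mod.confusion(pred[i], true[i], n_classes)
            if with_boundary:
                d = metrics_mod.boundary_distances(pred[i] > 0, true[i] > 0)
                if d is not None:
                    hds.append(d[0])
                    assds.append(d[1])
    result = metrics_mod.scalar_metrics(counts)
    if with_boundary and hds:
        result["hausdorff"] = float(np.mean(hds))
        result["assd"] = float(np.mean(assds))
    return result


def stability_runs(train_cfg: TrainConfig, data: list[SlicePair],
                   n_runs: int, seeds: list[int],
                   with_boundary: bool = False) -> StabilityReport:
    """Repeat fit/evaluate per seed with a fixed train/test split.

    The test set stays pinned to ``train_cfg.seed``; each run re-samples
    the validation subset and re-initializes weights from its own seed.
    """
    if n_runs != len(seeds):
        raise ValueError("n_runs must equal len(seeds)")
    rows = []
    te_idx = None
    for run_seed in seeds:
        # test pinned to the master seed; validation re-sampled per run
        split = split_dataset(len(data), train_cfg.train_fraction,
                              train_cfg.val_fraction,
                              seed=train_cfg.seed, val_seed=run_seed)
        te_idx = split[2]
        cfg = train_cfg.with_(seed=run_seed)
        model, _, _ = fit(cfg, data, split=split)
        rows.append(evaluate_model(model, [data[i] for i in te_idx],
                                   with_boundary=with_boundary))
    return StabilityReport.from_rows(rows)


# ---------------------------------------------------------------------------
# run directory persistence (CLI support)
# ---------------------------------------------------------------------------

def save_run(run_dir: str | Path, model: arch.LayerGraph,
             run_metrics: RunMetrics, train_cfg: TrainConfig) -> None:
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    arch.save_model(model, run_dir / "model.npz")
    cfg = {"learning_rate": train_cfg.learning_rate,
           "batch_size": train_cfg.batch_size,
           "epochs": train_cfg.epochs,
           "loss_name": train_cfg.loss_name,
           "output_loss_weights": list(train_cfg.output_loss_weights),
           "seed": train_cfg.seed,
           "model": train_cfg.model.to_dict()}
    (run_dir / "config.json").write_text(json.dumps(cfg, indent=2))
    with open(run_dir / "loss_history.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "train_loss", "val_loss"])
        for i, (tr, va) in enumerate(zip(run_metrics.train_loss,
                                         run_metrics.val_loss), start=1):
            writer.writerow([i, tr, va])
    if run_metrics.test_metrics:
        (run_dir / "metrics.json").write_text(
            json.dumps(run_metrics.test_metrics, indent=2))
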