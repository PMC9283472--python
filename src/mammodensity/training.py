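"""End-to-end training and inference for the multitask segmentation model.

The loop optimizes the per-task focal Tversky losses combined either with
learnable homoscedastic-uncertainty weights (``adaptive``, the default),
a fixed naive weight lambda (``naive``), or as a single task with the
other decoder absent (``single_breast`` / ``single_dense``).  Model
selection keeps the epoch with the best validation F-score on the dense
tissue — the main task — falling back to the breast task in single-breast
mode.  Everything is reproducible from one master seed, which derives the
data-split and shuffling streams (weight initialization is seeded
separately in :func:`~mammodensity.network.build_model`).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .density import percent_density
from .imaging_io import AnnotatedSample, BinaryMask, Mammogram, \
    normalize_intensity, resize_for_model, restore_to_original
from .losses import NaiveWeights, TverskyParams, adaptive_mtl_loss, \
    focal_tversky_loss, naive_mtl_loss
from .network import MultiTaskSegNet, NetworkConfig, build_model
from .seg_metrics import seg_score

__all__ = [
    "TrainConfig",
    "TrainReport",
    "preprocess_samples",
    "train",
    "lambda_grid",
    "predict_masks",
    "evaluate_model",
    "predict_pd",
]

LOSS_MODES = ("adaptive", "naive", "single_breast", "single_dense")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    lr_schedule: str | None = None        # None or "cosine"
    loss_mode: str = "adaptive"
    naive_lambda: float = 0.3
    threshold: float = 0.5
    seed: int = 0
    validation_fraction: float = 0.2
    tversky: TverskyParams = field(default_factory=TverskyParams)

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss_mode not in LOSS_MODES:
            raise ValueError(f"loss_mode must be one of {LOSS_MODES}")
        if self.loss_mode == "naive":
            NaiveWeights(self.naive_lambda)  # validates the open interval


@dataclass
class TrainReport:
    """Per-epoch training trace plus the selected best epoch."""

    frame: pd.DataFrame
    best_epoch: int
    tasks: tuple[str, ...]


def preprocess_samples(samples, side: int) -> list[AnnotatedSample]:
    """Min-max normalize images and resize images+masks to the model side."""
    out = []
    for s in samples:
        img = resize_for_model(normalize_intensity(s.image), side)
        breast = resize_for_model(s.breast, side)
        dense = resize_for_model(s.dense, side)
        # keep native size metadata for later restoration
        img.original_size = s.image.original_size
        breast.original_size = s.breast.original_size
        dense.original_size = s.dense.original_size
        ns = AnnotatedSample.__new__(AnnotatedSample)
        ns.image, ns.breast, ns.dense = img, breast, dense
        ns.true_pd, ns.sample_id = s.true_pd, s.sample_id
        out.append(ns)
    return out


def _stack_inputs(samples) -> np.ndarray:
    return np.stack([s.image.pixels for s in samples]).astype(np.float32)[:, None]


def _stack_targets(samples, task: str) -> np.ndarray:
    roi = np.stack([getattr(s, task).pixels for s in samples]).astype(np.float32)
    return np.stack([1.0 - roi, roi], axis=1)  # (B, 2, H, W) one-hot


def _tasks_for_mode(mode: str, heads) -> tuple[str, ...]:
    if mode == "single_breast":
        return ("breast",)
    if mode == "single_dense":
        return ("dense",)
    return tuple(heads)


def _validate(model, val_samples, threshold: float) -> dict[str, float]:
    """Mean F-score and IoU per task on a held-out split (eval mode)."""
    scores: dict[str, list] = {h: [] for h in model.config.heads}
    xs = _stack_inputs(val_samples)
    model.eval()
    try:
        for i in range(0, len(val_samples), 16):
            out = model.forward_tensors(nn.Tensor(xs[i:i + 16]))
            for h in model.config.heads:
                probs = out[h].data[:, 1]
                preds = (probs >= threshold).astype(np.uint8)
                for j, s in enumerate(val_samples[i:i + 16]):
                    scores[h].append(seg_score(preds[j], getattr(s, h).pixels))
    finally:
        model.train(True)
    result = {}
    for h, ss in scores.items():
        result[f"val_f_{h}"] = float(np.mean([s.fscore for s in ss]))
        result[f"val_iou_{h}"] = float(np.mean([s.iou for s in ss]))
    return result


def train(model: MultiTaskSegNet, data, cfg: TrainConfig,
          val_data=None) -> tuple[MultiTaskSegNet, TrainReport]:
    """Train in place and return the model at its best validation epoch.

    `data` is a collection of :class:`AnnotatedSample` already resized to
    the model's input side (use :func:`preprocess_samples`).  If
    `val_data` is None a fraction of `data` is held out according to
    ``cfg.validation_fraction``.
    """
    data = list(data)
    if not data:
        raise ValueError("training data is empty")
    side = model.config.input_side
    for s in data:
        if s.image.shape != (side, side):
            raise ValueError(f"sample not resized to {side}x{side}: {s.image.shape}")

    tasks = _tasks_for_mode(cfg.loss_mode, model.config.heads)
    for t in tasks:
        if t not in model.config.heads:
            raise ValueError(f"model has no '{t}' head for loss_mode={cfg.loss_mode}")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))
    if val_data is None:
        order = rng.permutation(len(data))
        n_val = max(1, int(round(cfg.validation_fraction * len(data))))
        if n_val >= len(data):
            raise ValueError("validation split leaves no training data")
        val_samples = [data[i] for i in order[:n_val]]
        train_samples = [data[i] for i in order[n_val:]]
    else:
        val_samples = list(val_data)
        train_samples = data

    x_all = _stack_inputs(train_samples)
    y_all = {t: _stack_targets(train_samples, t) for t in tasks}

    params = model.parameters()
    adaptive = cfg.loss_mode == "adaptive"
    if adaptive:
        params = params + model.uncertainty.parameters()
    if cfg.optimizer.lower() == "adam":
        opt = nn.Adam(params, lr=cfg.learning_rate)
    elif cfg.optimizer.lower() == "sgd":
        opt = nn.SGD(params, lr=cfg.learning_rate)
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")

    select_task = "dense" if "dense" in tasks else "breast"
    rows = []
    best = (-1.0, -1, None, None)  # (score, epoch, state, (s_b, s_d))
    n_train = len(train_samples)
    model.train(True)

    for epoch in range(cfg.epochs):
        if cfg.lr_schedule == "cosine":
            opt.lr = cfg.learning_rate * 0.5 * (1 + np.cos(np.pi * epoch / cfg.epochs))
        perm = rng.permutation(n_train)
        task_losses = {t: [] for t in tasks}
        totals = []
        for start in range(0, n_train, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            out = model.forward_tensors(nn.Tensor(x_all[idx]))
            losses = {t: focal_tversky_loss(out[t], y_all[t][idx], cfg.tversky)
                      for t in tasks}
            for t in tasks:
                if not np.isfinite(float(losses[t].data)):
                    raise RuntimeError(
                        f"non-finite {t} loss at epoch {epoch}; aborting")
            if adaptive:
                total = adaptive_mtl_loss(losses["breast"], losses["dense"],
                                          model.uncertainty)
            elif cfg.loss_mode == "naive":
                total = naive_mtl_loss(losses["breast"], losses["dense"],
                                       NaiveWeights(cfg.naive_lambda))
            else:
                total = losses[tasks[0]]
            if not np.isfinite(float(total.data)):
                raise RuntimeError(f"non-finite loss at epoch {epoch}; aborting")
            opt.zero_grad()
            total.backward()
            opt.step()
            totals.append(float(total.data))
            for t in tasks:
                task_losses[t].append(float(losses[t].data))

        row = {"epoch": epoch, "loss_total": float(np.mean(totals))}
        for t in tasks:
            row[f"loss_{t}"] = float(np.mean(task_losses[t]))
        if adaptive:
            row["sigma_b"] = model.uncertainty.sigma_b
            row["sigma_d"] = model.uncertainty.sigma_d
        row.update(_validate(model, val_samples, cfg.threshold))
        rows.append(row)

        score = row[f"val_f_{select_task}"]
        if score > best[0]:
            best = (score, epoch, copy.deepcopy(model.state_dict()),
                    (model.uncertainty.sigma_b, model.uncertainty.sigma_d))

    if best[2] is not None:
        model.load_state_dict(best[2])
    report = TrainReport(frame=pd.DataFrame(rows), best_epoch=best[1], tasks=tasks)
    return model, report


def lambda_grid(data, cfg: TrainConfig, grid, net_config: NetworkConfig,
                val_data=None) -> pd.DataFrame:
    """Train one naive-weighted model per lambda under identical seeds.

    Returns a table sorted by lambda with mean validation F-score and IoU
    per task, per view and pooled across views.
    """
    grid = sorted(float(g) for g in grid)
    if any(not 0.0 < g < 1.0 for g in grid):
        raise ValueError("lambda grid values must lie strictly in (0, 1)")
    rows = []
    for lam in grid:
        model = build_model(net_config, seed=cfg.seed)
        run_cfg = replace(cfg, loss_mode="naive", naive_lambda=lam)
        model, report = train(model, data, run_cfg, val_data=val_data)
        eval_samples = list(val_data) if val_data is not None else list(data)
        table = evaluate_model(model, eval_samples, threshold=cfg.threshold)
        for _, r in table.iterrows():
            rows.append({"lam": lam, "tissue": r["tissue"], "view": r["view"],
                         "fscore": r["fscore_mean"], "iou": r["iou_mean"]})
    return pd.DataFrame(rows, columns=["lam", "tissue", "view", "fscore", "iou"])


def predict_masks(model: MultiTaskSegNet, img: Mammogram,
                  threshold: float = 0.5):
    """Predict breast and dense masks at the image's native resolution.

    The image must already be intensity-normalized.  Probabilities >=
    `threshold` for the ROI class become foreground (ties go to
    foreground), then masks are restored to ``original_size`` by nearest
    neighbor.  Heads absent from the model yield None.
    """
    for p in model.parameters():
        if not np.all(np.isfinite(p.data)):
            raise ValueError("model has non-finite weights; cannot predict")
    side = model.config.input_side
    resized = resize_for_model(img, side)
    xs = resized.pixels.astype(np.float32)[None, None]
    model.eval()
    try:
        out = model.forward_tensors(nn.Tensor(xs))
    finally:
        model.train(True)
    size = img.original_size or img.shape
    results = {}
    for head in ("breast", "dense"):
        if head in out:
            roi = out[head].data[0, 1]
            mask = BinaryMask((roi >= threshold).astype(np.uint8), role=head,
                              original_size=size)
            results[head] = restore_to_original(mask, size)
        else:
            results[head] = None
    return results["breast"], results["dense"]


def evaluate_model(model: MultiTaskSegNet, samples,
                   threshold: float = 0.5) -> pd.DataFrame:
    """Per-view mean +- SD segmentation table for a trained model."""
    from .seg_metrics import evaluate_dataset

    pairs, views, tissues = [], [], []
    for s in samples:
        breast_pred, dense_pred = predict_masks(model, s.image, threshold)
        for head, pred in (("breast", breast_pred), ("dense", dense_pred)):
            if pred is None:
                continue
            pairs.append((pred, getattr(s, head)))
            views.append(s.image.view)
            tissues.append(head)
    return evaluate_dataset(pairs, views=views, tissues=tissues)


def predict_pd(model: MultiTaskSegNet, samples, threshold: float = 0.5):
    """Estimated percent density per sample (requires both heads)."""
    values = []
    for s in samples:
        breast_pred, dense_pred = predict_masks(model, s.image, threshold)
        if breast_pred is None or dense_pred is None:
            raise ValueError("percent density needs both breast and dense heads")
        if breast_pred.area() == 0:
            values.append(0.0)  # degenerate prediction: no breast found
        else:
            values.append(percent_density(breast_pred, dense_pred))
    return np.asarray(values)
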