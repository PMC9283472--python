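"""Pixel-overlap segmentation metrics and per-view aggregation.

Per mask pair: precision = |pred ∩ truth| / |pred|, recall =
|pred ∩ truth| / |truth|, F-score = 2PR/(P+R), IoU = |∩|/|∪|.  Tables
aggregate image-wise (macro) means with sample (n-1) standard deviations,
grouped by tissue and view plus a pooled CC-MLO row.

Empty-mask conventions: both masks empty -> all metrics 1 (perfect
agreement); exactly one empty -> 0; F with P = R = 0 -> 0.  This keeps the
metrics defined everywhere without NaNs leaking into dataset means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging_io import BinaryMask

__all__ = ["SegScore", "seg_score", "evaluate_dataset"]


@dataclass(frozen=True)
class SegScore:
    precision: float
    recall: float
    fscore: float
    iou: float
    n: int = 1
    sd: float | None = None


def _as_binary(mask) -> np.ndarray:
    arr = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask)
    if not np.all(np.isin(np.unique(arr), (0, 1))):
        raise ValueError("masks must be binary {0,1}")
    return arr.astype(bool)


def seg_score(pred, target) -> SegScore:
    """Overlap metrics for one predicted/ground-truth mask pair."""
    p = _as_binary(pred)
    t = _as_binary(target)
    if p.shape != t.shape:
        raise ValueError(f"dimension mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    np_, nt = int(p.sum()), int(t.sum())
    union = np_ + nt - tp
    if np_ == 0 and nt == 0:
        return SegScore(1.0, 1.0, 1.0, 1.0)
    precision = tp / np_ if np_ else 0.0
    recall = tp / nt if nt else 0.0
    fscore = (2 * precision * recall / (precision + recall)
              if (precision + recall) > 0 else 0.0)
    iou = tp / union if union else 0.0
    return SegScore(precision, recall, fscore, iou)


_METRICS = ("precision", "recall", "fscore", "iou")


def evaluate_dataset(pairs, views=None, tissues=None,
                     pooled_label: str = "CC-MLO") -> pd.DataFrame:
    """Mean +- SD metrics per (tissue, view) group plus pooled views.

    `pairs` is a sequence of (pred, target) mask pairs; `views` and
    `tissues` are matching label sequences (defaults: all "unknown" /
    "all").  Returns one row per tissue x (view union pooled) with
    image-wise means and sample standard deviations.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("cannot evaluate an empty collection")
    n = len(pairs)
    views = list(views) if views is not None else ["unknown"] * n
    tissues = list(tissues) if tissues is not None else ["all"] * n
    if len(views) != n or len(tissues) != n:
        raise ValueError("views/tissues labels must match the number of pairs")

    scores = [seg_score(p, t) for p, t in pairs]
    df = pd.DataFrame({
        "tissue": tissues,
        "view": views,
        **{m: [getattr(s, m) for s in scores] for m in _METRICS},
    })

    rows = []
    for tissue in sorted(df["tissue"].unique()):
        sub_t = df[df["tissue"] == tissue]
        groups = [(v, sub_t[sub_t["view"] == v]) for v in sorted(sub_t["view"].unique())]
        if len(groups) > 1:
            groups.append((pooled_label, sub_t))
        for view, sub in groups:
            row = {"tissue": tissue, "view": view, "n": len(sub)}
            for m in _METRICS:
                row[f"{m}_mean"] = float(sub[m].mean())
                row[f"{m}_sd"] = float(sub[m].std(ddof=1)) if len(sub) > 1 else 0.0
            rows.append(row)
    return pd.DataFrame(rows)
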