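"""Agreement statistics between percent-density series.

Pearson's r with a Fisher-z 95% confidence interval (standard error
1/sqrt(n-3)), Bland-Altman bias and limits of agreement (bias +- 1.96 x
sample SD of the differences), mean-difference summary tables, clinically
acceptable difference (CDI) acceptance rates, and BI-RADS category
accuracy.  Density values are optionally log-transformed (log(pd + 0.01),
the offset admitting PD = 0) before correlation/agreement, mirroring how
skewed density distributions are usually analyzed; CDI acceptance is
always counted on the raw percentage scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .density import birads_category

__all__ = [
    "CorrelationResult",
    "BlandAltmanResult",
    "pearson_ci",
    "bland_altman",
    "bland_altman_plot",
    "mean_difference_table",
    "birads_accuracy",
]

LOG_OFFSET = 0.01  # percentage points added before log transform


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    transform: str = "none"


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    within_loa_fraction: float
    within_cdi_fraction: float
    n: int
    transform: str = "none"


def _prepare(a, b, transform: str):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and equally long")
    if transform == "log":
        return np.log(a + LOG_OFFSET), np.log(b + LOG_OFFSET)
    if transform == "none":
        return a, b
    raise ValueError(f"unknown transform {transform!r}")


def pearson_ci(a, b, level: float = 0.95, transform: str = "none") -> CorrelationResult:
    """Pearson correlation with a Fisher-z confidence interval.

    With ``transform='log'`` both series are log-transformed first (PD
    values are right-skewed).  Requires n >= 3 and non-constant series.
    """
    ta, tb = _prepare(a, b, transform)
    n = ta.size
    if n < 3:
        raise ValueError("need at least 3 pairs for a confidence interval")
    if np.std(ta) == 0 or np.std(tb) == 0:
        raise ValueError("zero variance in a series; correlation undefined")
    res = stats.pearsonr(ta, tb)
    r = float(res.statistic)
    if abs(r) >= 1.0:
        lo = hi = r
    else:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        zcrit = stats.norm.ppf(0.5 + level / 2.0)
        lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    return CorrelationResult(r, float(lo), float(hi), float(res.pvalue), n, transform)


def bland_altman(a, b, transform: str = "none", cdi: float = 5.0) -> BlandAltmanResult:
    """Bland-Altman agreement of series `a` against series `b`.

    Differences are a - b on the (optionally transformed) scale; bias is
    their mean and the limits of agreement are bias +- 1.96 x sample SD.
    ``within_cdi_fraction`` counts |a - b| <= cdi on the *raw* scale
    regardless of the transform.
    """
    raw_a = np.asarray(a, dtype=np.float64)
    raw_b = np.asarray(b, dtype=np.float64)
    ta, tb = _prepare(a, b, transform)
    if ta.size < 2:
        raise ValueError("need at least 2 pairs")
    diffs = ta - tb
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    within_loa = float(np.mean((diffs >= lo) & (diffs <= hi)))
    within_cdi = float(np.mean(np.abs(raw_a - raw_b) <= cdi))
    return BlandAltmanResult(bias, sd, float(lo), float(hi),
                             within_loa, within_cdi, ta.size, transform)


def bland_altman_plot(a, b, out_path, transform: str = "none",
                      label_a: str = "method", label_b: str = "reference"):
    """Scatter of per-sample mean vs difference with bias and LoA lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ta, tb = _prepare(a, b, transform)
    res = bland_altman(a, b, transform=transform)
    means = (ta + tb) / 2.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, ta - tb, s=12, alpha=0.7)
    ax.axhline(res.bias, color="C0", ls=":", label=f"bias {res.bias:.3f}")
    for loa in (res.loa_low, res.loa_high):
        ax.axhline(loa, color="C3", ls=":")
    scale = "log PD" if transform == "log" else "PD (%)"
    ax.set_xlabel(f"mean of {label_a} and {label_b} [{scale}]")
    ax.set_ylabel(f"{label_a} − {label_b} [{scale}]")
    ax.legend(loc="upper right", frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return res


def mean_difference_table(methods: dict, reference) -> pd.DataFrame:
    """Per-method mean +- SD PD and signed mean difference vs the reference.

    A negative mean difference indicates the method underestimates density
    relative to the reference series.
    """
    ref = np.asarray(reference, dtype=np.float64)
    rows = [{
        "method": "reference",
        "mean": float(ref.mean()),
        "sd": float(ref.std(ddof=1)) if ref.size > 1 else 0.0,
        "mean_diff": 0.0,
    }]
    for name, series in methods.items():
        arr = np.asarray(series, dtype=np.float64)
        if arr.shape != ref.shape:
            raise ValueError(f"series {name!r} is not aligned with the reference")
        rows.append({
            "method": name,
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "mean_diff": float(arr.mean() - ref.mean()),
        })
    return pd.DataFrame(rows, columns=["method", "mean", "sd", "mean_diff"])


def birads_accuracy(pred_pd, true_categories) -> float:
    """Fraction of samples assigned to the correct BI-RADS density quartile."""
    pred = np.asarray(pred_pd, dtype=np.float64)
    truth = np.asarray(true_categories)
    if pred.shape != truth.shape:
        raise ValueError("series must be aligned")
    if not np.all(np.isin(truth, (1, 2, 3, 4))):
        raise ValueError("true categories must be in {1, 2, 3, 4}")
    pred_cat = np.array([birads_category(p) for p in pred])
    return float(np.mean(pred_cat == truth.astype(int)))
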