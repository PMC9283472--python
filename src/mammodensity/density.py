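"""Area-based percent density, the Otsu conventional baseline, BI-RADS
categories, and reference-PD construction from two readers.

Percent density is the white-pixel ratio of the two binary masks:

    PD = 100 * sum(dense) / sum(breast)

The conventional baseline segments dense tissue *within the breast area*
by (1) zeroing the background with the breast mask, (2) 5x5 Gaussian
blurring, (3) Otsu thresholding the 8-bit histogram of breast-interior
pixels, then applying the PD formula.  Zeroed background pixels are
excluded from the histogram — including them would swamp the lower class
(see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging_io import BinaryMask, Mammogram, apply_breast_mask

__all__ = [
    "DensityRecord",
    "ReferencePD",
    "percent_density",
    "otsu_threshold",
    "otsu_pd",
    "birads_category",
    "build_reference_pd",
]

PD_METHODS = ("model", "otsu", "readerA", "readerB", "reference",
              "libra", "quantra", "truth")


@dataclass(frozen=True)
class DensityRecord:
    """One per-image PD value with its provenance."""

    sample_id: str
    view: str
    pd: float
    method: str

    def __post_init__(self):
        if not 0.0 <= self.pd <= 100.0:
            raise ValueError(f"PD must lie in [0, 100], got {self.pd}")
        if self.method not in PD_METHODS:
            raise ValueError(f"unknown PD method {self.method!r}")


@dataclass(frozen=True)
class ReferencePD:
    """Two readers' PD values and their consensus where clinically close."""

    sample_id: str
    pd_a: float
    pd_b: float
    within_cdi: bool
    reference: float | None


def percent_density(breast: BinaryMask | np.ndarray,
                    dense: BinaryMask | np.ndarray) -> float:
    """PD = 100 * |dense| / |breast| from the raw pixel counts.

    The masks are not intersected first; if the dense mask leaks outside
    the breast a warning is raised and the result is clipped to 100 so the
    [0, 100] invariant holds.  An empty breast mask is an error (density
    is undefined).
    """
    b = breast.pixels if isinstance(breast, BinaryMask) else np.asarray(breast)
    d = dense.pixels if isinstance(dense, BinaryMask) else np.asarray(dense)
    if b.shape != d.shape:
        raise ValueError(f"mask dimension mismatch: {b.shape} vs {d.shape}")
    nb = int(b.sum())
    if nb == 0:
        raise ValueError("breast mask is empty; percent density undefined")
    if np.any(d > b):
        warnings.warn("dense mask extends outside the breast mask; "
                      "PD clipped to [0, 100]", stacklevel=2)
    return float(min(100.0, 100.0 * d.sum() / nb))


def otsu_threshold(values: np.ndarray) -> int:
    """Otsu's threshold over the full 256-bin 8-bit histogram.

    Returns the gray level t in [0, 255] maximizing the between-class
    variance of the split (<= t) vs (> t); the lowest maximizing level is
    returned on ties.  `values` must already be 8-bit (uint8 or integers
    in 0..255) and contain at least two distinct levels.
    """
    vals = np.asarray(values).ravel()
    if vals.size == 0:
        raise ValueError("no pixels to threshold")
    vals = vals.astype(np.int64)
    if vals.min() < 0 or vals.max() > 255:
        raise ValueError("values must be 8-bit (0..255)")
    hist = np.bincount(vals, minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("constant image: Otsu threshold undefined")
    p = hist / hist.sum()
    omega = np.cumsum(p)                      # class-0 mass for t = 0..255
    mu = np.cumsum(p * np.arange(256))        # class-0 first moment
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return int(np.argmax(sigma_b))


# 5x5 Gaussian kernel; sigma follows the common kernel-size rule
# 0.3 * ((k - 1) / 2 - 1) + 0.8 = 1.1 for k = 5
_GAUSS_K = 5
_GAUSS_SIGMA = 0.3 * ((_GAUSS_K - 1) * 0.5 - 1.0) + 0.8


def _gauss_kernel5() -> np.ndarray:
    x = np.arange(_GAUSS_K) - (_GAUSS_K - 1) / 2.0
    g = np.exp(-0.5 * (x / _GAUSS_SIGMA) ** 2)
    g /= g.sum()
    return np.outer(g, g)


def otsu_pd(img: Mammogram, breast: BinaryMask) -> float:
    """Conventional PD estimate by Otsu thresholding within the breast.

    Degenerate case: if the breast interior is constant after blurring
    and 8-bit quantization, no threshold exists and PD 0 is returned with
    a warning.
    """
    masked = apply_breast_mask(img, breast)
    blurred = ndimage.convolve(masked.pixels, _gauss_kernel5(), mode="nearest")
    quant = np.clip(np.round(blurred * 255), 0, 255).astype(np.uint8)
    inside = breast.pixels.astype(bool)
    if inside.sum() == 0:
        raise ValueError("breast mask is empty")
    vals = quant[inside]
    if np.unique(vals).size < 2:
        warnings.warn("constant breast region; Otsu PD defaults to 0", stacklevel=2)
        return 0.0
    level = otsu_threshold(vals)
    dense = (quant > level) & inside
    return percent_density(breast.pixels, dense.astype(np.uint8))


def birads_category(pd: float) -> int:
    """Four 25-percentage-point density categories (upper bound inclusive)."""
    if not 0.0 <= pd <= 100.0:
        raise ValueError(f"PD must lie in [0, 100], got {pd}")
    if pd <= 25.0:
        return 1
    if pd <= 50.0:
        return 2
    if pd <= 75.0:
        return 3
    return 4


def build_reference_pd(a, b, cdi: float = 5.0) -> list[ReferencePD]:
    """Combine two readers' PD series into reference values.

    `a` and `b` are sequences of :class:`DensityRecord` covering the same
    sample ids.  Pairs whose absolute difference is within the clinically
    acceptable difference (CDI, default +-5 PD points) are averaged into a
    reference; others are retained flagged ``within_cdi=False`` with no
    reference value.
    """
    map_a = {r.sample_id: r for r in a}
    map_b = {r.sample_id: r for r in b}
    if set(map_a) != set(map_b):
        missing = set(map_a) ^ set(map_b)
        raise ValueError(f"reader series do not cover the same samples: {sorted(missing)}")
    out = []
    for sid in map_a:
        pa, pb = map_a[sid].pd, map_b[sid].pd
        within = abs(pa - pb) <= cdi
        out.append(ReferencePD(sid, pa, pb, within,
                               (pa + pb) / 2.0 if within else None))
    return out


def records_to_frame(records) -> pd.DataFrame:
    """Density records as the CSV layout `sample_id,view,method,pd`."""
    return pd.DataFrame(
        [{"sample_id": r.sample_id, "view": r.view, "method": r.method, "pd": r.pd}
         for r in records],
        columns=["sample_id", "view", "method", "pd"],
    )
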