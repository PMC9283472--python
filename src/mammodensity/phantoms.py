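"""Synthetic mammogram-like phantoms with exact ground truth.

Each phantom is a half-elliptical "breast" against the left image edge on a
dark background, containing irregular bright "dense tissue" blobs built by
thresholding a sum of anisotropic Gaussian bumps.  MLO-style phantoms add a
bright triangular pectoral-muscle wedge in the top-left corner that is
*excluded* from the breast mask — the classic confounder when delineating
the breast area, since its intensity matches dense tissue.  Intensities are
softly blurred (tissue borders are not knife-edges) and corrupted with
additive Gaussian noise *after* the masks are fixed, so the ground truth
stays exact.

The dense-blob threshold is chosen as the quantile of the bump field inside
the breast that matches the requested percent density (PD), so realized PD
tracks the target closely; if blob coverage cannot reach the target the
blob set is re-drawn with more/larger blobs a bounded number of times.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging_io import AnnotatedSample, BinaryMask, Mammogram, save_image, save_mask

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset"]

MANIFEST_COLUMNS = ["id", "view", "true_pd", "image_path",
                    "breast_mask_path", "dense_mask_path"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom.

    ``intensity_levels`` orders the tissue brightness (background < fat <
    dense); the pectoral wedge is the brightest structure by default.
    ``pectoral_fraction`` is the image-area fraction of the wedge (MLO
    only).  ``blob_scale`` defaults to 0.16 * min(height, width) pixels.
    """

    height: int = 256
    width: int = 256
    view_style: str = "CC"
    breast_center_frac: float = 0.5        # vertical ellipse center / height
    breast_axes_frac: tuple[float, float] = (0.44, 0.78)  # (vertical, horizontal)
    pectoral_fraction: float = 0.15
    target_pd: float = 25.0
    n_dense_blobs: int = 6
    blob_scale: float | None = None
    intensity_levels: tuple[float, float, float, float] = (0.05, 0.35, 0.75, 0.9)
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.target_pd <= 100.0:
            raise ValueError("target_pd must lie in [0, 100]")
        bg, fat, dense, _ = self.intensity_levels
        if not bg < fat < dense:
            raise ValueError("intensity levels must satisfy background < fat < dense")
        if not 0.0 <= self.pectoral_fraction <= 0.4:
            raise ValueError("pectoral_fraction must lie in [0, 0.4]")
        if self.height < 32 or self.width < 32:
            raise ValueError("phantom images must be at least 32x32")
        if self.view_style not in ("CC", "MLO"):
            raise ValueError("view_style must be 'CC' or 'MLO'")
        if self.n_dense_blobs < 0:
            raise ValueError("n_dense_blobs must be non-negative")


PD_TOLERANCE = 2.0   # max |realized - target| PD, percentage points
MAX_RETRIES = 100


def _breast_mask(spec: PhantomSpec, rng: np.random.Generator):
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy = h * (spec.breast_center_frac + rng.uniform(-0.03, 0.03))
    ay = h * spec.breast_axes_frac[0] * rng.uniform(0.9, 1.1)
    ax = w * spec.breast_axes_frac[1] * rng.uniform(0.9, 1.1)
    breast = ((yy - cy) / ay) ** 2 + (xx / ax) ** 2 <= 1.0

    pectoral = np.zeros_like(breast)
    if spec.view_style == "MLO" and spec.pectoral_fraction > 0:
        x0 = w * rng.uniform(0.35, 0.55)
        y0 = 2.0 * spec.pectoral_fraction * h * w / x0
        y0 = min(y0, 0.95 * h)
        x0 = 2.0 * spec.pectoral_fraction * h * w / y0
        pectoral = (xx / x0 + yy / y0) < 1.0
        breast &= ~pectoral
    return breast, pectoral


def _bump_field(spec: PhantomSpec, breast: np.ndarray, n_blobs: int,
                scale: float, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    # candidate centers: interior of the breast, away from its boundary
    dist = ndimage.distance_transform_edt(breast)
    margin = max(2.0, 0.05 * min(h, w))
    cand = np.argwhere(dist > margin)
    if cand.size == 0:
        cand = np.argwhere(breast)
    field = np.zeros((h, w))
    for _ in range(n_blobs):
        cy, cx = cand[rng.integers(len(cand))]
        sy = scale * rng.uniform(0.5, 1.3)
        sx = scale * rng.uniform(0.5, 1.3)
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        field += np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))
    return field


def _dense_mask(spec: PhantomSpec, breast: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    n_breast = int(breast.sum())
    if spec.target_pd == 0.0 or spec.n_dense_blobs == 0:
        realized = 0.0
        if abs(realized - spec.target_pd) > PD_TOLERANCE:
            raise ValueError(
                f"target_pd={spec.target_pd} unreachable with "
                f"n_dense_blobs={spec.n_dense_blobs} ({spec!r})")
        return np.zeros_like(breast)

    n_blobs = spec.n_dense_blobs
    scale = spec.blob_scale or 0.16 * min(spec.height, spec.width)
    for _ in range(MAX_RETRIES):
        field = _bump_field(spec, breast, n_blobs, scale, rng)
        vals = field[breast]
        thr = np.quantile(vals, 1.0 - spec.target_pd / 100.0)
        dense = breast & (field > thr)
        realized = 100.0 * dense.sum() / n_breast
        if abs(realized - spec.target_pd) <= PD_TOLERANCE:
            return dense
        # flat regions of the field swallowed the quantile: densify blobs
        n_blobs += 2
        scale *= 1.15
    raise ValueError(
        f"could not realize target_pd={spec.target_pd} within "
        f"+-{PD_TOLERANCE} points after {MAX_RETRIES} retries ({spec!r})")


def generate_phantom(spec: PhantomSpec) -> tuple[AnnotatedSample, float]:
    """Generate one phantom; returns the sample and its exact PD.

    Deterministic for a given spec (the seed lives in the spec): the same
    spec yields bit-identical pixels and masks.
    """
    rng = np.random.default_rng(spec.seed)
    breast, pectoral = _breast_mask(spec, rng)
    dense = _dense_mask(spec, breast, rng)
    true_pd = 100.0 * float(dense.sum()) / float(breast.sum())

    bg, fat, dense_i, pect_i = spec.intensity_levels
    img = np.full(breast.shape, bg)
    img[breast] = fat
    img[dense] = dense_i
    img[pectoral] = pect_i
    img = ndimage.gaussian_filter(img, sigma=1.0)   # soften tissue borders
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    sample = AnnotatedSample(
        image=Mammogram(img, view=spec.view_style),
        breast=BinaryMask(breast.astype(np.uint8), role="breast"),
        dense=BinaryMask(dense.astype(np.uint8), role="dense"),
        true_pd=true_pd,
    )
    return sample, true_pd


def generate_dataset(
    n: int,
    spec_ranges: dict | None = None,
    seed: int = 0,
    out_dir=None,
    base_spec: PhantomSpec = PhantomSpec(),
) -> tuple[list[AnnotatedSample], pd.DataFrame]:
    """Generate `n` phantoms with per-sample randomized view and target PD.

    `spec_ranges` may override ``pd_range`` (uniform target-PD interval,
    default (5, 45)), ``view_mix`` (probability of MLO, default 0.5), and
    ``size`` (height, width).  If `out_dir` is given, images and masks are
    written as PNG and the manifest as ``manifest.csv``; paths are recorded
    relative to `out_dir`.  Fully reproducible from `seed`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = dict(spec_ranges or {})
    pd_lo, pd_hi = ranges.get("pd_range", (5.0, 45.0))
    view_mix = float(ranges.get("view_mix", 0.5))
    size = ranges.get("size", (base_spec.height, base_spec.width))

    rng = np.random.default_rng(seed)
    samples: list[AnnotatedSample] = []
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "images").mkdir(exist_ok=True)
        (out_dir / "masks").mkdir(exist_ok=True)

    for i in range(n):
        target = float(rng.uniform(pd_lo, pd_hi))
        view = "MLO" if rng.random() < view_mix else "CC"
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        spec = replace(base_spec, height=size[0], width=size[1],
                       target_pd=round(target, 3), view_style=view, seed=sub_seed)
        sample, true_pd = generate_phantom(spec)
        sid = f"phantom_{i:04d}"
        sample.sample_id = sid
        samples.append(sample)

        img_path = breast_path = dense_path = ""
        if out_dir is not None:
            img_path = f"images/{sid}.png"
            breast_path = f"masks/{sid}_breast.png"
            dense_path = f"masks/{sid}_dense.png"
            save_image(sample.image, out_dir / img_path)
            save_mask(sample.breast, out_dir / breast_path)
            save_mask(sample.dense, out_dir / dense_path)
        rows.append({"id": sid, "view": view, "true_pd": true_pd,
                     "image_path": img_path, "breast_mask_path": breast_path,
                     "dense_mask_path": dense_path})

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return samples, manifest
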