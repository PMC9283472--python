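"""Image and mask I/O plus the preprocessing chain used by the model.

Conventions
-----------
* Pixels are row-major float arrays with origin at the top-left.
* Mammogram intensities live in [0, 1]; integer files are scaled by the
  full range of their dtype on load (255 for 8-bit, 65535 for 16-bit).
* Masks are strictly binary: {0, 1} in memory, {0, 255} on disk, with a
  threshold at 128 when loading.
* Model-facing resizing is anisotropic straight to ``side x side``
  (bicubic for images, nearest-neighbor for masks); see docs/methods.md
  for why no aspect-preserving padding is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

__all__ = [
    "Mammogram",
    "BinaryMask",
    "AnnotatedSample",
    "load_image",
    "load_mask",
    "save_image",
    "save_mask",
    "apply_breast_mask",
    "normalize_intensity",
    "resize_for_model",
    "restore_to_original",
]

VIEWS = ("CC", "MLO", "unknown")


@dataclass
class Mammogram:
    """A grayscale mammogram with its acquisition view and native size."""

    pixels: np.ndarray
    view: str = "unknown"
    original_size: tuple[int, int] | None = None
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("mammogram pixels must be a 2-D grayscale grid")
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")
        if self.original_size is None:
            self.original_size = self.pixels.shape

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """A {0,1} mask for either the breast area or the dense tissue."""

    pixels: np.ndarray
    role: str = "breast"
    original_size: tuple[int, int] | None = None

    def __post_init__(self):
        arr = np.asarray(self.pixels)
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be strictly {0, 1}")
        self.pixels = arr.astype(np.uint8)
        if self.role not in ("breast", "dense"):
            raise ValueError("mask role must be 'breast' or 'dense'")
        if self.original_size is None:
            self.original_size = self.pixels.shape

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def area(self) -> int:
        return int(self.pixels.sum())


@dataclass
class AnnotatedSample:
    """One mammogram with its breast-area and dense-tissue ground truth."""

    image: Mammogram
    breast: BinaryMask
    dense: BinaryMask
    true_pd: float | None = None
    sample_id: str = ""

    def __post_init__(self):
        shapes = {self.image.shape, self.breast.shape, self.dense.shape}
        if len(shapes) != 1:
            raise ValueError(f"image and masks must share dimensions, got {shapes}")
        if np.any(self.dense.pixels > self.breast.pixels):
            warnings.warn(
                "dense mask has foreground outside the breast mask",
                stacklevel=2,
            )


# -- loading / saving ------------------------------------------------------

def load_image(path, view: str = "unknown") -> Mammogram:
    """Load a grayscale PNG/TIFF/DICOM image, scaled to [0, 1].

    Color images are rejected; DICOM rescale slope/intercept is applied
    before scaling by the stored bit depth.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        bits = int(getattr(ds, "BitsStored", 16))
        arr = arr / max(1.0, 2.0 ** bits - 1.0)
    else:
        with Image.open(path) as im:
            if im.mode in ("RGB", "RGBA", "P"):
                raise ValueError(f"{path} is not a grayscale image (mode {im.mode})")
            arr = np.asarray(im)
        if arr.ndim != 2:
            raise ValueError(f"{path} decoded to a non-2D array")
        if arr.dtype == np.uint8:
            arr = arr / 255.0
        elif arr.dtype in (np.uint16, np.int32):
            arr = arr / 65535.0
        else:
            arr = arr.astype(np.float64)
    return Mammogram(arr, view=view, original_size=arr.shape, source_id=path.stem)


def save_image(img: Mammogram | np.ndarray, path, bit_depth: int = 8) -> Path:
    """Write intensities in [0,1] as an 8- or 16-bit grayscale PNG/TIFF."""
    arr = img.pixels if isinstance(img, Mammogram) else np.asarray(img)
    arr = np.clip(arr, 0.0, 1.0)
    path = Path(path)
    if bit_depth == 8:
        out = np.round(arr * 255).astype(np.uint8)
        Image.fromarray(out, mode="L").save(path)
    elif bit_depth == 16:
        out = np.round(arr * 65535).astype(np.uint16)
        Image.fromarray(out, mode="I;16").save(path)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    return path


def load_mask(path, role: str = "breast") -> BinaryMask:
    """Load a {0,255} PNG mask; values >= 128 become foreground."""
    with Image.open(Path(path)) as im:
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a single-channel mask")
    return BinaryMask((arr >= 128).astype(np.uint8), role=role,
                      original_size=arr.shape)


def save_mask(mask: BinaryMask | np.ndarray, path) -> Path:
    arr = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask)
    path = Path(path)
    Image.fromarray((arr.astype(np.uint8) * 255), mode="L").save(path)
    return path


# -- preprocessing ---------------------------------------------------------

def apply_breast_mask(img: Mammogram, breast: BinaryMask) -> Mammogram:
    """Zero every pixel outside the breast area; idempotent."""
    if img.shape != breast.shape:
        raise ValueError(f"dimension mismatch: image {img.shape} vs mask {breast.shape}")
    return Mammogram(img.pixels * breast.pixels, view=img.view,
                     original_size=img.original_size, source_id=img.source_id)


def normalize_intensity(img: Mammogram, region: BinaryMask | None = None) -> Mammogram:
    """Min-max normalize to [0, 1], optionally over a region of interest only.

    A constant region (max == min) yields an all-zero image with a warning
    rather than an error, so degenerate inputs cannot crash a batch run.
    """
    px = img.pixels
    if region is not None:
        if region.shape != px.shape:
            raise ValueError("region mask dimensions do not match image")
        vals = px[region.pixels.astype(bool)]
    else:
        vals = px.ravel()
    if vals.size == 0:
        raise ValueError("normalization region is empty")
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        warnings.warn("constant intensity region; returning all zeros", stacklevel=2)
        out = np.zeros_like(px)
    else:
        out = (px - lo) / (hi - lo)
    return Mammogram(out, view=img.view, original_size=img.original_size,
                     source_id=img.source_id)


def _nearest_indices(n_out: int, n_in: int) -> np.ndarray:
    """Center-aligned nearest-neighbor source rows/columns for a resize."""
    centers = (np.arange(n_out) + 0.5) * (n_in / n_out)
    idx = np.floor(centers).astype(int)
    return np.clip(idx, 0, n_in - 1)


def _resize_mask_array(arr: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    rows = _nearest_indices(out_shape[0], arr.shape[0])
    cols = _nearest_indices(out_shape[1], arr.shape[1])
    return arr[np.ix_(rows, cols)]


def resize_for_model(item: Mammogram | BinaryMask, side: int = 256):
    """Resize to the square model input: bicubic for images, nearest for masks.

    The native size is preserved in ``original_size`` so predictions can be
    restored afterwards.
    """
    if side < 32:
        raise ValueError("model input side must be at least 32 pixels")
    if isinstance(item, Mammogram):
        if item.shape == (side, side):
            out = item.pixels.copy()
        else:
            out = _sk_resize(item.pixels, (side, side), order=3,
                             anti_aliasing=False, preserve_range=True)
            out = np.clip(out, 0.0, 1.0)  # bicubic overshoot
        return Mammogram(out, view=item.view, original_size=item.original_size,
                         source_id=item.source_id)
    if isinstance(item, BinaryMask):
        out = _resize_mask_array(item.pixels, (side, side))
        return BinaryMask(out, role=item.role, original_size=item.original_size)
    raise TypeError(f"cannot resize object of type {type(item)!r}")


def restore_to_original(item, original_size: tuple[int, int] | None = None,
                        threshold: float | None = None):
    """Resize a predicted mask or probability map back to native resolution.

    Masks use nearest-neighbor; float probability maps use bilinear
    interpolation and are optionally re-thresholded (``>= threshold`` is
    foreground).
    """
    if isinstance(item, BinaryMask):
        size = original_size or item.original_size
        if size is None:
            raise ValueError("original_size is required to restore a mask")
        out = _resize_mask_array(item.pixels, tuple(size))
        return BinaryMask(out, role=item.role, original_size=tuple(size))
    arr = np.asarray(item, dtype=np.float64)
    if original_size is None:
        raise ValueError("original_size is required to restore a probability map")
    out = _sk_resize(arr, tuple(original_size), order=1,
                     anti_aliasing=False, preserve_range=True)
    if threshold is not None:
        return (out >= threshold).astype(np.uint8)
    return out
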