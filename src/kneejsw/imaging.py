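"""Radiograph and label-mask containers, file I/O, and preprocessing.

Radiographs arrive as 16-bit DICOM or 8/16-bit PNG.  Preprocessing follows
standard practice for knee films: clip the intensity histogram between the
5th and 99th percentiles, affinely map the clipped range to [0, 1] (global
contrast normalization), and downscale to a square working resolution
(1024x1024 by default).  Label masks are single-channel 8-bit PNG rasters
with literal class values 0=background, 1=femur, 2=tibia, 3=fibula, and are
resized nearest-neighbour so the label set is preserved.

Pixel spacing is carried per axis as (row_mm, col_mm) because a non-square
resize makes the two differ; vertical joint-space widths use row_mm and
Euclidean distances use both.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

from .errors import FormatError

__all__ = [
    "Radiograph",
    "LabelMask",
    "load_radiograph",
    "load_mask",
    "save_mask",
    "save_radiograph_png",
    "normalize_intensity",
    "resize_square",
    "resize_mask_square",
    "hflip_radiograph",
    "hflip_mask",
]

VALID_CLASSES = (0, 1, 2, 3)
_OPPOSITE = {"left": "right", "right": "left", "bilateral": "bilateral",
             "unknown": "unknown"}


def _spacing_tuple(mm_per_pixel) -> tuple[float, float] | None:
    if mm_per_pixel is None:
        return None
    if np.isscalar(mm_per_pixel):
        mm = float(mm_per_pixel)
        if mm <= 0:
            raise ValueError("mm_per_pixel must be positive")
        return (mm, mm)
    row_mm, col_mm = (float(v) for v in mm_per_pixel)
    if row_mm <= 0 or col_mm <= 0:
        raise ValueError("mm_per_pixel entries must be positive")
    return (row_mm, col_mm)


@dataclass
class Radiograph:
    """A 2-D knee radiograph.

    ``pixels`` is a float array; after :func:`normalize_intensity` all values
    lie in [0, 1].  ``mm_per_pixel`` is (row_mm, col_mm) or None when the
    film carries no calibration.
    """

    pixels: np.ndarray
    original_bit_depth: int = 16
    mm_per_pixel: tuple[float, float] | None = None
    laterality: str = "unknown"
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"radiograph must be 2-D, got shape {self.pixels.shape}")
        self.mm_per_pixel = _spacing_tuple(self.mm_per_pixel)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelMask:
    """Per-pixel bone classes: 0 background, 1 femur, 2 tibia, 3 fibula."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.labels.shape}")
        bad = np.setdiff1d(np.unique(self.labels), VALID_CLASSES)
        if bad.size:
            raise ValueError(f"mask contains invalid class values {bad.tolist()}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def _load_png(path: Path) -> tuple[np.ndarray, int]:
    with Image.open(path) as im:
        if im.mode in ("I;16", "I;16B", "I"):
            depth = 16 if "16" in im.mode else 32
            arr = np.asarray(im, dtype=np.float64)
        elif im.mode == "L":
            depth = 8
            arr = np.asarray(im, dtype=np.float64)
        else:
            im2 = im.convert("L")
            depth = 8
            arr = np.asarray(im2, dtype=np.float64)
    return arr, depth


def load_radiograph(path) -> Radiograph:
    """Read a DICOM (Part 10) or PNG radiograph.

    Pixel spacing is taken from the DICOM PixelSpacing / ImagerPixelSpacing
    attribute ((row, col) mm) when present; PNG files carry no calibration.
    No intensity normalization is applied here.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom", ""):
        try:
            import pydicom
            ds = pydicom.dcmread(path)
            frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
            if frames > 1:
                raise FormatError(f"multiframe DICOM not supported: {path}")
            arr = ds.pixel_array.astype(np.float64)
            if arr.ndim != 2:
                raise FormatError(f"expected a single 2-D frame in {path}")
            depth = int(getattr(ds, "BitsStored", 16) or 16)
            spacing = getattr(ds, "PixelSpacing", None) or \
                getattr(ds, "ImagerPixelSpacing", None)
            mm = (float(spacing[0]), float(spacing[1])) if spacing is not None else None
            lat = {"L": "left", "R": "right", "B": "bilateral"}.get(
                str(getattr(ds, "Laterality", "")).upper(), "unknown")
            return Radiograph(pixels=arr, original_bit_depth=depth, mm_per_pixel=mm,
                              laterality=lat, source_id=path.name)
        except FormatError:
            raise
        except Exception as exc:
            raise FormatError(f"cannot read {path} as DICOM: {exc}") from exc
    if suffix == ".png":
        try:
            arr, depth = _load_png(path)
        except Exception as exc:
            raise FormatError(f"cannot read {path} as PNG: {exc}") from exc
        return Radiograph(pixels=arr, original_bit_depth=depth, source_id=path.name)
    raise FormatError(f"unsupported radiograph format for {path}")


def save_radiograph_png(r: Radiograph, path) -> None:
    """Write the radiograph as 16-bit PNG (values scaled from [0,1] if needed)."""
    arr = r.pixels
    if arr.max() <= 1.0:
        arr = arr * 65535.0
    Image.fromarray(np.clip(arr, 0, 65535).astype(np.uint16)).save(Path(path))


def load_mask(path) -> LabelMask:
    """Read an 8-bit single-channel PNG with literal labels 0-3."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L") if im.mode != "L" else im)
    except Exception as exc:
        raise FormatError(f"cannot read mask {path}: {exc}") from exc
    try:
        return LabelMask(labels=arr)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def save_mask(mask: LabelMask, path) -> None:
    Image.fromarray(mask.labels, mode="L").save(Path(path))


def normalize_intensity(r: Radiograph, p_low: float = 5.0, p_high: float = 99.0) -> Radiograph:
    """Histogram truncation plus global contrast normalization.

    Intensities are clipped to the [p_low, p_high] percentiles and the
    clipped range is affinely mapped to [0, 1].  The percentiles use the
    inclusive order statistics ('higher' for the low cut, 'lower' for the
    high cut), which makes the operation exactly idempotent: re-normalizing
    an already-normalized image finds cut points 0 and 1 and changes
    nothing.  A constant image maps to all zeros, as does a degenerate
    percentile range.
    """
    if not 0 < p_low < p_high < 100:
        raise ValueError("need 0 < p_low < p_high < 100")
    if r.pixels.size == 0:
        raise ValueError("empty image")
    lo = np.percentile(r.pixels, p_low, method="higher")
    hi = np.percentile(r.pixels, p_high, method="lower")
    if hi <= lo:
        lo, hi = r.pixels.min(), r.pixels.max()   # flat-histogram fallback
    if hi <= lo:
        out = np.zeros_like(r.pixels)
    else:
        out = (np.clip(r.pixels, lo, hi) - lo) / (hi - lo)
    return replace(r, pixels=out)


def _rescaled_spacing(mm, old_shape, new_shape):
    if mm is None:
        return None
    return (mm[0] * old_shape[0] / new_shape[0], mm[1] * old_shape[1] / new_shape[1])


def resize_square(r: Radiograph, size: int = 1024) -> Radiograph:
    """Bilinear resize to size x size; pixel spacing rescaled per axis."""
    if size < 32:
        raise ValueError("size must be >= 32")
    H, W = r.shape
    out = _sk_resize(r.pixels, (size, size), order=1, preserve_range=True,
                     anti_aliasing=(size < H or size < W))
    return replace(r, pixels=out,
                   mm_per_pixel=_rescaled_spacing(r.mm_per_pixel, (H, W), (size, size)))


def resize_mask_square(mask: LabelMask, size: int = 1024) -> LabelMask:
    """Nearest-neighbour resize; the label set is preserved exactly."""
    if size < 32:
        raise ValueError("size must be >= 32")
    out = _sk_resize(mask.labels, (size, size), order=0, preserve_range=True,
                     anti_aliasing=False)
    return LabelMask(labels=out.astype(np.uint8))


def hflip_radiograph(r: Radiograph) -> Radiograph:
    return replace(r, pixels=r.pixels[:, ::-1].copy(),
                   laterality=_OPPOSITE.get(r.laterality, "unknown"))


def hflip_mask(mask: LabelMask) -> LabelMask:
    return LabelMask(labels=mask.labels[:, ::-1].copy())
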