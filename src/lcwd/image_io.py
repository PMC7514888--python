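"""Grayscale image containers and file I/O.

All file interaction for the package is confined to this module (and the
CLI built on top of it).  Images are normalised into :class:`Image2D`, a
plain float64 matrix together with the dynamic-range ceiling used by PSNR.

Supported read formats: PNG, TIFF, single-frame grayscale DICOM, and
NIfTI-1 volumes (an axial slice is extracted).  Writing targets PNG
(8-bit) or TIFF (16-bit when the declared ceiling exceeds 255).
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import numpy as np

__all__ = ["Image2D", "read_image", "write_image"]

_PNG_EXTS = {".png"}
_TIFF_EXTS = {".tif", ".tiff"}
_DICOM_EXTS = {".dcm", ".dicom", ".ima"}
_NIFTI_EXTS = {".nii", ".nii.gz"}


@dataclasses.dataclass
class Image2D:
    """A real-valued H x W intensity matrix with a dynamic-range ceiling.

    Parameters
    ----------
    pixels
        2-D array of intensities; stored as float64.  Both dimensions must
        be at least 8 so that a 3x3 local-statistics map on the
        half-resolution diagonal sub-band is meaningful.
    max_intensity
        Positive ceiling of the intensity range (255 for 8-bit sources,
        65535 for 16-bit, data maximum for floating/DICOM sources).  Used
        as the peak value M in PSNR and as the reference for percentage
        noise levels.
    source
        Optional free-text provenance tag.
    """

    pixels: np.ndarray
    max_intensity: float = 255.0
    source: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got ndim={self.pixels.ndim}")
        h, w = self.pixels.shape
        if h < 8 or w < 8:
            raise ValueError(f"image must be at least 8x8, got {h}x{w}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain NaN or infinity")
        self.max_intensity = float(self.max_intensity)
        if not self.max_intensity > 0:
            raise ValueError("max_intensity must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def copy(self, **changes) -> "Image2D":
        out = dataclasses.replace(self, **changes)
        if "pixels" not in changes:
            out.pixels = self.pixels.copy()
        return out


def _to_gray(arr: np.ndarray) -> np.ndarray:
    """Collapse a channels-last colour image to its unweighted channel mean."""
    if arr.ndim == 3:
        return arr.astype(np.float64).mean(axis=-1)
    return arr.astype(np.float64)


def _ceiling_for_dtype(dtype: np.dtype, data: np.ndarray) -> float:
    if dtype == np.uint8:
        return 255.0
    if dtype == np.uint16:
        return 65535.0
    m = float(np.max(data)) if data.size else 0.0
    return m if m > 0 else 1.0


def _detect_format(path: Path, format_hint: str | None) -> str:
    if format_hint is not None:
        return format_hint.lower()
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return "nifti"
    ext = path.suffix.lower()
    if ext in _PNG_EXTS:
        return "png"
    if ext in _TIFF_EXTS:
        return "tiff"
    if ext in _DICOM_EXTS:
        return "dicom"
    if ext in _NIFTI_EXTS:
        return "nifti"
    raise ValueError(f"unsupported image format: {ext or path.name!r}")


def read_image(
    path: str | os.PathLike,
    format_hint: str | None = None,
    slice_index: int | None = None,
) -> Image2D:
    """Read a grayscale image and normalise it into an :class:`Image2D`.

    Multi-channel inputs are converted to the unweighted channel mean.
    DICOM modality rescale (slope/intercept) is applied when present;
    value-of-interest windowing is not, so downstream filters see raw
    intensities.  NIfTI volumes are sliced along the third axis
    (``slice_index``, default the middle slice).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = _detect_format(path, format_hint)

    if fmt in ("png", "tiff"):
        import imageio.v3 as iio

        raw = iio.imread(path)
        if raw.ndim not in (2, 3) or raw.size == 0:
            raise ValueError(f"expected 2-D image data in {path}, got shape {raw.shape}")
        pixels = _to_gray(raw)
        ceiling = _ceiling_for_dtype(raw.dtype, pixels)
        return Image2D(pixels, ceiling, source=str(path))

    if fmt == "dicom":
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
        if arr.ndim not in (2, 3) or arr.size == 0:
            raise ValueError(f"expected single-frame 2-D DICOM in {path}")
        arr = _to_gray(arr)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        return Image2D(arr, _ceiling_for_dtype(np.dtype(np.float64), arr), source=str(path))

    if fmt == "nifti":
        import nibabel as nib

        vol = np.asanyarray(nib.load(path).get_fdata())
        if vol.ndim < 2 or vol.size == 0:
            raise ValueError(f"expected >=2-D NIfTI data in {path}")
        while vol.ndim > 3:
            vol = vol[..., 0]
        if vol.ndim == 3:
            idx = vol.shape[2] // 2 if slice_index is None else slice_index
            vol = vol[:, :, idx]
        arr = vol.astype(np.float64)
        return Image2D(arr, _ceiling_for_dtype(np.dtype(np.float64), arr), source=str(path))

    raise ValueError(f"unsupported image format: {fmt!r}")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def write_image(image: Image2D, path: str | os.PathLike) -> None:
    """Write an image, clipping to [0, max_intensity] and quantising.

    8-bit container when ``max_intensity`` <= 255, 16-bit otherwise.
    Rounding is half-away-from-zero so that 127.5 stores as 128.
    """
    import imageio.v3 as iio

    path = Path(path)
    if not np.all(np.isfinite(image.pixels)):
        raise ValueError("cannot write non-finite pixels")
    clipped = np.clip(image.pixels, 0.0, image.max_intensity)
    quantised = _round_half_away(clipped)
    dtype = np.uint8 if image.max_intensity <= 255 else np.uint16
    ext = path.suffix.lower()
    if ext not in _PNG_EXTS | _TIFF_EXTS:
        raise ValueError(f"unsupported output format: {ext!r} (use PNG or TIFF)")
    iio.imwrite(path, quantised.astype(dtype))
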