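"""Single-level 2-D discrete wavelet transform and its exact inverse.

The denoising filter operates on the finest-scale diagonal detail band
(HH1) of a standard separable DWT: rows and columns are filtered with the
analysis pair (h, g) and downsampled by two, yielding the approximation
LL1 and the detail bands LH1 (horizontal), HL1 (vertical) and HH1
(diagonal).  Seven orthogonal families are supported — haar, db2, db4,
sym2, sym4, coif1 and coif2.

The default boundary mode is periodization: it is critically sampled,
orthogonal (Parseval holds on even sizes), and makes sub-band surgery
exactly invertible, so one can prove the filter touches only HH1.
Symmetric extension is available behind the ``boundary_mode`` flag.
Only a single decomposition level is exposed; the filter is defined on
first-level detail coefficients.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pywt

from .image_io import Image2D

__all__ = ["WaveletDecomposition", "decompose", "reconstruct", "SUPPORTED_WAVELETS"]

SUPPORTED_WAVELETS = ("haar", "db2", "db4", "sym2", "sym4", "coif1", "coif2")


@dataclasses.dataclass
class WaveletDecomposition:
    """The four scale-1 sub-bands plus the metadata needed for exact inversion."""

    LL: np.ndarray
    LH: np.ndarray
    HL: np.ndarray
    HH: np.ndarray
    wavelet: str
    boundary_mode: str
    original_shape: tuple[int, int]
    max_intensity: float = 255.0
    source: str | None = None

    def __post_init__(self) -> None:
        shapes = {b.shape for b in (self.LL, self.LH, self.HL, self.HH)}
        if len(shapes) != 1:
            raise ValueError(f"sub-band shapes differ: {shapes}")

    @property
    def subband_shape(self) -> tuple[int, int]:
        return self.HH.shape  # type: ignore[return-value]

    def replace_bands(self, **bands: np.ndarray) -> "WaveletDecomposition":
        """Return a copy with the named sub-bands substituted."""
        for name, arr in bands.items():
            if name not in ("LL", "LH", "HL", "HH"):
                raise ValueError(f"unknown sub-band {name!r}")
            if arr.shape != self.subband_shape:
                raise ValueError(
                    f"sub-band {name} shape {arr.shape} != {self.subband_shape}"
                )
        return dataclasses.replace(self, **bands)


def _validate_wavelet(wavelet: str) -> pywt.Wavelet:
    if wavelet not in SUPPORTED_WAVELETS:
        raise ValueError(
            f"unsupported wavelet {wavelet!r}; choose one of {SUPPORTED_WAVELETS}"
        )
    return pywt.Wavelet(wavelet)


def decompose(
    image: Image2D | np.ndarray,
    wavelet: str,
    boundary_mode: str = "periodization",
) -> WaveletDecomposition:
    """Single-level separable 2-D DWT.

    Accepts an :class:`Image2D` or a bare 2-D array (the latter bypasses
    the image-size invariants, which is convenient for coefficient-level
    experiments, but still requires each dimension to cover the analysis
    filter).
    """
    wav = _validate_wavelet(wavelet)
    if isinstance(image, Image2D):
        pixels = image.pixels
        ceiling = image.max_intensity
        source = image.source
    else:
        pixels = np.asarray(image, dtype=np.float64)
        if pixels.ndim != 2:
            raise ValueError("decompose requires a 2-D array")
        ceiling = 255.0
        source = None
    if min(pixels.shape) < wav.dec_len:
        raise ValueError(
            f"image {pixels.shape} smaller than the {wav.name} filter length {wav.dec_len}"
        )
    cA, (cH, cV, cD) = pywt.dwt2(pixels, wav, mode=boundary_mode)
    return WaveletDecomposition(
        LL=cA, LH=cH, HL=cV, HH=cD,
        wavelet=wavelet,
        boundary_mode=boundary_mode,
        original_shape=pixels.shape,
        max_intensity=ceiling,
        source=source,
    )


def reconstruct(decomp: WaveletDecomposition) -> Image2D:
    """Exact inverse DWT; returns an image of ``original_shape``.

    For odd input sizes the synthesis output is one sample larger per odd
    dimension and is trimmed back to the recorded shape.
    """
    wav = _validate_wavelet(decomp.wavelet)
    rec = pywt.idwt2(
        (decomp.LL, (decomp.LH, decomp.HL, decomp.HH)), wav, mode=decomp.boundary_mode
    )
    h, w = decomp.original_shape
    rec = rec[:h, :w]
    if rec.shape != (h, w):
        raise ValueError(
            f"reconstruction shape {rec.shape} inconsistent with original {decomp.original_shape}"
        )
    return Image2D(rec, decomp.max_intensity, source=decomp.source)
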