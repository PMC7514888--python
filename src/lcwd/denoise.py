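"""Local-complexity classification and zeroing of diagonal wavelet detail.

The filter decides, per HH1 coefficient, whether the local neighbourhood
is noise- or signal-dominant and zeroes the noise-dominant positions:

1. ``local_std_map`` — slide a 3x3 kernel over HH1 and record at every
   position p the population standard deviation

       sigma_p = sqrt( sum_m (y_m - ybar)^2 / 9 ),

   a proxy for local coefficient energy (smooth regions -> low energy,
   edges/texture -> high energy).
2. ``global_threshold`` — T = median of all N sigma values, a robust
   global estimate of the typical local energy.
3. ``alpha_map`` — a second 3x3 sliding pass, now over the sigma map:
   alpha_p = | sigma_center - median(3x3 sigma neighbourhood) |.  Large
   alpha marks positions whose local energy is an outlier against their
   own surroundings — isolated noise spikes rather than the coherent
   energy ridges produced by edges and texture.
4. ``apply_condition`` — hard-zero coefficients where alpha_p > T
   (strict); everything else passes through unaltered.

Both sliding passes use stride-1 windows with symmetric edge replication
so that sigma and alpha are defined at every position, and the population
(divide-by-9) estimator, not the sample one.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .image_io import Image2D
from .transform import WaveletDecomposition, decompose, reconstruct

__all__ = [
    "StdMap",
    "FilterDecision",
    "local_std_map",
    "global_threshold",
    "alpha_map",
    "apply_condition",
    "denoise",
    "hardzero_denoise",
]

_DETAIL_BANDS = ("LH", "HL", "HH")


@dataclasses.dataclass
class StdMap:
    """Per-position local standard deviation over a coefficient matrix."""

    sigma: np.ndarray
    n_positions: int

    def __post_init__(self) -> None:
        if np.any(self.sigma < 0):
            raise ValueError("standard deviations must be nonnegative")


@dataclasses.dataclass
class FilterDecision:
    """Full audit record of one filtering pass over HH1."""

    threshold: float
    alpha: np.ndarray
    noise_mask: np.ndarray
    wc_out: np.ndarray


def _windows3(a: np.ndarray) -> np.ndarray:
    """All 3x3 windows (stride 1, symmetric edge replication), flattened to 9."""
    padded = np.pad(a, 1, mode="symmetric")
    return sliding_window_view(padded, (3, 3)).reshape(a.shape + (9,))


def local_std_map(hh: np.ndarray) -> StdMap:
    """Population standard deviation of every 3x3 sliding window of ``hh``."""
    hh = np.asarray(hh, dtype=np.float64)
    if hh.ndim != 2 or min(hh.shape) < 3:
        raise ValueError(f"need a 2-D matrix of at least 3x3, got shape {hh.shape}")
    win = _windows3(hh)
    mean = win.mean(axis=-1)
    var = np.square(win - mean[..., None]).mean(axis=-1)
    return StdMap(np.sqrt(var), hh.size)


def global_threshold(stdmap: StdMap, convention: str = "lower") -> float:
    """Median of all local standard deviations.

    ``lower`` (default) uses the lower median for even counts — element
    ceil(N/2) of the sorted list — so T is always an observed sigma value;
    ``midpoint`` averages the two central elements.
    """
    flat = stdmap.sigma.ravel()
    if flat.size == 0:
        raise ValueError("empty standard-deviation map")
    if convention == "midpoint":
        return float(np.median(flat))
    if convention != "lower":
        raise ValueError(f"unknown median convention: {convention!r}")
    k = (flat.size - 1) // 2
    return float(np.partition(flat, k)[k])


def alpha_map(stdmap: StdMap) -> np.ndarray:
    """Absolute deviation of each sigma from the median of its 3x3 sigma window."""
    sigma = stdmap.sigma
    win = _windows3(sigma)
    med = np.median(win, axis=-1)
    return np.abs(sigma - med)


def apply_condition(hh: np.ndarray, alpha: np.ndarray, threshold: float) -> FilterDecision:
    """Hard-zero coefficients where ``alpha > threshold`` (strict)."""
    hh = np.asarray(hh, dtype=np.float64)
    alpha = np.asarray(alpha, dtype=np.float64)
    if hh.shape != alpha.shape:
        raise ValueError(f"shape mismatch: hh {hh.shape} vs alpha {alpha.shape}")
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    mask = alpha > threshold
    out = np.where(mask, 0.0, hh)
    return FilterDecision(float(threshold), alpha, mask, out)


def denoise(
    image: Image2D,
    wavelet: str,
    boundary_mode: str = "periodization",
    zero_scope: str = "center",
    median_convention: str = "lower",
) -> tuple[Image2D, FilterDecision]:
    """Full pipeline: DWT -> sigma map -> T -> alpha map -> zeroing -> IDWT.

    Only HH1 is modified; LL1, LH1 and HL1 pass through untouched.
    ``zero_scope`` controls what a flagged position zeroes: its own
    coefficient (``center``, the default, which keeps the decision a
    well-defined pointwise map) or its whole 3x3 kernel (``kernel``).
    Returns the restored image together with the decision record.
    """
    if zero_scope not in ("center", "kernel"):
        raise ValueError(f"unknown zero_scope: {zero_scope!r}")
    decomp = decompose(image, wavelet, boundary_mode)
    stdmap = local_std_map(decomp.HH)
    threshold = global_threshold(stdmap, median_convention)
    alpha = alpha_map(stdmap)
    decision = apply_condition(decomp.HH, alpha, threshold)
    if zero_scope == "kernel":
        mask = ndimage.binary_dilation(decision.noise_mask, structure=np.ones((3, 3), bool))
        decision = FilterDecision(
            decision.threshold, alpha, mask, np.where(mask, 0.0, decomp.HH)
        )
    restored = reconstruct(decomp.replace_bands(HH=decision.wc_out))
    return restored, decision


def hardzero_denoise(
    image: Image2D,
    wavelet: str,
    bands: frozenset[str] | set[str] | tuple[str, ...] = ("HH",),
    boundary_mode: str = "periodization",
) -> Image2D:
    """Zero entire detail sub-bands (the T=0 hard threshold) and reconstruct.

    Used by the wavelet-selection benchmark; the default zeroes only the
    diagonal band, the configuration that won the family comparison.
    """
    bands = set(bands)
    if not bands:
        raise ValueError("bands must be a nonempty subset of {LH, HL, HH}")
    unknown = bands - set(_DETAIL_BANDS)
    if unknown:
        raise ValueError(f"unknown detail bands: {sorted(unknown)}")
    decomp = decompose(image, wavelet, boundary_mode)
    zeroed = {b: np.zeros(decomp.subband_shape) for b in bands}
    return reconstruct(decomp.replace_bands(**zeroed))
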