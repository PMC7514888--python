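"""Objective image-quality metrics: PSNR and SSIM.

PSNR is the standard 10*log10(M^2 / MSE) with M the *declared* dynamic
range of the reference image (not the per-image data maximum).  SSIM is
the mean structural-similarity index in the universal configuration:
11x11 Gaussian window with sigma = 1.5, K1 = 0.01, K2 = 0.03, weighted
(population) local moments.  Identical images score PSNR = +inf and
SSIM = 1.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from skimage.metrics import structural_similarity

from .image_io import Image2D

__all__ = ["MetricsReport", "psnr", "ssim", "score"]

# Universal SSIM constants, pinned so reported numbers are stable across versions.
SSIM_K1 = 0.01
SSIM_K2 = 0.03
SSIM_SIGMA = 1.5
SSIM_WIN = 11


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    psnr: float
    ssim: float
    reference_id: str | None = None
    test_id: str | None = None


def _check_pair(reference: Image2D, test: Image2D) -> None:
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")


def psnr(reference: Image2D, test: Image2D) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    _check_pair(reference, test)
    mse = float(np.mean(np.square(reference.pixels - test.pixels)))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(reference.max_intensity**2 / mse)


def ssim(reference: Image2D, test: Image2D) -> float:
    """Mean structural similarity index; 1.0 for identical images."""
    _check_pair(reference, test)
    if min(reference.shape) < SSIM_WIN:
        raise ValueError(f"SSIM needs images of at least {SSIM_WIN}x{SSIM_WIN}")
    return float(
        structural_similarity(
            reference.pixels,
            test.pixels,
            data_range=reference.max_intensity,
            gaussian_weights=True,
            sigma=SSIM_SIGMA,
            win_size=SSIM_WIN,
            use_sample_covariance=False,
            K1=SSIM_K1,
            K2=SSIM_K2,
        )
    )


def score(reference: Image2D, test: Image2D) -> MetricsReport:
    """Bundle PSNR and SSIM into a report with provenance tags."""
    return MetricsReport(
        psnr=psnr(reference, test),
        ssim=ssim(reference, test),
        reference_id=reference.source,
        test_id=test.source,
    )
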