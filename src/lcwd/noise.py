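"""AWGN and Rician noise simulators.

AWGN adds an i.i.d. zero-mean Gaussian field of a given standard
deviation (intensity units on the image's own scale).  Rician noise
models magnitude MR acquisition: the clean signal x is perturbed in the
complex domain and the magnitude taken,

    y = sqrt((x + n1)^2 + n2^2),   n1, n2 ~ N(0, sigma_r) i.i.d.,

with sigma_r expressed as a percentage of the image's intensity ceiling
(the convention used by simulated-brain MR benchmarks: "9% Rician noise"
means sigma_r = 0.09 * max_intensity).  On dark background (x ≈ 0) this
produces the characteristic Rayleigh-distributed upward bias; for
x >> sigma_r it converges to additive Gaussian noise.

Noisy outputs are intentionally NOT clipped to the display range;
quantisation happens only when an image is written to disk, so metric
computations match the additive model exactly.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .image_io import Image2D

__all__ = ["NoiseSpec", "add_awgn", "add_rician", "add_noise"]


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    """Tagged union of the two supported noise models.

    ``awgn`` uses ``sigma`` (intensity units) and ignores ``percent``;
    ``rician`` uses ``percent`` (of ``max_intensity``) and ignores
    ``sigma``.  A fixed ``seed`` makes the corruption bit-reproducible.
    """

    model: str
    sigma: float | None = None
    percent: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("awgn", "rician"):
            raise ValueError(f"unknown noise model: {self.model!r}")
        if self.model == "awgn":
            if self.sigma is None:
                raise ValueError("awgn requires sigma")
            if self.sigma < 0:
                raise ValueError("sigma must be nonnegative")
        else:
            if self.percent is None:
                raise ValueError("rician requires percent")
            if self.percent < 0:
                raise ValueError("percent must be nonnegative")

    @property
    def level_label(self) -> str:
        if self.model == "awgn":
            return f"awgn(sigma={self.sigma:g})"
        return f"rician({self.percent:g}%)"


def add_awgn(image: Image2D, spec: NoiseSpec) -> Image2D:
    """Add zero-mean i.i.d. Gaussian noise of standard deviation ``spec.sigma``."""
    if spec.model != "awgn":
        raise ValueError("add_awgn requires an awgn NoiseSpec")
    rng = np.random.default_rng(spec.seed)
    noisy = image.pixels + rng.normal(0.0, spec.sigma, size=image.pixels.shape)
    return Image2D(noisy, image.max_intensity, source=image.source)


def add_rician(image: Image2D, spec: NoiseSpec) -> Image2D:
    """Corrupt a nonnegative image with Rician noise at ``spec.percent`` %.

    The two Gaussian fields are drawn from one seeded stream in a fixed
    order (real field fully, then imaginary field fully).
    """
    if spec.model != "rician":
        raise ValueError("add_rician requires a rician NoiseSpec")
    if np.any(image.pixels < 0):
        raise ValueError("Rician corruption requires nonnegative pixels")
    sigma_r = spec.percent / 100.0 * image.max_intensity
    rng = np.random.default_rng(spec.seed)
    n1 = rng.normal(0.0, sigma_r, size=image.pixels.shape)
    n2 = rng.normal(0.0, sigma_r, size=image.pixels.shape)
    noisy = np.hypot(image.pixels + n1, n2)
    return Image2D(noisy, image.max_intensity, source=image.source)


def add_noise(image: Image2D, spec: NoiseSpec) -> Image2D:
    """Dispatch on ``spec.model``."""
    if spec.model == "awgn":
        return add_awgn(image, spec)
    return add_rician(image, spec)
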