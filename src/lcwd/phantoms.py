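"""Synthetic ground-truth phantoms for denoising experiments.

Real MRI test sets cannot be redistributed, so the package generates
deterministic phantoms exhibiting the structures a detail-preserving
denoiser must handle: large homogeneous plateaus, sharp intensity edges,
and high-frequency texture.  ``mixed_brain_like`` mimics the gross
statistics of a magnitude MR slice — dark (zero) background, a few
tissue-level plateaus, and a thin bright cortical-like ribbon — so the
Rician background-bias regime is represented.

Every phantom is a deterministic function of its :class:`PhantomSpec`;
the same spec always yields a bit-identical matrix.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .image_io import Image2D

__all__ = ["PhantomSpec", "generate_phantom", "region_mask", "PHANTOM_KINDS"]

PHANTOM_KINDS = ("piecewise_ellipses", "checker_texture", "edge_ramp", "mixed_brain_like")

_REGION_LABELS = ("homogeneous", "edge_band", "texture")

_DEFAULT_LEVELS = {
    # background first; consecutive levels differ by >= 50 intensity units
    "edge_ramp": (40.0, 200.0),
    "piecewise_ellipses": (0.0, 120.0, 250.0),
    "checker_texture": (60.0, 140.0, 220.0),
    # background, gray matter, white matter, ventricle, cortical ribbon
    "mixed_brain_like": (0.0, 80.0, 140.0, 40.0, 220.0),
}

_CHECKER_TILE = 4  # pixels per checker tile


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Deterministic recipe for a ground-truth phantom."""

    height: int
    width: int
    kind: str
    seed: int = 0
    intensity_levels: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind: {self.kind!r}")
        if self.height < 32 or self.width < 32:
            raise ValueError("phantom dimensions must be >= 32")
        levels = self.intensity_levels
        if levels is None:
            levels = _DEFAULT_LEVELS[self.kind]
        levels = tuple(float(v) for v in levels)
        if any(not 0 <= v <= 255 for v in levels):
            raise ValueError("intensity levels must lie in [0, 255]")
        object.__setattr__(self, "intensity_levels", levels)

    @property
    def levels(self) -> tuple[float, ...]:
        return self.intensity_levels  # type: ignore[return-value]


def _ellipse_mask(h: int, w: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _render(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (pixels, labels); labels is an integer region-id map."""
    h, w = spec.height, spec.width
    levels = spec.levels
    rng = np.random.default_rng(spec.seed)

    if spec.kind == "edge_ramp":
        if len(levels) != 2:
            raise ValueError("edge_ramp takes exactly two intensity levels")
        labels = np.zeros((h, w), dtype=np.int64)
        labels[:, w // 2 :] = 1
        pixels = np.where(labels == 0, levels[0], levels[1]).astype(np.float64)
        return pixels, labels

    if spec.kind == "checker_texture":
        if len(levels) != 3:
            raise ValueError("checker_texture takes background + two tile levels")
        labels = np.zeros((h, w), dtype=np.int64)
        labels[:, w // 2 :] = 1
        yy, xx = np.mgrid[0:h, 0:w]
        checker = ((yy // _CHECKER_TILE) + (xx // _CHECKER_TILE)) % 2
        pixels = np.full((h, w), levels[0], dtype=np.float64)
        tile = np.where(checker == 0, levels[1], levels[2])
        pixels[labels == 1] = tile[labels == 1]
        return pixels, labels

    if spec.kind == "piecewise_ellipses":
        n_ellipses = len(levels) - 1
        if not 1 <= n_ellipses <= 4:
            raise ValueError("piecewise_ellipses takes a background level plus 1-4 ellipse levels")
        labels = np.zeros((h, w), dtype=np.int64)
        # one ellipse per quadrant so every level survives in the rendered image
        anchors = [(0.25, 0.25), (0.25, 0.75), (0.75, 0.25), (0.75, 0.75)]
        for i in range(n_ellipses):
            ay, ax = anchors[i]
            cy = ay * h + rng.uniform(-0.04, 0.04) * h
            cx = ax * w + rng.uniform(-0.04, 0.04) * w
            ry = rng.uniform(0.10, 0.16) * h
            rx = rng.uniform(0.10, 0.16) * w
            labels[_ellipse_mask(h, w, cy, cx, ry, rx)] = i + 1
        pixels = np.asarray(levels, dtype=np.float64)[labels]
        return pixels, labels

    # mixed_brain_like
    if len(levels) != 5:
        raise ValueError("mixed_brain_like takes 5 intensity levels")
    bg, gm, wm, csf, ribbon = levels
    cy = h / 2 + rng.uniform(-0.02, 0.02) * h
    cx = w / 2 + rng.uniform(-0.02, 0.02) * w
    head_ry = 0.40 * h * rng.uniform(0.95, 1.05)
    head_rx = 0.36 * w * rng.uniform(0.95, 1.05)
    head = _ellipse_mask(h, w, cy, cx, head_ry, head_rx)
    # cortical-like ribbon: the outer shell of the head, ~2 px thick
    interior = _ellipse_mask(h, w, cy, cx, head_ry - 2.5, head_rx - 2.5)
    wm_mask = _ellipse_mask(h, w, cy, cx, 0.24 * h, 0.22 * w)
    vent_dx = 0.07 * w
    vent = _ellipse_mask(h, w, cy, cx - vent_dx, 0.10 * h, 0.035 * w) | _ellipse_mask(
        h, w, cy, cx + vent_dx, 0.10 * h, 0.035 * w
    )
    labels = np.zeros((h, w), dtype=np.int64)
    labels[head & ~interior] = 4
    labels[interior] = 1
    labels[wm_mask & interior] = 2
    labels[vent & interior] = 3
    pixels = np.asarray([bg, gm, wm, csf, ribbon], dtype=np.float64)[labels]
    return pixels, labels


def generate_phantom(spec: PhantomSpec) -> Image2D:
    """Render the phantom described by ``spec`` (bit-reproducible)."""
    pixels, _ = _render(spec)
    return Image2D(pixels, 255.0, source=f"phantom:{spec.kind}:seed={spec.seed}")


def _discontinuity_band(labels: np.ndarray) -> np.ndarray:
    """Pixels within 1 px (Chebyshev) of a region boundary in the label map."""
    hi = ndimage.maximum_filter(labels, size=3, mode="nearest")
    lo = ndimage.minimum_filter(labels, size=3, mode="nearest")
    return hi != lo


def region_mask(spec: PhantomSpec, region: str) -> np.ndarray:
    """Binary mask of a named ground-truth region.

    ``homogeneous``, ``edge_band`` and ``texture`` masks are pairwise
    disjoint.  ``edge_band`` is the set of pixels within 1 px of an
    intensity discontinuity of the macroscopic region geometry (tile
    boundaries inside a texture region do not count).  ``texture`` exists
    only for ``checker_texture``.
    """
    if region not in _REGION_LABELS:
        raise ValueError(f"unknown region label: {region!r}")
    pixels, labels = _render(spec)
    h, w = labels.shape

    if spec.kind == "checker_texture":
        texture = labels == 1
        band = _discontinuity_band(labels) & ~texture
        if region == "texture":
            return texture
        if region == "edge_band":
            return band
        return (labels == 0) & ~band

    if region == "texture":
        raise ValueError(f"region 'texture' is not applicable to kind {spec.kind!r}")

    band = _discontinuity_band(labels)
    if region == "edge_band":
        return band
    if spec.kind == "edge_ramp":
        # both plateaus are homogeneous
        return ~band
    # homogeneous region = the background plateau away from any edge
    counts = np.bincount(labels.ravel())
    modal = int(np.argmax(counts))
    return (labels == modal) & ~band
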