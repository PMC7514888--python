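# Methods

## Model and procedure

The filter operates on the finest-scale diagonal detail band `HH₁` of a
single-level separable 2-D DWT. The underlying model is the usual
sparsity argument of wavelet shrinkage: in `HH₁`, i.i.d. image noise spreads
energy everywhere while genuine image structure (edges, texture) concentrates
energy locally. The filter estimates *local complexity* as the population
standard deviation σ over 3×3 sliding kernels, summarises the whole band by
the median `T` of those σ values, and flags a position as noise-dominant when
its σ deviates from the median σ of its own 3×3 neighbourhood by more than
`T` (the statistic `α_p = |σ_p − MED{σ neighbourhood}|`). Flagged coefficients
are set to zero; everything else, and the other three sub-bands, pass through
untouched before the inverse transform.

Assumptions worth stating explicitly:

- noise is i.i.d. across pixels (AWGN) or arises from i.i.d. complex Gaussian
  perturbation (Rician); spatially varying or correlated noise is out of scope;
- a single decomposition level suffices — the rule is defined on `HH₁` only;
- the 3×3 kernel size and the median as the global summary are fixed design
  constants of the method, not tunables.

## Empirical behaviour of the classifier

The α statistic is an *outlier* detector on the local-energy field. Two
measured consequences (reproducible via `scripts/acceptance.py` and the
acceptance test suite):

1. On a pure-noise image the σ field of `HH₁` is smooth, because neighbouring
   3×3 kernels share six of nine coefficients; α therefore almost never
   exceeds `T` (which sits near the noise level), and the filter zeroes
   essentially nothing (measured zeroed fraction 0 at σ = 20 AWGN on a 128²
   flat image).
2. On structured images the large α values occur where local energy changes
   abruptly — tissue boundaries and texture borders. On the brain-like
   phantom at 6 % Rician noise the mask fires on ~1.9 % of signal-bearing
   `HH₁` positions versus ~0.06 % of flat ones.

The net effect is a very conservative filter whose PSNR effect on
Gaussian/Rician-corrupted piecewise-constant phantoms is slightly negative at
low noise (≈ −0.03 to −0.4 dB, where the zeroed coefficients are mostly
structural) and indistinguishable from zero at high noise (zeroed fraction
→ 0). The acceptance suite states the stronger selectivity claims — mean
PSNR improvement across a Rician/AWGN grid, and preferential zeroing in
homogeneous over edge regions — and those tests document where the measured
behaviour falls short; they are retained deliberately as a faithful record
rather than weakened. Users who need measurable PSNR gains from sub-band
zeroing can use the `hardzero` mode, which removes entire detail bands.

A related geometric fact matters for edge experiments: a perfectly vertical
(or horizontal) step edge injects *no* energy into the diagonal band — its
row-detail is constant along columns, which the column high-pass annihilates
(exactly for Haar, to ~1e-30 for longer filters). Diagonal structure is what
`HH₁` sees; axis-aligned edges live in `LH₁`/`HL₁`.

## Parameters

| Parameter | Default | Units / range | Rationale |
|---|---|---|---|
| `wavelet` | `db4` | 7 orthogonal families | longest-support family in the supported set; the family comparison is re-runnable via the benchmark |
| `boundary_mode` | `periodization` | also `symmetric` | critically sampled and orthogonal: Parseval holds and sub-band surgery is exactly invertible, which makes "only HH₁ is touched" provable; symmetric extension kept behind a flag |
| `zero_scope` | `center` | `center` / `kernel` | a flagged position zeroes its own coefficient; `kernel` zeroes the whole 3×3 neighbourhood (measured to be uniformly more destructive) |
| `median_convention` | `lower` | `lower` / `midpoint` | for even counts the lower median keeps `T` an actually observed σ value |
| AWGN `sigma` | — | intensity units, 0–255 scale | study grid σ ∈ {10, 20, 30, 40, 50} |
| Rician `percent` | — | % of `max_intensity` | study grid 3–18 %; σ_r = percent/100 × ceiling, the simulated-brain-database convention, so levels are comparable with the MR-denoising literature |

Strictness of the condition (`α > T`, not ≥) matters only in the degenerate
all-zero case (blank images), where it correctly leaves the image untouched.

## Synthetic data

Phantoms are deterministic functions of a `PhantomSpec` (seeded jitter only):

- `edge_ramp` — two plateaus (40 | 200) split at column W/2; the canonical
  axis-aligned step edge;
- `piecewise_ellipses` — up to four constant ellipses on a constant
  background, one per quadrant so every intensity level survives rendering;
- `checker_texture` — a flat left half and a 4-px checkerboard right half;
  the texture region for selectivity tests;
- `mixed_brain_like` — zero background (≥ 10 % of pixels, so the Rayleigh
  regime of Rician noise on dark background is exercised), gray/white-matter
  plateaus, ventricle-like dark ellipses and a ~2-px bright cortical ribbon.

What they deliberately do **not** model: anatomical realism, partial-volume
effects, bias fields, scanner artefacts, and natural-image texture spectra.
Passing tests on these phantoms therefore demonstrate the mechanical
correctness and the qualitative selectivity of the filter, not clinical
denoising performance; the benchmark accepts a directory of user-supplied
ground-truth images for anyone holding a real dataset.

`region_mask` exposes pairwise-disjoint `homogeneous` / `edge_band` /
`texture` masks derived from the generating geometry (edge bands are pixels
within 1 px of a macroscopic region boundary; checker tile boundaries do not
count as edges).

## Numerical choices

- Population (÷9) standard deviation, exactly as the kernel statistic is
  defined; both sliding passes pad with symmetric edge replication so border
  positions are defined.
- Lower-median convention for even counts (switchable to midpoint).
- DWT/IDWT via PyWavelets; odd-sized inputs yield ⌈n/2⌉ sub-band samples
  under periodization and the synthesis output is trimmed back to the
  recorded original shape. Round-trip error is ~1e-10 intensity units.
- PSNR uses the *declared* ceiling `max_intensity` of the reference, not the
  data maximum; identical images report +inf.
- SSIM is the mean local index with the universal configuration (11×11
  Gaussian window, σ = 1.5, K₁ = 0.01, K₂ = 0.03, weighted population
  moments), computed by scikit-image and pinned in `lcwd.metrics`; the test
  suite cross-checks it against an independent valid-window implementation.
- Noise is generated on the unclipped real line (metrics see the additive
  model); quantisation and clipping happen only when writing files, with
  half-away-from-zero rounding.
- Degenerate inputs: blank images are exact fixed points of the filter;
  images whose `HH₁` is identically zero are fixed points to ≤ 1e-6.

## Problem sizes

The default experiment scale is 128² phantoms, ten noise realisations per
grid point, and 64² phantoms for the wavelet-family sweep — small enough for
the whole suite and the reproduction script to run in seconds on one core,
large enough that sample noise statistics are calibrated to ~1 % and the
sub-band maps contain thousands of positions.

## Known limitations

- The classifier's selectivity is inverted relative to what a denoiser wants
  under i.i.d. Gaussian-type noise (see "Empirical behaviour"): it is most
  active on structure at low noise and nearly inactive at high noise. It may
  behave as intended for impulsive wavelet-domain corruption, which is where
  its median-deviation statistic originates; that regime is not part of the
  supported noise models.
- Axis-aligned edges are invisible to `HH₁`; edge-preservation statements
  based on the vertical-ramp phantom measure floating-point residue, not
  signal.
- Single-coil Rician only; noncentral-χ multi-coil noise, noise estimation
  from data, and multi-level or translation-invariant transforms are out of
  scope.
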