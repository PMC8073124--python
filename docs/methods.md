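# Methods

This note documents the models and procedures `ftirgrid` implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer would want
written down.

## The pipeline

A dataset is a matrix of absorbance spectra (rows = cells) on a shared
strictly increasing wavenumber axis in cm⁻¹. Every combination of the
three preprocessing steps is executed as

1. remove the water-vapor region (default 3650–3800 cm⁻¹; columns
   dropped, never interpolated),
2. denoise,
3. interpolate linearly across the CO₂ region (default 2300–2400 cm⁻¹)
   so baseline methods see a gap-free axis,
4. baseline-correct,
5. trim the CO₂ region out again,
6. normalize,

applied **independently** to the model set and the test set — the test
set never influences any data-driven statistic (PQN's mean standard is
recomputed per set for the same reason, at the cost of a small
train/test distribution shift that is itself one of PQN's known
failure modes).

The exact CO₂/water-vapor bounds are conventions of this package (the
gases pin the neighborhoods, not the bounds); both are configurable
`SpectralRegion`s.

## Methods and parameter grids

The default grid is 45 × 21 × 3 = 2835 combinations:

| step | method | parameters |
|---|---|---|
| denoise | EIL | λ ∈ {2, 3, …, 24} (23) |
| denoise | SG | degree {2,3} × odd frame {11..29} (20) |
| denoise | FT | retained window ∈ {100, 320} points (2) |
| baseline | DER | degree {2,3} × odd frame {19..29} (12) |
| baseline | RB | fixed anchors (1) |
| baseline | POL | degree ∈ {3,4,5} (3) |
| baseline | ALS | p = 0.1, λ ∈ {10⁶,10⁷,10⁸} (3) |
| baseline | RMIE / MEEMSC | fixed engine defaults (1 + 1) |
| normalize | CON / TSN / PQN | — (3) |

Notes on individual methods:

- **EIL/Whittaker.** Minimizes Σ(yᵢ−zᵢ)² + λΣ(Δ²zᵢ)² with unit weights;
  solved by sparse LU of the pentadiagonal system, factorized once per
  (length, λ) and reused across rows. λ→0 returns the input, λ→∞ tends
  to the least-squares line.
- **SG.** `scipy.signal.savgol_filter` with polynomial edge handling
  (`mode="interp"`); the second-derivative variant divides by the axis
  spacing squared, so DER output has units AU·cm².
- **FT.** Real-FFT truncation: the retained "window" counts rFFT
  coefficients including the zero-frequency term; a window of at least
  n//2 + 1 is the identity.
- **RB.** The nine default anchor frequencies (1001…3519 cm⁻¹) bound
  eight intervals; the spectrum minimum in each interval becomes a knot
  and the piecewise-linear interpolant through the knots is subtracted.
  The terminal segments are extended linearly past the outermost knots
  so that an exactly linear baseline is removed completely (flat
  extension would leave ramps at the axis edges). A spline through the
  knots is a known alternative; the straight-line variant is the
  default and only implemented form.
- **POL.** Least-squares polynomial through the spectrum values at the
  anchor frequencies (9 anchors > degree+1, so a fit rather than an
  interpolation), evaluated on the full axis and subtracted.
- **ALS.** Iterated weighted Whittaker with w = p where y > z and 1−p
  where y ≤ z; stops when the weight vector is unchanged between
  iterations or after 50 iterations (flagged in the log if not
  converged). At convergence the baseline is a p-expectile smoother:
  for Gaussian residuals about 19% of points fall below it at p = 0.1.
  A claim sometimes made — that the below-baseline fraction approaches
  p itself — holds only when the baseline model can follow the data's
  lower envelope closely; the tests assert the expectile behavior.
- **Mie-EMSC engine (RMIE, MEEMSC).** Per spectrum and iteration: the
  reference's absorbance is Hilbert-transformed (discrete
  Kramers–Kronig) into a zero-mean refractive-index fluctuation; for a
  10×10 grid of sphere diameters d ∈ [2, 8] µm and refractive indices
  n ∈ [1.1, 1.4] the optical path ρ(ν) = 2πνd(n−1 + ½(n−1)·n̂_kk(ν))
  (clipped at 0) is mapped through the van-de-Hulst extinction
  efficiency; the 100-curve family is mean-centered and compressed to 7
  orthonormal principal loadings; EMSC solves
  y ≈ b·ref + a·1 + Σgₖ·loadingₖ and corrects to (y − a − Σgₖlₖ)/b; the
  corrected spectrum becomes the next reference. RMIE runs exactly 5
  iterations; MEEMSC iterates to a relative change below 10⁻⁴ (max 30)
  with the reference update damped 50/50 for stability. The published
  codes' multi-parameter "PreRun" optimization is out of scope; the
  grid size, basis size, fluctuation coupling and damping are this
  package's defaults, not claims about those codes. When no measured
  Matrigel spectrum is supplied, a synthetic protein-dominated
  stand-in (`generate_reference`) is used and flagged as synthetic.
- **CON.** Division by the value at the axis point nearest 1656 cm⁻¹
  (Amide I). For derivative spectra the absolute value at that point is
  used so the band point maps to ±1 without flipping the spectrum.
  Nearest-point rather than max-in-window is chosen for determinism.
- **TSN.** Division by the sum of absorbances; the absolute-value sum is
  used whenever any value is negative (derivative or baseline-corrected
  spectra), where a signed sum is ill-defined as a size measure.
- **PQN.** Standard = feature-wise mean of the set; quotients only where
  |x_s| > 10⁻⁸·max|x_s| (baseline-corrected spectra are near zero over
  large stretches and would otherwise blow up the quotient
  distribution); scaling factor = median quotient.

## Chemometrics

- **Kennard–Stone split.** Within each class independently: seed with
  the most distant pair (Euclidean, on raw spectra — the split precedes
  preprocessing), then repeatedly add the candidate maximizing its
  minimum distance to the selected set, until ⌊0.75·n⌋ per class. For
  class sizes (14,7,7,10,10) this gives 34 model and 14 test spectra;
  floor is the only rounding consistent with that split. Fully
  deterministic; ties resolve to the lowest index.
- **PLS core.** Mean-centered PLS1 NIPALS. One fit at `lv_max`
  components yields the coefficient vector at every truncation
  1..lv_max (β_k = W_k(P_kᵀW_k)⁻¹q_k), so a LOOCV curve costs one fit
  per fold instead of one per (fold, LV). Multi-column responses (the
  0/1 class-membership matrix) are fitted as independent PLS1
  sub-models sharing one LV count, matching a five-model one-vs-all
  classifier reported with a single LV per combination. A response that
  deflates to zero before `lv_max` keeps its last coefficient vector
  for the remaining truncations.
- **Responses.** Regression: ordinal progression coding RWPE-1 → −2,
  22Rv1 → −1, PC3 → 0, Du145 → 1, LNCaP → 2 (the ordering of the three
  metastatic lines is conventional). Classification: one-vs-all 0/1
  membership, assignment by maximum predicted membership, ties to the
  lowest class index (logged).
- **LV selection (1..8).** Regression: the smallest LV whose RMSECV is
  strictly below the next two values (a genuine local minimum) wins;
  otherwise the global minimum. Classification: accuracy argmax, ties
  to the smaller LV. LOOCV with n−1 samples caps the usable LV count at
  n−2; larger requests are clamped with a warning.
- **Metrics.** RMSECV/RMSEP as root-mean-square errors; accuracy as the
  fraction of matching labels. Failed combinations carry the failing
  stage and message in their record and are excluded from summaries.

## Synthetic data generator

`generate_study(seed)` emulates the measurement design end to end: five
class profiles (14/7/7/10/10 spectra) share the protein bands (Amide I
1656, Amide II 1545, Amide A 3290, Amide B 3070 cm⁻¹, plus minor
backbone bands) and differ through class-specific amplitude multipliers
on nucleic-acid-region (944–1140 cm⁻¹) and CH-stretch-region
(2800–3000 cm⁻¹) bands. Per spectrum, band amplitudes jitter
log-normally (σ = 5%) and centers normally (σ = 1 cm⁻¹). Distortions per
spectrum: scale·(clean + Mie fringe) + polynomial baseline + CO₂/
water-vapor artifact bands + white noise, with scale ∈ [0.8, 1.2],
fringes from van-de-Hulst spheres (d ∈ [2, 8] µm, n ∈ [1.1, 1.4]),
baseline coefficients drawn per degree, and noise σ = 0.006 AU
representing the 256-scan acquisition. The exact generating components
of every spectrum are retained in `meta["truth"]`, so tests can verify
corrections against ground truth.

Scan-count noise reduction is modelled as σ ∝ 1/√scans: emulating a
32-scan acquisition from a 256-scan one adds independent Gaussian noise
with σ_add = σ_base·√(256/32 − 1) ≈ 2.65·σ_base, with σ_base estimated
from a detrended signal-free window (1750–1800 cm⁻¹) when not supplied.

Effect sizes are free parameters (no public quantitative reference for
between-line spectral differences exists at this granularity); they are
fixed so that the undistorted study is cleanly separable by PLS-DA
(LOOCV accuracy ≥ 0.95) while the distorted study loses a measurable
amount of external accuracy under 32-scan noise — the qualitative regime
the pipeline comparison is designed to probe. What passing tests on this
generator show is that the machinery is correct and the noise effect is
directionally reproduced; they do not certify method rankings on real
cells, whose class differences, scatter statistics and detector
artifacts are richer than band-plus-distortion models.

Known unmodelled features: detector-resolution line shapes, correlated
(pink) noise, FPA spatial effects and pixel averaging, true atmospheric
rotational fine structure, and sample-to-substrate interference.

## Numerical choices and degenerate inputs

- Whittaker/ALS systems are solved sparsely (LU); the dense-matrix
  equivalents serve as test oracles at 10⁻⁶–10⁻⁸.
- The van-de-Hulst formula switches to its series ρ²/2 − ρ⁴/36 below
  ρ = 10⁻³ to avoid catastrophic cancellation; ρ must be non-negative.
- EMSC refuses to divide by a multiplicative coefficient below 10⁻⁸ in
  magnitude (non-identifiable fit); in the grid runner such spectra
  pass through unchanged and the record is flagged.
- A Mie curve family of rank below the requested basis size reduces the
  basis with a warning.
- The best-decile summary uses the intersection of the bottom-decile
  sets of RMSECV and RMSEP (stable first-occurrence ranking); if the
  intersection is empty the ⌈0.1·n⌉ records with the smallest summed
  rank are taken.
- Grid execution is deterministic given (dataset seed, noise seed,
  config); per-combination JSON caching makes reruns bitwise identical.

## Problem sizes used in tests

The acceptance suite runs the full study shape (48 × 1582) for
splitting, a 30-combination seeded subsample of the grid for the
end-to-end noise comparison, and small toys (n ≤ 300) for every oracle
comparison; the Monte-Carlo noise-model check uses 2·10⁵ draws. These
sizes make the whole suite complete in a few minutes on one CPU while
keeping every statistical assertion comfortably powered.
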