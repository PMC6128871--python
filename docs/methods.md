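# Methods

## Spectral model and units

A spectrum is a 1-D absorbance trace A(ν̃) on a wavenumber grid ν̃ in cm⁻¹,
nominally 4000–650 cm⁻¹ at 4 cm⁻¹ instrument resolution (stored at ~2 cm⁻¹
point spacing). Files written in percent transmittance are converted with
A = 2 − log₁₀(%T); the inverse %T = 10^(2−A) is exact, and %T ≤ 0 is a hard
conversion error reported with the offending wavenumber. Instruments write
grids descending; loading canonicalizes to ascending once so that
derivatives and integrals never need sign bookkeeping. The grid is never
resampled on load — only the PCA step, which needs a common basis,
interpolates (linearly, onto the first spectrum's grid restricted to the
overlapping range).

Total area is the composite trapezoid on the native, possibly non-uniform
grid: standard, and exact for the piecewise-linear fixtures the tests use.
Negative absorbances (instrument baseline artifacts) are permitted and
integrate with sign; a non-positive total area is logged and any
normalization against it refused.

## Peak quantification

The quantification statistic is the normalized corrected peak height, in
units of cm (absorbance divided by absorbance·cm⁻¹):

1. *Endpoints.* A grid point in the expected endpoint window is a
   local-minimum candidate when its absorbance is ≤ both full-spectrum
   neighbors (plateaus admitted). The candidate with minimal absorbance
   wins; ties break to the lowest wavenumber — the tie-break is not part of
   the underlying idea but determinism requires one. When the window is
   monotone, the fallback is the point maximizing the discrete second
   derivative (central differences on the native grid, non-uniform-spacing
   form), i.e. the strongest convex kink where a shoulder meets background.
   No smoothing is applied by default, keeping the operation parameter-free;
   an odd-width moving-average pre-smoother is available via
   `smooth_width` for noisy data.
2. *Baseline.* The straight line through the two endpoint absorbances is
   subtracted; corrected values at the endpoints are exactly zero, and
   endpoints must be exact grid points (no silent interpolation). Negative
   corrected values elsewhere in the segment are retained; only the segment
   maximum defines the height.
3. *Normalization.* The corrected height is divided by the total spectrum
   area. The statistic is therefore invariant to overall scaling of the
   spectrum, and the corrected height is invariant to any global affine
   ramp wherever the underlying signal is linear through the endpoint
   windows. On smooth band tails an added ramp can move the detected
   endpoint by a few grid points; the resulting height change is second
   order (the tests cover both the exact and the realistic case).

Default endpoint windows bracket each nominal band position by roughly
40–120 cm⁻¹ (carb 1030: [850–1000 | 1080–1180]; arom15 1510:
[1420–1480 | 1520–1560]; arom16 1630: [1540–1600 | 1660–1760]; aliph28
2850: [2780–2840 | 2860–2890]; aliph29 2920: [2880–2910 | 2950–3010]).
They are defaults to be recalibrated per instrument/sample set via the YAML
peaks config. The ~1630 band's nominal position is itself approximate
(literature values range to ~1615); it is configurable.

The silicate screen measures the kaolinite doublet (3695, 3620 cm⁻¹) and
the general silicate band (780 cm⁻¹) as normalized corrected heights and
flags a sample when (both kaolinite bands, or the 780 band) exceed the
presence threshold *and* the carb band exceeds the "large" threshold —
mineral bands matter precisely because they overlap the carbohydrate peak.
Defaults (presence 5·10⁻⁵ cm, large-carb 8·10⁻⁴ cm) correspond to corrected
heights of ~0.015 and ~0.24 absorbance on a typical organic-matter spectrum
of area ~300; there is no community-standard numeric threshold, so the flag
is advisory and never deletes data — exclusion is a metadata decision
recorded in the run config.

## Calibration

Simple OLS of wet-chemistry composition (wt%) on normalized height, with
R² = 1 − SSE/SStot, the two-sided slope t-test p (identical to the F-test
with one predictor), and SEE = √(SSE/(n−2)). SEE is attached as the
constant per-sample prediction uncertainty — the conventional choice for a
calibration curve applied far from its design points; per-point prediction
intervals would understate shared calibration error and are deliberately
not the default. Estimates outside [0, 100] wt% are returned unclipped with
a warning: clipping would bias cross-sample comparisons. No weighting, no
intercept suppression.

The aromatic predictor is selected among arom15, arom16, and their *sum
used as a single x-variable* (not a two-covariate fit); candidates are
ranked by R² with ties preserving the listed order. Class exclusions:
OMG (glossy magazine, clay coating inflating the carb band) from the
carbohydrate fit, OFF (office paper, delignified pulp) from the aromatic
fit — with 58 standards, 54 enter each regression.

## Trend statistics

- *Surface summaries*: per-core mean and sample SD (n−1) over sections with
  midpoint depth ≤ 50 cm. Midpoint membership is the conventional choice
  for interval sections. Single-section cores carry no SD; cores with no
  qualifying section are omitted with a warning.
- *Latitude/temperature regressions*: unweighted OLS on per-core surface
  means (one point per core). Weighting by within-core SD was considered
  and rejected: the SDs describe real depth heterogeneity, not measurement
  error, so inverse-variance weighting would over-trust homogeneous cores.
- *Group contrasts*: Student's pooled-variance t (not Welch), df = n₁+n₂−2.
  Degenerate inputs are handled explicitly: singleton groups →
  not determinable (NaN with a warning); equal constant groups → t=0, p=1;
  zero pooled variance with unequal means → p=0 with a warning.
- *LOESS*: tricube-weighted local polynomial (degree 2, span 0.75 defaults),
  ceil(span·n) nearest points per query. The 95% band is a pointwise normal
  approximation from the local fit's equivalent-kernel standard error, with
  σ² estimated from the residuals using n − tr(L) approximate degrees of
  freedom; a t-based band would differ imperceptibly at the dataset sizes
  involved. A degree-2 fit reproduces globally quadratic data exactly,
  which the tests exploit as an oracle.
- *PCA*: spectra rescaled so each integrates to exactly 100 (samples with
  non-positive area excluded with a warning), columns centered but not
  variance-scaled (the ordination convention for spectra, where the
  wavenumber variables share units), full SVD. Loading signs are fixed by
  making each component's largest-magnitude element positive, for
  reproducibility.
- *External vectors*: each variable is regressed (with intercept) on the
  first two score axes; the arrow is the normalized coefficient vector, its
  R² the fit quality, and significance is a permutation p over row shuffles
  of the variable, (hits+1)/(n_perm+1), default n_perm = 999 with a
  mandatory seed. Depth, latitude and temperature are fitted on peat rows
  only (plants have no depth and their origin latitudes are nominal).
- *Latitude split*: high latitude means ≥ 45°N exactly, so a 45.x°N site is
  high-latitude.
- *Humification indices* (aromatic:carbohydrate and aliphatic:carbohydrate
  normalized-height ratios) are provided for comparison with the
  band-ratio literature; a non-positive carb height makes them undefined
  (NaN with a warning) rather than infinite.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (parameters, seed); repeated calls are
bit-identical.

*Spectra* are Gaussian band mixtures plus an affine baseline and white
absorbance noise. Gaussian shape (rather than Lorentzian/Voigt) is the
simplest shape with analytic area and is sufficient to exercise endpoint
logic; noise is added in absorbance, not transmittance, to keep the
ground-truth map linear. Composition-encoding spectra fix the total area at
300 absorbance·cm⁻¹ by topping up with a broad featureless band
(center 3400 cm⁻¹, σ 250 — an O–H-like background), so a band of normalized
height h is drawn with absolute height h·300 and the normalized height is
exact by construction.

*Calibration sets* (default n = 58: 4 OMG, 4 OFF, the rest round-robin over
six other classes) draw true compositions uniformly, map them to heights
through a linear map (10 000 wt%/cm for carbohydrates, 8 000 wt%/cm for the
summed aromatic bands — magnitudes placing normalized heights in the
few-×10⁻³ cm range typical of organic matter), and re-observe composition
with Gaussian noise. Defaults were chosen by inverting the headline fit
statistics of the reference wet-chemistry calibration this module emulates:
composition ranges (20–82 wt% carbohydrate, 10–30.4 wt% Klason lignin) and
noise SDs (9 and 5 wt%) give expected R² ≈ 0.80 and 0.58 with SEE ≈ 9 and
5 wt%. OMG standards carry an additive carb-height bias (clay band) and OFF
standards an aromatic bias (delignified pulp), so the class exclusions are
consequential. The aromatic composition is split between the two ring bands
with per-sample jitter (SD 0.08 of the 0.55/0.45 split) whose sum is exact,
reproducing the empirical fact that the summed predictor beats either band.

*Standard spectra* add a broad variable background band (1570 cm⁻¹, σ 100,
height uniform on 0.05–0.40 absorbance) under the aromatic region. Straight
baselines remove it almost entirely; raw heights absorb it. The height
range was set by an attenuation calculation — the added x-noise on the raw
summed predictor (~5.6·10⁻⁴ cm SD) attenuates the aromatic R² by a factor
of ~0.64, reproducing the observed degradation of an uncorrected aromatic
calibration, while the carbohydrate band sits on clean background and its
fit is essentially unchanged. Residual background curvature leaves a few
percent bias in corrected aromatic heights; tests tolerate this
(it is physical — straight baselines are approximations under broad
features).

*Transects* (default 12 cores, 4–68°N, sections every 10 cm to 145 cm,
3 plants per core) encode surface composition linear in latitude
(+0.4 wt%/° carbohydrates from 42 wt% at the equator; −0.45 wt%/° aromatics
from 48 wt%), a carbohydrate decline of −0.15 wt%/cm with depth in cores
≥ 45°N, and 5 wt% per-sample composition noise — magnitudes matching the
global contrast between *Sphagnum*-dominated northern peat and woody
(sub)tropical peat. Mean annual temperature is a crude latitudinal lapse
(28 − 0.45·lat °C). Plants are offset +8 wt% in carbohydrates relative to
surface peat. Transect spectra carry no baseline drift by default — drift
handling is validated at the unit level; adding it here would bias the
area normalization of every sample identically and obscure the slope
oracle.

What the generators do **not** emulate: Lorentzian/Voigt band shapes and
band asymmetry, ATR penetration-depth wavelength dependence, water-vapor
and CO₂ lines, correlated (pink) noise, band-position drift with
composition, and covariance between compound classes in real peat. Passing
tests therefore demonstrate correctness of the algorithms and statistics
under known ground truth, not instrument-grade accuracy on real spectra;
on real data the endpoint windows and silicate thresholds must be
calibrated to the instrument and sample set.

## Numerical choices and edge cases

- Ties in argmin/argmax (endpoints, peak position) break to the lowest
  wavenumber, everywhere.
- Endpoint windows must contain ≥ 3 grid points and must not touch the
  first/last sample (full-spectrum neighbors are needed for the minimum
  test and the second derivative).
- `total_area ≤ 0` refuses normalization with an error rather than emitting
  signed nonsense.
- Permutation p-values use the add-one estimator, so p ≥ 1/(n_perm+1) and a
  perfectly aligned variable cannot report p = 0.
- PCA explained variances use the n−1 convention; their sum equals the
  total variance of the preprocessed matrix to numerical precision.
- CSV round trips parse floats in round-trip mode so written spectra reload
  bit-identically.

## Problem sizes

The test suite and the acceptance script run everything at desk scale: the
58-standard calibration set, transects of 6–12 cores with 2–15 sections,
500-replicate parameter-recovery sweeps on height tables (no spectra), and
999 permutations for vector fits. The full suite runs in a few seconds; the
acceptance script in under ten.

## Known limitations

- Straight-line baselines under broad overlapping features leave a small
  correlated residual in corrected heights (quantified above); curve
  fitting / deconvolution of overlapping bands is out of scope.
- Whole-spectrum multivariate calibration (e.g. PLS) is deliberately not
  implemented; the method's premise is isolating individually interpretable
  bands.
- The LOESS band is pointwise, not simultaneous, and uses a normal rather
  than t reference.
- No JCAMP-DX reader; two-column CSV and spreadsheet-matrix workbooks only.
- Calibrations are linear and unweighted by construction; heteroscedastic
  wet-chemistry error is not modeled.
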