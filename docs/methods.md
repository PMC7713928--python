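# Methods

## Scope and model overview

`preyview` models how two kinds of reef-fish prey — a small goby with one or
two cone classes plus a possible blue cone, and a mysid shrimp with a single
visual pigment — perceive the colour, brightness and spatial pattern of
fish-sized objects under natural underwater light.  The pipeline is:
reflectance and irradiance spectra → receptor quantum catches →
receptor-noise-limited perceptual distances (JND units) → group-level
statistics (PERMANOVA, dispersion, bootstrap effect sizes) → acuity-limited
scene renderings.

All spectral computation happens on a working grid of 300–700 nm at 1 nm
with the trapezoid rule; this matches the normalisation window conventional
for ocular-media measurements and typical spectrometer output.  Irradiance is
quantal (photons · cm⁻² · s⁻¹ · nm⁻¹); an energy-to-quantal helper
(multiply by λ/hc) is provided for energy-calibrated input.

## Receptor model

Pigment absorbance uses the standard vitamin-A1 template: an α band
parameterised by λmax (peak normalised to 1) plus the small UV β band whose
position and width track λmax.  Only the A1 chromophore is implemented —
the modelled species are shallow-water marine — and the β band can be
disabled by flag.  Effective sensitivity is the pointwise product of the
template with the ocular-media transmission normalised to its maximum; the
product is deliberately not renormalised so a strongly filtering lens lowers
total sensitivity.  The same lens applies to all cone channels and the
achromatic channel (light traverses one lens); the mysid viewer has no
ocular-media term because none is measured for it (transmission assumed 1).

Built-in viewers: goby dichromat (531, 539 nm), goby trichromat (455, 531,
539 nm), both behind a logistic synthetic lens with T50 = 410.5 nm (the
midpoint of the measured 410–411 nm range; logistic rate 0.15 nm⁻¹, a sharp
teleost-like cut-off); mysid monochromat (520 nm).

## Noise and perceptual distances

Channel noise follows the receptor-noise-limited framework:
e_i = ω_ref · sqrt(η_ref / η_i) with the longest-wavelength channel as
reference.  Defaults are the framework's conventional values, because the
study system provides no direct measurements: Weber fraction ω = 0.1 on the
reference channel, achromatic Weber 0.1, equal cone abundances.  All are
configuration keys; conclusions about near-threshold contrasts should be
read as conditional on these defaults.  The achromatic channel is the summed
catch of the double-cone pair for the goby (double cones conventionally
subserve luminance) and the single channel for the mysid; the rule is
overridable.

Chromatic distance uses the exact di-/trichromatic noise-limited formulas on
log catch ratios; it is a pseudo-metric (symmetric, zero at identity;
triangle inequality exact in the dichromat case) and invariant to a common
scaling of the illuminant.  Von Kries normalisation is available but off by
default — the analysis this package implements does not use it, and with a
shared background it cancels exactly in dS.

Quantum catches are floored at 10⁻¹² of the illuminant-only catch so log
ratios stay finite for perfectly black synthetic patches.

## Bootstrap perceptual effect size

For two groups of individuals the bootstrap resamples individuals with
replacement within each group, forms per-channel geometric-mean catches
(arithmetic means available behind a flag for sensitivity analysis), and
measures dS and dL between the group means; 1000 replicates by default, 95%
percentile intervals, deterministic under a seed.  A patch is flagged
"likely discriminable" exactly when a CI lower bound exceeds the threshold
(default 1 JND).  Percentile intervals at field-realistic group sizes
(n ≈ 7–10) are expected to undercover slightly relative to nominal (the
bootstrap variance of a mean underestimates by (n−1)/n per group); the
acceptance suite measures the realised coverage rather than assuming 95%.

## Distance-matrix statistics

PERMANOVA is one-way: SS_total = N⁻¹Σ_{i<j}d²_ij, within-group sums
weighted by group size, pseudo-F from among/within mean squares, R² as the
among fraction, and p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm) under label
permutation (999 permutations by default; the +1 convention keeps the p-value
unbiased and bounded away from zero).  On univariate Euclidean data the
pseudo-F reduces exactly to the classical one-way ANOVA F, which the tests
exploit as an oracle; scikit-bio's independent implementation is used as a
cross-check, never as the implementation.

Pairwise post hoc tests rerun the statistic on group-pair submatrices with
multiplicity adjustment (Bonferroni default, Holm and Benjamini–Hochberg
available, delegated to statsmodels).  Dispersion homogeneity embeds the
distance matrix by principal coordinates (Gower double-centring +
eigendecomposition) and measures each point's distance to its group centroid
with the standard negative-eigenvalue correction (squared contributions of
negative-eigenvalue axes subtracted, floored at 0); the omnibus statistic is
a one-way ANOVA F on those distances with a label-permutation p.  Pairwise
dispersion contrasts use the same permutation machinery with adjustment —
a deliberate substitution for a studentized-range (Tukey HSD) follow-up,
avoiding quantile tables while keeping the Levene-extension design.

In the full pipeline the tests run per body patch on matrices of pairwise
JND distances between individuals (chromatic and achromatic separately);
each individual contributes one catch vector per patch.

## Acuity

The stereology chain: fractionator total T = Σ counts / asf; Scheaffer CE
implemented as the simple-random-sampling relative standard error of the
mean site count (the cited source gives no formula and no site-level data
are published to verify against); densities as totals over areas.
Anatomical SRP: focal length = Matthiessen's ratio × lens radius (default
2.55, the standard teleost value, exposed because published tables sometimes
imply a slightly different effective constant), retinal magnification
f·π/180 mm/deg, linear Nyquist density √D for a square lattice (hexagonal
option: √(2D/√3)), SRP = half the linear density per degree.  Shrinkage
correction is omitted (reported below 5% in the motivating data).
Behavioural (optomotor) acuity converts stripe width and reaction distance
to a subtended angle, 2·arctan(w/2d).

## Scene filtering

Scenes are single-channel linear-intensity rasters with a physical width and
viewing distance; display-encoded images must be gamma-decoded (exponent
2.2) first, enforced by an explicit state flag.  The filter multiplies the
2-D Fourier transform by MTF(ν) = exp(−3.56(αν)²) with α the viewer's MRA;
the constant 3.56 (≈3% contrast at the resolution limit ν = 1/α) is a named,
overridable parameter.  Frequencies are mapped to cycles/degree isotropically
using the horizontal angular scale of the scene.  No windowing or padding by
default (natural scenes without hard borders; FFT wraparound accepted); a
mirror-pad flag exists.  The DC term is untouched, so mean intensity is
preserved up to the final clip to [0, 1], and two passes with MRAs α₁, α₂
compose exactly into one pass at √(α₁² + α₂²).

## Synthetic data generator

The generator defines the study conditions the tests and acceptance checks
run under; it emulates structure, not photorealism.

- **Water column**: quantal surface spectrum (broad Gaussian peaking at
  520 nm, width 130 nm) attenuated as I(λ,z) = I₀(λ)e^{−K(λ)z} with a
  coastal-shaped K(λ): base 0.10 m⁻¹, UV term 2.4·e^{−(λ−300)/42}, red term
  0.04·e^{(λ−560)/40}.  These constants were fixed once so the photon-median
  wavelength of the preset sits at ~517–518 nm for 0–7.5 m, inside the
  512–520 nm band reported for shallow Caribbean reef water.
- **Species**: seven patch mean-reflectance templates (flat / sigmoidal
  long-pass "yellow" / Gaussian bump / dark-flat caricatures of real fish
  patches), five species with n = 10, 9, 7, 8, 8 individuals — the study
  design shape.  Individual variation is multiplicative log-normal with two
  components: a flat brightness factor (sd 0.05) and a smooth blue-red
  spectral tilt (same sd by default).  The tilt matters: a flat factor alone
  cancels exactly in log catch differences, leaving chromatic statistics
  with zero within-group variance; the tilt supplies realistic chromatic
  individual variation.
- **Calibrated scenarios**: `make_mimicry_scenario` builds a model/mimic
  pair whose *population geometric-mean* JND separation hits a target, by
  bisection on the depth of a smooth long-pass darkening of the mimic's
  target patches.  The calibration evaluates the population geometric-mean
  catches analytically (Gauss–Hermite quadrature over the tilt coefficient —
  the tilt enters the catch integral nonlinearly, so the expectation of the
  log catch is not the log catch at the mean reflectance), and the bisection
  runs to 0.01% before being checked against the 1% acceptance tolerance.
  Chromatic distance is the calibration target for di-/trichromats; the
  achromatic distance is used for the monochromat, whose chromatic distance
  is undefined.  Multi-JND chromatic targets are genuinely unreachable for
  the 531/539 goby dichromat — its two pigments are 8 nm apart, which is the
  biological point — and the generator raises rather than saturating
  silently.
- **Scenes**: textured background (Gaussian noise, sd 0.02) with an
  elliptical body; optional vertical bars implemented as a mean-preserving
  stripe modulation (dark bars, brighter interspaces) so a bar-less and a
  barred fish differ only in pattern, not mean brightness; optional dark
  eyespot with a bright surround ring.
- **MSP samples**: Normal λmax draws with presets for the measured rod
  (500.2 ± 1.48, n = 17) and cones (538.8 ± 1.28, n = 13; 530.9 ± 1.51,
  n = 21).

What the generator does *not* emulate: spatial correlation of reflectance
across patches, measurement error structure of real spectrometers, veiling
light and scattering, temporal vision, UV patterning.  Passing tests
demonstrate that the pipeline's statistics behave correctly under the
assumed data-generating process, not that any particular field system meets
those assumptions.

## Numerical choices and degenerate inputs

- Linear interpolation everywhere; out-of-range extension is zero for
  irradiance/sensitivity and endpoint-held for reflectance/transmission.
- λP50 and T50 interpolate linearly within the bracketing grid step; T50
  takes the last upward 0.5-crossing, robust to UV-side noise.
- Negative measured spectral values are clipped to zero with a logged
  warning; reflectance/transmission may overshoot 1 by up to 5% (white-
  standard calibration overshoot) but no more.
- An all-zero irradiance, a transmission that never crosses 50%, a
  single-group PERMANOVA, an all-zero distance matrix and a monochromat
  chromatic distance all raise typed errors rather than returning NaN.
- PERMANOVA with no variance anywhere reports F = 0, p = 1.
- Seeds: every stochastic routine takes either an integer seed or a shared
  `numpy` Generator; pipeline stage seeds derive from the run seed via
  `SeedSequence` with a stable CRC of the stage name, so results are
  independent of execution order.

## Problem sizes used in the acceptance run

The acceptance script uses 1000 null simulations (199 permutations each) for
the PERMANOVA type-I rate and 200 scenario repeats (1000 bootstrap
replicates each) for the 2-JND recovery — sizes chosen to bound the Monte
Carlo standard error of a 5% rejection rate below 0.7 percentage points and
of the coverage estimate below 2 points.

## Known limitations

- The receptor-noise parameters (Weber fractions, cone ratios) are assumed,
  not measured; absolute JND values scale directly with them.
- The dispersion test permutes distances-to-centroid rather than refitting
  the embedding per permutation; this matches the common implementation of
  the Levene-extension design but is approximate for strongly non-Euclidean
  matrices.
- Scene filtering treats the viewer as a shift-invariant linear system with
  a single-parameter MTF; contrast-sensitivity shape, photon noise and
  temporal dynamics are out of scope.
- The anatomical SRP chain is an upper bound on acuity (it assumes every
  ganglion-cell-layer cell samples the image).
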