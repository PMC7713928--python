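# preyview

Visual-ecology toolkit for testing mimicry hypotheses **through the eyes of
the intended receiver**.  The motivating system is aggressive mimicry on
Caribbean coral reefs: a predatory hamlet that resembles a harmless
butterflyfish can approach its prey — small gobies and mysid shrimp — without
triggering escape.  Whether the deception works depends not on how similar
the fish look to us, but on whether the *prey's* visual system can tell them
apart.  `preyview` implements that receiver-centred analysis end to end:

- **Spectra** — sampled irradiance/reflectance/transmission curves, with the
  field's summary statistics λ<sub>P50</sub> (photon-median wavelength of
  underwater light) and T<sub>50</sub> (lens 50% cut-off).
- **Receptors** — A1 visual-pigment absorbance templates (α + β band),
  ocular-media filtering, and built-in viewers: a goby dichromat
  (531/539 nm cones behind a ~410 nm cut-off lens), a goby trichromat
  (adds a 455 nm cone) and a mysid monochromat (520 nm).
- **Receptor-noise-limited discrimination** — quantum catches
  Q<sub>i</sub> = ∫R(λ)I(λ)S<sub>i</sub>(λ)dλ, chromatic distance dS and
  achromatic distance dL in just-noticeable-difference (JND) units, and the
  bootstrap perceptual effect size: resample individuals, take per-channel
  geometric-mean catches, and flag a body patch "likely discriminable" when
  the 95% CI of the distance lies above 1 JND.
- **Distance-matrix statistics** — one-way PERMANOVA (pseudo-F, R²,
  permutation p), pairwise post hoc tests with p-adjustment, and a
  Levene-style test of multivariate dispersion homogeneity via principal
  coordinates.
- **Acuity** — retinal ganglion-cell stereology (fractionator totals,
  Scheaffer's CE), anatomical spatial resolving power from peak cell density
  and Matthiessen's ratio, optomotor behavioural acuity, and angle
  conversions.
- **Scene rendering** — Fourier-domain filtering of scenes by the viewer's
  modulation transfer function MTF(ν) = exp(−3.56(αν)²), where α is the
  minimum resolvable angle: what a goby or a mysid actually sees at 25–50 cm.
- **Synthetic data** — a generator reproducing the statistical structure of
  the study design (5 species × 7 body patches × 7–10 individuals,
  depth-attenuated reef irradiance, MSP λ<sub>max</sub> samples, fish scenes
  with bars and eyespots), so the whole pipeline is testable without field
  data.

The core perceptual model assumes discrimination thresholds are set by
photoreceptor noise: for receptor channels with noise e<sub>i</sub> and log
catch differences Δf<sub>i</sub>, a dichromat's chromatic distance is
dS = |Δf₁ − Δf₂| / √(e₁² + e₂²), with the standard three-channel
generalisation for trichromats, and dL = |ln(Q<sub>L</sub>ᵃ/Q<sub>L</sub>ᵇ)|
/ e<sub>L</sub> for the luminance channel; dS = 1 JND is the nominal
detection threshold.

## Worked example

```python
import numpy as np
import preyview as pv
from preyview.synthetic import make_illuminant, make_mimicry_scenario, make_population
from preyview.rnl import QuantumCatchTable, bootstrap_coldist

# anatomical acuity of a goby retina (peak GCL density, lens diameter)
est = pv.srp_anatomical(peak_density=84000, lens_diameter=0.83)
print(f"anatomical SRP: {est.srp:.3f} cyc/deg  (MRA {est.mra:.3f} deg)")

# the synthetic reef water column
il = make_illuminant(depth=5.0)
print(f"lambda_P50 at 5 m: {pv.lambda_p50(il):.1f} nm")

# a calibrated model/mimic pair seen by the trichromatic goby
goby = pv.goby_trichromat()
model, mimic = make_mimicry_scenario(2.0, goby, il, seed=1)
pops = {"model": make_population(model, 1), "mimic": make_population(mimic, 2)}
table = QuantumCatchTable.from_populations(pops, il, goby)
res = bootstrap_coldist(table, "model", "mimic", patch=5, n_boot=1000, seed=0)
print(f"patch 5 dS = {res.mean_ds:.2f} JND, 95% CI ({res.ds_ci[0]:.2f}, {res.ds_ci[1]:.2f})")
print(f"likely discriminable: {res.discriminable(1.0)}")
```

prints

```
anatomical SRP: 2.677 cyc/deg  (MRA 0.374 deg)
lambda_P50 at 5 m: 517.1 nm
patch 5 dS = 1.98 JND, 95% CI (1.91, 2.05)
likely discriminable: True
```

The SRP is the Nyquist limit implied by the ganglion-cell mosaic (higher =
sharper vision; its reciprocal is the minimum resolvable angle in degrees).
λ<sub>P50</sub> ≈ 517 nm is blue-green light typical of shallow reef water.
The bootstrap says the two synthetic species sit ~2 JND apart in the goby's
colour space at that patch — above the 1 JND threshold, so the goby should
be able to tell them apart there.

Statistical tests follow the fit/results idiom:

```python
from preyview.multivariate import DistanceMatrix, Permanova
rng = np.random.default_rng(0)
pts = np.concatenate([rng.normal(0, 1, (8, 2)), rng.normal(1.5, 1, (8, 2))])
dm = DistanceMatrix.from_points(pts, groups=["a"] * 8 + ["b"] * 8)
print(Permanova(dm).fit(n_permutations=999, seed=0).summary())
```

```
One-way PERMANOVA (permutation MANOVA on a distance matrix)
  observations: 16   groups: 2
  df (among, within): (1, 14)
  pseudo-F: 17.9518
  R^2:      0.5618
  p-value:  0.0010  (999 permutations)
```

A `preyview` console script exposes the stages
(`simulate`, `qcatch`, `coldist`, `stats`, `acuity-anatomy`, `acuity-view`,
`run`); `preyview run --seed 1 --out results/` executes the full viewer ×
depth analysis on a simulated bundle and writes TSV tables, filtered PNG
scenes and a run manifest.

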