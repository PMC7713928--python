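"""Synthetic inputs with the statistical structure the analysis expects.

The generator emulates the study design of the field system: five reef-fish
species (two putative model-mimic pairs plus a non-mimic), seven homologous
body patches per fish, 7-10 individuals per species, depth-attenuated coastal
reef irradiance, microspectrophotometry lambda-max samples and simple fish
scenes with vertical bars and an eyespot.  Individual variation in reflectance
is multiplicative log-normal, which keeps reflectance positive and makes the
spread proportional to the mean, as in real spectrometer data.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .receptors import VisualSystem
from .rnl import (
    NoiseModel,
    achromatic_distance,
    catch_vector,
    chromatic_distance,
    receptor_noise,
)
from .scene import SceneImage
from .spectra import DEFAULT_GRID, Spectrum, WavelengthGrid, lambda_p50

__all__ = [
    "IlluminantSpec",
    "SpeciesSpec",
    "make_illuminant",
    "make_population",
    "make_mimicry_scenario",
    "make_msp_sample",
    "make_fish_scene",
    "MSP_PRESETS",
    "default_study_species",
    "flat_patch",
    "step_patch",
    "bump_patch",
    "dark_patch",
]

N_PATCHES = 7


# ---------------------------------------------------------------------------
# underwater irradiance


@dataclass(frozen=True)
class IlluminantSpec:
    """Surface irradiance and diffuse attenuation of a coastal water column.

    The defaults caricature shallow tropical reef water: a broad surface
    spectrum peaking in the blue-green and an attenuation curve with its
    minimum near 500 nm rising into the UV and the red, so that the
    photon-median wavelength (lambda_P50) of the transmitted light sits in the
    low 510s nm at reef depths.
    """

    depth: float = 0.0
    surface_peak: float = 520.0
    surface_width: float = 130.0
    k_base: float = 0.10
    k_uv_amp: float = 2.4
    k_uv_scale: float = 42.0
    k_red_amp: float = 0.04
    k_red_scale: float = 40.0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if min(self.k_base, self.k_uv_amp, self.k_uv_scale, self.k_red_amp,
               self.k_red_scale) <= 0:
            raise ValueError("attenuation parameters must be positive")

    def surface(self, grid: WavelengthGrid = DEFAULT_GRID) -> np.ndarray:
        wl = grid.wavelengths
        return np.exp(-(((wl - self.surface_peak) / self.surface_width) ** 2))

    def attenuation(self, grid: WavelengthGrid = DEFAULT_GRID) -> np.ndarray:
        """Diffuse attenuation K(lambda) in 1/m."""
        wl = grid.wavelengths
        return (
            self.k_base
            + self.k_uv_amp * np.exp(-(wl - 300.0) / self.k_uv_scale)
            + self.k_red_amp * np.exp((wl - 560.0) / self.k_red_scale)
        )


def make_illuminant(
    spec: IlluminantSpec | None = None,
    grid: WavelengthGrid = DEFAULT_GRID,
    depth: float | None = None,
) -> Spectrum:
    """Quantal downwelling irradiance I(l, z) = I_surface(l) exp(-K(l) z)."""
    spec = spec or IlluminantSpec()
    if depth is not None:
        spec = replace(spec, depth=depth)
    vals = spec.surface(grid) * np.exp(-spec.attenuation(grid) * spec.depth)
    return Spectrum(
        grid.wavelengths, vals, "irradiance_photons", name=f"illum_{spec.depth:g}m"
    )


# ---------------------------------------------------------------------------
# reflectance templates and species populations


def flat_patch(level: float, grid: WavelengthGrid = DEFAULT_GRID) -> np.ndarray:
    return np.full(grid.wavelengths.size, float(level))


def step_patch(
    edge: float = 500.0,
    low: float = 0.05,
    high: float = 0.6,
    softness: float = 12.0,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> np.ndarray:
    """Sigmoidal long-pass reflectance: the classic 'yellow patch' shape."""
    wl = grid.wavelengths
    return low + (high - low) / (1.0 + np.exp(-(wl - edge) / softness))


def bump_patch(
    center: float,
    width: float = 40.0,
    amplitude: float = 0.4,
    baseline: float = 0.08,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> np.ndarray:
    wl = grid.wavelengths
    return baseline + amplitude * np.exp(-(((wl - center) / width) ** 2))


def dark_patch(level: float = 0.05, grid: WavelengthGrid = DEFAULT_GRID) -> np.ndarray:
    return flat_patch(level, grid)


@dataclass(frozen=True)
class SpeciesSpec:
    """Per-patch mean reflectances plus log-normal individual variation.

    ``mean_reflectance`` maps patch id (1-7) to a mean reflectance sampled on
    ``grid``.  Individual variation is multiplicative log-normal with two
    components: a flat brightness factor (sd ``variation_sd``) and a smooth
    spectral tilt (sd ``shape_sd``, defaulting to ``variation_sd``).  The tilt
    is what gives individuals chromatic -- not just achromatic -- spread: a
    flat factor alone cancels exactly in log catch differences and would leave
    every chromatic statistic with zero within-group variance.
    """

    label: str
    mean_reflectance: Mapping[int, np.ndarray]
    n_individuals: int = 8
    variation_sd: float | Mapping[int, float] = 0.05
    shape_sd: float | Mapping[int, float] | None = None
    grid: WavelengthGrid = DEFAULT_GRID

    def __post_init__(self) -> None:
        if set(self.mean_reflectance.keys()) != set(range(1, N_PATCHES + 1)):
            raise ValueError(f"species must define patches 1..{N_PATCHES}")
        if self.n_individuals < 2:
            raise ValueError("need n_individuals >= 2")
        for p, r in self.mean_reflectance.items():
            arr = np.asarray(r, float)
            if arr.shape != self.grid.wavelengths.shape:
                raise ValueError(f"patch {p} reflectance not on the species grid")
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError(f"patch {p} mean reflectance outside [0, 1]")

    @staticmethod
    def _lookup(value, patch: int) -> float:
        sd = float(value.get(patch, 0.0)) if isinstance(value, Mapping) else float(value)
        if sd < 0:
            raise ValueError("variation sd must be >= 0")
        return sd

    def sd_for(self, patch: int) -> float:
        return self._lookup(self.variation_sd, patch)

    def shape_sd_for(self, patch: int) -> float:
        src = self.variation_sd if self.shape_sd is None else self.shape_sd
        return self._lookup(src, patch)

    def with_patch(self, patch: int, mean: np.ndarray) -> "SpeciesSpec":
        new = dict(self.mean_reflectance)
        new[patch] = np.asarray(mean, float)
        return replace(self, mean_reflectance=new)


def _tilt(wl: np.ndarray) -> np.ndarray:
    """Smooth spectral tilt basis, -1 at the blue end to +1 at the red end."""
    return np.clip((wl - 500.0) / 200.0, -1.0, 1.0)


def make_population(
    spec: SpeciesSpec,
    seed: int | np.random.Generator | None = None,
) -> list[dict[int, Spectrum]]:
    """Draw a population.

    Individual i, patch p: R_ip(l) = clip(Rbar_p(l) * exp(a + b * tilt(l)), 0, 1)
    with a ~ Normal(0, sd_p^2) (brightness) and b ~ Normal(0, shape_sd_p^2)
    (spectral tilt).  Deterministic under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    wl = spec.grid.wavelengths
    tilt = _tilt(wl)
    out = []
    for i in range(spec.n_individuals):
        patches = {}
        for p in sorted(spec.mean_reflectance):
            a = rng.normal(0.0, spec.sd_for(p)) if spec.sd_for(p) > 0 else 0.0
            b = rng.normal(0.0, spec.shape_sd_for(p)) if spec.shape_sd_for(p) > 0 else 0.0
            vals = np.clip(
                spec.mean_reflectance[p] * np.exp(a + b * tilt), 0.0, 1.0
            )
            patches[p] = Spectrum(wl, vals, "reflectance", name=f"{spec.label}_p{p}")
        out.append(patches)
    return out


def default_study_species(
    grid: WavelengthGrid = DEFAULT_GRID,
    variation_sd: float = 0.05,
) -> list[SpeciesSpec]:
    """Five-species preset mirroring the study design shape.

    Two 'yellow' species (putative model-mimic pair 1), two 'dark' species
    (pair 2) and a barred generalist; sample sizes 10, 9, 7, 8, 8.
    """
    yellow = {
        1: step_patch(505, 0.06, 0.55, grid=grid),
        2: step_patch(500, 0.05, 0.6, grid=grid),
        3: bump_patch(560, 45, 0.35, 0.1, grid=grid),
        4: flat_patch(0.35, grid),
        5: step_patch(495, 0.07, 0.65, grid=grid),
        6: bump_patch(545, 50, 0.3, 0.12, grid=grid),
        7: dark_patch(0.08, grid),
    }
    dark = {
        1: dark_patch(0.05, grid),
        2: dark_patch(0.06, grid),
        3: bump_patch(620, 60, 0.08, 0.04, grid=grid),
        4: dark_patch(0.07, grid),
        5: dark_patch(0.05, grid),
        6: bump_patch(480, 50, 0.06, 0.05, grid=grid),
        7: dark_patch(0.04, grid),
    }
    barred = {
        1: step_patch(510, 0.05, 0.5, grid=grid),
        2: dark_patch(0.06, grid),
        3: flat_patch(0.4, grid),
        4: bump_patch(580, 40, 0.3, 0.08, grid=grid),
        5: step_patch(500, 0.06, 0.55, grid=grid),
        6: dark_patch(0.05, grid),
        7: flat_patch(0.3, grid),
    }

    def shifted(base: Mapping[int, np.ndarray], factor: float) -> dict[int, np.ndarray]:
        return {p: np.clip(r * factor, 0.0, 1.0) for p, r in base.items()}

    return [
        SpeciesSpec("barred_nonmimic", barred, 10, variation_sd, grid=grid),
        SpeciesSpec("dark_mimic", shifted(dark, 1.15), 9, variation_sd, grid=grid),
        SpeciesSpec("yellow_mimic", shifted(yellow, 0.95), 7, variation_sd, grid=grid),
        SpeciesSpec("yellow_model", yellow, 8, variation_sd, grid=grid),
        SpeciesSpec("dark_model", dark, 8, variation_sd, grid=grid),
    ]


# ---------------------------------------------------------------------------
# calibrated model/mimic scenario


def _geomean_catches(
    spec: SpeciesSpec,
    patch: int,
    system: VisualSystem,
    illuminant: Spectrum,
) -> np.ndarray:
    """Population geometric-mean quantum catches for one patch.

    The tilt component of the individual variation enters the catch integral
    nonlinearly, so E[log Q] differs from log Q at the mean reflectance
    (Jensen's inequality); it is evaluated by Gauss-Hermite quadrature over
    the tilt coefficient.  The flat brightness factor has zero log-mean and
    drops out.  Clipping at reflectance 1 is ignored (accurate away from
    saturation).
    """
    wl = spec.grid.wavelengths
    tilt = _tilt(wl)
    sd = spec.shape_sd_for(patch)
    base = np.asarray(spec.mean_reflectance[patch], float)
    from .spectra import resample as _resample

    i_vals = _resample(illuminant, spec.grid).values
    sens = np.stack([s.values for s in system.sensitivities(spec.grid)])
    weight = i_vals[None, :] * sens
    if sd == 0:
        q = np.trapezoid(base[None, :] * weight, wl, axis=1)
        return np.maximum(q, 1e-300)
    nodes, wts = np.polynomial.hermite_e.hermegauss(21)
    log_q = np.zeros(system.n_channels)
    for b, w in zip(sd * nodes, wts / np.sqrt(2.0 * np.pi)):
        refl = base * np.exp(b * tilt)
        q = np.trapezoid(refl[None, :] * weight, wl, axis=1)
        log_q += w * np.log(np.maximum(q, 1e-300))
    return np.exp(log_q)


def _mean_separation(
    model: SpeciesSpec,
    mimic: SpeciesSpec,
    patch: int,
    system: VisualSystem,
    illuminant: Spectrum,
    noise: NoiseModel,
) -> float:
    """JND distance between the population geometric-mean catches of a patch."""
    qa = _geomean_catches(model, patch, system, illuminant)
    qb = _geomean_catches(mimic, patch, system, illuminant)
    if system.n_channels >= 2:
        return chromatic_distance(qa, qb, noise)
    return achromatic_distance(qa, qb, system, noise)


def make_mimicry_scenario(
    separation_jnd: float,
    system: VisualSystem,
    illuminant: Spectrum,
    seed: int | None = None,
    patches: Sequence[int] = (5,),
    n_model: int = 8,
    n_mimic: int = 8,
    variation_sd: float = 0.05,
    grid: WavelengthGrid = DEFAULT_GRID,
    tolerance: float = 0.01,
    max_iter: int = 50,
) -> tuple[SpeciesSpec, SpeciesSpec]:
    """Model/mimic species pair with a calibrated perceptual separation.

    Starting from a shared yellow-patch phenotype, the mimic's mean
    reflectance on each target patch is darkened long-wave of ~520 nm by a
    factor exp(-t); t is found by bisection so that the JND distance between
    the noiseless patch means (chromatic for di-/trichromats, achromatic for a
    monochromat) hits ``separation_jnd`` within ``tolerance`` (relative).
    ``separation_jnd = 0`` returns statistically identical populations.
    """
    if separation_jnd < 0:
        raise ValueError("separation_jnd must be >= 0")
    bad = [p for p in patches if not (1 <= p <= N_PATCHES)]
    if bad:
        raise ValueError(f"patch ids out of range: {bad}")
    base = {
        1: step_patch(505, 0.06, 0.55, grid=grid),
        2: step_patch(500, 0.05, 0.6, grid=grid),
        3: bump_patch(560, 45, 0.35, 0.1, grid=grid),
        4: flat_patch(0.35, grid),
        5: step_patch(495, 0.07, 0.65, grid=grid),
        6: bump_patch(545, 50, 0.3, 0.12, grid=grid),
        7: flat_patch(0.25, grid),
    }
    model = SpeciesSpec("model", base, n_model, variation_sd, grid=grid)
    mimic = SpeciesSpec("mimic", dict(base), n_mimic, variation_sd, grid=grid)
    if separation_jnd == 0:
        return model, mimic

    noise = receptor_noise(system)
    wl = grid.wavelengths
    # smooth long-pass perturbation weight: 0 below ~500 nm, 1 above ~540 nm
    weight = 1.0 / (1.0 + np.exp(-(wl - 520.0) / 10.0))

    def apply(t: float) -> SpeciesSpec:
        out = mimic
        for p in patches:
            perturbed = base[p] * np.exp(-t * weight)
            out = out.with_patch(p, np.clip(perturbed, 0.0, 1.0))
        return out

    def achieved(t: float) -> float:
        cand = apply(t)
        vals = [
            _mean_separation(model, cand, p, system, illuminant, noise)
            for p in patches
        ]
        return float(np.mean(vals))

    t_hi = 1.0
    while achieved(t_hi) < separation_jnd:
        t_hi *= 2.0
        if t_hi > 64.0:
            raise ValueError(
                f"separation of {separation_jnd} JND unreachable for viewer "
                f"{system.label!r} (reflectance saturated)"
            )
    t_lo = 0.0
    t_mid = 0.5 * t_hi
    for _ in range(max_iter):
        t_mid = 0.5 * (t_lo + t_hi)
        d = achieved(t_mid)
        if abs(d - separation_jnd) <= 1e-4 * separation_jnd:
            break
        if d < separation_jnd:
            t_lo = t_mid
        else:
            t_hi = t_mid
    d = achieved(t_mid)
    if abs(d - separation_jnd) > tolerance * separation_jnd:
        raise ValueError(
            f"mimicry-scenario calibration did not converge: achieved {d:.4f} "
            f"for target {separation_jnd}"
        )
    return model, apply(t_mid)


# ---------------------------------------------------------------------------
# microspectrophotometry samples

#: (mean lambda_max nm, sd nm, study sample size)
MSP_PRESETS = {
    "rod": (500.2, 1.48, 17),
    "cone_539": (538.8, 1.28, 13),
    "cone_531": (530.9, 1.51, 21),
}


def make_msp_sample(
    n: int,
    mean_lambda_max: float,
    sd: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Normal lambda-max draws emulating a microspectrophotometry sample."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.normal(mean_lambda_max, sd, size=n)


# ---------------------------------------------------------------------------
# fish scenes


def make_fish_scene(
    width_px: int = 256,
    height_px: int = 160,
    bars: int = 0,
    eyespot: bool = False,
    body_contrast: float = 0.25,
    noise_sd: float = 0.02,
    physical_width: float = 40.0,
    viewing_distance: float = 25.0,
    seed: int | np.random.Generator | None = None,
) -> SceneImage:
    """Textured scene with an elliptical fish body and optional markings.

    ``bars`` dark vertical bars across the body emulate a barred phenotype;
    ``eyespot`` adds a dark posterior spot with a bright surround ring.
    Output is linear intensity with seeded background noise.
    """
    if width_px < 64 or height_px < 64:
        raise ValueError("scene must be at least 64 x 64 pixels")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height_px, 0:width_px]
    img = 0.45 + rng.normal(0.0, noise_sd, size=(height_px, width_px))

    cx, cy = width_px * 0.5, height_px * 0.5
    ax, ay = width_px * 0.32, height_px * 0.22
    body = (((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2) <= 1.0
    img[body] = 0.45 + body_contrast

    if bars > 0:
        # mean-preserving stripe modulation: dark bars, brighter interspaces
        span = 1.6 * ax
        period = span / bars
        phase = ((xx - (cx - 0.8 * ax)) % period) < 0.5 * period
        in_span = body & (np.abs(xx - cx) < 0.8 * ax)
        img[in_span & phase] = 0.45
        img[in_span & ~phase] = 0.45 + 2 * body_contrast

    if eyespot:
        ex, ey = cx + 0.75 * ax, cy
        r = 0.28 * ay
        dist = np.hypot(xx - ex, yy - ey)
        img[dist <= 1.8 * r] = min(0.45 + body_contrast + 0.25, 1.0)  # bright ring
        img[dist <= r] = 0.05  # dark centre

    return SceneImage(
        np.clip(img, 0.0, 1.0),
        physical_width=physical_width,
        viewing_distance=viewing_distance,
        gamma_state="linear",
    )
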