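"""Sampled spectra and the summary statistics used throughout the pipeline.

A :class:`Spectrum` is a sampled function of wavelength (nm) with a declared
quantity kind.  Irradiance is always quantal (photons cm^-2 s^-1 nm^-1); energy
units must be converted with :func:`energy_to_quantal` before use, because
quantum catches count photons, not energy.

Two field-standard summary statistics live here:

* ``lambda_p50`` -- the wavelength that halves the cumulative photon count of
  an irradiance spectrum, the classic single-number description of underwater
  light colour.
* ``t50`` -- the 50% cut-off wavelength of an ocular-media transmission curve
  after normalisation to its maximum in the 300-700 nm window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "SPECTRUM_KINDS",
    "Spectrum",
    "WavelengthGrid",
    "resample",
    "integrate",
    "lambda_p50",
    "t50",
    "energy_to_quantal",
    "read_spectra_csv",
    "write_spectra_csv",
]

logger = logging.getLogger(__name__)

SPECTRUM_KINDS = ("irradiance_photons", "reflectance", "transmission", "sensitivity")

#: kinds whose values are bounded fractions (calibration overshoot tolerated)
_BOUNDED_KINDS = ("reflectance", "transmission")

WAVELENGTH_MIN = 300.0
WAVELENGTH_MAX = 750.0


class SpectrumError(ValueError):
    """Invalid spectral input."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Regular wavelength grid in nm.  Default: 300-700 nm at 1 nm."""

    start: float = 300.0
    stop: float = 700.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if not (self.start < self.stop):
            raise SpectrumError(f"grid start {self.start} must be < stop {self.stop}")
        if self.step <= 0:
            raise SpectrumError(f"grid step must be positive, got {self.step}")

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)


#: the working grid used by default across the package
DEFAULT_GRID = WavelengthGrid()


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectrum: strictly increasing wavelengths (nm) and values.

    Negative values (spectrometer noise near zero) are clipped to 0 with a
    logged warning rather than rejected.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "reflectance"
    name: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise SpectrumError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise SpectrumError("a spectrum needs at least 2 samples")
        if not np.all(np.diff(wl) > 0):
            raise SpectrumError("wavelengths must be strictly increasing")
        if wl[0] < WAVELENGTH_MIN or wl[-1] > WAVELENGTH_MAX:
            raise SpectrumError(
                f"wavelengths must lie within [{WAVELENGTH_MIN:g}, {WAVELENGTH_MAX:g}] nm"
            )
        if self.kind not in SPECTRUM_KINDS:
            raise SpectrumError(f"unknown spectrum kind {self.kind!r}")
        if not np.all(np.isfinite(vals)):
            raise SpectrumError("spectrum values must be finite")
        if np.any(vals < 0):
            logger.warning(
                "spectrum %r: clipping %d negative values to 0",
                self.name,
                int(np.sum(vals < 0)),
            )
            vals = np.clip(vals, 0.0, None)
        if self.kind in _BOUNDED_KINDS and np.any(vals > 1.05):
            raise SpectrumError(
                f"{self.kind} values must be <= 1.05, max is {vals.max():.4g}"
            )
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "Spectrum":
        return Spectrum(self.wavelengths, values, kind or self.kind, self.name)

    def scaled(self, factor: float) -> "Spectrum":
        return self.with_values(self.values * factor)


def resample(spectrum: Spectrum, grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """Linearly interpolate ``spectrum`` onto ``grid``.

    Outside the measured range, irradiance and sensitivity fall to zero (no
    photons / no absorbance measured) while reflectance and transmission hold
    their endpoint value (a surface property does not vanish off-range).
    """
    wl = grid.wavelengths
    if spectrum.wavelengths[-1] < wl[0] or spectrum.wavelengths[0] > wl[-1]:
        raise SpectrumError("spectrum does not overlap the target grid")
    if spectrum.kind in ("irradiance_photons", "sensitivity"):
        vals = np.interp(wl, spectrum.wavelengths, spectrum.values, left=0.0, right=0.0)
    else:
        vals = np.interp(wl, spectrum.wavelengths, spectrum.values)
    return Spectrum(wl, vals, spectrum.kind, spectrum.name)


def integrate(spectrum: Spectrum) -> float:
    """Trapezoidal integral of the spectrum over its support."""
    return float(np.trapezoid(spectrum.values, spectrum.wavelengths))


def lambda_p50(irradiance: Spectrum) -> float:
    """Wavelength that halves the cumulative photon count of an irradiance.

    Computed as the first wavelength at which the cumulative trapezoidal
    integral reaches half the total, with linear interpolation inside the
    bracketing step.  Invariant under positive scaling of the spectrum.
    """
    if irradiance.kind != "irradiance_photons":
        raise SpectrumError("lambda_p50 requires an irradiance_photons spectrum")
    wl, vals = irradiance.wavelengths, irradiance.values
    cum = cumulative_trapezoid(vals, wl, initial=0.0)
    total = cum[-1]
    if total <= 0:
        raise SpectrumError("lambda_p50 undefined for an all-zero spectrum")
    half = 0.5 * total
    idx = int(np.searchsorted(cum, half))
    if idx == 0:
        return float(wl[0])
    # linear interpolation of the cumulative curve within the bracketing step
    frac = (half - cum[idx - 1]) / (cum[idx] - cum[idx - 1])
    return float(wl[idx - 1] + frac * (wl[idx] - wl[idx - 1]))


def t50(transmission: Spectrum) -> float:
    """50% cut-off of a transmission curve, normalised to its 300-700 nm max.

    Returns the longest-wavelength upward crossing of 0.5 on the rising limb,
    which is robust to short-wavelength noise in lens transmission scans.
    """
    if transmission.kind != "transmission":
        raise SpectrumError("t50 requires a transmission spectrum")
    wl, vals = transmission.wavelengths, transmission.values
    window = (wl >= 300.0) & (wl <= 700.0)
    if not np.any(window) or vals[window].max() <= 0:
        raise SpectrumError("t50 undefined: no positive transmission in 300-700 nm")
    norm = vals / vals[window].max()
    below = norm[:-1] < 0.5
    above = norm[1:] >= 0.5
    crossings = np.nonzero(below & above)[0]
    if crossings.size == 0:
        raise SpectrumError("t50 undefined: transmission never crosses 50%")
    i = int(crossings[-1])
    frac = (0.5 - norm[i]) / (norm[i + 1] - norm[i])
    return float(wl[i] + frac * (wl[i + 1] - wl[i]))


_HC = 1.98644586e-16  # h*c in J*nm


def energy_to_quantal(spectrum: Spectrum) -> Spectrum:
    """Convert an energy-unit irradiance to photon units (multiply by lambda/hc)."""
    vals = spectrum.values * spectrum.wavelengths / _HC
    return Spectrum(spectrum.wavelengths, vals, "irradiance_photons", spectrum.name)


def read_spectra_csv(
    path: str | Path, kind: str = "reflectance"
) -> list[Spectrum]:
    """Read spectra from CSV: first column ``wl`` (nm), one spectrum per column."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SpectrumError(f"{path}: need a wavelength column plus >=1 spectrum")
    wl_col = df.columns[0]
    try:
        wl = df[wl_col].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise SpectrumError(f"{path}: non-numeric wavelength column: {exc}") from exc
    steps = np.diff(wl)
    if np.any(steps <= 0):
        row = int(np.argmax(steps <= 0)) + 1
        raise SpectrumError(f"{path}: wavelengths not strictly increasing at row {row}")
    spectra = []
    for col in df.columns[1:]:
        try:
            vals = df[col].astype(float).to_numpy()
        except (TypeError, ValueError) as exc:
            raise SpectrumError(f"{path}: non-numeric cell in column {col!r}: {exc}") from exc
        spectra.append(Spectrum(wl, vals, kind, name=str(col)))
    return spectra


def write_spectra_csv(path: str | Path, spectra: Sequence[Spectrum]) -> None:
    """Write spectra sharing a wavelength axis to CSV (column ``wl`` first)."""
    if not spectra:
        raise SpectrumError("no spectra to write")
    wl = spectra[0].wavelengths
    for s in spectra[1:]:
        if s.wavelengths.shape != wl.shape or not np.allclose(s.wavelengths, wl):
            raise SpectrumError("all spectra must share one wavelength axis")
    data = {"wl": wl}
    for i, s in enumerate(spectra):
        data[s.name or f"spectrum_{i + 1}"] = s.values
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.8g")
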