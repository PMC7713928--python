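"""Spatial-resolution estimation from retinal anatomy and behaviour.

Anatomical spatial resolving power (SRP, cycles/degree) follows the classic
ganglion-cell stereology chain: total ganglion-cell-layer cells estimated from
systematically sampled count sites and the areal sampling fraction; peak cell
density converted to a linear Nyquist density; focal length from the lens via
Matthiessen's ratio (f ~ 2.55 x lens radius in teleosts).  The minimum
resolvable angle (MRA, degrees) is the reciprocal of SRP.  Behavioural acuity
comes from optomotor stripe-following: the subtended angle of the finest
followed stripe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RetinaSample",
    "AcuityEstimate",
    "total_cells",
    "scheaffer_ce",
    "mean_density",
    "srp_anatomical",
    "mra_from_srp",
    "optomotor_mra",
    "subtended_angle",
    "read_retina_sample",
]

#: standard teleost Matthiessen ratio: focal length = ratio x lens radius
MATTHIESSEN_RATIO = 2.55


@dataclass(frozen=True)
class RetinaSample:
    """Stereology counts for one retina.

    ``site_counts`` are per-site cell counts from systematic sampling,
    ``asf`` the areal sampling fraction, ``retinal_area`` in mm^2 and
    ``lens_diameter`` in mm.
    """

    site_counts: tuple[float, ...]
    asf: float
    retinal_area: float
    lens_diameter: float

    def __post_init__(self) -> None:
        counts = tuple(float(c) for c in self.site_counts)
        if len(counts) < 1:
            raise ValueError("need at least one count site")
        if any(c < 0 for c in counts):
            raise ValueError("site counts must be non-negative")
        if not (0 < self.asf <= 1):
            raise ValueError("asf must lie in (0, 1]")
        if self.retinal_area <= 0 or self.lens_diameter <= 0:
            raise ValueError("retinal_area and lens_diameter must be positive")
        object.__setattr__(self, "site_counts", counts)


@dataclass(frozen=True)
class AcuityEstimate:
    """Spatial resolving power (cycles/degree) and its reciprocal MRA (degrees)."""

    srp: float
    source: str = "anatomical"

    def __post_init__(self) -> None:
        if self.srp <= 0:
            raise ValueError("srp must be positive")

    @property
    def mra(self) -> float:
        return 1.0 / self.srp


def total_cells(sample: RetinaSample) -> float:
    """Fractionator estimate of the total cell population: sum(counts) / asf."""
    return float(sum(sample.site_counts) / sample.asf)


def scheaffer_ce(sample: RetinaSample) -> float:
    """Coefficient of error of the count: the simple-random-sampling relative
    standard error of the mean site count, (s / sqrt(n)) / mean."""
    counts = np.asarray(sample.site_counts)
    if counts.size < 2:
        raise ValueError("CE needs at least 2 sites")
    m = counts.mean()
    if m == 0:
        raise ValueError("CE undefined for an all-zero count")
    return float(counts.std(ddof=1) / math.sqrt(counts.size) / m)


def mean_density(total: float, area: float) -> float:
    """Mean areal cell density (cells/mm^2) = total / retinal area."""
    if area <= 0:
        raise ValueError("area must be positive")
    return float(total / area)


def srp_anatomical(
    peak_density: float,
    lens_diameter: float,
    matthiessen: float = MATTHIESSEN_RATIO,
    lattice: str = "square",
) -> AcuityEstimate:
    """Upper-limit SRP from peak ganglion-cell density and lens size.

    Focal length f = matthiessen x lens radius; retinal magnification
    f * pi / 180 mm per degree; linear Nyquist density sqrt(D) cells/mm for a
    square lattice (sqrt(2 D / sqrt(3)) for hexagonal); SRP is half the linear
    density of cells per degree.
    """
    if peak_density <= 0 or lens_diameter <= 0 or matthiessen <= 0:
        raise ValueError("inputs must be positive")
    focal = matthiessen * lens_diameter / 2.0
    magnification = focal * math.pi / 180.0  # mm per degree of visual angle
    if lattice == "square":
        linear = math.sqrt(peak_density)
    elif lattice == "hexagonal":
        linear = math.sqrt(2.0 * peak_density / math.sqrt(3.0))
    else:
        raise ValueError(f"unknown lattice {lattice!r}")
    srp = linear * magnification / 2.0
    return AcuityEstimate(srp=srp, source="anatomical")


def mra_from_srp(srp: float) -> float:
    """Minimum resolvable angle in degrees: 1 / SRP."""
    if srp <= 0:
        raise ValueError("srp must be positive")
    return 1.0 / srp


def optomotor_mra(stripe_width: float, distance: float) -> float:
    """Behavioural MRA from optomotor following: 2 atan(w / 2d), degrees."""
    if stripe_width <= 0 or distance <= 0:
        raise ValueError("stripe width and distance must be positive")
    return math.degrees(2.0 * math.atan(0.5 * stripe_width / distance))


def subtended_angle(actual_width: float, viewing_distance: float) -> float:
    """Visual angle (degrees) of an object of given width at a given distance."""
    if actual_width <= 0 or viewing_distance <= 0:
        raise ValueError("width and distance must be positive")
    return math.degrees(2.0 * math.atan(actual_width / (2.0 * viewing_distance)))


def read_retina_sample(counts_csv: str | Path, meta_yaml: str | Path) -> RetinaSample:
    """Read a retina sample from a (site_id, count) CSV plus YAML metadata
    (asf, retinal_area, lens_diameter)."""
    df = pd.read_csv(counts_csv)
    if "count" not in df.columns:
        raise ValueError(f"{counts_csv}: expected a 'count' column")
    meta = yaml.safe_load(Path(meta_yaml).read_text())
    return RetinaSample(
        site_counts=tuple(df["count"].astype(float)),
        asf=float(meta["asf"]),
        retinal_area=float(meta["retinal_area"]),
        lens_diameter=float(meta["lens_diameter"]),
    )
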