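"""Pollen-volume quantification and floral-longevity estimation.

Pollen per floral unit is estimated from haemocytometer assays: pollen from a
known number of floral units is suspended in a known volume, grains in a small
aliquot are counted, and the count is scaled back up. Grain volume is the
ellipsoid

    V = (4/3) * pi * (A/2) * (B/2)**2

with major axis A and minor axis B (μm), averaged over measured grains.
The per-24 h pollen rate divides total volume per unit by floral longevity.

Longevity is estimated by a two-visit census of a fixed survey area under an
approximately stable flower population:

    L = (2a + (b - c)) / ((b - c) * d)

with a = open floral units at the first visit, b/c = newly opened / newly
closed units at the second visit, d = days between visits. As printed the
estimator is undefined for a perfectly stationary census (b = c); a turnover
variant (2a + (b - c)) / ((b + c) * d), which is defined in that case and
recovers the true lifetime for d = 1, is available behind ``method``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateObservationError,
    DomainError,
    InputError,
    InvalidEstimateError,
)

#: 1 μl = 1 mm³ = 1e9 μm³.
UM3_PER_UL = 1e9

LONGEVITY_METHODS = ("difference", "turnover")


@dataclass(frozen=True)
class PollenGrainDims:
    """Mean grain axis lengths (μm) for one species."""

    major_axis_um: float
    minor_axis_um: float
    n_grains_measured: int = 1

    def __post_init__(self) -> None:
        if self.minor_axis_um <= 0 or self.major_axis_um <= 0:
            raise DomainError("grain axes must be positive")
        if self.major_axis_um < self.minor_axis_um:
            raise DomainError(
                f"major axis ({self.major_axis_um}) < minor axis ({self.minor_axis_um})"
            )
        if self.n_grains_measured < 1:
            raise DomainError("n_grains_measured must be >= 1")


def grain_volume(dims: PollenGrainDims) -> float:
    """Ellipsoid volume (μm³) of a pollen grain; a sphere when A = B."""
    a, b = dims.major_axis_um, dims.minor_axis_um
    return (4.0 / 3.0) * math.pi * (a / 2.0) * (b / 2.0) ** 2


def mean_grain_volume(
    major_axes_um: Sequence[float], minor_axes_um: Sequence[float]
) -> float:
    """Mean of per-grain ellipsoid volumes (not the volume of mean axes)."""
    major = np.asarray(major_axes_um, dtype=float)
    minor = np.asarray(minor_axes_um, dtype=float)
    if major.shape != minor.shape or major.size == 0:
        raise InputError("major and minor axis arrays must be non-empty and aligned")
    vols = [
        grain_volume(PollenGrainDims(a, b)) for a, b in zip(major, minor)
    ]
    return float(np.mean(vols))


@dataclass(frozen=True)
class PollenAssay:
    """One haemocytometer assay: grains counted in an aliquot of a suspension
    made from ``n_floral_units`` pooled floral units."""

    species: str
    aliquot_count: float
    aliquot_volume_ul: float
    suspension_volume_ul: float
    n_floral_units: int

    def __post_init__(self) -> None:
        if self.aliquot_volume_ul <= 0 or self.suspension_volume_ul <= 0:
            raise DomainError("assay volumes must be positive")
        if self.aliquot_volume_ul > self.suspension_volume_ul:
            raise DomainError("aliquot volume exceeds suspension volume")
        if self.aliquot_count < 0:
            raise DomainError("grain count cannot be negative")
        if self.n_floral_units < 1:
            raise DomainError("n_floral_units must be >= 1")


def grains_per_floral_unit(assay: PollenAssay) -> float:
    """Scale an aliquot count up to grains per floral unit."""
    per_ul = assay.aliquot_count / assay.aliquot_volume_ul
    return per_ul * assay.suspension_volume_ul / assay.n_floral_units


def pollen_volume_per_unit(grains: float, mean_grain_volume_um3: float) -> float:
    """Total pollen volume per floral unit (μl) = grains × mean grain volume."""
    if grains < 0 or mean_grain_volume_um3 < 0:
        raise DomainError("grains and grain volume must be non-negative")
    return grains * mean_grain_volume_um3 / UM3_PER_UL


@dataclass(frozen=True)
class LongevityObservation:
    """Two-visit census counts for the longevity estimator."""

    open_first: float  # a: open units at the first visit
    newly_open_second: float  # b: newly opened by the second visit
    newly_closed_second: float  # c: newly closed by the second visit
    interval_days: float  # d: days between visits

    def __post_init__(self) -> None:
        if min(self.open_first, self.newly_open_second, self.newly_closed_second) < 0:
            raise DomainError("census counts cannot be negative")
        if self.interval_days <= 0:
            raise DomainError("interval_days must be positive")


def floral_longevity(obs: LongevityObservation, method: str = "difference") -> float:
    """Floral longevity in days from a two-visit census.

    ``method="difference"`` applies the estimator as printed,
    (2a+(b−c))/((b−c)·d); it is undefined at b = c and negative for a
    shrinking census (b < c) — both are raised, never silently returned.
    ``method="turnover"`` uses (2a+(b−c))/((b+c)·d), defined for any census
    with turnover, which recovers the true lifetime of a stationary
    population observed at a 1-day interval.
    """
    if method not in LONGEVITY_METHODS:
        raise InputError(f"unknown longevity method {method!r}")
    a = obs.open_first
    b = obs.newly_open_second
    c = obs.newly_closed_second
    d = obs.interval_days
    numerator = 2.0 * a + (b - c)
    if method == "difference":
        if b == c:
            raise DegenerateObservationError(
                "longevity estimator undefined for a stationary census (b = c); "
                "consider method='turnover'"
            )
        denom = (b - c) * d
    else:
        if b + c == 0:
            raise DegenerateObservationError(
                "no turnover observed (b = c = 0); longevity unidentifiable"
            )
        denom = (b + c) * d
    estimate = numerator / denom
    if estimate <= 0:
        raise InvalidEstimateError(
            f"longevity estimate {estimate:.3g} days is non-positive "
            f"(a={a}, b={b}, c={c}, d={d}); observation rejected"
        )
    return estimate


def pollen_per_unit_per_day(volume_per_unit_ul: float, longevity_days: float) -> float:
    """Daily pollen presentation rate: total volume spread over floral life."""
    if longevity_days <= 0:
        raise DomainError(f"longevity must be positive, got {longevity_days!r}")
    if volume_per_unit_ul < 0:
        raise DomainError("pollen volume cannot be negative")
    return volume_per_unit_ul / longevity_days


@dataclass(frozen=True)
class SpeciesPollenEstimate:
    """Species-level pollen reward with its daily rate."""

    species: str
    volume_per_unit_ul: float
    sem_ul: float  # NaN when n == 1
    longevity_days: float
    volume_per_unit_per_day_ul: float
    n: int


def summarise_species_pollen(
    assays: Sequence[PollenAssay],
    dims: PollenGrainDims,
    longevity_days: float,
) -> SpeciesPollenEstimate:
    """Mean ± SEM pollen volume per floral unit across assays, plus the
    per-24 h rate obtained by dividing the mean by species longevity."""
    if not assays:
        raise InputError("summarise_species_pollen requires at least one assay")
    species = {a.species for a in assays}
    if len(species) != 1:
        raise InputError(f"assays mix species: {sorted(species)}")
    if longevity_days <= 0:
        raise DomainError("longevity must be positive")
    vol = grain_volume(dims)
    per_assay = np.array(
        [pollen_volume_per_unit(grains_per_floral_unit(a), vol) for a in assays]
    )
    n = per_assay.size
    mean = float(per_assay.mean())
    sem = float(per_assay.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
    return SpeciesPollenEstimate(
        species=assays[0].species,
        volume_per_unit_ul=mean,
        sem_ul=sem,
        longevity_days=longevity_days,
        volume_per_unit_per_day_ul=pollen_per_unit_per_day(mean, longevity_days),
        n=n,
    )


# ---------------------------------------------------------------------------
# delimited-text I/O

ASSAY_COLUMNS = [
    "species",
    "aliquot_count",
    "aliquot_volume_ul",
    "suspension_volume_ul",
    "n_floral_units",
]
DIMS_COLUMNS = ["species", "major_um", "minor_um", "n"]
LONGEVITY_COLUMNS = ["species", "a", "b", "c", "interval_days"]


def read_pollen_assays(path) -> dict[str, list[PollenAssay]]:
    df = pd.read_csv(path)
    _require(df, ASSAY_COLUMNS, "pollen assay")
    out: dict[str, list[PollenAssay]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.species, []).append(
            PollenAssay(
                species=row.species,
                aliquot_count=float(row.aliquot_count),
                aliquot_volume_ul=float(row.aliquot_volume_ul),
                suspension_volume_ul=float(row.suspension_volume_ul),
                n_floral_units=int(row.n_floral_units),
            )
        )
    return out


def read_grain_dims(path) -> dict[str, PollenGrainDims]:
    df = pd.read_csv(path)
    _require(df, DIMS_COLUMNS, "grain dimensions")
    return {
        row.species: PollenGrainDims(float(row.major_um), float(row.minor_um), int(row.n))
        for row in df.itertuples(index=False)
    }


def read_longevity_observations(path) -> dict[str, list[LongevityObservation]]:
    df = pd.read_csv(path)
    _require(df, LONGEVITY_COLUMNS, "longevity observation")
    out: dict[str, list[LongevityObservation]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.species, []).append(
            LongevityObservation(
                open_first=float(row.a),
                newly_open_second=float(row.b),
                newly_closed_second=float(row.c),
                interval_days=float(row.interval_days),
            )
        )
    return out


def species_longevity(
    observations: Iterable[LongevityObservation], method: str = "difference"
) -> float:
    """Single species-level longevity: mean over valid observations."""
    estimates = [floral_longevity(o, method=method) for o in observations]
    if not estimates:
        raise InputError("no longevity observations supplied")
    return float(np.mean(estimates))


def summarise_all_species(
    assays_by_species: dict[str, list[PollenAssay]],
    dims_by_species: dict[str, PollenGrainDims],
    longevity_by_species: dict[str, float],
) -> pd.DataFrame:
    """Per-species pollen summary table across a collection of assays."""
    rows = []
    for species in sorted(assays_by_species):
        if species not in dims_by_species:
            raise InputError(f"no grain dimensions for species {species!r}")
        if species not in longevity_by_species:
            raise InputError(f"no longevity for species {species!r}")
        est = summarise_species_pollen(
            assays_by_species[species],
            dims_by_species[species],
            longevity_by_species[species],
        )
        rows.append(
            {
                "species": est.species,
                "pollen_per_unit_ul": est.volume_per_unit_ul,
                "pollen_sem_ul": est.sem_ul,
                "longevity_days": est.longevity_days,
                "pollen_per_unit_day_ul": est.volume_per_unit_per_day_ul,
                "n": est.n,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species",
            "pollen_per_unit_ul",
            "pollen_sem_ul",
            "longevity_days",
            "pollen_per_unit_day_ul",
            "n",
        ],
    )


def _require(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = set(columns) - set(df.columns)
    if missing:
        raise InputError(f"{what} file missing columns: {sorted(missing)}")
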