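"""Nectar standing-crop quantification from refractometer assays.

Per-flower nectar rewards are measured as the sugar mass accumulated over a
fixed period (24 h standing crop, insects excluded). Two field protocols feed
this module:

* **direct** — nectar drawn into a microcapillary; its volume ``v`` (ml) and
  sugar concentration ``C`` (degrees Brix, g sucrose per 100 g solution) are
  read directly;
* **flush** — flowers too small to probe are flushed with a known volume of
  distilled water and the Brix of the resulting solution is read; the added
  water volume stands in for the solution volume (residual nectar volume is
  assumed negligible, a configurable correction is available).

Either way the sugar mass (mg) of a sample is

    s = 10 * d * v * C

where ``d`` is the density (g/ml) of a sucrose solution at concentration
``C``, obtained from the empirical polynomial

    d = 0.0037921*C + 0.0000178*C**2 + 0.9988603

Species-level summaries rescale each sample to a 24 h accumulation window and
report the mean sugar mass per floral unit in micrograms with +/- 1 SEM.
All-zero species (possible false zeros for hard-to-flush flowers) are kept and
flagged rather than dropped.

Unit conventions: file I/O uses microlitres for volumes; in-memory samples use
millilitres; per-sample masses are mg; species summaries are micrograms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InputError

#: Upper Brix bound of the density polynomial's calibration range (g/100 g).
BRIX_MAX = 85.0

#: Coefficients of the sucrose-solution density polynomial, low order first.
DENSITY_COEFFS = (0.9988603, 0.0037921, 0.0000178)

_PROTOCOLS = ("direct", "flush")


def sucrose_density(brix: float) -> float:
    """Density (g/ml) of a sucrose solution at concentration ``brix``.

    Parameters
    ----------
    brix : float
        Sugar concentration in degrees Brix (g sucrose / 100 g solution),
        valid on [0, 85].

    Returns
    -------
    float
        Solution density in g/ml; 0.9988603 (pure water) at ``brix=0`` and
        strictly increasing in ``brix``.
    """
    if not 0.0 <= brix <= BRIX_MAX:
        raise DomainError(
            f"Brix reading {brix!r} outside the calibrated range [0, {BRIX_MAX}]"
        )
    c0, c1, c2 = DENSITY_COEFFS
    return c0 + brix * (c1 + c2 * brix)


def nectar_sugar_mass(volume_ml: float, brix: float) -> float:
    """Sugar mass (mg) in a nectar sample: ``s = 10 * d * v * C``.

    ``volume_ml`` is the nectar (or flush solution) volume in ml and ``brix``
    the refractometer reading. Returns 0 when either is zero.
    """
    if volume_ml < 0:
        raise DomainError(f"negative nectar volume: {volume_ml!r} ml")
    return 10.0 * sucrose_density(brix) * volume_ml * brix


def flush_sugar_mass(
    flush_volume_ml: float,
    brix_of_solution: float,
    residual_nectar_ml: float = 0.0,
) -> float:
    """Sugar mass (mg) recovered by flushing a flower with distilled water.

    The solution volume is taken as the added water volume plus an optional
    ``residual_nectar_ml`` correction (default 0: nectar volume is assumed
    negligible relative to the flush).
    """
    if flush_volume_ml <= 0:
        raise DomainError(
            f"flush protocol requires a positive water volume, got {flush_volume_ml!r} ml"
        )
    if residual_nectar_ml < 0:
        raise DomainError(f"negative residual nectar volume: {residual_nectar_ml!r}")
    return nectar_sugar_mass(flush_volume_ml + residual_nectar_ml, brix_of_solution)


@dataclass(frozen=True)
class NectarSample:
    """One nectar assay of one floral unit.

    Exactly one of ``nectar_volume_ml`` (direct protocol) or
    ``flush_volume_ml`` (flush protocol) must be set, matching ``protocol``.
    """

    species: str
    protocol: str
    brix: float
    nectar_volume_ml: float | None = None
    flush_volume_ml: float | None = None
    accumulation_hours: float = 24.0

    def __post_init__(self) -> None:
        if self.protocol not in _PROTOCOLS:
            raise InputError(f"unknown nectar protocol {self.protocol!r}")
        if not 0.0 <= self.brix <= BRIX_MAX:
            raise DomainError(f"Brix {self.brix!r} outside [0, {BRIX_MAX}]")
        if self.accumulation_hours <= 0:
            raise DomainError(
                f"accumulation_hours must be positive, got {self.accumulation_hours!r}"
            )
        if self.protocol == "direct":
            if self.nectar_volume_ml is None or self.flush_volume_ml is not None:
                raise InputError(
                    "direct protocol requires nectar_volume_ml and no flush_volume_ml"
                )
            if self.nectar_volume_ml < 0:
                raise DomainError(f"negative nectar volume {self.nectar_volume_ml!r}")
        else:
            if self.flush_volume_ml is None or self.nectar_volume_ml is not None:
                raise InputError(
                    "flush protocol requires flush_volume_ml and no nectar_volume_ml"
                )
            if self.flush_volume_ml <= 0:
                raise DomainError(f"flush volume must be positive, got {self.flush_volume_ml!r}")

    def sugar_mass_mg(self) -> float:
        """Sugar mass (mg) of this sample, before 24 h rescaling."""
        if self.protocol == "direct":
            return nectar_sugar_mass(self.nectar_volume_ml, self.brix)
        return flush_sugar_mass(self.flush_volume_ml, self.brix)

    def sugar_ug_per_24h(self) -> float:
        """Sugar mass scaled linearly to a 24 h accumulation window, in μg."""
        return self.sugar_mass_mg() * 1000.0 * 24.0 / self.accumulation_hours


@dataclass(frozen=True)
class SpeciesNectarEstimate:
    """Species-level nectar reward: mean μg sugar per floral unit per 24 h."""

    species: str
    mean_sugar_ug: float
    sem_ug: float  # NaN when n == 1 (SEM undefined for a single sample)
    n: int
    zero_flagged: bool = False


def summarise_species_nectar(samples: Sequence[NectarSample]) -> SpeciesNectarEstimate:
    """Aggregate replicate nectar samples of one species.

    Each sample is rescaled to 24 h and converted to μg; the summary is the
    mean with SEM (sd/sqrt(n), NaN when n = 1). ``zero_flagged`` marks species
    for which every sample returned zero sugar — treated as a possible false
    zero, not as evidence of no secretion.
    """
    if not samples:
        raise InputError("summarise_species_nectar requires at least one sample")
    species = {s.species for s in samples}
    if len(species) != 1:
        raise InputError(f"samples mix species: {sorted(species)}")
    masses = np.array([s.sugar_ug_per_24h() for s in samples], dtype=float)
    n = masses.size
    mean = float(masses.mean())
    sem = float(masses.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
    return SpeciesNectarEstimate(
        species=samples[0].species,
        mean_sugar_ug=mean,
        sem_ug=sem,
        n=n,
        zero_flagged=bool(np.all(masses == 0.0)),
    )


# ---------------------------------------------------------------------------
# delimited-text I/O (volumes in μl in files, ml in memory)

CSV_COLUMNS = [
    "species",
    "protocol",
    "nectar_volume_ul",
    "flush_volume_ul",
    "brix_pct",
    "accumulation_h",
]


def read_nectar_samples(path) -> list[NectarSample]:
    """Read nectar samples from CSV (columns: species, protocol,
    nectar_volume_ul, flush_volume_ul, brix_pct, accumulation_h)."""
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"nectar sample file missing columns: {sorted(missing)}")
    samples = []
    for row in df.itertuples(index=False):
        direct = row.protocol == "direct"
        nectar_ul = row.nectar_volume_ul
        flush_ul = row.flush_volume_ul
        samples.append(
            NectarSample(
                species=row.species,
                protocol=row.protocol,
                brix=float(row.brix_pct),
                nectar_volume_ml=float(nectar_ul) / 1000.0 if direct else None,
                flush_volume_ml=float(flush_ul) / 1000.0 if not direct else None,
                accumulation_hours=float(row.accumulation_h),
            )
        )
    return samples


def samples_to_frame(samples: Iterable[NectarSample]) -> pd.DataFrame:
    """Long-format frame of samples using the file unit convention (μl)."""
    rows = []
    for s in samples:
        rows.append(
            {
                "species": s.species,
                "protocol": s.protocol,
                "nectar_volume_ul": None
                if s.nectar_volume_ml is None
                else s.nectar_volume_ml * 1000.0,
                "flush_volume_ul": None
                if s.flush_volume_ml is None
                else s.flush_volume_ml * 1000.0,
                "brix_pct": s.brix,
                "accumulation_h": s.accumulation_hours,
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def summarise_all_species(samples: Iterable[NectarSample]) -> pd.DataFrame:
    """Per-species summary table over a mixed-species sample collection."""
    by_species: dict[str, list[NectarSample]] = {}
    for s in samples:
        by_species.setdefault(s.species, []).append(s)
    rows = []
    for species in sorted(by_species):
        est = summarise_species_nectar(by_species[species])
        rows.append(
            {
                "species": est.species,
                "nectar_per_unit_day_ug": est.mean_sugar_ug,
                "nectar_sem_ug": est.sem_ug,
                "n": est.n,
                "zero_flagged": est.zero_flagged,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["species", "nectar_per_unit_day_ug", "nectar_sem_ug", "n", "zero_flagged"],
    )
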