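"""Pollinator-currency conversions for meadow pollen budgets.

Converts pollen volumes into masses (density 1.2 g/ml) and expresses daily
meadow production as honeybee-worker equivalents (~150 mg pollen rears one
worker), solitary-bee brood-cell equivalents (5.2–80 mg per cell depending on
body size), and fractions of the ~20 kg of pollen (and 120 kg of nectar) a
honeybee colony harvests per year. All conversions are linear; equivalents
are reported as real numbers, not floored counts.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError


@dataclass(frozen=True)
class EquivalenceConstants:
    pollen_density_g_per_ml: float = 1.2
    honeybee_worker_pollen_g: float = 0.150
    solitary_cell_pollen_range_g: tuple[float, float] = (0.0052, 0.080)
    colony_annual_pollen_kg: float = 20.0
    colony_annual_nectar_kg: float = 120.0
    meadow_area_m2: float = 300.0

    def __post_init__(self) -> None:
        values = (
            self.pollen_density_g_per_ml,
            self.honeybee_worker_pollen_g,
            *self.solitary_cell_pollen_range_g,
            self.colony_annual_pollen_kg,
            self.colony_annual_nectar_kg,
            self.meadow_area_m2,
        )
        if any(v <= 0 for v in values):
            raise DomainError("all equivalence constants must be positive")


DEFAULTS = EquivalenceConstants()


def pollen_volume_to_mass(
    volume_ml: float, constants: EquivalenceConstants = DEFAULTS
) -> float:
    """Pollen mass (g) from volume (ml); 1 kg/dm³ = 1 g/ml."""
    if volume_ml < 0:
        raise DomainError("pollen volume cannot be negative")
    return volume_ml * constants.pollen_density_g_per_ml


def meadow_daily_pollen_mass(
    per_m2_mass_g: float, constants: EquivalenceConstants = DEFAULTS
) -> float:
    """Whole-meadow daily pollen mass (g/day) from the per-m² rate."""
    if per_m2_mass_g < 0:
        raise DomainError("pollen mass cannot be negative")
    return per_m2_mass_g * constants.meadow_area_m2


def honeybee_worker_equivalents(
    daily_mass_g: float, constants: EquivalenceConstants = DEFAULTS
) -> float:
    """Workers/day a meadow's daily pollen could rear."""
    if daily_mass_g < 0:
        raise DomainError("pollen mass cannot be negative")
    return daily_mass_g / constants.honeybee_worker_pollen_g


def solitary_bee_cell_equivalents(daily_mass_g: float, per_cell_g: float) -> float:
    """Brood cells/day at a given pollen provision mass per cell."""
    if daily_mass_g < 0:
        raise DomainError("pollen mass cannot be negative")
    if per_cell_g <= 0:
        raise DomainError("per-cell pollen mass must be positive")
    return daily_mass_g / per_cell_g


def colony_requirement_fraction(
    season_total_mass_g: float,
    constants: EquivalenceConstants = DEFAULTS,
    resource: str = "pollen",
) -> float:
    """Season total as a fraction of a honeybee colony's annual harvest
    (20 kg pollen or 120 kg nectar by default)."""
    if season_total_mass_g < 0:
        raise DomainError("season total cannot be negative")
    if resource == "pollen":
        annual_kg = constants.colony_annual_pollen_kg
    elif resource == "nectar":
        annual_kg = constants.colony_annual_nectar_kg
    else:
        raise DomainError(f"unknown resource {resource!r}")
    return season_total_mass_g / (annual_kg * 1000.0)
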