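"""Quadrat-survey aggregation into meadow-level resource budgets.

Floral abundance is surveyed in 1 m² quadrats: each record is the count of
open floral units of one species in one quadrat of one site/treatment/round.
Joining counts to per-unit daily rewards (species resource profiles) gives

    resource per m²/day = sum over species of density (units/m²) × reward/unit/day
    resource per meadow/day = per-m² value × meadow area (default 300 m²)

Confidence intervals are propagated from between-quadrat count variation: the
per-quadrat total resource (counts × rewards summed within each quadrat) is
treated as the sampling unit and the CI is mean ± z·SE over quadrats.
Reward SEMs are not propagated.

Species without a resource profile ("unmeasured") are excluded from the sums;
a ``coverage`` statistic — the fraction of counted floral units belonging to
measured species — makes the omission visible.

The module also provides the sampling-effort machinery used to choose a
scheme: random subsampling of quadrats without replacement, and a paired
comparison of the full 20-quadrat scheme with the 7 edge-quadrat subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InputError

TREATMENTS = ("A1", "A2", "P", "C")
DEFAULT_MEADOW_AREA_M2 = 300.0

#: columns required in a long-format quadrat count table
COUNT_COLUMNS = ["site", "treatment", "round", "quadrat_id", "species", "count"]

#: columns of a species resource profile table
PROFILE_COLUMNS = [
    "species",
    "nectar_per_unit_day_ug",
    "pollen_per_unit_day_ul",
]


@dataclass(frozen=True)
class MeadowResourceEstimate:
    """Daily nectar/pollen budget of one meadow at one survey round.

    Nectar in mg (per m² and per meadow), pollen in μl. ``species_shares``
    maps resource name -> {species: proportion of that resource}.
    """

    site: str
    treatment: str
    round: int
    n_quadrats: int
    nectar_per_m2_day_mg: float
    nectar_ci_mg: tuple[float, float]
    pollen_per_m2_day_ul: float
    pollen_ci_ul: tuple[float, float]
    meadow_nectar_day_mg: float
    meadow_pollen_day_ul: float
    species_shares: dict[str, dict[str, float]]
    coverage: float
    area_m2: float = DEFAULT_MEADOW_AREA_M2

    def to_row(self) -> dict:
        return {
            "site": self.site,
            "treatment": self.treatment,
            "round": self.round,
            "n_quadrats": self.n_quadrats,
            "nectar_per_m2_day_mg": self.nectar_per_m2_day_mg,
            "nectar_ci_lo_mg": self.nectar_ci_mg[0],
            "nectar_ci_hi_mg": self.nectar_ci_mg[1],
            "pollen_per_m2_day_ul": self.pollen_per_m2_day_ul,
            "pollen_ci_lo_ul": self.pollen_ci_ul[0],
            "pollen_ci_hi_ul": self.pollen_ci_ul[1],
            "meadow_nectar_day_mg": self.meadow_nectar_day_mg,
            "meadow_pollen_day_ul": self.meadow_pollen_day_ul,
            "coverage": self.coverage,
            "area_m2": self.area_m2,
        }


def _check_counts(counts: pd.DataFrame) -> None:
    missing = {"quadrat_id", "species", "count"} - set(counts.columns)
    if missing:
        raise InputError(f"count table missing columns: {sorted(missing)}")
    if (counts["count"] < 0).any():
        raise InputError("negative floral-unit counts present")
    dup = counts.duplicated(subset=["quadrat_id", "species"])
    if dup.any():
        bad = counts.loc[dup, ["quadrat_id", "species"]].iloc[0]
        raise InputError(
            f"duplicate (quadrat, species) rows, e.g. {tuple(bad)}; "
            "counts must be unique per quadrat and species"
        )


def _quadrat_matrix(
    counts: pd.DataFrame, roster: Sequence[str] | None = None
) -> pd.DataFrame:
    """Quadrat × species count matrix with explicit zeros.

    ``roster`` lists every surveyed quadrat id so that quadrats in which
    nothing flowered still contribute zeros; by default the roster is the set
    of quadrat ids appearing in the table.
    """
    _check_counts(counts)
    mat = counts.pivot_table(
        index="quadrat_id", columns="species", values="count", fill_value=0.0
    )
    if roster is not None:
        roster = list(dict.fromkeys(roster))
        extra = set(mat.index) - set(roster)
        if extra:
            raise InputError(f"counts reference quadrats not in roster: {sorted(extra)}")
        mat = mat.reindex(index=roster, fill_value=0.0)
    return mat.astype(float)


def species_density(
    counts: pd.DataFrame, roster: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-species mean floral-unit density (units/m²) with SE over quadrats.

    ``counts`` holds the records of one site/round; species absent from a
    quadrat count as zero there.
    """
    mat = _quadrat_matrix(counts, roster)
    if mat.shape[0] == 0:
        raise InputError("no quadrats in count table")
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    se = mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else mean * np.nan
    return pd.DataFrame(
        {"species": mean.index, "mean_per_m2": mean.values, "se_per_m2": np.asarray(se)}
    ).reset_index(drop=True)


def _reward_vectors(
    species: Sequence[str], profiles: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nectar (μg) and pollen (μl) per-unit-per-day vectors aligned with
    ``species``, plus a boolean 'measured' mask. Species with no profile row
    (or a profile flagged unmeasured) contribute nothing and trigger a
    warning, never a silent drop."""
    prof = profiles.set_index("species")
    nectar = np.zeros(len(species))
    pollen = np.zeros(len(species))
    measured = np.zeros(len(species), dtype=bool)
    unmatched = []
    for i, sp in enumerate(species):
        if sp not in prof.index:
            unmatched.append(sp)
            continue
        row = prof.loc[sp]
        if "measured" in prof.columns and not bool(row["measured"]):
            continue
        measured[i] = True
        nectar[i] = float(row["nectar_per_unit_day_ug"])
        pollen[i] = float(row["pollen_per_unit_day_ul"])
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} surveyed species have no resource profile and are "
            f"excluded from resource sums: {sorted(unmatched)}",
            stacklevel=2,
        )
    return nectar, pollen, measured


def _ci(totals: np.ndarray, level: float) -> tuple[float, float, float]:
    """Point estimate and normal CI from per-quadrat totals."""
    n = totals.size
    point = float(totals.mean())
    if n > 1:
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * totals.std(ddof=1) / np.sqrt(n)
    else:
        half = np.nan
    return point, point - half, point + half


def meadow_resources(
    counts: pd.DataFrame,
    profiles: pd.DataFrame,
    area_m2: float = DEFAULT_MEADOW_AREA_M2,
    ci_level: float = 0.95,
    roster: Sequence[str] | None = None,
    site: str = "",
    treatment: str = "",
    round_index: int = 0,
) -> MeadowResourceEstimate:
    """Aggregate one site/round's quadrat counts into a daily resource budget."""
    if area_m2 <= 0:
        raise DomainError("meadow area must be positive")
    if not 0.0 < ci_level < 1.0:
        raise DomainError("ci_level must be in (0, 1)")
    mat = _quadrat_matrix(counts, roster)
    if mat.shape[0] == 0:
        raise InputError("no quadrats in count table")
    species = list(mat.columns)
    nectar_w, pollen_w, measured = _reward_vectors(species, profiles)

    arr = mat.to_numpy()
    nectar_totals_mg = arr @ nectar_w / 1000.0  # μg -> mg per quadrat (1 m²)
    pollen_totals_ul = arr @ pollen_w

    nectar_point, nlo, nhi = _ci(nectar_totals_mg, ci_level)
    pollen_point, plo, phi = _ci(pollen_totals_ul, ci_level)

    total_units = arr.sum()
    coverage = float(arr[:, measured].sum() / total_units) if total_units > 0 else 1.0

    shares: dict[str, dict[str, float]] = {"nectar": {}, "pollen": {}}
    nectar_by_sp = arr.sum(axis=0) * nectar_w
    pollen_by_sp = arr.sum(axis=0) * pollen_w
    for name, by_sp in (("nectar", nectar_by_sp), ("pollen", pollen_by_sp)):
        tot = by_sp.sum()
        if tot > 0:
            shares[name] = {
                sp: float(v / tot) for sp, v in zip(species, by_sp) if v > 0
            }

    return MeadowResourceEstimate(
        site=site,
        treatment=treatment,
        round=round_index,
        n_quadrats=mat.shape[0],
        nectar_per_m2_day_mg=nectar_point,
        nectar_ci_mg=(nlo, nhi),
        pollen_per_m2_day_ul=pollen_point,
        pollen_ci_ul=(plo, phi),
        meadow_nectar_day_mg=nectar_point * area_m2,
        meadow_pollen_day_ul=pollen_point * area_m2,
        species_shares=shares,
        coverage=coverage,
        area_m2=area_m2,
    )


def seasonal_series(
    counts: pd.DataFrame,
    profiles: pd.DataFrame,
    area_m2: float = DEFAULT_MEADOW_AREA_M2,
    ci_level: float = 0.95,
    rosters: Mapping[tuple, Sequence[str]] | None = None,
) -> list[MeadowResourceEstimate]:
    """Per-round budgets for every (site, treatment, round) group, ordered by
    round within site. Rounds absent from the table are gaps, not zeros;
    rounds present with all-zero counts yield zero estimates."""
    for col in COUNT_COLUMNS:
        if col not in counts.columns:
            raise InputError(f"count table missing column {col!r}")
    out: list[MeadowResourceEstimate] = []
    for (site, treatment, rnd), grp in counts.groupby(
        ["site", "treatment", "round"], sort=True
    ):
        roster = rosters.get((site, treatment, rnd)) if rosters else None
        out.append(
            meadow_resources(
                grp,
                profiles,
                area_m2=area_m2,
                ci_level=ci_level,
                roster=roster,
                site=str(site),
                treatment=str(treatment),
                round_index=int(rnd),
            )
        )
    return out


def series_to_frame(series: Iterable[MeadowResourceEstimate]) -> pd.DataFrame:
    """Long-format results table, one row per site/treatment/round."""
    return pd.DataFrame([e.to_row() for e in series])


def species_contribution_stack(
    series: Iterable[MeadowResourceEstimate], resource: str = "nectar"
) -> pd.DataFrame:
    """Round × species matrix of resource shares (stacked-area plot data).

    Shares in each row sum to 1 where the round's total resource is positive;
    rows for zero-resource rounds are all zero.
    """
    if resource not in ("nectar", "pollen"):
        raise InputError(f"unknown resource {resource!r}")
    rows = {}
    for est in series:
        rows[(est.site, est.treatment, est.round)] = est.species_shares.get(resource, {})
    stack = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    stack.index = pd.MultiIndex.from_tuples(stack.index, names=["site", "treatment", "round"])
    return stack.sort_index()


def per_quadrat_totals(
    counts: pd.DataFrame,
    profiles: pd.DataFrame,
    roster: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-quadrat total nectar (mg) and pollen (μl) — the sampling units for
    CIs and for the subsampling simulation."""
    mat = _quadrat_matrix(counts, roster)
    nectar_w, pollen_w, _ = _reward_vectors(list(mat.columns), profiles)
    arr = mat.to_numpy()
    return pd.DataFrame(
        {
            "quadrat_id": mat.index,
            "nectar_mg": arr @ nectar_w / 1000.0,
            "pollen_ul": arr @ pollen_w,
        }
    ).reset_index(drop=True)


def subsample_simulation(
    counts: pd.DataFrame,
    profiles: pd.DataFrame,
    n_quadrats_grid: Sequence[int],
    n_reps: int,
    seed: int,
    roster: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Sampling-effort simulation: estimate the meadow mean from random
    subsets of quadrats drawn without replacement.

    For each subset size ``n`` in ``n_quadrats_grid``, draws ``n_reps``
    subsets and records, per resource, the mean and the across-replicate
    variance of the subset-mean estimate. Deterministic for a given seed.
    """
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    totals = per_quadrat_totals(counts, profiles, roster)
    values = totals[["nectar_mg", "pollen_ul"]].to_numpy()
    n_avail = values.shape[0]
    grid = list(n_quadrats_grid)
    if any(n < 1 or n > n_avail for n in grid):
        raise InputError(
            f"subset sizes must be within [1, {n_avail}] (available quadrats)"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for n in grid:
        # random subsets without replacement via argsort of uniform keys
        keys = rng.random((n_reps, n_avail))
        idx = np.argsort(keys, axis=1)[:, :n]
        for j, resource in enumerate(("nectar_mg", "pollen_ul")):
            rep_means = values[idx, j].mean(axis=1)
            rows.append(
                {
                    "n_quadrats": n,
                    "resource": resource,
                    "mean_estimate": float(rep_means.mean()),
                    "var_estimate": float(rep_means.var(ddof=0)),
                    "n_reps": n_reps,
                }
            )
    return pd.DataFrame(rows)


def scheme_comparison(
    counts: pd.DataFrame,
    profiles: pd.DataFrame,
    n_edge: int = 7,
    roster: Sequence[str] | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Paired comparison of the full-quadrat estimate with the edge-subset
    scheme (the study's 7 edge quadrats vs all 20).

    Quadrat positions ('edge'/'internal') come from the roster when it is a
    DataFrame with a ``position`` column, otherwise from the count table.
    Returns one row per resource with both estimates and the signed percent
    difference of the subset relative to the full scheme.
    """
    if isinstance(roster, pd.DataFrame):
        if "position" not in roster.columns:
            raise InputError("roster DataFrame needs a 'position' column")
        positions = (
            roster[["quadrat_id", "position"]]
            .drop_duplicates()
            .set_index("quadrat_id")["position"]
        )
        roster_ids: Sequence[str] | None = roster["quadrat_id"].tolist()
    else:
        if "position" not in counts.columns:
            raise InputError("scheme comparison requires a 'position' column")
        positions = (
            counts[["quadrat_id", "position"]]
            .drop_duplicates()
            .set_index("quadrat_id")["position"]
        )
        roster_ids = roster
    totals_full = per_quadrat_totals(counts, profiles, roster_ids)
    edge_ids = [q for q in totals_full["quadrat_id"] if positions.get(q) == "edge"]
    edge_ids = edge_ids[:n_edge]
    if not edge_ids:
        raise InputError("no edge quadrats available for the subset scheme")
    sub = totals_full[totals_full["quadrat_id"].isin(edge_ids)]
    rows = []
    for resource in ("nectar_mg", "pollen_ul"):
        full = float(totals_full[resource].mean())
        subset = float(sub[resource].mean())
        pct = 100.0 * (subset - full) / full if full != 0 else np.nan if subset else 0.0
        rows.append(
            {
                "resource": resource,
                "estimate_full": full,
                "n_full": len(totals_full),
                "estimate_subset": subset,
                "n_subset": len(sub),
                "pct_difference": pct,
            }
        )
    return pd.DataFrame(rows)


def seasonal_integral(
    days: Sequence[float],
    values: Sequence[float],
    method: str = "trapezoid",
) -> float:
    """Season-total resource per m² from a daily-rate time series.

    ``method="trapezoid"`` integrates the observed series directly.
    ``method="fitted_curve"`` fits a unimodal curve — Gaussian in log space,
    i.e. a concave quadratic in log(rate) — to the positive points and
    returns its closed-form area, which smooths over the coarse survey grid.
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if days.size != values.size or days.size < 2:
        raise InputError("need at least two (day, value) points")
    order = np.argsort(days)
    days, values = days[order], values[order]
    if method == "trapezoid":
        return float(np.trapezoid(values, days))
    if method != "fitted_curve":
        raise InputError(f"unknown integration method {method!r}")
    pos = values > 0
    if pos.sum() < 3:
        raise InputError("fitted_curve needs at least three positive points")
    a2, a1, a0 = np.polyfit(days[pos], np.log(values[pos]), 2)
    if a2 >= 0:
        # no interior peak; fall back to the empirical integral
        return float(np.trapezoid(values, days))
    # integral over the real line of exp(a2 t^2 + a1 t + a0)
    return float(np.exp(a0 - a1**2 / (4.0 * a2)) * np.sqrt(np.pi / -a2))
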