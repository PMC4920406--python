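"""Synthetic species pools, assays and quadrat surveys with known truth.

The generator emulates the statistical structure of urban sown-meadow
surveys so every downstream stage can be validated against planted ground
truth:

* **Dominance-skewed abundance** — species base densities are lognormal with
  a large sigma, so a handful of species reach 10²–10⁴ floral units/m² while
  many sit below 0.1/m².
* **Treatment phenology** — Gaussian bloom curves on the log-density scale
  over six survey rounds (early May … early September). Perennial mixes peak
  around early August (round 4), annual mixes late August–September
  (round ~5.5), weed species early in the season, and the mown control
  carries only weeds at ~1/100 density.
* **Rewards** — per-unit daily nectar sugar is log-uniform on
  0.6–2921 μg and total pollen volume on 0.0004–15.9 μl, spanning the
  observed extremes; longevities are uniform on 1–14.8 days (quantised to
  0.25 d so integer census counts reproduce them exactly).
* **Counts** — negative binomial around the true mean density, capturing the
  overdispersion of clumped flowering; the Poisson limit is reached as the
  dispersion parameter grows.
* **Morphology** — stamen numbers and anther classes are drawn so that
  measured pollen follows a planted coefficient vector (the published one by
  default), letting the morphology regression be checked by parameter
  recovery.

A single integer seed drives one generator stream; identical configs are
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import nectar as nq
from . import pollen as pq
from .errors import InputError
from .models import PollenMorphologyModel

ROUND_LABELS = {
    1: "early May",
    2: "June",
    3: "July",
    4: "early August",
    5: "late August",
    6: "September",
}

#: days after the first survey for each round (three-week intervals)
ROUND_DAY_OFFSETS = {r: 21.0 * (r - 1) for r in range(1, 7)}


@dataclass(frozen=True)
class Phenology:
    """Gaussian bloom curve: peak round and width (in rounds)."""

    peak_round: float
    width_rounds: float

    def factor(self, rnd: np.ndarray | float) -> np.ndarray | float:
        return np.exp(-((np.asarray(rnd, dtype=float) - self.peak_round) ** 2)
                      / (2.0 * self.width_rounds**2))


DEFAULT_PHENOLOGY: Mapping[str, Phenology] = {
    "annual": Phenology(5.5, 1.0),
    "perennial": Phenology(4.0, 1.2),
    "weed": Phenology(1.5, 1.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for the synthetic generator."""

    seed: int
    n_species: int = 60
    weed_fraction: float = 0.30
    asteraceae_fraction: float = 0.35
    dominance_sigma: float = 2.5  # lognormal sigma (base e) of base densities
    base_density_scale: float = 3.0  # median peak density, units/m²
    nectar_range_ug: tuple[float, float] = (0.6, 2921.0)
    pollen_range_ul: tuple[float, float] = (0.0004, 15.9)
    longevity_range_days: tuple[float, float] = (1.0, 14.8)
    #: Gaussian-copula correlation between log abundance and per-unit reward;
    #: negative because superabundant species carry low per-flower rewards,
    #: which makes total resource scale sublinearly with total counts.
    abundance_reward_rho: float = -0.6
    phenology: Mapping[str, Phenology] = field(
        default_factory=lambda: dict(DEFAULT_PHENOLOGY)
    )
    #: sd (in rounds) of species-level jitter around the group bloom peak;
    #: species flower at staggered times within a mix, so survey-to-survey
    #: composition shifts rather than scaling proportionally
    phenology_jitter_rounds: float = 1.5
    control_scale: float = 0.01  # control meadows carry weeds at ~1/100 density
    #: weed densities in sown meadows relative to their seed-bank potential;
    #: large weeds are removed during management, so weeds reach full density
    #: only early in the season relative to the sown mix's later peak
    weed_scale_in_sown: float = 0.1
    site_sigma: float = 0.5  # lognormal site-by-species density multiplier
    n_cities: int = 1
    n_sites: int = 2  # replicates per treatment per city
    n_rounds: int = 6
    quadrats_per_site: int = 20
    nb_dispersion: float = 1.5  # negative-binomial size; Poisson as -> inf
    assay_cv: float = 0.3  # lognormal sigma of assay-level noise
    nectar_samples_range: tuple[int, int] = (3, 22)
    pollen_assays_range: tuple[int, int] = (2, 22)
    morphology_sigma: float = 0.3  # log-scale noise around planted coefficients
    morphology_model: PollenMorphologyModel = field(
        default_factory=PollenMorphologyModel.published
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InputError("a seed is mandatory (reproducibility contract)")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth for every downstream stage."""

    species: pd.DataFrame  # per-species rewards, longevity, group flags
    density: pd.DataFrame  # true mean density per city/site/treatment/round/species
    resources: pd.DataFrame  # true per-m²/day resource per city/site/treatment/round


@dataclass(frozen=True)
class SpeciesPool:
    profiles: pd.DataFrame  # SpeciesResourceProfile table (truth rewards)
    morphology: pd.DataFrame  # MorphologyRecord table with measured pollen
    truth: GroundTruth


def _quantise_longevity(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    """Longevities on a 0.25-day grid so integer census counts (b−c=8, d=1)
    reproduce them exactly."""
    raw = rng.uniform(lo, hi, size=n)
    return np.maximum(1.0, np.round(raw * 4.0) / 4.0)


def generate_species_pool(config: GeneratorConfig) -> SpeciesPool:
    """Draw the species pool: rewards, longevity, group membership, base
    densities and a morphology table consistent with the planted model."""
    rng = config.rng(stream=1)
    n = config.n_species
    names = [f"sp{i:03d}" for i in range(1, n + 1)]

    n_weed = int(round(config.weed_fraction * n))
    groups = np.array(["weed"] * n_weed + ["annual", "perennial"] * ((n - n_weed) // 2 + 1))[:n]
    rng.shuffle(groups)
    asteraceae = rng.random(n) < config.asteraceae_fraction

    # abundance and rewards share a Gaussian copula: z_d drives log density,
    # rewards are log-uniform with rank correlation rho to abundance
    from scipy.stats import norm as _norm

    rho = config.abundance_reward_rho
    z_density = rng.normal(size=n)
    base_density = np.exp(
        np.log(config.base_density_scale) + config.dominance_sigma * z_density
    )

    def _coupled_loguniform(lo: float, hi: float) -> np.ndarray:
        z = rho * z_density + np.sqrt(1.0 - rho**2) * rng.normal(size=n)
        u = _norm.cdf(z)
        return np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))

    nectar = _coupled_loguniform(*config.nectar_range_ug)
    pollen_total = _coupled_loguniform(*config.pollen_range_ul)
    longevity = _quantise_longevity(rng, *config.longevity_range_days, n)
    pollen_daily = pollen_total / longevity

    # morphology drawn so refitting recovers the planted coefficient vector
    model = config.morphology_model
    stamens = np.where(
        asteraceae,
        5,
        np.round(np.exp(rng.uniform(np.log(1.0), np.log(60.0), size=n))).astype(int),
    ).astype(int)
    stamens = np.maximum(stamens, 1)
    classes = np.where(
        asteraceae, "tiny", rng.choice(["large", "medium", "small"], size=n)
    )
    class_coef = np.array(
        [
            {"large": 0.0, "medium": model.coef_medium,
             "small": model.coef_small, "tiny": model.coef_tiny}[c]
            for c in classes
        ]
    )
    eta = model.intercept + model.coef_inv_stamens / stamens + class_coef
    measured_pollen = np.exp(eta + rng.normal(0.0, config.morphology_sigma, size=n))

    peak_jitter = rng.normal(0.0, config.phenology_jitter_rounds, size=n)

    species_df = pd.DataFrame(
        {
            "species": names,
            "group": groups,
            "asteraceae": asteraceae,
            "peak_jitter_rounds": peak_jitter,
            "floral_unit_kind": np.where(asteraceae, "capitulum", "flower"),
            "nectar_per_unit_day_ug": nectar,
            "pollen_per_unit_ul": pollen_total,
            "longevity_days": longevity,
            "pollen_per_unit_day_ul": pollen_daily,
            "base_density_per_m2": base_density,
        }
    )

    profiles = pd.DataFrame(
        {
            "species": names,
            "nectar_per_unit_day_ug": nectar,
            "nectar_sem_ug": 0.0,
            "pollen_per_unit_day_ul": pollen_daily,
            "pollen_sem_ul": 0.0,
            "longevity_days": longevity,
            "floral_unit_kind": species_df["floral_unit_kind"],
            "measured": True,
        }
    )

    morphology = pd.DataFrame(
        {
            "species": names,
            "stamen_number": stamens,
            "anther_class": classes,
            "measured_pollen_ul": measured_pollen,
        }
    )

    density, resources = _truth_tables(species_df, config)
    truth = GroundTruth(species=species_df, density=density, resources=resources)
    return SpeciesPool(profiles=profiles, morphology=morphology, truth=truth)


def _treatment_group(treatment: str) -> str:
    return {"A1": "annual", "A2": "annual", "P": "perennial"}.get(treatment, "weed")


def _truth_density(
    species_df: pd.DataFrame,
    config: GeneratorConfig,
    treatment: str,
    rnd: int,
    site_mult: np.ndarray,
) -> np.ndarray:
    """True mean density of each species in one treatment at one round."""
    groups = species_df["group"].to_numpy()
    base = species_df["base_density_per_m2"].to_numpy() * site_mult
    jitter = species_df["peak_jitter_rounds"].to_numpy()
    out = np.zeros(len(species_df))

    def _factor(mask: np.ndarray, phen: Phenology) -> np.ndarray:
        return np.exp(
            -((rnd - (phen.peak_round + jitter[mask])) ** 2)
            / (2.0 * phen.width_rounds**2)
        )

    weed_phen = config.phenology["weed"]
    weeds = groups == "weed"
    if treatment == "C":
        out[weeds] = base[weeds] * _factor(weeds, weed_phen) * config.control_scale
        return out
    sown_group = _treatment_group(treatment)
    sown = groups == sown_group
    out[sown] = base[sown] * _factor(sown, config.phenology[sown_group])
    out[weeds] = base[weeds] * _factor(weeds, weed_phen) * config.weed_scale_in_sown
    return out


def _site_multipliers(config: GeneratorConfig, n_species: int) -> dict:
    rng = config.rng(stream=2)
    mults = {}
    for city in range(1, config.n_cities + 1):
        for treatment in TREATMENTS_ORDER:
            for site in range(1, config.n_sites + 1):
                mults[(city, treatment, site)] = np.exp(
                    rng.normal(0.0, config.site_sigma, size=n_species)
                )
    return mults


TREATMENTS_ORDER = ("A1", "A2", "P", "C")


def _truth_tables(
    species_df: pd.DataFrame, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    mults = _site_multipliers(config, len(species_df))
    names = species_df["species"].to_numpy()
    nectar = species_df["nectar_per_unit_day_ug"].to_numpy()
    pollen = species_df["pollen_per_unit_day_ul"].to_numpy()
    dens_rows, res_rows = [], []
    for (city, treatment, site), mult in mults.items():
        site_id = f"c{city}_{treatment}_s{site}"
        for rnd in range(1, config.n_rounds + 1):
            dens = _truth_density(species_df, config, treatment, rnd, mult)
            keep = dens > 0
            dens_rows.append(
                pd.DataFrame(
                    {
                        "city": f"c{city}",
                        "site": site_id,
                        "treatment": treatment,
                        "round": rnd,
                        "species": names[keep],
                        "true_density_per_m2": dens[keep],
                    }
                )
            )
            res_rows.append(
                {
                    "city": f"c{city}",
                    "site": site_id,
                    "treatment": treatment,
                    "round": rnd,
                    "true_nectar_mg_m2_day": float(dens @ nectar) / 1000.0,
                    "true_pollen_ul_m2_day": float(dens @ pollen),
                }
            )
    density = pd.concat(dens_rows, ignore_index=True)
    return density, pd.DataFrame(res_rows)


# ---------------------------------------------------------------------------
# assays


@dataclass(frozen=True)
class AssayBundle:
    nectar_samples: list  # list[nq.NectarSample]
    pollen_assays: dict  # species -> list[pq.PollenAssay]
    grain_dims: dict  # species -> pq.PollenGrainDims
    longevity_obs: dict  # species -> list[pq.LongevityObservation]


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative mean-1 lognormal noise; exactly 1 when cv = 0."""
    if cv == 0:
        return np.ones(size)
    sigma = cv
    return rng.lognormal(-0.5 * sigma**2, sigma, size=size)


def generate_assays(pool: SpeciesPool, config: GeneratorConfig) -> AssayBundle:
    """Raw assay tables whose summaries estimate the pool truth.

    With ``assay_cv=0`` the per-species summaries reproduce truth exactly
    (pollen aliquot counts are kept as real-valued expectations for that
    reason); longevity census counts are integers constructed to invert the
    printed estimator at d = 1 with a growing census (b > c)."""
    rng = config.rng(stream=3)
    truth = pool.truth.species
    nectar_samples: list[nq.NectarSample] = []
    pollen_assays: dict[str, list[pq.PollenAssay]] = {}
    grain_dims: dict[str, pq.PollenGrainDims] = {}
    longevity_obs: dict[str, list[pq.LongevityObservation]] = {}

    for row in truth.itertuples(index=False):
        # nectar: back out capillary volume from the target sugar mass at a
        # plausible Brix reading
        n_samp = int(rng.integers(*config.nectar_samples_range, endpoint=True))
        noise = _lognormal_noise(rng, config.assay_cv, n_samp)
        target_ug = row.nectar_per_unit_day_ug * noise
        brix = rng.uniform(20.0, 50.0, size=n_samp)
        for s_ug, c in zip(target_ug, brix):
            volume_ml = (s_ug / 1000.0) / (10.0 * nq.sucrose_density(c) * c)
            nectar_samples.append(
                nq.NectarSample(
                    species=row.species,
                    protocol="direct",
                    brix=float(c),
                    nectar_volume_ml=float(volume_ml),
                )
            )

        # pollen: grain geometry then expected aliquot counts
        minor = float(rng.uniform(10.0, 40.0))
        major = minor * float(rng.uniform(1.0, 1.5))
        dims = pq.PollenGrainDims(major, minor, n_grains_measured=100)
        grain_dims[row.species] = dims
        gv = pq.grain_volume(dims)
        grains_per_unit = row.pollen_per_unit_ul * pq.UM3_PER_UL / gv
        n_assay = int(rng.integers(*config.pollen_assays_range, endpoint=True))
        noise = _lognormal_noise(rng, config.assay_cv, n_assay)
        assays = []
        for f in noise:
            n_units = int(rng.integers(5, 15))
            suspension = 1000.0
            aliquot = 1.0
            expected = grains_per_unit * f * n_units * aliquot / suspension
            assays.append(
                pq.PollenAssay(
                    species=row.species,
                    aliquot_count=float(expected),
                    aliquot_volume_ul=aliquot,
                    suspension_volume_ul=suspension,
                    n_floral_units=n_units,
                )
            )
        pollen_assays[row.species] = assays

        # longevity: integer census with b - c = 8, d = 1, a = 4(L - 1)
        a = int(round(4.0 * (row.longevity_days - 1.0)))
        longevity_obs[row.species] = [
            pq.LongevityObservation(
                open_first=a, newly_open_second=12, newly_closed_second=4,
                interval_days=1.0,
            )
        ]

    return AssayBundle(
        nectar_samples=nectar_samples,
        pollen_assays=pollen_assays,
        grain_dims=grain_dims,
        longevity_obs=longevity_obs,
    )


# ---------------------------------------------------------------------------
# surveys


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, k: float) -> np.ndarray:
    """Negative-binomial counts with mean mu and dispersion k (variance
    mu + mu²/k); Poisson in the k -> inf limit."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if np.any(pos):
        if np.isfinite(k):
            p = k / (k + mu[pos])
            out[pos] = rng.negative_binomial(k, p)
        else:
            out[pos] = rng.poisson(mu[pos])
    return out


def generate_surveys(
    pool: SpeciesPool, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quadrat count records across cities/sites/treatments/rounds.

    Returns ``(counts, roster)``: counts is sparse long format (zero counts
    omitted); roster lists every surveyed quadrat so empty quadrats remain
    countable downstream.
    """
    rng = config.rng(stream=4)
    names = pool.truth.species["species"].to_numpy()
    dens = pool.truth.density
    count_rows, roster_rows = [], []
    groups = dens.groupby(["city", "site", "treatment", "round"], sort=True)
    for (city, site, treatment, rnd), grp in groups:
        mu = np.zeros(len(names))
        idx = {sp: i for i, sp in enumerate(names)}
        for sp, d in zip(grp["species"], grp["true_density_per_m2"]):
            mu[idx[sp]] = d
        for q in range(1, config.quadrats_per_site + 1):
            quadrat_id = f"{site}_q{q:02d}"
            position = "edge" if q % 2 == 1 else "internal"
            roster_rows.append(
                {
                    "city": city,
                    "site": site,
                    "treatment": treatment,
                    "round": rnd,
                    "quadrat_id": quadrat_id,
                    "position": position,
                }
            )
            counts = _nb_draw(rng, mu, config.nb_dispersion)
            nz = counts > 0
            for sp, cnt in zip(names[nz], counts[nz]):
                count_rows.append(
                    {
                        "city": city,
                        "site": site,
                        "treatment": treatment,
                        "round": rnd,
                        "quadrat_id": quadrat_id,
                        "position": position,
                        "species": sp,
                        "count": int(cnt),
                    }
                )
    counts_df = pd.DataFrame(
        count_rows,
        columns=[
            "city", "site", "treatment", "round",
            "quadrat_id", "position", "species", "count",
        ],
    )
    roster_df = pd.DataFrame(
        roster_rows,
        columns=["city", "site", "treatment", "round", "quadrat_id", "position"],
    )
    return counts_df, roster_df


# ---------------------------------------------------------------------------
# estimator-calibration simulation


def simulate_ci_coverage(
    config: GeneratorConfig,
    n_site_rounds: int,
    draw_seed: int,
    resource: str = "nectar",
    ci_level: float = 0.95,
    min_expected_units: float = 1.0,
) -> dict:
    """Calibration check of the survey estimator's count-based CI.

    Draws quadrat counts around the generator's true mean densities for
    successive site-rounds (cycling through the truth table as needed,
    skipping effectively flowerless surveys below ``min_expected_units``
    expected floral units/m²) and records how often the normal CI over
    per-quadrat resource totals brackets the true per-m² daily resource.
    Returns the coverage fraction, the number of simulated site-rounds and
    the mean estimate/truth ratio (estimator bias check).
    """
    if resource not in ("nectar", "pollen"):
        raise InputError(f"unknown resource {resource!r}")
    from scipy.stats import norm as _norm

    z = _norm.ppf(0.5 + ci_level / 2.0)
    rng = np.random.default_rng(draw_seed)
    pool = generate_species_pool(config)
    names = pool.truth.species["species"].to_numpy()
    if resource == "nectar":
        w = pool.truth.species["nectar_per_unit_day_ug"].to_numpy() / 1000.0
        col = "true_nectar_mg_m2_day"
    else:
        w = pool.truth.species["pollen_per_unit_day_ul"].to_numpy()
        col = "true_pollen_ul_m2_day"
    idx = {sp: i for i, sp in enumerate(names)}
    truth_res = pool.truth.resources.set_index(["city", "site", "treatment", "round"])
    groups = list(pool.truth.density.groupby(["city", "site", "treatment", "round"]))
    nq_ = config.quadrats_per_site
    k = config.nb_dispersion
    covered, ratios = [], []
    gi = 0
    while len(covered) < n_site_rounds:
        key, grp = groups[gi % len(groups)]
        gi += 1
        if gi > 100 * max(n_site_rounds, len(groups)):
            raise InputError("too few floriferous site-rounds in the truth table")
        mu = np.zeros(len(names))
        for sp, d in zip(grp["species"], grp["true_density_per_m2"]):
            mu[idx[sp]] = d
        if mu.sum() < min_expected_units:
            continue
        counts = _nb_draw(rng, np.tile(mu, (nq_, 1)), k)
        totals = counts @ w
        m = totals.mean()
        se = totals.std(ddof=1) / np.sqrt(nq_)
        truth = float(truth_res.loc[key, col])
        covered.append(m - z * se <= truth <= m + z * se)
        if truth > 0:
            ratios.append(m / truth)
    return {
        "coverage": float(np.mean(covered)),
        "n": len(covered),
        "mean_estimate_truth_ratio": float(np.mean(ratios)),
    }


# ---------------------------------------------------------------------------
# bundle generation and CSV export


def generate_all(config: GeneratorConfig):
    """Species pool, assays and surveys in one call."""
    pool = generate_species_pool(config)
    assays = generate_assays(pool, config)
    counts, roster = generate_surveys(pool, config)
    return pool, assays, counts, roster


def write_bundle(outdir: str | Path, config: GeneratorConfig) -> dict[str, Path]:
    """Generate everything and write the CSV dialects the other modules read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pool, assays, counts, roster = generate_all(config)

    paths = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        p = outdir / name
        df.to_csv(p, index=False)
        paths[name] = p

    _write("species_profiles.csv", pool.profiles)
    _write("morphology.csv", pool.morphology)
    _write("truth_species.csv", pool.truth.species)
    _write("truth_resources.csv", pool.truth.resources)
    _write("nectar_samples.csv", nq.samples_to_frame(assays.nectar_samples))
    _write(
        "pollen_assays.csv",
        pd.DataFrame(
            [
                {
                    "species": a.species,
                    "aliquot_count": a.aliquot_count,
                    "aliquot_volume_ul": a.aliquot_volume_ul,
                    "suspension_volume_ul": a.suspension_volume_ul,
                    "n_floral_units": a.n_floral_units,
                }
                for assay_list in assays.pollen_assays.values()
                for a in assay_list
            ]
        ),
    )
    _write(
        "grain_dims.csv",
        pd.DataFrame(
            [
                {
                    "species": sp,
                    "major_um": d.major_axis_um,
                    "minor_um": d.minor_axis_um,
                    "n": d.n_grains_measured,
                }
                for sp, d in assays.grain_dims.items()
            ]
        ),
    )
    _write(
        "longevity_obs.csv",
        pd.DataFrame(
            [
                {
                    "species": sp,
                    "a": o.open_first,
                    "b": o.newly_open_second,
                    "c": o.newly_closed_second,
                    "interval_days": o.interval_days,
                }
                for sp, obs in assays.longevity_obs.items()
                for o in obs
            ]
        ),
    )
    _write("quadrat_counts.csv", counts)
    _write("quadrat_roster.csv", roster)
    return paths
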