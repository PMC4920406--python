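"""End-to-end orchestration: assays → profiles → budgets → models → report.

``run_pipeline`` is a pure function of (inputs, config, seed): given either a
directory of raw CSV tables or a synthetic-generator config, it produces the
species resource profiles, per-site-per-round meadow budgets, seasonal
contribution stacks, the two predictive model fits, a bee-equivalents table
and a plain-text treatment report, all written under one output directory
with a run log. Warnings (reward coverage < 0.99, unmatched species, invalid
longevity observations) are collected into the log, never swallowed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import equivalents as eq
from . import models, nectar, pollen, survey, synth
from .errors import InputError

COVERAGE_TARGET = 0.99


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs and knobs for one pipeline run.

    Either ``input_dir`` (CSV tables as written by :func:`synth.write_bundle`
    or assembled by hand) or ``synth_config`` must be given.
    """

    outdir: str
    input_dir: str | None = None
    synth_config: synth.GeneratorConfig | None = None
    area_m2: float = survey.DEFAULT_MEADOW_AREA_M2
    scheme: int = 20
    ci_level: float = 0.95
    excluded_sites: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in (7, 20):
            raise InputError("sampling scheme must be 7 or 20")
        if not 0.0 < self.ci_level < 1.0:
            raise InputError("ci_level must be in (0, 1)")
        if (self.input_dir is None) == (self.synth_config is None):
            raise InputError("exactly one of input_dir / synth_config is required")


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    synth_cfg = None
    if "synth" in raw:
        synth_cfg = synth.GeneratorConfig(**raw["synth"])
    return PipelineConfig(
        outdir=raw["outdir"],
        input_dir=raw.get("input_dir"),
        synth_config=synth_cfg,
        area_m2=float(raw.get("area_m2", survey.DEFAULT_MEADOW_AREA_M2)),
        scheme=int(raw.get("scheme", 20)),
        ci_level=float(raw.get("ci_level", 0.95)),
        excluded_sites=tuple(raw.get("excluded_sites", ())),
        seed=int(raw.get("seed", 0)),
    )


def build_profiles(input_dir: Path, log: list[str]) -> pd.DataFrame:
    """Species resource profiles from raw assay tables."""
    samples = nectar.read_nectar_samples(input_dir / "nectar_samples.csv")
    nectar_df = nectar.summarise_all_species(samples)
    assays = pollen.read_pollen_assays(input_dir / "pollen_assays.csv")
    dims = pollen.read_grain_dims(input_dir / "grain_dims.csv")
    obs = pollen.read_longevity_observations(input_dir / "longevity_obs.csv")
    longevities = {}
    for sp, sp_obs in obs.items():
        try:
            longevities[sp] = pollen.species_longevity(sp_obs)
        except (pollen.DegenerateObservationError, pollen.InvalidEstimateError) as exc:
            log.append(f"WARNING longevity rejected for {sp}: {exc}")
    pollen_df = pollen.summarise_all_species(
        {sp: a for sp, a in assays.items() if sp in longevities}, dims, longevities
    )
    profiles = nectar_df.merge(pollen_df, on="species", how="outer")
    profiles["measured"] = (
        profiles["nectar_per_unit_day_ug"].notna()
        & profiles["pollen_per_unit_day_ul"].notna()
    )
    for col in ("nectar_per_unit_day_ug", "pollen_per_unit_day_ul"):
        profiles[col] = profiles[col].fillna(0.0)
    n_zero = int(profiles.get("zero_flagged", pd.Series(dtype=bool)).sum())
    if n_zero:
        log.append(f"NOTE {n_zero} species flagged as all-zero nectar (possible false zeros)")
    return profiles


def make_report(estimates: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment summary statistics of daily resource levels.

    Mean, median and quartiles per treatment for nectar (mg/m²/day) and
    pollen (μl/m²/day); empty treatments yield explicit NA rows.
    """
    rows = []
    for treatment in survey.TREATMENTS:
        grp = estimates[estimates["treatment"] == treatment]
        for col, resource in (
            ("nectar_per_m2_day_mg", "nectar"),
            ("pollen_per_m2_day_ul", "pollen"),
        ):
            if grp.empty:
                rows.append(
                    {
                        "treatment": treatment,
                        "resource": resource,
                        "n_surveys": 0,
                        "mean": np.nan,
                        "median": np.nan,
                        "q25": np.nan,
                        "q75": np.nan,
                    }
                )
                continue
            v = grp[col].to_numpy()
            rows.append(
                {
                    "treatment": treatment,
                    "resource": resource,
                    "n_surveys": len(v),
                    "mean": float(np.mean(v)),
                    "median": float(np.median(v)),
                    "q25": float(np.percentile(v, 25)),
                    "q75": float(np.percentile(v, 75)),
                }
            )
    return pd.DataFrame(rows)


def equivalents_table(estimates: pd.DataFrame, constants: eq.EquivalenceConstants) -> pd.DataFrame:
    """Bee-equivalent conversions of each site-round pollen budget."""
    rows = []
    cell_lo, cell_hi = constants.solitary_cell_pollen_range_g
    for row in estimates.itertuples(index=False):
        volume_ml = row.pollen_per_m2_day_ul / 1000.0
        mass_g_m2 = eq.pollen_volume_to_mass(volume_ml, constants)
        daily_g = mass_g_m2 * row.area_m2
        rows.append(
            {
                "site": row.site,
                "treatment": row.treatment,
                "round": row.round,
                "pollen_g_m2_day": mass_g_m2,
                "pollen_g_meadow_day": daily_g,
                "honeybee_workers_day": eq.honeybee_worker_equivalents(daily_g, constants),
                "solitary_cells_day_large": eq.solitary_bee_cell_equivalents(daily_g, cell_hi),
                "solitary_cells_day_small": eq.solitary_bee_cell_equivalents(daily_g, cell_lo),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns output paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed={config.seed}", f"scheme={config.scheme}",
                      f"area_m2={config.area_m2}", f"ci_level={config.ci_level}"]

    if config.synth_config is not None:
        input_dir = outdir / "synthetic_inputs"
        synth.write_bundle(input_dir, config.synth_config)
        log.append(f"synthetic inputs generated with seed {config.synth_config.seed}")
    else:
        input_dir = Path(config.input_dir)
        if not input_dir.exists():
            raise InputError(f"input directory not found: {input_dir}")

    for required in ("quadrat_counts.csv",):
        if not (input_dir / required).exists():
            raise InputError(f"stage 'load': missing input file {input_dir / required}")

    # stage 1: species profiles (from assays if present, else precomputed)
    if (input_dir / "nectar_samples.csv").exists():
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            profiles = build_profiles(input_dir, log)
        log.extend(f"WARNING {w.message}" for w in caught)
    elif (input_dir / "species_profiles.csv").exists():
        profiles = pd.read_csv(input_dir / "species_profiles.csv")
    else:
        raise InputError("stage 'profiles': no assay tables or species_profiles.csv")

    # stage 2: survey aggregation
    counts = pd.read_csv(input_dir / "quadrat_counts.csv")
    roster_path = input_dir / "quadrat_roster.csv"
    rosters = None
    if roster_path.exists():
        roster = pd.read_csv(roster_path)
        rosters = {
            key: grp["quadrat_id"].tolist()
            for key, grp in roster.groupby(["site", "treatment", "round"])
        }
    if config.excluded_sites:
        before = counts["site"].nunique()
        counts = counts[~counts["site"].isin(config.excluded_sites)]
        log.append(
            f"excluded {before - counts['site'].nunique()} failed sites: "
            f"{sorted(config.excluded_sites)}"
        )
    if config.scheme == 7:
        counts = counts[counts["position"] == "edge"]
        if rosters:
            edge = roster[roster["position"] == "edge"]
            rosters = {
                key: grp["quadrat_id"].tolist()[:7]
                for key, grp in edge.groupby(["site", "treatment", "round"])
            }
        counts = counts.merge(
            pd.concat(
                [
                    pd.DataFrame({"quadrat_id": v}).assign(site=k[0], treatment=k[1], round=k[2])
                    for k, v in rosters.items()
                ]
            )
            if rosters
            else counts[["site", "treatment", "round", "quadrat_id"]].drop_duplicates(),
            on=["site", "treatment", "round", "quadrat_id"],
        )

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        series = survey.seasonal_series(
            counts, profiles, area_m2=config.area_m2, ci_level=config.ci_level,
            rosters=rosters,
        )
    log.extend(f"WARNING {w.message}" for w in caught)
    estimates = survey.series_to_frame(series)
    low_cov = estimates[estimates["coverage"] < COVERAGE_TARGET]
    for row in low_cov.itertuples(index=False):
        log.append(
            f"WARNING coverage {row.coverage:.3f} < {COVERAGE_TARGET} for "
            f"{row.site} round {row.round}"
        )

    # stage 3: contribution stacks
    stacks = {
        res: survey.species_contribution_stack(series, resource=res)
        for res in ("nectar", "pollen")
    }

    # stage 4: predictive models on the aggregated surveys
    model_texts = []
    if (input_dir / "morphology.csv").exists():
        morph_df = pd.read_csv(input_dir / "morphology.csv")
        records = [
            models.MorphologyRecord(
                species=r.species,
                stamen_number=int(r.stamen_number),
                anther_class=r.anther_class,
                measured_pollen_ul=float(r.measured_pollen_ul),
            )
            for r in morph_df.itertuples(index=False)
        ]
        morph_model = models.fit_pollen_morphology_model(records)
        model_texts.append(models.model_to_text(morph_model))
        log.append(
            f"morphology model fitted: n={morph_model.n}, adj_r2={morph_model.adj_r2:.3f}"
        )
    total_counts = (
        counts.groupby(["site", "treatment", "round"])["count"].sum()
        / estimates.set_index(["site", "treatment", "round"])["n_quadrats"]
    ).reindex(estimates.set_index(["site", "treatment", "round"]).index)
    for res, col in (("nectar", "nectar_per_m2_day_mg"), ("pollen", "pollen_per_m2_day_ul")):
        try:
            cr_model = models.fit_count_resource_model(
                total_counts.to_numpy(),
                estimates[col].to_numpy(),
                resource=res,
            )
        except InputError as exc:
            log.append(f"WARNING count-resource model ({res}) not fitted: {exc}")
            continue
        model_texts.append(models.model_to_text(cr_model))
        log.append(
            f"count-resource model ({res}): slope={cr_model.slope:.3f}, "
            f"adj_r2={cr_model.adj_r2:.3f}, n={cr_model.n}"
        )

    # stage 5: equivalents and report
    constants = eq.EquivalenceConstants(meadow_area_m2=config.area_m2)
    equiv = equivalents_table(estimates, constants)
    report = make_report(estimates)

    paths: dict[str, Path] = {}

    def _save(name: str, df: pd.DataFrame, index: bool = False) -> None:
        p = outdir / name
        df.to_csv(p, index=index)
        paths[name] = p

    _save("species_profiles.csv", profiles)
    _save("meadow_estimates.csv", estimates)
    _save("contribution_stack_nectar.csv", stacks["nectar"], index=True)
    _save("contribution_stack_pollen.csv", stacks["pollen"], index=True)
    _save("equivalents.csv", equiv)
    _save("treatment_report.csv", report)

    report_txt = outdir / "treatment_report.txt"
    report_txt.write_text(
        "Daily resource levels by treatment (nectar mg/m2/day, pollen ul/m2/day)\n\n"
        + report.to_string(index=False, na_rep="NA")
        + "\n"
    )
    paths["treatment_report.txt"] = report_txt

    if model_texts:
        models_path = outdir / "model_fits.txt"
        models_path.write_text("\n".join(model_texts))
        paths["model_fits.txt"] = models_path

    log_path = outdir / "run_log.txt"
    log_path.write_text("\n".join(log) + "\n")
    paths["run_log.txt"] = log_path
    return paths
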