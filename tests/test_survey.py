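"""Quadrat aggregation, budget CIs, subsampling and seasonal integration."""

import numpy as np
import pandas as pd
import pytest

from meadowforage import survey
from meadowforage.errors import DomainError, InputError
from tests.conftest import make_counts


class TestSpeciesDensity:
    def test_mean_and_se_over_quadrats(self):
        counts = make_counts([2, 4, 6])
        out = survey.species_density(counts).set_index("species")
        assert out.loc["alpha", "mean_per_m2"] == pytest.approx(4.0)
        assert out.loc["alpha", "se_per_m2"] == pytest.approx(1.1547, abs=1e-4)

    def test_absent_species_count_zero_in_other_quadrats(self):
        counts = pd.concat(
            [
                make_counts([7], species="alpha"),
                make_counts([0] * 0, species="beta"),  # no rows at all
            ]
        )
        roster = [f"q{i}" for i in range(7)]
        out = survey.species_density(make_counts([7]), roster=roster)
        assert out.set_index("species").loc["alpha", "mean_per_m2"] == pytest.approx(1.0)

    def test_duplicate_rows_rejected(self):
        counts = make_counts([2, 4])
        dup = pd.concat([counts, counts.iloc[[0]]])
        with pytest.raises(InputError, match="duplicate"):
            survey.species_density(dup)


class TestMeadowResources:
    def test_point_arithmetic(self, simple_profiles):
        # one species at 10 units/m2, 100 ug/unit/day -> 1 mg/m2/day
        counts = make_counts([10, 10, 10])
        est = survey.meadow_resources(counts, simple_profiles, area_m2=300.0)
        assert est.nectar_per_m2_day_mg == pytest.approx(1.0)
        assert est.meadow_nectar_day_mg == pytest.approx(300.0)
        assert est.coverage == 1.0

    def test_zero_counts_everywhere(self, simple_profiles):
        counts = make_counts([0, 0, 0])
        est = survey.meadow_resources(counts, simple_profiles)
        assert est.nectar_per_m2_day_mg == 0.0
        assert est.pollen_per_m2_day_ul == 0.0
        assert est.coverage == 1.0

    def test_species_shares_by_construction(self, simple_profiles):
        # alpha contributes 9x beta's nectar: 9 units x 100 vs 10 units x 10
        counts = pd.concat(
            [
                make_counts([9], species="alpha"),
                make_counts([10], species="beta"),
            ]
        )
        est = survey.meadow_resources(counts, simple_profiles)
        assert est.species_shares["nectar"]["alpha"] == pytest.approx(0.9)
        assert est.species_shares["nectar"]["beta"] == pytest.approx(0.1)

    def test_ci_brackets_point_and_uses_quadrat_variation(self, simple_profiles):
        counts = make_counts([5, 10, 15, 20])
        est = survey.meadow_resources(counts, simple_profiles)
        lo, hi = est.nectar_ci_mg
        assert lo < est.nectar_per_m2_day_mg < hi
        # hand computation: totals are counts x 0.1 mg
        totals = np.array([0.5, 1.0, 1.5, 2.0])
        half = 1.96 * totals.std(ddof=1) / 2.0
        assert hi - est.nectar_per_m2_day_mg == pytest.approx(half, rel=1e-3)

    def test_unprofiled_species_warns_and_reduces_coverage(self, simple_profiles):
        counts = pd.concat(
            [
                make_counts([10], species="alpha"),
                make_counts([30], species="mystery"),
            ]
        )
        with pytest.warns(UserWarning, match="mystery"):
            est = survey.meadow_resources(counts, simple_profiles)
        assert est.coverage == pytest.approx(0.25)
        # unmeasured species contributes nothing to sums
        assert est.nectar_per_m2_day_mg == pytest.approx(1.0)

    def test_linear_in_rewards_and_densities(self, simple_profiles):
        counts = make_counts([3, 5, 7])
        est = survey.meadow_resources(counts, simple_profiles)
        doubled_profiles = simple_profiles.assign(
            nectar_per_unit_day_ug=simple_profiles["nectar_per_unit_day_ug"] * 2
        )
        est2 = survey.meadow_resources(counts, doubled_profiles)
        assert est2.nectar_per_m2_day_mg == pytest.approx(2 * est.nectar_per_m2_day_mg)
        counts2 = counts.assign(count=counts["count"] * 3)
        est3 = survey.meadow_resources(counts2, simple_profiles)
        assert est3.nectar_per_m2_day_mg == pytest.approx(3 * est.nectar_per_m2_day_mg)

    def test_conservation_shares_times_total(self, simple_profiles):
        counts = pd.concat(
            [make_counts([4, 2], species="alpha"), make_counts([8, 6], species="beta")]
        )
        est = survey.meadow_resources(counts, simple_profiles)
        for resource in ("nectar", "pollen"):
            assert sum(est.species_shares[resource].values()) == pytest.approx(
                1.0, abs=1e-9
            )


class TestSeasonalSeries:
    def _multi_round(self, per_round_counts, species="alpha"):
        frames = []
        for rnd, quadrats in per_round_counts.items():
            frames.append(make_counts(quadrats, species=species, rnd=rnd))
        return pd.concat(frames, ignore_index=True)

    def test_flat_series(self, simple_profiles):
        counts = self._multi_round({r: [5, 5] for r in range(1, 7)})
        series = survey.seasonal_series(counts, simple_profiles)
        values = [e.nectar_per_m2_day_mg for e in series]
        assert values == pytest.approx([0.5] * 6)

    def test_peak_round_matches_generator(self, simple_profiles):
        shape = {1: [1], 2: [4], 3: [9], 4: [16], 5: [9], 6: [4]}
        series = survey.seasonal_series(self._multi_round(shape), simple_profiles)
        peak = max(series, key=lambda e: e.nectar_per_m2_day_mg)
        assert peak.round == 4

    def test_missing_round_is_gap_and_zero_round_is_zero(self, simple_profiles):
        counts = self._multi_round({1: [5], 3: [0]})
        series = survey.seasonal_series(counts, simple_profiles)
        rounds = [e.round for e in series]
        assert rounds == [1, 3]
        assert series[1].nectar_per_m2_day_mg == 0.0

    def test_contribution_stack_rows_sum_to_one(self, simple_profiles):
        counts = pd.concat(
            [
                self._multi_round({1: [5], 2: [5]}, species="alpha"),
                self._multi_round({1: [5], 2: [5]}, species="beta"),
            ]
        )
        series = survey.seasonal_series(counts, simple_profiles)
        stack = survey.species_contribution_stack(series, "nectar")
        assert np.allclose(stack.sum(axis=1), 1.0)

    def test_single_species_share_is_one(self, simple_profiles):
        series = survey.seasonal_series(
            self._multi_round({1: [5], 2: [9]}), simple_profiles
        )
        stack = survey.species_contribution_stack(series, "pollen")
        assert np.allclose(stack["alpha"], 1.0)

    def test_weed_only_round_gets_full_share(self):
        profiles = pd.DataFrame(
            {
                "species": ["sown", "weed"],
                "nectar_per_unit_day_ug": [100.0, 50.0],
                "pollen_per_unit_day_ul": [0.5, 0.2],
                "measured": [True, True],
            }
        )
        counts = pd.concat(
            [
                make_counts([10], species="weed", rnd=1),
                make_counts([10], species="sown", rnd=2),
                make_counts([10], species="weed", rnd=2),
            ]
        )
        series = survey.seasonal_series(counts, profiles)
        stack = survey.species_contribution_stack(series, "nectar")
        first = stack.xs(1, level="round").iloc[0]
        assert first.get("weed", 0.0) == pytest.approx(1.0)


class TestSubsampling:
    def test_exhaustive_draw_is_exact_with_zero_variance(self, simple_profiles):
        counts = make_counts([1, 2, 3, 4, 5])
        out = survey.subsample_simulation(counts, simple_profiles, [5], 50, seed=1)
        nectar = out[out["resource"] == "nectar_mg"].iloc[0]
        assert nectar["var_estimate"] == pytest.approx(0.0, abs=1e-18)
        assert nectar["mean_estimate"] == pytest.approx(3.0 * 0.1)

    def test_same_seed_is_deterministic(self, simple_profiles):
        counts = make_counts(list(range(12)))
        a = survey.subsample_simulation(counts, simple_profiles, [3, 6], 200, seed=9)
        b = survey.subsample_simulation(counts, simple_profiles, [3, 6], 200, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_subset_larger_than_available_rejected(self, simple_profiles):
        with pytest.raises(InputError):
            survey.subsample_simulation(
                make_counts([1, 2]), simple_profiles, [3], 10, seed=1
            )

    def test_variance_declines_with_effort(self, simple_profiles, rng):
        counts = make_counts(list(rng.negative_binomial(2, 0.05, size=40)))
        out = survey.subsample_simulation(
            counts, simple_profiles, [5, 20], 2000, seed=3
        )
        nectar = out[out["resource"] == "nectar_mg"].set_index("n_quadrats")
        assert nectar.loc[5, "var_estimate"] > nectar.loc[20, "var_estimate"]

    def test_estimator_unbiased_across_reps(self, simple_profiles, rng):
        counts = make_counts(list(rng.poisson(20, size=30)))
        out = survey.subsample_simulation(counts, simple_profiles, [10], 4000, seed=5)
        full_mean = survey.per_quadrat_totals(counts, simple_profiles)["nectar_mg"].mean()
        nectar = out[out["resource"] == "nectar_mg"].iloc[0]
        mc_se = np.sqrt(nectar["var_estimate"] / 4000)
        assert nectar["mean_estimate"] == pytest.approx(full_mean, abs=4 * mc_se)


class TestSchemeComparison:
    def _with_positions(self, quadrat_counts):
        counts = make_counts(quadrat_counts)
        counts["position"] = [
            "edge" if i % 2 == 0 else "internal" for i in range(len(counts))
        ]
        return counts

    def test_identical_quadrats_give_zero_difference(self, simple_profiles):
        counts = self._with_positions([5] * 20)
        out = survey.scheme_comparison(counts, simple_profiles)
        assert out["pct_difference"].abs().max() == pytest.approx(0.0)

    def test_unbiased_over_many_meadows(self, simple_profiles, rng):
        diffs = []
        for _ in range(200):
            counts = self._with_positions(list(rng.poisson(8, size=20)))
            out = survey.scheme_comparison(counts, simple_profiles)
            diffs.append(out["pct_difference"].iloc[0])
        assert abs(np.mean(diffs)) < 3 * np.std(diffs) / np.sqrt(len(diffs)) + 2.0

    def test_position_column_required(self, simple_profiles):
        with pytest.raises(InputError):
            survey.scheme_comparison(make_counts([1, 2]), simple_profiles)


class TestSeasonalIntegral:
    def test_triangle_by_trapezoid(self):
        assert survey.seasonal_integral([0, 10, 20], [0, 10, 0]) == pytest.approx(100.0)

    def test_flat_series(self):
        assert survey.seasonal_integral([0, 30], [2.5, 2.5]) == pytest.approx(75.0)

    def test_fitted_curve_matches_gaussian_closed_form(self):
        amp, mu, sd = 12.0, 50.0, 15.0
        days = np.linspace(0, 105, 6)
        values = amp * np.exp(-((days - mu) ** 2) / (2 * sd**2))
        est = survey.seasonal_integral(days, values, method="fitted_curve")
        exact = amp * sd * np.sqrt(2 * np.pi)
        assert est == pytest.approx(exact, rel=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            survey.seasonal_integral([0], [1.0])
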