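"""Suppression filtering, selection bias, geographic splits, ratio audits."""

import numpy as np
import pandas as pd
import pytest

from countylex.core_io import CountyRecord, MortalityEntry, ValidationError
from countylex.language_scoring import dictionary_score, scores_to_frame
from countylex.robustness_checks import (
    crud_scan,
    latitude_split,
    percent_lower,
    range_factor,
    rate_ratio,
    selection_bias_test,
    suppression_filter,
)
from countylex.synthetic_data import (
    SyntheticConfig,
    generate_counties,
    generate_mortality,
    generate_study,
)

CAUSE = "I25.1"


def _county(fips, pop, deaths=None, years=2.0, rate=None, lat=np.nan):
    mortality = {}
    if deaths is not None:
        mortality[CAUSE] = MortalityEntry(
            cause=CAUSE, deaths=deaths, years=years,
            rate=rate if rate is not None else deaths / pop * 100_000 / years,
        )
    return CountyRecord(
        fips=fips, name=f"c{fips}", state="XX", population=pop,
        centroid_lat=lat, mortality=mortality,
    )


class TestSuppressionFilter:
    def test_above_threshold_kept(self):
        # 25 deaths over 2 years -> 12.5/yr, included
        kept, dropped = suppression_filter(
            [_county("00001", 20_007, deaths=25)], CAUSE, 10.0
        )
        assert len(kept) == 1 and not dropped

    def test_below_threshold_dropped(self):
        # 17 deaths over 2 years -> 8.5/yr, excluded
        kept, dropped = suppression_filter(
            [_county("00001", 71_492, deaths=17)], CAUSE, 10.0
        )
        assert not kept and len(dropped) == 1
        assert "8.50" in dropped[0][1]

    def test_boundary_is_inclusive(self):
        # exactly 10/yr: "at least" keeps it
        kept, _ = suppression_filter(
            [_county("00001", 50_000, deaths=20)], CAUSE, 10.0
        )
        assert len(kept) == 1

    def test_missing_cause_dropped_with_reason(self):
        kept, dropped = suppression_filter([_county("00001", 1000)], CAUSE, 10.0)
        assert not kept
        assert dropped[0][1] == "no data"

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        counties = [
            _county(f"{i:05d}", 10_000, deaths=int(d))
            for i, d in enumerate(rng.integers(0, 60, size=40), start=1)
        ]
        kept_sets = []
        for thr in (0.0, 5.0, 10.0, 20.0):
            kept, _ = suppression_filter(counties, CAUSE, thr)
            kept_sets.append({c.fips for c in kept})
        for lo, hi in zip(kept_sets, kept_sets[1:]):
            assert hi <= lo  # raising the threshold never adds a county

    def test_selection_property_small_counties_need_higher_rates(self):
        """With true rates independent of population and baseline near the
        threshold, the release rule keeps only high-rate small counties, so
        kept below-median-population counties average a higher observed rate
        than kept above-median ones (directional, over many replicates)."""
        diffs = []
        for seed in range(100):
            cfg = SyntheticConfig(
                n_counties=120, seed=seed, rho_language_outcome=0.0,
                pop_log10_range=(3.5, 5.5), baseline_rate=30.0,
                rate_dispersion=0.3,
            )
            counties, truth = generate_counties(cfg)
            generate_mortality(counties, truth, cfg)
            kept, _ = suppression_filter(counties, CAUSE, 10.0)
            if len(kept) < 10:
                continue
            pops = np.array([c.population for c in kept])
            rates = np.array([c.mortality[CAUSE].rate for c in kept])
            med = np.median(pops)
            if (pops < med).sum() < 2 or (pops >= med).sum() < 2:
                continue
            diffs.append(rates[pops < med].mean() - rates[pops >= med].mean())
        assert len(diffs) >= 50
        assert np.mean(diffs) > 0


class TestSelectionBiasTest:
    def test_null_calibration(self):
        """Rates independent of population: rejections at alpha=.05 stay in
        the binomial 99% band."""
        rejections = 0
        n_reps = 60
        for seed in range(n_reps):
            cfg = SyntheticConfig(
                n_counties=200, seed=seed, pop_log10_range=(4.5, 6.5),
                baseline_rate=100.0, rate_dispersion=0.2,
            )
            counties, truth = generate_counties(cfg)
            generate_mortality(counties, truth, cfg)
            tt, _ = selection_bias_test(counties, CAUSE)
            rejections += tt.p < 0.05
        upper = 0.05 + 2.576 * np.sqrt(0.05 * 0.95 / n_reps)
        assert rejections / n_reps <= upper

    def test_monotone_rate_in_population_detected(self):
        rng = np.random.default_rng(9)
        counties = []
        for i in range(60):
            pop = int(10 ** rng.uniform(3, 6))
            rate = 200.0 - 20.0 * np.log10(pop)
            counties.append(_county(f"{i + 1:05d}", pop, deaths=10, rate=rate))
        tt, split = selection_bias_test(counties, CAUSE)
        assert tt.mean_a > tt.mean_b  # below-median mean exceeds above-median
        assert tt.t > 0

    def test_two_counties_is_degenerate(self):
        counties = [_county("00001", 100, deaths=20), _county("00002", 200, deaths=20)]
        with pytest.raises(ValidationError):
            selection_bias_test(counties, CAUSE)

    def test_equal_populations_rejected(self):
        counties = [_county(f"{i:05d}", 1000, deaths=20 + i) for i in range(1, 6)]
        with pytest.raises(ValidationError, match="degenerate"):
            selection_bias_test(counties, CAUSE)

    def test_group_sizes_near_equal(self):
        rng = np.random.default_rng(10)
        counties = [
            _county(f"{i:05d}", int(p), deaths=30)
            for i, p in enumerate(rng.integers(1_000, 1_000_000, 31), start=1)
        ]
        _, split = selection_bias_test(counties, CAUSE)
        sizes = pd.Series(split.groups).value_counts()
        assert abs(sizes["below"] - sizes["above"]) <= 1


class TestLatitudeSplit:
    def _study(self, seed=0, n=240):
        cfg = SyntheticConfig(
            n_counties=n, seed=seed, rho_language_outcome=0.4,
            pop_log10_range=(4.5, 6.5), baseline_rate=100.0,
            rate_dispersion=0.5, vocab_size=400,
        )
        counties, table, dic, _ = generate_study(cfg)
        scores = scores_to_frame(dictionary_score(table, dic))
        return counties, scores

    def test_hand_median_and_group_assignment(self):
        counties = [
            _county(f"{i:05d}", 1000, deaths=25 + i, lat=lat)
            for i, lat in enumerate((30.0, 35.0, 40.0, 45.0) * 3, start=1)
        ]
        counties_scores = pd.DataFrame({
            "fips": [c.fips for c in counties],
            "variable_id": "v",
            "value": np.linspace(0, 1, len(counties)),
        })
        res = latitude_split(counties, counties_scores, CAUSE, [])
        assert res.split_value == pytest.approx(37.5)
        north = {f for f, g in res.groups.items() if g == "north"}
        expected_north = {c.fips for c in counties if c.centroid_lat > 37.5}
        assert north == expected_north

    def test_groups_partition_with_near_equal_sizes(self):
        counties, scores = self._study()
        res = latitude_split(counties, scores, CAUSE, [])
        sizes = pd.Series(res.groups).value_counts()
        assert sizes.sum() == len(counties)
        assert abs(sizes["north"] - sizes["south"]) <= 1

    def test_homogeneous_effect_similar_across_halves(self):
        """A nationwide latent effect shows comparable correlations in the
        two halves: the difference stays within 3 combined SEs per seed."""
        for seed in range(8):
            counties, scores = self._study(seed=seed)
            res = latitude_split(counties, scores, CAUSE, [])
            (rn,) = [r for r in res.group_stats["north"]]
            (rs,) = [r for r in res.group_stats["south"]]
            se = np.sqrt(1 / (rn.n - 3) + 1 / (rs.n - 3))
            assert abs(np.arctanh(rn.r) - np.arctanh(rs.r)) < 3 * se

    def test_identical_latitudes_rejected(self):
        counties = [
            _county(f"{i:05d}", 1000, deaths=30, lat=40.0) for i in range(1, 12)
        ]
        scores = pd.DataFrame(
            {"fips": [c.fips for c in counties], "variable_id": "v", "value": 0.5}
        )
        with pytest.raises(ValidationError, match="degenerate"):
            latitude_split(counties, scores, CAUSE, [])


class TestRatios:
    def test_range_factor_extreme_coding_variability(self):
        counties = [
            _county("00001", 100_000, deaths=100, rate=13.4),
            _county("00002", 100_000, deaths=100, rate=185.0),
        ]
        assert range_factor(counties, CAUSE) == pytest.approx(13.8, abs=0.05)

    def test_range_factor_typical_causes(self):
        cancer = [
            _county("00001", 100_000, deaths=100, rate=102.4),
            _county("00002", 100_000, deaths=100, rate=326.7),
        ]
        allcause = [
            _county("00001", 100_000, deaths=100, rate=478.8),
            _county("00002", 100_000, deaths=100, rate=1390.3),
        ]
        assert range_factor(cancer, CAUSE) == pytest.approx(3.19, abs=0.005)
        assert range_factor(allcause, CAUSE) == pytest.approx(2.90, abs=0.005)

    def test_range_factor_equal_rates(self):
        counties = [
            _county(f"{i:05d}", 1000, deaths=30, rate=50.0) for i in range(1, 4)
        ]
        assert range_factor(counties, CAUSE) == 1.0

    def test_range_factor_zero_rate_rejected(self):
        counties = [
            _county("00001", 1000, deaths=0, rate=0.0),
            _county("00002", 1000, deaths=30, rate=50.0),
        ]
        with pytest.raises(ValidationError):
            range_factor(counties, CAUSE)

    def test_percent_lower_jackson_vs_clay(self):
        assert percent_lower(45.4, 59.5) == pytest.approx(23.7, abs=0.05)

    def test_percent_lower_edges(self):
        assert percent_lower(42.0, 42.0) == 0.0
        assert percent_lower(0.0, 10.0) == 100.0
        with pytest.raises(ValidationError):
            percent_lower(5.0, 0.0)

    def test_rate_ratio_profanity_example(self):
        # 9 occurrences among 29,872 vs 9,271 among 50,219 inhabitants
        assert rate_ratio(9, 29_872, 9_271, 50_219) == pytest.approx(612.7, abs=0.5)

    def test_rate_ratio_equal_rates_and_scale_invariance(self):
        assert rate_ratio(10, 1000, 20, 2000) == pytest.approx(1.0)
        assert rate_ratio(3, 500, 7, 900) == pytest.approx(
            rate_ratio(3, 1000, 7, 1800)
        )

    def test_rate_ratio_zero_numerator_is_infinite(self):
        assert rate_ratio(0, 1000, 5, 1000) == float("inf")


class TestCrudScan:
    def _counties_with_causes(self, seed, n=300):
        rng = np.random.default_rng(seed)
        counties = []
        for i in range(n):
            c = _county(f"{i + 1:05d}", 10_000)
            c.mortality["A"] = MortalityEntry("A", 10, 2.0, float(rng.gamma(9, 5)))
            c.mortality["B"] = MortalityEntry("B", 10, 2.0, float(rng.gamma(9, 5)))
            counties.append(c)
        return counties

    def test_diagonal_is_unity_and_matrix_symmetric(self):
        counties = self._counties_with_causes(0)
        matrix, _ = crud_scan(counties, ["A", "B"])
        assert matrix.loc["A", "A"] == 1.0
        assert matrix.loc["A", "B"] == pytest.approx(matrix.loc["B", "A"], abs=1e-12)

    def test_independent_causes_near_zero(self):
        n = 1000
        for seed in range(5):
            counties = self._counties_with_causes(seed, n=n)
            matrix, _ = crud_scan(counties, ["A", "B"])
            assert abs(matrix.loc["A", "B"]) < 3 / np.sqrt(n)

    def test_shared_confound_produces_crud(self):
        """Causes driven by a common county factor correlate strongly —
        the crud factor that makes aggregate 'findings' cheap."""
        rng = np.random.default_rng(3)
        n = 400
        latent = rng.standard_normal(n)
        counties = []
        for i in range(n):
            c = _county(f"{i + 1:05d}", 10_000)
            c.mortality["assault"] = MortalityEntry(
                "assault", 10, 2.0, float(np.exp(0.5 * latent[i] + 0.3 * rng.standard_normal() + 2))
            )
            c.mortality["cancer"] = MortalityEntry(
                "cancer", 10, 2.0, float(np.exp(0.5 * latent[i] + 0.3 * rng.standard_normal() + 5))
            )
            counties.append(c)
        matrix, long_form = crud_scan(counties, ["assault", "cancer"])
        assert matrix.loc["assault", "cancer"] > 0.4
        assert long_form[0].ci_low > 0

    def test_single_cause_rejected(self):
        with pytest.raises(ValidationError):
            crud_scan(self._counties_with_causes(0), ["A"])

    def test_zero_variance_pair_marked_absent(self):
        counties = self._counties_with_causes(1, n=50)
        for c in counties:
            c.mortality["C"] = MortalityEntry("C", 10, 2.0, 42.0)
        matrix, _ = crud_scan(counties, ["A", "C"])
        assert np.isnan(matrix.loc["A", "C"])
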