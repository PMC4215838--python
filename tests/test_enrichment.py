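"""Odds of presence, pooled geometric means, chi-square and enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from episcreen.enrichment import (CladeEnrichmentAnalysis, chi_square_gof,
                                  enrichment_table, odds_of_presence,
                                  pooled_odds, significance_stars)
from episcreen.io import level_universes, relative_abundance
from episcreen.screen import ResponseScreen


class TestOddsOfPresence:
    def test_proportional_composition_gives_one(self):
        odds, corrected = odds_of_presence(2, 10, 20, 100)
        assert odds == 1.0 and not corrected

    def test_hand_computed_example(self):
        odds, corrected = odds_of_presence(5, 10, 10, 100)
        assert odds == pytest.approx((5 / 5) / (10 / 90)) == pytest.approx(9.0)
        assert not corrected

    def test_continuity_correction(self):
        odds, corrected = odds_of_presence(0, 10, 10, 100)
        assert odds == pytest.approx((0.5 / 10.5) / (10.5 / 90.5), abs=1e-9)
        assert odds == pytest.approx(0.410, abs=5e-4)
        assert corrected

    def test_saturated_clade_is_one(self):
        # a clade covering the whole community has identical composition
        # inside any subgroup
        odds, corrected = odds_of_presence(10, 10, 100, 100)
        assert odds == 1.0 and not corrected

    @pytest.mark.parametrize("args", [(5, 4, 10, 100), (5, 10, 4, 100),
                                      (1, 10, 101, 100)])
    def test_inconsistent_counts_rejected(self, args):
        with pytest.raises(ValueError):
            odds_of_presence(*args)

    def test_empty_subgroup_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            odds_of_presence(0, 0, 10, 100)

    @given(st.integers(1, 40), st.integers(1, 40), st.integers(1, 200))
    @settings(max_examples=150, deadline=None)
    def test_complement_duality(self, a, extra_m, extra_M):
        # for a two-clade split with no zero cells, odds(X) > 1 inside a
        # subgroup iff odds(not-X) < 1
        m = a + extra_m
        A, M = a + 5, m + extra_M + 5
        if M - A < m - a or A > M:
            return
        ox, cx = odds_of_presence(a, m, A, M)
        oy, cy = odds_of_presence(m - a, m, M - A, M)
        if cx or cy:
            return
        assert ox == pytest.approx(1.0 / oy, rel=1e-12)


class TestPooledOdds:
    def test_constant_series(self):
        res = pooled_odds([2, 2, 2, 2])
        assert (res.geometric_mean, res.ci_low, res.ci_high) == (2.0, 2.0, 2.0)

    def test_log_symmetry(self):
        assert pooled_odds([0.5, 2]).geometric_mean == pytest.approx(1.0)

    def test_matches_direct_arithmetic(self):
        odds = [1.0, 2.0, 4.0, 8.0]
        logs = [math.log(v) for v in odds]
        mean = sum(logs) / 4
        sd = math.sqrt(sum((v - mean) ** 2 for v in logs) / 3)
        t = stats.t.ppf(0.975, 3)
        res = pooled_odds(odds)
        assert res.geometric_mean == pytest.approx(math.exp(mean))
        assert res.ci_low == pytest.approx(math.exp(mean - t * sd / 2))
        assert res.ci_high == pytest.approx(math.exp(mean + t * sd / 2))

    def test_single_stratum_degenerate(self):
        res = pooled_odds([3.0])
        assert res.degenerate
        assert res.ci_low == pytest.approx(3.0) == res.ci_high

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            pooled_odds([1.0, 0.0])

    @given(st.floats(0.01, 100), st.integers(1, 8))
    @settings(max_examples=100, deadline=None)
    def test_constant_series_returns_constant(self, value, k):
        res = pooled_odds([value] * k)
        assert res.geometric_mean == pytest.approx(value, rel=1e-9)


class TestChiSquare:
    def test_observed_equals_expected(self):
        chi2, p, stars = chi_square_gof(10, 50, 100, 500)  # E = 10
        assert chi2 == 0.0 and p == 1.0 and stars == "ns"

    def test_hand_computed_example(self):
        chi2, p, _ = chi_square_gof(20, 50, 100, 500)
        assert chi2 == pytest.approx(100 * (1 / 10 + 1 / 40)) == pytest.approx(12.5)
        assert p == pytest.approx(stats.chi2.sf(12.5, 1))

    def test_star_thresholds(self):
        assert significance_stars(0.5) == "ns"
        assert significance_stars(0.049) == "*"
        assert significance_stars(0.024) == "**"
        assert significance_stars(0.0009) == "***"

    def test_degenerate_expectation_rejected(self):
        with pytest.raises(ValueError):
            chi_square_gof(0, 10, 0, 100)

    @given(st.integers(0, 30), st.integers(1, 170))
    @settings(max_examples=100, deadline=None)
    def test_complement_label_swap_invariance(self, a, spare):
        m, A, M = 30, 60, 200
        a = min(a, A)
        chi_x = chi_square_gof(a, m, A, M)[0]
        chi_y = chi_square_gof(m - a, m, M - A, M)[0]
        assert chi_x == pytest.approx(chi_y, rel=1e-12)


def _screen(study, compound="dmsp"):
    est = ResponseScreen(compounds=[compound]).fit(
        relative_abundance(study.counts), study.metadata)
    return est.classes_


class TestEnrichmentTable:
    def test_planted_deterred_clade_flagged(self, planted_study):
        classes = _screen(planted_study)
        universes = level_universes(planted_study.counts, planted_study.metadata)
        table = enrichment_table(classes, planted_study.clades, universes)
        row = table[(table.clade == "Firmicutes") & (table.subgroup == "negative")
                    & (table.compound == "dmsp")].iloc[0]
        assert row["geometric_mean"] > 1.0
        assert row["p_value"] < 0.05
        assert row["k"] == 11  # 5 temperature + 6 light strata

    def test_single_clade_scheme_gives_unit_odds(self, small_study):
        classes = _screen(small_study)
        clades = pd.Series("everything", index=small_study.counts.columns)
        universes = level_universes(small_study.counts, small_study.metadata)
        table = enrichment_table(classes, clades, universes)
        assert np.allclose(table["geometric_mean"], 1.0)

    def test_shuffled_clade_labels_destroy_significance(self, planted_study):
        classes = _screen(planted_study)
        universes = level_universes(planted_study.counts, planted_study.metadata)
        rng = np.random.default_rng(5)
        rejections = total = 0
        for _ in range(25):
            shuffled = pd.Series(rng.permutation(planted_study.clades.to_numpy()),
                                 index=planted_study.clades.index)
            table = enrichment_table(classes, shuffled, universes)
            rejections += int((table["p_value"] < 0.05).sum())
            total += len(table)
        rate = rejections / total
        # the test is conservative for large subgroups, so the null
        # rejection rate must sit at or below the nominal level
        assert rate <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / total)

    def test_per_experiment_strata(self, small_study):
        classes = _screen(small_study)
        universes = level_universes(small_study.counts, small_study.metadata)
        table = enrichment_table(classes, small_study.clades, universes,
                                 strata="per_experiment")
        assert table["k"].max() <= 2

    def test_estimator_wrapper(self, small_study):
        classes = _screen(small_study)
        universes = level_universes(small_study.counts, small_study.metadata)
        est = CladeEnrichmentAnalysis().fit(classes, small_study.clades, universes)
        assert set(est.table_["subgroup"]) <= {"positive", "negative"}
        assert est.get_params()["strata"] == "per_level"
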