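"""Spearman screen, sign-consistency classes and null behaviour."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from episcreen.calibration import naive_spearman, null_rank_sign_probability
from episcreen.io import relative_abundance
from episcreen.screen import (ResponseScreen, classify_consistency,
                              level_correlations, spearman_rho,
                              subgroup_fractions)
from episcreen.simulate import (ExperimentDesign, PlantedEffect,
                                SimulationConfig, simulate_study)


class TestSpearmanRho:
    @pytest.mark.parametrize("x,y,rho,sign", [
        ([1, 2, 3, 4, 5], [2, 4, 6, 8, 10], 1.0, "positive"),
        ([1, 2, 3, 4, 5], [5, 4, 3, 2, 1], -1.0, "negative"),
        ([1, 2, 3, 4, 5], [3, 3, 3, 3, 3], float("nan"), "undefined"),
    ])
    def test_examples(self, x, y, rho, sign):
        got_rho, got_sign = spearman_rho(x, y)
        assert got_sign == sign
        if not math.isnan(rho):
            assert got_rho == pytest.approx(rho)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [1, 2])

    @pytest.mark.parametrize("x,y", [
        ([1, 1, 2, 3, 3], [1, 2, 3, 4, 5]),
        ([0, 0, 0, 1, 2], [2, 2, 1, 0, 0]),
        ([1, 2, 2, 2, 5], [5, 1, 1, 3, 2]),
    ])
    def test_tie_handling_matches_naive_oracle(self, x, y):
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(naive_spearman(x, y), abs=1e-12)

    @given(st.lists(st.integers(0, 9), min_size=4, max_size=8),
           st.randoms(use_true_random=False))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry(self, y, rnd):
        x = list(range(len(y)))
        rnd.shuffle(x)
        rho_fwd, sign_fwd = spearman_rho(x, y)
        rho_rev, sign_rev = spearman_rho(x, [-v for v in y])
        if sign_fwd == "undefined":
            assert sign_rev == "undefined"
        else:
            assert rho_rev == pytest.approx(-rho_fwd, abs=1e-12)

    @given(st.lists(st.integers(1, 50), min_size=4, max_size=8, unique=True))
    @settings(max_examples=100, deadline=None)
    def test_monotone_transform_invariance(self, x):
        y = [((-1) ** i) * v for i, v in enumerate(x)]
        rho, _ = spearman_rho(x, y)
        rho_t, _ = spearman_rho([math.exp(v / 10.0) for v in x], y)
        assert rho_t == pytest.approx(rho, abs=1e-12)


class TestLevelCorrelations:
    def _meta(self):
        rows = []
        for level, concs in [("L1", [1.0, 2.0, 3.0, 4.0, 5.0]),
                             ("L2", [2.0, 2.0, 2.0, 2.0, 2.0])]:
            for i, c in enumerate(concs, 1):
                rows.append({"sample_id": f"{level}_r{i}", "experiment": "temperature",
                             "level_label": level, "replicate": i,
                             "dmsp_ng_cm2": c, "proline_ng_cm2": 0.01,
                             "fucoxanthin_ng_cm2": 10.0})
        return pd.DataFrame(rows)

    def _abund(self, meta):
        # otu_up rises with DMSP at L1; otu_absent undetected at L1;
        # otu_flat constant where detected
        data = {}
        data["otu_up"] = [0.1, 0.2, 0.3, 0.4, 0.5] + [0.1] * 5
        data["otu_absent"] = [0.0] * 5 + [0.2, 0.1, 0.3, 0.2, 0.1]
        data["otu_flat"] = [0.2] * 10
        return pd.DataFrame(data, index=meta["sample_id"])

    def test_detection_and_signs(self):
        meta = self._meta()
        rec = level_correlations(self._abund(meta), meta, "dmsp")
        up_l1 = rec[(rec.otu_id == "otu_up") & (rec.level_label == "L1")]
        assert up_l1["sign"].item() == "positive"
        assert up_l1["n"].item() == 5
        # not detected at L1 -> no record there, but one at L2
        absent = rec[rec.otu_id == "otu_absent"]
        assert set(absent["level_label"]) == {"L2"}
        # constant abundance -> undefined; constant concentration too (L2)
        flat = rec[rec.otu_id == "otu_flat"]
        assert set(flat["sign"]) == {"undefined"}

    def test_missing_compound_column(self):
        meta = self._meta().drop(columns=["proline_ng_cm2"])
        with pytest.raises(ValueError, match="proline"):
            level_correlations(self._abund(self._meta()), meta, "proline")

    def test_too_few_replicates(self):
        meta = self._meta().iloc[[0, 1, 5, 6, 7, 8, 9]]
        with pytest.raises(ValueError, match=">= 3"):
            level_correlations(self._abund(self._meta()), meta, "dmsp")


def _records(signs, otu="o1", compound="dmsp", experiment="temperature"):
    return pd.DataFrame({
        "otu_id": otu, "compound": compound, "experiment": experiment,
        "level_label": [f"L{i}" for i in range(len(signs))],
        "rho": [{"positive": 0.5, "negative": -0.5, "zero": 0.0,
                 "undefined": float("nan")}[s] for s in signs],
        "n": 5, "sign": list(signs),
    })


class TestClassification:
    @pytest.mark.parametrize("signs,label,n_eval", [
        (("positive", "positive", "positive"), "positive", 3),
        (("negative", "negative"), "negative", 2),
        (("positive", "negative"), "neutral", 2),
        (("positive", "zero", "positive"), "neutral", 2),
        (("undefined", "undefined"), "unevaluable", 0),
        (("positive", "undefined"), "positive", 1),
    ])
    def test_label_rules(self, signs, label, n_eval):
        out = classify_consistency(_records(signs))
        assert out["label"].item() == label
        assert out["levels_evaluated"].item() == n_eval

    def test_min_levels_gate(self):
        out = classify_consistency(_records(("positive",)), min_levels=2)
        assert out["label"].item() == "unevaluable"
        out2 = classify_consistency(_records(("positive", "positive")), min_levels=2)
        assert out2["label"].item() == "positive"

    def test_permutation_invariance(self):
        rec = pd.concat([_records(("positive", "negative", "zero"), otu="a"),
                         _records(("negative", "negative"), otu="b")],
                        ignore_index=True)
        shuffled = rec.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = classify_consistency(rec).sort_values("otu_id").reset_index(drop=True)
        b = classify_consistency(shuffled).sort_values("otu_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestSubgroupFractions:
    def test_example(self):
        classes = pd.concat(
            [classify_consistency(_records(s, otu=f"o{i}"))
             for i, s in enumerate([("negative",)] * 3 + [("positive",)] * 3
                                   + [("positive", "negative")] * 4)],
            ignore_index=True)
        frac = subgroup_fractions(classes)
        row = frac.loc[("dmsp", "temperature")]
        assert row.tolist() == pytest.approx([0.3, 0.3, 0.4, 0.0])
        assert frac.sum(axis=1).item() == pytest.approx(1.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            subgroup_fractions(pd.DataFrame(columns=["compound", "experiment", "label"]))


class TestNullBehaviour:
    def test_null_fractions_bounded_by_rank_probability(self):
        # continuous abundances, no coupling, every OTU detected at all
        # 5 levels: P(consistently positive) <= p0^5 where p0 = P(rho>0)
        # under random ranks (exhaustive enumeration over 120 permutations)
        rng = np.random.default_rng(12)
        n_otus, levels, reps = 4000, 5, 5
        rows = []
        for li in range(levels):
            for r in range(reps):
                rows.append({"sample_id": f"L{li}_r{r}", "experiment": "temperature",
                             "level_label": f"L{li}", "replicate": r,
                             "dmsp_ng_cm2": float(rng.lognormal(0, 1)),
                             "proline_ng_cm2": 0.01, "fucoxanthin_ng_cm2": 1.0})
        meta = pd.DataFrame(rows)
        abund = pd.DataFrame(rng.lognormal(0, 1, size=(len(meta), n_otus)),
                             index=meta["sample_id"],
                             columns=[f"o{i}" for i in range(n_otus)])
        classes = classify_consistency(level_correlations(abund, meta, "dmsp"))
        frac = subgroup_fractions(classes).loc[("dmsp", "temperature")]
        p0 = null_rank_sign_probability()
        bound = p0 ** levels + 3 * math.sqrt(p0 ** levels / n_otus)
        assert frac["positive"] <= bound
        assert frac["negative"] <= bound
        se_diff = math.sqrt(2 * p0 ** levels / n_otus)
        assert abs(frac["positive"] - frac["negative"]) <= 3 * se_diff

    def test_planted_responder_detected_across_levels(self):
        # calibrated by simulation: a single fully-occupant OTU with
        # beta=-2 shows a negative sign at >= 4 of 5 levels in ~91% of
        # studies; assert >= 0.84 (3 MC SE below) over 150 runs.
        runs, hits = 150, 0
        cfg = SimulationConfig(
            n_otus=500,
            experiments=[ExperimentDesign("temperature",
                                          ["5°C", "10°C", "15°C", "20°C", "25°C"],
                                          5, 1352)],
            planted_effects=[PlantedEffect("dmsp", "deterred", -2.0, n_otus=1,
                                           occupancy=1.0)])
        for ss in np.random.SeedSequence(7).spawn(runs):
            b = simulate_study(cfg, seed=ss)
            planted = b.truth.loc[b.truth.beta_dmsp < 0, "otu_id"].iloc[0]
            rec = level_correlations(relative_abundance(b.counts), b.metadata, "dmsp")
            sub = rec[rec.otu_id == planted]
            hits += (sub["sign"] == "negative").sum() >= 4
        assert hits / runs >= 0.84


class TestResponseScreenEstimator:
    def test_fit_produces_partition(self, small_study):
        est = ResponseScreen(compounds=["dmsp"]).fit(
            relative_abundance(small_study.counts), small_study.metadata)
        classes = est.classes_
        # one label per detected OTU per (compound, experiment)
        assert not classes.duplicated(["otu_id", "compound", "experiment"]).any()
        assert set(classes["label"]) <= {"positive", "negative", "neutral",
                                         "unevaluable"}
        assert est.fractions_.sum(axis=1).round(9).eq(1.0).all()
        assert est.get_params()["min_levels"] == 1
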