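"""Calibration and validation routines for the screening pipeline.

The headline community fractions of the original experiments depend on
deposited raw sequence data and an upstream 454 processing stack, so the
pipeline is validated by properties instead: an independent brute-force
oracle for the rank correlation, null-symmetry and type-I-error
calibration on synthetic null studies, planted-effect (parameter
recovery) simulations, and confidence-interval coverage of the pooled
odds. Each routine returns plain numbers and is deterministic given its
seed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from itertools import permutations

from .datasets import COMPOUNDS
from .enrichment import chi_square_gof, enrichment_table, pooled_odds
from .io import level_universes
from .screen import ResponseScreen, spearman_rho, subgroup_fractions
from .simulate import PlantedEffect, SimulationConfig, simulate_study


# ---------------------------------------------------------------------------
# Independent Spearman oracle (pure-python average ranks + Pearson)


def naive_spearman(x, y) -> float:
    """Brute-force Spearman: average ranks by counting, then Pearson sums.

    Deliberately written with explicit loops and no ranking library so
    it is an independent oracle for :func:`episcreen.screen.spearman_rho`.
    Returns NaN for constant vectors.
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    if len(set(x)) < 2 or len(set(y)) < 2:
        return float("nan")

    def ranks(v):
        out = []
        for vi in v:
            less = sum(1 for vj in v if vj < vi)
            equal = sum(1 for vj in v if vj == vi)
            out.append(less + (equal + 1) / 2.0)
        return out

    rx, ry = ranks(x), ranks(y)
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    sxx = sum((a - mx) ** 2 for a in rx)
    syy = sum((b - my) ** 2 for b in ry)
    return sxy / math.sqrt(sxx * syy)


def spearman_oracle_max_diff(seed: int = 0, n_random: int = 1000) -> dict:
    """Max |rho - oracle| over all 120 rank permutations of n=5 and
    ``n_random`` random tie-containing vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    x = [1, 2, 3, 4, 5]
    n_checked = 0
    for perm in permutations(x):
        rho, _ = spearman_rho(x, perm)
        worst = max(worst, abs(rho - naive_spearman(x, perm)))
        n_checked += 1
    for _ in range(n_random):
        a = rng.integers(0, 4, size=5)
        b = rng.integers(0, 4, size=5)
        rho, sign = spearman_rho(a, b)
        oracle = naive_spearman(a, b)
        if math.isnan(oracle) or sign == "undefined":
            assert math.isnan(oracle) and sign == "undefined"
        else:
            worst = max(worst, abs(rho - oracle))
        n_checked += 1
    return {"max_abs_diff": worst, "n": n_checked}


def null_rank_sign_probability() -> float:
    """P(rho > 0) for random ranks at n=5, by exhaustive enumeration."""
    base = [1, 2, 3, 4, 5]
    pos = sum(1 for p in permutations(base) if naive_spearman(base, p) > 0)
    return pos / math.factorial(5)


# ---------------------------------------------------------------------------
# Null calibration on synthetic null studies


def null_symmetry(n_runs: int = 50, seed: int = 0, n_otus: int = 2000) -> dict:
    """Positive/negative subgroup symmetry on null studies (no coupling).

    Runs ``n_runs`` full synthetic studies with no planted effects,
    screens all compounds, and reports the mean difference between
    positive- and negative-class fractions (averaged over compound ×
    experiment cells) in units of its Monte-Carlo standard error.
    """
    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    diffs, pos, neg = [], [], []
    for ss in seeds:
        bundle = simulate_study(SimulationConfig(n_otus=n_otus), seed=ss)
        screen = ResponseScreen().fit(bundle.counts, bundle.metadata)
        frac = screen.fractions_
        diffs.append(float((frac["positive"] - frac["negative"]).mean()))
        pos.append(float(frac["positive"].mean()))
        neg.append(float(frac["negative"].mean()))
    diffs = np.asarray(diffs)
    se = diffs.std(ddof=1) / math.sqrt(n_runs)
    return {"mean_diff": float(diffs.mean()), "se": float(se),
            "z": float(abs(diffs.mean()) / se) if se > 0 else 0.0,
            "frac_positive": float(np.mean(pos)),
            "frac_negative": float(np.mean(neg)), "n": n_runs}


def chi2_type1_rate(n_reps: int = 10000, seed: int = 0,
                    M: int = 8000, A: int = 800, m: int = 400,
                    alpha: float = 0.05) -> dict:
    """Type-I error of the chi-square test under a uniformly drawn subgroup.

    A subgroup of size ``m`` is drawn uniformly from a community of
    ``M`` OTUs containing a clade of size ``A``; the clade count inside
    the subgroup is then hypergeometric. The sampling fraction m/M is
    kept small so the overlap between subgroup and reference community
    is negligible and the nominal 1-df level applies.
    """
    rng = np.random.default_rng(seed)
    a_draws = rng.hypergeometric(A, M - A, m, size=n_reps)
    rejected = 0
    for a in a_draws:
        _chi2, p, _stars = chi_square_gof(int(a), m, A, M)
        rejected += p < alpha
    return {"rate": rejected / n_reps, "n": n_reps}


# ---------------------------------------------------------------------------
# Parameter recovery: planted deterred clade


def planted_clade_recovery(n_runs: int = 200, seed: int = 0,
                           n_otus: int = 2000, beta: float = -3.0,
                           clade: str = "Firmicutes", n_planted: int = 20,
                           compound: str = "dmsp") -> dict:
    """Fraction of studies flagging a planted deterred clade.

    Each study plants ``n_planted`` fully occupant OTUs of one clade
    with strong negative coupling to one compound. The clade counts as
    recovered when its pooled odds in the compound-negative subgroup
    exceed 1 **and** its chi-square p-value is below 0.05.
    """
    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    hits = 0
    for ss in seeds:
        config = SimulationConfig(n_otus=n_otus, planted_effects=[
            PlantedEffect(compound, "deterred", beta, n_otus=n_planted,
                          clade=clade, occupancy=1.0)])
        bundle = simulate_study(config, seed=ss)
        screen = ResponseScreen(compounds=[compound]).fit(bundle.counts, bundle.metadata)
        universes = level_universes(bundle.counts, bundle.metadata)
        table = enrichment_table(screen.classes_, bundle.clades, universes)
        row = table[(table["clade"] == clade) & (table["compound"] == compound)
                    & (table["subgroup"] == "negative")]
        if len(row) == 1:
            r = row.iloc[0]
            hits += bool(r["geometric_mean"] > 1.0) and bool(r["p_value"] < 0.05)
    return {"rate": hits / n_runs, "n": n_runs}


# ---------------------------------------------------------------------------
# CI coverage of the pooled geometric mean


def pooled_odds_ci_coverage(n_reps: int = 10000, k: int = 11,
                            true_gm: float = 1.5, log_sd: float = 0.5,
                            seed: int = 0) -> dict:
    """Coverage of the 95% CI under lognormal per-stratum odds."""
    rng = np.random.default_rng(seed)
    covered = 0
    mu = math.log(true_gm)
    for _ in range(n_reps):
        odds = np.exp(rng.normal(mu, log_sd, size=k))
        res = pooled_odds(odds)
        covered += res.ci_low <= true_gm <= res.ci_high
    return {"coverage": covered / n_reps, "n": n_reps}
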