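"""Clade over-representation within compound-positive/-negative subgroups.

For a clade with ``A`` members in a community of ``M`` detected OTUs, of
which ``a`` fall inside a subgroup of size ``m`` (e.g. the DMSP-negative
OTUs), the odds of presence are

    odds = [a / (m - a)] / [A / (M - A)]

Odds > 1 mean the clade is more prevalent inside the subgroup than in
the total community; odds < 1 the inverse. One odds value is computed
per treatment level (the stratum's community is the OTUs detected at
that level), pooled across both experiments as a geometric mean with a
t-based 95% confidence interval on the log scale. Divergence of the
observed subgroup count from its expectation E = m·A/M is tested with a
1-df chi-square goodness-of-fit statistic on experiment-pooled counts,

    chi2 = (a - E)^2 * (1/E + 1/(m - E)).

Zero cells receive a Haldane–Anscombe +0.5 continuity correction (added
to all four odds terms) and are flagged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

#: chi-square star thresholds, most stringent first.
STAR_THRESHOLDS = [(0.001, "***"), (0.025, "**"), (0.05, "*")]

ENRICHMENT_COLUMNS = ["clade", "compound", "subgroup", "k", "geometric_mean",
                      "ci_low", "ci_high", "chi2", "p_value", "significance",
                      "n_continuity_cells"]


def significance_stars(p: float) -> str:
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


def odds_of_presence(a: int, m: int, A: int, M: int) -> tuple[float, bool]:
    """Odds of a clade's presence in a subgroup relative to the community.

    Returns ``(odds, corrected)`` where ``corrected`` flags the +0.5
    continuity correction applied when any of a, m−a, A, M−A is zero.
    """
    if not (0 <= a <= min(m, A) and A <= M and m <= M):
        raise ValueError(f"inconsistent counts a={a}, m={m}, A={A}, M={M}")
    if m == 0 or M == 0:
        raise ValueError("undefined odds: empty subgroup or community")
    if a * M == A * m:
        # identical composition in subgroup and community (this covers the
        # saturated-clade case, where the raw ratio is 0/0): odds are 1 by
        # definition, no continuity needed
        return 1.0, False
    corrected = min(a, m - a, A, M - A) == 0
    if corrected:
        af, bf, Af, Bf = a + 0.5, m - a + 0.5, A + 0.5, M - A + 0.5
    else:
        af, bf, Af, Bf = a, m - a, A, M - A
    return (af / bf) / (Af / Bf), corrected


@dataclass
class PooledOdds:
    geometric_mean: float
    ci_low: float
    ci_high: float
    k: int
    degenerate: bool  # k == 1: the CI is the point itself


def pooled_odds(odds) -> PooledOdds:
    """Geometric mean of per-stratum odds with a 95% t-interval.

    GM = exp(mean(ln odds)); CI = exp(mean ± t_{0.975,k-1}·sd/√k) on the
    log scale. A single stratum gives a degenerate point interval.
    """
    odds = np.asarray(odds, dtype=float)
    if odds.size == 0:
        raise ValueError("need at least one odds value")
    if np.any(odds <= 0):
        raise ValueError("all odds must be positive (apply continuity upstream)")
    logs = np.log(odds)
    k = logs.size
    gm = math.exp(logs.mean())
    if k == 1:
        return PooledOdds(gm, gm, gm, 1, True)
    se = logs.std(ddof=1) / math.sqrt(k)
    t = stats.t.ppf(0.975, k - 1)
    return PooledOdds(gm, math.exp(logs.mean() - t * se),
                      math.exp(logs.mean() + t * se), k, False)


def chi_square_gof(a: int, m: int, A: int, M: int) -> tuple[float, float, str]:
    """1-df goodness-of-fit test of subgroup count vs community expectation.

    Returns ``(chi2, p_value, stars)``. Skipped (ValueError) when the
    expectation E = m·A/M is degenerate (0 or m).
    """
    if m < 1 or M < 1:
        raise ValueError("need m >= 1 and M >= 1")
    E = m * A / M
    if E <= 0 or E >= m:
        raise ValueError(f"degenerate expectation E={E} for m={m}")
    chi2 = (a - E) ** 2 * (1.0 / E + 1.0 / (m - E))
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p, significance_stars(p)


def _subgroup_sets(classes: pd.DataFrame) -> dict:
    """(compound, experiment, subgroup) → set of OTU ids."""
    out = {}
    sub = classes[classes["label"].isin(["positive", "negative"])]
    for (comp, exp, lab), grp in sub.groupby(["compound", "experiment", "label"]):
        out[(comp, exp, lab)] = set(grp["otu_id"])
    return out


def enrichment_table(classes: pd.DataFrame, clades: pd.Series,
                     universes: dict, strata: str = "per_level") -> pd.DataFrame:
    """Full enrichment table, one row per (clade, compound, subgroup).

    Parameters
    ----------
    classes : response classes (from :func:`episcreen.screen.classify_consistency`).
    clades : Series mapping otu_id → clade name.
    universes : ``{(experiment, level_label): otu-id set}`` of detected
        OTUs per treatment level (see :func:`episcreen.io.level_universes`).
    strata : ``"per_level"`` (default; one odds value per treatment level
        of either experiment) or ``"per_experiment"`` (one per experiment).

    Geometric means pool all strata of both experiments; the chi-square
    test uses counts pooled over the two experiment-wide universes.
    Clades absent from every stratum are omitted with a log note.
    """
    if strata not in ("per_level", "per_experiment"):
        raise ValueError(f"unknown strata mode {strata!r}")
    clades = clades.astype(str)
    groups = _subgroup_sets(classes)
    compounds = sorted(classes["compound"].unique())
    experiments = list(dict.fromkeys(e for (e, _l) in universes))
    # experiment-wide universes = union of level universes
    exp_universe = {e: set().union(*(u for (ee, _l), u in universes.items() if ee == e))
                    for e in experiments}
    if strata == "per_level":
        strata_keys = list(universes)
        stratum_universe = dict(universes)
    else:
        strata_keys = [(e, None) for e in experiments]
        stratum_universe = {(e, None): exp_universe[e] for e in experiments}

    clade_names = [c for c in pd.unique(clades) ]
    clade_members = {c: set(clades.index[clades == c]) for c in clade_names}
    rows = []
    for compound in compounds:
        for subgroup in ("negative", "positive"):
            sub_by_exp = {e: groups.get((compound, e, subgroup), set())
                          for e in experiments}
            for clade in clade_names:
                members = clade_members[clade]
                odds_vals, n_corrected, k = [], 0, 0
                present_anywhere = False
                for (e, _lvl), U in ((key, stratum_universe[key]) for key in strata_keys):
                    M = len(U)
                    sub_otus = sub_by_exp[e] & U
                    m = len(sub_otus)
                    A = len(members & U)
                    if A > 0:
                        present_anywhere = True
                    if m == 0 or M == 0:
                        logger.warning("skipping stratum %r for clade %r: empty "
                                       "subgroup or community", (e, _lvl), clade)
                        continue
                    a = len(members & sub_otus)
                    o, corr = odds_of_presence(a, m, A, M)
                    odds_vals.append(o)
                    n_corrected += corr
                    k += 1
                if not present_anywhere:
                    logger.info("clade %r absent from every stratum; row omitted", clade)
                    continue
                if k == 0:
                    continue
                pooled = pooled_odds(odds_vals)
                # chi-square on experiment-pooled counts
                a_p = sum(len(clade_members[clade] & sub_by_exp[e] & exp_universe[e])
                          for e in experiments)
                m_p = sum(len(sub_by_exp[e] & exp_universe[e]) for e in experiments)
                A_p = sum(len(clade_members[clade] & exp_universe[e]) for e in experiments)
                M_p = sum(len(exp_universe[e]) for e in experiments)
                try:
                    chi2, p, stars = chi_square_gof(a_p, m_p, A_p, M_p)
                except ValueError:
                    chi2, p, stars = float("nan"), float("nan"), "ns"
                    logger.warning("chi-square skipped for clade %r / %s-%s",
                                   clade, compound, subgroup)
                rows.append((clade, compound, subgroup, pooled.k,
                             pooled.geometric_mean, pooled.ci_low, pooled.ci_high,
                             chi2, p, stars, n_corrected))
    return pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)


class CladeEnrichmentAnalysis(BaseEstimator):
    """Odds-of-presence enrichment as a scikit-learn style estimator.

    Parameters
    ----------
    strata : ``"per_level"`` or ``"per_experiment"`` pooling strata.

    Attributes (after :meth:`fit`)
    ------------------------------
    table_ : the enrichment table (DataFrame).
    """

    def __init__(self, strata: str = "per_level"):
        self.strata = strata

    def fit(self, classes: pd.DataFrame, clades: pd.Series, universes: dict):
        self.table_ = enrichment_table(classes, clades, universes, strata=self.strata)
        return self
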