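"""Univariate treatment statistics: ANOVA, assumption checks, Box-Cox,
Tukey HSD with compact letters, and simple linear regression.

These mirror the standard analysis of per-level compound concentrations:
a one-way ANOVA per compound and experiment, gated by Shapiro–Wilk
(normality of residuals) and Levene (homoscedasticity) checks, with a
Box-Cox transform applied to the response when homoscedasticity fails,
followed by Tukey's honest significant difference post-hoc comparisons
summarised as a compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    degenerate: bool = False  # zero within-group variance
    boxcox_lambda: float | None = None


@dataclass
class AssumptionChecks:
    shapiro_p: float | None
    levene_p: float | None
    normal: bool | None
    homoscedastic: bool | None


@dataclass
class TukeyResult:
    groups: list
    p_matrix: np.ndarray  # pairwise p-values, symmetric
    letters: dict         # group -> letter string
    alpha: float


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def _check_groups(data: Mapping[str, Sequence[float]], min_n: int = 2):
    if len(data) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {}
    for name, values in data.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < min_n:
            raise ValueError(f"group {name!r} has {arr.size} observations; "
                             f"need >= {min_n}")
        arrays[name] = arr
    return arrays


def one_way_anova(data: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA (between/within decomposition)."""
    arrays = _check_groups(data)
    values = list(arrays.values())
    k = len(values)
    n = sum(v.size for v in values)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in values)
    if ss_within == 0:
        return AnovaResult(float("nan"), k - 1, n - k, float("nan"), degenerate=True)
    res = stats.f_oneway(*values)
    return AnovaResult(float(res.statistic), k - 1, n - k, float(res.pvalue))


def check_assumptions(data: Mapping[str, Sequence[float]],
                      alpha: float = 0.05) -> AssumptionChecks:
    """Shapiro–Wilk on pooled residuals and Levene across groups.

    Flags are True when the assumption is *not* rejected at ``alpha``;
    degenerate inputs (constant data, n < 3) skip the test (None).
    """
    arrays = _check_groups(data)
    values = list(arrays.values())
    residuals = np.concatenate([v - v.mean() for v in values])
    shapiro_p = normal = None
    if residuals.size >= 3 and np.ptp(residuals) > 0:
        shapiro_p = float(stats.shapiro(residuals).pvalue)
        normal = shapiro_p > alpha
    levene_p = homoscedastic = None
    if all(np.ptp(v) > 0 for v in values):
        levene_p = float(stats.levene(*values).pvalue)
        homoscedastic = levene_p > alpha
    return AssumptionChecks(shapiro_p, levene_p, normal, homoscedastic)


#: Box-Cox profile-likelihood grid.
BOXCOX_GRID = np.round(np.arange(-3.0, 3.0 + 1e-9, 0.01), 10)


def box_cox(x, shift: bool = False) -> tuple[float, np.ndarray]:
    """Box-Cox transform with λ chosen on a grid [−3, 3] (step 0.01).

    λ maximises the profile log-likelihood; y^(λ) = (y^λ − 1)/λ, with
    the natural log at λ = 0. Zeros are only allowed with ``shift=True``
    (adds half the smallest positive value, documented in the return via
    the transform itself).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("Box-Cox requires non-negative data")
    if np.any(x == 0):
        if not shift:
            raise ValueError("data contain zeros; pass shift=True to offset")
        x = x + 0.5 * x[x > 0].min()
    n = x.size
    logx = np.log(x)
    sum_logx = logx.sum()
    best_lam, best_ll = 0.0, -np.inf
    for lam in BOXCOX_GRID:
        y = _boxcox_transform(x, lam, logx)
        var = y.var()
        if var <= 0:
            continue
        ll = -0.5 * n * np.log(var) + (lam - 1.0) * sum_logx
        if ll > best_ll:
            best_ll, best_lam = ll, float(lam)
    return best_lam, _boxcox_transform(x, best_lam, logx)


def _boxcox_transform(x, lam, logx=None):
    if lam == 0:
        return np.log(x) if logx is None else logx.copy()
    return (np.power(x, lam) - 1.0) / lam


def inverse_box_cox(y, lam: float) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if lam == 0:
        return np.exp(y)
    return np.power(lam * y + 1.0, 1.0 / lam)


def tukey_hsd(data: Mapping[str, Sequence[float]], alpha: float = 0.05) -> TukeyResult:
    """Tukey HSD pairwise comparisons plus a compact letter display.

    Pairwise p-values come from the studentized-range distribution;
    groups sharing a letter are not significantly different at ``alpha``.
    Letters are assigned with the greedy insert-and-absorb algorithm
    (letter sets are not unique in general; this one is deterministic
    for a given group order by descending mean).
    """
    arrays = _check_groups(data)
    names = list(arrays)
    res = stats.tukey_hsd(*[arrays[g] for g in names])
    p = np.asarray(res.pvalue)
    significant = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            significant[(names[i], names[j])] = bool(p[i, j] < alpha)
    letters = compact_letter_display(names, significant,
                                     order=sorted(names, key=lambda g: -arrays[g].mean()))
    return TukeyResult(names, p, letters, alpha)


def compact_letter_display(groups: Sequence, significant: Mapping[tuple, bool],
                           order: Sequence | None = None) -> dict:
    """Insert-and-absorb compact letter display.

    ``significant[(g1, g2)]`` (either key order) marks pairs that differ.
    Returns ``{group: letters}`` such that two groups share a letter iff
    no significant difference separates them within some letter column.
    """
    order = list(order) if order is not None else list(groups)

    def differ(g1, g2):
        return significant.get((g1, g2), significant.get((g2, g1), False))

    columns = [set(order)]  # start from one column holding everyone
    for i, g1 in enumerate(order):
        for g2 in order[i + 1:]:
            if not differ(g1, g2):
                continue
            for col in [c for c in columns if g1 in c and g2 in c]:
                columns.remove(col)
                columns.append(col - {g1})
                columns.append(col - {g2})
            # absorb columns contained in another
            columns = [c for c in columns
                       if not any(c < other for other in columns)]
            # deduplicate
            seen, uniq = set(), []
            for c in columns:
                key = frozenset(c)
                if key not in seen:
                    seen.add(key)
                    uniq.append(c)
            columns = uniq
    # stable column order: by first member in `order`
    columns.sort(key=lambda c: min(order.index(g) for g in c) if c else len(order))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in order}
    for idx, col in enumerate(c for c in columns if c):
        for g in order:
            if g in col:
                letters[g] += alphabet[idx % len(alphabet)]
    return letters


def linear_fit(x, y) -> RegressionFit:
    """Ordinary least squares simple regression with r²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    return RegressionFit(float(res.slope), float(res.intercept),
                         float(res.rvalue ** 2), float(res.pvalue))


def treatment_summary(meta, alpha: float = 0.05):
    """Per-compound, per-experiment ANOVA/Tukey table from sample metadata.

    Applies the Box-Cox transform to the response when Levene's test
    rejects homoscedasticity, mirroring the conditional use in the
    analysis workflow. Returns a tidy DataFrame.
    """
    import pandas as pd

    from .datasets import COMPOUNDS
    from .io import concentration_column

    rows = []
    for experiment, sub in meta.groupby("experiment", sort=False):
        for compound in COMPOUNDS:
            col = concentration_column(compound)
            groups = {lvl: g[col].to_numpy(dtype=float)
                      for lvl, g in sub.groupby("level_label", sort=False)}
            checks = check_assumptions(groups, alpha)
            lam = None
            if checks.homoscedastic is False:
                positive = all((v > 0).all() for v in groups.values())
                pooled = np.concatenate(list(groups.values()))
                lam, _ = box_cox(pooled, shift=not positive)
                offset = 0.0 if positive else 0.5 * pooled[pooled > 0].min()
                groups = {k: _boxcox_transform(v + offset, lam)
                          for k, v in groups.items()}
            anova = one_way_anova(groups)
            anova.boxcox_lambda = lam
            letters = {}
            if not anova.degenerate:
                letters = tukey_hsd(groups, alpha).letters
            rows.append({
                "experiment": experiment, "compound": compound,
                "F": anova.F, "df_between": anova.df_between,
                "df_within": anova.df_within, "p_value": anova.p_value,
                "shapiro_p": checks.shapiro_p, "levene_p": checks.levene_p,
                "boxcox_lambda": lam,
                "tukey_letters": ";".join(f"{k}={v}" for k, v in letters.items()),
            })
    return pd.DataFrame(rows)
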