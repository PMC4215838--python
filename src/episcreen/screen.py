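"""Within-level Spearman screen and sign-consistency classification.

Treatment effects on the epibacterial community are confounded with any
indirect effect acting through host defence chemistry, so abundance–
concentration associations are assessed strictly *within* each treatment
level: for every treatment level, Spearman's ρ is computed across that
level's five algal replicates between the relative abundance of each
OTU detected at the level and the measured surface concentration of each
compound. An OTU is then labelled, per compound and experiment,

* ``positive``  — every evaluable level gives ρ > 0,
* ``negative``  — every evaluable level gives ρ < 0,
* ``neutral``   — signs disagree across levels, or some level gives ρ = 0
  exactly (the dichotomy is strictly positive-or-negative),
* ``unevaluable`` — no level yields a defined sign (constant vectors), or
  fewer than ``min_levels`` evaluable levels support a consistent call.

Only the *sign* of ρ is used; no per-correlation significance test is
involved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datasets import COMPOUNDS
from .io import concentration_column

#: |rho| at or below this is treated as exactly zero (rank arithmetic on
#: small n yields exact zeros up to float rounding).
ZERO_TOL = 1e-12

SIGN_POSITIVE = "positive"
SIGN_NEGATIVE = "negative"
SIGN_ZERO = "zero"
SIGN_UNDEFINED = "undefined"

CORRELATION_COLUMNS = ["otu_id", "compound", "experiment", "level_label",
                       "rho", "n", "sign"]
CLASS_COLUMNS = ["otu_id", "compound", "experiment", "label", "levels_evaluated"]


def spearman_rho(x, y) -> tuple[float, str]:
    """Spearman rank correlation and its sign label.

    Returns ``(rho, sign)`` where sign is ``positive``/``negative``/
    ``zero``; a constant vector makes ρ undefined and returns
    ``(nan, "undefined")``. Ties receive average ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), SIGN_UNDEFINED
    rho = stats.spearmanr(x, y).statistic
    return float(rho), _sign_label(rho)


def _sign_label(rho: float) -> str:
    if np.isnan(rho):
        return SIGN_UNDEFINED
    if rho > ZERO_TOL:
        return SIGN_POSITIVE
    if rho < -ZERO_TOL:
        return SIGN_NEGATIVE
    return SIGN_ZERO


def _bulk_rank_corr(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman ρ of each column of X against y; NaN where undefined."""
    n = y.shape[0]
    rx = stats.rankdata(X, axis=0)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean(axis=0)
    ryc = ry - ry.mean()
    sx = np.sqrt((rxc ** 2).sum(axis=0))
    sy = np.sqrt((ryc ** 2).sum())
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rxc.T @ ryc) / denom
    rho[denom == 0] = np.nan
    if sy == 0:
        rho[:] = np.nan
    return rho


def level_correlations(abund: pd.DataFrame, meta: pd.DataFrame,
                       compound: str) -> pd.DataFrame:
    """Per-level Spearman records for every OTU detected at that level.

    ``abund`` is a samples × OTUs abundance (or count) table; ``meta``
    the sample metadata. Returns one record per (detected OTU, level)
    with columns ``otu_id, compound, experiment, level_label, rho, n,
    sign``. OTUs with zero counts in all of a level's replicates are not
    detected there and produce no record.
    """
    col = concentration_column(compound)
    if col not in meta.columns:
        raise ValueError(f"metadata lacks column {col!r}")
    frames = []
    for (exp, level), grp in meta.groupby(["experiment", "level_label"], sort=False):
        samples = [s for s in grp["sample_id"] if s in abund.index]
        if len(samples) < 3:
            raise ValueError(
                f"level ({exp}, {level}) has {len(samples)} samples in the "
                "table; need >= 3")
        sub = abund.loc[samples]
        detected = (sub.to_numpy() > 0).any(axis=0)
        otus = abund.columns[detected]
        X = sub.to_numpy()[:, detected]
        conc = grp.set_index("sample_id").loc[samples, col].to_numpy(dtype=float)
        rho = _bulk_rank_corr(X, conc)
        sign = np.where(np.isnan(rho), SIGN_UNDEFINED,
                        np.where(rho > ZERO_TOL, SIGN_POSITIVE,
                                 np.where(rho < -ZERO_TOL, SIGN_NEGATIVE, SIGN_ZERO)))
        frames.append(pd.DataFrame({
            "otu_id": otus, "compound": compound, "experiment": exp,
            "level_label": level, "rho": rho, "n": len(samples), "sign": sign,
        }))
    if not frames:
        return pd.DataFrame(columns=CORRELATION_COLUMNS)
    return pd.concat(frames, ignore_index=True)[CORRELATION_COLUMNS]


def classify_consistency(records: pd.DataFrame, min_levels: int = 1) -> pd.DataFrame:
    """Collapse per-level correlation records into response classes.

    One row per (otu_id, compound, experiment) with ``label`` and
    ``levels_evaluated`` (levels contributing a defined, nonzero sign).
    """
    if records.empty:
        return pd.DataFrame(columns=CLASS_COLUMNS)
    counts = (records.groupby(["otu_id", "compound", "experiment"], sort=False)["sign"]
              .value_counts().unstack(fill_value=0))
    for s in (SIGN_POSITIVE, SIGN_NEGATIVE, SIGN_ZERO, SIGN_UNDEFINED):
        if s not in counts.columns:
            counts[s] = 0
    npos = counts[SIGN_POSITIVE].to_numpy()
    nneg = counts[SIGN_NEGATIVE].to_numpy()
    nzero = counts[SIGN_ZERO].to_numpy()
    evaluable = npos + nneg + nzero
    consistent_pos = (npos > 0) & (nneg == 0) & (nzero == 0)
    consistent_neg = (nneg > 0) & (npos == 0) & (nzero == 0)
    label = np.select(
        [evaluable == 0,
         consistent_pos & (npos >= min_levels),
         consistent_neg & (nneg >= min_levels),
         consistent_pos | consistent_neg],  # consistent but under min_levels
        ["unevaluable", "positive", "negative", "unevaluable"],
        default="neutral",
    )
    out = counts.index.to_frame(index=False)
    out["label"] = label
    out["levels_evaluated"] = npos + nneg
    return out[CLASS_COLUMNS]


def subgroup_fractions(classes: pd.DataFrame) -> pd.DataFrame:
    """Fractions of each label per (compound, experiment); rows sum to 1."""
    if classes.empty:
        raise ValueError("empty class set")
    frac = (classes.groupby(["compound", "experiment"], sort=False)["label"]
            .value_counts(normalize=True).unstack(fill_value=0.0))
    for lab in ("positive", "negative", "neutral", "unevaluable"):
        if lab not in frac.columns:
            frac[lab] = 0.0
    return frac[["positive", "negative", "neutral", "unevaluable"]]


class ResponseScreen(BaseEstimator):
    """Sign-consistency screen as a scikit-learn style estimator.

    Parameters
    ----------
    compounds : sequence of str or None
        Compounds to screen (default: all three).
    min_levels : int
        Minimum number of evaluable levels required to support a
        positive/negative call (default 1).

    Attributes (after :meth:`fit`)
    ------------------------------
    correlations_ : tidy per-level Spearman records.
    classes_ : per-OTU response classes.
    fractions_ : subgroup fractions per (compound, experiment).
    """

    def __init__(self, compounds=None, min_levels: int = 1):
        self.compounds = compounds
        self.min_levels = min_levels

    def fit(self, X: pd.DataFrame, meta: pd.DataFrame):
        """Screen abundance table ``X`` against ``meta`` concentrations."""
        compounds = list(self.compounds) if self.compounds is not None else list(COMPOUNDS)
        recs = [level_correlations(X, meta, c) for c in compounds]
        self.correlations_ = (pd.concat(recs, ignore_index=True)
                              if recs else pd.DataFrame(columns=CORRELATION_COLUMNS))
        self.classes_ = classify_consistency(self.correlations_, self.min_levels)
        self.fractions_ = subgroup_fractions(self.classes_) if len(self.classes_) else None
        return self
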