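"""EC50-threshold assessment of chemical defence sufficiency.

A bacterial strain counts as inhibited under a treatment condition when
the mean surface concentration of a compound reaches its published
half-maximal settlement-inhibition threshold (mean ≥ EC50, inclusive —
"0.01 ng cm⁻² or more"). Crossing every strain × compound pair with
every treatment condition yields an inhibition matrix; a condition is
considered defended ("any_defence") when at least one compound inhibits
at least one strain.

EC50s published as a range produce two calls: the default uses the range
minimum (any inhibitory activity plausible), the conservative companion
column the range maximum. All concentrations are handled in ng cm⁻².
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datasets import load_condition_means, load_ec50_panel
from .io import concentration_column

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["strain", "compound", "experiment", "level_label",
                "mean_ng_cm2", "ec50_min_ng_cm2", "ec50_max_ng_cm2",
                "inhibited", "inhibited_at_max"]


def inhibition_call(mean_conc: float, ec50: float) -> bool:
    """True iff the mean surface concentration reaches the EC50 (inclusive)."""
    if mean_conc < 0:
        raise ValueError(f"negative concentration {mean_conc}")
    if ec50 <= 0:
        raise ValueError(f"EC50 must be positive, got {ec50}")
    return bool(mean_conc >= ec50)


def strain_matrix(means: pd.DataFrame, ec50s: pd.DataFrame) -> pd.DataFrame:
    """Cross strains × compounds × conditions into inhibition calls.

    ``means``: tidy condition means with columns ``experiment,
    level_label, compound, mean_ng_cm2`` (see
    :func:`episcreen.datasets.load_condition_means`). ``ec50s``: columns
    ``strain, compound, ec50_min_ng_cm2, ec50_max_ng_cm2``. Strains
    lacking an EC50 for a compound simply contribute no entries.
    """
    if ec50s.empty:
        return pd.DataFrame(columns=CALL_COLUMNS)
    merged = means.merge(ec50s, on="compound", how="inner")
    missing = set(ec50s["compound"]) - set(means["compound"])
    if missing:
        logger.warning("no condition means for compound(s) %s; entries omitted",
                       sorted(missing))
    merged["inhibited"] = merged["mean_ng_cm2"] >= merged["ec50_min_ng_cm2"]
    merged["inhibited_at_max"] = merged["mean_ng_cm2"] >= merged["ec50_max_ng_cm2"]
    return merged[CALL_COLUMNS].sort_values(
        ["experiment", "level_label", "compound", "strain"]).reset_index(drop=True)


def sufficiency_summary(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-condition defence summary.

    Returns one row per (experiment, level_label) with the number of
    inhibited (strain, compound) pairs — at the range-minimum and
    range-maximum EC50 — and ``any_defence`` (≥ 1 pair inhibited at the
    default call).
    """
    if matrix.empty:
        raise ValueError("empty inhibition matrix")
    grp = matrix.groupby(["experiment", "level_label"], sort=False)
    out = grp.agg(n_inhibited=("inhibited", "sum"),
                  n_inhibited_at_max=("inhibited_at_max", "sum"),
                  n_pairs=("inhibited", "size")).reset_index()
    out["any_defence"] = out["n_inhibited"] > 0
    return out


def replicate_inhibition(meta: pd.DataFrame, ec50s: pd.DataFrame) -> pd.DataFrame:
    """Sensitivity mode: per-condition fraction of replicates above EC50.

    Uses the per-replicate measured concentrations from the sample
    metadata instead of treatment-level means.
    """
    rows = []
    for _, e in ec50s.iterrows():
        col = concentration_column(e["compound"])
        for (exp, level), grp in meta.groupby(["experiment", "level_label"], sort=False):
            conc = grp[col].to_numpy(dtype=float)
            rows.append((e["strain"], e["compound"], exp, level,
                         float(np.mean(conc >= e["ec50_min_ng_cm2"])),
                         float(np.mean(conc >= e["ec50_max_ng_cm2"]))))
    return pd.DataFrame(rows, columns=["strain", "compound", "experiment",
                                       "level_label", "frac_replicates_inhibited",
                                       "frac_replicates_inhibited_at_max"])


def condition_means_from_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Derive tidy condition means (mean, sd per level) from sample metadata."""
    from .datasets import COMPOUNDS
    rows = []
    for (exp, level), grp in meta.groupby(["experiment", "level_label"], sort=False):
        for compound in COMPOUNDS:
            conc = grp[concentration_column(compound)].to_numpy(dtype=float)
            rows.append((exp, level, np.nan, compound,
                         float(conc.mean()), float(conc.std(ddof=1))))
    return pd.DataFrame(rows, columns=["experiment", "level_label", "level_value",
                                       "compound", "mean_ng_cm2", "sd_ng_cm2"])


def read_ec50_table(path) -> pd.DataFrame:
    """Read a user EC50 TSV (strain, compound, ec50_value[, ec50_value_max],
    ec50_unit) and normalise units to ng cm⁻²."""
    df = pd.read_csv(path, sep="\t")
    factors = df["ec50_unit"].map({"ng_cm2": 1.0, "ug_cm2": 1000.0})
    if factors.isna().any():
        bad = df.loc[factors.isna(), "ec50_unit"].unique().tolist()
        raise ValueError(f"unknown EC50 unit(s) {bad}; use ng_cm2 or ug_cm2")
    out = df[["strain", "compound"]].copy()
    out["ec50_min_ng_cm2"] = df["ec50_value"].astype(float) * factors
    max_col = df["ec50_value_max"] if "ec50_value_max" in df else df["ec50_value"]
    out["ec50_max_ng_cm2"] = max_col.astype(float) * factors
    if (out["ec50_min_ng_cm2"] <= 0).any():
        raise ValueError("EC50 values must be positive")
    return out


class InhibitionClassifier(BaseEstimator):
    """EC50-threshold classifier in scikit-learn style.

    Parameters
    ----------
    ec50s : DataFrame or None
        EC50 panel (ng cm⁻²); ``None`` uses the bundled strain panel.

    After :meth:`fit` (which takes tidy condition means; ``None`` uses
    the bundled condition table) the fitted attributes are ``matrix_``
    (the long-format call table) and ``summary_`` (per-condition
    sufficiency).
    """

    def __init__(self, ec50s: pd.DataFrame | None = None):
        self.ec50s = ec50s

    def fit(self, means: pd.DataFrame | None = None, y=None):
        ec50s = self.ec50s if self.ec50s is not None else load_ec50_panel()
        means = means if means is not None else load_condition_means()
        self.matrix_ = strain_matrix(means, ec50s)
        self.summary_ = sufficiency_summary(self.matrix_)
        return self

    def predict(self, means: pd.DataFrame) -> pd.DataFrame:
        """Inhibition calls for new condition means (no state change)."""
        ec50s = self.ec50s if self.ec50s is not None else load_ec50_panel()
        return strain_matrix(means, ec50s)
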