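"""Bundled reference tables for the Fucus vesiculosus antifouling system.

Two small tables ship with the package:

* mean (sd) surface concentrations of the three defence metabolites —
  DMSP, proline and fucoxanthin — on apical tips of *F. vesiculosus*
  across five water temperatures (5–25 °C) and six light regimes
  (0–100 % of natural sunlight), in ng cm⁻²;
* previously determined half-maximal settlement-inhibition thresholds
  (EC50) of five marine bacterial isolates from rockweed habitats for the
  same compounds. EC50s reported as a range carry both range extremes;
  fucoxanthin thresholds are published in µg cm⁻² and normalised to
  ng cm⁻² on load.

Both are published measurements used as *inputs* by
:mod:`episcreen.defence` and, optionally, as the concentration model of
the synthetic-study generator.
"""

from __future__ import annotations

import pandas as pd

COMPOUNDS = ("dmsp", "proline", "fucoxanthin")

#: experiment -> ordered (level_label, level_value) pairs.
TREATMENT_LEVELS = {
    "temperature": [("5°C", 5.0), ("10°C", 10.0), ("15°C", 15.0),
                    ("20°C", 20.0), ("25°C", 25.0)],
    "light": [("0%", 0.0), ("5%", 5.0), ("13%", 13.0),
              ("23%", 23.0), ("44%", 44.0), ("100%", 100.0)],
}

#: rarefaction depth used for each experiment's amplicon libraries.
RAREFACTION_DEPTH = {"temperature": 1352, "light": 1024}

#: replicate algal individuals per treatment level.
N_REPLICATES = 5

# (mean, sd) surface concentration in ng cm^-2, per compound per level,
# in the level order of TREATMENT_LEVELS.
_CONDITION_MEANS = {
    "temperature": {
        "dmsp": [(0.46, 0.30), (0.17, 0.07), (0.59, 0.75), (0.96, 0.76), (0.16, 0.13)],
        "proline": [(0.009, 0.002), (0.006, 0.003), (0.01, 0.006), (0.004, 0.001), (0.004, 0.001)],
        "fucoxanthin": [(18.0, 11.08), (29.0, 6.81), (74.0, 37.84), (84.0, 22.53), (400.0, 187.04)],
    },
    "light": {
        "dmsp": [(0.45, 0.43), (0.1, 0.04), (0.17, 0.10), (0.1, 0.09), (0.03, 0.16), (0.3, 0.57)],
        "proline": [(0.01, 0.006), (0.025, 0.01), (0.02, 0.04), (0.03, 0.12), (0.02, 0.17), (0.03, 0.39)],
        "fucoxanthin": [(159.0, 84.36), (206.0, 63.0), (150.0, 187.0), (353.0, 94.0), (146.0, 101.0), (192.0, 85.21)],
    },
}

# strain, compound, (ec50_low, ec50_high), unit.  A single published value
# is stored with low == high.
_EC50_PANEL = [
    ("Bacillus aquimaris", "dmsp", (0.05, 0.05), "ng_cm2"),
    ("Ulvibacter littoralis", "dmsp", (0.05, 0.05), "ng_cm2"),
    ("Alteromonadaceae E1", "dmsp", (0.05, 0.05), "ng_cm2"),
    ("ISA 7311", "dmsp", (0.05, 0.05), "ng_cm2"),
    ("Cytophaga sp.", "dmsp", (0.38, 0.38), "ng_cm2"),
    ("Bacillus aquimaris", "proline", (0.01, 0.13), "ng_cm2"),
    ("Ulvibacter littoralis", "proline", (0.01, 0.13), "ng_cm2"),
    ("Alteromonadaceae E1", "proline", (0.01, 0.13), "ng_cm2"),
    ("ISA 7311", "proline", (0.01, 0.13), "ng_cm2"),
    ("Cytophaga sp.", "proline", (0.13, 0.13), "ng_cm2"),
    ("Bacillus aquimaris", "fucoxanthin", (1.4, 6.0), "ug_cm2"),
    ("Ulvibacter littoralis", "fucoxanthin", (1.4, 6.0), "ug_cm2"),
    ("Alteromonadaceae E1", "fucoxanthin", (1.4, 6.0), "ug_cm2"),
    ("Cytophaga sp.", "fucoxanthin", (1.4, 6.0), "ug_cm2"),
    ("ISA 7311", "fucoxanthin", (6.0, 6.0), "ug_cm2"),
]

_UNIT_TO_NG = {"ng_cm2": 1.0, "ug_cm2": 1000.0}


def load_condition_means() -> pd.DataFrame:
    """Mean surface concentrations per treatment condition.

    Returns a tidy frame with columns ``experiment``, ``level_label``,
    ``level_value``, ``compound``, ``mean_ng_cm2``, ``sd_ng_cm2``.
    """
    rows = []
    for experiment, levels in TREATMENT_LEVELS.items():
        for i, (label, value) in enumerate(levels):
            for compound in COMPOUNDS:
                mean, sd = _CONDITION_MEANS[experiment][compound][i]
                rows.append((experiment, label, value, compound, mean, sd))
    return pd.DataFrame(rows, columns=["experiment", "level_label", "level_value",
                                       "compound", "mean_ng_cm2", "sd_ng_cm2"])


def load_ec50_panel() -> pd.DataFrame:
    """EC50 panel of the five bacterial test strains, in ng cm⁻².

    Columns: ``strain``, ``compound``, ``ec50_min_ng_cm2``,
    ``ec50_max_ng_cm2``. Range minima are what the default inhibition
    call uses; maxima support the conservative call.
    """
    rows = []
    for strain, compound, (low, high), unit in _EC50_PANEL:
        f = _UNIT_TO_NG[unit]
        rows.append((strain, compound, low * f, high * f))
    return pd.DataFrame(rows, columns=["strain", "compound",
                                       "ec50_min_ng_cm2", "ec50_max_ng_cm2"])
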