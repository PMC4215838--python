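import numpy as np
import pandas as pd
import pytest

from episcreen.simulate import (ExperimentDesign, PlantedEffect,
                                SimulationConfig, simulate_study)


@pytest.fixture
def toy_counts():
    """2 samples x 3 OTUs."""
    return pd.DataFrame([[5, 0, 5], [2, 8, 0]],
                        index=["s1", "s2"], columns=["otu1", "otu2", "otu3"])


@pytest.fixture
def small_meta():
    """One experiment, two levels, five replicates, one varying compound."""
    rows = []
    rng = np.random.default_rng(0)
    for level, base in [("L1", 1.0), ("L2", 2.0)]:
        for rep in range(1, 6):
            rows.append({
                "sample_id": f"{level}_r{rep}", "experiment": "temperature",
                "level_label": level, "replicate": rep,
                "dmsp_ng_cm2": base + 0.1 * rep,
                "proline_ng_cm2": float(rng.uniform(0.001, 0.02)),
                "fucoxanthin_ng_cm2": float(rng.uniform(10, 300)),
            })
    return pd.DataFrame(rows)


@pytest.fixture
def small_study():
    """Fast synthetic study: 300 OTUs, both experiments, no planted effects."""
    return simulate_study(SimulationConfig(n_otus=300), seed=42)


@pytest.fixture
def planted_study():
    """Study with a strongly deterred 20-OTU Firmicutes clade (DMSP)."""
    config = SimulationConfig(n_otus=2000, planted_effects=[
        PlantedEffect("dmsp", "deterred", -3.0, n_otus=20,
                      clade="Firmicutes", occupancy=1.0)])
    return simulate_study(config, seed=7)
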