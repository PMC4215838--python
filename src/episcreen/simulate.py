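"""Synthetic study generator with known ground truth.

Emulates the downstream product of the two mesocosm experiments: rarefied
OTU count tables (fixed depth per experiment), five algal replicates per
treatment level over five temperature / six light levels, a few thousand
OTUs with long-tailed lognormal base abundances, patchy occupancy (most
OTUs absent from most samples), per-replicate surface concentrations of
the three defence compounds drawn lognormally around the published
per-level means/SDs, and an optional minority of *planted* OTUs whose
abundance is monotonically coupled to a compound concentration.

Coupling acts on the within-level z-score of a sample's concentration —
a planted OTU's sampling intensity is multiplied by ``exp(beta * z)`` —
so that planted effects create the within-level correlations the screen
looks for rather than across-level trends. Counts are multinomial at the
experiment's depth (so every sample sums exactly to depth); a Dirichlet
overdispersion knob adds extra compositional noise when wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .datasets import (COMPOUNDS, N_REPLICATES, RAREFACTION_DEPTH,
                       TREATMENT_LEVELS, load_condition_means)

#: representative Greengenes-style lineage per default clade (the clade
#: scheme assigns each back to its clade; "other"/"unclassified" buckets
#: get lineages that fall through the named selectors).
CLADE_LINEAGES = {
    "Rhodobacteraceae": "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__Rhodobacterales; f__Rhodobacteraceae",
    "Flavobacteriaceae": "k__Bacteria; p__Bacteroidetes; c__Flavobacteriia; o__Flavobacteriales; f__Flavobacteriaceae",
    "Saprospiraceae": "k__Bacteria; p__Bacteroidetes; c__Sphingobacteriia; o__Sphingobacteriales; f__Saprospiraceae",
    "Alteromonadaceae": "k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; o__Alteromonadales; f__Alteromonadaceae",
    "Pseudoalteromonadaceae": "k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; o__Alteromonadales; f__Pseudoalteromonadaceae",
    "Vibrionaceae": "k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; o__Vibrionales; f__Vibrionaceae",
    "Hyphomonadaceae": "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__Rhodobacterales; f__Hyphomonadaceae",
    "Sphingomonadaceae": "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__Sphingomonadales; f__Sphingomonadaceae",
    "Thiotrichales": "k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; o__Thiotrichales; f__Thiotrichaceae",
    "Oceanospirillales": "k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; o__Oceanospirillales; f__Halomonadaceae",
    "Rhizobiales": "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__Rhizobiales; f__Phyllobacteriaceae",
    "Other Alphaproteobacteria": "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__Kiloniellales",
    "Other Gammaproteobacteria": "k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; o__Xanthomonadales",
    "Deltaproteobacteria": "k__Bacteria; p__Proteobacteria; c__Deltaproteobacteria; o__Myxococcales",
    "Other Flavobacteriia": "k__Bacteria; p__Bacteroidetes; c__Flavobacteriia; o__Flavobacteriales; f__Cryomorphaceae",
    "Sphingobacteriia": "k__Bacteria; p__Bacteroidetes; c__Sphingobacteriia; o__Sphingobacteriales; f__Chitinophagaceae",
    "Cytophagia": "k__Bacteria; p__Bacteroidetes; c__Cytophagia; o__Cytophagales; f__Flammeovirgaceae",
    "Unclassified Proteobacteria": "k__Bacteria; p__Proteobacteria",
    "Other Bacteroidetes": "k__Bacteria; p__Bacteroidetes",
    "Firmicutes": "k__Bacteria; p__Firmicutes; c__Bacilli; o__Bacillales; f__Bacillaceae",
    "Actinobacteria": "k__Bacteria; p__Actinobacteria; c__Actinobacteria; o__Actinomycetales",
    "Cyanobacteria": "k__Bacteria; p__Cyanobacteria; c__Synechococcophycideae; o__Synechococcales",
    "Planctomycetes": "k__Bacteria; p__Planctomycetes; c__Planctomycetia; o__Pirellulales",
    "Verrucomicrobia": "k__Bacteria; p__Verrucomicrobia; c__Verrucomicrobiae; o__Verrucomicrobiales",
    "Other phyla": "k__Bacteria; p__Chloroflexi; c__Anaerolineae",
    "Unclassified": "k__Bacteria",
}

#: default clade composition of the synthetic community — Rhodobacteraceae
#: and Flavobacteriaceae dominate, as they do on Fucus surfaces.
DEFAULT_CLADE_PROPORTIONS = {
    "Rhodobacteraceae": 0.24, "Flavobacteriaceae": 0.15, "Saprospiraceae": 0.08,
    "Alteromonadaceae": 0.03, "Pseudoalteromonadaceae": 0.02, "Vibrionaceae": 0.02,
    "Hyphomonadaceae": 0.02, "Sphingomonadaceae": 0.02, "Thiotrichales": 0.02,
    "Oceanospirillales": 0.02, "Rhizobiales": 0.03,
    "Other Alphaproteobacteria": 0.08, "Other Gammaproteobacteria": 0.06,
    "Deltaproteobacteria": 0.02, "Other Flavobacteriia": 0.03,
    "Sphingobacteriia": 0.02, "Cytophagia": 0.02,
    "Unclassified Proteobacteria": 0.03, "Other Bacteroidetes": 0.02,
    "Firmicutes": 0.02, "Actinobacteria": 0.01, "Cyanobacteria": 0.01,
    "Planctomycetes": 0.01, "Verrucomicrobia": 0.01,
    "Other phyla": 0.02, "Unclassified": 0.02,
}


@dataclass
class ExperimentDesign:
    name: str
    levels: list
    n_replicates: int
    depth: int


@dataclass
class PlantedEffect:
    """An OTU set whose abundance is coupled to a compound concentration.

    ``beta`` is the log-intensity slope on the within-level z-score of
    the concentration; deterred effects have beta < 0, attracted beta >
    0. ``clade`` restricts the planted OTUs to one clade (first
    ``n_otus`` members); otherwise OTUs are drawn at random. Planted
    OTUs get ``occupancy`` (default 1: present in every sample).
    """
    compound: str
    direction: str  # "deterred" | "attracted"
    beta: float
    n_otus: int = 20
    clade: str | None = None
    occupancy: float = 1.0

    def __post_init__(self):
        if self.direction not in ("deterred", "attracted"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.direction == "deterred" and self.beta > 0:
            raise ValueError("deterred effects need beta <= 0")
        if self.direction == "attracted" and self.beta < 0:
            raise ValueError("attracted effects need beta >= 0")
        if self.compound not in COMPOUNDS:
            raise ValueError(f"unknown compound {self.compound!r}")


def default_experiments() -> list:
    return [
        ExperimentDesign("temperature", [l for l, _ in TREATMENT_LEVELS["temperature"]],
                         N_REPLICATES, RAREFACTION_DEPTH["temperature"]),
        ExperimentDesign("light", [l for l, _ in TREATMENT_LEVELS["light"]],
                         N_REPLICATES, RAREFACTION_DEPTH["light"]),
    ]


@dataclass
class SimulationConfig:
    """Study design and generative parameters.

    Defaults reproduce the study conditions: 5 temperature + 6 light
    levels, 5 replicates each, depths 1352/1024, 2000 OTUs, lognormal
    base intensities (sigma=2 gives the long abundance tail), Beta(0.4,
    1.2) per-OTU occupancy (mean ≈ 0.25, so most OTUs are missing from
    most samples), and per-replicate concentrations drawn lognormally
    around the published per-level mean/SD.
    """
    experiments: list = field(default_factory=default_experiments)
    n_otus: int = 2000
    clade_proportions: dict = field(default_factory=lambda: dict(DEFAULT_CLADE_PROPORTIONS))
    base_log_mu: float = 0.0
    base_log_sigma: float = 2.0
    occupancy_a: float = 0.4
    occupancy_b: float = 1.2
    planted_effects: list = field(default_factory=list)
    concentrations: pd.DataFrame | None = None  # tidy means; None = bundled
    cv_scale: float = 1.0  # multiplies every level's SD; 0 = noise-free
    dirichlet_scale: float | None = None  # overdispersion; None = plain multinomial
    seed: int | None = None


@dataclass
class StudyBundle:
    counts: pd.DataFrame      # samples x OTUs, each row sums to its depth
    metadata: pd.DataFrame    # sample records incl. true concentrations
    lineages: pd.Series       # otu_id -> lineage string
    clades: pd.Series         # otu_id -> clade name
    truth: pd.DataFrame       # per-OTU ground truth (clade, betas, occupancy)
    config: SimulationConfig


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and SD."""
    if mean <= 0:
        raise ValueError("lognormal mean must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def generate_concentrations(config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Sample metadata with per-replicate surface concentrations.

    Per level and compound, replicate concentrations are lognormal with
    the level's mean and SD (scaled by ``cv_scale``; 0 makes every
    replicate equal the level mean). A level mean of zero yields zeros.
    """
    if config.cv_scale < 0:
        raise ValueError("cv_scale must be >= 0")
    rng = np.random.default_rng(rng if rng is not None else config.seed)
    means = config.concentrations if config.concentrations is not None else load_condition_means()
    lut = means.set_index(["experiment", "level_label", "compound"])
    rows = []
    for exp in config.experiments:
        for level in exp.levels:
            for rep in range(1, exp.n_replicates + 1):
                rec = {"sample_id": f"{exp.name}_{level}_r{rep}",
                       "experiment": exp.name, "level_label": level,
                       "replicate": rep}
                for compound in COMPOUNDS:
                    mean = float(lut.loc[(exp.name, level, compound), "mean_ng_cm2"])
                    sd = float(lut.loc[(exp.name, level, compound), "sd_ng_cm2"]) * config.cv_scale
                    if mean == 0.0 or sd == 0.0:
                        value = mean
                    else:
                        mu, sigma = _lognormal_params(mean, sd)
                        value = float(rng.lognormal(mu, sigma))
                    rec[f"{compound}_ng_cm2"] = value
                rows.append(rec)
    return pd.DataFrame(rows, columns=cio.METADATA_COLUMNS)


def _assign_clades(config: SimulationConfig, rng) -> tuple[pd.Series, pd.Series]:
    props = pd.Series(config.clade_proportions, dtype=float)
    props = props / props.sum()
    counts = np.floor(props.to_numpy() * config.n_otus).astype(int)
    # distribute the remainder to the largest clades
    for i in np.argsort(-props.to_numpy())[: config.n_otus - counts.sum()]:
        counts[i] += 1
    otu_ids = [f"otu{i:05d}" for i in range(config.n_otus)]
    clade_per_otu = np.repeat(props.index.to_numpy(), counts)
    rng.shuffle(clade_per_otu)
    clades = pd.Series(clade_per_otu, index=otu_ids, name="clade")
    lineages = clades.map(CLADE_LINEAGES).rename("lineage")
    return lineages, clades


def _resolve_planted(config: SimulationConfig, clades: pd.Series, rng) -> pd.DataFrame:
    """Per-OTU beta matrix (n_otus × compounds) and occupancy overrides."""
    betas = pd.DataFrame(0.0, index=clades.index, columns=list(COMPOUNDS))
    occ_override = pd.Series(np.nan, index=clades.index)
    for eff in config.planted_effects:
        if eff.clade is not None:
            pool = clades.index[clades == eff.clade]
            if len(pool) < eff.n_otus:
                raise ValueError(f"clade {eff.clade!r} has only {len(pool)} OTUs; "
                                 f"cannot plant {eff.n_otus}")
            chosen = pool[: eff.n_otus]
        else:
            free = betas.index[(betas != 0).sum(axis=1) == 0]
            chosen = rng.choice(free, size=eff.n_otus, replace=False)
        betas.loc[chosen, eff.compound] = eff.beta
        occ_override.loc[chosen] = eff.occupancy
    return betas, occ_override


def generate_community(config: SimulationConfig, metadata: pd.DataFrame,
                       rng=None) -> tuple[pd.DataFrame, pd.Series, pd.Series, pd.DataFrame]:
    """Generate counts, taxonomy, clade assignment and ground truth."""
    for exp in config.experiments:
        if exp.depth < 1:
            raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(rng if rng is not None else config.seed)
    lineages, clades = _assign_clades(config, rng)
    n = config.n_otus
    base = rng.lognormal(config.base_log_mu, config.base_log_sigma, size=n)
    occupancy = rng.beta(config.occupancy_a, config.occupancy_b, size=n)
    betas, occ_override = _resolve_planted(config, clades, rng)
    occupancy = np.where(np.isnan(occ_override.to_numpy()), occupancy,
                         occ_override.to_numpy())
    beta_mat = betas.to_numpy()  # n x n_compounds

    # within-level z-scores of each compound concentration
    z = np.zeros((len(metadata), len(COMPOUNDS)))
    for ci, compound in enumerate(COMPOUNDS):
        col = metadata[f"{compound}_ng_cm2"].to_numpy(dtype=float)
        for (_e, _l), grp in metadata.groupby(["experiment", "level_label"], sort=False):
            idx = grp.index.to_numpy()
            sd = col[idx].std()
            z[idx, ci] = 0.0 if sd == 0 else (col[idx] - col[idx].mean()) / sd

    depth_by_exp = {e.name: e.depth for e in config.experiments}
    counts = np.zeros((len(metadata), n), dtype=np.int64)
    present = rng.random((len(metadata), n)) < occupancy[None, :]
    log_base = np.log(base)
    for si in range(len(metadata)):
        lam = np.exp(log_base + beta_mat @ z[si])
        lam = np.where(present[si], lam, 0.0)
        total = lam.sum()
        if total == 0:  # pathological occupancy settings; fall back to uniform
            lam = np.ones(n)
            total = float(n)
        p = lam / total
        if config.dirichlet_scale is not None:
            alpha = np.clip(p * config.dirichlet_scale, 1e-12, None)
            p = rng.dirichlet(alpha)
        depth = depth_by_exp[metadata["experiment"].iloc[si]]
        counts[si] = rng.multinomial(depth, p)
    counts_df = pd.DataFrame(counts, index=metadata["sample_id"].to_numpy(),
                             columns=clades.index)
    truth = pd.DataFrame({"otu_id": clades.index, "clade": clades.to_numpy(),
                          "base_intensity": base, "occupancy": occupancy})
    for ci, compound in enumerate(COMPOUNDS):
        truth[f"beta_{compound}"] = beta_mat[:, ci]
        truth[f"direction_{compound}"] = np.select(
            [beta_mat[:, ci] < 0, beta_mat[:, ci] > 0],
            ["deterred", "attracted"], default="none")
    return counts_df, lineages, clades, truth.reset_index(drop=True)


def simulate_study(config: SimulationConfig | None = None, seed=None) -> StudyBundle:
    """End-to-end generation of one synthetic study."""
    config = config if config is not None else SimulationConfig()
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    metadata = generate_concentrations(config, rng)
    counts, lineages, clades, truth = generate_community(config, metadata, rng)
    return StudyBundle(counts, metadata, lineages, clades, truth, config)


def write_fixture(bundle: StudyBundle, outdir) -> dict:
    """Write a bundle as the TSV formats the I/O layer reads.

    Emits ``counts.tsv`` (OTUs in rows), ``metadata.tsv``,
    ``taxonomy.tsv`` and ``ground_truth.tsv``; returns their paths.
    Re-reading counts/metadata/taxonomy reproduces the bundle's tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    cio.write_otu_table(bundle.counts, paths["counts"])
    cio.write_metadata(bundle.metadata, paths["metadata"])
    cio.write_taxonomy(bundle.lineages, paths["taxonomy"])
    bundle.truth.to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths
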