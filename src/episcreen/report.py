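"""End-to-end pipeline runs from a config mapping, plus the forest plot.

A run executes the five analysis stages in order — input/rarefaction,
correlation screen, clade enrichment, defence assessment, treatment
statistics — writes every output table as TSV, and records a
machine-readable manifest (package and library versions, seed, the full
config, and a SHA-256 digest of every output file) so each random
decision in a run can be traced back to its seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datasets import COMPOUNDS, load_condition_means, load_ec50_panel
from .defence import (condition_means_from_metadata, read_ec50_table,
                      strain_matrix, sufficiency_summary)
from .enrichment import enrichment_table
from .io import (CladeScheme, default_clade_scheme, level_universes, rarefy,
                 read_metadata, read_otu_table, read_taxonomy,
                 relative_abundance)
from .screen import ResponseScreen
from .simulate import PlantedEffect, SimulationConfig, simulate_study, write_fixture
from .stats import treatment_summary

logger = logging.getLogger(__name__)

STAGES = ["community_io", "response_screen", "clade_enrichment",
          "defence_assessment", "treatment_stats"]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _config_to_simulation(block: dict, seed) -> SimulationConfig:
    planted = [PlantedEffect(**p) for p in block.get("planted", [])]
    kwargs = {k: block[k] for k in ("n_otus", "base_log_mu", "base_log_sigma",
                                    "occupancy_a", "occupancy_b", "cv_scale",
                                    "dirichlet_scale") if k in block}
    return SimulationConfig(planted_effects=planted, seed=seed, **kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, seed: int | None = None, outdir=None) -> dict:
    """Execute the full pipeline; returns the run manifest.

    ``config`` holds either an ``inputs:`` block (paths to counts,
    metadata and taxonomy TSVs) or a ``simulate:`` block (passed to the
    synthetic generator), plus optional ``rarefy: {depth, seed}``,
    ``compounds``, ``min_levels``, ``strata``, ``clade_scheme`` (YAML
    path), ``ec50_table`` (TSV path), ``condition_means``
    (``from_metadata`` | ``bundled`` | a TSV path) and ``alpha``.
    """
    outdir = Path(outdir if outdir is not None else config.get("outdir", "episcreen_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else config.get("seed")
    outputs: dict[str, Path] = {}

    has_inputs = "inputs" in config
    has_sim = "simulate" in config
    if has_inputs == has_sim:
        raise ValueError("config needs exactly one of 'inputs' or 'simulate'")

    # stage 1: community_io
    if has_sim:
        bundle = simulate_study(_config_to_simulation(config["simulate"] or {}, seed))
        fixture = write_fixture(bundle, outdir / "simulated")
        outputs.update({f"simulated_{k}": v for k, v in fixture.items()})
        counts, meta, lineages = bundle.counts, bundle.metadata, bundle.lineages
    else:
        paths = config["inputs"]
        counts = read_otu_table(paths["counts"],
                                orientation=paths.get("orientation", "otus_in_rows"))
        meta = read_metadata(paths["metadata"])
        lineages = read_taxonomy(paths["taxonomy"])
        rare = config.get("rarefy")
        if rare:
            depth = rare.get("depth") or int(counts.sum(axis=1).min())
            counts = rarefy(counts, depth, seed=rare.get("seed", seed))
    abund = relative_abundance(counts)

    # stage 2: response_screen
    compounds = config.get("compounds", list(COMPOUNDS))
    screen = ResponseScreen(compounds=compounds,
                            min_levels=config.get("min_levels", 1))
    screen.fit(abund, meta)
    outputs["correlations"] = outdir / "correlations.tsv"
    screen.correlations_.to_csv(outputs["correlations"], sep="\t", index=False)
    outputs["classes"] = outdir / "classes.tsv"
    screen.classes_.to_csv(outputs["classes"], sep="\t", index=False)
    outputs["fractions"] = outdir / "fractions.tsv"
    screen.fractions_.reset_index().to_csv(outputs["fractions"], sep="\t", index=False)

    # stage 3: clade_enrichment
    scheme = (CladeScheme.from_yaml(config["clade_scheme"])
              if config.get("clade_scheme") else default_clade_scheme())
    clades = scheme.assign(lineages.reindex(counts.columns).dropna())
    universes = level_universes(counts, meta)
    enrich = enrichment_table(screen.classes_, clades, universes,
                              strata=config.get("strata", "per_level"))
    outputs["enrichment"] = outdir / "enrichment.tsv"
    enrich.to_csv(outputs["enrichment"], sep="\t", index=False)

    # stage 4: defence_assessment
    ec50s = (read_ec50_table(config["ec50_table"]) if config.get("ec50_table")
             else load_ec50_panel())
    means_mode = config.get("condition_means", "from_metadata")
    if means_mode == "from_metadata":
        means = condition_means_from_metadata(meta)
    elif means_mode == "bundled":
        means = load_condition_means()
    else:
        means = pd.read_csv(means_mode, sep="\t")
    calls = strain_matrix(means, ec50s)
    outputs["defence_calls"] = outdir / "defence_calls.tsv"
    calls.to_csv(outputs["defence_calls"], sep="\t", index=False)
    outputs["defence_summary"] = outdir / "defence_summary.tsv"
    sufficiency_summary(calls).to_csv(outputs["defence_summary"], sep="\t", index=False)

    # stage 5: treatment_stats
    stats_table = treatment_summary(meta, alpha=config.get("alpha", 0.05))
    outputs["treatment_stats"] = outdir / "treatment_stats.tsv"
    stats_table.to_csv(outputs["treatment_stats"], sep="\t", index=False)

    manifest = {
        "episcreen_version": __version__,
        "library_versions": _library_versions(),
        "seed": seed,
        "config": _jsonable(config),
        "stages": STAGES,
        "outputs": {k: {"path": str(v), "sha256": _sha256(Path(v))}
                    for k, v in outputs.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    _write_summary(outdir / "summary.txt", screen, enrich, calls)
    return manifest


def _library_versions() -> dict:
    import numpy, scipy, sklearn  # noqa: E401
    return {"numpy": numpy.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "scikit-learn": sklearn.__version__}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _write_summary(path: Path, screen, enrich: pd.DataFrame, calls: pd.DataFrame) -> None:
    lines = ["episcreen run summary", "=" * 22, ""]
    lines.append("Subgroup fractions (per compound x experiment):")
    lines.append(screen.fractions_.round(4).to_string())
    lines.append("")
    sig = enrich[enrich["significance"] != "ns"]
    lines.append(f"Significant clade enrichments: {len(sig)} of {len(enrich)} rows")
    if len(sig):
        lines.append(sig.round(4).to_string(index=False))
    lines.append("")
    if len(calls):
        summary = sufficiency_summary(calls)
        lines.append("Defence sufficiency per condition:")
        lines.append(summary.to_string(index=False))
    path.write_text("\n".join(lines) + "\n")


def plot_enrichment(enrichment: pd.DataFrame | str, outfile) -> bool:
    """Forest-style plot of geometric-mean odds ± 95% CI per clade.

    One panel per compound; negative subgroups in red, positive in
    green, stars above significant bars. Returns False (no-op with a
    warning) for an empty table.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(enrichment, (str, Path)):
        enrichment = pd.read_csv(enrichment, sep="\t")
    if enrichment.empty:
        logger.warning("empty enrichment table; nothing to plot")
        return False
    compounds = list(dict.fromkeys(enrichment["compound"]))
    clades = list(dict.fromkeys(enrichment["clade"]))
    fig, axes = plt.subplots(1, len(compounds),
                             figsize=(4.2 * len(compounds), 0.32 * len(clades) + 1.5),
                             sharey=True, squeeze=False)
    colors = {"negative": "#c0392b", "positive": "#27ae60"}
    offset = {"negative": -0.18, "positive": 0.18}
    ypos = {c: i for i, c in enumerate(clades)}
    for ax, compound in zip(axes[0], compounds):
        sub = enrichment[enrichment["compound"] == compound]
        for _, row in sub.iterrows():
            y = ypos[row["clade"]] + offset.get(row["subgroup"], 0.0)
            ax.errorbar(row["geometric_mean"], y,
                        xerr=[[row["geometric_mean"] - row["ci_low"]],
                              [row["ci_high"] - row["geometric_mean"]]],
                        fmt="o", ms=3.5, color=colors.get(row["subgroup"], "k"),
                        elinewidth=1, capsize=2)
            if row["significance"] != "ns":
                ax.annotate(row["significance"], (row["ci_high"], y),
                            fontsize=7, va="center", xytext=(3, 0),
                            textcoords="offset points")
        ax.axvline(1.0, color="grey", lw=0.8, ls="--")
        ax.set_xscale("log")
        ax.set_title(compound)
        ax.set_xlabel("odds of presence (GM ± 95% CI)")
    axes[0][0].set_yticks(range(len(clades)))
    axes[0][0].set_yticklabels(clades, fontsize=8)
    axes[0][0].invert_yaxis()
    fig.tight_layout()
    fig.savefig(outfile, dpi=150)
    plt.close(fig)
    return True
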