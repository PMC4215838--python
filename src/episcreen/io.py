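"""Tabular I/O for OTU count tables, sample metadata and taxonomy.

The community observation unit is an integer OTU count table held as a
:class:`pandas.DataFrame` with samples in rows and OTUs in columns.
On-disk tables are plain TSV; the common amplicon convention of OTUs in
rows is the default file orientation. Sample metadata is a TSV with one
row per algal replicate: experiment, treatment level, replicate index and
the measured surface concentration of each defence compound in ng cm⁻².
Taxonomy is a two-column TSV of Greengenes-style lineage strings
(``k__...; p__...; c__...``).

This module also performs rarefaction — seeded random subsampling of
each sample's reads, without replacement, to a common depth — and
derives relative abundances and per-level detection sets.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .datasets import COMPOUNDS

logger = logging.getLogger(__name__)

RANK_PREFIXES = [("kingdom", "k__"), ("phylum", "p__"), ("class", "c__"),
                 ("order", "o__"), ("family", "f__"), ("genus", "g__"),
                 ("species", "s__")]

METADATA_COLUMNS = ["sample_id", "experiment", "level_label", "replicate"] + [
    f"{c}_ng_cm2" for c in COMPOUNDS
]


class FormatError(ValueError):
    """An input file violates the expected tabular format."""


# ---------------------------------------------------------------------------
# OTU tables


def validate_otu_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check OTU-table invariants; returns the validated frame.

    Samples in rows, OTUs in columns, non-negative integer counts, no
    duplicate identifiers on either axis, every sample total > 0.
    """
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()].tolist()
        raise FormatError(f"duplicate sample ids: {dup}")
    if table.columns.duplicated().any():
        dup = table.columns[table.columns.duplicated()].tolist()
        raise FormatError(f"duplicate OTU ids: {dup}")
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("counts must be numeric")
    if np.any(values < 0):
        raise FormatError("counts must be non-negative")
    if not np.allclose(values, np.round(values)):
        raise FormatError("counts must be integers")
    table = table.astype(np.int64)
    totals = table.sum(axis=1)
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise FormatError(f"samples with zero total count: {empty}")
    return table


def read_otu_table(path, orientation: str = "otus_in_rows") -> pd.DataFrame:
    """Read a TSV count table into a samples × OTUs integer DataFrame.

    ``orientation`` declares how the file is laid out: ``"otus_in_rows"``
    (first column OTU id, one column per sample — the common amplicon
    convention, default) or ``"samples_in_rows"``.
    """
    if orientation not in ("otus_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "otus_in_rows":
        df = df.T
    df.index.name = None
    df.columns.name = None
    try:
        return validate_otu_table(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_otu_table(table: pd.DataFrame, path,
                    orientation: str = "otus_in_rows") -> None:
    """Write a samples × OTUs table back to TSV (lossless for integers)."""
    if orientation == "otus_in_rows":
        out = table.T.rename_axis("otu_id")
    elif orientation == "samples_in_rows":
        out = table.rename_axis("sample_id")
    else:
        raise ValueError(f"unknown orientation: {orientation!r}")
    out.to_csv(path, sep="\t")


def read_biom_table(path) -> pd.DataFrame:
    """Read a BIOM 2.1 table (requires the optional ``biom-format`` package)."""
    try:
        import biom  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading BIOM files requires the optional 'biom-format' package; "
            "install it or convert the table to TSV"
        ) from exc
    bt = biom.load_table(path)  # pragma: no cover
    df = bt.to_dataframe(dense=True).T  # pragma: no cover
    return validate_otu_table(df)  # pragma: no cover


# ---------------------------------------------------------------------------
# Sample metadata


def read_metadata(path) -> pd.DataFrame:
    """Read the sample-metadata TSV.

    Expects columns ``sample_id``, ``experiment``, ``level_label``,
    ``replicate`` and one ``<compound>_ng_cm2`` column per compound.
    """
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "level_label": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    if meta["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    key = meta[["experiment", "level_label", "replicate"]]
    if key.duplicated().any():
        raise FormatError(f"{path}: duplicate (experiment, level, replicate) keys")
    conc = meta[[f"{c}_ng_cm2" for c in COMPOUNDS]]
    if (conc.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative concentrations")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def concentration_column(compound: str) -> str:
    if compound not in COMPOUNDS:
        raise ValueError(f"unknown compound {compound!r}; expected one of {COMPOUNDS}")
    return f"{compound}_ng_cm2"


# ---------------------------------------------------------------------------
# Taxonomy and clade schemes


def parse_lineage(lineage: str) -> dict:
    """Parse a Greengenes-style lineage string into a rank → taxon dict.

    Empty placeholders (``f__``) and missing ranks are omitted.
    """
    out = {}
    for field in str(lineage).split(";"):
        field = field.strip()
        for rank, prefix in RANK_PREFIXES:
            if field.startswith(prefix):
                name = field[len(prefix):].strip()
                if name:
                    out[rank] = name
                break
    return out


def read_taxonomy(path) -> pd.Series:
    """Read a two-column ``otu_id<TAB>lineage`` TSV into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: taxonomy file needs otu_id and lineage columns")
    ser = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="lineage")
    if ser.index.duplicated().any():
        raise FormatError(f"{path}: duplicate OTU ids in taxonomy")
    return ser


def write_taxonomy(lineages: pd.Series, path) -> None:
    out = lineages.rename("lineage").rename_axis("otu_id").reset_index()
    out.to_csv(path, sep="\t", index=False)


class CladeScheme:
    """Ordered mixed-rank clade selectors with guaranteed totality.

    A scheme is a priority-ordered list of selectors, each a mapping with
    ``name``, ``rank`` and ``taxon``. A selector matches an OTU when its
    lineage carries that taxon at that rank; ``taxon: "*"`` matches any
    OTU with *some* named taxon at the rank. Two extensions give
    catch-all semantics:

    * ``require_missing: <rank>`` restricts a selector to lineages with
      no named taxon at ``<rank>`` (e.g. "unclassified Proteobacteria" =
      phylum Proteobacteria with no class);
    * a final ``{name: ..., rank: null}`` selector matches everything,
      guaranteeing every OTU maps to exactly one clade. If absent, an
      ``"Unclassified"`` catch-all is appended automatically.
    """

    def __init__(self, selectors: Sequence[Mapping]):
        selectors = [dict(s) for s in selectors]
        if not selectors or selectors[-1].get("rank") is not None:
            selectors.append({"name": "Unclassified", "rank": None})
        names = [s["name"] for s in selectors]
        if len(set(names)) != len(names):
            raise ValueError("clade names must be unique")
        self.selectors = selectors

    @property
    def clade_names(self) -> list:
        return [s["name"] for s in self.selectors]

    def assign_one(self, lineage: str) -> str:
        parsed = parse_lineage(lineage)
        for sel in self.selectors:
            rank = sel.get("rank")
            if rank is None:
                return sel["name"]
            taxon = parsed.get(rank)
            want = sel.get("taxon")
            req_missing = sel.get("require_missing")
            if req_missing is not None and parsed.get(req_missing) is not None:
                continue
            if want == "*":
                if taxon is not None:
                    return sel["name"]
            elif taxon is not None and taxon == want:
                return sel["name"]
        raise AssertionError("unreachable: scheme has a catch-all")

    def assign(self, lineages: pd.Series) -> pd.Series:
        """Map each OTU's lineage to its clade name (a Series)."""
        unique = lineages.astype(str).unique()
        lut = {lin: self.assign_one(lin) for lin in unique}
        return lineages.astype(str).map(lut).rename("clade")

    @classmethod
    def from_yaml(cls, path) -> "CladeScheme":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(doc["clades"] if isinstance(doc, dict) else doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"clades": self.selectors}, fh, sort_keys=False)


#: Default 26-clade mixed-rank scheme: the families, orders, classes and
#: phyla that dominate Fucus-associated communities, with "other" and
#: "unclassified" buckets. Fully user-configurable via YAML.
DEFAULT_CLADE_SELECTORS = [
    {"name": "Rhodobacteraceae", "rank": "family", "taxon": "Rhodobacteraceae"},
    {"name": "Flavobacteriaceae", "rank": "family", "taxon": "Flavobacteriaceae"},
    {"name": "Saprospiraceae", "rank": "family", "taxon": "Saprospiraceae"},
    {"name": "Alteromonadaceae", "rank": "family", "taxon": "Alteromonadaceae"},
    {"name": "Pseudoalteromonadaceae", "rank": "family", "taxon": "Pseudoalteromonadaceae"},
    {"name": "Vibrionaceae", "rank": "family", "taxon": "Vibrionaceae"},
    {"name": "Hyphomonadaceae", "rank": "family", "taxon": "Hyphomonadaceae"},
    {"name": "Sphingomonadaceae", "rank": "family", "taxon": "Sphingomonadaceae"},
    {"name": "Thiotrichales", "rank": "order", "taxon": "Thiotrichales"},
    {"name": "Oceanospirillales", "rank": "order", "taxon": "Oceanospirillales"},
    {"name": "Rhizobiales", "rank": "order", "taxon": "Rhizobiales"},
    {"name": "Other Alphaproteobacteria", "rank": "class", "taxon": "Alphaproteobacteria"},
    {"name": "Other Gammaproteobacteria", "rank": "class", "taxon": "Gammaproteobacteria"},
    {"name": "Deltaproteobacteria", "rank": "class", "taxon": "Deltaproteobacteria"},
    {"name": "Other Flavobacteriia", "rank": "class", "taxon": "Flavobacteriia"},
    {"name": "Sphingobacteriia", "rank": "class", "taxon": "Sphingobacteriia"},
    {"name": "Cytophagia", "rank": "class", "taxon": "Cytophagia"},
    {"name": "Unclassified Proteobacteria", "rank": "phylum", "taxon": "Proteobacteria",
     "require_missing": "class"},
    {"name": "Other Bacteroidetes", "rank": "phylum", "taxon": "Bacteroidetes"},
    {"name": "Firmicutes", "rank": "phylum", "taxon": "Firmicutes"},
    {"name": "Actinobacteria", "rank": "phylum", "taxon": "Actinobacteria"},
    {"name": "Cyanobacteria", "rank": "phylum", "taxon": "Cyanobacteria"},
    {"name": "Planctomycetes", "rank": "phylum", "taxon": "Planctomycetes"},
    {"name": "Verrucomicrobia", "rank": "phylum", "taxon": "Verrucomicrobia"},
    {"name": "Other phyla", "rank": "phylum", "taxon": "*"},
    {"name": "Unclassified", "rank": None},
]


def default_clade_scheme() -> CladeScheme:
    return CladeScheme(DEFAULT_CLADE_SELECTORS)


# ---------------------------------------------------------------------------
# Rarefaction, relative abundance, detection


def rarefy(table: pd.DataFrame, depth: int, seed=None) -> pd.DataFrame:
    """Subsample each sample's reads to a fixed depth without replacement.

    Draws a multivariate hypergeometric subsample per sample, i.e. a
    uniform random subset of that sample's reads. Samples whose total is
    below ``depth`` are dropped with a logged warning. Identical seeds
    give identical tables.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.sum(axis=1)
    keep = totals >= depth
    dropped = totals.index[~keep].tolist()
    if dropped:
        logger.warning("rarefy: dropping %d sample(s) below depth %d: %s",
                       len(dropped), depth, dropped)
    logger.info("rarefy: depth=%d seed=%r, %d samples retained",
                depth, seed, int(keep.sum()))
    counts = table.loc[keep].to_numpy()
    out = np.empty_like(counts)
    for i, row in enumerate(counts):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return pd.DataFrame(out, index=table.index[keep], columns=table.columns)


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Row-normalise counts to relative abundances (rows sum to 1)."""
    totals = table.sum(axis=1)
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise ValueError(f"samples with zero total count: {empty}")
    return table.div(totals, axis=0)


def detected_otus(table: pd.DataFrame, samples: Iterable) -> set:
    """OTUs with a nonzero count in at least one of the listed samples."""
    samples = list(samples)
    unknown = [s for s in samples if s not in table.index]
    if unknown:
        raise ValueError(f"unknown sample ids: {unknown}")
    if not samples:
        return set()
    present = (table.loc[samples] > 0).any(axis=0)
    return set(table.columns[present])


def level_universes(table: pd.DataFrame, meta: pd.DataFrame) -> dict:
    """Per (experiment, level_label) sets of OTUs detected at that level."""
    universes = {}
    for (exp, level), grp in meta.groupby(["experiment", "level_label"], sort=False):
        samples = [s for s in grp["sample_id"] if s in table.index]
        universes[(exp, level)] = detected_otus(table, samples)
    return universes


class Rarefier(TransformerMixin, BaseEstimator):
    """Rarefaction as a scikit-learn style transformer on count tables.

    Parameters
    ----------
    depth : int or None
        Target reads per sample. ``None`` (default) uses the minimum
        sample total of the table passed to :meth:`fit`.
    seed : int or None
        Seed of the subsampling generator; recorded in ``seed_``.
    """

    def __init__(self, depth: int | None = None, seed: int | None = None):
        self.depth = depth
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None):
        X = validate_otu_table(X)
        self.depth_ = int(X.sum(axis=1).min()) if self.depth is None else int(self.depth)
        self.seed_ = self.seed
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "depth_"):
            raise AttributeError("Rarefier is not fitted; call fit first")
        return rarefy(validate_otu_table(X), self.depth_, seed=self.seed_)
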