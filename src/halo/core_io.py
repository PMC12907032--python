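"""Readers, writers and table preprocessing.

The universal currency of the pipeline is a :class:`CommunityTable` — an
integer taxa × samples count matrix — together with a taxonomy table, a
sample metadata table and a rooted phylogeny whose tips map into the
table's taxa.  All on-disk formats are plain text: TSV for tables and
Newick for trees.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

SEASONS = ("summer", "autumn", "winter", "spring")

#: Salinity category edges in g/L.  Bins are half-open [lo, hi) with the top
#: bin closed above: [0, 40) -> low, [40, 100) -> mid, [100, inf) -> high.
SALINITY_EDGES = (40.0, 100.0)
SALINITY_CATEGORIES = ("low", "mid", "high")

METADATA_NUMERIC = (
    "latitude",
    "longitude",
    "salinity",
    "temperature",
    "ph",
    "dissolved_oxygen",
    "organic_matter",
)


class FormatError(ValueError):
    """Raised when an on-disk table violates the format contract."""


@dataclass
class CommunityTable:
    """Integer count matrix, taxa as rows, samples as columns.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix indexed by taxon id (rows) and sample
        id (columns).  Ids must be unique.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            raise FormatError("duplicate taxon ids")
        if df.columns.has_duplicates:
            raise FormatError("duplicate sample ids")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric cells in count table")
        if np.isnan(arr.astype(float)).any():
            raise FormatError("NaN cells in count table")
        if (arr < 0).any():
            raise FormatError("negative counts")
        if not np.allclose(arr, np.round(arr)):
            raise FormatError("non-integer counts")
        self.counts = df.astype(np.int64)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def matrix(self) -> np.ndarray:
        """Counts as a (taxa, samples) int64 array."""
        return self.counts.to_numpy()

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def taxon_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("zero-total sample(s): cannot normalise")
        return self.counts / totals

    def select_samples(self, sample_ids) -> "CommunityTable":
        return CommunityTable(self.counts.loc[:, list(sample_ids)])

    def select_taxa(self, taxon_ids) -> "CommunityTable":
        return CommunityTable(self.counts.loc[list(taxon_ids)])

    def drop_empty_taxa(self) -> "CommunityTable":
        keep = self.counts.sum(axis=1) > 0
        return CommunityTable(self.counts.loc[keep])

    def __eq__(self, other) -> bool:
        if not isinstance(other, CommunityTable):
            return NotImplemented
        return self.counts.equals(other.counts)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_count_table(path, orientation: str = "taxa_rows") -> CommunityTable:
    """Read a TSV count table.

    ``orientation`` names what the file's *rows* are; the in-memory table is
    always normalised to taxa × samples.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "samples_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CommunityTable(df)


def write_count_table(table: CommunityTable, path, orientation: str = "taxa_rows") -> None:
    df = table.counts if orientation == "taxa_rows" else table.counts.T
    df.to_csv(path, sep="\t", index_label="id")


def read_taxonomy(path) -> pd.DataFrame:
    """Read a TSV taxonomy: taxon id index, one column per rank."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        raise FormatError("duplicate taxon ids in taxonomy")
    if df.isna().any().any() or (df == "").any().any():
        raise FormatError("empty rank strings in taxonomy; use an explicit "
                          "'unclassified' sentinel")
    return df


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    taxonomy.to_csv(path, sep="\t", index_label="taxon_id")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample metadata table against the schema invariants."""
    required = {"site", "season", "salinity", "latitude", "longitude"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"metadata missing columns: {sorted(missing)}")
    bad = set(meta["season"]) - set(SEASONS)
    if bad:
        raise FormatError(f"invalid season value(s): {sorted(bad)}; "
                          f"expected one of {SEASONS}")
    for col in METADATA_NUMERIC:
        if col in meta.columns:
            meta[col] = pd.to_numeric(meta[col])
    if (meta["salinity"] < 0).any():
        raise FormatError("negative salinity")
    expected = meta["salinity"].map(assign_salinity_category)
    if "salinity_category" in meta.columns:
        mism = meta.index[meta["salinity_category"] != expected]
        if len(mism):
            raise FormatError(
                f"salinity_category inconsistent with salinity for {list(mism)}")
    else:
        meta = meta.copy()
        meta["salinity_category"] = expected
    return meta


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree; unrooted trees are midpoint-rooted."""
    tree = TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        raise FormatError("duplicate tip labels in tree")
    if len(tree.children) > 2:
        logger.info("input tree is unrooted (basal polytomy); rooting at midpoint")
        tree = tree.root_at_midpoint()
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise FormatError("negative branch length")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped with a warning; the
    draw per sample is multivariate hypergeometric, so repeated rarefaction
    with the same seed is bit-identical.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals
    keep = totals[totals >= depth].index
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below depth {depth}: {dropped}")
    if len(keep) == 0:
        raise ValueError(f"all samples below rarefaction depth {depth}")
    out = {}
    for s in keep:
        col = table.counts[s].to_numpy()
        out[s] = rng.multivariate_hypergeometric(col, depth)
    df = pd.DataFrame(out, index=table.counts.index)
    return CommunityTable(df)


def agglomerate(table: CommunityTable, taxonomy: pd.DataFrame, rank: str) -> CommunityTable:
    """Sum counts over taxa sharing the full lineage down to ``rank``.

    Taxa unclassified at ``rank`` are grouped under a lineage-qualified
    sentinel (``unclassified_<parent>``) so that unclassified members of
    distinct parent lineages are not merged.
    """
    if rank not in taxonomy.columns:
        raise ValueError(f"rank {rank!r} not in taxonomy ranks {list(taxonomy.columns)}")
    missing = [t for t in table.taxon_ids if t not in taxonomy.index]
    if missing:
        raise ValueError(f"taxa missing from taxonomy: {missing[:10]}")
    ranks = list(taxonomy.columns)
    upto = ranks[: ranks.index(rank) + 1]
    lineages = []
    for t in table.taxon_ids:
        row = taxonomy.loc[t, upto]
        vals = list(row)
        if str(vals[-1]).startswith("unclassified"):
            parent = next((v for v in reversed(vals[:-1])
                           if not str(v).startswith("unclassified")), "root")
            vals[-1] = f"unclassified_{parent}"
        lineages.append("|".join(map(str, vals)))
    grouped = table.counts.groupby(pd.Index(lineages, name="lineage"), sort=True).sum()
    return CommunityTable(grouped)


def filter_taxa(table: CommunityTable, min_total_rel_abund: float = 0.0,
                min_prevalence: int = 0) -> CommunityTable:
    """Abundance + prevalence filter.

    Retains taxa whose total reads are at least ``min_total_rel_abund`` of
    the grand total AND that are present (count > 0) in at least
    ``min_prevalence`` samples.  The sample set is unchanged.
    """
    if min_total_rel_abund < 0 or min_prevalence < 0:
        raise ValueError("thresholds must be >= 0")
    grand = table.counts.to_numpy().sum()
    rel = table.taxon_totals / grand if grand > 0 else table.taxon_totals * 0.0
    prev = (table.counts > 0).sum(axis=1)
    keep = (rel >= min_total_rel_abund) & (prev >= min_prevalence)
    return CommunityTable(table.counts.loc[keep])


def assign_salinity_category(salinity: float) -> str:
    """Map salinity (g/L) to 'low' / 'mid' / 'high'.

    Bins are [0, 40) / [40, 100) / [100, inf); the boundary values 40 and
    100 belong to the upper bin.
    """
    if salinity < 0:
        raise ValueError(f"negative salinity: {salinity}")
    if salinity < SALINITY_EDGES[0]:
        return "low"
    if salinity < SALINITY_EDGES[1]:
        return "mid"
    return "high"
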