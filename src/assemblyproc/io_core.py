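"""Count-table containers, file I/O, and table normalisations.

The central object is :class:`CountTable`, a taxa x samples matrix of
non-negative integer read counts, as exported by typical amplicon
pipelines.  All downstream statistics consume this canonical
orientation (taxa as rows, samples as columns).  Rarefaction,
conversion to relative abundance and habitat-scoped abundance
filtering live here because every analysis stage starts from one of
those normalised forms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

logger = logging.getLogger(__name__)

__all__ = [
    "CountTable",
    "RelAbundTable",
    "SampleMetadata",
    "PhyloTree",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "read_env_table",
    "read_tree",
    "rarefy",
    "to_relative",
    "filter_by_abundance",
]


class IdentifierError(ValueError):
    """Duplicate or mismatched taxon/sample identifiers."""


class FormatError(ValueError):
    """Malformed input file or table."""


def _check_unique(ids, kind: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise IdentifierError(f"duplicate {kind} identifiers: {sorted(set(dups))}")


@dataclass
class CountTable:
    """Non-negative integer abundances, taxa as rows x samples as columns.

    Parameters
    ----------
    data : pandas.DataFrame
        Integer counts with taxon identifiers as the index and sample
        identifiers as the columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise FormatError("count table must have at least 1 taxon and 1 sample")
        _check_unique(self.data.index, "taxon")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("count table contains non-numeric cells")
        if not np.all(np.isfinite(values)):
            raise FormatError("count table contains non-finite cells")
        if np.any(values < 0):
            raise FormatError("count table contains negative counts")
        if not np.allclose(values, np.round(values)):
            raise FormatError("count table contains non-integer counts")
        self.data = self.data.astype(np.int64)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def select_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.data.loc[:, list(sample_ids)].copy())

    def select_taxa(self, taxon_ids) -> "CountTable":
        return CountTable(self.data.loc[list(taxon_ids), :].copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass
class RelAbundTable:
    """Per-sample relative abundances; columns sum to 1 (or 0 if empty)."""

    data: pd.DataFrame
    zero_samples: list[str] = field(default_factory=list)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class SampleMetadata:
    """Categorical habitat factors per sample (region, size fraction, layer...)."""

    data: pd.DataFrame  # index: sample_id, columns: factor names

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        self.data.index = self.data.index.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def factor(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"unknown factor {name!r}; available: {list(self.data.columns)}")
        labels = self.data[name]
        if labels.isna().any():
            missing = list(labels.index[labels.isna()])
            raise ValueError(f"factor {name!r} has missing labels for samples {missing}")
        return labels.astype(str)

    def crossed_factor(self, names: list[str], sep: str = "x") -> pd.Series:
        """Cross several factors into one (e.g. fraction x region)."""
        parts = [self.factor(n) for n in names]
        out = parts[0].copy()
        for p in parts[1:]:
            out = out.str.cat(p, sep=sep)
        out.name = sep.join(names)
        return out

    def groups(self, factor: str) -> dict[str, list[str]]:
        labels = self.factor(factor)
        return {lvl: list(labels.index[labels == lvl]) for lvl in sorted(labels.unique())}


@dataclass
class PhyloTree:
    """Rooted tree with branch lengths; tips must match taxon identifiers."""

    tree: skbio.TreeNode

    def __post_init__(self) -> None:
        tips = [t.name for t in self.tree.tips()]
        if any(t is None for t in tips):
            raise FormatError("tree has unnamed tips")
        _check_unique(tips, "tip")
        for node in self.tree.traverse(include_self=False):
            if node.length is None:
                raise FormatError("tree has missing branch lengths")
            if node.length < 0:
                raise FormatError(f"negative branch length {node.length} in tree")

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def to_newick(self) -> str:
        import io

        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()


def read_count_table(path, orientation: str = "taxa_rows") -> CountTable:
    """Read a TSV count table into canonical taxa x samples orientation.

    ``orientation`` says what the file's rows are: ``taxa_rows`` (default)
    or ``samples_rows`` (the table is transposed on read).
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"orientation must be taxa_rows or samples_rows, got {orientation!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0, comment="#")
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.empty:
        raise FormatError(f"empty count table: {path}")
    # pandas mangles duplicate column headers ("x", "x.1"); detect from raw header
    with open(path, encoding="utf-8") as fh:
        header = ["#"]
        while header and header[0].startswith("#"):
            header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "column")
    if orientation == "samples_rows":
        df = df.T
    return CountTable(df)


def write_count_table(table: CountTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str, comment="#")
    if df.empty:
        raise FormatError(f"empty metadata table: {path}")
    return SampleMetadata(df)


def read_env_table(path) -> pd.DataFrame:
    """Samples x numeric environmental variables (salinity, temperature, ...)."""
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, comment="#")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or not np.all(np.isfinite(values)):
        raise FormatError("environmental table must be numeric and finite")
    _check_unique(df.index, "sample")
    return df


def read_tree(path) -> PhyloTree:
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse Newick tree {path}: {exc}") from exc
    return PhyloTree(tree)


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample without replacement to a common read depth.

    Uses multivariate-hypergeometric draws per sample, so each retained
    sample sums exactly to ``depth``.  Samples whose total is below
    ``depth`` are dropped with a warning rather than erroring, matching
    how studies rarefy to the minimum observed depth.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = [s for s in table.sample_ids if totals[s] >= depth]
    dropped = [s for s in table.sample_ids if totals[s] < depth]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} samples below depth {depth}: {dropped}", stacklevel=2)
    if not keep:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    out = {}
    for s in keep:
        col = table.data[s].to_numpy()
        if col.sum() == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
    df = pd.DataFrame(out, index=table.taxon_ids)
    return CountTable(df)


def to_relative(table: CountTable) -> RelAbundTable:
    """Divide each sample column by its total; all-zero samples stay zero."""
    counts = table.counts.astype(float)
    totals = counts.sum(axis=0)
    zero_samples = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if zero_samples:
        warnings.warn(f"all-zero samples left as zeros: {zero_samples}", stacklevel=2)
    safe = np.where(totals > 0, totals, 1.0)
    rel = counts / safe
    df = pd.DataFrame(rel, index=table.taxon_ids, columns=table.sample_ids)
    return RelAbundTable(df, zero_samples=zero_samples)


def filter_by_abundance(
    table: CountTable,
    metadata: SampleMetadata,
    factor: str,
    threshold: float = 0.01,
    mode: str = "mean",
) -> dict[str, CountTable]:
    """Per-habitat abundance filter: one filtered table per factor level.

    ``mode="mean"`` keeps a taxon in a habitat when its mean relative
    abundance across that habitat's samples exceeds ``threshold``;
    ``mode="sample"`` keeps it when any single sample in the habitat
    exceeds the threshold.  Each returned table is restricted to the
    habitat's samples.
    """
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    if mode not in ("mean", "sample"):
        raise ValueError(f"mode must be 'mean' or 'sample', got {mode!r}")
    rel = to_relative(table)
    groups = metadata.groups(factor)
    out: dict[str, CountTable] = {}
    for level, samples in groups.items():
        samples = [s for s in samples if s in table.data.columns]
        if not samples:
            continue
        sub = rel.data[samples]
        if mode == "mean":
            keep = sub.mean(axis=1) > threshold
        else:
            keep = (sub > threshold).any(axis=1)
        kept = table.data.loc[keep, samples]
        if kept.empty:
            logger.warning("abundance filter removed every taxon for habitat %s", level)
            continue
        out[level] = CountTable(kept.copy())
    return out
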