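"""Specificity-occupancy analysis and specialist detection.

For a taxon S and habitat H, specificity is the mean relative abundance
of S across H's samples divided by the sum of those habitat means over
all habitats (1 means habitat-exclusive), and occupancy is the fraction
of H's samples in which S occurs.  A specialist for H is a taxon with
both specificity and occupancy at or above a threshold (0.7 by
convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .io_core import CountTable, RelAbundTable, SampleMetadata, to_relative

__all__ = [
    "SpecOccRecord",
    "specificity",
    "occupancy",
    "spec_occ_records",
    "specialists",
    "shared_unique",
]


@dataclass
class SpecOccRecord:
    taxon_id: str
    habitat: str
    specificity: float
    occupancy: float
    specialist: bool


def _habitat_means(table, metadata: SampleMetadata, factor: str, use_relative: bool) -> pd.DataFrame:
    """Mean abundance per (taxon, habitat); columns are habitat levels."""
    if isinstance(table, CountTable):
        data = to_relative(table).data if use_relative else table.data.astype(float)
    elif isinstance(table, RelAbundTable):
        data = table.data
    else:
        raise TypeError(f"expected CountTable or RelAbundTable, got {type(table).__name__}")
    groups = metadata.groups(factor)
    means = {}
    for level, samples in groups.items():
        samples = [s for s in samples if s in data.columns]
        if not samples:
            raise ValueError(f"habitat level {level!r} has no samples in the table")
        means[level] = data[samples].mean(axis=1)
    return pd.DataFrame(means)


def specificity(table, metadata: SampleMetadata, factor: str, use_relative: bool = True) -> pd.DataFrame:
    """Per-(taxon, habitat) specificity; rows sum to 1.

    Taxa absent from every sample have undefined specificity and are
    dropped with a warning.  ``use_relative=False`` computes habitat
    means on raw counts instead of relative abundances; on a rarefied
    (equal-depth) table the two coincide.
    """
    means = _habitat_means(table, metadata, factor, use_relative)
    row_sums = means.sum(axis=1)
    absent = row_sums == 0
    if absent.any():
        warnings.warn(
            f"{int(absent.sum())} taxa absent from all samples excluded from specificity", stacklevel=2
        )
        means = means.loc[~absent]
        row_sums = row_sums.loc[~absent]
    return means.div(row_sums, axis=0)


def occupancy(table, metadata: SampleMetadata, factor: str) -> pd.DataFrame:
    """Per-(taxon, habitat) occurrence frequency across the habitat's samples."""
    data = table.data
    groups = metadata.groups(factor)
    out = {}
    for level, samples in groups.items():
        samples = [s for s in samples if s in data.columns]
        if not samples:
            raise ValueError(f"habitat level {level!r} has no samples in the table")
        out[level] = (data[samples] > 0).sum(axis=1) / len(samples)
    return pd.DataFrame(out)


def spec_occ_records(
    table,
    metadata: SampleMetadata,
    factor: str,
    threshold: float = 0.7,
    use_relative: bool = True,
) -> list[SpecOccRecord]:
    """Combine specificity and occupancy into per-(taxon, habitat) records."""
    if not 0 < threshold <= 1:
        raise ValueError(f"specialist threshold must be in (0, 1], got {threshold}")
    spec = specificity(table, metadata, factor, use_relative=use_relative)
    occ = occupancy(table, metadata, factor).loc[spec.index]
    records = []
    for taxon in spec.index:
        for habitat in spec.columns:
            s = float(spec.at[taxon, habitat])
            o = float(occ.at[taxon, habitat])
            records.append(SpecOccRecord(str(taxon), str(habitat), s, o, s >= threshold and o >= threshold))
    return records


def specialists(records: list[SpecOccRecord], threshold: float = 0.7) -> dict[str, list[SpecOccRecord]]:
    """Specialists (specificity >= tau and occupancy >= tau), grouped by habitat."""
    if not 0 < threshold <= 1:
        raise ValueError(f"specialist threshold must be in (0, 1], got {threshold}")
    out: dict[str, list[SpecOccRecord]] = {}
    for rec in records:
        if rec.specificity >= threshold and rec.occupancy >= threshold:
            out.setdefault(rec.habitat, []).append(rec)
    return out


def records_to_frame(records: list[SpecOccRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.taxon_id, r.habitat, r.specificity, r.occupancy, r.specialist) for r in records],
        columns=["taxon", "habitat", "specificity", "occupancy", "specialist"],
    )


def shared_unique(tables: dict[str, CountTable]) -> dict[frozenset, set[str]]:
    """Venn-style membership over per-group presence sets.

    Returns, for every non-empty combination of groups, the set of taxa
    present (count > 0) in exactly those groups.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 groups")
    presence = {
        g: set(t.data.index[(t.data > 0).any(axis=1)].astype(str)) for g, t in tables.items()
    }
    names = sorted(presence)
    out: dict[frozenset, set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(presence[g] for g in combo))
            outside = set.union(set(), *(presence[g] for g in names if g not in combo))
            out[frozenset(combo)] = inside - outside
    return out
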