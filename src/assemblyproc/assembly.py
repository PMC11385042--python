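"""Null-model partitioning of community assembly processes.

Implements the two-matrix Stegen-style framework at whole-community
level: abundance-weighted beta mean nearest taxon distance (betaMNTD),
its standardized effect size betaNTI against a taxa-shuffle null,
the abundance-based Raup-Crick index on Bray-Curtis (RC_bray), and the
five-way classification of sample pairs:

* betaNTI >  +1.96          -> heterogeneous selection (HeS)
* betaNTI <  -1.96          -> homogeneous selection (HoS)
* |betaNTI| <= 1.96 and RC_bray > +0.95 -> dispersal limitation (DL)
* |betaNTI| <= 1.96 and RC_bray < -0.95 -> homogenizing dispersal (HD)
* otherwise                 -> drift and other weak processes

Boundary comparisons are strict, so betaNTI = 1.96 or |RC| = 0.95
falls through to the weaker category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .diversity import DistanceMatrix
from .io_core import CountTable, PhyloTree, RelAbundTable, to_relative

__all__ = [
    "PairwiseNullResult",
    "AssemblyResult",
    "PROCESS_LABELS",
    "cophenetic",
    "beta_mntd",
    "beta_nti",
    "raup_crick_bray",
    "classify_processes",
    "process_fractions",
]

PROCESS_LABELS = ("HeS", "HoS", "DL", "HD", "drift")

BNTI_THRESHOLD = 1.96
RC_THRESHOLD = 0.95


@dataclass
class PairwiseNullResult:
    sample_a: str
    sample_b: str
    observed: float
    null_mean: float
    null_sd: float
    score: float  # betaNTI (z-score) or RC_bray (rescaled rank); nan if degenerate
    n_null: int
    degenerate: bool = False


@dataclass
class AssemblyResult:
    labels: pd.DataFrame  # columns: sample_a, sample_b, process
    fractions: pd.DataFrame  # index: group, columns: PROCESS_LABELS


def cophenetic(tree: PhyloTree) -> DistanceMatrix:
    """Patristic (sum of branch lengths) distance between every tip pair."""
    tips = tree.tip_names
    if len(tips) < 2:
        return DistanceMatrix(tips, np.zeros((len(tips), len(tips))))
    skdm = tree.tree.tip_tip_distances()
    return DistanceMatrix(list(skdm.ids), np.asarray(skdm.data, dtype=float))


def _align(table: RelAbundTable | CountTable, phy_dm: DistanceMatrix):
    """Abundance matrix and phylo distances restricted to the table's taxa."""
    if isinstance(table, CountTable):
        table = to_relative(table)
    taxa = [str(t) for t in table.taxon_ids]
    missing = set(taxa) - set(phy_dm.ids)
    # taxa with any abundance must be placed on the tree
    present_anywhere = set(np.asarray(table.taxon_ids)[(table.data.to_numpy() > 0).any(axis=1)])
    bad = missing & {str(t) for t in present_anywhere}
    if bad:
        raise ValueError(f"taxa absent from the phylogeny: {sorted(bad)[:10]} (n={len(bad)})")
    keep = [t for t in taxa if t not in missing]
    f = table.data.loc[keep].to_numpy(dtype=float)
    d = phy_dm.reorder(keep).values
    return f, d, list(table.sample_ids)


def _bmntd_pairs(f: np.ndarray, d: np.ndarray, pairs, present, weights) -> np.ndarray:
    """betaMNTD for the given sample pairs.

    ``present[j]`` are indices of taxa present in sample j; ``weights[j]``
    the matching per-taxon weights (relative abundances or 1/richness).
    """
    out = np.empty(len(pairs))
    for idx, (j, k) in enumerate(pairs):
        pj, pk = present[j], present[k]
        sub = d[np.ix_(pj, pk)]
        out[idx] = 0.5 * (weights[j] @ sub.min(axis=1) + weights[k] @ sub.min(axis=0))
    return out


def _presence_weights(f: np.ndarray, weighted: bool):
    n_samples = f.shape[1]
    present, weights = [], []
    for j in range(n_samples):
        pj = np.flatnonzero(f[:, j] > 0)
        if pj.size == 0:
            raise ValueError(f"sample index {j} has no taxa; betaMNTD undefined")
        present.append(pj)
        if weighted:
            w = f[pj, j]
            weights.append(w / w.sum())
        else:
            weights.append(np.full(pj.size, 1.0 / pj.size))
    return present, weights


def beta_mntd(table: RelAbundTable | CountTable, phy_dm: DistanceMatrix, weighted: bool = True) -> DistanceMatrix:
    """Beta mean nearest taxon distance between every sample pair.

    For samples j, k:  0.5 * [ sum_i f_ij * min_{i' in k} d(i, i')
    + sum_i f_ik * min_{i' in j} d(i, i') ], minima over taxa present in
    the other sample; shared taxa contribute zero.  ``weighted=False``
    replaces abundances with 1/richness.
    """
    f, d, sample_ids = _align(table, phy_dm)
    n = len(sample_ids)
    if n < 2:
        raise ValueError("betaMNTD needs at least 2 samples")
    present, weights = _presence_weights(f, weighted)
    pairs = list(combinations(range(n), 2))
    vals = _bmntd_pairs(f, d, pairs, present, weights)
    out = np.zeros((n, n))
    for (j, k), v in zip(pairs, vals):
        out[j, k] = out[k, j] = v
    return DistanceMatrix(sample_ids, out)


def beta_nti(
    table: RelAbundTable | CountTable,
    tree: PhyloTree | DistanceMatrix,
    n_null: int = 999,
    weighted: bool = True,
    seed: int = 0,
) -> list[PairwiseNullResult]:
    """betaNTI per sample pair against the taxa-shuffle null.

    The null shuffles taxon identities on the cophenetic matrix
    (equivalently permutes its rows and columns together) while holding
    abundances fixed, recomputes betaMNTD for every pair, and reports
    the z-score (observed - null mean) / null sd.  Pairs whose null
    distribution has zero spread are flagged degenerate (score = nan).
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    phy_dm = cophenetic(tree) if isinstance(tree, PhyloTree) else tree
    f, d, sample_ids = _align(table, phy_dm)
    n = len(sample_ids)
    present, weights = _presence_weights(f, weighted)
    pairs = list(combinations(range(n), 2))
    obs = _bmntd_pairs(f, d, pairs, present, weights)
    rng = np.random.default_rng(seed)
    n_taxa = d.shape[0]
    nulls = np.empty((n_null, len(pairs)))
    for b in range(n_null):
        perm = rng.permutation(n_taxa)
        dp = d[np.ix_(perm, perm)]
        nulls[b] = _bmntd_pairs(f, dp, pairs, present, weights)
    mu = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    results = []
    for idx, (j, k) in enumerate(pairs):
        degenerate = sd[idx] == 0
        score = np.nan if degenerate else (obs[idx] - mu[idx]) / sd[idx]
        results.append(
            PairwiseNullResult(
                sample_ids[j], sample_ids[k], float(obs[idx]), float(mu[idx]),
                float(sd[idx]), float(score), n_null, bool(degenerate),
            )
        )
    return results


def _bray_curtis_counts(x: np.ndarray, y: np.ndarray) -> float:
    den = x.sum() + y.sum()
    return float(np.abs(x - y).sum() / den)


def _null_sample(rng, richness: int, total: int, occ_prob: np.ndarray, ab_prob: np.ndarray, n_taxa: int) -> np.ndarray:
    """Draw one null community preserving richness and total individuals.

    Taxa enter with probability proportional to their occurrence
    frequency across samples; the remaining individuals are then spread
    over the chosen taxa proportionally to their dataset-wide relative
    abundance.
    """
    chosen = rng.choice(n_taxa, size=richness, replace=False, p=occ_prob)
    counts = np.zeros(n_taxa, dtype=np.int64)
    counts[chosen] = 1  # each chosen taxon gets the one individual guaranteeing presence
    remaining = total - richness
    if remaining > 0:
        w = ab_prob[chosen]
        counts[chosen] += rng.multinomial(remaining, w / w.sum())
    return counts


def raup_crick_bray(table: CountTable, n_null: int = 999, seed: int = 0) -> list[PairwiseNullResult]:
    """Abundance-based Raup-Crick on Bray-Curtis, per sample pair.

    Each null community preserves the observed richness and total reads
    of its sample; RC = 2 * [P(null BC < obs) + 0.5 * P(null BC = obs)] - 1,
    so RC is in [-1, 1], with -1 meaning the pair is far more similar
    than the null expects (homogenizing dispersal territory) and +1 far
    less similar (dispersal limitation).
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    counts = table.counts
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        empty = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"samples with zero total reads: {empty}")
    n_taxa, n_samples = counts.shape
    occurrence = (counts > 0).sum(axis=1).astype(float)
    pool = occurrence > 0
    if not np.all(pool):
        counts = counts[pool]
        n_taxa = counts.shape[0]
        occurrence = occurrence[pool]
    occ_prob = occurrence / occurrence.sum()
    rel_total = (counts / totals).sum(axis=1)
    ab_prob = rel_total / rel_total.sum()
    richness = (counts > 0).sum(axis=0)
    rng = np.random.default_rng(seed)
    sample_ids = table.sample_ids
    results = []
    for j, k in combinations(range(n_samples), 2):
        obs = _bray_curtis_counts(counts[:, j], counts[:, k])
        below = ties = 0
        for _ in range(n_null):
            nj = _null_sample(rng, int(richness[j]), int(totals[j]), occ_prob, ab_prob, n_taxa)
            nk = _null_sample(rng, int(richness[k]), int(totals[k]), occ_prob, ab_prob, n_taxa)
            bc = _bray_curtis_counts(nj, nk)
            if bc < obs - 1e-12:
                below += 1
            elif abs(bc - obs) <= 1e-12:
                ties += 1
        rc = 2.0 * (below + 0.5 * ties) / n_null - 1.0
        results.append(
            PairwiseNullResult(sample_ids[j], sample_ids[k], obs, np.nan, np.nan, float(rc), n_null)
        )
    return results


def classify_processes(
    bnti: list[PairwiseNullResult], rc: list[PairwiseNullResult]
) -> pd.DataFrame:
    """Five-way process label per sample pair from betaNTI and RC_bray."""
    key = lambda r: frozenset((r.sample_a, r.sample_b))  # noqa: E731
    rc_map = {key(r): r for r in rc}
    if {key(r) for r in bnti} != set(rc_map):
        raise ValueError("betaNTI and RC_bray cover different sample pairs")
    rows = []
    for b in bnti:
        r = rc_map[key(b)]
        if b.degenerate:
            label = "degenerate"
        elif b.score > BNTI_THRESHOLD:
            label = "HeS"
        elif b.score < -BNTI_THRESHOLD:
            label = "HoS"
        elif r.score > RC_THRESHOLD:
            label = "DL"
        elif r.score < -RC_THRESHOLD:
            label = "HD"
        else:
            label = "drift"
        rows.append((b.sample_a, b.sample_b, b.observed, b.score, r.score, label))
    return pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "bmntd_obs", "bnti", "rc_bray", "process"]
    )


def process_fractions(labels: pd.DataFrame, metadata=None, factor: str | None = None) -> pd.DataFrame:
    """Fraction of each process label among within-group sample pairs.

    Without metadata all pairs form one group ("all").  Degenerate pairs
    are excluded from the denominators.  Groups with fewer than two
    samples contribute no pairs and are skipped with a warning.
    """
    df = labels[labels["process"] != "degenerate"]
    if metadata is None or factor is None:
        groups = {"all": None}
        membership = None
    else:
        membership = metadata.factor(factor)
        groups = {lvl: set(membership.index[membership == lvl]) for lvl in sorted(membership.unique())}
    rows = {}
    for grp, samples in groups.items():
        if samples is None:
            sub = df
        else:
            if len(samples) < 2:
                warnings.warn(f"group {grp!r} has < 2 samples; skipped", stacklevel=2)
                continue
            sub = df[df["sample_a"].isin(samples) & df["sample_b"].isin(samples)]
        if len(sub) == 0:
            warnings.warn(f"group {grp!r} has no within-group pairs; skipped", stacklevel=2)
            continue
        frac = sub["process"].value_counts(normalize=True)
        rows[grp] = [float(frac.get(lbl, 0.0)) for lbl in PROCESS_LABELS]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(PROCESS_LABELS))
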