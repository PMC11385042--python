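"""Alpha diversity, Bray-Curtis dissimilarity, PCoA, PERMANOVA, and Mantel.

Conventions: Shannon is in nats; Simpson is the Gini-Simpson form
``1 - sum(p_i^2)``; Chao1 is the bias-corrected estimator, which needs
no special case when doubletons are absent.  Permutation p-values use
the add-one estimator ``(1 + #extreme) / (1 + B)`` so they are never
exactly zero and are unbiased for the Monte-Carlo null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import CountTable, RelAbundTable, SampleMetadata

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermutationTestResult",
    "richness",
    "shannon",
    "simpson",
    "chao1",
    "alpha_diversity_table",
    "bray_curtis",
    "pcoa",
    "permanova",
    "mantel",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with ordered identifiers."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} does not match {n} ids")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix has non-finite entries")
        if np.any(v < -1e-12):
            raise ValueError("distance matrix has negative entries")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-10):
            raise ValueError("distance matrix diagonal is not zero")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, ids) -> "DistanceMatrix":
        idx = [self.ids.index(str(i)) for i in ids]
        return DistanceMatrix([self.ids[i] for i in idx], self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("square distance matrix must have matching index and columns")
        return cls(list(df.index), df.to_numpy(dtype=float))


@dataclass
class OrdinationResult:
    ids: list[str]
    coordinates: np.ndarray  # n_samples x n_axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported)
    proportions: np.ndarray  # variance explained per retained axis


@dataclass
class PermutationTestResult:
    statistic: float
    effect_size: float  # R^2 for PERMANOVA, r for Mantel
    permutation_p: float
    n_permutations: int
    seed: int


# ---------------------------------------------------------------- alpha

def richness(counts) -> int:
    """Number of taxa observed (count > 0) in one sample."""
    c = np.asarray(counts)
    return int(np.sum(c > 0))


def _props(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("diversity index undefined for an all-zero sample")
    p = c / total
    return p[p > 0]


def shannon(counts) -> float:
    """Shannon entropy H' = -sum p_i ln p_i, in nats."""
    p = _props(counts)
    return float(-np.sum(p * np.log(p)))


def simpson(counts) -> float:
    """Gini-Simpson index 1 - sum p_i^2."""
    p = _props(counts)
    return float(1.0 - np.sum(p**2))


def chao1(counts) -> float:
    """Bias-corrected Chao1: S_obs + F1*(F1-1) / (2*(F2+1))."""
    c = np.asarray(counts)
    if not np.allclose(c, np.round(c)):
        raise ValueError("chao1 requires integer counts")
    s_obs = int(np.sum(c > 0))
    f1 = int(np.sum(c == 1))
    f2 = int(np.sum(c == 2))
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def alpha_diversity_table(table: CountTable, indices=("richness", "shannon", "simpson", "chao1")) -> pd.DataFrame:
    """One row per sample, one column per requested index."""
    funcs = {"richness": richness, "shannon": shannon, "simpson": simpson, "chao1": chao1}
    unknown = set(indices) - set(funcs)
    if unknown:
        raise ValueError(f"unknown indices: {sorted(unknown)}")
    rows = {s: {ix: funcs[ix](table.data[s].to_numpy()) for ix in indices} for s in table.sample_ids}
    return pd.DataFrame.from_dict(rows, orient="index")[list(indices)]


# ---------------------------------------------------------------- beta

def bray_curtis(table: CountTable | RelAbundTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis: sum|x-y| / sum(x+y) over taxa."""
    x = table.data.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("Bray-Curtis needs at least 2 samples")
    totals = x.sum(axis=0)
    num = np.abs(x[:, :, None] - x[:, None, :]).sum(axis=0)
    den = totals[:, None] + totals[None, :]
    if np.any((den == 0) & ~np.eye(x.shape[1], dtype=bool)):
        raise ValueError("Bray-Curtis undefined between two all-zero samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        bc = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(bc, 0.0)
    return DistanceMatrix(list(table.sample_ids), bc)


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical scaling (principal coordinate analysis).

    Eigendecomposes the double-centred matrix -1/2 * J D^2 J.  Coordinates
    are eigenvector * sqrt(eigenvalue) for positive eigenvalues only;
    negative eigenvalues are reported as-is, with no correction.
    """
    d2 = dm.values**2
    n = dm.n
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-12 * max(1.0, abs(float(evals[0])))
    n_pos = int(pos.sum())
    if n_axes is None:
        n_axes = n_pos
    if n_axes > n_pos:
        import warnings

        warnings.warn(f"only {n_pos} positive eigenvalues; truncating from {n_axes} axes", stacklevel=2)
        n_axes = n_pos
    coords = evecs[:, :n_axes] * np.sqrt(evals[:n_axes])
    total_pos = evals[pos].sum()
    props = evals[:n_axes] / total_pos if total_pos > 0 else np.zeros(n_axes)
    return OrdinationResult(list(dm.ids), coords, evals, props)


def _permanova_stat(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances, one factor."""
    n = values.shape[0]
    d2 = values**2
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    levels = np.unique(labels)
    for lvl in levels:
        idx = np.where(labels == lvl)[0]
        m = len(idx)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(m, k=1)].sum() / m
    ss_between = ss_total - ss_within
    g = len(levels)
    f = (ss_between / (g - 1)) / (ss_within / (n - g))
    r2 = ss_between / ss_total
    return f, r2


def permanova(dm: DistanceMatrix, groups, n_permutations: int = 999, seed: int = 0) -> PermutationTestResult:
    """One-factor PERMANOVA with a label-permutation p-value.

    ``groups`` is a sequence of labels aligned with ``dm.ids`` or a
    mapping/Series keyed by sample id.
    """
    if isinstance(groups, (dict, pd.Series)):
        labels = np.asarray([str(groups[i]) for i in dm.ids])
    else:
        labels = np.asarray([str(g) for g in groups])
        if len(labels) != dm.n:
            raise ValueError("groups length does not match distance matrix")
    levels, counts = np.unique(labels, return_counts=True)
    if len(levels) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if np.any(counts < 2):
        small = levels[counts < 2]
        raise ValueError(f"every group needs >= 2 members; too small: {list(small)}")
    f_obs, r2 = _permanova_stat(dm.values, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        f_perm, _ = _permanova_stat(dm.values, rng.permutation(labels))
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermutationTestResult(f_obs, r2, p, n_permutations, seed)


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    method: str = "pearson",
    n_permutations: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Mantel correlation between two distance matrices over the same samples.

    The statistic is the Pearson or Spearman correlation of the upper
    triangles; the null permutes rows and columns of ``dm2`` simultaneously.
    The p-value is one-sided for positive association.
    """
    if dm1.ids != dm2.ids:
        raise ValueError("distance matrices must share identical ids in identical order")
    if dm1.n < 4:
        raise ValueError("Mantel test needs at least 4 samples")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be pearson or spearman, got {method!r}")
    iu = np.triu_indices(dm1.n, k=1)
    x = dm1.values[iu]

    if method == "spearman":
        from scipy.stats import rankdata

        x = rankdata(x)

        def vec(v2: np.ndarray) -> np.ndarray:
            return rankdata(v2[iu])

    else:

        def vec(v2: np.ndarray) -> np.ndarray:
            return v2[iu]

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a @ a) * (b @ b))
        if denom == 0:
            raise ValueError("Mantel correlation undefined: zero variance in a matrix")
        return float((a @ b) / denom)

    r_obs = corr(x, vec(dm2.values))
    rng = np.random.default_rng(seed)
    exceed = 0
    n = dm1.n
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        v2 = dm2.values[np.ix_(perm, perm)]
        if corr(x, vec(v2)) >= r_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermutationTestResult(r_obs, r_obs, p, n_permutations, seed)
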