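"""Synthetic communities with known assembly regimes.

Generates the test bed for every analysis stage: a Yule phylogeny, a
lognormal metacommunity, and habitat-structured count tables produced
either by neutral immigration-drift dynamics (sampling the Sloan
stationary Beta distribution directly, so the neutral-model estimator
can be validated as a true parameter-recovery oracle) or by
phylogenetically conserved environmental filtering (Brownian traits on
the tree, Gaussian fitness around per-habitat optima).
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass, field
from importlib import resources

import dendropy
import numpy as np
import pandas as pd
import skbio

from .io_core import CountTable, PhyloTree, SampleMetadata

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "simulate_metacommunity",
    "simulate_neutral",
    "simulate_selection",
    "simulate_dataset",
    "fixture_small",
    "fixture_expectations",
]


@dataclass
class SimulationConfig:
    """Bundle of generator settings; the seed fully determines the output."""

    seed: int = 0
    n_taxa: int = 200
    n_samples: int = 24
    reads_per_sample: int = 2000
    regime: str = "neutral"  # neutral | selection
    m: float = 0.1
    selection_strength: float = 5.0
    habitat_optima: dict[str, float] = field(default_factory=lambda: {"H1": -1.5, "H2": 1.5})
    lognormal_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.n_taxa < 2 or self.n_samples < 1 or self.reads_per_sample < 1:
            raise ValueError("sizes must be positive (n_taxa >= 2)")
        if not 0 < self.m <= 1:
            raise ValueError(f"m must be in (0, 1], got {self.m}")
        if self.regime not in ("neutral", "selection"):
            raise ValueError(f"regime must be neutral or selection, got {self.regime!r}")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")


def simulate_tree(n_taxa: int, seed: int) -> PhyloTree:
    """Pure-birth (Yule) tree with unit birth rate; tips t1..tn, ultrametric."""
    if n_taxa < 2:
        raise ValueError(f"need at least 2 taxa, got {n_taxa}")
    rng = random.Random(seed)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=rng,
    )
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{i}"
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    sk = skbio.TreeNode.read(io.StringIO(newick), format="newick")
    return PhyloTree(sk)


def simulate_metacommunity(n_taxa: int, lognormal_sd: float, seed: int) -> np.ndarray:
    """Lognormal species-abundance distribution, normalized, sorted descending."""
    if lognormal_sd <= 0:
        raise ValueError(f"lognormal_sd must be > 0, got {lognormal_sd}")
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=lognormal_sd, size=n_taxa)
    p = np.sort(raw)[::-1]
    return p / p.sum()


def _make_table(counts: np.ndarray, taxon_ids, sample_ids) -> CountTable:
    return CountTable(pd.DataFrame(counts, index=list(taxon_ids), columns=list(sample_ids)))


def simulate_neutral(
    p: np.ndarray, m: float, n_reads: int, n_samples: int, seed: int,
    taxon_ids=None, sample_ids=None,
) -> CountTable:
    """Counts under Sloan neutral dynamics at stationarity.

    For every sample, each taxon's local relative abundance is drawn
    from Beta(N*m*p_i, N*m*(1-p_i)) with N = n_reads, the composition is
    renormalized, and n_reads individuals are drawn multinomially.
    """
    p = np.asarray(p, dtype=float)
    if not 0 < m <= 1:
        raise ValueError(f"m must be in (0, 1], got {m}")
    rng = np.random.default_rng(seed)
    n_taxa = p.size
    nm = n_reads * m
    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    for j in range(n_samples):
        x = rng.beta(nm * p, nm * (1.0 - p))
        total = x.sum()
        if total == 0:  # vanishingly rare; fall back to the metacommunity itself
            x = p.copy()
            total = 1.0
        counts[:, j] = rng.multinomial(n_reads, x / total)
    taxon_ids = taxon_ids or [f"t{i + 1}" for i in range(n_taxa)]
    sample_ids = sample_ids or [f"s{j + 1}" for j in range(n_samples)]
    return _make_table(counts, taxon_ids, sample_ids)


def brownian_traits(tree: PhyloTree, seed: int) -> pd.Series:
    """Unit-rate Brownian trait per tip, standardized by the stationary SD.

    The trait covariance between two tips is their shared path length
    from the root; values are divided by sqrt(mean tip depth) so habitat
    optima can be expressed in SD units of the trait.
    """
    from .assembly import cophenetic

    tips = tree.tip_names
    dm = cophenetic(tree).reorder(tips)
    depths = {}
    for tip in tree.tree.tips():
        depths[tip.name] = tip.accumulate_to_ancestor(tree.tree)
    depth_vec = np.array([depths[t] for t in tips])
    # shared path length = (depth_i + depth_j - d_ij) / 2
    cov = (depth_vec[:, None] + depth_vec[None, :] - dm.values) / 2.0
    rng = np.random.default_rng(seed)
    jitter = 1e-9 * np.mean(np.diag(cov))
    chol = np.linalg.cholesky(cov + jitter * np.eye(len(tips)))
    traits = chol @ rng.standard_normal(len(tips))
    sd = np.sqrt(np.mean(depth_vec))
    return pd.Series(traits / sd, index=tips)


def simulate_selection(
    tree: PhyloTree,
    habitats: pd.Series,
    strength: float,
    env_optima: dict[str, float],
    p: np.ndarray,
    n_reads: int,
    seed: int,
) -> CountTable:
    """Counts under phylogenetically conserved environmental filtering.

    ``habitats`` maps sample id -> habitat label.  Each taxon carries a
    Brownian trait; in a sample of habitat h the sampling weight of
    taxon i is p_i * exp(-strength * (trait_i - optimum_h)^2), i.e.
    soft Gaussian filtering around the habitat optimum, and counts are
    multinomial at depth n_reads.  strength = 0 reduces to plain
    multinomial sampling of the metacommunity.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    missing = set(habitats.unique()) - set(env_optima)
    if missing:
        raise ValueError(f"habitats without an optimum: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    traits = brownian_traits(tree, seed=int(rng.integers(2**31)))
    taxa = list(traits.index)
    p = np.asarray(p, dtype=float)
    if p.size != len(taxa):
        raise ValueError(f"metacommunity size {p.size} != {len(taxa)} tips")
    trait_vec = traits.to_numpy()
    counts = np.zeros((len(taxa), len(habitats)), dtype=np.int64)
    for j, (sample, h) in enumerate(habitats.items()):
        w = p * np.exp(-strength * (trait_vec - env_optima[str(h)]) ** 2)
        total = w.sum()
        if total == 0:
            raise RuntimeError(f"selection wiped out all taxa in sample {sample}")
        counts[:, j] = rng.multinomial(n_reads, w / total)
    return _make_table(counts, taxa, list(habitats.index))


def simulate_dataset(config: SimulationConfig) -> tuple[CountTable, PhyloTree, SampleMetadata]:
    """End-to-end generator: tree + metadata + counts under the chosen regime.

    Samples are split evenly between two habitats (H1, H2); all
    sub-generators draw their seeds from one stream so a single config
    seed fixes the entire dataset.
    """
    root = np.random.default_rng(config.seed)
    seeds = root.integers(2**31, size=5)
    tree = simulate_tree(config.n_taxa, seed=int(seeds[0]))
    p_sorted = simulate_metacommunity(config.n_taxa, config.lognormal_sd, seed=int(seeds[1]))
    # assign abundances to tips in random order: the metacommunity rank
    # must carry no phylogenetic signal, or the neutral regime would not be null
    assign = np.random.default_rng(int(seeds[4])).permutation(config.n_taxa)
    p_by_tip = p_sorted[assign]
    tips = tree.tip_names
    sample_ids = [f"s{j + 1}" for j in range(config.n_samples)]
    habitat_labels = list(config.habitat_optima)
    habs = pd.Series(
        [habitat_labels[j % len(habitat_labels)] for j in range(config.n_samples)],
        index=sample_ids, name="habitat",
    )
    meta = SampleMetadata(pd.DataFrame({"habitat": habs}))
    if config.regime == "neutral":
        table = simulate_neutral(
            p_by_tip, config.m, config.reads_per_sample, config.n_samples,
            seed=int(seeds[2]), taxon_ids=tips, sample_ids=sample_ids,
        )
    else:
        table = simulate_selection(
            tree, habs, config.selection_strength, config.habitat_optima,
            p_by_tip, config.reads_per_sample, seed=int(seeds[3]),
        )
    return table, tree, meta


_FIXTURE_COUNTS = {
    #        s1  s2  s3  s4  s5  s6
    "tA": [5, 5, 4, 0, 0, 0],
    "tB": [5, 5, 4, 0, 0, 0],
    "tC": [0, 0, 2, 2, 0, 0],
    "tD": [0, 0, 0, 4, 4, 4],
    "tE": [0, 0, 0, 4, 4, 4],
    "tF": [0, 0, 0, 0, 2, 2],
}

_FIXTURE_NEWICK = "((tA:1,tB:1):2,((tC:1.5,tD:1.5):0.5,(tE:1,tF:1):1):1);"


def fixture_small() -> tuple[CountTable, PhyloTree, SampleMetadata]:
    """Deterministic 6-taxon x 6-sample dataset with two habitats.

    Built so the headline statistics have closed-form values: samples
    s1 and s2 are identical two-taxon communities (Shannon = ln 2,
    Bray-Curtis 0), taxa tA/tB occur only in habitat H1 and tD/tE/tF
    only in H2 (specificity 1), and tF misses the 0.7 occupancy bar on
    purpose.  Expected values live in ``data/fixture_small_expected.tsv``.
    """
    samples = [f"s{j}" for j in range(1, 7)]
    table = CountTable(pd.DataFrame(_FIXTURE_COUNTS, index=samples).T)
    tree = PhyloTree(skbio.TreeNode.read(io.StringIO(_FIXTURE_NEWICK), format="newick"))
    meta = SampleMetadata(
        pd.DataFrame({"habitat": ["H1", "H1", "H1", "H2", "H2", "H2"]}, index=samples)
    )
    return table, tree, meta


def fixture_expectations() -> pd.DataFrame:
    """Hand-computed expected statistics for :func:`fixture_small`."""
    ref = resources.files("assemblyproc").joinpath("data/fixture_small_expected.tsv")
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t")
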