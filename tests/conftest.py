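import numpy as np
import pandas as pd
import pytest

from assemblyproc import CountTable, SampleMetadata, fixture_small


@pytest.fixture(scope="session")
def small():
    """Deterministic 6-taxon x 6-sample fixture with two habitats."""
    table, tree, meta = fixture_small()
    return {"table": table, "tree": tree, "meta": meta}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_count_table(rng, n_taxa=10, n_samples=6, depth=100, sparsity=0.3):
    """Sparse over-dispersed random counts; every sample non-empty."""
    lam = rng.lognormal(1.0, 1.0, size=(n_taxa, n_samples))
    counts = rng.poisson(lam * depth / (n_taxa * np.e))
    counts[rng.random((n_taxa, n_samples)) < sparsity] = 0
    for j in range(n_samples):
        if counts[:, j].sum() == 0:
            counts[rng.integers(n_taxa), j] = 1
    return CountTable(
        pd.DataFrame(
            counts,
            index=[f"t{i}" for i in range(n_taxa)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )


def metadata_for(table, n_levels=2, factor="habitat"):
    labels = [f"H{j % n_levels + 1}" for j in range(len(table.sample_ids))]
    return SampleMetadata(pd.DataFrame({factor: labels}, index=table.sample_ids))
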