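import io

import numpy as np
import pandas as pd
import pytest
import skbio

from assemblyproc import (
    CountTable,
    PhyloTree,
    beta_mntd,
    beta_nti,
    classify_processes,
    cophenetic,
    process_fractions,
    raup_crick_bray,
    to_relative,
)
from assemblyproc.assembly import PROCESS_LABELS, PairwiseNullResult
from assemblyproc.diversity import DistanceMatrix

from conftest import metadata_for, random_count_table


def _tree(newick):
    return PhyloTree(skbio.TreeNode.read(io.StringIO(newick), format="newick"))


def brute_force_bmntd(rel, phy, weighted=True):
    """Literal double loop over the betaMNTD definition."""
    taxa = list(rel.index)
    samples = list(rel.columns)
    n = len(samples)
    out = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            total = 0.0
            for a, b in ((samples[j], samples[k]), (samples[k], samples[j])):
                present_a = [t for t in taxa if rel.at[t, a] > 0]
                present_b = [t for t in taxa if rel.at[t, b] > 0]
                wsum = sum(rel.at[t, a] for t in present_a)
                for t in present_a:
                    nearest = min(phy.at[t, u] for u in present_b)
                    w = rel.at[t, a] / wsum if weighted else 1.0 / len(present_a)
                    total += w * nearest
            out[j, k] = total / 2.0
    return out


class TestCophenetic:
    def test_hand_values(self):
        dm = cophenetic(_tree("((A:1,B:1):1,C:2);")).to_frame()
        assert dm.loc["A", "B"] == 2.0
        assert dm.loc["A", "C"] == 4.0
        assert dm.loc["B", "C"] == 4.0

    def test_star_tree(self):
        dm = cophenetic(_tree("(A:3,B:3,C:3,D:3);"))
        off = dm.values[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 6.0)

    def test_fixture_tree(self, small):
        dm = cophenetic(small["tree"]).to_frame()
        assert dm.loc["tC", "tD"] == pytest.approx(3.0)
        assert dm.loc["tE", "tF"] == pytest.approx(2.0)
        assert dm.loc["tA", "tC"] == pytest.approx(6.0)


class TestBetaMNTD:
    def test_identical_communities_zero(self):
        t = CountTable(pd.DataFrame({"s1": [2, 3, 0], "s2": [2, 3, 0]}, index=list("ABC")))
        dm = beta_mntd(t, cophenetic(_tree("((A:1,B:1):1,C:2);")))
        assert dm.values[0, 1] == pytest.approx(0.0)

    def test_single_taxon_pair(self):
        # sample j holds only A, sample k only C: betaMNTD is d(A, C) = 4
        t = CountTable(pd.DataFrame({"s1": [5, 0, 0], "s2": [0, 0, 5]}, index=list("ABC")))
        dm = beta_mntd(t, cophenetic(_tree("((A:1,B:1):1,C:2);")))
        assert dm.values[0, 1] == pytest.approx(4.0)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_brute_force_oracle(self, rng, weighted):
        tree = _tree("(((A:1,B:1):1,(C:0.5,D:0.5):1.5):1,((E:1,F:1):0.5,(G:0.2,H:0.2):1.3):1.5);")
        phy = cophenetic(tree).to_frame()
        for _ in range(10):
            counts = rng.integers(0, 5, size=(8, 4))
            for j in range(4):
                if counts[:, j].sum() == 0:
                    counts[rng.integers(8), j] = 1
            t = CountTable(pd.DataFrame(counts, index=list("ABCDEFGH"), columns=[f"s{j}" for j in range(4)]))
            rel = to_relative(t).data
            ours = beta_mntd(t, cophenetic(tree), weighted=weighted)
            expected = brute_force_bmntd(rel, phy, weighted=weighted)
            assert np.allclose(ours.values, expected, atol=1e-12)

    def test_missing_taxon_rejected(self):
        t = CountTable(pd.DataFrame({"s1": [1, 1], "s2": [1, 1]}, index=["A", "Z"]))
        with pytest.raises(ValueError, match="absent from the phylogeny"):
            beta_mntd(t, cophenetic(_tree("((A:1,B:1):1,C:2);")))


class TestBetaNTI:
    def test_identical_communities_degenerate(self):
        # identical membership: every nearest-taxon distance is 0 under any
        # tip relabeling as well, so the null has zero spread
        tree = _tree("(((A:1,B:1):1,(C:0.5,D:0.5):1.5):1,(E:2,F:2):1);")
        counts = pd.DataFrame({"s1": [4, 0, 3, 0, 2, 0], "s2": [4, 0, 3, 0, 2, 0]}, index=list("ABCDEF"))
        res = beta_nti(CountTable(counts), tree, n_null=199, seed=1)
        assert len(res) == 1
        assert res[0].observed == 0.0
        assert res[0].degenerate and np.isnan(res[0].score)

    def test_nearly_identical_communities_strongly_negative(self):
        # one rare private taxon per sample keeps the null non-degenerate;
        # observed betaMNTD stays near the distribution's minimum
        tree = _tree("(((A:1,B:1):1,(C:0.5,D:0.5):1.5):1,(E:2,F:2):1);")
        counts = pd.DataFrame(
            {"s1": [40, 1, 30, 0, 20, 0], "s2": [40, 0, 30, 1, 20, 0]}, index=list("ABCDEF")
        )
        res = beta_nti(CountTable(counts), tree, n_null=199, seed=1)
        assert res[0].score < -1.0

    def test_determinism(self, rng):
        from assemblyproc import synthetic as syn

        cfg = syn.SimulationConfig(seed=9, n_taxa=30, n_samples=5, reads_per_sample=200)
        table, tree, _ = syn.simulate_dataset(cfg)
        a = beta_nti(table, tree, n_null=99, seed=4)
        b = beta_nti(table, tree, n_null=99, seed=4)
        assert [r.score for r in a] == [r.score for r in b]

    def test_null_shuffle_preserves_observed(self):
        tree = _tree("((A:1,B:1):1,C:2);")
        t = CountTable(pd.DataFrame({"s1": [5, 0, 0], "s2": [0, 0, 5]}, index=list("ABC")))
        res = beta_nti(t, tree, n_null=49, seed=0)
        assert res[0].observed == pytest.approx(4.0)
        assert res[0].n_null == 49


class TestRaupCrick:
    def test_bounds_and_determinism(self, rng):
        t = random_count_table(rng, n_taxa=12, n_samples=5, depth=80)
        res = raup_crick_bray(t, n_null=99, seed=2)
        again = raup_crick_bray(t, n_null=99, seed=2)
        assert all(-1 <= r.score <= 1 for r in res)
        assert [r.score for r in res] == [r.score for r in again]

    def test_identical_rich_samples_near_minus_one(self, rng):
        # two identical samples drawn from a diverse pool: observed BC = 0
        pool = rng.integers(1, 20, size=30)
        cols = {"s1": pool, "s2": pool}
        for j in range(3, 9):
            cols[f"s{j}"] = rng.permutation(pool)
        t = CountTable(pd.DataFrame(cols, index=[f"t{i}" for i in range(30)]))
        res = raup_crick_bray(t, n_null=199, seed=5)
        pair = next(r for r in res if {r.sample_a, r.sample_b} == {"s1", "s2"})
        assert pair.score == pytest.approx(-1.0, abs=0.02)

    def test_zero_total_sample_rejected(self):
        t = CountTable(pd.DataFrame({"s1": [1, 1], "s2": [0, 0]}, index=["a", "b"]))
        with pytest.raises(ValueError, match="zero total"):
            raup_crick_bray(t, n_null=9, seed=0)


def _pair(a, b, bnti, rc):
    return (
        PairwiseNullResult(a, b, 1.0, 1.0, 1.0, bnti, 9),
        PairwiseNullResult(a, b, 0.5, np.nan, np.nan, rc, 9),
    )


class TestClassification:
    @pytest.mark.parametrize(
        "bnti,rc,expected",
        [
            (2.5, 0.99, "HeS"),
            (2.5, -0.99, "HeS"),  # betaNTI takes precedence
            (-2.5, 0.0, "HoS"),
            (0.4, 0.99, "DL"),
            (0.4, -0.99, "HD"),
            (0.4, 0.0, "drift"),
            (-1.96, 0.0, "drift"),  # strict boundary: |betaNTI| not > 1.96
            (1.96, 0.0, "drift"),
            (0.0, 0.95, "drift"),  # strict boundary: |RC| not > 0.95
            (0.0, -0.95, "drift"),
        ],
    )
    def test_threshold_rules(self, bnti, rc, expected):
        b, r = _pair("s1", "s2", bnti, rc)
        labels = classify_processes([b], [r])
        assert labels["process"].tolist() == [expected]

    def test_pair_mismatch_rejected(self):
        b, _ = _pair("s1", "s2", 0.0, 0.0)
        _, r = _pair("s1", "s3", 0.0, 0.0)
        with pytest.raises(ValueError, match="different sample pairs"):
            classify_processes([b], [r])

    def test_degenerate_pair_labelled(self):
        b = PairwiseNullResult("s1", "s2", 1.0, 1.0, 0.0, np.nan, 9, degenerate=True)
        _, r = _pair("s1", "s2", 0.0, 0.0)
        labels = classify_processes([b], [r])
        assert labels["process"].tolist() == ["degenerate"]

    def test_every_pair_gets_exactly_one_label(self, rng):
        pairs = []
        for i in range(50):
            b, r = _pair(f"a{i}", f"b{i}", rng.normal(scale=2), rng.uniform(-1, 1))
            pairs.append((b, r))
        labels = classify_processes([p[0] for p in pairs], [p[1] for p in pairs])
        assert len(labels) == 50
        assert set(labels["process"]) <= set(PROCESS_LABELS)


class TestProcessFractions:
    def test_counting(self):
        rows = [("s1", "s2", "HeS")] * 5 + [("s1", "s3", "HoS")] * 2 + [("s2", "s3", "drift")] * 3
        labels = pd.DataFrame(
            [(a, b, 0, 0, 0, proc) for a, b, proc in rows],
            columns=["sample_a", "sample_b", "bmntd_obs", "bnti", "rc_bray", "process"],
        )
        fr = process_fractions(labels)
        assert fr.loc["all"].tolist() == pytest.approx([0.5, 0.2, 0.0, 0.0, 0.3])

    def test_fractions_sum_to_one(self, rng):
        t = random_count_table(rng, n_taxa=10, n_samples=8)
        meta = metadata_for(t, n_levels=2)
        rows = []
        ids = t.sample_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                rows.append((ids[i], ids[j], 0, 0, 0, rng.choice(PROCESS_LABELS)))
        labels = pd.DataFrame(rows, columns=["sample_a", "sample_b", "bmntd_obs", "bnti", "rc_bray", "process"])
        fr = process_fractions(labels, meta, "habitat")
        assert np.allclose(fr.sum(axis=1), 1.0, atol=1e-9)

    def test_small_group_skipped(self, rng):
        t = random_count_table(rng, n_taxa=5, n_samples=5)
        meta = metadata_for(t, n_levels=5)  # every group has one sample
        labels = pd.DataFrame(
            [(t.sample_ids[0], t.sample_ids[1], 0, 0, 0, "drift")],
            columns=["sample_a", "sample_b", "bmntd_obs", "bnti", "rc_bray", "process"],
        )
        with pytest.warns(UserWarning):
            fr = process_fractions(labels, meta, "habitat")
        assert fr.empty
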