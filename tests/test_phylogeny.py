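import io

import numpy as np
import pytest

from wrky.io_formats import SeqRecord
from wrky.phylogeny import (
    DistanceMatrix,
    bootstrap_support,
    kmer_distance,
    nj_tree,
    pairwise_distance,
)

from oracles import random_additive_tree


def _aln(rows):
    return [SeqRecord(f"s{i}", r) for i, r in enumerate(rows)]


class TestPairwiseDistance:
    def test_identical_rows_zero(self):
        dm = pairwise_distance(_aln(["ACDEF", "ACDEF", "ACDEF"]))
        assert np.all(dm.d == 0)

    def test_p_distance_counts_mismatches(self):
        a = "A" * 100
        b = "C" * 5 + "A" * 95
        dm = pairwise_distance(_aln([a, b]))
        assert dm.d[0, 1] == pytest.approx(0.05)

    def test_poisson_correction(self):
        a = "A" * 100
        b = "C" * 5 + "A" * 95
        dm = pairwise_distance(_aln([a, b]), model="poisson")
        assert dm.d[0, 1] == pytest.approx(-np.log(0.95))

    def test_pairwise_gap_deletion(self):
        dm = pairwise_distance(_aln(["AC-EF", "ACD-F", "ACDEF"]))
        # s0/s1 share only columns 0,1,4 -> identical there
        assert dm.d[0, 1] == 0

    def test_no_comparable_columns_names_pair(self):
        with pytest.raises(ValueError, match="s0.*s1"):
            pairwise_distance(_aln(["A---", "-C--", "ACGT"]))


class TestNJ:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(("A", "B", "C"),
                            np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float))
        tree = nj_tree(dm)
        assert tree.newick() == "(A:1,B:2,C:4);"

    def test_four_taxon_additive_matrix(self):
        # path lengths of ((A:1,B:2):1,(C:3,D:4))
        labels = ("A", "B", "C", "D")
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = nj_tree(DistanceMatrix(labels, d))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        plm = tree.path_length_matrix()
        assert np.allclose(plm.d, d, atol=1e-9)

    def test_equal_distance_tie_is_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(("A", "B", "C", "D"), d)
        assert nj_tree(dm).newick() == nj_tree(dm).newick()

    def test_rejects_tiny_matrices(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("A", "B"), np.array([[0, 1], [1, 0.0]])))

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_recovery_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        labels, D, bips = random_additive_tree(n, rng)
        tree = nj_tree(DistanceMatrix(labels, D))
        assert tree.bipartitions() == bips
        assert np.allclose(tree.path_length_matrix().d, D, atol=1e-9)

    def test_matches_dendropy_on_noisy_matrix(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(3)
        labels, D, _ = random_additive_tree(8, rng)
        noise = rng.uniform(0, 0.05, size=D.shape)
        D = D + noise + noise.T
        np.fill_diagonal(D, 0)
        mine = nj_tree(DistanceMatrix(labels, D)).bipartitions()

        csv = "," + ",".join(labels) + "\n" + "\n".join(
            lab + "," + ",".join(f"{v:.10f}" for v in row)
            for lab, row in zip(labels, D)
        )
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(csv), delimiter=","
        )
        their_tree = pdm.nj_tree()
        theirs = set()
        all_leaves = frozenset(labels)
        for node in their_tree.preorder_node_iter():
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 1 < len(side) < len(labels) - 1:
                if min(labels) in side:
                    side = all_leaves - side
                theirs.add(side)
        assert mine == theirs


class TestBootstrap:
    def _saturating_alignment(self):
        # every column supports the AB|CD split
        rows = {"A": "AAAACCCC", "B": "AAAACCCC",
                "C": "TTTTGGGG", "D": "TTTTGGGG"}
        return [SeqRecord(k, v) for k, v in sorted(rows.items())]

    def test_saturating_signal_gives_full_support(self):
        tree = bootstrap_support(self._saturating_alignment(),
                                 n_replicates=50, seed=0)
        nwk = tree.newick(with_support=True)
        assert "100" in nwk

    def test_same_seed_same_supports(self):
        aln = self._saturating_alignment()
        t1 = bootstrap_support(aln, 20, seed=5)
        t2 = bootstrap_support(aln, 20, seed=5)
        assert t1.newick(with_support=True) == t2.newick(with_support=True)

    def test_single_replicate_supports_binary(self):
        rng = np.random.default_rng(1)
        rows = ["".join(rng.choice(list("ACDE"), size=30)) for _ in range(5)]
        tree = bootstrap_support(_aln(rows), n_replicates=1, seed=2)

        supports = []

        def walk(node):
            for child, _ in node.children:
                if child.support is not None:
                    supports.append(child.support)
                walk(child)

        walk(tree.root)
        assert supports and set(supports) <= {0.0, 100.0}

    def test_supports_invariant_to_leaf_order(self):
        aln = self._saturating_alignment()
        t1 = bootstrap_support(aln, 30, seed=9)
        t2 = bootstrap_support(aln[::-1], 30, seed=9)
        b1 = {tuple(sorted(b)) for b in t1.bipartitions()}
        b2 = {tuple(sorted(b)) for b in t2.bipartitions()}
        assert b1 == b2


class TestKmerDistance:
    def test_identical_sequences_zero(self):
        recs = [SeqRecord("a", "MKVLLD"), SeqRecord("b", "MKVLLD")]
        assert kmer_distance(recs).d[0, 1] == 0

    def test_disjoint_sequences_max(self):
        recs = [SeqRecord("a", "AAAAAA"), SeqRecord("b", "CCCCCC")]
        assert kmer_distance(recs).d[0, 1] == 1.0
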