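"""p-distances, neighbour joining, bootstrap, species monophyly."""

import numpy as np
import pytest

from scatbarcode.phylo import (
    DistanceMatrix,
    bootstrap_support,
    neighbor_joining,
    p_distance_matrix,
    species_monophyly,
)
from scatbarcode.seqcore import BarcodeSeq


# ---------------------------------------------------------------------------
# random additive-tree oracle: build a random unrooted binary tree, read off
# exact path-length distances, and demand NJ reproduce splits and lengths
# ---------------------------------------------------------------------------

def random_additive_tree(n, rng):
    """Return (labels, distance matrix, splits, total_length)."""
    labels = [f"t{i+1}" for i in range(n)]
    # adjacency with branch lengths; start from a star on 3 leaves
    next_internal = [n]
    edges = {}

    def add_edge(a, b, ln):
        edges[(a, b)] = ln
        edges[(b, a)] = ln

    center = next_internal[0]
    next_internal[0] += 1
    for leaf in range(3):
        add_edge(leaf, center, float(rng.uniform(0.5, 2.0)))
    for leaf in range(3, n):
        # subdivide a random existing edge and hang the new leaf off it
        a, b = list(edges)[rng.integers(len(edges))]
        ln = edges.pop((a, b))
        edges.pop((b, a))
        mid = next_internal[0]
        next_internal[0] += 1
        cut = float(rng.uniform(0.25, 0.75)) * ln
        add_edge(a, mid, cut)
        add_edge(mid, b, ln - cut)
        add_edge(mid, leaf, float(rng.uniform(0.5, 2.0)))

    # all-pairs leaf distances by BFS over the tree
    adj = {}
    for (a, b), ln in edges.items():
        adj.setdefault(a, []).append((b, ln))
    def dists_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, ln in adj[u]:
                if v not in out:
                    out[v] = out[u] + ln
                    stack.append(v)
        return out
    mat = np.zeros((n, n))
    for i in range(n):
        d = dists_from(i)
        for j in range(n):
            mat[i, j] = d[j]

    # non-trivial splits: leaf-set on one side of each internal-internal edge
    anchor = min(labels)
    splits = set()
    seen = set()
    for (a, b) in list(edges):
        if (b, a) in seen or a < n or b < n:
            seen.add((a, b))
            continue
        seen.add((a, b))
        # leaves reachable from a without crossing b
        side = set()
        stack = [a]
        visited = {a, b}
        while stack:
            u = stack.pop()
            if u < n:
                side.add(labels[u])
            for v, _ in adj[u]:
                if v not in visited:
                    visited.add(v)
                    stack.append(v)
        side = frozenset(side)
        if anchor in side:
            side = frozenset(labels) - side
        if 2 <= len(side) <= n - 2:
            splits.add(side)
    total = sum(edges[(a, b)] for (a, b) in edges if a < b)
    return labels, mat, splits, total


def tree_length(ptree):
    return sum(
        e.length or 0.0
        for e in ptree.tree.preorder_edge_iter()
        if e.head_node.parent_node is not None
    )


class TestPDistance:
    def test_identical_and_defined(self):
        dm = p_distance_matrix([BarcodeSeq("a", "ACGT" * 31 + "AC")] * 2)
        assert dm.values[0, 1] == 0.0

    def test_ten_differences_over_126(self):
        a = "A" * 126
        b = "G" * 10 + "A" * 116
        dm = p_distance_matrix([BarcodeSeq("a", a), BarcodeSeq("b", b)])
        assert dm.values[0, 1] == pytest.approx(10 / 126)

    def test_pairwise_deletion_denominator(self):
        a = "N" * 6 + "A" * 120
        b = "C" * 6 + "G" * 10 + "A" * 110
        dm = p_distance_matrix([BarcodeSeq("a", a), BarcodeSeq("b", b)])
        assert dm.denominators[0, 1] == 120
        assert dm.values[0, 1] == pytest.approx(10 / 120)

    def test_no_comparable_sites_errors(self):
        with pytest.raises(ValueError, match="comparable"):
            p_distance_matrix([BarcodeSeq("a", "NNNN"), BarcodeSeq("b", "ACGT")])


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # ((A:1,B:2):1,(C:3,D:4)) -> quartet AB|CD with exact branch lengths
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 0, 0],
            ],
            dtype=float,
        )
        d[3, 2] = d[2, 3] = 7.0
        ptree = neighbor_joining(DistanceMatrix(labels, d))
        assert ptree.bipartitions() == {frozenset({"C", "D"})}
        assert tree_length(ptree) == pytest.approx(1 + 2 + 1 + 3 + 4)

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        ptree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        lengths = sorted(
            lf.edge.length for lf in ptree.tree.leaf_node_iter()
        )
        assert lengths == pytest.approx([1.0, 2.0, 3.0])

    def test_equidistant_matrix_is_deterministic(self):
        d = np.ones((5, 5)) - np.eye(5)
        labels = list("abcde")
        t1 = neighbor_joining(DistanceMatrix(labels, d.copy()))
        t2 = neighbor_joining(DistanceMatrix(labels, d.copy()))
        assert t1.to_newick() == t2.to_newick()

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [3, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b", "c"], d)

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_additive_matrices_recovered_exactly(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(10):
            labels, mat, splits, total = random_additive_tree(n, rng)
            ptree = neighbor_joining(DistanceMatrix(labels, mat))
            assert ptree.bipartitions() == splits
            assert tree_length(ptree) == pytest.approx(total)


class TestBootstrap:
    def _aln_two_clades(self, n_support=80, n_noise=46, seed=0):
        rng = np.random.default_rng(seed)
        cols = []
        for _ in range(n_support):  # columns supporting AB|CD
            x, y = rng.choice(list("ACGT"), size=2, replace=False)
            cols.append([x, x, y, y])
        for _ in range(n_noise):
            cols.append(rng.choice(list("ACGT"), size=4))
        arr = np.array(cols).T
        return [
            BarcodeSeq(lab, "".join(row))
            for lab, row in zip("ABCD", arr)
        ]

    def test_unanimous_columns_give_full_support(self):
        aln = self._aln_two_clades(n_support=60, n_noise=0, seed=1)
        ptree = bootstrap_support(aln, n_replicates=100, seed=5)
        assert ptree.supports is not None
        assert ptree.supports[frozenset({"C", "D"})] == pytest.approx(100.0)

    def test_identical_sequences_flagged_no_signal(self):
        aln = [BarcodeSeq(lab, "ACGT" * 10) for lab in "abcd"]
        ptree = bootstrap_support(aln, n_replicates=50, seed=3)
        assert ptree.no_signal
        assert ptree.supports is None

    def test_seeded_reproducibility(self):
        aln = self._aln_two_clades(seed=2)
        s1 = bootstrap_support(aln, n_replicates=60, seed=11).supports
        s2 = bootstrap_support(aln, n_replicates=60, seed=11).supports
        assert s1 == s2

    def test_converges_to_large_replicate_reference(self):
        # 126 columns: 80 supporting AB|CD, 46 random noise
        aln = self._aln_two_clades(n_support=80, n_noise=46, seed=4)
        split = frozenset({"C", "D"})
        small = bootstrap_support(aln, n_replicates=500, seed=7)
        big = bootstrap_support(aln, n_replicates=2000, seed=8)
        assert small.supports[split] == pytest.approx(
            big.supports[split], abs=5.0
        )
        assert all(0 <= v <= 100 for v in small.supports.values())


class TestSpeciesMonophyly:
    def _tree_from(self, seqs):
        return neighbor_joining(p_distance_matrix(seqs))

    def test_clean_clades_detected(self):
        a = "A" * 60 + "C" * 6
        b = "G" * 60 + "C" * 6
        seqs = [
            BarcodeSeq("a1", a),
            BarcodeSeq("a2", a[:-1] + "T"),
            BarcodeSeq("b1", b),
            BarcodeSeq("b2", b[:-1] + "T"),
        ]
        ptree = self._tree_from(seqs)
        res = species_monophyly(
            ptree, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        )
        assert res["A"]["monophyletic"] and res["B"]["monophyletic"]

    def test_interleaved_species_not_monophyletic(self):
        x = "A" * 50 + "C" * 10
        y = "G" * 50 + "C" * 10
        seqs = [
            BarcodeSeq("a1", x),
            BarcodeSeq("b1", x[:-1] + "T"),
            BarcodeSeq("a2", y),
            BarcodeSeq("b2", y[:-1] + "T"),
        ]
        ptree = self._tree_from(seqs)
        res = species_monophyly(
            ptree, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        )
        assert not res["A"]["monophyletic"]
        assert not res["B"]["monophyletic"]

    def test_single_tip_trivially_monophyletic(self):
        seqs = [
            BarcodeSeq("a1", "A" * 40),
            BarcodeSeq("b1", "G" * 40),
            BarcodeSeq("c1", "T" * 40),
        ]
        res = species_monophyly(
            self._tree_from(seqs), {"a1": "A", "b1": "B", "c1": "C"}
        )
        assert all(v["monophyletic"] for v in res.values())
        assert res["A"]["support"] is None

    def test_unlabelled_tip_rejected(self):
        seqs = [
            BarcodeSeq("a1", "A" * 40),
            BarcodeSeq("b1", "G" * 40),
            BarcodeSeq("c1", "T" * 40),
        ]
        with pytest.raises(ValueError, match="c1"):
            species_monophyly(self._tree_from(seqs), {"a1": "A", "b1": "B"})

    def test_agrees_with_bruteforce_bipartitions(self):
        rng = np.random.default_rng(55)
        for _ in range(5):
            n = int(rng.integers(4, 10))
            labels, mat, splits, _ = random_additive_tree(n, rng)
            ptree = neighbor_joining(DistanceMatrix(labels, mat))
            species_of = {lab: f"g{i % 3}" for i, lab in enumerate(labels)}
            res = species_monophyly(ptree, species_of)
            anchor = min(labels)
            for sp, info in res.items():
                tips = frozenset(
                    l for l in labels if species_of[l] == sp
                )
                if len(tips) == 1 or len(tips) >= n - 1:
                    assert info["monophyletic"]
                    continue
                canonical = (
                    frozenset(labels) - tips if anchor in tips else tips
                )
                assert info["monophyletic"] == (canonical in splits)
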