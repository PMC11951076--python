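"""Alignment, distances, NJ reconstruction, bootstrap and monophyly."""

import itertools

import dendropy
import numpy as np
import pytest

import pufatyper as pt
from pufatyper.phylo import MSA, DistanceMatrix


# ---------------------------------------------------------------------------
# Independent random additive-tree generator (oracle input)
# ---------------------------------------------------------------------------

def random_additive_matrix(n_taxa: int, rng) -> tuple[DistanceMatrix, set[frozenset]]:
    """Random binary unrooted tree with positive branch lengths; returns its
    path-distance matrix and the set of non-trivial bipartitions."""
    labels = [f"t{i}" for i in range(n_taxa)]
    # grow an unrooted tree by splitting random edges
    edges = {}  # (u, v) -> length
    nodes = [0, 1, 2, 3]
    edges[(0, 3)] = rng.uniform(0.5, 3.0)
    edges[(1, 3)] = rng.uniform(0.5, 3.0)
    edges[(2, 3)] = rng.uniform(0.5, 3.0)
    next_node = 4
    tip_nodes = [0, 1, 2]
    while len(tip_nodes) < n_taxa:
        u, v = list(edges)[rng.integers(0, len(edges))]
        length = edges.pop((u, v))
        mid, tip = next_node, next_node + 1
        next_node += 2
        split = rng.uniform(0.2, 0.8) * length
        edges[(u, mid)] = split
        edges[(v, mid)] = length - split
        edges[(tip, mid)] = rng.uniform(0.5, 3.0)
        tip_nodes.append(tip)
    adj = {}
    for (u, v), length in edges.items():
        adj.setdefault(u, {})[v] = length
        adj.setdefault(v, {})[u] = length
    label_of = dict(zip(tip_nodes, labels))

    def distances_from(start):
        dist = {start: 0.0}
        stack = [start]
        while stack:
            x = stack.pop()
            for y, L in adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + L
                    stack.append(y)
        return dist

    d = np.zeros((n_taxa, n_taxa))
    for i, u in enumerate(tip_nodes):
        dist = distances_from(u)
        for j, v in enumerate(tip_nodes):
            d[i, j] = dist[v]
    np.fill_diagonal(d, 0.0)

    splits = set()
    for (u, v) in edges:
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            x = stack.pop()
            if x in label_of:
                side.add(label_of[x])
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 2 <= len(side) <= n_taxa - 2:
            splits.add(frozenset(side) if "t0" not in side
                       else frozenset(set(labels) - side))
    return DistanceMatrix(tuple(labels), (d + d.T) / 2), splits


class TestMSA:
    def test_rejects_ragged_rows(self):
        with pytest.raises(pt.InputError):
            MSA(("a", "b"), ("AC-", "AC"))

    def test_ungap_recovers_input(self):
        msa = MSA(("a",), ("A-C-D",))
        assert msa.ungapped("a") == "ACD"


class TestPDistance:
    def test_identical_rows(self):
        d = pt.p_distance_matrix(MSA(("a", "b"), ("ACDEF", "ACDEF")))
        assert d.values[0, 1] == 0.0

    def test_three_of_ten_comparable_mismatches(self):
        a = "ACDEFGHIKL"
        b = "ACDEFGAAAL"  # mismatches at 3 of 10 columns
        d = pt.p_distance_matrix(MSA(("a", "b"), (a, b)))
        assert d.values[0, 1] == pytest.approx(0.3)

    def test_gapped_columns_excluded(self):
        d = pt.p_distance_matrix(MSA(("a", "b"), ("AC-EF", "ACD-F")))
        # comparable: columns 0,1,4 -> no mismatches
        assert d.values[0, 1] == 0.0

    def test_matches_bruteforce_count_oracle(self):
        rng = np.random.default_rng(3)
        chars = np.array(list("ACDE-"))
        for _ in range(20):
            rows = tuple("".join(chars[rng.integers(0, 5, size=30)]) for _ in range(4))
            msa = MSA(tuple(f"s{i}" for i in range(4)), rows)
            d = pt.p_distance_matrix(msa)
            for i, j in itertools.combinations(range(4), 2):
                comp = mism = 0
                for a, b in zip(rows[i], rows[j]):
                    if a != "-" and b != "-":
                        comp += 1
                        mism += a != b
                expected = mism / comp if comp else 1.0
                assert d.values[i, j] == pytest.approx(expected)

    def test_no_comparable_columns_gives_one(self):
        d = pt.p_distance_matrix(MSA(("a", "b"), ("A---", "---C")))
        assert d.values[0, 1] == 1.0

    def test_poisson_correction_capped(self):
        d = pt.p_distance_matrix(MSA(("a", "b"), ("AAAA", "CCCC")), correction="poisson")
        assert d.values[0, 1] == pytest.approx(-np.log(1 - 0.95))


class TestNJ:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # path distances of the unrooted tree AB|CD with tip lengths 1,2,3,4
        # and internal edge 1
        ids = ("A", "B", "C", "D")
        d = np.array([[0.0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]])
        tree = pt.nj_tree(DistanceMatrix(ids, d))
        assert frozenset({"A", "B"}) in tree.edge_sides()
        for a, b in itertools.combinations(ids, 2):
            i, j = ids.index(a), ids.index(b)
            assert tree.path_length(a, b) == pytest.approx(d[i, j])

    def test_three_taxon_closed_form(self):
        ids = ("A", "B", "C")
        d = np.array([[0.0, 3, 4], [3, 0, 5], [4, 5, 0]])
        tree = pt.nj_tree(DistanceMatrix(ids, d))
        # la = (dab+dac-dbc)/2 = 1, lb = 2, lc = 3
        assert tree.path_length("A", "B") == pytest.approx(3)
        assert tree.path_length("A", "C") == pytest.approx(4)
        assert tree.path_length("B", "C") == pytest.approx(5)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_additive_matrices_recovered(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        dm, true_splits = random_additive_matrix(n, rng)
        tree = pt.nj_tree(dm)
        assert set(tree.bipartitions()) == true_splits
        for i, j in itertools.combinations(range(n), 2):
            assert tree.path_length(dm.ids[i], dm.ids[j]) == pytest.approx(dm.values[i, j])

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1], [2, 0]])
        with pytest.raises(pt.InputError):
            pt.nj_tree(DistanceMatrix(("a", "b"), d))

    def test_negative_branch_clamped_to_zero(self):
        ids = ("A", "B", "C", "D")
        d = np.array([[0.0, 0.1, 1, 1], [0.1, 0, 1, 1], [1, 1, 0, 0.01], [1, 1, 0.01, 0]])
        tree = pt.nj_tree(DistanceMatrix(ids, d))
        assert all(length >= 0 for _, _, length in tree.edges())

    def test_newick_parseable_by_dendropy(self):
        rng = np.random.default_rng(4)
        dm, _ = random_additive_matrix(6, rng)
        newick = pt.nj_tree(dm).newick()
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set(dm.ids)


class TestBootstrap:
    def _saturated_msa(self):
        rows = tuple(("A" if i < 2 else "C") * 100 + ("W" if i < 2 else "Y") * 100
                     for i in range(4))
        return MSA(("t1", "t2", "t3", "t4"), rows)

    def test_saturated_signal_gives_full_support(self):
        tree = pt.bootstrap_support(self._saturated_msa(), n_reps=100, seed=1)
        assert list(tree.support.values()) == [1.0]

    def test_single_replicate_supports_are_binary(self):
        tree = pt.bootstrap_support(self._saturated_msa(), n_reps=1, seed=2)
        assert set(tree.support.values()) <= {0.0, 1.0}

    def test_same_seed_reproducible(self):
        a = pt.bootstrap_support(self._saturated_msa(), n_reps=20, seed=5)
        b = pt.bootstrap_support(self._saturated_msa(), n_reps=20, seed=5)
        assert a.support == b.support

    def test_zero_reps_rejected(self):
        with pytest.raises(pt.InputError):
            pt.bootstrap_support(self._saturated_msa(), n_reps=0)


class TestMonophyly:
    def test_trivial_subsets(self):
        dm, _ = random_additive_matrix(6, np.random.default_rng(0))
        tree = pt.nj_tree(dm)
        assert pt.is_monophyletic(tree, set(dm.ids))       # all tips
        assert pt.is_monophyletic(tree, {dm.ids[0]})       # single tip
        assert pt.is_monophyletic(tree, set())             # empty

    def test_unknown_tip_rejected(self):
        dm, _ = random_additive_matrix(4, np.random.default_rng(1))
        with pytest.raises(pt.InputError):
            pt.is_monophyletic(pt.nj_tree(dm), {"ghost"})

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_dendropy_bipartitions(self, seed):
        """Cross-check every 2..n-2 subset against dendropy's split encoding."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        dm, _ = random_additive_matrix(n, rng)
        tree = pt.nj_tree(dm)
        dtree = dendropy.Tree.get(data=tree.newick(), schema="newick")
        dtree.encode_bipartitions()
        d_splits = set()
        for edge in dtree.preorder_edge_iter():
            if edge.bipartition is None:
                continue
            side = frozenset(t.label for t in
                             edge.bipartition.leafset_taxa(dtree.taxon_namespace))
            d_splits.add(side)
            d_splits.add(frozenset(set(dm.ids) - side))
        rng2 = np.random.default_rng(seed + 100)
        for _ in range(30):
            k = int(rng2.integers(2, n - 1))
            subset = frozenset(np.array(dm.ids)[rng2.permutation(n)[:k]].tolist())
            assert pt.is_monophyletic(tree, subset) == (subset in d_splits)


class TestProgressiveAlign:
    def test_identical_pair_gapless(self):
        msa = pt.progressive_align([("a", "MKVLIT"), ("b", "MKVLIT")])
        assert msa.rows == ("MKVLIT", "MKVLIT")

    def test_single_gap_column(self):
        msa = pt.progressive_align([("a", "ACDEFG"), ("b", "ACEFG")])
        assert msa.n_columns == 6
        assert msa.rows == ("ACDEFG", "AC-EFG")

    def test_rows_ungap_to_inputs(self):
        seqs = [("a", "MKVLITAGPT"), ("b", "MKVLIAGPT"), ("c", "MEVLITAGWT")]
        msa = pt.progressive_align(seqs)
        for sid, seq in seqs:
            assert msa.ungapped(sid) == seq

    def test_input_order_invariance(self):
        seqs = [(f"s{i}", s) for i, s in enumerate(
            ["MKVLITAAGPT", "MKVLISAGPT", "MEVLITAGWT", "AKVLITAGPTY", "MKVAITAGPT"])]
        ref = pt.progressive_align(seqs)
        ref_map = dict(zip(ref.ids, ref.rows))
        for perm in ([4, 3, 2, 1, 0], [2, 0, 4, 1, 3]):
            msa = pt.progressive_align([seqs[i] for i in perm])
            assert dict(zip(msa.ids, msa.rows)) == ref_map

    def test_fewer_than_two_rejected(self):
        with pytest.raises(pt.InputError):
            pt.progressive_align([("a", "MKV")])
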