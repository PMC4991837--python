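"""p-distance, neighbor joining, bootstrap, clade composition."""

import itertools

import dendropy
import numpy as np
import pytest

from wrkyscan.phylo import (Alignment, bootstrap_support, clade_composition,
                            internal_splits, nj_tree, p_distance)


def _random_additive(rng, n):
    """Random binary tree with positive branch lengths; returns (splits,
    distance matrix, ids)."""
    ids = [f"t{i}" for i in range(n)]
    # random agglomeration builds the tree; path distances are additive
    nodes = {i: ({ids[i]}, {ids[i]: 0.0}) for i in range(n)}
    # each node: (leafset, dict leaf -> distance to this node)
    splits = []
    keys = list(nodes)
    dist = {}
    while len(keys) > 1:
        i, j = rng.choice(len(keys), 2, replace=False)
        a, b = keys[int(i)], keys[int(j)]
        la, da = nodes.pop(a)
        lb, db = nodes.pop(b)
        keys = [k for k in keys if k not in (a, b)]
        ea, eb = rng.uniform(0.05, 0.5), rng.uniform(0.05, 0.5)
        for x in la:
            for y in lb:
                dist[frozenset((x, y))] = da[x] + ea + db[y] + eb
        new = max(nodes, default=-1) + 1 + n
        merged = la | lb
        nodes[new] = (merged, {**{x: da[x] + ea for x in la},
                               **{y: db[y] + eb for y in lb}})
        keys.append(new)
        if 2 <= len(merged) <= n - 2:
            splits.append(frozenset(merged))
    D = np.zeros((n, n))
    for x in range(n):
        for y in range(x + 1, n):
            D[x, y] = D[y, x] = dist[frozenset((ids[x], ids[y]))]
    # canonicalize splits to the side containing the smallest id
    anchor = min(ids)
    canon = set()
    for s in splits:
        side = s if anchor in s else frozenset(ids) - s
        canon.add(frozenset(side))
    return canon, D, ids


class TestPDistance:
    def test_identical_rows_zero(self):
        a = Alignment(["a", "b"], ["AAAA", "AAAA"])
        assert p_distance(a)[0, 1] == 0.0

    def test_quarter_mismatch(self):
        a = Alignment(["a", "b"], ["AAAA", "AAAT"])
        assert p_distance(a)[0, 1] == pytest.approx(0.25)

    def test_pairwise_gap_deletion(self):
        a = Alignment(["a", "b"], ["A-AA", "AAAT"])
        assert p_distance(a)[0, 1] == pytest.approx(1 / 3)

    def test_complete_deletion(self):
        a = Alignment(["a", "b", "c"], ["A-AA", "AAAT", "AAAA"])
        D = p_distance(a, gap_mode="complete")
        assert D[0, 1] == pytest.approx(1 / 3)

    def test_zero_comparable_sites_names_pair(self):
        a = Alignment(["x", "y"], ["A--", "-AA"])
        with pytest.raises(ValueError, match="x.*y"):
            p_distance(a)


class TestNJ:
    def test_three_taxon_closed_form(self):
        D = np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]])
        tree = nj_tree(D, ["t1", "t2", "t3"])
        lens = {leaf.taxon.label: leaf.edge.length
                for leaf in tree.leaf_node_iter()}
        assert lens["t1"] == pytest.approx(0.1)
        assert lens["t2"] == pytest.approx(0.1)
        assert lens["t3"] == pytest.approx(0.3)

    def test_four_taxon_split_vs_enumeration(self):
        # additive matrix from ((A,B),(C,D)); the correct topology is the
        # one satisfying the four-point condition
        ids = ["A", "B", "C", "D"]
        D = np.array([
            [0.0, 0.3, 1.0, 1.1],
            [0.3, 0.0, 1.1, 1.2],
            [1.0, 1.1, 0.0, 0.3],
            [1.1, 1.2, 0.3, 0.0],
        ])
        # oracle: enumerate the three possible splits
        best = min(
            [("AB|CD", D[0, 1] + D[2, 3]), ("AC|BD", D[0, 2] + D[1, 3]),
             ("AD|BC", D[0, 3] + D[1, 2])],
            key=lambda kv: kv[1])[0]
        assert best == "AB|CD"
        tree = nj_tree(D, ids)
        assert internal_splits(tree) == {frozenset({"A", "B"})}

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1.0, 2], [1.1, 0, 2], [2, 2, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(D, list("abc"))

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.zeros((2, 2)), ["a", "b"])

    def test_negative_branches_clamped(self):
        D = np.array([
            [0.0, 0.1, 0.6, 0.6],
            [0.1, 0.0, 0.05, 0.6],
            [0.6, 0.05, 0.0, 0.1],
            [0.6, 0.6, 0.1, 0.0],
        ])
        tree = nj_tree(D, list("abcd"))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0

    @pytest.mark.parametrize("n", [4, 5, 6, 8, 12])
    def test_additive_recovery(self, n):
        """NJ recovers the generating topology from additive distances."""
        rng = np.random.default_rng(n)
        for _ in range(20):
            want, D, ids = _random_additive(rng, n)
            tree = nj_tree(D, ids)
            assert internal_splits(tree) == want

    def test_deterministic_under_ties(self):
        D = np.ones((4, 4)) - np.eye(4)
        t1 = nj_tree(D, list("abcd")).as_string(schema="newick")
        t2 = nj_tree(D, list("abcd")).as_string(schema="newick")
        assert t1 == t2

    def test_crosscheck_skbio(self):
        """Independent NJ implementation (scikit-bio) yields the same
        topology on a random metric matrix."""
        skbio = pytest.importorskip("skbio")
        from io import StringIO

        rng = np.random.default_rng(5)
        n = 8
        X = rng.uniform(0.1, 1.0, size=(n, 12))
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                D[i, j] = np.abs(X[i] - X[j]).sum()
        ids = [f"s{i}" for i in range(n)]
        ours = nj_tree(D, ids)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(D, ids))
        tns = ours.taxon_namespace
        d2 = dendropy.Tree.get(data=str(theirs), schema="newick",
                               taxon_namespace=tns,
                               preserve_underscores=True)
        assert internal_splits(ours) == internal_splits(d2)


class TestBootstrap:
    def _two_clade_alignment(self, rng, per_clade=6, cols=60):
        baseA = "".join(rng.choice(list("ACDEFGHIK"), cols))
        baseB = "".join(rng.choice(list("LMNPQRSTV"), cols))
        ids, rows = [], []
        for k in range(per_clade):
            for base, tag in ((baseA, "a"), (baseB, "b")):
                row = list(base)
                for p in rng.choice(cols, 3, replace=False):
                    row[p] = "WY"[int(rng.integers(2))]
                ids.append(f"{tag}{k}")
                rows.append("".join(row))
        return Alignment(ids, rows)

    def test_divergent_clades_high_support(self, rng):
        aln = self._two_clade_alignment(rng)
        tree, supports = bootstrap_support(aln, B=200, seed=7)
        clade_a = frozenset(i for i in aln.ids if i.startswith("a"))
        assert supports[clade_a] >= 95

    def test_single_replicate_supports_binary(self, rng):
        aln = self._two_clade_alignment(rng, per_clade=3, cols=30)
        _, supports = bootstrap_support(aln, B=1, seed=0)
        assert set(supports.values()) <= {0.0, 100.0}

    def test_same_seed_reproducible(self, rng):
        aln = self._two_clade_alignment(rng, per_clade=4, cols=40)
        _, s1 = bootstrap_support(aln, B=50, seed=3)
        _, s2 = bootstrap_support(aln, B=50, seed=3)
        assert s1 == s2

    def test_leaf_order_invariance(self, rng):
        aln = self._two_clade_alignment(rng, per_clade=4, cols=40)
        perm = list(reversed(range(len(aln))))
        aln2 = Alignment([aln.ids[i] for i in perm],
                         [aln.rows[i] for i in perm])
        _, s1 = bootstrap_support(aln, B=30, seed=9)
        _, s2 = bootstrap_support(aln2, B=30, seed=9)
        assert s1 == s2


class TestCladeComposition:
    def _tree(self, newick):
        return dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)

    def test_monophyletic_union(self):
        t = self._tree("((x1,x2),(x3,(y1,y2)));")
        labels = {"x1": "III", "x2": "III", "x3": "Ib", "y1": "IIc",
                  "y2": "IIc"}
        rep = clade_composition(t, labels, {"IIc": frozenset({"IIc"})})
        assert rep["IIc"]["monophyletic"] and rep["IIc"]["cover"] == 1

    def test_split_group_cover_two(self):
        t = self._tree("((c1,x1),(c2,x2),(x3,x4));")
        labels = {"c1": "IIc", "c2": "IIc", "x1": "III", "x2": "III",
                  "x3": "III", "x4": "III"}
        rep = clade_composition(t, labels, {"IIc": frozenset({"IIc"})})
        assert not rep["IIc"]["monophyletic"]
        assert rep["IIc"]["cover"] == 2

    def test_single_leaf_group_trivially_monophyletic(self):
        t = self._tree("((a,b),(c,d));")
        labels = {"a": "Ia", "b": "III", "c": "III", "d": "III"}
        rep = clade_composition(t, labels, {"Ia": frozenset({"Ia"})})
        assert rep["Ia"]["monophyletic"]

    def test_unlabeled_leaf_rejected(self):
        t = self._tree("((a,b),(c,d));")
        with pytest.raises(ValueError, match="unlabeled"):
            clade_composition(t, {"a": "Ia"}, {"Ia": frozenset({"Ia"})})
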