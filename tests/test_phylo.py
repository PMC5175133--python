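"""p-distance, neighbor joining, midpoint rooting and bootstrap supports."""

import numpy as np
import pytest

from profam.phylo import (
    DistanceMatrix,
    PhyloError,
    PhyloTree,
    TreeNode,
    bootstrap_support,
    midpoint_root,
    nj,
    p_distance,
)
from profam.seqio import Alignment
from profam.synthetic import gen_alignment

from oracles import brute_p_distance


def random_additive_tree(rng, n_taxa):
    """Random binary unrooted tree with positive lengths; returns (taxa,
    distance matrix, bipartitions) computed independently of the NJ code."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    # random sequential attachment: start from a 3-star, attach each new leaf
    # to a randomly chosen existing edge
    nodes = {t: [] for t in taxa[:3]}
    center = "internal0"
    edges = {}

    def add_edge(a, b, w):
        edges[frozenset((a, b))] = w

    adj = {center: []}
    for t in taxa[:3]:
        adj.setdefault(t, [])
        adj[center].append(t)
        adj[t].append(center)
        add_edge(center, t, float(rng.uniform(0.5, 3.0)))
    internal_count = 1
    for t in taxa[3:]:
        edge = list(edges.keys())[int(rng.integers(len(edges)))]
        a, b = tuple(edge)
        w = edges.pop(edge)
        adj[a].remove(b)
        adj[b].remove(a)
        mid = f"internal{internal_count}"
        internal_count += 1
        adj[mid] = [a, b, t]
        adj[a].append(mid)
        adj[b].append(mid)
        adj.setdefault(t, []).append(mid)
        split = float(rng.uniform(0.2, 0.8))
        add_edge(a, mid, w * split)
        add_edge(mid, b, w * (1 - split))
        add_edge(mid, t, float(rng.uniform(0.5, 3.0)))

    # all-pairs leaf distances by traversal
    def dists_from(start):
        out = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in out:
                    out[v] = out[u] + edges[frozenset((u, v))]
                    stack.append(v)
        return out

    D = np.zeros((n_taxa, n_taxa))
    for i, t in enumerate(taxa):
        reach = dists_from(t)
        for j, s in enumerate(taxa):
            D[i, j] = reach[s]
    D = (D + D.T) / 2.0  # remove float jitter from per-row traversal order
    np.fill_diagonal(D, 0.0)

    # true non-trivial bipartitions from internal edges
    taxa_set = frozenset(taxa)
    anchor = min(taxa_set)
    parts = set()
    for edge in edges:
        a, b = tuple(edge)
        # leaves on b's side when the edge is cut
        seen = {a, b}
        stack = [b]
        side = set()
        while stack:
            u = stack.pop()
            if u in taxa_set:
                side.add(u)
            for v in adj[u]:
                if v not in seen and frozenset((u, v)) != edge:
                    seen.add(v)
                    stack.append(v)
        if 2 <= len(side) <= n_taxa - 2:
            fs = frozenset(side)
            parts.add(fs if anchor not in fs else taxa_set - fs)
    return taxa, D, parts


class TestPDistance:
    def make_aln(self, rows, ids=None):
        ids = ids or tuple(f"s{i}" for i in range(len(rows)))
        return Alignment(ids=tuple(ids), rows=tuple(rows))

    def test_identical_rows_zero(self):
        aln = self.make_aln(["AAAA", "AAAA", "AAAA"])
        assert np.allclose(p_distance(aln).d, 0.0)

    def test_single_difference(self):
        aln = self.make_aln(["AAAA", "AAAT", "AAAA"])
        D = p_distance(aln)
        assert D[("s0", "s1")] == pytest.approx(0.25)

    def test_pairwise_deletion_skips_gap_sites(self):
        aln = self.make_aln(["AA-A", "AATA", "AAAA"])
        D = p_distance(aln, "pairwise-deletion")
        assert D[("s0", "s1")] == 0.0  # 3 comparable sites, all equal

    def test_complete_deletion_drops_gapped_columns(self):
        aln = self.make_aln(["AC-A", "ACTA", "GCTA"])
        D = p_distance(aln, "complete-deletion")
        # column 3 removed everywhere; s0 vs s2 differ at 1 of 3 kept sites
        assert D[("s0", "s2")] == pytest.approx(1 / 3)

    def test_matches_site_enumeration_oracle(self, rng):
        letters = np.array(list("ACDEFG-"))
        rows = ["".join(rng.choice(letters, size=60)) for _ in range(5)]
        aln = self.make_aln(rows)
        D = p_distance(aln, "pairwise-deletion")
        for i in range(5):
            for j in range(i + 1, 5):
                assert D.d[i, j] == pytest.approx(brute_p_distance(rows[i], rows[j]))

    def test_symmetry_and_row_order_invariance(self, rng):
        aln = gen_alignment(n_clades=3, leaves_per_clade=2, length=100, seed=1)
        D = p_distance(aln)
        assert np.allclose(D.d, D.d.T)
        rev = Alignment(ids=aln.ids[::-1], rows=aln.rows[::-1])
        Drev = p_distance(rev)
        for a in aln.ids:
            for b in aln.ids:
                if a != b:
                    assert D[(a, b)] == Drev[(a, b)]

    def test_no_comparable_sites_is_error(self):
        aln = self.make_aln(["AA--", "--AA", "AAAA"])
        with pytest.raises(PhyloError, match="comparable"):
            p_distance(aln, "pairwise-deletion")


class TestNJ:
    def test_three_taxa_closed_form(self):
        taxa = ("a", "b", "c")
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = nj(DistanceMatrix(taxa, d))
        dist = tree.leaf_distances()
        assert dist[("a", "b")] == pytest.approx(3.0)
        assert dist[("a", "c")] == pytest.approx(4.0)
        assert dist[("b", "c")] == pytest.approx(5.0)

    def test_four_taxon_additive_matrix_recovered(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) -> path distances below
        taxa = ("a", "b", "c", "d")
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], float)
        tree = nj(DistanceMatrix(taxa, d))
        dist = tree.leaf_distances()
        for (x, y), expected in {("a", "b"): 3, ("a", "c"): 5, ("a", "d"): 6,
                                 ("b", "c"): 6, ("b", "d"): 7, ("c", "d"): 7}.items():
            assert dist[(x, y)] == pytest.approx(expected, abs=1e-9)
        assert tree.bipartitions() == {frozenset({"c", "d"})}

    def test_random_additive_matrices_exactly_recovered(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 13))
            taxa, D, true_parts = random_additive_tree(rng, n)
            tree = nj(DistanceMatrix(tuple(taxa), D))
            dist = tree.leaf_distances()
            for i in range(n):
                for j in range(i + 1, n):
                    key = tuple(sorted((taxa[i], taxa[j])))
                    assert abs(dist[key] - D[i, j]) <= 1e-9
            assert tree.bipartitions() == true_parts

    def test_agrees_with_independent_nj_implementation(self, rng):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        taxa, D, _ = random_additive_tree(rng, 8)
        ours = nj(DistanceMatrix(tuple(taxa), D)).bipartitions()
        sk_tree = skbio_nj(SkbioDM(D, ids=taxa))
        anchor = min(taxa)
        taxa_set = frozenset(taxa)
        theirs = set()
        for node in sk_tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(taxa) - 2:
                theirs.add(side if anchor not in side else taxa_set - side)
        assert ours == theirs

    def test_leaf_count_preserved(self, rng):
        taxa, D, _ = random_additive_tree(rng, 9)
        assert sorted(nj(DistanceMatrix(tuple(taxa), D)).leaf_names()) == sorted(taxa)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
        with pytest.raises(PhyloError):
            DistanceMatrix(("a", "b", "c"), d)


def tree_depths(tree):
    """Root-to-leaf distances of a rooted tree."""
    out = {}

    def walk(node, acc):
        if node.is_leaf():
            out[node.name] = acc
        for c in node.children:
            walk(c, acc + (c.length or 0.0))

    walk(tree.root, 0.0)
    return out


class TestMidpoint:
    def test_two_leaf_tree(self):
        a = TreeNode(name="a", length=1.0)
        b = TreeNode(name="b", length=3.0)
        rooted = midpoint_root(PhyloTree(root=TreeNode(children=[a, b])))
        depths = tree_depths(rooted)
        assert depths["a"] == pytest.approx(2.0)
        assert depths["b"] == pytest.approx(2.0)

    def test_caterpillar_diameter_endpoints_equidistant(self, rng):
        taxa, D, _ = random_additive_tree(rng, 6)
        unrooted = nj(DistanceMatrix(tuple(taxa), D))
        pairs = unrooted.leaf_distances()
        (far_a, far_b), diameter = max(pairs.items(), key=lambda kv: kv[1])
        rooted = midpoint_root(unrooted)
        depths = tree_depths(rooted)
        assert depths[far_a] == pytest.approx(diameter / 2, abs=1e-9)
        assert depths[far_b] == pytest.approx(diameter / 2, abs=1e-9)

    def test_symmetric_tree_roots_on_central_edge(self):
        left = TreeNode(length=1.0, children=[TreeNode(name="a", length=1.0),
                                              TreeNode(name="b", length=1.0)])
        c = TreeNode(name="c", length=1.0)
        d = TreeNode(name="d", length=1.0)
        # unrooted: ((a,b),c,d) with the (a,b) stem of length 1
        tree = PhyloTree(root=TreeNode(children=[left, c, d]))
        depths = tree_depths(midpoint_root(tree))
        assert depths["a"] == pytest.approx(depths["c"])

    def test_rooted_tree_has_binary_root(self, rng):
        taxa, D, _ = random_additive_tree(rng, 7)
        rooted = midpoint_root(nj(DistanceMatrix(tuple(taxa), D)))
        assert rooted.is_rooted
        assert sorted(rooted.leaf_names()) == sorted(taxa)

    def test_preserves_leaf_path_lengths(self, rng):
        taxa, D, _ = random_additive_tree(rng, 8)
        unrooted = nj(DistanceMatrix(tuple(taxa), D))
        assert unrooted.leaf_distances() == pytest.approx(
            midpoint_root(unrooted).leaf_distances(), abs=1e-9)


class TestBootstrap:
    def test_single_replicate_supports_binary(self):
        aln = gen_alignment(n_clades=3, leaves_per_clade=2, length=120, seed=2)
        tree = bootstrap_support(aln, replicates=1, seed=0)
        sup = [n.support for n in tree.root.iter_nodes() if n.support is not None]
        assert sup and all(s in (0.0, 1.0) for s in sup)

    def test_fixed_seed_reproducible(self):
        aln = gen_alignment(n_clades=3, leaves_per_clade=2, length=120, seed=2)
        t1 = bootstrap_support(aln, replicates=25, seed=9)
        t2 = bootstrap_support(aln, replicates=25, seed=9)
        s1 = [n.support for n in t1.root.iter_nodes() if n.support is not None]
        s2 = [n.support for n in t2.root.iter_nodes() if n.support is not None]
        assert s1 == s2

    def test_strong_signal_gives_high_supports(self):
        aln = gen_alignment(n_clades=4, leaves_per_clade=2, length=300,
                            within_divergence=0.05, between_divergence=0.3, seed=7)
        tree = bootstrap_support(aln, replicates=100, seed=1)
        sup = [n.support for n in tree.root.iter_nodes() if n.support is not None]
        assert len(sup) == 5  # 8-leaf unrooted binary tree: 5 internal edges
        assert min(sup) >= 0.9

    def test_bipartitions_invariant_under_leaf_renaming(self):
        aln = gen_alignment(n_clades=3, leaves_per_clade=2, length=150, seed=4)
        tree = nj(p_distance(aln))
        mapping = {name: f"x_{name}" for name in aln.ids}
        renamed_aln = Alignment(ids=tuple(mapping[i] for i in aln.ids), rows=aln.rows)
        renamed_tree = nj(p_distance(renamed_aln))
        ours = {frozenset(mapping[n] for n in part) for part in tree.bipartitions()}
        # canonicalisation may flip sides when the anchor changes; compare splits
        full = frozenset(mapping.values())

        def canon(parts):
            return {frozenset((fs, full - fs)) for fs in parts}

        assert canon(ours) == canon(renamed_tree.bipartitions())
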