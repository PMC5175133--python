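"""Distance-based protein phylogeny: p-distance, neighbor-joining, midpoint
rooting, and column-resampling bootstrap supports.

The p-distance between two aligned sequences is the proportion of differing
sites over the sites comparable in both (gap handling is configurable).
Trees are built with the Saitou-Nei neighbor-joining agglomeration, which is
exact on additive distance matrices; negative branch lengths are clamped to
zero with the deficit moved to the sister edge, the standard remedy. Supports
are the fraction of column-resampled replicate trees containing each internal
leaf bipartition of the reference tree.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .seqio import Alignment

GAP_POLICIES = ("pairwise-deletion", "complete-deletion")


class PhyloError(ValueError):
    pass


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if d.shape != (n, n):
            raise PhyloError("distance matrix shape does not match taxa")
        if not np.allclose(d, d.T, atol=1e-12):
            raise PhyloError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise PhyloError("distance matrix diagonal is not zero")
        if (d < -1e-12).any():
            raise PhyloError("negative distances")
        object.__setattr__(self, "d", d)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return float(self.d[i, j])


@dataclass
class TreeNode:
    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def iter_leaves(self):
        if self.is_leaf():
            yield self
        else:
            for c in self.children:
                yield from c.iter_leaves()

    def iter_nodes(self):
        yield self
        for c in self.children:
            yield from c.iter_nodes()


@dataclass
class PhyloTree:
    """A phylogenetic tree; unrooted trees carry a trifurcating root node."""

    root: TreeNode
    dropped_replicates: int = 0  # bootstrap replicates discarded as degenerate

    @property
    def is_rooted(self) -> bool:
        return len(self.root.children) == 2

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.iter_leaves()]

    def _adjacency(self) -> dict[int, list[tuple[TreeNode, float]]]:
        adj: dict[int, list[tuple[TreeNode, float]]] = {}
        self._index: dict[int, TreeNode] = {}

        def walk(node: TreeNode) -> None:
            self._index[id(node)] = node
            adj.setdefault(id(node), [])
            for c in node.children:
                length = c.length if c.length is not None else 0.0
                adj[id(node)].append((c, length))
                adj.setdefault(id(c), []).append((node, length))
                walk(c)

        walk(self.root)
        return adj

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path lengths between all leaf pairs (keys sorted name pairs)."""
        adj = self._adjacency()
        leaves = list(self.root.iter_leaves())
        out: dict[tuple[str, str], float] = {}
        for leaf in leaves:
            dist = {id(leaf): 0.0}
            stack = [leaf]
            while stack:
                node = stack.pop()
                for nb, length in adj[id(node)]:
                    if id(nb) not in dist:
                        dist[id(nb)] = dist[id(node)] + length
                        stack.append(nb)
            for other in leaves:
                if other.name < leaf.name:
                    out[(other.name, leaf.name)] = dist[id(other)]
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions, one frozenset per internal edge.

        Each bipartition is canonicalised as the side NOT containing the
        alphabetically first leaf, so the representation is invariant to
        rooting and traversal order.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        parts: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 2 <= len(below) <= len(all_leaves) - 2:
                side = below if anchor not in below else all_leaves - below
                parts.add(side)
            return below

        walk(self.root)
        return parts


def p_distance(aln: Alignment, gap_policy: str = "pairwise-deletion") -> DistanceMatrix:
    """Proportion of differing residues per pair over comparable columns.

    ``pairwise-deletion`` compares, per pair, the columns where neither row
    has a gap; ``complete-deletion`` first drops every column containing a
    gap in any row. A pair with zero comparable columns is an error.
    """
    if gap_policy not in GAP_POLICIES:
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    if aln.n_rows < 3:
        raise PhyloError("p_distance needs at least 3 rows")
    mat = np.array([list(row) for row in aln.rows])
    nongap = mat != "-"
    if gap_policy == "complete-deletion":
        keep = nongap.all(axis=0)
        if not keep.any():
            raise PhyloError("no gap-free columns under complete-deletion")
        mat = mat[:, keep]
        nongap = nongap[:, keep]
    n = aln.n_rows
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        comparable = nongap[i] & nongap[j]
        m = int(comparable.sum())
        if m == 0:
            raise PhyloError(f"no comparable sites for pair ({aln.ids[i]}, {aln.ids[j]})")
        diffs = int((mat[i, comparable] != mat[j, comparable]).sum())
        d[i, j] = d[j, i] = diffs / m
    return DistanceMatrix(taxa=tuple(aln.ids), d=d)


def nj(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor-joining; unrooted (trifurcating root).

    Q-matrix ties are broken by the lowest (i, j) index pair of the current
    matrix. Negative limb lengths are clamped to 0 with the deficit added to
    the sister limb, preserving the pair's summed length.
    """
    n = len(D.taxa)
    if n < 3:
        raise PhyloError("nj needs at least 3 taxa")
    d = D.d.copy()
    nodes: list[TreeNode] = [TreeNode(name=t) for t in D.taxa]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = divmod(int(np.argmin(q)), m)  # row-major argmin = lowest (i, j)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.pad(d[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        d[-1, :-1] = d[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [parent]

    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = max(0.0, 0.5 * (dab + dac - dbc))
    b.length = max(0.0, 0.5 * (dab + dbc - dac))
    c.length = max(0.0, 0.5 * (dac + dbc - dab))
    return PhyloTree(root=TreeNode(children=[a, b, c]))


def _edge_key(x: TreeNode, y: TreeNode) -> frozenset[int]:
    return frozenset((id(x), id(y)))


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root the tree at the midpoint of its longest leaf-to-leaf path.

    The two endpoints of the diameter path end up equidistant from the new
    root. With all-zero branch lengths the diameter is 0 and the root is
    placed on the first edge of a deterministic preorder traversal.
    """
    leaves = list(tree.root.iter_leaves())
    if len(leaves) < 2:
        raise PhyloError("midpoint rooting needs at least 2 leaves")

    adj: dict[int, list[tuple[TreeNode, float]]] = {}
    node_of: dict[int, TreeNode] = {}
    edge_attr: dict[frozenset[int], tuple[float, float | None]] = {}

    def build(node: TreeNode) -> None:
        node_of[id(node)] = node
        adj.setdefault(id(node), [])
        for c in node.children:
            length = c.length if c.length is not None else 0.0
            adj[id(node)].append((c, length))
            adj.setdefault(id(c), []).append((node, length))
            edge_attr[_edge_key(node, c)] = (length, c.support)
            build(c)

    build(tree.root)

    def paths_from(start: TreeNode) -> dict[int, tuple[float, list[TreeNode]]]:
        seen = {id(start): (0.0, [start])}
        stack = [start]
        while stack:
            node = stack.pop()
            dist, path = seen[id(node)]
            for nb, length in adj[id(node)]:
                if id(nb) not in seen:
                    seen[id(nb)] = (dist + length, path + [nb])
                    stack.append(nb)
        return seen

    # diameter pair; ties resolved by sorted leaf-name pair for determinism
    best = None
    for leaf in sorted(leaves, key=lambda x: x.name):
        reach = paths_from(leaf)
        for other in sorted(leaves, key=lambda x: x.name):
            if other.name <= leaf.name:
                continue
            dist, path = reach[id(other)]
            if best is None or dist > best[0] + 1e-15:
                best = (dist, path)
    diameter, path = best
    half = diameter / 2.0

    # locate the edge on the path where the cumulative distance crosses half
    cum = 0.0
    x = path[0]
    y = path[1] if len(path) > 1 else path[0]
    offset = 0.0
    for a, b in zip(path, path[1:]):
        length = edge_attr[_edge_key(a, b)][0]
        if cum + length >= half - 1e-15:
            x, y = a, b
            offset = half - cum
            break
        cum += length

    def hang(node: TreeNode, came_from: TreeNode) -> TreeNode:
        length, support = edge_attr[_edge_key(node, came_from)]
        new = TreeNode(
            name=node.name,
            length=length,
            support=support if not node.is_leaf() else None,
        )
        for nb, _ in adj[id(node)]:
            if nb is not came_from:
                new.children.append(hang(nb, node))
        return new

    edge_len, edge_support = edge_attr[_edge_key(x, y)]
    side_x = hang(x, y)
    side_y = hang(y, x)
    side_x.length = offset
    side_y.length = edge_len - offset
    # the split edge's support applies to both halves of the old edge
    if not side_x.is_leaf():
        side_x.support = edge_support
    if not side_y.is_leaf():
        side_y.support = edge_support

    def collapse_unary(node: TreeNode) -> TreeNode:
        # re-rooting can leave pass-through nodes (e.g. the old trifurcating
        # root of a 2-leaf tree); merge them into their single child
        node.children = [collapse_unary(c) for c in node.children]
        if len(node.children) == 1 and node.name is None:
            child = node.children[0]
            child.length = (child.length or 0.0) + (node.length or 0.0)
            return child
        return node

    side_x = collapse_unary(side_x)
    side_y = collapse_unary(side_y)
    return PhyloTree(root=TreeNode(children=[side_x, side_y]),
                     dropped_replicates=tree.dropped_replicates)


def bootstrap_support(
    aln: Alignment,
    replicates: int = 500,
    seed: int = 0,
    gap_policy: str = "pairwise-deletion",
) -> PhyloTree:
    """NJ tree from the full alignment with bootstrap supports on internal nodes.

    Each replicate resamples alignment columns with replacement, recomputes
    the p-distance matrix and the NJ tree; the support of an internal edge is
    the fraction of successful replicates whose tree contains the same leaf
    bipartition. Replicates in which some pair has no comparable sites are
    dropped and counted in ``dropped_replicates``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    reference = nj(p_distance(aln, gap_policy))
    ref_parts = reference.bipartitions()
    counts = {part: 0 for part in ref_parts}
    rng = np.random.default_rng(seed)
    L = aln.n_cols
    used = 0
    dropped = 0
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        rows = tuple("".join(row[c] for c in cols) for row in aln.rows)
        rep_aln = Alignment(ids=aln.ids, rows=rows)
        try:
            rep_tree = nj(p_distance(rep_aln, gap_policy))
        except PhyloError:
            dropped += 1
            continue
        used += 1
        rep_parts = rep_tree.bipartitions()
        for part in ref_parts:
            if part in rep_parts:
                counts[part] += 1
    if used == 0:
        raise PhyloError("every bootstrap replicate was degenerate")

    all_leaves = frozenset(aln.ids)
    anchor = min(all_leaves)

    def annotate(node: TreeNode, is_root: bool) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c, False) for c in node.children))
        if not is_root and 2 <= len(below) <= len(all_leaves) - 2:
            side = below if anchor not in below else all_leaves - below
            node.support = counts[side] / used
        return below

    annotate(reference.root, True)
    reference.dropped_replicates = dropped
    return reference
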