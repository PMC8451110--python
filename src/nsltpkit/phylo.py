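"""Distance-based phylogeny: p-distances, neighbour-joining, bootstrap.

The tree inference follows Saitou & Nei's neighbour-joining with the
standard Q-criterion.  Tie-breaks are deterministic (smallest Q, then the
lexicographically smallest pair of subtree labels) and negative branch
lengths are clamped to zero, so a given distance matrix always yields
the same tree.  Bootstrap support resamples alignment columns with
replacement; each replicate's random stream is derived from the master
seed and the replicate index, so results do not depend on evaluation
order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .classify import AnchoredAlignment

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "p_distance",
    "nj_tree",
    "bootstrap_support",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if self.matrix.min() < -1e-12:
            raise ValueError("distances must be non-negative")


class _Node:
    __slots__ = ("label", "children", "sort_key", "support")

    def __init__(self, label: Optional[str] = None,
                 children: Optional[list[tuple["_Node", float]]] = None,
                 sort_key: str = ""):
        self.label = label
        self.children: list[tuple[_Node, float]] = children or []
        self.sort_key = sort_key if sort_key else (label or "")
        self.support: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Unrooted tree, stored rooted at an internal trifurcation."""

    root: _Node
    ids: list[str] = field(default_factory=list)

    def newick(self, with_support: bool = False) -> str:
        def render(node: _Node) -> str:
            if node.is_leaf:
                return node.label or ""
            inner = ",".join(f"{render(child)}:{length:.10g}" for child, length in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:.10g}"
            return f"({inner}){label}"

        return render(self.root) + ";"

    def leaf_labels(self) -> list[str]:
        labels: list[str] = []

        def walk(node: _Node) -> None:
            if node.is_leaf:
                labels.append(node.label or "")
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return labels

    def path_lengths(self) -> DistanceMatrix:
        """Leaf-to-leaf path lengths through the tree."""
        labels = sorted(self.leaf_labels())
        index = {name: i for i, name in enumerate(labels)}
        n = len(labels)
        mat = np.zeros((n, n))

        def walk(node: _Node, dist_so_far: dict[str, float]) -> dict[str, float]:
            # returns leaf -> distance to this node
            if node.is_leaf:
                return {node.label or "": 0.0}
            below: dict[str, float] = {}
            child_maps = []
            for child, length in node.children:
                cmap = {leaf: d + length for leaf, d in walk(child, dist_so_far).items()}
                child_maps.append(cmap)
            for amap, bmap in itertools.combinations(child_maps, 2):
                for la, da in amap.items():
                    for lb, db in bmap.items():
                        mat[index[la], index[lb]] = mat[index[lb], index[la]] = da + db
            for cmap in child_maps:
                below.update(cmap)
            return below

        walk(self.root, {})
        return DistanceMatrix(labels, mat)

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each written as the leaf set not containing
        the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_labels())
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()

        def walk(node: _Node) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label or ""])
            below = frozenset().union(*(walk(child) for child, _ in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                side = all_leaves - below if anchor in below else below
                splits.add(side)
            return below

        for child, _ in self.root.children:
            walk(child)
        return splits


def p_distance(alignment: AnchoredAlignment, on_empty: str = "error") -> DistanceMatrix:
    """Pairwise p-distance with pairwise deletion of gapped columns.

    ``on_empty`` controls pairs with zero comparable columns: "error"
    raises naming the pair, "max" records a distance of 1.0 (used inside
    bootstrap replicates, where a resample can drop all shared columns).
    """
    if len(alignment.rows) < 2:
        raise ValueError("p_distance requires at least two rows")
    rows = np.array([list(row) for row in alignment.rows])
    gap = rows == "-"
    n = len(alignment.ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            usable = ~(gap[i] | gap[j])
            total = int(usable.sum())
            if total == 0:
                if on_empty == "max":
                    d = 1.0
                else:
                    raise ValueError(
                        f"no comparable columns between {alignment.ids[i]!r} "
                        f"and {alignment.ids[j]!r}"
                    )
            else:
                d = float((rows[i, usable] != rows[j, usable]).sum()) / total
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(list(alignment.ids), mat)


def nj_tree(dist: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbour-joining with deterministic tie-breaking."""
    n = len(dist.ids)
    if n < 2:
        raise ValueError("neighbour-joining requires at least 2 taxa")
    nodes = [_Node(label=name) for name in dist.ids]
    if n == 2:
        import warnings

        warnings.warn("only 2 taxa: returning the unique trivial tree", stacklevel=2)
        d = float(dist.matrix[0, 1])
        root = _Node(children=[(nodes[0], d / 2.0), (nodes[1], d / 2.0)],
                     sort_key=min(nodes[0].sort_key, nodes[1].sort_key))
        return PhyloTree(root=root, ids=list(dist.ids))

    d = dist.matrix.astype(float).copy()
    active = list(range(n))
    node_of = {i: nodes[i] for i in active}

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for i, j in itertools.combinations(active, 2):
            q = (m - 2) * d[i, j] - r[i] - r[j]
            a, b = node_of[i], node_of[j]
            pair_key = tuple(sorted((a.sort_key, b.sort_key)))
            key = (q, pair_key)
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        a, b = node_of[i], node_of[j]
        first, second = sorted(((a, li), (b, lj)), key=lambda item: item[0].sort_key)
        parent = _Node(children=[first, second], sort_key=first[0].sort_key)
        # distances from the new node u: d(u,k) = (d(i,k)+d(j,k)-d(i,j))/2
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        node_of[i] = parent
        active.remove(j)

    if len(active) == 3:
        i, j, k = active
        li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
        lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
        lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        children = sorted(
            ((node_of[i], max(li, 0.0)), (node_of[j], max(lj, 0.0)), (node_of[k], max(lk, 0.0))),
            key=lambda item: item[0].sort_key,
        )
        root = _Node(children=children, sort_key=children[0][0].sort_key)
    else:  # pragma: no cover - unreachable for n >= 3
        raise AssertionError("agglomeration must end with 3 nodes")
    return PhyloTree(root=root, ids=list(dist.ids))


def _resample(alignment: AnchoredAlignment, rng: np.random.Generator) -> AnchoredAlignment:
    width = alignment.width
    cols = rng.integers(0, width, size=width)
    rows = ["".join(row[c] for c in cols) for row in alignment.rows]
    blocks = [alignment.column_blocks[c] for c in cols] if alignment.column_blocks else []
    return AnchoredAlignment(ids=list(alignment.ids), rows=rows, column_blocks=blocks)


def bootstrap_support(
    alignment: AnchoredAlignment,
    n_replicates: int = 1000,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree from the full alignment, with per-edge bootstrap supports.

    Support of an internal split is the percentage of column-resampled
    replicates whose NJ tree contains the same bipartition.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if len(alignment.rows) < 4:
        raise ValueError("bootstrap support requires at least 4 rows")
    reference = nj_tree(p_distance(alignment))
    counts: dict[frozenset[str], int] = {split: 0 for split in reference.bipartitions()}
    for rep in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(rep,)))
        replicate = _resample(alignment, rng)
        tree = nj_tree(p_distance(replicate, on_empty="max"))
        for split in tree.bipartitions():
            if split in counts:
                counts[split] += 1

    all_leaves = frozenset(reference.leaf_labels())
    anchor = min(all_leaves)

    def annotate(node: _Node) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.label or ""])
        below = frozenset().union(*(annotate(child) for child, _ in node.children))
        if 1 < len(below) < len(all_leaves) - 1:
            side = all_leaves - below if anchor in below else below
            node.support = 100.0 * counts.get(side, 0) / n_replicates
        return below

    for child, _ in reference.root.children:
        annotate(child)
    return reference
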