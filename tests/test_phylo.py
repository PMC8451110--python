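"""Neighbour-joining correctness, p-distances and bootstrap support."""

import numpy as np
import pytest

from nsltpkit.classify import AnchoredAlignment
from nsltpkit.phylo import DistanceMatrix, bootstrap_support, nj_tree, p_distance


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """Random unrooted binary tree; returns (distance matrix, bipartitions).

    Built by sequential leaf attachment; path lengths computed on the
    explicit graph, independently of the NJ implementation under test.
    """
    labels = [f"T{i}" for i in range(n_leaves)]
    # graph: adjacency with branch lengths
    edges: dict[tuple[str, str], float] = {}
    nodes = [labels[0], labels[1]]
    next_internal = 0

    def add_edge(a, b, w):
        edges[(a, b)] = w
        edges[(b, a)] = w

    add_edge(labels[0], labels[1], float(rng.uniform(0.1, 1.0)))
    for leaf in labels[2:]:
        # split a random existing edge with a new internal node
        a, b = list(edges)[int(rng.integers(0, len(edges)))]
        w = edges[(a, b)]
        inner = f"I{next_internal}"
        next_internal += 1
        for key in ((a, b), (b, a)):
            del edges[key]
        cut = float(rng.uniform(0.25, 0.75)) * w
        add_edge(a, inner, cut)
        add_edge(inner, b, w - cut)
        add_edge(inner, leaf, float(rng.uniform(0.1, 1.0)))
        nodes.append(leaf)

    # all-pairs path lengths by BFS over the tree
    adjacency: dict[str, list[tuple[str, float]]] = {}
    for (a, b), w in edges.items():
        adjacency.setdefault(a, []).append((b, w))
    mat = np.zeros((n_leaves, n_leaves))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nbr, w in adjacency[cur]:
                if nbr not in dist:
                    dist[nbr] = dist[cur] + w
                    stack.append(nbr)
        for j, dst in enumerate(labels):
            mat[i, j] = dist[dst]

    # true bipartitions from internal edges
    splits = set()
    leafset = frozenset(labels)
    anchor = min(leafset)
    for (a, b) in {tuple(sorted(e)) for e in edges}:
        if a.startswith("I") and b.startswith("I"):
            # leaves on b's side of edge (a, b)
            seen = {a, b}
            stack = [b]
            side = set()
            while stack:
                cur = stack.pop()
                if not cur.startswith("I"):
                    side.add(cur)
                for nbr, _ in adjacency[cur]:
                    if nbr not in seen:
                        seen.add(nbr)
                        stack.append(nbr)
            if 1 < len(side) < n_leaves - 1:
                splits.add(frozenset(side) if anchor not in side else leafset - frozenset(side))
    return DistanceMatrix(labels, mat), splits


class TestPDistance:
    def _aln(self, rows, ids=None):
        ids = ids or [f"r{i}" for i in range(len(rows))]
        return AnchoredAlignment(ids=ids, rows=rows)

    def test_identical_rows(self):
        dm = p_distance(self._aln(["ACGTACGT", "ACGTACGT"]))
        assert dm.matrix[0, 1] == 0.0

    def test_two_of_twenty_mismatches(self):
        a = "A" * 20
        b = "A" * 18 + "CC"
        dm = p_distance(self._aln([a, b]))
        assert dm.matrix[0, 1] == pytest.approx(0.10)

    def test_pairwise_deletion_of_gapped_columns(self):
        dm = p_distance(self._aln(["AC-T", "A-GT"]))
        # only columns 1 and 4 are comparable; both match
        assert dm.matrix[0, 1] == 0.0

    def test_gap_only_overlap_raises_naming_the_pair(self):
        with pytest.raises(ValueError, match="r0.*r1"):
            p_distance(self._aln(["A--", "-AA"]))

    def test_gap_only_overlap_max_mode(self):
        dm = p_distance(self._aln(["A--", "-AA"]), on_empty="max")
        assert dm.matrix[0, 1] == 1.0


class TestNeighborJoining:
    def test_four_taxon_worked_example(self):
        d = np.array(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], dtype=float
        )
        tree = nj_tree(DistanceMatrix(list("ABCD"), d))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        paths = tree.path_lengths()
        idx = {name: i for i, name in enumerate(paths.ids)}
        # the matrix is additive for external branches 1 and internal branch 2
        assert paths.matrix[idx["A"], idx["B"]] == pytest.approx(2.0)
        assert paths.matrix[idx["A"], idx["C"]] == pytest.approx(4.0)
        assert paths.matrix[idx["C"], idx["D"]] == pytest.approx(2.0)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 5], [3, 0, 4], [5, 4, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], d))
        lengths = {child.label: w for child, w in tree.root.children}
        assert lengths["a"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["b"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["c"] == pytest.approx((5 + 4 - 3) / 2)

    def test_two_taxa_trivial_tree_with_warning(self):
        d = np.array([[0, 1.0], [1.0, 0]])
        with pytest.warns(UserWarning):
            tree = nj_tree(DistanceMatrix(["a", "b"], d))
        assert sorted(tree.leaf_labels()) == ["a", "b"]

    def test_recovers_random_additive_trees(self):
        rng = np.random.default_rng(29)
        for _ in range(30):
            n = int(rng.integers(4, 13))
            dm, splits = random_additive_tree(n, rng)
            tree = nj_tree(dm)
            assert tree.bipartitions() == splits
            paths = tree.path_lengths()
            order = [paths.ids.index(name) for name in dm.ids]
            assert np.allclose(paths.matrix[np.ix_(order, order)], dm.matrix, atol=1e-9)

    def test_newick_round_trips_through_dendropy(self):
        import dendropy

        rng = np.random.default_rng(31)
        dm, _ = random_additive_tree(8, rng)
        tree = nj_tree(dm)
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert sorted(leaf.taxon.label for leaf in parsed.leaf_node_iter()) == sorted(dm.ids)
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        for i, a in enumerate(dm.ids):
            for j in range(i + 1, len(dm.ids)):
                b = dm.ids[j]
                assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(
                    dm.matrix[i, j], abs=1e-6
                )


class TestBootstrap:
    @staticmethod
    def _two_clade_alignment():
        # identical within clades, saturated between: every resample keeps the split
        rows = ["AAAAAAAAAA"] * 3 + ["CCCCCCCCCC"] * 3
        return AnchoredAlignment(ids=[f"L{i}" for i in range(6)], rows=rows)

    def test_clean_split_gets_full_support(self):
        tree = bootstrap_support(self._two_clade_alignment(), n_replicates=100, seed=1)
        supports = []

        def walk(node):
            if node.support is not None:
                supports.append(node.support)
            for child, _ in node.children:
                walk(child)

        walk(tree.root)
        assert supports and all(s == 100.0 for s in supports)

    def test_deterministic_given_seed(self):
        aln = self._two_clade_alignment()
        t1 = bootstrap_support(aln, n_replicates=50, seed=7)
        t2 = bootstrap_support(aln, n_replicates=50, seed=7)
        assert t1.newick(with_support=True) == t2.newick(with_support=True)

    def test_supports_bounded(self):
        rng = np.random.default_rng(5)
        rows = ["".join("ACGT"[i] for i in rng.integers(0, 4, size=30)) for _ in range(6)]
        aln = AnchoredAlignment(ids=[f"L{i}" for i in range(6)], rows=rows)
        tree = bootstrap_support(aln, n_replicates=50, seed=3)

        def walk(node):
            if node.support is not None:
                assert 0.0 <= node.support <= 100.0
            for child, _ in node.children:
                walk(child)

        walk(tree.root)

    def test_rejects_bad_inputs(self):
        aln = self._two_clade_alignment()
        with pytest.raises(ValueError):
            bootstrap_support(aln, n_replicates=0, seed=1)
        small = AnchoredAlignment(ids=["a", "b"], rows=["AAA", "CCC"])
        with pytest.raises(ValueError):
            bootstrap_support(small, n_replicates=10, seed=1)

    def test_synthetic_type_clades_are_strongly_supported(self):
        from nsltpkit import synthetic_data as sd
        from nsltpkit.classify import build_anchored_alignment
        from nsltpkit.screen import run_screen

        cfg = sd.CohortConfig(
            plan=sd.compact_plan({"1": 3, "2": 3, "D": 3, "G": 3}),
            decoy_counts={"cys_deficient": 0, "nss_lacking": 0,
                          "proline_rich": 0, "storage_like": 0},
            seed=37,
        )
        proteins, manifest = sd.generate_proteins(cfg)
        candidates, _ = run_screen(proteins)
        accepted = [c for c in candidates if c.accepted]
        aln = build_anchored_alignment(
            [(c.protein.id, c.match, c.protein.sequence) for c in accepted]
        )
        tree = bootstrap_support(aln, n_replicates=200, seed=41)
        supports = {}

        def walk(node):
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset().union(*(walk(child) for child, _ in node.children))
            if node.support is not None:
                supports[below] = node.support
            return below

        for child, _ in tree.root.children:
            walk(child)
        full = frozenset(tree.leaf_labels())
        planted = {}
        for name, truth in manifest.proteins.items():
            planted.setdefault(truth.kind, set()).add(name)
        for type_label, members in planted.items():
            clade = frozenset(members)
            support = supports.get(clade, supports.get(full - clade))
            assert support is not None, f"type {type_label} members not monophyletic"
            assert support >= 95.0
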