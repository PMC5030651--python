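"""Tests of MST construction, layout and Pajek serialization.

Independent oracles: exhaustive spanning-tree enumeration via Prüfer
sequences (n^(n-2) trees at n <= 6), scipy's sparse-graph MST for weight
cross-checks, and networkx's Pajek reader for format interoperability.
"""

import io
import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import minimum_spanning_tree as scipy_mst

from phconnect.connectivity import DistanceMatrix, group_correlation, to_distance
from phconnect.filtration import single_linkage
from phconnect.mst import (
    SpanningTree,
    export_pajek,
    layout_positions,
    minimum_spanning_tree,
    read_pajek,
    tree_path_distances,
)
from phconnect.synthetic_cohort import (
    CONTROL,
    LESION,
    RegionScheme,
    SimulationConfig,
    simulate_cohort,
)
from tests.conftest import random_distance_matrix


def _prufer_tree_edges(seq, n):
    """Decode a Prüfer sequence into the edge list of a labeled tree."""
    degree = [1] * n
    for k in seq:
        degree[k] += 1
    edges = []
    seq = list(seq)
    leaves = sorted(i for i in range(n) if degree[i] == 1)
    for k in seq:
        leaf = leaves.pop(0)
        edges.append((leaf, k))
        degree[k] -= 1
        if degree[k] == 1:
            import bisect

            bisect.insort(leaves, k)
    edges.append((leaves[0], leaves[1]))
    return edges


def _exhaustive_min_weight(d: np.ndarray) -> float:
    n = d.shape[0]
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        w = sum(d[i, j] for i, j in _prufer_tree_edges(seq, n))
        best = min(best, w)
    return best


class TestMinimumSpanningTree:
    def test_three_region_chain(self, chain_dm):
        tree = minimum_spanning_tree(chain_dm)
        assert set((a, b) for a, b, _ in tree.edges) == {("A", "B"), ("B", "C")}
        assert tree.total_weight == pytest.approx(0.3)

    def test_two_regions_single_edge(self):
        d = np.array([[0.0, 0.7], [0.7, 0.0]])
        dm = DistanceMatrix(region_labels=("A", "B"), d=d, metric_tag="one_minus_r")
        tree = minimum_spanning_tree(dm)
        assert tree.edges == (("A", "B", 0.7),)

    def test_weight_matches_exhaustive_prufer_oracle(self, rng):
        for n in (4, 5, 6):
            for _ in range(8):
                dm = random_distance_matrix(rng, n)
                tree = minimum_spanning_tree(dm)
                assert tree.total_weight == pytest.approx(_exhaustive_min_weight(dm.d))

    def test_weight_matches_scipy_on_larger_matrices(self, rng):
        for _ in range(20):
            dm = random_distance_matrix(rng, 12)
            tree = minimum_spanning_tree(dm)
            assert tree.total_weight == pytest.approx(scipy_mst(dm.d).sum())

    def test_edge_weights_equal_merge_heights(self, rng):
        dm = random_distance_matrix(rng, 10)
        tree = minimum_spanning_tree(dm)
        heights = single_linkage(dm).merge_heights
        assert sorted(w for _, _, w in tree.edges) == pytest.approx(sorted(heights))

    def test_slm_and_distance_msts_have_equal_weight(self, rng):
        for _ in range(20):
            dm = random_distance_matrix(rng, 9)
            sl = single_linkage(dm)
            t_d = minimum_spanning_tree(dm)
            t_s = minimum_spanning_tree(sl)
            assert t_s.source == "slm" and t_d.source == "distance"
            assert t_d.total_weight == pytest.approx(t_s.total_weight)

    def test_non_finite_entries_rejected(self):
        d = np.array([[0.0, np.inf], [np.inf, 0.0]])
        dm = DistanceMatrix(region_labels=("A", "B"), d=d, metric_tag="one_minus_r")
        with pytest.raises(ValueError, match="non-finite"):
            minimum_spanning_tree(dm)

    def test_determinism_under_ties(self):
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(region_labels=("D", "B", "A", "C"), d=d, metric_tag="one_minus_r")
        tree = minimum_spanning_tree(dm)
        assert [tuple(sorted((a, b))) for a, b, _ in tree.edges] == [
            ("A", "B"), ("A", "C"), ("A", "D"),
        ]


def _block_subtree_connected(tree: SpanningTree, block: set[str]) -> bool:
    g = nx.Graph((a, b) for a, b, _ in tree.edges)
    return nx.is_connected(g.subgraph(block))


class TestModularity:
    def test_strong_block_forms_connected_subtree_in_control(self):
        """With a tight basal-ganglia block, its regions cluster into one
        subtree of the control MST; disrupting the block in the lesion group
        lowers that rate (the 'not modularized' observation, as a literal
        subtree statistic)."""
        scheme = RegionScheme.default()
        block = set(scheme.module_members("basal_ganglia"))
        disruption = tuple(
            (a, b, 0.3)
            for a, b in itertools.combinations(sorted(block), 2)
        )
        hits_control = hits_lesion = 0
        n_sim = 100
        for k in range(n_sim):
            config = SimulationConfig(
                base_corr=0.9, cross_corr=0.3, seed=1000 + k,
                disrupted_pairs=disruption,
            )
            table = simulate_cohort(config)
            # built from the raw distance matrix: the ultrametric SLM is full
            # of exactly tied weights, so its MST edge set is an arbitrary
            # (if deterministic) choice among many minima
            for group in (CONTROL, LESION):
                dist = to_distance(group_correlation(table, group))
                tree = minimum_spanning_tree(dist)
                ok = _block_subtree_connected(tree, block)
                if group == CONTROL:
                    hits_control += ok
                else:
                    hits_lesion += ok
        assert hits_control >= 95
        assert hits_lesion < hits_control


class TestLayout:
    def test_two_node_tree_embeds_exactly(self):
        tree = SpanningTree(region_labels=("A", "B"), edges=(("A", "B", 0.4),))
        pos = layout_positions(tree, seed=0)
        d = np.hypot(*(np.array(pos["A"]) - np.array(pos["B"])))
        assert d == pytest.approx(0.4, abs=1e-4)

    def test_same_seed_identical_coordinates(self):
        tree = SpanningTree(
            region_labels=("A", "B", "C", "D"),
            edges=(("A", "B", 0.2), ("B", "C", 0.3), ("C", "D", 0.1)),
        )
        assert layout_positions(tree, seed=3) == layout_positions(tree, seed=3)

    def test_star_tree_symmetric_radii(self):
        leaves = tuple(f"L{k}" for k in range(5))
        tree = SpanningTree(
            region_labels=("HUB",) + leaves,
            edges=tuple(("HUB", leaf, 0.5) for leaf in leaves),
        )
        pos = layout_positions(tree, seed=1)
        hub = np.array(pos["HUB"])
        radii = [np.hypot(*(np.array(pos[l]) - hub)) for l in leaves]
        assert max(radii) - min(radii) < 1e-3

    def test_stress_non_increasing(self):
        tree = SpanningTree(
            region_labels=("A", "B", "C", "D", "E"),
            edges=(("A", "B", 0.2), ("B", "C", 0.5), ("C", "D", 0.1), ("B", "E", 0.3)),
        )
        delta = tree_path_distances(tree)
        iu = np.triu_indices(5, k=1)

        def stress_of(pos):
            x = np.array([pos[l] for l in tree.region_labels])
            diff = x[:, None, :] - x[None, :, :]
            dcur = np.sqrt((diff**2).sum(-1))
            return ((delta[iu] - dcur[iu]) ** 2).sum()

        stresses = [
            stress_of(layout_positions(tree, seed=2, max_iter=it)) for it in (1, 3, 10, 100, 1000)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(stresses, stresses[1:]))


class TestPajek:
    def test_two_node_file_shape(self):
        tree = SpanningTree(region_labels=("A", "B"), edges=(("A", "B", 0.7),))
        lines = [l for l in export_pajek(tree).splitlines() if not l.startswith("%")]
        assert lines[0] == "*Vertices 2"
        assert lines[1:3] == ['1 "A"', '2 "B"']
        assert lines[3] == "*Edges"
        assert lines[4].split() == ["1", "2", "0.7"]

    def test_twenty_regions_give_19_edge_lines(self, default_table):
        dist = to_distance(group_correlation(default_table, "control"))
        tree = minimum_spanning_tree(dist)
        text = export_pajek(tree)
        edge_lines = text.split("*Edges\n", 1)[1].strip().splitlines()
        assert len(edge_lines) == 19

    def test_roundtrip_identical_edges(self, rng):
        dm = random_distance_matrix(rng, 8)
        tree = minimum_spanning_tree(dm)
        back = read_pajek(export_pajek(tree))
        assert back.region_labels == tree.region_labels
        assert back.edges == tree.edges
        assert back.source == tree.source

    def test_crlf_and_case_tolerated(self):
        tree = SpanningTree(region_labels=("A", "B"), edges=(("A", "B", 0.7),))
        text = export_pajek(tree).replace("\n", "\r\n").replace("*Vertices", "*vertices")
        back = read_pajek(text)
        assert back.edges == tree.edges

    def test_networkx_can_read_our_dialect(self, rng, tmp_path):
        dm = random_distance_matrix(rng, 6)
        tree = minimum_spanning_tree(dm)
        path = tmp_path / "tree.net"
        export_pajek(tree, path)
        g = nx.read_pajek(str(path))
        assert {tuple(sorted((a, b))) for a, b in g.edges()} == {
            tuple(sorted((a, b))) for a, b, _ in tree.edges
        }

    def test_quoted_label_rejected(self):
        with pytest.raises(ValueError, match="double quote"):
            export_pajek(
                SpanningTree(region_labels=('A"x', "B"), edges=(('A"x', "B", 0.1),))
            )
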