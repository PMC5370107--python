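"""Threshold filtering, components, merge hierarchy."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from infonet import (
    AdjacencyMatrix,
    ThresholdGrid,
    components_by_matrix_power,
    connected_components,
    connectivity_profile,
    filter_adjacency,
    merge_multiplicity,
    sweep,
)
from conftest import random_normalized_adjacency


def adjacency(values, normalized=True):
    values = np.asarray(values, dtype=float)
    return AdjacencyMatrix(
        values=values, ids=[f"n{i}" for i in range(len(values))],
        normalized=normalized,
    )


def grid_scan_merge_multiplicity(a, i, j, grid):
    """Independent oracle: exhaustive component computation at every c."""
    for c in grid:
        part = connected_components(filter_adjacency(a, float(c)))
        if part.block_of(i) == part.block_of(j):
            return float(c)
    return None


class TestThresholdGrid:
    def test_default_grid_is_descending_two_decimal(self):
        grid = ThresholdGrid.default()
        assert len(grid) == 91
        assert grid.values[0] == 1.0 and grid.values[-1] == 0.1
        assert np.all(np.diff(grid.values) < 0)

    def test_floor(self):
        grid = ThresholdGrid.default()
        assert grid.floor(0.337) == 0.33
        assert grid.floor(1.0) == 1.0
        assert grid.floor(0.05) is None


class TestFilterAdjacency:
    def test_c_one_keeps_only_maximal_entries(self):
        a = adjacency([[0, 0.9, 0.2], [0.9, 0, 0.5], [0.2, 0.5, 0]])
        filtered = filter_adjacency(a, 1.0)
        assert filtered.values[0, 1] == 0.9
        assert filtered.values[1, 2] == 0.0
        assert filtered.values[0, 2] == 0.0

    def test_hand_checked_threshold(self):
        a = adjacency([[0, 0.9, 0.2], [0.9, 0, 0.5], [0.2, 0.5, 0]])
        filtered = filter_adjacency(a, 0.5)  # T_c = 0.45
        assert filtered.values[0, 2] == 0.0
        assert filtered.values[1, 2] == 0.5
        assert filtered.values[0, 1] == 0.9
        assert np.array_equal(filtered.values, filtered.values.T)

    def test_idempotent(self, rng):
        a = random_normalized_adjacency(rng, 6)
        once = filter_adjacency(a, 0.6)
        twice = filter_adjacency(once, 0.6)
        assert np.array_equal(once.values, twice.values)

    def test_all_zero_matrix_rejected(self):
        a = adjacency(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="no edges"):
            filter_adjacency(a, 0.5)


class TestConnectedComponents:
    def test_no_edges_gives_singletons(self):
        part = connected_components(adjacency(np.zeros((4, 4))))
        assert part.blocks == [(0,), (1,), (2,), (3,)]

    def test_complete_graph_gives_one_block(self):
        values = np.ones((5, 5)) - np.eye(5)
        part = connected_components(adjacency(values))
        assert part.blocks == [tuple(range(5))]

    def test_path_plus_isolated_node(self):
        values = np.zeros((4, 4))
        values[0, 1] = values[1, 0] = 0.5
        values[1, 2] = values[2, 1] = 0.4
        part = connected_components(adjacency(values))
        assert part.blocks == [(0, 1, 2), (3,)]
        assert components_by_matrix_power(adjacency(values)).blocks == part.blocks


class TestComponentsByMatrixPower:
    def test_path_graph_sum_positive_everywhere(self):
        values = np.zeros((3, 3))
        values[0, 1] = values[1, 0] = 0.5
        values[1, 2] = values[2, 1] = 0.4
        # explicit two-step expansion: A + A^2 is positive off the path ends
        a_sum = values + values @ values
        assert np.all(a_sum[np.ix_([0, 1, 2], [0, 1, 2])] + np.eye(3) > 0)
        part = components_by_matrix_power(adjacency(values))
        assert part.blocks == [(0, 1, 2)]

    def test_two_disjoint_edges_block_diagonal(self):
        values = np.zeros((4, 4))
        values[0, 1] = values[1, 0] = 0.8
        values[2, 3] = values[3, 2] = 0.6
        part = components_by_matrix_power(adjacency(values))
        assert part.blocks == [(0, 1), (2, 3)]

    def test_zero_edge_pair_gives_singletons(self):
        part = components_by_matrix_power(adjacency(np.zeros((2, 2))))
        assert part.blocks == [(0,), (1,)]

    def test_agrees_with_union_find_on_random_graphs(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 13))
            a = random_normalized_adjacency(rng, n, edge_prob=rng.uniform(0.1, 0.9))
            assert (
                components_by_matrix_power(a).blocks
                == connected_components(a).blocks
            )


class TestConnectivityProfile:
    def test_zero_across_components(self):
        values = np.zeros((4, 4))
        values[0, 1] = values[1, 0] = 0.9
        values[2, 3] = values[3, 2] = 0.8
        a = adjacency(values)
        profile = connectivity_profile(a, 0, 2, ThresholdGrid.default())
        assert all(v == 0.0 for _, v in profile)

    def test_two_node_network_returns_edge_weight(self):
        a = adjacency([[0, 0.7], [0.7, 0]])
        profile = connectivity_profile(a, 0, 1, ThresholdGrid(values=np.array([1.0])))
        assert profile == [(1.0, pytest.approx(0.7))]

    def test_three_node_path_matches_power_expansion(self):
        w1, w2 = 0.8, 0.6
        values = np.zeros((3, 3))
        values[0, 1] = values[1, 0] = w1
        values[1, 2] = values[2, 1] = w2
        a = adjacency(values)
        c = 0.5  # T_c = 0.4 keeps both edges
        f = filter_adjacency(a, c).values
        powers = [f, f @ f]
        expected = sum(
            powers[n - 1][0, 2] ** (1.0 / n) for n in (1, 2)
            if powers[n - 1][0, 2] > 0
        ) / 2.0
        (entry,) = [v for g, v in connectivity_profile(a, 0, 2, ThresholdGrid(values=np.array([c]))) if g == c]
        assert entry == pytest.approx(expected, abs=1e-9)

    def test_positive_iff_merge_multiplicity_at_least_c(self, rng):
        grid = ThresholdGrid.default(step=0.05)
        for _ in range(5):
            a = random_normalized_adjacency(rng, 6, edge_prob=0.4)
            if a.max_offdiag() == 0.0:
                continue
            for i, j in [(0, 3), (1, 4)]:
                mm = merge_multiplicity(a, i, j, grid)
                for c, value in connectivity_profile(a, i, j, grid):
                    assert (value > 0) == (mm is not None and mm >= c - 1e-9)

    def test_same_node_rejected(self):
        a = adjacency([[0, 0.5], [0.5, 0]])
        with pytest.raises(ValueError):
            connectivity_profile(a, 1, 1, ThresholdGrid.default())


class TestSweep:
    def test_two_nodes_merge_at_c_one(self):
        a = adjacency([[0, 0.4], [0.4, 0]])
        tree = sweep(a)
        assert len(tree.roots) == 1
        assert tree.roots[0].c == 1.0

    def test_hand_checked_merge_multiplicities(self):
        a = adjacency([[0, 0.9, 0.3], [0.9, 0, 0.3], [0.3, 0.3, 0]])
        tree = sweep(a)
        merges = tree.merges()
        # {0,1} at c=1.0; node 2 joins at largest grid c with 0.9c <= 0.3
        assert merges[0] == (1.0, (0, 1))
        assert merges[1] == (0.33, (0, 1, 2))

    def test_partitions_nest_down_the_grid(self, rng):
        grid = ThresholdGrid.default()
        for _ in range(5):
            a = random_normalized_adjacency(rng, 8)
            parts = [
                connected_components(filter_adjacency(a, float(c))) for c in grid
            ]
            for higher, lower in zip(parts[:-1], parts[1:]):
                lower_blocks = [set(b) for b in lower.blocks]
                for block in higher.blocks:
                    assert sum(set(block) <= lb for lb in lower_blocks) == 1

    def test_cut_reproduces_direct_partitions(self, rng):
        grid = ThresholdGrid.default()
        a = random_normalized_adjacency(rng, 9)
        tree = sweep(a, grid)
        for c in grid.values[::7]:
            direct = connected_components(filter_adjacency(a, float(c)))
            assert tree.cut(float(c)).blocks == direct.blocks

    def test_newick_and_json_exports(self, tmp_path):
        a = adjacency([[0, 0.9, 0.3], [0.9, 0, 0.3], [0.3, 0.3, 0]])
        tree = sweep(a)
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        assert "n2" in nwk and "0.33" in nwk
        out = tmp_path / "tree.json"
        tree.to_json(out)
        import json

        data = json.loads(out.read_text())
        assert data["roots"][0]["c"] == 0.33
        assert sorted(data["roots"][0]["members"]) == ["n0", "n1", "n2"]


class TestMergeMultiplicity:
    def test_maximal_edge_pair_merges_at_one(self):
        a = adjacency([[0, 0.9, 0.3], [0.9, 0, 0.3], [0.3, 0.3, 0]])
        assert merge_multiplicity(a, 0, 1) == 1.0

    def test_disconnected_pair_returns_none(self):
        values = np.zeros((3, 3))
        values[0, 1] = values[1, 0] = 0.9
        assert merge_multiplicity(adjacency(values), 0, 2) is None

    def test_matches_exhaustive_grid_scan(self, rng):
        grid = ThresholdGrid.default()
        for _ in range(10):
            a = random_normalized_adjacency(rng, 6, edge_prob=0.5)
            if a.max_offdiag() == 0.0:
                continue
            for i in range(6):
                for j in range(i + 1, 6):
                    assert merge_multiplicity(a, i, j, grid) == grid_scan_merge_multiplicity(a, i, j, grid)


class TestSingleLinkageEquivalence:
    def test_matches_scipy_single_linkage_partitions(self, rng):
        """Cutting the merge tree at any grid c equals single-linkage flat
        clusters on dissimilarity A_max - a at height A_max(1 - c)."""
        grid = ThresholdGrid.default()
        for _ in range(10):
            n = int(rng.integers(4, 12))
            a = random_normalized_adjacency(rng, n, edge_prob=1.0)
            amax = a.max_offdiag()
            d = amax - a.values
            np.fill_diagonal(d, 0.0)
            link = linkage(squareform(d, checks=False), method="single")
            tree = sweep(a, grid)
            for c in grid.values[::9]:
                labels_scipy = fcluster(link, t=amax * (1.0 - c) + 1e-12,
                                        criterion="distance")
                mine = tree.cut(float(c)).labels()
                # same partition up to label names
                pairs_equal = (
                    (labels_scipy[:, None] == labels_scipy[None, :])
                    == (mine[:, None] == mine[None, :])
                )
                assert pairs_equal.all()
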