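"""Layouts, Voronoi adjacency, thresholding and vertex ordering."""

import numpy as np
import pytest

import eegfu
from eegfu.model import (
    CoherenceNetwork,
    ElectrodeLayout,
    is_voronoi_connected,
    local_average_coherence,
    significance_threshold,
    significant_graph,
    voronoi_adjacency,
)


def bisector_sample_adjacency(layout: ElectrodeLayout) -> set[frozenset]:
    """Independent Voronoi-neighbor oracle: a pair shares a positive-length
    cell boundary iff some point on their bisector is strictly nearer to
    the pair than to every other site."""
    pos = layout.positions
    n = len(pos)
    span = float(np.ptp(pos, axis=0).max()) or 1.0
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            d = pos[j] - pos[i]
            d = d / np.linalg.norm(d)
            perp = np.array([-d[1], d[0]])
            mid = (pos[i] + pos[j]) / 2.0
            for t in np.linspace(-6.0 * span, 6.0 * span, 3001):
                x = mid + t * perp
                di = np.linalg.norm(x - pos[i])
                others = [
                    np.linalg.norm(x - pos[k]) for k in range(n) if k not in (i, j)
                ]
                if not others or min(others) > di + 1e-9 * span:
                    out.add(frozenset((layout.labels[i], layout.labels[j])))
                    break
    return out


class TestLayoutValidation:
    def test_duplicate_positions_name_colliding_labels(self):
        with pytest.raises(ValueError, match="C3.*C4|C4.*C3"):
            ElectrodeLayout(("C3", "C4"), np.array([[0.0, 0.0], [0.0, 0.0]]))

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ElectrodeLayout(("a", "a"), np.array([[0.0, 0.0], [1.0, 0.0]]))

    def test_label_position_count_mismatch(self):
        with pytest.raises(ValueError):
            ElectrodeLayout(("a",), np.array([[0.0, 0.0], [1.0, 0.0]]))


class TestVoronoiAdjacency:
    def test_grid_is_four_connectivity(self, table1):
        _, adj = table1
        assert adj.neighbors("f") == ("b", "e", "g", "j")
        assert adj.neighbors("a") == ("b", "e")
        assert adj.neighbors("g") == ("c", "f", "h", "k")
        # no diagonals anywhere
        assert not adj.are_neighbors("a", "f")
        assert not adj.are_neighbors("g", "j")

    def test_two_electrodes_always_adjacent(self):
        layout = ElectrodeLayout(("x", "y"), np.array([[0.0, 0.0], [3.0, 1.0]]))
        adj = voronoi_adjacency(layout)
        assert adj.are_neighbors("x", "y")

    def test_collinear_layout_is_a_chain(self):
        layout = ElectrodeLayout(
            ("a", "b", "c", "d"),
            np.array([[0.0, 0.0], [3.0, 0.0], [1.0, 0.0], [2.0, 0.0]]),
        )
        adj = voronoi_adjacency(layout)
        assert adj.neighbors("a") == ("c",)
        assert adj.neighbors("c") == ("a", "d")
        assert adj.neighbors("d") == ("b", "c")
        assert adj.neighbors("b") == ("d",)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bisector_sampling_oracle(self, seed):
        rng = np.random.default_rng(seed)
        layout = ElectrodeLayout(
            tuple(f"e{i}" for i in range(10)), rng.uniform(0, 10, (10, 2))
        )
        adj = voronoi_adjacency(layout)
        assert set(adj.pairs) == bisector_sample_adjacency(layout)

    @pytest.mark.parametrize("seed", range(100))
    def test_symmetric_irreflexive_random_layouts(self, seed):
        rng = np.random.default_rng(10_000 + seed)
        n = int(rng.integers(2, 12))
        layout = ElectrodeLayout(
            tuple(f"e{i}" for i in range(n)), rng.uniform(0, 5, (n, 2))
        )
        adj = voronoi_adjacency(layout)
        for pair in adj.pairs:
            assert len(pair) == 2  # irreflexive
            u, v = tuple(pair)
            assert adj.are_neighbors(u, v) and adj.are_neighbors(v, u)
        assert len(adj.pairs) >= 1


class TestVoronoiConnected:
    def test_connected_set_on_grid(self, grid_adjacency):
        assert is_voronoi_connected({"a", "b", "e", "f", "i", "j"}, grid_adjacency)

    def test_empty_and_singleton_are_connected(self, grid_adjacency):
        assert is_voronoi_connected(set(), grid_adjacency)
        assert is_voronoi_connected({"c"}, grid_adjacency)

    def test_disconnected_set(self, grid_adjacency):
        assert not is_voronoi_connected({"a", "d"}, grid_adjacency)

    def test_unknown_label_raises(self, grid_adjacency):
        with pytest.raises(KeyError):
            is_voronoi_connected({"nope"}, grid_adjacency)


class TestSignificanceThreshold:
    def test_reference_values(self):
        assert significance_threshold(0.01, 13) == pytest.approx(
            1.0 - 0.01 ** (1.0 / 12.0), abs=1e-12
        )
        assert significance_threshold(0.01, 13) == pytest.approx(0.31871, abs=5e-6)
        assert significance_threshold(0.05, 2) == pytest.approx(0.95)

    def test_limit_p_to_one_gives_zero(self):
        assert significance_threshold(1 - 1e-12, 13) < 1e-12

    @pytest.mark.parametrize("bad_L", [1, 0, -3])
    def test_undefined_below_two_segments(self, bad_L):
        with pytest.raises(ValueError):
            significance_threshold(0.01, bad_L)

    @pytest.mark.parametrize("bad_p", [0.0, 1.0, -0.1, 2.0])
    def test_invalid_probability(self, bad_p):
        with pytest.raises(ValueError):
            significance_threshold(bad_p, 13)


class TestSignificantGraph:
    def test_table1_pattern_matches_adjacency_matrix(self, table1):
        network, _ = table1
        G = significant_graph(network)
        assert G.number_of_edges() == 27
        # isolated vertices keep their nodes
        assert set(G.nodes) == set(network.layout.labels)
        assert G.degree("c") == 0 and G.degree("k") == 0
        # closed inequality: values exactly at theta are edges
        assert G.has_edge("a", "g") and G["a"]["g"]["weight"] == 0.20

    def test_high_threshold_edge_set(self, table1):
        network, _ = table1
        strong = CoherenceNetwork(network.layout, network.coherence, 0.7)
        G = significant_graph(strong)
        expected = {
            frozenset(p)
            for p in [("d", "h"), ("d", "l"), ("f", "g"), ("g", "l"), ("h", "l"), ("d", "g")]
        }
        assert {frozenset(e) for e in G.edges} == expected

    def test_threshold_above_max_empties_graph(self, table1):
        network, _ = table1
        G = significant_graph(
            CoherenceNetwork(network.layout, network.coherence, 0.73)
        )
        assert G.number_of_edges() == 0

    def test_edge_count_monotone_in_theta(self, table1):
        network, _ = table1
        counts = [
            significant_graph(
                CoherenceNetwork(network.layout, network.coherence, t)
            ).number_of_edges()
            for t in np.linspace(0.0, 1.0, 21)
        ]
        assert counts == sorted(counts, reverse=True)
        # theta = 0: every strictly positive coherence becomes an edge
        assert counts[0] == 12 * 11 // 2


class TestLocalAverageCoherence:
    def test_table1_descending_order(self, table1):
        network, adj = table1
        _, order = local_average_coherence(network, adj)
        assert order == list("hafebldgijck")

    def test_value_of_h(self, table1):
        network, adj = table1
        values, _ = local_average_coherence(network, adj)
        assert values["h"] == pytest.approx((0.71 + 0.69 + 0.72) / 3)

    def test_uniform_matrix_gives_constant_values(self, grid_layout_3x4, grid_adjacency):
        n = len(grid_layout_3x4)
        # 0.5 is exactly representable, so every mean ties exactly
        mat = np.full((n, n), 0.5)
        np.fill_diagonal(mat, 0.0)
        network = CoherenceNetwork(grid_layout_3x4, mat, 0.2)
        values, order = local_average_coherence(network, grid_adjacency)
        assert all(v == pytest.approx(0.5) for v in values.values())
        # ties resolved by ascending label order
        assert order == sorted(network.layout.labels)

    def test_subthreshold_coherences_are_included(self, table1):
        # b averages over a, c, f: the 0.10 coherence to c must count,
        # otherwise b would outrank f in the descending order
        network, adj = table1
        values, _ = local_average_coherence(network, adj)
        assert values["b"] == pytest.approx((0.65 + 0.10 + 0.63) / 3)
        assert values["f"] > values["b"]


class TestNetworkValidation:
    def test_asymmetric_matrix_rejected(self, grid_layout_3x4):
        n = len(grid_layout_3x4)
        mat = np.zeros((n, n))
        mat[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            CoherenceNetwork(grid_layout_3x4, mat, 0.2)

    def test_nonzero_diagonal_rejected(self, grid_layout_3x4):
        n = len(grid_layout_3x4)
        mat = np.eye(n) * 0.5
        with pytest.raises(ValueError, match="diagonal"):
            CoherenceNetwork(grid_layout_3x4, mat, 0.2)

    def test_out_of_range_values_rejected(self, grid_layout_3x4):
        n = len(grid_layout_3x4)
        mat = np.zeros((n, n))
        mat[0, 1] = mat[1, 0] = 1.5
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            CoherenceNetwork(grid_layout_3x4, mat, 0.2)
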