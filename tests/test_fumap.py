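"""FU summaries, map construction, and rendering."""

import itertools
import json

import numpy as np
import pytest

import eegfu
from eegfu.fumap import (
    average_coherence,
    build_fu_map,
    inter_fu_coherence,
    render_fu_map,
    summarize_fus,
)
from eegfu.model import Partition


@pytest.fixture(scope="module")
def ccb_partition(table1):
    network, adj = table1
    return eegfu.detect_community_cliques(network, adj)


class TestAverageCoherence:
    def test_dhl_average(self, table1):
        network, _ = table1
        assert average_coherence({"d", "h", "l"}, network) == pytest.approx(0.71)

    def test_pair_average_is_the_single_value(self, table1):
        network, _ = table1
        assert average_coherence({"h", "l"}, network) == pytest.approx(0.72)

    def test_uniform_fu(self, grid_layout_3x4):
        n = len(grid_layout_3x4)
        mat = np.full((n, n), 0.42)
        np.fill_diagonal(mat, 0.0)
        net = eegfu.CoherenceNetwork(grid_layout_3x4, mat, 0.2)
        assert average_coherence({"a", "b", "f", "e"}, net) == pytest.approx(0.42)

    def test_small_fu_returns_absent_marker(self, table1):
        network, _ = table1
        assert average_coherence({"c"}, network) is None
        assert average_coherence(set(), network) is None


class TestInterFUCoherence:
    def test_singleton_pair(self, table1):
        network, _ = table1
        assert inter_fu_coherence({"c"}, {"k"}, network) == pytest.approx(0.10)

    def test_ccb_fus_value(self, table1):
        network, _ = table1
        c = inter_fu_coherence(set("abefij"), set("gdhl"), network)
        assert c == pytest.approx(3.51 / 24)

    @pytest.mark.parametrize("seed", range(10))
    def test_symmetry_and_double_loop_oracle(self, seed, table1):
        network, _ = table1
        rng = np.random.default_rng(seed)
        labels = list(network.layout.labels)
        rng.shuffle(labels)
        k = int(rng.integers(1, 6))
        C1, C2 = set(labels[:k]), set(labels[k : k + int(rng.integers(1, 6))])
        naive = np.mean(
            [network.value(u, v) for u in sorted(C1) for v in sorted(C2)]
        )
        assert inter_fu_coherence(C1, C2, network) == pytest.approx(naive)
        assert inter_fu_coherence(C1, C2, network) == pytest.approx(
            inter_fu_coherence(C2, C1, network)
        )

    def test_overlap_rejected(self, table1):
        network, _ = table1
        with pytest.raises(ValueError, match="overlap"):
            inter_fu_coherence({"a", "b"}, {"b", "c"}, network)


class TestSummary:
    def test_barycenter_is_member_mean(self, table1, ccb_partition):
        network, _ = table1
        summary = summarize_fus(ccb_partition, network)
        i = ccb_partition.communities.index(tuple("abefij"))
        expected = np.mean(
            [network.layout.position_of(v) for v in "abefij"], axis=0
        )
        assert summary.barycenters[i] == pytest.approx(tuple(expected))

    def test_total_strength_reported(self, table1, ccb_partition):
        network, _ = table1
        summary = summarize_fus(ccb_partition, network)
        i = ccb_partition.communities.index(tuple("dghl"))
        assert summary.total_strength[i] == pytest.approx(4.22)


class TestBuildFUMap:
    def test_table1_ccb_two_displayed_no_line_at_theta(
        self, table1, ccb_partition
    ):
        network, _ = table1
        spec = build_fu_map(ccb_partition, network, display_min_size=2)
        assert len(spec.displayed) == 2
        # inter-FU coherence 0.14625 < theta 0.2: no line
        assert spec.lines == ()

    def test_line_appears_below_its_value(self, table1, ccb_partition):
        network, _ = table1
        spec = build_fu_map(
            ccb_partition, network, display_min_size=2, line_threshold=0.1
        )
        assert len(spec.lines) == 1
        assert spec.lines[0][6] == pytest.approx(0.14625)

    def test_strict_line_threshold_at_exact_value(self, table1, ccb_partition):
        network, _ = table1
        closed = build_fu_map(
            ccb_partition, network, display_min_size=2,
            line_threshold=0.14625,
        )
        strict = build_fu_map(
            ccb_partition, network, display_min_size=2,
            line_threshold=0.14625, strict_lines=True,
        )
        assert len(closed.lines) == 1 and strict.lines == ()

    def test_all_singletons_all_white(self, table1):
        network, _ = table1
        part = Partition(tuple((v,) for v in network.layout.labels))
        spec = build_fu_map(part, network)
        assert all(g is None for g in spec.cell_gray)
        assert spec.circles == () and spec.lines == ()

    def test_min_size_above_largest_fu_all_white(self, table1, ccb_partition):
        network, _ = table1
        spec = build_fu_map(ccb_partition, network, display_min_size=7)
        assert all(g is None for g in spec.cell_gray)

    @pytest.mark.parametrize("seed", range(50))
    def test_adjacent_displayed_fus_never_share_gray(self, seed, table1):
        network, adj = table1
        rng = np.random.default_rng(seed)
        assignment = {
            v: int(rng.integers(0, 4)) for v in network.layout.labels
        }
        part = Partition.from_labels(assignment)
        spec = build_fu_map(part, network, display_min_size=1, adjacency=adj)
        gray_of_fu = {}
        for v, g in zip(spec.labels, spec.cell_gray):
            gray_of_fu[part.label_of(v)] = g
        for i, j in itertools.combinations(range(1, len(part.communities) + 1), 2):
            members_i, members_j = part.communities[i - 1], part.communities[j - 1]
            touching = any(
                adj.are_neighbors(u, v) for u in members_i for v in members_j
            )
            if touching and gray_of_fu[i] is not None and gray_of_fu[j] is not None:
                assert gray_of_fu[i] != gray_of_fu[j]


class TestRender:
    def test_svg_has_one_polygon_per_electrode(self, table1, ccb_partition, tmp_path):
        network, _ = table1
        spec = build_fu_map(ccb_partition, network, display_min_size=2)
        out = tmp_path / "map.svg"
        render_fu_map(spec, out)
        assert out.read_text().count("<polygon") == 12

    def test_svg_byte_stable(self, table1, ccb_partition, tmp_path):
        network, _ = table1
        spec = build_fu_map(ccb_partition, network, display_min_size=2)
        a, b = tmp_path / "a.svg", tmp_path / "b.svg"
        render_fu_map(spec, a)
        render_fu_map(
            build_fu_map(ccb_partition, network, display_min_size=2), b
        )
        assert a.read_bytes() == b.read_bytes()

    def test_montage_smoke(self, tmp_path):
        layout = eegfu.montage_10_20()
        n = len(layout)
        rng = np.random.default_rng(0)
        mat = rng.uniform(0.0, 0.6, (n, n))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0.0)
        net = eegfu.CoherenceNetwork(layout, mat, 0.3)
        part = Partition(
            (
                ("Fp1", "Fp2", "Fz", "F3", "F4"),
                ("O1", "O2", "Pz", "P3", "P4"),
                ("Cz", "C3", "C4"),
            )
        )
        spec = build_fu_map(part, net, display_min_size=3, clip="circle")
        render_fu_map(spec, tmp_path / "montage.svg")
        render_fu_map(spec, tmp_path / "montage.png")
        assert (tmp_path / "montage.svg").stat().st_size > 0
        assert (tmp_path / "montage.png").stat().st_size > 0

    def test_png_render(self, table1, ccb_partition, tmp_path):
        network, _ = table1
        spec = build_fu_map(ccb_partition, network, display_min_size=2)
        out = tmp_path / "map.png"
        render_fu_map(spec, out)
        assert out.stat().st_size > 0

    def test_spec_json_roundtrips(self, table1, ccb_partition, tmp_path):
        network, _ = table1
        spec = build_fu_map(ccb_partition, network, display_min_size=2)
        path = tmp_path / "spec.json"
        spec.to_json(path)
        data = json.loads(path.read_text())
        assert data["displayed"] == list(spec.displayed)
        assert len(data["cells"]) == 12
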