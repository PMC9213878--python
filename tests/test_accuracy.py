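"""The matched-node accuracy procedure: trimming, splitting, resampling,
distances and summaries."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cmiwarp.accuracy import (
    MatchedJunction,
    SegmentMatch,
    SegmentTopologyError,
    compute_step_count,
    matched_node_distances,
    resample_segment,
    split_segments,
    summarize_accuracy,
    trim_free_ends,
    warping_accuracy,
)
from tests.conftest import make_landmarks, make_skeleton


def path_skeleton():
    # a -- b -- c -- d along x, 10 um apart
    return make_skeleton(
        {1: (0, 0, 0), 2: (10, 0, 0), 3: (20, 0, 0), 4: (30, 0, 0)},
        [(1, 2), (2, 3), (3, 4)],
    )


def h_skeleton(shift=(0.0, 0.0, 0.0)):
    """H-shaped vasculature: crossbar X(2)–mid(7)–Y(5), two arms per side."""
    s = np.asarray(shift, dtype=float)
    nodes = {
        1: (0, 0, 0),      # A
        2: (10, 0, 0),     # X (degree 3)
        3: (20, 0, 0),     # C
        4: (0, 20, 0),     # B
        5: (10, 20, 0),    # Y (degree 3)
        6: (20, 20, 0),    # D
        7: (10, 10, 0),    # crossbar midpoint (degree 2)
    }
    nodes = {i: tuple(np.asarray(p, float) + s) for i, p in nodes.items()}
    edges = [(1, 2), (3, 2), (2, 7), (7, 5), (5, 4), (5, 6)]
    return make_skeleton(nodes, edges)


H_JUNCTION_IDS = [1, 2, 3, 4, 5, 6]


def junction_table(node_ids, modalities):
    return {f"J{i}": {m: i for m in modalities} for i in node_ids}


class TestTrimFreeEnds:
    def test_free_end_edges_removed_up_to_junctions(self):
        trimmed = trim_free_ends(path_skeleton(), {2, 3})
        g = trimmed.graph()
        assert set(g.nodes) == {2, 3}
        assert set(g.edges) == {(2, 3)}

    def test_skeleton_with_only_matched_leaves_unchanged(self):
        sk = path_skeleton()
        trimmed = trim_free_ends(sk, {1, 4})
        assert set(trimmed.graph().nodes) == {1, 2, 3, 4}
        assert len(trimmed.graph().edges) == 3

    def test_y_tree_with_single_matched_junction_reduces_to_one_node(self):
        sk = make_skeleton(
            {1: (0, 0, 0), 2: (10, 0, 0), 3: (20, 5, 0), 4: (20, -5, 0), 5: (30, 5, 0)},
            [(1, 2), (2, 3), (2, 4), (3, 5)],
        )
        trimmed = trim_free_ends(sk, {2})
        assert set(trimmed.graph().nodes) == {2}

    def test_absent_junction_id_is_error(self):
        with pytest.raises(KeyError, match="99"):
            trim_free_ends(path_skeleton(), {99})

    def test_low_degree_matched_junction_warns_but_is_kept(self, caplog):
        with caplog.at_level("WARNING"):
            trimmed = trim_free_ends(path_skeleton(), {1, 4})
        assert "degree" in caplog.text
        assert 1 in trimmed.graph().nodes


class TestSplitSegments:
    def test_single_path_three_modalities_gives_one_segment(self):
        nodes = {i: (2.0 * i, 0, 0) for i in range(1, 13)}
        edges = [(i, i + 1) for i in range(1, 12)]
        skels = {m: make_skeleton(nodes, edges) for m in ("2p", "sxrt", "sbem")}
        junctions = [MatchedJunction("Ja", {m: 1 for m in skels}),
                     MatchedJunction("Jb", {m: 12 for m in skels})]
        segments = split_segments(skels, junctions)
        assert len(segments) == 1
        seg = segments[0]
        assert seg.labels == ("Ja", "Jb")
        for m in skels:
            assert seg.polylines[m].shape == (12, 3)
            assert seg.lengths()[m] == pytest.approx(22.0)

    def test_h_shape_segment_count_matches_path_enumeration_oracle(self):
        skels = {"a": h_skeleton(), "b": h_skeleton()}
        table = junction_table(H_JUNCTION_IDS, skels)
        junctions = [MatchedJunction(lbl, ids) for lbl, ids in table.items()]
        segments = split_segments(skels, junctions)

        # oracle: exhaustively enumerate simple paths between junction pairs
        # whose interior contains no other junction
        g = h_skeleton().graph()
        jset = set(H_JUNCTION_IDS)
        expected = set()
        for a in H_JUNCTION_IDS:
            for b in H_JUNCTION_IDS:
                if a < b:
                    for path in nx.all_simple_paths(g, a, b):
                        if not (set(path[1:-1]) & jset):
                            expected.add((a, b))
        assert len(expected) == 5
        assert len(segments) == len(expected)
        assert {tuple(sorted(int(l[1:]) for l in s.labels)) for s in segments} == expected

    def test_segment_absent_from_one_modality_is_excluded(self, caplog):
        full = h_skeleton()
        # modality "b" lacks the D arm entirely (already trimmed there)
        partial_nodes = {i: tuple(full.node(i).position) for i in (1, 2, 3, 4, 5, 7)}
        partial = make_skeleton(partial_nodes, [(1, 2), (3, 2), (2, 7), (7, 5), (5, 4)])
        skels = {"a": full, "b": partial}
        labels = [1, 2, 3, 4, 5]
        junctions = [MatchedJunction(f"J{i}", {"a": i, "b": i}) for i in labels]
        trimmed_a = trim_free_ends(full, set(labels))
        with caplog.at_level("WARNING"):
            segments = split_segments({"a": trimmed_a, "b": partial}, junctions)
        assert len(segments) == 4

    def test_unmatched_branching_node_is_error(self):
        # Y with matched tips but unmatched centre
        sk = make_skeleton(
            {1: (0, 0, 0), 2: (10, 0, 0), 3: (20, 5, 0), 4: (20, -5, 0)},
            [(1, 2), (2, 3), (2, 4)],
        )
        junctions = [MatchedJunction(f"J{i}", {"a": i}) for i in (1, 3, 4)]
        with pytest.raises(SegmentTopologyError, match="branching"):
            split_segments({"a": sk}, junctions)


class TestStepCount:
    def test_mean_length_ten_micron_gives_twenty_points(self):
        assert compute_step_count([10.0, 10.2, 9.8]) == 20

    def test_short_segment_clamped_to_two(self):
        assert compute_step_count([0.4, 0.4, 0.4]) == 2

    def test_default_step_is_half_micron(self):
        from cmiwarp.accuracy import DEFAULT_STEP_UM

        assert DEFAULT_STEP_UM == 0.5

    @pytest.mark.parametrize("lengths", [[0.0, 1.0], [-1.0], []])
    def test_nonpositive_lengths_rejected(self, lengths):
        with pytest.raises(ValueError):
            compute_step_count(lengths)


class TestResample:
    def test_straight_segment_every_half_micron(self):
        poly = np.array([[0, 0, 0], [10, 0, 0]], dtype=float)
        pts = resample_segment(poly, 21)
        np.testing.assert_allclose(pts[:, 0], np.arange(21) * 0.5, atol=1e-12)

    def test_n_two_returns_exact_endpoints(self):
        poly = np.array([[0, 0, 0], [3, 4, 0], [3, 4, 12]], dtype=float)
        pts = resample_segment(poly, 2)
        np.testing.assert_array_equal(pts, poly[[0, -1]])

    def test_l_shape_midpoint_is_the_corner(self):
        poly = np.array([[0, 0, 0], [5, 0, 0], [5, 5, 0]], dtype=float)
        pts = resample_segment(poly, 3)
        np.testing.assert_allclose(pts[1], [5, 0, 0], atol=1e-12)

    def test_zero_length_polyline_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            resample_segment(np.zeros((3, 3)), 5)


def straight_segment(offset=(0.0, 0.0, 0.0), modalities=("a", "b")):
    poly = np.linspace([0, 0, 0], [10, 0, 0], 11)
    return SegmentMatch(
        labels=("J1", "J2"),
        polylines={
            m: poly + (np.asarray(offset) if m != "a" else 0.0) for m in modalities
        },
    )


class TestMatchedNodeDistances:
    def test_identical_polylines_identity_warps_give_zero(self):
        seg = straight_segment().resample()
        rec = matched_node_distances([seg], {"a": None, "b": None}, reference="a")
        assert rec["distance_um"].max() == 0.0
        assert len(rec) == seg.n

    def test_rigid_offset_gives_constant_distance(self):
        seg = straight_segment(offset=(3.0, 0.0, 0.0)).resample()
        rec = matched_node_distances([seg], {"a": None, "b": None}, reference="a")
        np.testing.assert_allclose(rec["distance_um"], 3.0, atol=1e-12)

    def test_mismatched_point_counts_rejected(self):
        seg = straight_segment().resample()
        seg.points["b"] = seg.points["b"][:-1]
        with pytest.raises(ValueError, match="mismatched"):
            matched_node_distances([seg], {"a": None, "b": None}, reference="a")

    def test_record_count_is_sum_of_step_counts_per_pair(self):
        segs = [straight_segment().resample(), straight_segment().resample(0.25)]
        rec = matched_node_distances(segs, {"a": None, "b": None}, reference="a")
        assert len(rec) == sum(s.n for s in segs)


class TestSummarize:
    def test_constant_records(self):
        rec = pd.DataFrame(
            {"segment": "s", "step": range(4), "pair": "a->b",
             "x": 0.0, "y": 0.0, "z": 0.0, "distance_um": 2.0}
        )
        s = summarize_accuracy(rec)["a->b"]
        assert s["mean_um"] == s["min_um"] == s["max_um"] == 2.0

    def test_mean_of_two_records(self):
        rec = pd.DataFrame(
            {"segment": "s", "step": [0, 1], "pair": "a->b",
             "x": 0.0, "y": 0.0, "z": 0.0, "distance_um": [1.0, 3.0]}
        )
        assert summarize_accuracy(rec)["a->b"]["mean_um"] == 2.0

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError, match="no matched-node"):
            summarize_accuracy(pd.DataFrame(columns=["pair", "distance_um"]))


class TestEndToEnd:
    def test_identical_skeletons_identity_warps_zero_distance(self):
        skels = {"a": h_skeleton(), "b": h_skeleton()}
        table = junction_table(H_JUNCTION_IDS, skels)
        identity_lm = make_landmarks(
            np.array([[0, 0, 0], [160, 0, 0], [0, 160, 0], [0, 0, 160], [80, 80, 80]], float),
            np.array([[0, 0, 0], [160, 0, 0], [0, 160, 0], [0, 0, 160], [80, 80, 80]], float),
        )
        records, summary = warping_accuracy(
            skels, table, {"a": None, "b": identity_lm}, reference="a"
        )
        assert records["distance_um"].max() <= 1e-9
        assert summary["a->b"]["mean_um"] <= 1e-9

    def test_rigid_shift_absorbed_by_fitted_warp(self, rng):
        # shifting one modality and its landmarks must not change distances
        shift = np.array([25.0, -10.0, 12.0])
        base_pts = rng.uniform(0, 30, (20, 3))
        skels = {"a": h_skeleton(), "b": h_skeleton(shift=shift)}
        table = junction_table(H_JUNCTION_IDS, skels)
        lm = make_landmarks(base_pts + shift, base_pts)  # moving = b space, fixed = a
        records, summary = warping_accuracy(skels, table, {"a": None, "b": lm}, reference="a")
        assert summary["a->b"]["mean_um"] <= 1e-6

    def test_bookkeeping_total_records(self):
        skels = {"a": h_skeleton(), "b": h_skeleton()}
        table = junction_table(H_JUNCTION_IDS, skels)
        pts = np.array([[0, 0, 0], [30, 0, 0], [0, 30, 0], [0, 0, 30], [15, 15, 15]], float)
        records, _ = warping_accuracy(
            skels, table, {"a": None, "b": make_landmarks(pts, pts)}, reference="a"
        )
        per_pair = records.groupby("pair").size()
        n_expected = records.groupby("segment")["step"].max() + 1
        assert per_pair["a->b"] == n_expected.sum()
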