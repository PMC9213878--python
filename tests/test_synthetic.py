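"""Synthetic scenes: vessel trees, modality simulation, scoring tables."""

import numpy as np
import pytest

from cmiwarp.accuracy import split_segments, trim_free_ends, warping_accuracy
from cmiwarp.accuracy import MatchedJunction
from cmiwarp.artefacts import occurrence_rate, perfect_rate, prevalence
from cmiwarp.synthetic import (
    AffineDeformation,
    GroundTruthScene,
    SmoothDeformation,
    default_scene,
    generate_scoring_table,
    generate_vessel_tree,
    junction_node_ids,
    prune_thin_branches,
    random_smooth_deformation,
    scene_junction_table,
    simulate_modality,
    simulate_scene,
)
from cmiwarp.warping import fit_warp


class TestVesselTree:
    def test_seed_determinism(self):
        a = generate_vessel_tree(123, n_junctions=6)
        b = generate_vessel_tree(123, n_junctions=6)
        assert a.n_nodes == b.n_nodes
        for n in a.iter_nodes():
            np.testing.assert_array_equal(b.node(n.id).position, n.position)

    def test_distinct_seeds_give_distinct_trees(self):
        a = generate_vessel_tree(1, n_junctions=6)
        b = generate_vessel_tree(2, n_junctions=6)
        pa = np.sort(np.concatenate([n.position for n in a.iter_nodes()]))
        pb = np.sort(np.concatenate([n.position for n in b.iter_nodes()]))
        assert pa.shape != pb.shape or not np.allclose(pa, pb)

    def test_single_junction_is_y_shaped(self):
        sk = generate_vessel_tree(5, n_junctions=1)
        assert len(junction_node_ids(sk)) == 1
        g = sk.graph()
        assert sum(1 for n in g.nodes if g.degree(n) == 1) == 3  # three free ends

    @pytest.mark.parametrize("n_junctions", [1, 5, 12])
    def test_invariants_and_junction_count(self, n_junctions):
        sk = generate_vessel_tree(7, n_junctions=n_junctions)
        sk.validate()  # connected + acyclic
        assert len(junction_node_ids(sk)) == n_junctions
        pos = np.array([n.position for n in sk.iter_nodes()])
        assert pos.min() >= 0 and pos.max() <= 160.0

    def test_branches_are_tortuous(self):
        # mean arc/chord over inter-junction segments comfortably above 1.2
        sk = generate_vessel_tree(11, n_junctions=8)
        junctions = junction_node_ids(sk)
        trimmed = trim_free_ends(sk, set(junctions))
        segs = split_segments(
            {"x": trimmed}, [MatchedJunction(f"J{i}", {"x": i}) for i in junctions]
        )
        ratios = []
        for s in segs:
            poly = s.polylines["x"]
            chord = np.linalg.norm(poly[-1] - poly[0])
            if chord > 1e-9:
                ratios.append(s.lengths()["x"] / chord)
        assert np.mean(ratios) >= 1.2

    def test_radii_decrease_toward_tips_and_prune_keeps_connectivity(self):
        sk = generate_vessel_tree(3, n_junctions=10, radius_range=(0.5, 4.0))
        radii = np.array([n.radius for n in sk.iter_nodes()])
        pruned = prune_thin_branches(sk, float(np.percentile(radii, 30)))
        pruned.validate()
        assert 0 < pruned.n_nodes < sk.n_nodes

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_vessel_tree(1, n_junctions=0)


def two_modality_scene(seed, deform_b, sigma_lm=0.0, sigma_tr=0.0, thr_b=0.0,
                       n_landmarks=20, n_junctions=8):
    base = generate_vessel_tree(seed, n_junctions=n_junctions)
    return GroundTruthScene(
        base=base,
        deformations={"ref": AffineDeformation.identity(), "mov": deform_b},
        landmark_sigma={"ref": 0.0, "mov": sigma_lm},
        tracing_sigma={"ref": 0.0, "mov": sigma_tr},
        radius_threshold={"ref": 0.0, "mov": thr_b},
        seed=seed,
        n_landmarks=n_landmarks,
    )


class TestSimulateModality:
    def test_identity_deformation_zero_jitter_reproduces_base(self):
        scene = two_modality_scene(4, AffineDeformation.identity())
        sk, _ = simulate_modality(scene, "mov")
        for n in scene.base.iter_nodes():
            np.testing.assert_allclose(sk.node(n.id).position, n.position, atol=1e-12)

    def test_threshold_above_all_radii_is_error(self):
        scene = two_modality_scene(4, AffineDeformation.identity(), thr_b=100.0)
        with pytest.raises(ValueError, match="nothing remains|junction"):
            simulate_modality(scene, "mov")

    def test_landmarks_fittable_by_construction(self):
        scene = two_modality_scene(8, AffineDeformation.scaling(1.05), sigma_lm=1.0)
        _, lm = simulate_modality(scene, "mov")
        warp = fit_warp(lm)  # would raise on coplanar/degenerate sets
        assert warp.residual_max_um <= 1e-6

    def test_pruning_consistent_across_modalities(self):
        scene = two_modality_scene(9, AffineDeformation.scaling(1.1), thr_b=1.0,
                                   n_junctions=10)
        sk_ref, _ = simulate_modality(scene, "ref")
        sk_mov, _ = simulate_modality(scene, "mov")
        ids_ref = sorted(n.id for n in sk_ref.iter_nodes())
        ids_mov = sorted(n.id for n in sk_mov.iter_nodes())
        assert ids_ref == ids_mov  # same branches removed everywhere
        table = scene_junction_table(scene)
        skels = {
            m: trim_free_ends(s, {v[m] for v in table.values()})
            for m, s in (("ref", sk_ref), ("mov", sk_mov))
        }
        junctions = [MatchedJunction(lbl, dict(ids)) for lbl, ids in table.items()]
        segs = split_segments(skels, junctions)
        assert segs  # identical segment sets -> none excluded
        assert all(set(s.polylines) == {"ref", "mov"} for s in segs)

    def test_affine_scene_recovered_below_half_micron(self):
        # affine ground truth lies in the warp's span: only polyline
        # discretization remains
        matrix = np.diag([1.06, 0.98, 1.03]) + np.array(
            [[0, 0.02, 0], [0.01, 0, -0.02], [0, 0.015, 0]]
        )
        deform = AffineDeformation(matrix, np.array([4.0, -6.0, 9.0]))
        scene = two_modality_scene(12, deform, n_landmarks=20)
        skels, lms = simulate_scene(scene)
        records, summary = warping_accuracy(
            skels, scene_junction_table(scene),
            {"ref": None, "mov": lms["mov"]}, reference="ref",
        )
        assert summary["mov->ref"]["mean_um"] <= 0.5


class TestSmoothDeformations:
    def test_random_deformations_are_diffeomorphic(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            d = random_smooth_deformation(rng)
            assert d.min_jacobian_det(160.0) > 0

    def test_default_scene_is_deterministic_and_valid(self):
        a = default_scene(21)
        b = default_scene(21)
        a.validate_diffeomorphic()
        ska, _ = simulate_modality(a, "2p")
        skb, _ = simulate_modality(b, "2p")
        for n in ska.iter_nodes():
            np.testing.assert_array_equal(skb.node(n.id).position, n.position)


class TestScoringTableGenerator:
    def test_zero_probability_means_all_perfect(self):
        t = generate_scoring_table(1, n_samples=50, n_experiments=5,
                                   artefact_probs={"sideways": 0.0, "crack": 0.0})
        assert perfect_rate(t) == 1.0

    def test_certain_artefact_has_full_occurrence_and_prevalence(self):
        t = generate_scoring_table(1, n_samples=50, n_experiments=5,
                                   artefact_probs={"sideways": 1.0, "crack": 0.0})
        assert occurrence_rate(t, "sideways") == 1.0
        assert prevalence(t, "sideways") == 1.0

    def test_occurrence_within_3_se_of_bernoulli_rate(self):
        p, n = 0.2, 10_000
        t = generate_scoring_table(99, n_samples=n, n_experiments=25,
                                   artefact_probs={"sideways": p})
        se = np.sqrt(p * (1 - p) / n)
        assert abs(occurrence_rate(t, "sideways") - p) <= 3 * se

    def test_experiment_random_effect_spreads_penetrance(self):
        from cmiwarp.artefacts import penetrance

        flat = generate_scoring_table(6, n_samples=2000, n_experiments=20,
                                      artefact_probs={"sideways": 0.3})
        bumpy = generate_scoring_table(6, n_samples=2000, n_experiments=20,
                                       artefact_probs={"sideways": 0.3},
                                       experiment_sigma=2.0)
        var_flat = np.var(list(penetrance(flat, "sideways").per_group.values()))
        var_bumpy = np.var(list(penetrance(bumpy, "sideways").per_group.values()))
        assert var_bumpy > var_flat

    def test_metadata_constant_within_experiment(self):
        t = generate_scoring_table(3, n_samples=120, n_experiments=6)
        per_exp = t.data.groupby("experiment_id")["thickness"].nunique()
        assert (per_exp == 1).all()

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            generate_scoring_table(1, artefact_probs={"sideways": 1.5})
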