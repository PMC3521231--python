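"""Divide-and-conquer orchestration: planning, alignment, stitching."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from cfmds import (
    AlignmentTransform,
    DissimilarityMatrix,
    Embedding,
    MemoryBudget,
    ParameterError,
    apply_transform,
    choose_plan,
    classical_mds,
    distance_correlation,
    dnc_mds,
    features_to_distances,
    make_clustered,
    solve_alignment,
    SyntheticSpec,
)
from conftest import random_point_matrix


class TestChoosePlan:
    def test_one_shot_when_matrix_fits(self):
        plan = choose_plan(150, MemoryBudget(1000))
        assert plan.mode == "one_shot"
        assert plan.p == 1

    def test_explicit_overrides_win(self):
        plan = choose_plan(9300, MemoryBudget(1000), p=10, s=150, seed=0)
        assert plan.mode == "divide_and_conquer"
        assert plan.p == 10 and plan.s == 150
        assert all(len(sub) == 930 for sub in plan.subsets)
        assert plan.s * plan.p == 1500  # pooled anchor matrix is 1500 x 1500

    def test_auto_derivation_satisfies_capacity(self):
        budget = MemoryBudget(100)
        plan = choose_plan(1000, budget, default_s=10)
        assert plan.mode == "divide_and_conquer"
        assert max(len(sub) for sub in plan.subsets) <= budget.max_objects
        assert plan.s * plan.p <= budget.max_objects
        assert plan.s <= 1000 // plan.p

    def test_override_violating_subset_size_rejected(self):
        with pytest.raises(ParameterError):
            choose_plan(100, MemoryBudget(10), p=10, s=11)

    def test_tiny_n_rejected(self):
        with pytest.raises(ParameterError):
            choose_plan(1, MemoryBudget(10))


class TestSolveAlignment:
    def test_identity_when_target_equals_source(self):
        _, D = random_point_matrix(6, 2, 0)
        e = classical_mds(D, 2)
        t = solve_alignment(e, e, affine=True)
        np.testing.assert_allclose(t.linear, np.eye(2), atol=1e-9)
        np.testing.assert_allclose(t.translation, 0, atol=1e-9)

    def test_pure_translation_recovered(self):
        _, D = random_point_matrix(6, 2, 1)
        e = classical_mds(D, 2)
        shifted = Embedding(coords=e.coords + [3.0, -2.0], ids=e.ids)
        t = solve_alignment(e, shifted, affine=True)
        np.testing.assert_allclose(t.linear, np.eye(2), atol=1e-9)
        np.testing.assert_allclose(t.translation, [3.0, -2.0], atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_affine_map_recovered(self, seed):
        rng = np.random.default_rng(seed)
        src = rng.standard_normal((8, 2))
        G = rng.standard_normal((2, 2))
        h = rng.standard_normal(2)
        target = src @ G + h
        t = solve_alignment(Embedding(coords=src), Embedding(coords=target),
                            affine=True)
        np.testing.assert_allclose(t.linear, G.T, atol=1e-8)
        np.testing.assert_allclose(t.translation, h, atol=1e-8)

    def test_linear_only_has_zero_translation(self):
        rng = np.random.default_rng(0)
        src = rng.standard_normal((5, 2))
        t = solve_alignment(Embedding(coords=src),
                            Embedding(coords=src @ [[0.0, 1.0], [-1.0, 0.0]]),
                            affine=False)
        np.testing.assert_array_equal(t.translation, [0.0, 0.0])

    def test_shape_mismatch_rejected(self):
        from cfmds import ValidationError

        with pytest.raises(ValidationError):
            solve_alignment(Embedding(coords=np.zeros((3, 2))),
                            Embedding(coords=np.zeros((4, 2))))


class TestApplyTransform:
    def test_identity(self):
        e = Embedding(coords=np.array([[1.0, 2.0], [3.0, 4.0]]))
        t = AlignmentTransform(linear=np.eye(2), translation=np.zeros(2))
        np.testing.assert_array_equal(apply_transform(t, e).coords, e.coords)

    def test_scaling(self):
        e = Embedding(coords=np.array([[1.0, 0.0]]))
        t = AlignmentTransform(linear=2 * np.eye(2), translation=np.zeros(2))
        np.testing.assert_array_equal(apply_transform(t, e).coords, [[2.0, 0.0]])

    def test_rotation_90_degrees(self):
        e = Embedding(coords=np.array([[1.0, 0.0]]))
        rot = np.array([[0.0, -1.0], [1.0, 0.0]])  # counter-clockwise 90 deg
        t = AlignmentTransform(linear=rot, translation=np.zeros(2))
        np.testing.assert_allclose(apply_transform(t, e).coords, [[0.0, 1.0]],
                                   atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        from cfmds import ValidationError

        e = Embedding(coords=np.zeros((2, 3)))
        t = AlignmentTransform(linear=np.eye(2), translation=np.zeros(2))
        with pytest.raises(ValidationError):
            apply_transform(t, e)


class TestDncMds:
    @pytest.mark.parametrize("sampling", ["random", "maxmin"])
    def test_exact_recovery_on_planar_points(self, sampling):
        pts, D = random_point_matrix(60, 2, seed=11)
        plan = choose_plan(60, MemoryBudget(25), p=3, s=6, sampling=sampling, seed=11)
        e = dnc_mds(D, 2, plan)
        np.testing.assert_allclose(squareform(pdist(e.coords)), D.values, atol=1e-6)

    def test_one_shot_plan_delegates_to_classical(self, small_matrix):
        plan = choose_plan(4, MemoryBudget(10))
        e = dnc_mds(small_matrix, 2, plan)
        ref = classical_mds(small_matrix, 2)
        np.testing.assert_array_equal(e.coords, ref.coords)
        assert e.meta["plan"]["mode"] == "one_shot"

    def test_original_id_order_restored(self):
        _, D = random_point_matrix(30, 2, seed=2)
        plan = choose_plan(30, MemoryBudget(15), p=3, s=4, seed=2)
        e = dnc_mds(D, 2, plan)
        assert e.ids == D.ids

    def test_deterministic(self):
        _, D = random_point_matrix(40, 2, seed=5)
        plan = choose_plan(40, MemoryBudget(20), p=4, s=5, seed=5)
        a = dnc_mds(D, 2, plan)
        b = dnc_mds(D, 2, plan)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_sampling_mode_does_not_perturb_partition(self):
        _, D = random_point_matrix(40, 2, seed=5)
        pr = choose_plan(40, MemoryBudget(20), p=4, s=5, sampling="random", seed=5)
        pm = choose_plan(40, MemoryBudget(20), p=4, s=5, sampling="maxmin", seed=5)
        assert pr.subsets == pm.subsets

    def test_subset_smaller_than_m_plus_one_rejected(self):
        _, D = random_point_matrix(6, 2, seed=0)
        plan = choose_plan(6, MemoryBudget(4), p=3, s=2, seed=0)
        with pytest.raises(ParameterError, match="smaller m or fewer partitions"):
            dnc_mds(D, 2, plan)

    def test_metadata_records_plan_and_residuals(self):
        _, D = random_point_matrix(30, 2, seed=7)
        plan = choose_plan(30, MemoryBudget(15), p=3, s=5, seed=7)
        e = dnc_mds(D, 2, plan)
        assert e.meta["plan"]["p"] == 3
        assert len(e.meta["alignment_rms"]) == 3
        assert max(e.meta["alignment_rms"]) < 1e-6  # exact data aligns exactly

    def test_linear_only_loses_exactness_but_runs(self):
        """The literal linear-only map cannot absorb block translations."""
        _, D = random_point_matrix(60, 2, seed=3)
        plan = choose_plan(60, MemoryBudget(25), p=3, s=8, seed=3)
        e_affine = dnc_mds(D, 2, plan)
        e_linear = dnc_mds(D, 2, plan, linear_only=True)
        ref = classical_mds(D, 2)
        assert distance_correlation(ref, e_affine) > 0.999999
        assert distance_correlation(ref, e_linear) <= 1.0  # runs, possibly worse

    def test_anchor_benefit_is_monotone_in_s(self):
        """Mean distance correlation does not decrease as anchors increase."""
        spec = SyntheticSpec(n=200, ambient_dim=10, n_clusters=4, seed=0)
        D = features_to_distances(make_clustered(spec))
        ref = classical_mds(D, 2)
        means = []
        for s in (3, 4, 20):  # m+1, 2m, 10m with m=2
            corrs = []
            for seed in range(20):
                plan = choose_plan(200, MemoryBudget(5000), p=4, s=s, seed=seed)
                corrs.append(distance_correlation(ref, dnc_mds(D, 2, plan)))
            means.append(np.mean(corrs))
        assert means[1] >= means[0] - 0.02
        assert means[2] >= means[1] - 0.02
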