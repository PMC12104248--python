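"""Affine alignment to ground-truth coordinates and discrepancy scoring."""

import numpy as np
import pytest

from pwlds.alignment import (
    AlignmentTransform,
    apply_alignment,
    align_to_truth,
    classify_quality,
    discrepancy_score,
    fixed_points,
    solve_alignment,
)
from pwlds.model import LinearMode, PWLModel, RecurrentTransition
from pwlds.synthetic import GroundTruthSpec, build_default_truth


def _transformed_copy(model, F, g):
    """Re-express a model in transformed coordinates x_hat = F x + g (the
    observationally equivalent model an estimator might return)."""
    Finv = np.linalg.inv(F)
    modes = [LinearMode(F @ m.A @ Finv,
                        F @ m.b + g - F @ m.A @ Finv @ g,
                        F @ m.Q @ F.T) for m in model.modes]
    trans = RecurrentTransition(model.transition.R @ Finv,
                                model.transition.r - model.transition.R @ Finv @ g,
                                model.transition.stick_order.copy(),
                                model.transition.hard)
    from pwlds.model import EmissionMap, InitialState
    emission = EmissionMap(model.emission.C @ Finv,
                           model.emission.d - model.emission.C @ Finv @ g,
                           model.emission.family,
                           None if model.emission.S is None else model.emission.S.copy())
    initial = InitialState(F @ model.initial.mean + g,
                           F @ model.initial.cov @ F.T,
                           model.initial.mode_probs.copy())
    return PWLModel(modes, trans, emission, initial)


@pytest.fixture
def truth5(gaussian_truth):
    return gaussian_truth


class TestSolveAlignment:
    def test_identity(self, truth5):
        C, d = truth5.emission.C, truth5.emission.d
        t = solve_alignment(C, d, C, d)
        np.testing.assert_allclose(t.F, np.eye(2), atol=1e-10)
        np.testing.assert_allclose(t.g, np.zeros(2), atol=1e-10)

    def test_constructed_round_trip(self, truth5):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        h = rng.normal(size=2)
        C, d = truth5.emission.C, truth5.emission.d
        C_hat = C @ np.linalg.inv(M)
        d_hat = d - C_hat @ h
        t = solve_alignment(C, d, C_hat, d_hat)
        np.testing.assert_allclose(t.F, M, atol=1e-10)
        np.testing.assert_allclose(t.g, h, atol=1e-10)

    def test_tall_map_via_pseudo_inverse(self):
        rng = np.random.default_rng(1)
        C = rng.normal(size=(5, 2))
        d = rng.normal(size=5)
        M = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        h = rng.normal(size=2)
        C_hat = C @ np.linalg.inv(M)
        d_hat = d - C_hat @ h
        t = solve_alignment(C, d, C_hat, d_hat)
        np.testing.assert_allclose(t.F, M, atol=1e-9)
        np.testing.assert_allclose(t.g, h, atol=1e-9)

    def test_inconsistent_rank_deficient_warns(self):
        C = np.array([[1.0, 0.0], [2.0, 0.0]])
        C_hat = np.array([[1.0, 0.0], [1.0, 0.0]])  # rank 1, inconsistent
        with pytest.warns(UserWarning, match="least-squares"):
            t = solve_alignment(C, np.zeros(2), C_hat, np.zeros(2))
        assert t.residual > 1e-6


class TestApplyAlignment:
    def test_identity_leaves_model_unchanged(self, truth5):
        t = AlignmentTransform(np.eye(2), np.zeros(2))
        out = apply_alignment(truth5, t)
        for m_in, m_out in zip(truth5.modes, out.modes):
            np.testing.assert_allclose(m_in.A, m_out.A)
            np.testing.assert_allclose(m_in.b, m_out.b)
        np.testing.assert_allclose(truth5.transition.R, out.transition.R)

    def test_transform_then_inverse_recovers(self, truth5):
        rng = np.random.default_rng(2)
        F = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        g = rng.normal(size=2)
        fwd = apply_alignment(truth5, AlignmentTransform(F, g))
        # inverse transform of (F, g) is (F^{-1}, -F^{-1} g)
        Finv = np.linalg.inv(F)
        back = apply_alignment(fwd, AlignmentTransform(Finv, -Finv @ g))
        for m_in, m_out in zip(truth5.modes, back.modes):
            np.testing.assert_allclose(m_in.A, m_out.A, atol=1e-10)
            np.testing.assert_allclose(m_in.b, m_out.b, atol=1e-10)

    def test_alignment_round_trip_recovers_truth(self, truth5):
        rng = np.random.default_rng(3)
        F = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        g = rng.normal(size=2)
        estimated = _transformed_copy(truth5, F, g)
        aligned, t = align_to_truth(estimated, truth5)
        for m_t, m_a in zip(truth5.modes, aligned.modes):
            np.testing.assert_allclose(m_t.A, m_a.A, atol=1e-8)
            np.testing.assert_allclose(m_t.b, m_a.b, atol=1e-8)
        np.testing.assert_allclose(truth5.transition.R, aligned.transition.R,
                                   atol=1e-8)
        np.testing.assert_allclose(truth5.transition.r, aligned.transition.r,
                                   atol=1e-8)
        np.testing.assert_allclose(truth5.emission.C, aligned.emission.C,
                                   atol=1e-8)

    def test_singular_transform_rejected(self, truth5):
        with pytest.raises(np.linalg.LinAlgError):
            apply_alignment(truth5, AlignmentTransform(np.zeros((2, 2)),
                                                       np.zeros(2)))

    def test_fixed_points_commute_with_alignment(self, truth5):
        rng = np.random.default_rng(4)
        F = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        g = rng.normal(size=2)
        moved = apply_alignment(truth5, AlignmentTransform(F, g))
        fp_t, _ = fixed_points(truth5)
        fp_m, _ = fixed_points(moved)
        Finv = np.linalg.inv(F)
        for k in (1, 2):
            np.testing.assert_allclose(fp_m[k], Finv @ (fp_t[k] - g), atol=1e-8)


def _single_mode(A, b):
    from pwlds.model import EmissionMap, InitialState
    return PWLModel([LinearMode(A, b, np.eye(2))], None,
                    EmissionMap(np.eye(2), np.zeros(2), "gaussian", np.eye(2)),
                    InitialState(np.zeros(2), np.eye(2), [1.0]))


class TestFixedPoints:
    def test_contraction_fixed_point(self):
        # (I - 0.5 I) x* = (0.5, 3) solved by hand: x* = (1, 6)
        pts, stable = fixed_points(_single_mode(0.5 * np.eye(2), [0.5, 3.0]))
        np.testing.assert_allclose(pts[0], [1.0, 6.0])
        assert stable[0]

    def test_zero_dynamics_fixed_point_is_bias(self):
        pts, stable = fixed_points(_single_mode(np.zeros((2, 2)), [2.0, -1.0]))
        np.testing.assert_allclose(pts[0], [2.0, -1.0])
        assert stable[0]

    def test_expanding_mode_flagged_unstable(self):
        _, stable = fixed_points(_single_mode(1.2 * np.eye(2), np.zeros(2)))
        assert not stable[0]

    def test_random_walk_mode_undefined(self, truth):
        pts, _ = fixed_points(truth)
        assert np.all(np.isnan(pts[0]))   # accumulation mode: A = I


class TestDiscrepancyScore:
    def test_truth_vs_itself_is_zero(self, truth5):
        rep = discrepancy_score(truth5, truth5)
        assert rep.total == pytest.approx(0.0, abs=1e-12)
        assert rep.label == "excellent"

    def test_transform_then_align_scores_zero(self, truth5):
        rng = np.random.default_rng(5)
        F = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        g = rng.normal(size=2)
        estimated = _transformed_copy(truth5, F, g)
        aligned, _ = align_to_truth(estimated, truth5)
        rep = discrepancy_score(aligned, truth5)
        assert rep.total == pytest.approx(0.0, abs=1e-6)

    def test_moved_attractor_contribution(self, truth5):
        # moving the Mode-2 attractor from (1,6) to (1,7) shifts the mean
        # matched-attractor distance by 0.5 (mean of {1, 0})
        moved = build_default_truth(GroundTruthSpec(attractor_1=(1.0, 7.0)),
                                    emission=truth5.emission)
        rep = discrepancy_score(moved, truth5)
        assert rep.attractor_distance == pytest.approx(0.5, abs=1e-8)

    def test_permutation_invariance(self, truth5):
        # relabeling the estimated model's modes must not change the score
        perm = [2, 0, 1]
        inv_order = np.argsort(np.asarray(perm)[truth5.transition.stick_order])
        modes = [truth5.modes[i] for i in perm]
        # stick positions keep pointing at the same physical regions
        new_order = np.array([perm.index(int(i))
                              for i in truth5.transition.stick_order])
        trans = RecurrentTransition(truth5.transition.R.copy(),
                                    truth5.transition.r.copy(),
                                    new_order, truth5.transition.hard)
        relabeled = PWLModel(modes, trans, truth5.emission, truth5.initial)
        rep = discrepancy_score(relabeled, truth5)
        assert rep.total == pytest.approx(0.0, abs=1e-10)

    def test_mode_count_mismatch_charges_max_boundary(self, truth5, gaussian_emission):
        from pwlds.model import EmissionMap, InitialState
        lds = PWLModel([truth5.modes[1]], None, gaussian_emission,
                       InitialState(np.zeros(2), np.eye(2), [1.0]))
        with pytest.warns(UserWarning, match="mode-count"):
            rep = discrepancy_score(lds, truth5)
        from pwlds.alignment import BOUNDARY_SCALE
        assert rep.boundary_disagreement == pytest.approx(BOUNDARY_SCALE)


class TestClassifyQuality:
    @pytest.mark.parametrize("score,label", [
        (0.15, "excellent"),      # reference example of an excellent fit
        (0.55, "good"),           # reference example of a good fit
        (2.47, "poor"),           # reference example of a poor fit
        (0.5, "good"),            # closed lower endpoint
        (2.0, "good"),            # closed upper endpoint
        (0.0, "excellent"),
    ])
    def test_thresholds(self, score, label):
        assert classify_quality(score) == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_quality(-0.1)
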