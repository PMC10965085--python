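"""Orthogonal alignment: Procrustes optimality and cloud-size invariance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import orthogonal_procrustes
from scipy.stats import ortho_group

from semdrift.alignment import (align_runs_and_average, alignment_residual,
                                center, chain_align_time, cloud_size,
                                equalize_cloud_size, is_orthogonal,
                                procrustes_rotation)


def random_orthogonal(dim, seed):
    return ortho_group.rvs(dim, random_state=seed)


class TestCenterAndCloudSize:
    def test_center_zeroes_means_and_is_idempotent(self, rng):
        W = rng.standard_normal((40, 6)) + 3.0
        C = center(W)
        assert np.allclose(C.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(center(C), C)

    def test_constant_rows_center_to_zero(self):
        W = np.ones((5, 3)) * 2.5
        assert np.allclose(center(W), 0.0)

    def test_hand_value(self):
        assert cloud_size(np.array([[0.0, 0.0], [2.0, 0.0]])) == 1.0

    def test_single_row_zero(self):
        assert cloud_size(np.array([[3.0, 4.0]])) == 0.0

    def test_translation_invariance(self, rng):
        W = rng.standard_normal((30, 4))
        assert np.isclose(cloud_size(W), cloud_size(W + 7.5), rtol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 30),
           d=st.integers(2, 6))
    def test_orthogonal_invariance(self, seed, n, d):
        """Tr V is conserved by any orthogonal map — the symmetry that
        justifies restricting alignment to O(D)."""
        rng = np.random.default_rng(seed)
        W = rng.standard_normal((n, d)) * rng.uniform(0.1, 10)
        Q = random_orthogonal(d, seed)
        size = cloud_size(W)
        assert abs(cloud_size(W @ Q) - size) <= 1e-12 * max(size, 1.0)


class TestProcrustes:
    def test_identity_on_equal_inputs(self, rng):
        W = center(rng.standard_normal((20, 4)))
        assert np.allclose(procrustes_rotation(W, W), np.eye(4), atol=1e-10)

    def test_exact_recovery_of_known_rotation(self, rng):
        W = center(rng.standard_normal((15, 5)))
        Q = random_orthogonal(5, 3)
        R = procrustes_rotation(W @ Q, W)
        assert np.allclose(R, Q.T, atol=1e-9)
        assert np.linalg.norm((W @ Q) @ R - W) < 1e-9

    def test_result_is_orthogonal_and_matches_scipy(self, rng):
        A = center(rng.standard_normal((25, 6)))
        B = center(rng.standard_normal((25, 6)))
        R = procrustes_rotation(A, B)
        assert is_orthogonal(R)
        R_ref, _ = orthogonal_procrustes(A, B)
        assert np.allclose(R, R_ref, atol=1e-10)

    def test_reflections_permitted(self):
        W = center(np.random.default_rng(5).standard_normal((10, 3)))
        Q = np.diag([1.0, 1.0, -1.0])  # improper rotation
        R = procrustes_rotation(W @ Q, W)
        assert np.isclose(np.linalg.det(R), -1.0, atol=1e-9)
        assert np.linalg.norm(W @ Q @ R - W) < 1e-9

    def test_beats_random_candidates(self, rng):
        """Analytic solution vs a brute-force search over sampled O(3)."""
        W_ref = center(rng.standard_normal((6, 3)))
        Q0 = random_orthogonal(3, 11)
        W_src = center(W_ref @ Q0 + 0.05 * rng.standard_normal((6, 3)))
        R = procrustes_rotation(W_src, W_ref)
        analytic = np.sum((W_src @ R - W_ref) ** 2)
        qs, _ = np.linalg.qr(rng.standard_normal((20_000, 3, 3)))
        residuals = np.sum(
            (np.einsum("nd,bde->bne", W_src, qs) - W_ref) ** 2,
            axis=(1, 2))
        assert analytic <= residuals.min() + 1e-12

    def test_degenerate_input_returns_identity(self):
        Z = np.zeros((4, 3))
        assert np.array_equal(procrustes_rotation(Z, Z), np.eye(3))


class TestAlignRunsAndAverage:
    def test_single_run_returned_centered(self, rng):
        W = rng.standard_normal((12, 4)) + 2.0
        assert np.allclose(align_runs_and_average([W]), center(W))

    def test_exact_degeneracy_collapses(self, rng):
        """Runs that are orthogonal transforms of one matrix average to
        that matrix up to a global orthogonal map."""
        W = center(rng.standard_normal((30, 4)))
        runs = [W @ random_orthogonal(4, s) for s in range(5)]
        mean = align_runs_and_average(runs)
        R = procrustes_rotation(mean, W)
        assert np.linalg.norm(mean @ R - W) < 1e-8
        assert alignment_residual(runs, mean) < 1e-8

    def test_residual_non_increasing(self, rng):
        runs = [center(rng.standard_normal((25, 3))) for _ in range(4)]
        reference = runs[0]
        residuals = []
        for _ in range(12):
            aligned = [W @ procrustes_rotation(W, reference) for W in runs]
            reference = np.mean(aligned, axis=0)
            residuals.append(alignment_residual(runs, reference))
        assert all(b <= a + 1e-9 for a, b in zip(residuals, residuals[1:]))

    def test_reduces_inter_run_spread(self, rng):
        base = center(rng.standard_normal((40, 5)))
        runs = [base @ random_orthogonal(5, s)
                + 0.1 * rng.standard_normal((40, 5)) for s in range(4)]
        mean = align_runs_and_average(runs)
        before = np.mean([np.linalg.norm(center(a) - center(b))
                          for a in runs for b in runs])
        aligned = [center(W) @ procrustes_rotation(center(W), mean)
                   for W in runs]
        after = np.mean([np.linalg.norm(a - b)
                         for a in aligned for b in aligned])
        assert after < before


class TestChainAlignTime:
    def test_identical_windows_give_constant_trajectories(self, rng):
        W = rng.standard_normal((20, 4))
        emb = chain_align_time([W, W, W])
        assert all(np.allclose(M, np.eye(4), atol=1e-9) for M in emb.maps)
        assert np.allclose(emb.positions[0], emb.positions[2], atol=1e-9)

    def test_pure_symmetry_motion_removed(self, rng):
        W = center(rng.standard_normal((25, 4)))
        mats = [W]
        for s in range(3):
            mats.append(mats[-1] @ random_orthogonal(4, s + 40))
        emb = chain_align_time(mats)
        disp = emb.positions[-1] - emb.positions[0]
        assert np.max(np.abs(disp)) < 1e-8

    def test_all_maps_orthogonal_and_cloud_constant(self, rng):
        mats = [rng.standard_normal((30, 5)) * (1 + 0.3 * t)
                for t in range(4)]
        emb = chain_align_time(mats)
        for R in emb.maps:
            assert is_orthogonal(R)
        sizes = [cloud_size(emb.positions[t]) for t in range(4)]
        assert np.allclose(sizes, sizes[0], rtol=1e-9)

    def test_equalize_off_keeps_sizes(self, rng):
        mats = [rng.standard_normal((30, 5)) * (1 + t) for t in range(3)]
        emb = chain_align_time(mats, equalize=False)
        for t, M in enumerate(mats):
            assert np.isclose(cloud_size(emb.positions[t]), cloud_size(M),
                              rtol=1e-9)

    def test_vocabulary_mismatch_fatal(self, rng):
        from semdrift.corpus import Vocabulary
        mats = [rng.standard_normal((10, 3))] * 2
        with pytest.raises(ValueError, match="ocabulary"):
            chain_align_time(mats, vocabulary=Vocabulary(("a", "b")))


class TestEqualizeCloudSize:
    def test_already_equal_unchanged(self, rng):
        W = center(rng.standard_normal((20, 3)))
        out = equalize_cloud_size([W, W.copy()])
        assert np.allclose(out[1], W)

    def test_doubled_matrix_restored(self, rng):
        W = center(rng.standard_normal((20, 3)))
        out = equalize_cloud_size([W, 2.0 * W])
        assert np.allclose(out[1], W, atol=1e-12)

    def test_sizes_equal_after(self, rng):
        mats = [center(rng.standard_normal((15, 4))) * s
                for s in (1.0, 3.3, 0.2)]
        sizes = [cloud_size(W) for W in equalize_cloud_size(mats)]
        assert np.allclose(sizes, sizes[0], rtol=1e-12)

    def test_zero_cloud_fatal(self):
        with pytest.raises(ValueError, match="cloud"):
            equalize_cloud_size([np.zeros((4, 2))])
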