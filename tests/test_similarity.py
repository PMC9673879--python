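"""Interaction-profile kernels, RWR smoothing and the heterogeneous network."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from _oracles import cosine_oracle, gip_oracle, hip_oracle, rwr_closed_form
from gsamda.similarity import (
    RWRParams,
    build_heterogeneous_network,
    cosine_profile_similarity,
    fuse_similarity,
    fused_profile_similarity,
    gip_similarity,
    hip_similarity,
    rwr_smooth,
)

binary_matrices = arrays(
    np.float64, (8, 6), elements=st.sampled_from([0.0, 1.0])
).filter(lambda A: A.sum() > 0)


class TestGIP:
    def test_hand_worked_two_by_two(self):
        # orthogonal unit profiles: gamma = 1, squared distance 2
        A = np.array([[1.0, 0.0], [0.0, 1.0]])
        S = gip_similarity(A, "drug").values
        np.testing.assert_allclose(S, [[1, np.exp(-2)], [np.exp(-2), 1]], atol=1e-12)
        assert S[0, 1] == pytest.approx(0.13534, abs=1e-5)

    def test_identical_profiles_give_one(self):
        A = np.array([[1.0, 0.0], [1.0, 0.0]])
        np.testing.assert_allclose(gip_similarity(A, "drug").values, 1.0)

    @settings(derandomize=True, max_examples=40)
    @given(binary_matrices)
    def test_matches_bruteforce_oracle(self, A):
        for axis, P in (("drug", A), ("microbe", A.T)):
            if (P * P).sum() == 0:
                continue
            S = gip_similarity(A, axis).values
            np.testing.assert_allclose(S, gip_oracle(P), atol=1e-12)

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError, match="at least one association"):
            gip_similarity(np.zeros((3, 4)), "drug")

    def test_bounds_symmetry_unit_diagonal(self, rng):
        A = (rng.random((10, 7)) < 0.3).astype(float)
        A[0, 0] = 1
        S = gip_similarity(A, "microbe").values
        assert S.min() > 0 and S.max() <= 1
        np.testing.assert_allclose(S, S.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(S), 1.0)


class TestHIP:
    @pytest.mark.parametrize(
        "p_i, p_j, expected",
        [
            ([1, 0, 0, 1], [1, 1, 0, 0], 0.5),   # 2 of 4 positions differ
            ([1, 1, 1], [1, 1, 1], 1.0),          # identical
            ([1, 0], [0, 1], 0.0),                # complementary
        ],
    )
    def test_hand_cases(self, p_i, p_j, expected):
        A = np.array([p_i, p_j], dtype=float)
        assert hip_similarity(A, "drug").values[0, 1] == pytest.approx(expected)

    @settings(derandomize=True, max_examples=40)
    @given(binary_matrices)
    def test_matches_bruteforce_oracle(self, A):
        for axis, P in (("drug", A), ("microbe", A.T)):
            S = hip_similarity(A, axis).values
            np.testing.assert_allclose(S, hip_oracle(P), atol=1e-12)

    def test_denominator_is_profile_length_not_ones_count(self):
        # profiles of length 4 sharing no positions: 2 differing positions
        # out of length 4, not out of |ones| = 1
        A = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]])
        assert hip_similarity(A, "drug").values[0, 1] == pytest.approx(0.5)

    def test_large_axis_path_matches_oracle(self, rng):
        # >256 profiles takes the algebraic (distance-based) code path
        A = (rng.random((300, 5)) < 0.4).astype(float)
        S = hip_similarity(A, "drug").values
        np.testing.assert_allclose(S, hip_oracle(A), atol=1e-12)


class TestFuseAndNetwork:
    def test_fused_is_elementwise_mean(self, rng):
        A = (rng.random((6, 4)) < 0.5).astype(float)
        A[0, 0] = 1
        g = gip_similarity(A, "drug")
        h = hip_similarity(A, "drug")
        f = fuse_similarity(g, h).values
        np.testing.assert_allclose(f, (g.values + h.values) / 2, atol=1e-15)
        np.testing.assert_allclose(np.diag(f), 1.0)

    def test_fuse_shape_mismatch_errors(self):
        A = np.array([[1.0, 0.0], [0.0, 1.0]])
        B = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="shape"):
            fuse_similarity(gip_similarity(A, "drug"), hip_similarity(B, "microbe"))

    def test_network_blocks(self, rng):
        A = (rng.random((5, 3)) < 0.5).astype(float)
        A[0, 0] = 1
        S_r = fused_profile_similarity(A, "drug")
        S_m = fused_profile_similarity(A, "microbe")
        net = build_heterogeneous_network(S_r, S_m, A)
        np.testing.assert_array_equal(net.S_r, S_r.values)
        np.testing.assert_array_equal(net.S_m, S_m.values)
        np.testing.assert_array_equal(net.A, A)
        np.testing.assert_allclose(net.N, net.N.T, atol=1e-12)

    def test_trivial_one_by_one(self):
        net = build_heterogeneous_network(
            np.array([[1.0]]), np.array([[1.0]]), np.array([[0.0]])
        )
        np.testing.assert_array_equal(net.N, np.eye(2))

    def test_permutation_equivariance(self, rng):
        A = (rng.random((7, 5)) < 0.4).astype(float)
        A[0, 0] = 1
        perm = rng.permutation(7)
        S = fused_profile_similarity(A, "drug").values
        S_p = fused_profile_similarity(A[perm], "drug").values
        np.testing.assert_allclose(S_p[np.ix_(np.argsort(perm), np.argsort(perm))], S,
                                   atol=1e-12)


class TestCosine:
    def test_hand_cases(self):
        D = np.array([[1.0, 1.0, 0.0], [1.0, 0.0, 1.0]])
        assert cosine_profile_similarity(D).values[0, 1] == pytest.approx(0.5)
        D2 = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert cosine_profile_similarity(D2).values[0, 1] == pytest.approx(0.0)

    def test_zero_rows_are_finite(self):
        D = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 0.0]])
        S = cosine_profile_similarity(D).values
        assert np.isfinite(S).all()
        np.testing.assert_allclose(np.diag(S), 1.0)
        assert S[0, 1] == 0.0 and S[0, 2] == 0.0

    def test_matches_bruteforce_oracle(self, rng):
        D = (rng.random((9, 6)) < 0.4).astype(float)
        np.testing.assert_allclose(
            cosine_profile_similarity(D).values, cosine_oracle(D), atol=1e-12
        )


class TestRWR:
    def test_identity_is_fixed_point(self):
        S = np.eye(4)
        out = rwr_smooth(S, RWRParams(restart_prob=0.3)).values
        np.testing.assert_allclose(out, np.eye(4), atol=1e-9)

    def test_rows_sum_to_one(self, rng):
        S = rng.random((12, 12))
        out = rwr_smooth(S, RWRParams()).values
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-6)

    def test_chain_matches_closed_form(self):
        S = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 1.0], [0.0, 1.0, 1.0]])
        params = RWRParams(restart_prob=0.1, tol=1e-12, max_iter=5000)
        out = rwr_smooth(S, params).values
        np.testing.assert_allclose(out, rwr_closed_form(S, 0.1), atol=1e-9)

    def test_fifty_node_instance_matches_closed_form(self, rng):
        S = rng.random((50, 50)) * (rng.random((50, 50)) < 0.2)
        params = RWRParams(restart_prob=0.1, tol=1e-10, max_iter=5000)
        out = rwr_smooth(S, params).values
        np.testing.assert_allclose(out, rwr_closed_form(S, 0.1), atol=1e-6)

    def test_zero_column_gets_uniform_teleport(self):
        S = np.array([[0.0, 1.0], [0.0, 1.0]])  # node 0 unreachable column
        out = rwr_smooth(S, RWRParams()).values
        assert np.isfinite(out).all()
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-6)

    def test_nonconvergence_warns(self, rng):
        S = rng.random((6, 6))
        with pytest.warns(RuntimeWarning, match="did not converge"):
            rwr_smooth(S, RWRParams(restart_prob=0.9, tol=1e-15, max_iter=2))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            RWRParams(restart_prob=1.5)
        with pytest.raises(ValueError):
            RWRParams(tol=-1)
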