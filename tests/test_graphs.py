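import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import sparse

from stgf.graphs import (
    default_grouping,
    make_composite_frames,
    normalize_filter,
    spatial_knn_graph,
    temporal_graph,
    temporal_mask,
)
from stgf.kinetics import FrameSchedule


def random_adjacency(n: int, seed: int, density: float = 0.4) -> sparse.csr_array:
    """Random symmetric nonnegative adjacency with unit self-loops."""
    rng = np.random.default_rng(seed)
    A = rng.random((n, n)) * (rng.random((n, n)) < density)
    W = np.maximum(A, A.T)
    np.fill_diagonal(W, 1.0)
    return sparse.csr_array(W)


class TestCompositeFrames:
    def test_default_grouping_gives_four_composites(self):
        rng = np.random.default_rng(0)
        Y = rng.random((50, 24))
        comps = make_composite_frames(Y)
        assert comps.n_groups == 4
        assert comps.grouping == (
            tuple(range(0, 8)), tuple(range(8, 16)),
            tuple(range(16, 20)), tuple(range(20, 24)),
        )
        for w in comps.weights:
            assert sum(w) == pytest.approx(1.0)

    def test_single_group_uniform_weights_is_framewise_mean(self):
        rng = np.random.default_rng(1)
        Y = rng.random((30, 6))
        comps = make_composite_frames(Y, grouping=(tuple(range(6)),))
        assert np.allclose(comps.Z[:, 0], Y.mean(axis=1))

    def test_constant_input_convexity(self):
        Y = np.full((20, 24), 3.5)
        comps = make_composite_frames(Y)
        assert np.allclose(comps.Z, 3.5)

    def test_duration_weights_follow_schedule(self):
        sched = FrameSchedule.from_segments(((2, 20.0), (2, 60.0)))
        Y = np.ones((10, 4))
        comps = make_composite_frames(Y, grouping=((0, 1, 2, 3),), schedule=sched)
        assert comps.weights[0] == pytest.approx((0.125, 0.125, 0.375, 0.375))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            make_composite_frames(np.ones((5, 4)), grouping=((0, 1), ()))


class TestSpatialGraph:
    def test_identical_features_all_weights_one(self):
        Z = np.ones((12, 3))
        gf = spatial_knn_graph(Z, k=4, sigma_s=0.5)
        assert np.allclose(gf.W.toarray()[gf.W.toarray() > 0], 1.0)

    def test_kernel_value_at_sigma_distance(self):
        # two nodes separated by exactly sigma -> weight e^-1
        Z = np.array([[0.0], [0.5], [10.0], [10.5]])
        gf = spatial_knn_graph(Z, k=1, sigma_s=0.5)
        W = gf.W.toarray()
        assert W[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_knn_matches_brute_force_search(self):
        """Scalar features {0,1,2,10,11,12}, k=2: two 3-cliques."""
        feats = np.array([0.0, 1, 2, 10, 11, 12])[:, None]
        gf = spatial_knn_graph(feats, k=2, sigma_s=1.0)
        W = gf.W.toarray()
        # brute-force oracle
        n = 6
        expected = np.eye(n)
        for m in range(n):
            d = np.abs(feats[:, 0] - feats[m, 0])
            d[m] = np.inf
            for j in np.argsort(d, kind="stable")[:2]:
                expected[m, j] = expected[j, m] = np.exp(-d[j] ** 2)
        assert np.allclose(W, expected)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(2)
        Z = rng.random((40, 4))
        gf = spatial_knn_graph(Z, k=6, sigma_s=0.5)
        W = gf.W.toarray()
        assert np.allclose(W, W.T)
        assert np.allclose(np.diag(W), 1.0)
        assert W.min() >= 0 and W.max() <= 1 + 1e-12

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="k="):
            spatial_knn_graph(np.random.default_rng(0).random((5, 2)), k=5)


class TestTemporalMask:
    def test_uniform_frames_full_mask(self):
        Y = np.full((36, 4), 2.0)
        mask = temporal_mask(Y, (6, 6), tau=0.5)
        assert mask.all()

    def test_single_hot_bin_halo(self):
        """Mask of an impulse equals thresholding an explicit 3x3 kernel."""
        Y = np.zeros((81, 1))
        Y[4 * 9 + 4, 0] = 1.0
        tau, sigma = 0.3, 0.85
        mask = temporal_mask(Y, (9, 9), tau=tau, smooth_sigma=sigma)
        # independent arithmetic: normalized 3x3 Gaussian kernel
        d2 = np.add.outer(np.arange(-1, 2) ** 2, np.arange(-1, 2) ** 2)
        ker = np.exp(-d2 / (2 * sigma**2))
        ker /= ker.sum()
        expected = np.zeros((9, 9))
        expected[3:6, 3:6] = ker
        assert np.array_equal(mask, (expected > tau * ker.max()).ravel())

    def test_mask_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        Y = rng.random((49, 5))
        small = temporal_mask(Y, (7, 7), tau=0.2)
        large = temporal_mask(Y, (7, 7), tau=0.8)
        assert np.all(large <= small)  # larger tau -> subset

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            temporal_mask(np.ones((4, 2)), (2, 2), tau=1.5)


class TestTemporalGraph:
    def test_window_arithmetic(self):
        rng = np.random.default_rng(4)
        Y = rng.random((36, 24)) + 0.1
        gf = temporal_graph(Y, (6, 6), window=9, sigma_t=1.0)
        W = gf.W.toarray()
        # frame 12 (1-based) = index 11: candidates 8..16 1-based = 7..15
        assert set(np.nonzero(W[11])[0]) == set(range(7, 16))
        # frame 1 = index 0: candidates 1..5 1-based = 0..4
        assert set(np.nonzero(W[0])[0]) == set(range(0, 5))

    def test_identical_frames_unit_weights(self):
        Y = np.tile(np.random.default_rng(5).random(25)[:, None] + 0.5, (1, 10))
        gf = temporal_graph(Y, (5, 5), window=5, sigma_t=1.0)
        W = gf.W.toarray()
        assert np.allclose(W[W > 0], 1.0)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            temporal_graph(np.ones((4, 3)), (2, 2), window=4)

    def test_frame_scales_positive(self):
        rng = np.random.default_rng(6)
        Y = rng.random((36, 8))
        gf = temporal_graph(Y, (6, 6), window=3)
        assert np.all(gf.frame_scales > 0)


class TestNormalizeFilter:
    def test_all_ones_two_by_two(self):
        F = normalize_filter(np.ones((2, 2))).toarray()
        assert np.allclose(F, 0.5)
        assert np.allclose(F @ np.array([1.0, 3.0]), [2.0, 2.0])

    def test_identity_preserved(self):
        F = normalize_filter(np.eye(4)).toarray()
        assert np.allclose(F, np.eye(4))

    def test_asymmetric_rejected(self):
        W = np.eye(3)
        W[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            normalize_filter(W)

    def test_zero_degree_rejected(self):
        W = np.zeros((3, 3))
        W[0, 0] = 1.0
        with pytest.raises(ValueError, match="zero-degree"):
            normalize_filter(W)

    @given(st.integers(min_value=2, max_value=60), st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_spectral_contract_random_graphs(self, n, seed):
        """Eigenvalues of D^(-1/2) W D^(-1/2) lie in [-1,1]; the top
        eigenpair is (1, D^(1/2) 1) — checked against a dense eigensolver."""
        W = random_adjacency(n, seed)
        F = normalize_filter(W).toarray()
        vals = np.linalg.eigvalsh(F)
        assert vals.min() >= -1 - 1e-10
        assert vals.max() <= 1 + 1e-10
        d = np.asarray(W.sum(axis=1)).ravel()
        v = np.sqrt(d)
        assert np.allclose(F @ v, v, atol=1e-10 * np.linalg.norm(v))

    def test_filtering_non_expansive(self):
        rng = np.random.default_rng(8)
        W = random_adjacency(30, 9)
        F = normalize_filter(W)
        for _ in range(10):
            z = rng.standard_normal(30)
            assert np.linalg.norm(F @ z) <= np.linalg.norm(z) * (1 + 1e-12)
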