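import numpy as np
import pytest
from scipy import sparse

import stgf
from stgf.config import GraphConfig, ReconConfig, StoppingConfig
from stgf.engine import STGFModel, apply_st_filter, run_stgf, stopping_measure
from stgf.graphs import normalize_filter


class TestApplyFilter:
    def test_identity_filters_are_noop(self):
        Y = np.random.default_rng(0).random((6, 4))
        I6, I4 = sparse.eye_array(6, format="csr"), sparse.eye_array(4, format="csr")
        assert np.allclose(apply_st_filter(Y, I6, I4), Y)

    def test_spatial_averaging_example(self):
        Y = np.array([[1.0, 2.0], [3.0, 4.0]])
        F_S = np.full((2, 2), 0.5)
        out = apply_st_filter(Y, F_S, np.eye(2))
        assert np.allclose(out, [[2.0, 3.0], [2.0, 3.0]])

    def test_temporal_averaging_example(self):
        Y = np.array([[1.0, 2.0], [3.0, 4.0]])
        F_T = np.full((2, 2), 0.5)
        out = apply_st_filter(Y, np.eye(2), F_T)
        assert np.allclose(out, [[1.5, 1.5], [3.5, 3.5]])

    def test_shape_mismatch_rejected(self):
        Y = np.ones((3, 2))
        with pytest.raises(ValueError):
            apply_st_filter(Y, np.eye(2), np.eye(2))
        with pytest.raises(ValueError):
            apply_st_filter(Y, np.eye(3), np.eye(3))


class TestStoppingMeasure:
    def test_no_change_gives_zero(self):
        Y = np.ones((4, 3))
        I = np.ones((5, 3))
        assert stopping_measure(Y, Y, I, I) == 0.0

    def test_equation_arithmetic(self):
        """2% sinogram change, 0% image change, w=(0.5,0.5) -> 0.01,
        which does NOT satisfy the strict < epsilon=0.01 test."""
        Y = np.ones((4, 3))
        Y_next = Y * 1.02
        I = np.ones((5, 3))
        cfg = StoppingConfig(epsilon=0.01, w1=0.5, w2=0.5)
        m = stopping_measure(Y, Y_next, I, I, cfg)
        assert m == pytest.approx(0.01, abs=1e-12)
        assert not (m < cfg.epsilon)

    def test_degenerate_weights_select_single_domain(self):
        rng = np.random.default_rng(1)
        Y, Y2 = rng.random((4, 2)), rng.random((4, 2))
        I, I2 = rng.random((9, 2)), rng.random((9, 2))
        cfg = StoppingConfig(epsilon=0.01, w1=1.0, w2=0.0)
        expected = np.linalg.norm(Y2 - Y) / np.linalg.norm(Y)
        assert stopping_measure(Y, Y2, I, I2, cfg) == pytest.approx(expected)

    def test_zero_norm_previous_is_converged_with_warning(self):
        with pytest.warns(UserWarning, match="zero-norm"):
            m = stopping_measure(np.zeros((2, 2)), np.ones((2, 2)),
                                 np.zeros((2, 2)), np.zeros((2, 2)))
        assert m == 0.0


def small_engine_inputs(side=15, seed=0):
    system = stgf.build_system_matrix(side, side, side)
    rng = np.random.default_rng(seed)
    Y = rng.poisson(20.0, (system.n_bins, 6)).astype(float)
    return system, Y


class TestEngine:
    def test_infinite_epsilon_single_pass(self):
        system, Y = small_engine_inputs()
        graph = GraphConfig(grouping=((0, 1, 2), (3, 4, 5)), k_neighbors=10,
                            window=3, rescale_counts=False,
                            scale_equalized_temporal=False)
        res = run_stgf(Y, system, graph=graph,
                       stopping=StoppingConfig(epsilon=np.inf, t_max=10),
                       recon=ReconConfig(n_iterations=3, inner_iterations=3))
        assert res.n_iter == 1
        assert res.converged
        # output equals one two-sided filtering pass with the same filters
        model = STGFModel(Y, system, graph=graph)
        expected = apply_st_filter(Y, model._spatial_filter(Y), model._temporal_filter(Y))
        assert np.allclose(res.sinogram, expected)

    def test_constant_sinogram_converges_immediately(self):
        """Constant data with a complete spatial graph and full temporal
        window: all similarities are 1, the normalized filters preserve the
        constant signal, and the measure is 0 at the first pass."""
        system, _ = small_engine_inputs(side=9)
        Y = np.full((system.n_bins, 3), 4.0)
        graph = GraphConfig(grouping=((0,), (1, 2)), k_neighbors=system.n_bins - 1,
                            window=9)
        res = run_stgf(Y, system, graph=graph,
                       stopping=StoppingConfig(epsilon=0.01, t_max=5),
                       recon=ReconConfig(n_iterations=3, inner_iterations=3))
        assert res.converged
        assert res.n_iter == 1
        assert res.history["measure"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.sinogram, Y)

    def test_modes_match_identity_filter_runs(self, tiny_dataset, tiny_system):
        """S-GF equals the engine with F_T frozen at the identity, and
        T-GF equals the engine with F_S frozen (direct comparison)."""
        stopping = StoppingConfig(epsilon=1e-9, t_max=2, stop_on_stagnation=False)
        recon = ReconConfig(n_iterations=4, inner_iterations=4)
        common = dict(background=tiny_dataset.background,
                      schedule=tiny_dataset.schedule,
                      graph=tiny_dataset.config.graph,
                      stopping=stopping, recon=recon)

        class FrozenT(STGFModel):
            def _temporal_filter(self, Y):
                return sparse.eye_array(Y.shape[1], format="csr")

        class FrozenS(STGFModel):
            def _spatial_filter(self, Y):
                return sparse.eye_array(Y.shape[0], format="csr")

        Y0 = tiny_dataset.noisy[0].astype(float)
        sgf = STGFModel(Y0, tiny_system, mode="sgf", **common).fit()
        frozen_t = FrozenT(Y0, tiny_system, mode="stgf", **common).fit()
        assert np.allclose(sgf.sinogram, frozen_t.sinogram)

        tgf = STGFModel(Y0, tiny_system, mode="tgf", **common).fit()
        frozen_s = FrozenS(Y0, tiny_system, mode="stgf", **common).fit()
        assert np.allclose(tgf.sinogram, frozen_s.sinogram)

    def test_termination_and_nonnegativity(self, tiny_dataset, tiny_system):
        res = STGFModel.from_dataset(tiny_dataset, 0, system=tiny_system).fit()
        assert res.n_iter <= tiny_dataset.config.stopping.t_max
        assert res.stop_reason in ("epsilon", "stagnation", "t_max")
        assert np.all(res.sinogram >= 0)
        assert np.all(res.images >= 0)
        assert np.all(np.isfinite(res.history["measure"]))

    def test_nonnegative_input_required(self, tiny_system):
        Y = -np.ones((tiny_system.n_bins, 3))
        with pytest.raises(ValueError, match="nonnegative"):
            STGFModel(Y, tiny_system)

    def test_summary_reports_key_fields(self, tiny_dataset, tiny_system):
        res = STGFModel.from_dataset(tiny_dataset, 0, system=tiny_system).fit()
        text = res.summary()
        assert "Iterations" in text and "Epsilon" in text
        assert res.mode.upper() in text

    def test_repeated_filtering_power_iteration(self):
        """Repeated application of a fixed normalized filter drives a signal
        toward the top eigenvector direction D^(1/2) 1 (dense oracle)."""
        rng = np.random.default_rng(11)
        A = rng.random((20, 20)) * (rng.random((20, 20)) < 0.5)
        W = np.maximum(A, A.T)
        np.fill_diagonal(W, 1.0)
        F = normalize_filter(W).toarray()
        d = W.sum(axis=1)
        top = np.sqrt(d) / np.linalg.norm(np.sqrt(d))
        z = rng.random(20) + 0.1
        for _ in range(400):
            z = F @ z
            z /= np.linalg.norm(z)
        assert abs(float(top @ z)) > 1 - 1e-8
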