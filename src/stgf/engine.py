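"""Iterative spatio-temporal graph filtering of dynamic sinograms.

The engine exposes a statsmodels-style pair: :class:`STGFModel` is built
from the noisy dynamic sinogram and the tomographic system model, and its
:meth:`~STGFModel.fit` runs the iterative loop

    1. rebuild the spatial filter F_S from composite frames of Y(i),
    2. rebuild the temporal filter F_T from the frames of Y(i),
    3. update Y(i+1) = F_S Y(i) F_T^T,
    4. reconstruct I(i+1) by MLEM from Y(i+1),
    5. stop when w1*||dY||_F/||Y||_F + w2*||dI||_F/||I||_F < epsilon
       or after t_max passes,

returning an :class:`STGFResults` with the denoised sinogram, the final
reconstructions, the convergence history and a text summary.  The filters
are re-estimated from the progressively cleaner signal at every pass; this
bootstrapping is the method's central mechanism, so filter caching is
opt-in only.  Ablation modes fix one filter at the identity: ``"sgf"``
(spatial only) and ``"tgf"`` (temporal only).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .config import GraphConfig, ReconConfig, StoppingConfig
from .graphs import (
    make_composite_frames,
    spatial_knn_graph,
    temporal_graph,
    temporal_mask,
)
from .kinetics import FrameSchedule
from .projection import SystemModel, mlem_frames

__all__ = ["STGFModel", "STGFResults", "apply_st_filter", "stopping_measure", "run_stgf"]

MODES = ("stgf", "sgf", "tgf")


def apply_st_filter(Y: np.ndarray, F_S, F_T) -> np.ndarray:
    """One two-sided filtering pass Y' = F_S . Y . F_T^T.

    Both filters are nonnegative, so the output is clipped only for float
    round-off below zero.
    """
    Y = np.asarray(Y, dtype=float)
    if F_S.shape != (Y.shape[0], Y.shape[0]):
        raise ValueError(f"F_S shape {F_S.shape} does not match {Y.shape[0]} bins")
    if F_T.shape != (Y.shape[1], Y.shape[1]):
        raise ValueError(f"F_T shape {F_T.shape} does not match {Y.shape[1]} frames")
    out = np.asarray(F_S @ Y @ F_T.T)
    return np.maximum(out, 0.0)


def stopping_measure(
    Y_prev: np.ndarray,
    Y_next: np.ndarray,
    I_prev: np.ndarray,
    I_next: np.ndarray,
    config: StoppingConfig | None = None,
) -> float:
    """Dual-domain relative change w1*||dY||/||Y|| + w2*||dI||/||I||.

    A zero-norm previous iterate in either domain contributes zero (the
    domain is declared converged) with a warning.
    """
    if config is None:
        config = StoppingConfig()

    def rel(prev, nxt):
        nprev = np.linalg.norm(prev)
        if nprev == 0:
            warnings.warn("zero-norm previous iterate: domain treated as converged")
            return 0.0
        return float(np.linalg.norm(np.asarray(nxt) - np.asarray(prev)) / nprev)

    return config.w1 * rel(Y_prev, Y_next) + config.w2 * rel(I_prev, I_next)


@dataclass
class STGFResults:
    """Fit results of the iterative graph-filtering model.

    Attributes
    ----------
    sinogram : ndarray (m_s, F)
        Denoised sinogram Y*.
    images : ndarray (n_pixels, F)
        MLEM reconstruction of Y*.
    initial_images : ndarray
        MLEM reconstruction of the *input* sinogram (the noisy baseline).
    converged : bool
        Whether the dual-domain criterion was met before ``t_max``.
    n_iter : int
        Number of completed filtering passes.
    history : DataFrame
        Per-pass stopping measure and per-domain relative changes.
    """

    model: "STGFModel"
    sinogram: np.ndarray
    images: np.ndarray
    initial_images: np.ndarray
    converged: bool
    n_iter: int
    history: pd.DataFrame
    mode: str
    stop_reason: str = "epsilon"
    elapsed_s: float = 0.0

    def summary(self) -> str:
        cfg = self.model.stopping
        rows = [
            ("Mode", self.mode.upper()),
            ("Sinogram bins", self.sinogram.shape[0]),
            ("Frames", self.sinogram.shape[1]),
            ("Iterations", self.n_iter),
            ("Converged", self.converged),
            ("Stop reason", self.stop_reason),
            ("Epsilon", cfg.epsilon),
            ("Weights (w1, w2)", f"({cfg.w1:g}, {cfg.w2:g})"),
            ("T_max", cfg.t_max),
            (
                "Final measure",
                f"{self.history['measure'].iloc[-1]:.6f}" if len(self.history) else "n/a",
            ),
            ("Elapsed [s]", f"{self.elapsed_s:.2f}"),
        ]
        width = 58
        lines = ["Spatio-Temporal Graph Filtering Results".center(width), "=" * width]
        lines += [f"{k + ':':<24}{v}" for k, v in rows]
        lines.append("-" * width)
        lines.append(self.history.to_string(index=False))
        lines.append("=" * width)
        return "\n".join(lines)

    def plot_convergence(self, ax=None):
        """Stopping-measure trace vs iteration (log scale)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogy(self.history["iteration"], self.history["measure"], "o-")
        ax.axhline(self.model.stopping.epsilon, ls="--", c="gray", label="epsilon")
        ax.set_xlabel("iteration")
        ax.set_ylabel("dual-domain measure")
        ax.legend()
        return ax

    def plot_frame(self, frame: int = 0, ax=None):
        """Reconstructed image for one frame."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        side = self.model.system.side
        ax.imshow(self.images[:, frame].reshape(side, side), cmap="magma")
        ax.set_title(f"frame {frame}")
        ax.axis("off")
        return ax


class STGFModel:
    """Single-scan adaptive graph-filtering denoiser for a dynamic sinogram.

    Parameters
    ----------
    sinogram : ndarray (m_s, F)
        Noisy dynamic sinogram Y(0), nonnegative counts.
    system : SystemModel
        Tomographic projector used for the MLEM feedback loop.
    background : ndarray (m_s, F) or (m_s,), optional
        Expected randoms+scatter means used in the MLEM denominator.
    schedule : FrameSchedule, optional
        Provides frame durations for duration-weighted composite frames.
    mode : {"stgf", "sgf", "tgf"}
        Full spatio-temporal filtering, spatial-only or temporal-only.
    """

    def __init__(
        self,
        sinogram: np.ndarray,
        system: SystemModel,
        background: np.ndarray | None = None,
        schedule: FrameSchedule | None = None,
        graph: GraphConfig | None = None,
        stopping: StoppingConfig | None = None,
        recon: ReconConfig | None = None,
        mode: str = "stgf",
    ) -> None:
        Y0 = np.asarray(sinogram, dtype=float)
        if Y0.ndim != 2:
            raise ValueError("sinogram must be 2-D (bins x frames)")
        if Y0.shape[0] != system.n_bins:
            raise ValueError(
                f"sinogram has {Y0.shape[0]} bins but system has {system.n_bins}"
            )
        if np.any(Y0 < 0):
            raise ValueError("sinogram must be nonnegative")
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.Y0 = Y0
        self.system = system
        self.background = background
        self.schedule = schedule
        self.graph = graph or GraphConfig()
        self.stopping = stopping or StoppingConfig()
        self.recon = recon or ReconConfig()
        self.mode = mode
        self._knn_cache = None

    @classmethod
    def from_dataset(cls, dataset, realization: int = 0, system=None, mode="stgf", **kw):
        """Build the model from a :class:`~stgf.simulate.SimulatedDataset`."""
        system = system or dataset.system()
        cfg = dataset.config
        return cls(
            dataset.noisy[realization],
            system,
            background=dataset.background,
            schedule=dataset.schedule,
            graph=kw.pop("graph", cfg.graph),
            stopping=kw.pop("stopping", cfg.stopping),
            recon=kw.pop("recon", cfg.recon),
            mode=mode,
            **kw,
        )

    # -- filter construction ---------------------------------------------

    def _spatial_filter(self, Y: np.ndarray):
        g = self.graph
        comps = make_composite_frames(Y, grouping=g.grouping, schedule=self.schedule)
        gf = spatial_knn_graph(
            comps,
            k=g.k_neighbors,
            sigma_s=g.sigma_s,
            shape=(self.system.n_angles, self.system.n_radial),
            patch_radius=g.patch_radius,
            neighbor_idx=self._knn_cache if g.cache_knn else None,
        )
        if g.cache_knn:
            self._knn_cache = gf.neighbor_idx
        return gf.F

    def _temporal_filter(self, Y: np.ndarray):
        """Temporal filter, optionally conjugated by the per-frame scales.

        Frame similarity is judged on variance-normalized frames; with
        ``scale_equalized_temporal`` the filtering itself happens in that
        same normalized space and each frame's scale is restored after,
        i.e. the effective operator is N F_T N^(-1) with N = diag(frame
        stds).  This reduces to plain F_T when all frame scales agree and
        prevents high-count late frames from flooding low-count early
        frames through small cross-scale weights.
        """
        g = self.graph
        shape = (self.system.n_angles, self.system.n_radial)
        mask = temporal_mask(Y, shape, tau=g.mask_tau, smooth_sigma=g.smooth_sigma)
        gf = temporal_graph(
            Y,
            shape,
            window=g.window,
            sigma_t=g.sigma_t,
            mask=mask,
            smooth_sigma=g.smooth_sigma,
            distance=g.temporal_distance,
        )
        if g.scale_equalized_temporal:
            s = gf.frame_scales
            return (s[:, None] * gf.F.toarray()) / s[None, :]
        return gf.F

    def _reconstruct(self, Y: np.ndarray, n_iterations: int) -> np.ndarray:
        x0 = np.where(self.system.fov, self.recon.init_value, 0.0)
        return mlem_frames(
            self.system.H,
            Y,
            r=self.background,
            n_iterations=n_iterations,
            x0=x0,
            eps=self.recon.eps,
        )

    # -- fitting ----------------------------------------------------------

    def fit(self, verbose: bool = False) -> STGFResults:
        """Run the iterative filtering loop and reconstruct the result."""
        t0 = time.perf_counter()
        m_s, F = self.Y0.shape
        eye_s = sparse.eye_array(m_s, format="csr")
        eye_t = sparse.eye_array(F, format="csr")

        Y = self.Y0.copy()
        inner = self.recon.inner
        I = self._reconstruct(Y, inner)
        initial_images = I.copy()

        rows = []
        converged = False
        stop_reason = "t_max"
        n_iter = 0
        prev_measure = np.inf
        for i in range(self.stopping.t_max):
            F_S = eye_s if self.mode == "tgf" else self._spatial_filter(Y)
            F_T = eye_t if self.mode == "sgf" else self._temporal_filter(Y)
            Y_next = apply_st_filter(Y, F_S, F_T)
            if self.graph.rescale_counts:
                col = Y.sum(axis=0)
                col_next = Y_next.sum(axis=0)
                Y_next = Y_next * np.divide(
                    col, col_next, out=np.ones_like(col), where=col_next > 0
                )[None, :]
            I_next = self._reconstruct(Y_next, inner)
            measure = stopping_measure(Y, Y_next, I, I_next, self.stopping)
            dY = float(np.linalg.norm(Y_next - Y) / max(np.linalg.norm(Y), 1e-300))
            dI = float(np.linalg.norm(I_next - I) / max(np.linalg.norm(I), 1e-300))
            if verbose:
                print(f"[{self.mode}] pass {i + 1}: measure={measure:.5f}")
            if self.stopping.stop_on_stagnation and measure >= prev_measure:
                # The pass failed to shrink the dual-domain change: the
                # contraction phase is over, so reject it and stop.
                stop_reason = "stagnation"
                break
            n_iter = i + 1
            rows.append(
                {"iteration": n_iter, "measure": measure, "rel_dY": dY, "rel_dI": dI}
            )
            Y, I = Y_next, I_next
            prev_measure = measure
            if measure < self.stopping.epsilon:
                converged = True
                stop_reason = "epsilon"
                break

        if self.recon.inner != self.recon.n_iterations:
            I = self._reconstruct(Y, self.recon.n_iterations)

        history = pd.DataFrame(rows, columns=["iteration", "measure", "rel_dY", "rel_dI"])
        return STGFResults(
            model=self,
            sinogram=Y,
            images=I,
            initial_images=initial_images,
            converged=converged,
            n_iter=n_iter,
            history=history,
            mode=self.mode,
            stop_reason=stop_reason,
            elapsed_s=time.perf_counter() - t0,
        )


def run_stgf(
    Y0: np.ndarray,
    system: SystemModel,
    background: np.ndarray | None = None,
    schedule: FrameSchedule | None = None,
    graph: GraphConfig | None = None,
    stopping: StoppingConfig | None = None,
    recon: ReconConfig | None = None,
    mode: str = "stgf",
    verbose: bool = False,
) -> STGFResults:
    """Functional entry point; equivalent to ``STGFModel(...).fit()``."""
    return STGFModel(
        Y0,
        system,
        background=background,
        schedule=schedule,
        graph=graph,
        stopping=stopping,
        recon=recon,
        mode=mode,
    ).fit(verbose=verbose)
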