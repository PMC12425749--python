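"""Data-adaptive spatial and temporal graph filters.

Both filters are symmetrically normalized adjacency matrices
F = D^(-1/2) W D^(-1/2) built from the *current* sinogram estimate:

* the spatial graph connects sinogram bins whose feature vectors — their
  values across a handful of duration-weighted composite frames — are close
  (k-nearest-neighbor sparsification, Gaussian kernel weights);
* the temporal graph connects time frames within a sliding window, with
  weights from the Gaussian kernel of the distance between pre-smoothed,
  masked, variance-normalized frames.

Self-loops of weight 1 are always retained, so every degree is positive
and the normalized filter has spectrum in [-1, 1] with top eigenpair
(1, D^(1/2) 1) on each connected component — the filter is a proper graph
low-pass operator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter
from sklearn.neighbors import NearestNeighbors

from .config import GraphConfig
from .kinetics import FrameSchedule

__all__ = [
    "CompositeFrameSet",
    "GraphFilter",
    "default_grouping",
    "make_composite_frames",
    "spatial_knn_graph",
    "temporal_mask",
    "temporal_graph",
    "normalize_filter",
]


def default_grouping(n_frames: int = 24) -> tuple[tuple[int, ...], ...]:
    """Default composite grouping (0-based): frames 1-8, 9-16, 17-20, 21-24
    of the 24-frame schedule.  For other frame counts, four contiguous
    groups of proportional size are used."""
    if n_frames == 24:
        edges = [0, 8, 16, 20, 24]
    else:
        edges = [round(n_frames * e / 24) for e in (0, 8, 16, 20, 24)]
        edges = sorted(set(int(e) for e in edges))
        if edges[0] != 0:
            edges.insert(0, 0)
        if edges[-1] != n_frames:
            edges.append(n_frames)
    return tuple(tuple(range(a, b)) for a, b in zip(edges[:-1], edges[1:]) if b > a)


@dataclass
class CompositeFrameSet:
    """Duration-weighted fusions of adjacent frames.

    ``Z`` holds the raw composites (bins x groups); ``Z_norm`` has each
    column divided by its standard deviation (columns with zero spread are
    left unscaled).
    """

    Z: np.ndarray
    Z_norm: np.ndarray
    grouping: tuple[tuple[int, ...], ...]
    weights: tuple[tuple[float, ...], ...]

    @property
    def n_groups(self) -> int:
        return self.Z.shape[1]


@dataclass
class GraphFilter:
    """Sparse symmetric adjacency with its normalized low-pass filter."""

    W: sparse.csr_array
    degrees: np.ndarray
    F: sparse.csr_array
    sigma: float
    neighbor_idx: np.ndarray | None = None
    frame_scales: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    def export(self, path: str | Path, **meta) -> None:
        """Write W in coordinate text format plus a JSON sidecar."""
        path = Path(path)
        coo = self.W.tocoo()
        np.savetxt(
            path,
            np.column_stack([coo.row, coo.col, coo.data]),
            fmt="%d %d %.12g",
            header=f"{self.n_nodes} {self.n_nodes} {coo.nnz}",
        )
        sidecar = {"n_nodes": int(self.n_nodes), "sigma": self.sigma, **meta}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def normalize_filter(W: sparse.sparray | np.ndarray) -> sparse.csr_array:
    """Symmetric normalization F = D^(-1/2) W D^(-1/2).

    ``W`` must be symmetric and nonnegative with strictly positive degrees
    (guaranteed when self-loops are present).
    """
    Wc = sparse.csr_array(W)
    if Wc.shape[0] != Wc.shape[1]:
        raise ValueError("W must be square")
    if (abs(Wc - Wc.T)).max() > 1e-10:
        raise ValueError("W must be symmetric")
    if Wc.nnz and Wc.data.min() < 0:
        raise ValueError("W must be nonnegative")
    d = np.asarray(Wc.sum(axis=1)).ravel()
    if np.any(d <= 0):
        raise ValueError("zero-degree node: add self-loops before normalizing")
    dm = sparse.dia_array((1.0 / np.sqrt(d)[None, :], [0]), shape=Wc.shape)
    return sparse.csr_array(dm @ Wc @ dm)


def _finish(W: sparse.csr_array, sigma: float) -> GraphFilter:
    d = np.asarray(W.sum(axis=1)).ravel()
    return GraphFilter(W=W, degrees=d, F=normalize_filter(W), sigma=sigma)


def make_composite_frames(
    Y: np.ndarray,
    grouping: tuple[tuple[int, ...], ...] | None = None,
    weights=None,
    schedule: FrameSchedule | None = None,
) -> CompositeFrameSet:
    """Fuse adjacent frames into composite frames and variance-normalize.

    Weights within each group default to the member frames' durations
    (count-weighted fusion, matching Poisson statistics) when a schedule
    is given, else to uniform; they are normalized to sum to one.
    """
    Y = np.asarray(Y, dtype=float)
    n_frames = Y.shape[1]
    if grouping is None:
        grouping = default_grouping(n_frames)
    norm_weights: list[tuple[float, ...]] = []
    cols = []
    for g, members in enumerate(grouping):
        members = tuple(int(m) for m in members)
        if len(members) == 0:
            raise ValueError(f"composite group {g} is empty")
        if min(members) < 0 or max(members) >= n_frames:
            raise ValueError(f"group {g} indexes frames outside 0..{n_frames - 1}")
        if weights is not None:
            w = np.asarray(weights[g], dtype=float)
        elif schedule is not None:
            w = np.asarray(schedule.durations)[list(members)]
        else:
            w = np.ones(len(members))
        w = w / w.sum()
        norm_weights.append(tuple(w))
        cols.append(Y[:, list(members)] @ w)
    Z = np.column_stack(cols)

    std = Z.std(axis=0)
    Z_norm = Z / np.where(std > 0, std, 1.0)[None, :]
    return CompositeFrameSet(
        Z=Z, Z_norm=Z_norm, grouping=tuple(tuple(m) for m in grouping),
        weights=tuple(norm_weights),
    )


def _patch_features(Z: np.ndarray, shape: tuple[int, int], radius: int) -> np.ndarray:
    """Concatenate the local (2r+1)^2 patch of each composite frame per bin."""
    n_ang, n_rad = shape
    G = Z.shape[1]
    imgs = Z.T.reshape(G, n_ang, n_rad)
    pads = np.pad(imgs, ((0, 0), (radius, radius), (radius, radius)), mode="reflect")
    feats = []
    for dy in range(2 * radius + 1):
        for dx in range(2 * radius + 1):
            feats.append(pads[:, dy : dy + n_ang, dx : dx + n_rad].reshape(G, -1))
    return np.concatenate(feats, axis=0).T


def spatial_knn_graph(
    composites: CompositeFrameSet | np.ndarray,
    k: int = 80,
    sigma_s: float = 0.5,
    shape: tuple[int, int] | None = None,
    patch_radius: int = 0,
    neighbor_idx: np.ndarray | None = None,
) -> GraphFilter:
    """Sparse spatial similarity graph over sinogram bins.

    Each bin's feature vector is its row of the variance-normalized
    composite-frame matrix (optionally augmented with a local patch
    context when ``patch_radius > 0``).  The k nearest neighbors by
    Euclidean distance are retained with Gaussian-kernel weights
    w = exp(-||z_m - z_n||^2 / sigma_s^2); the graph is symmetrized by
    elementwise maximum and unit self-loops are added.
    """
    if sigma_s <= 0:
        raise ValueError("sigma_s must be positive")
    Z = composites.Z_norm if isinstance(composites, CompositeFrameSet) else np.asarray(composites, float)
    n = Z.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of nodes ({n})")
    if patch_radius > 0:
        if shape is None:
            raise ValueError("patch features require the sinogram shape")
        Z = _patch_features(Z, shape, patch_radius)

    # k+1 neighbors including the node itself; the self entry (distance 0)
    # is dropped and re-added as an explicit unit self-loop.  A cached
    # neighbor index (opt-in approximation) skips the search and only
    # recomputes the kernel weights from the current features.
    if neighbor_idx is None:
        nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute").fit(Z)
        dist, idx = nn.kneighbors(Z)
    else:
        idx = np.asarray(neighbor_idx)
        dist = np.linalg.norm(Z[:, None, :] - Z[idx, :], axis=2)
    rows = np.repeat(np.arange(n), k + 1)
    cols = idx.ravel()
    vals = np.exp(-(dist.ravel() ** 2) / sigma_s**2)
    keep = rows != cols
    W = sparse.coo_array((vals[keep], (rows[keep], cols[keep])), shape=(n, n)).tocsr()
    W = W.maximum(W.T)
    W = W.maximum(sparse.eye_array(n, format="csr"))
    gf = _finish(sparse.csr_array(W), sigma_s)
    gf.neighbor_idx = idx
    return gf


def temporal_mask(
    Y: np.ndarray,
    shape: tuple[int, int],
    tau: float = 0.1,
    smooth_sigma: float = 0.85,
) -> np.ndarray:
    """High-activity bin mask for the temporal similarity measure.

    Each frame is pre-smoothed with a 3x3 Gaussian kernel (reflect edges);
    bins whose time-summed smoothed value exceeds ``tau`` times the maximum
    of that sum are kept.  An empty mask falls back to all bins with a
    warning.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    smoothed = _smooth_frames(Y, shape, smooth_sigma)
    total = smoothed.sum(axis=1)
    mask = total > tau * total.max()
    if not mask.any():
        warnings.warn("temporal mask empty: falling back to all bins")
        mask = np.ones_like(mask)
    return mask


def _smooth_frames(Y: np.ndarray, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """3x3 Gaussian pre-smoothing of each frame (radius-1 truncation)."""
    Y = np.asarray(Y, dtype=float)
    n_ang, n_rad = shape
    out = np.empty_like(Y)
    for f in range(Y.shape[1]):
        out[:, f] = gaussian_filter(
            Y[:, f].reshape(n_ang, n_rad), sigma=sigma, mode="reflect", radius=1
        ).ravel()
    return out


def temporal_graph(
    Y: np.ndarray,
    shape: tuple[int, int],
    window: int = 9,
    sigma_t: float = 1.0,
    mask: np.ndarray | None = None,
    tau: float = 0.1,
    smooth_sigma: float = 0.85,
    distance: str = "mean",
) -> GraphFilter:
    """Temporal similarity graph over time frames.

    Frames p, q with |p - q| <= (window-1)/2 are connected with weight
    exp(-d(p, q) / sigma_t^2), where d is the squared Euclidean distance
    between the pre-smoothed, masked, per-frame variance-normalized frames
    (``distance="mean"`` divides by the number of masked bins so sigma_t
    stays order-one regardless of mask size; ``"sum"`` uses the raw norm).
    The window is truncated at the sequence ends; unit self-loops added.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if sigma_t <= 0:
        raise ValueError("sigma_t must be positive")
    if distance not in ("mean", "sum"):
        raise ValueError("distance must be 'mean' or 'sum'")

    Y = np.asarray(Y, dtype=float)
    n_frames = Y.shape[1]
    smoothed = _smooth_frames(Y, shape, smooth_sigma)
    if mask is None:
        mask = temporal_mask(Y, shape, tau=tau, smooth_sigma=smooth_sigma)
    V = smoothed[mask, :]
    std = V.std(axis=0)
    V = V / np.where(std > 0, std, 1.0)[None, :]

    half = (window - 1) // 2
    W = np.zeros((n_frames, n_frames))
    for p in range(n_frames):
        for q in range(max(0, p - half), min(n_frames, p + half + 1)):
            d2 = float(np.sum((V[:, p] - V[:, q]) ** 2))
            if distance == "mean":
                d2 /= V.shape[0]
            W[p, q] = np.exp(-d2 / sigma_t**2)
    np.fill_diagonal(W, 1.0)
    W = np.maximum(W, W.T)
    gf = _finish(sparse.csr_array(W), sigma_t)
    gf.frame_scales = np.where(std > 0, std, 1.0)
    return gf
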