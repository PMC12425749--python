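"""Parallel-beam system model and MLEM reconstruction.

The system matrix H implements Siddon-style length-weighted line integrals:
entry (i, j) is the intersection length of ray i with pixel j.  Rays are
organized as ``n_angles`` uniform view angles on [0, pi), each with
``n_radial`` unit-spaced parallel rays centered on the image.  Because H is
an explicit sparse matrix, backprojection is its exact transpose and the
adjoint identity holds to machine precision.

MLEM is the standard multiplicative Poisson maximum-likelihood update

    x <- x * ( H^T( p / (H x + r) ) ) / ( H^T 1 )

with an additive background/randoms term r and denominators guarded at a
small epsilon.  The per-frame update is vectorized across all time frames
of a dynamic sequence, which share one system matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse

__all__ = [
    "SystemModel",
    "build_system_matrix",
    "forward",
    "backproject",
    "mlem",
    "mlem_frames",
    "poisson_loglik",
]

_LENGTH_TOL = 1e-9


def _angle_rays(
    theta: float, offsets: np.ndarray, side: int, lines: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """COO entries (ray index, pixel index, length) for one view angle."""
    half = side / 2.0
    ct, st = np.cos(theta), np.sin(theta)
    # Ray: p(t) = (rho*ct - t*st, rho*st + t*ct)
    px, py = offsets * ct, offsets * st
    dx, dy = -st, ct

    def slab(p0, d):
        if abs(d) > 1e-12:
            t1, t2 = (-half - p0) / d, (half - p0) / d
            return np.minimum(t1, t2), np.maximum(t1, t2)
        inside = np.abs(p0) <= half
        lo = np.where(inside, -np.inf, np.inf)
        hi = np.where(inside, np.inf, -np.inf)
        return lo, hi

    xlo, xhi = slab(px, dx)
    ylo, yhi = slab(py, dy)
    t_lo = np.maximum(xlo, ylo)
    t_hi = np.minimum(xhi, yhi)
    hits = t_hi > t_lo
    t_lo = np.where(hits, t_lo, 0.0)
    t_hi = np.where(hits, t_hi, 0.0)

    crossings = [t_lo[:, None], t_hi[:, None]]
    if abs(dx) > 1e-12:
        crossings.append((lines[None, :] - px[:, None]) / dx)
    if abs(dy) > 1e-12:
        crossings.append((lines[None, :] - py[:, None]) / dy)
    ts = np.concatenate(crossings, axis=1)
    ts = np.clip(ts, t_lo[:, None], t_hi[:, None])
    ts.sort(axis=1)

    lens = np.diff(ts, axis=1)
    mids = 0.5 * (ts[:, 1:] + ts[:, :-1])
    mx = px[:, None] + mids * dx
    my = py[:, None] + mids * dy
    cols = np.floor(mx + half).astype(np.int64)
    rows = np.floor(my + half).astype(np.int64)
    ok = (
        (lens > _LENGTH_TOL)
        & (cols >= 0)
        & (cols < side)
        & (rows >= 0)
        & (rows < side)
    )
    ray_idx = np.broadcast_to(np.arange(offsets.size)[:, None], lens.shape)
    pix = rows * side + cols
    return ray_idx[ok], pix[ok], lens[ok]


def build_system_matrix(
    image_side: int, n_angles: int, n_radial: int
) -> "SystemModel":
    """Construct the sparse Siddon projector for the given geometry.

    Parameters
    ----------
    image_side : int
        Image is ``image_side x image_side`` unit pixels.
    n_angles : int
        Number of uniform view angles on [0, pi).
    n_radial : int
        Number of unit-spaced radial bins per angle, centered on the image.

    Returns
    -------
    SystemModel
        With ``H`` of shape (n_angles*n_radial, image_side**2).
    """
    if image_side < 1 or n_angles < 1 or n_radial < 1:
        raise ValueError("all geometry dimensions must be >= 1")

    offsets = np.arange(n_radial, dtype=float) - (n_radial - 1) / 2.0
    lines = np.arange(image_side + 1, dtype=float) - image_side / 2.0
    angles = np.pi * np.arange(n_angles) / n_angles

    rows_all, cols_all, vals_all = [], [], []
    for a, theta in enumerate(angles):
        r, c, v = _angle_rays(theta, offsets, image_side, lines)
        rows_all.append(r + a * n_radial)
        cols_all.append(c)
        vals_all.append(v)

    H = sparse.coo_array(
        (
            np.concatenate(vals_all),
            (np.concatenate(rows_all), np.concatenate(cols_all)),
        ),
        shape=(n_angles * n_radial, image_side * image_side),
    ).tocsr()
    H.sum_duplicates()
    return SystemModel(H=H, side=image_side, n_angles=n_angles, n_radial=n_radial)


@dataclass
class SystemModel:
    """Sparse tomographic projector with geometry and sensitivity."""

    H: sparse.csr_array
    side: int
    n_angles: int
    n_radial: int

    def __post_init__(self) -> None:
        self.sensitivity = np.asarray(self.H.T @ np.ones(self.H.shape[0]))
        c = (self.side - 1) / 2.0
        yy, xx = np.mgrid[0 : self.side, 0 : self.side].astype(float)
        disk = (xx - c) ** 2 + (yy - c) ** 2 <= (self.side / 2.0) ** 2
        self.fov = disk.ravel() & (self.sensitivity > 0)

    @property
    def n_bins(self) -> int:
        return self.H.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.H.shape[1]

    def forward(self, image: np.ndarray) -> np.ndarray:
        return forward(self, image)

    def backproject(self, sinogram: np.ndarray) -> np.ndarray:
        return backproject(self, sinogram)

    def mlem(self, p, r=None, n_iterations=100, **kw) -> np.ndarray:
        """MLEM with the model's default FOV-disk initialization."""
        x0 = kw.pop("x0", None)
        if x0 is None:
            x0 = np.where(self.fov, 1.0, 0.0)
        return mlem(self.H, p, r=r, n_iterations=n_iterations, x0=x0, **kw)


def forward(system: SystemModel, image: np.ndarray) -> np.ndarray:
    """Forward-project image(s): columns of shape (n_pixels,) or (n_pixels, F)."""
    img = np.asarray(image, dtype=float)
    if img.shape == (system.side, system.side):
        img = img.ravel()
    if img.shape[0] != system.n_pixels:
        raise ValueError(
            f"image has {img.shape[0]} pixels, system expects {system.n_pixels}"
        )
    return np.asarray(system.H @ img)


def backproject(system: SystemModel, sinogram: np.ndarray) -> np.ndarray:
    """Apply the exact transpose H^T to sinogram(s)."""
    sino = np.asarray(sinogram, dtype=float)
    if sino.shape[0] != system.n_bins:
        raise ValueError(
            f"sinogram has {sino.shape[0]} bins, system expects {system.n_bins}"
        )
    return np.asarray(system.H.T @ sino)


def _as_operator(H):
    if sparse.issparse(H):
        return H
    return np.asarray(H, dtype=float)


def mlem(
    H,
    p: np.ndarray,
    r=None,
    n_iterations: int = 100,
    x0: np.ndarray | None = None,
    eps: float = 1e-12,
) -> np.ndarray:
    """Single-frame MLEM; see :func:`mlem_frames` for the dynamic version."""
    p = np.asarray(p, dtype=float).ravel()
    out = mlem_frames(H, p[:, None], r=None if r is None else np.asarray(r, dtype=float).ravel()[:, None],
                      n_iterations=n_iterations,
                      x0=None if x0 is None else np.asarray(x0, dtype=float).ravel()[:, None],
                      eps=eps)
    return out[:, 0]


def mlem_frames(
    H,
    P: np.ndarray,
    r=None,
    n_iterations: int = 100,
    x0: np.ndarray | None = None,
    eps: float = 1e-12,
) -> np.ndarray:
    """MLEM reconstruction of a dynamic sequence, vectorized over frames.

    Parameters
    ----------
    H : sparse or dense matrix, (m_s, n)
        System matrix shared by all frames.
    P : ndarray, (m_s, F)
        Measured sinogram counts per frame; must be >= 0.
    r : ndarray (m_s, F) or (m_s,) or None
        Expected background (randoms + scatter) per bin; None means zero.
    x0 : ndarray (n, F) or (n,) or None
        Initial image; defaults to ones.  Pixels with zero sensitivity or
        zero initial value remain zero (multiplicative update).
    """
    H = _as_operator(H)
    m, n = H.shape
    P = np.asarray(P, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    if P.shape[0] != m:
        raise ValueError(f"sinogram has {P.shape[0]} bins, H expects {m}")
    if np.any(P < 0):
        raise ValueError("sinogram counts must be nonnegative")
    F = P.shape[1]

    if r is None:
        R = np.zeros((m, F))
    else:
        R = np.asarray(r, dtype=float)
        R = np.broadcast_to(R[:, None] if R.ndim == 1 else R, (m, F)).copy()
    if np.any(R < 0):
        raise ValueError("background must be nonnegative")

    if x0 is None:
        X = np.ones((n, F))
    else:
        X = np.asarray(x0, dtype=float)
        X = np.broadcast_to(X[:, None] if X.ndim == 1 else X, (n, F)).astype(float).copy()

    sens = np.asarray(H.T @ np.ones(m)).ravel()
    X[sens <= 0, :] = 0.0

    if P.sum() == 0 and R.sum() == 0:
        warnings.warn("all-zero sinogram with zero background: returning zero image")
        return np.zeros((n, F))

    denom = np.maximum(sens, eps)[:, None]
    for _ in range(n_iterations):
        proj = np.asarray(H @ X) + R
        ratio = P / np.maximum(proj, eps)
        X = X * np.asarray(H.T @ ratio) / denom
    return X


def poisson_loglik(p: np.ndarray, expected: np.ndarray, eps: float = 1e-12) -> float:
    """Poisson log-likelihood sum(p*log(lambda) - lambda), up to constants."""
    lam = np.maximum(np.asarray(expected, dtype=float), eps)
    p = np.asarray(p, dtype=float)
    return float(np.sum(p * np.log(lam) - lam))
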