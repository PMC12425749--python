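"""Evaluation metrics: normalized MSE, bias/variance, MAE, SSIM, CNR.

Conventions:

* ``mse`` is normalized by the energy of the truth,
  sum((x - x_true)^2) / sum(x_true^2), optionally reported in percent;
* ``bias_variance`` follows the ensemble definitions over O noisy
  realizations, both normalized by the truth;
* ``mae`` is a plain mean absolute deviation over a (region) mask;
* ``ssim`` is the mean local structural-similarity index with uniform
  square windows and the standard stabilization constants
  C1 = (0.01 L)^2, C2 = (0.03 L)^2 where L is the truth's dynamic range.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .phantom import Phantom

__all__ = [
    "mse",
    "bias_variance",
    "mae",
    "ssim",
    "region_masks",
    "contrast_noise",
    "evaluate_images",
    "region_mae_table",
]


def mse(x: np.ndarray, x_true: np.ndarray, as_percent: bool = False) -> float:
    """Truth-normalized mean squared error sum((x-xt)^2)/sum(xt^2)."""
    x = np.asarray(x, dtype=float)
    xt = np.asarray(x_true, dtype=float)
    if x.shape != xt.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xt.shape}")
    denom = float(np.sum(xt**2))
    if denom == 0:
        raise ValueError("x_true must not be identically zero")
    val = float(np.sum((x - xt) ** 2) / denom)
    return 100.0 * val if as_percent else val


def bias_variance(
    realizations: np.ndarray, x_true: np.ndarray
) -> tuple[float, float]:
    """Ensemble bias and variance over O realizations.

    Bias = sum_j(mean_i x_j^i - x_j^true) / sum_j x_j^true;
    Var  = (1/O) sum_i sum_j (x_j^i - mean_i x_j^i)^2 / sum_j (x_j^true)^2.
    """
    X = np.asarray(realizations, dtype=float)
    xt = np.asarray(x_true, dtype=float)
    if X.ndim < 2 or X.shape[1:] != xt.shape:
        raise ValueError("realizations must be stacked along axis 0 over x_true's shape")
    O = X.shape[0]
    if O < 1:
        raise ValueError("need at least one realization")
    mean = X.mean(axis=0)
    denom_b = float(np.sum(xt))
    denom_v = float(np.sum(xt**2))
    if denom_b == 0 or denom_v == 0:
        raise ValueError("x_true must not be identically zero")
    bias = float(np.sum(mean - xt) / denom_b)
    var = float(np.sum((X - mean[None]) ** 2) / O / denom_v)
    return bias, var


def mae(x: np.ndarray, x_true: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Mean absolute deviation, optionally restricted to a region mask."""
    x = np.asarray(x, dtype=float)
    xt = np.asarray(x_true, dtype=float)
    if x.shape != xt.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xt.shape}")
    diff = np.abs(x - xt)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != x.shape:
            raise ValueError("mask shape must match the images")
        if not mask.any():
            raise ValueError("empty region mask")
        diff = diff[mask]
    return float(diff.mean())


def ssim(
    x: np.ndarray,
    x_true: np.ndarray,
    win_size: int = 8,
    data_range: float | None = None,
    sample_covariance: bool = False,
) -> float:
    """Mean local SSIM with uniform ``win_size`` x ``win_size`` windows.

    ``data_range`` defaults to max(x_true) - min(x_true); when the pair is
    constant (range 0) the stabilization constants fall back to a unit
    range so the result is defined (1 for identical images).
    """
    x = np.asarray(x, dtype=float)
    xt = np.asarray(x_true, dtype=float)
    if x.shape != xt.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xt.shape}")
    if min(x.shape) < win_size:
        raise ValueError("images smaller than the SSIM window")
    L = float(np.ptp(xt)) if data_range is None else float(data_range)
    if L <= 0:
        L = 1.0
    C1, C2 = (0.01 * L) ** 2, (0.03 * L) ** 2

    filt = lambda a: uniform_filter(a, size=win_size)  # noqa: E731
    mu_x, mu_y = filt(x), filt(xt)
    mu_xx, mu_yy, mu_xy = filt(x * x), filt(xt * xt), filt(x * xt)
    vx = mu_xx - mu_x**2
    vy = mu_yy - mu_y**2
    cov = mu_xy - mu_x * mu_y
    if sample_covariance:
        npix = win_size ** x.ndim
        corr = npix / (npix - 1)
        vx, vy, cov = corr * vx, corr * vy, corr * cov

    S = ((2 * mu_x * mu_y + C1) * (2 * cov + C2)) / (
        (mu_x**2 + mu_y**2 + C1) * (vx + vy + C2)
    )
    pad = (win_size - 1) // 2
    crop = tuple(slice(pad, s - pad) for s in S.shape)
    return float(S[crop].mean())


def region_masks(phantom: Phantom) -> dict[str, np.ndarray]:
    """Flattened boolean pixel masks per named phantom region.

    The lesion is reported under the conventional name ``tumor``.
    """
    renames = {"lesion": "tumor"}
    out = {}
    for code, name in sorted(phantom.region_names.items()):
        out[renames.get(name, name)] = phantom.region_mask(code).ravel()
    return out


def contrast_noise(
    image: np.ndarray, roi_box: tuple[slice, slice], bg_box: tuple[slice, slice]
) -> tuple[float, float]:
    """ROI mean and normalized background noise for contrast-noise curves.

    Returns (mean over ``roi_box``, std over ``bg_box`` divided by its
    mean).  Boxes are (row, column) slices into the 2-D image.
    """
    img = np.asarray(image, dtype=float)
    roi = img[roi_box]
    bg = img[bg_box]
    bg_mean = bg.mean()
    if bg_mean == 0:
        raise ValueError("background box has zero mean")
    return float(roi.mean()), float(bg.std() / bg_mean)


def evaluate_images(
    images: np.ndarray, truth: np.ndarray, side: int
) -> pd.DataFrame:
    """Per-frame image metrics (MSE %, SSIM) for one reconstruction stack."""
    F = images.shape[1]
    rows = []
    for f in range(F):
        img = images[:, f].reshape(side, side)
        tru = truth[:, f].reshape(side, side)
        rows.append(
            {
                "frame": f + 1,
                "mse_pct": mse(img, tru, as_percent=True),
                "ssim": ssim(img, tru),
            }
        )
    return pd.DataFrame(rows)


def region_mae_table(
    images_by_method: dict[str, np.ndarray],
    truth: np.ndarray,
    phantom: Phantom,
) -> pd.DataFrame:
    """Per-region MAE averaged over frames for several methods.

    MAE is computed frame by frame on the (n_pixels, F) stacks, then
    averaged over frames; rows are regions, columns are methods.
    """
    masks = region_masks(phantom)
    F = truth.shape[1]
    table = {}
    for method, imgs in images_by_method.items():
        col = {}
        for region, m in masks.items():
            vals = [mae(imgs[:, f], truth[:, f], m) for f in range(F)]
            col[region] = float(np.mean(vals))
        table[method] = col
    return pd.DataFrame(table)
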