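"""Parametric head phantom with background, gray, white and lesion regions.

The phantom is a Zubal-style look-alike built from simple analytic shapes:
an elliptical head/brain outline, a gray-matter shell, a white-matter core
and a small square lesion centered on the grid.  The label map can be
replaced wholesale (``Phantom(label_grid=...)``) if a real atlas is
available; nothing downstream depends on how the labels were produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PhantomConfig

__all__ = ["REGION_CODES", "Phantom", "make_phantom"]

#: Region code assignment; codes partition the grid.
REGION_CODES: dict[str, int] = {"background": 0, "gray": 1, "white": 2, "lesion": 3}


@dataclass
class Phantom:
    """Labeled activity grid.

    Attributes
    ----------
    label_grid : ndarray of int, shape (side, side)
        One region code per pixel (codes partition the grid).
    region_names : dict
        Mapping from integer code to region name.
    pixel_size : float
        Pixel edge length in arbitrary length units.
    """

    label_grid: np.ndarray
    region_names: dict[int, str] = field(
        default_factory=lambda: {v: k for k, v in REGION_CODES.items()}
    )
    pixel_size: float = 1.0

    @property
    def side(self) -> int:
        return self.label_grid.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.label_grid.size

    def region_mask(self, region: str | int) -> np.ndarray:
        """Boolean mask of the named (or coded) region."""
        if isinstance(region, str):
            codes = {v: k for k, v in self.region_names.items()}
            if region not in codes:
                raise KeyError(f"unknown region {region!r}; have {sorted(codes)}")
            region = codes[region]
        return self.label_grid == region

    def region_counts(self) -> dict[str, int]:
        return {
            name: int(np.count_nonzero(self.label_grid == code))
            for code, name in sorted(self.region_names.items())
        }


def make_phantom(
    side: int = 111,
    lesion_side: int = 5,
    config: PhantomConfig | None = None,
) -> Phantom:
    """Build the parametric head phantom.

    Parameters
    ----------
    side : int
        Grid side in pixels; must be odd and positive so the lesion
        centers exactly on the middle pixel.
    lesion_side : int
        Side of the central square lesion; odd, ``1 <= lesion_side <= side``.
    config : PhantomConfig, optional
        Overrides geometry fractions (and, if given, side/lesion_side).

    Returns
    -------
    Phantom
        Label grid with background (0) outside the brain ellipse, a
        gray-matter shell (1), a white-matter core (2) and the lesion (3)
        overwriting the core center.
    """
    if config is not None:
        side = config.side
        lesion_side = config.lesion_side
        outer_axes = config.outer_axes
        inner_scale = config.inner_scale
    else:
        outer_axes = PhantomConfig.outer_axes
        inner_scale = PhantomConfig.inner_scale

    for name, v in (("side", side), ("lesion_side", lesion_side)):
        if v < 1:
            raise ValueError(f"{name} must be positive, got {v}")
        if v % 2 == 0:
            raise ValueError(
                f"{name} must be odd so the lesion centers exactly, got {v}"
            )
    if lesion_side > side:
        raise ValueError("lesion_side cannot exceed side")

    c = (side - 1) / 2.0
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    rx, ry = outer_axes[0] * side, outer_axes[1] * side
    outer = ((xx - c) / rx) ** 2 + ((yy - c) / ry) ** 2 <= 1.0
    inner = ((xx - c) / (inner_scale * rx)) ** 2 + (
        (yy - c) / (inner_scale * ry)
    ) ** 2 <= 1.0

    labels = np.zeros((side, side), dtype=np.int64)
    labels[outer] = REGION_CODES["gray"]
    labels[inner] = REGION_CODES["white"]

    half = (lesion_side - 1) // 2
    lo, hi = int(c) - half, int(c) + half + 1
    labels[lo:hi, lo:hi] = REGION_CODES["lesion"]

    return Phantom(label_grid=labels)
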