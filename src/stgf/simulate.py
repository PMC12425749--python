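"""Dynamic-PET simulation: ground-truth frames, count noise, full datasets.

The simulator follows a fixed protocol: populate the phantom regions with
compartment-model TACs, frame-average them onto the acquisition schedule,
forward-project each frame and weight by frame duration to obtain
noise-free count sinograms, then corrupt in two stages — (1) add a uniform
randoms+scatter background worth a fixed fraction of the true counts,
(2) rescale everything to a fixed total number of expected counts and draw
Poisson counts per bin.  Repeating the draw with independent sub-seeds
yields a set of independent noisy realizations sharing one expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import NoiseConfig, RunConfig
from .kinetics import FrameSchedule, frame_integrate, input_function, solve_tissue_tac
from .phantom import Phantom, make_phantom
from .projection import SystemModel, build_system_matrix

__all__ = [
    "SimulatedDataset",
    "build_activity_frames",
    "corrupt",
    "simulate_dataset",
]


def build_activity_frames(
    phantom: Phantom, region_frame_activities: dict[int | str, np.ndarray]
) -> np.ndarray:
    """Paint per-region frame activities onto the phantom grid.

    Parameters
    ----------
    phantom : Phantom
    region_frame_activities : dict
        Region code (or name) -> per-frame activity vector, one entry for
        every region code present in the phantom.

    Returns
    -------
    ndarray, (n_pixels, n_frames)
        Pixel (j, f) carries the activity of pixel j's region at frame f.
    """
    name_to_code = {v: k for k, v in phantom.region_names.items()}
    by_code: dict[int, np.ndarray] = {}
    for key, tac in region_frame_activities.items():
        code = name_to_code[key] if isinstance(key, str) else int(key)
        by_code[code] = np.asarray(tac, dtype=float)

    codes_present = np.unique(phantom.label_grid)
    missing = [int(c) for c in codes_present if int(c) not in by_code]
    if missing:
        names = [phantom.region_names.get(c, str(c)) for c in missing]
        raise ValueError(f"missing frame activities for region(s): {names}")

    n_frames = len(next(iter(by_code.values())))
    out = np.zeros((phantom.n_pixels, n_frames))
    labels = phantom.label_grid.ravel()
    for code, tac in by_code.items():
        if len(tac) != n_frames:
            raise ValueError("all regions must have the same number of frames")
        out[labels == code, :] = tac[None, :]
    if np.any(out < 0):
        raise ValueError("activities must be nonnegative")
    return out


def corrupt(
    noise_free: np.ndarray,
    config: NoiseConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply the two-stage count-noise model to noise-free sinograms.

    Stage 1 adds a background ``r`` that is uniform across bins within each
    frame and apportioned across frames proportionally to each frame's true
    counts, so that sum(r) = background_fraction * sum(trues) exactly.
    Stage 2 rescales trues + background globally so the total expectation
    equals ``total_counts``, then draws one Poisson realization.

    Returns
    -------
    expected : ndarray, same shape as input
        Scaled expected counts (trues + background).
    background : ndarray
        Scaled background means r, suitable as the MLEM ``r`` term.
    noisy : ndarray of int
        One Poisson realization with mean ``expected``.
    """
    if config is None:
        config = NoiseConfig()
    T = np.asarray(noise_free, dtype=float)
    if np.any(T < 0):
        raise ValueError("noise-free sinograms must be nonnegative")
    total_trues = T.sum()
    if total_trues <= 0:
        raise ValueError("zero total activity: cannot scale counts")

    m_s = T.shape[0]
    frame_trues = T.sum(axis=0)
    r = np.broadcast_to(
        config.background_fraction * frame_trues / m_s, T.shape
    ).copy()

    scale = config.total_counts / (total_trues + r.sum())
    expected = scale * (T + r)
    background = scale * r

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = rng.poisson(expected)
    return expected, background, noisy


@dataclass
class SimulatedDataset:
    """Container for one simulated dynamic-PET study.

    Shapes: ``truth_activity``/``truth_scaled`` are (n_pixels, F),
    sinogram members are (m_s, F), ``noisy`` is (R, m_s, F).
    ``truth_scaled`` is the activity image expressed in the same scaled
    count units as the sinograms (activity * frame duration * global
    scale), i.e. the ground truth that MLEM reconstructions estimate.
    """

    phantom: Phantom
    schedule: FrameSchedule
    truth_activity: np.ndarray
    truth_scaled: np.ndarray
    noise_free: np.ndarray
    expected: np.ndarray
    background: np.ndarray
    noisy: np.ndarray
    scale: float
    seeds: tuple[int, ...]
    config: RunConfig
    results: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_realizations(self) -> int:
        return self.noisy.shape[0]

    def system(self) -> SystemModel:
        """Rebuild the (deterministic) system matrix for this geometry."""
        g = self.config.geometry
        return build_system_matrix(self.phantom.side, g.n_angles, g.n_radial)


def simulate_dataset(
    config: RunConfig | None = None,
    seed: int | None = None,
    system: SystemModel | None = None,
    seeds: tuple[int, ...] | None = None,
) -> SimulatedDataset:
    """Run the full simulation protocol.

    Parameters
    ----------
    config : RunConfig
        Defaults to :meth:`RunConfig.default` (111x111 phantom,
        24-frame/3600 s schedule, 20% background, 8e6 counts,
        20 realizations).
    seed : int
        Master seed; per-realization sub-seeds are spawned from it
        deterministically.  Defaults to ``config.seed``.
    system : SystemModel, optional
        Reuse a prebuilt projector (must match the configured geometry).
    seeds : tuple of int, optional
        Explicit per-realization seeds (overrides spawning); duplicates
        are warned about since they produce identical realizations.
    """
    if config is None:
        config = RunConfig.default()
    if seed is None:
        seed = config.seed

    phantom = make_phantom(config=config.phantom)
    schedule = FrameSchedule.from_segments(config.schedule_segments)

    # Dense kinetic grid: 1.5 s sampling over the scan (in minutes).
    t_end = schedule.total_seconds / 60.0
    t_fine = np.linspace(0.0, t_end, int(schedule.total_seconds / 1.5) + 1)
    cp = lambda t: input_function(t, config.input_function)  # noqa: E731

    frame_acts: dict[str, np.ndarray] = {}
    for region, params in config.kinetics.items():
        tac = solve_tissue_tac(params, cp, t_fine)
        frame_acts[region] = frame_integrate(t_fine, tac, schedule)

    truth_activity = build_activity_frames(phantom, frame_acts)

    if system is None:
        system = build_system_matrix(
            phantom.side, config.geometry.n_angles, config.geometry.n_radial
        )
    elif system.side != phantom.side:
        raise ValueError("system geometry does not match phantom side")

    durations_s = np.asarray(schedule.durations)
    noise_free = np.asarray(system.H @ truth_activity) * durations_s[None, :]

    R = config.noise.n_realizations
    if seeds is None:
        ss = np.random.SeedSequence(seed)
        seeds = tuple(int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(R))
    else:
        seeds = tuple(int(s) for s in seeds)
        if len(seeds) != R:
            raise ValueError(f"need {R} seeds, got {len(seeds)}")
        if len(set(seeds)) != len(seeds):
            warnings.warn("duplicate seeds: realizations will be identical")

    expected = background = None
    noisy = np.empty((R,) + noise_free.shape, dtype=np.int64)
    for i, s in enumerate(seeds):
        expected, background, noisy[i] = corrupt(noise_free, config.noise, seed=s)

    scale = float(config.noise.total_counts / (noise_free.sum() * (1 + config.noise.background_fraction)))
    truth_scaled = truth_activity * durations_s[None, :] * scale

    return SimulatedDataset(
        phantom=phantom,
        schedule=schedule,
        truth_activity=truth_activity,
        truth_scaled=truth_scaled,
        noise_free=noise_free,
        expected=expected,
        background=background,
        noisy=noisy,
        scale=scale,
        seeds=seeds,
        config=config,
    )
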