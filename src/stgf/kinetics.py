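"""Tracer kinetics: input function, compartment model, frame integration.

Regional time-activity curves (TACs) are produced by the two-tissue
(three-compartment) model

    dC1/dt = K1*Cp(t) - (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 - k4*C2
    TAC(t) = (1 - vb)*(C1 + C2) + vb*Cp(t)

driven by a Feng-style tri-exponential plasma input Cp.  All rates are in
1/min and times in minutes.  TACs are sampled onto the acquisition frame
schedule as interval averages, consistent with count integration over each
frame's duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .config import DEFAULT_SCHEDULE_SEGMENTS, InputFunctionParams, KineticParams

__all__ = ["FrameSchedule", "input_function", "solve_tissue_tac", "frame_integrate"]


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping acquisition frames.

    ``starts`` and ``durations`` are in seconds; minute-based views are
    provided for the kinetics code.
    """

    starts: tuple[float, ...]
    durations: tuple[float, ...]

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        durs = np.asarray(self.durations, dtype=float)
        if starts.shape != durs.shape or starts.ndim != 1 or starts.size == 0:
            raise ValueError("starts and durations must be equal-length 1-D")
        if np.any(durs <= 0):
            raise ValueError("frame durations must be positive")
        ends = starts + durs
        if not np.allclose(starts[1:], ends[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")

    @classmethod
    def from_segments(
        cls, segments: tuple[tuple[int, float], ...] = DEFAULT_SCHEDULE_SEGMENTS
    ) -> "FrameSchedule":
        """Expand (count, duration) segments into a schedule.

        The default segments give the 24-frame, 3600 s protocol
        4x20 s, 4x40 s, 4x60 s, 4x180 s, 8x300 s.
        """
        durations: list[float] = []
        for count, dur in segments:
            durations.extend([float(dur)] * int(count))
        starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return cls(starts=tuple(starts), durations=tuple(durations))

    @property
    def n_frames(self) -> int:
        return len(self.starts)

    @property
    def ends(self) -> np.ndarray:
        return np.asarray(self.starts) + np.asarray(self.durations)

    @property
    def total_seconds(self) -> float:
        return float(self.ends[-1])

    @property
    def starts_min(self) -> np.ndarray:
        return np.asarray(self.starts) / 60.0

    @property
    def ends_min(self) -> np.ndarray:
        return self.ends / 60.0

    @property
    def durations_min(self) -> np.ndarray:
        return np.asarray(self.durations) / 60.0


def input_function(
    times: np.ndarray, params: InputFunctionParams | None = None
) -> np.ndarray:
    """Evaluate the plasma input curve Cp at the given times (minutes).

    Cp(t) = (A1*t - A2 - A3) e^(-l1 t) + A2 e^(-l2 t) + A3 e^(-l3 t).
    The curve is exactly zero at t = 0 and clipped at zero elsewhere
    (the analytic form can go infinitesimally negative near the origin
    for unusual parameter choices).
    """
    if params is None:
        params = InputFunctionParams()
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be nondecreasing")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    a1, a2, a3 = params.amplitudes
    l1, l2, l3 = params.decays
    cp = (a1 * t - a2 - a3) * np.exp(-l1 * t) + a2 * np.exp(-l2 * t) + a3 * np.exp(-l3 * t)
    return np.maximum(cp, 0.0)


def solve_tissue_tac(
    params: KineticParams,
    input_curve,
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Solve the two-tissue compartment model for the total tissue TAC.

    Parameters
    ----------
    params : KineticParams
        Rate constants (1/min) and blood volume fraction.
    input_curve : callable
        Plasma input Cp(t) in minutes; must be defined on [0, max(times)].
    times : array
        Output times in minutes, nondecreasing, >= 0.

    Returns
    -------
    ndarray
        Nonnegative total activity (1 - vb)*(C1 + C2) + vb*Cp at ``times``.

    Notes
    -----
    Uses the stiff-capable LSODA integrator with rtol 1e-8.  Integrator
    failure raises rather than returning a clipped result.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ValueError("times must be nondecreasing and >= 0")

    K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4

    def _cp(tt: float) -> float:
        val = input_curve(np.asarray([tt], dtype=float))
        return float(np.asarray(val).reshape(-1)[0])

    def rhs(tt, y):
        c1, c2 = y
        return [K1 * _cp(tt) - (k2 + k3) * c1 + k4 * c2, k3 * c1 - k4 * c2]

    t_end = float(t[-1]) if t.size else 0.0
    if t_end == 0.0 or K1 == 0.0:
        c_total = np.zeros_like(t)
    else:
        sol = solve_ivp(
            rhs,
            (0.0, t_end),
            [0.0, 0.0],
            method="LSODA",
            t_eval=t,
            rtol=rtol,
            atol=atol,
            max_step=0.25,
        )
        if not sol.success:
            raise RuntimeError(f"compartment-model integration failed: {sol.message}")
        c_total = sol.y[0] + sol.y[1]

    cp_t = np.asarray(input_curve(t), dtype=float)
    tac = (1.0 - params.vb) * c_total + params.vb * cp_t
    return np.maximum(tac, 0.0)


def frame_integrate(
    times: np.ndarray, tac: np.ndarray, schedule: FrameSchedule
) -> np.ndarray:
    """Average a densely sampled TAC over each frame of the schedule.

    ``times`` are in minutes and must cover the schedule span; the TAC is
    linearly interpolated between samples, so the frame value is the exact
    time-average of the piecewise-linear curve over the frame interval.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(tac, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and tac must be equal-length 1-D arrays")
    if t[0] > schedule.starts_min[0] + 1e-12 or t[-1] < schedule.ends_min[-1] - 1e-12:
        raise ValueError(
            "schedule extends beyond TAC support: "
            f"TAC covers [{t[0]:g}, {t[-1]:g}] min, schedule needs "
            f"[{schedule.starts_min[0]:g}, {schedule.ends_min[-1]:g}] min"
        )

    out = np.empty(schedule.n_frames)
    for f, (a, b) in enumerate(zip(schedule.starts_min, schedule.ends_min)):
        inside = t[(t > a) & (t < b)]
        grid = np.concatenate([[a], inside, [b]])
        vals = np.interp(grid, t, y)
        out[f] = np.trapezoid(vals, grid) / (b - a)
    return out
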