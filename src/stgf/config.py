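"""Configuration objects for the dynamic-PET graph-filtering pipeline.

Every tunable of the pipeline — phantom geometry, tracer kinetics, frame
schedule, count statistics, projector geometry, graph construction, the
stopping rule and MLEM — lives in one of the frozen dataclasses below and is
collected into a :class:`RunConfig`.  Configs serialize losslessly to plain
YAML so that any run can be reproduced from its config echo and seed alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "KineticParams",
    "InputFunctionParams",
    "PhantomConfig",
    "NoiseConfig",
    "GeometryConfig",
    "GraphConfig",
    "StoppingConfig",
    "ReconConfig",
    "RunConfig",
    "DEFAULT_KINETICS",
    "DEFAULT_SCHEDULE_SEGMENTS",
    "save_config",
    "load_config",
]

#: Frame schedule as (count, duration-in-seconds) segments:
#: 4x20 s, 4x40 s, 4x60 s, 4x180 s, 8x300 s -> 24 frames, 3600 s total.
DEFAULT_SCHEDULE_SEGMENTS: tuple[tuple[int, float], ...] = (
    (4, 20.0),
    (4, 40.0),
    (4, 60.0),
    (4, 180.0),
    (8, 300.0),
)


@dataclass(frozen=True)
class KineticParams:
    """Two-tissue (three-compartment) model rate constants.

    Parameters
    ----------
    K1, k2, k3, k4 : float
        Exchange rate constants in 1/min: plasma -> free tissue (K1),
        free tissue -> plasma (k2), free -> bound (k3), bound -> free (k4).
    vb : float
        Fractional blood volume contributing the plasma signal directly.
    """

    K1: float
    k2: float
    k3: float
    k4: float
    vb: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be >= 0")
        if not 0.0 <= self.vb <= 1.0:
            raise ValueError("blood volume fraction vb must lie in [0, 1]")


#: FDG-like default kinetics per phantom region.  The lesion is the hottest
#: region (largest net influx K1*k3/(k2+k3)); background is nearly cold.
DEFAULT_KINETICS: dict[str, KineticParams] = {
    "background": KineticParams(0.020, 0.200, 0.010, 0.010),
    "gray": KineticParams(0.102, 0.130, 0.062, 0.0068),
    "white": KineticParams(0.054, 0.109, 0.045, 0.0058),
    "lesion": KineticParams(0.150, 0.120, 0.080, 0.0050),
}


@dataclass(frozen=True)
class InputFunctionParams:
    """Feng-style tri-exponential arterial input function.

    Cp(t) = (A1*t - A2 - A3) e^(-l1 t) + A2 e^(-l2 t) + A3 e^(-l3 t),
    with amplitudes in arbitrary activity units and decays in 1/min.
    The curve is zero at t = 0 by construction.
    """

    amplitudes: tuple[float, float, float] = (851.1225, 21.8798, 20.8113)
    decays: tuple[float, float, float] = (4.133859, 0.01043449, 0.1190996)


@dataclass(frozen=True)
class PhantomConfig:
    """Parametric head-phantom geometry (fractions are of the grid side)."""

    side: int = 111
    lesion_side: int = 5
    outer_axes: tuple[float, float] = (0.44, 0.48)
    inner_scale: float = 0.72


@dataclass(frozen=True)
class NoiseConfig:
    """Two-stage count-noise model: uniform background then Poisson draws."""

    background_fraction: float = 0.20
    total_counts: float = 8.0e6
    n_realizations: int = 20


@dataclass(frozen=True)
class GeometryConfig:
    """Parallel-beam projector geometry (angles uniform on [0, pi))."""

    n_angles: int = 111
    n_radial: int = 111


@dataclass(frozen=True)
class GraphConfig:
    """Parameters of the adaptive spatial and temporal graph filters.

    ``grouping=None`` selects the default 24-frame composite grouping
    (frames 1-8, 9-16, 17-20, 21-24, 1-based).  ``temporal_distance``
    chooses between the per-bin mean squared frame distance (``"mean"``,
    default — keeps sigma_t order-one regardless of bin count) and the raw
    summed squared distance (``"sum"``).
    """

    grouping: tuple[tuple[int, ...], ...] | None = None
    k_neighbors: int = 80
    sigma_s: float = 0.5
    window: int = 9
    sigma_t: float = 1.0
    mask_tau: float = 0.1
    smooth_sigma: float = 0.85
    patch_radius: int = 0
    temporal_distance: str = "mean"
    scale_equalized_temporal: bool = True
    cache_knn: bool = False
    rescale_counts: bool = True

    def __post_init__(self) -> None:
        if self.temporal_distance not in ("mean", "sum"):
            raise ValueError("temporal_distance must be 'mean' or 'sum'")


@dataclass(frozen=True)
class StoppingConfig:
    """Dual-domain stopping rule: w1*relchange(Y) + w2*relchange(I) < epsilon.

    With ``stop_on_stagnation`` the loop also halts at the first pass that
    fails to decrease the measure: once the dual-domain change stops
    shrinking, the iteration has left its contraction phase and further
    passes only diffuse signal mass along the graph.  The stagnating pass
    is rejected (the previous iterate is returned).
    """

    epsilon: float = 0.01
    w1: float = 0.5
    w2: float = 0.5
    t_max: int = 50
    stop_on_stagnation: bool = True

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.w1 < 0 or self.w2 < 0 or self.w1 + self.w2 <= 0:
            raise ValueError("weights must be >= 0 with w1 + w2 > 0")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")


@dataclass(frozen=True)
class ReconConfig:
    """MLEM settings; ``inner_iterations`` (inside the filtering loop)
    defaults to ``n_iterations`` when None."""

    n_iterations: int = 100
    inner_iterations: int | None = None
    init_value: float = 1.0
    eps: float = 1e-12

    @property
    def inner(self) -> int:
        return self.n_iterations if self.inner_iterations is None else self.inner_iterations


@dataclass
class RunConfig:
    """Complete, serializable description of one simulation/denoising run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    graph: GraphConfig = field(default_factory=GraphConfig)
    stopping: StoppingConfig = field(default_factory=StoppingConfig)
    recon: ReconConfig = field(default_factory=ReconConfig)
    kinetics: dict[str, KineticParams] = field(
        default_factory=lambda: dict(DEFAULT_KINETICS)
    )
    input_function: InputFunctionParams = field(default_factory=InputFunctionParams)
    schedule_segments: tuple[tuple[int, float], ...] = DEFAULT_SCHEDULE_SEGMENTS
    seed: int = 0

    @classmethod
    def default(cls) -> "RunConfig":
        """The full simulation profile: 111x111 phantom, 20 realizations."""
        return cls()

    @classmethod
    def demo(cls) -> "RunConfig":
        """Reduced desk-scale profile: 63x63 phantom, 5 realizations.

        Projector geometry mirrors the image side; MLEM keeps the full
        100-iteration protocol and the outer filtering loop is capped at
        12 passes (the stopping rule fires well before that in practice).
        """
        return cls(
            phantom=PhantomConfig(side=63),
            geometry=GeometryConfig(n_angles=63, n_radial=63),
            noise=NoiseConfig(n_realizations=5),
            stopping=StoppingConfig(t_max=12),
        )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kinetics"] = {k: dataclasses.asdict(v) for k, v in self.kinetics.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        def _tups(x):
            if isinstance(x, (list, tuple)):
                return tuple(_tups(v) for v in x)
            return x

        kin = {k: KineticParams(**v) for k, v in d["kinetics"].items()}
        return cls(
            phantom=PhantomConfig(**{**d["phantom"], "outer_axes": _tups(d["phantom"]["outer_axes"])}),
            geometry=GeometryConfig(**d["geometry"]),
            noise=NoiseConfig(**d["noise"]),
            graph=GraphConfig(**{**d["graph"], "grouping": _tups(d["graph"]["grouping"])}),
            stopping=StoppingConfig(**d["stopping"]),
            recon=ReconConfig(**d["recon"]),
            kinetics=kin,
            input_function=InputFunctionParams(
                amplitudes=_tups(d["input_function"]["amplitudes"]),
                decays=_tups(d["input_function"]["decays"]),
            ),
            schedule_segments=_tups(d["schedule_segments"]),
            seed=int(d["seed"]),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(config.to_yaml())


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_yaml(Path(path).read_text())
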