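"""Dataset container I/O (HDF5 primary, NPZ fallback) and NIfTI export.

Container schema (version 1) — HDF5 groups / NPZ keys:

==========================  ==========================================
``labels``                  phantom label grid (side, side)
``truth_activity``          ground-truth activity (n_pixels, F)
``truth_scaled``            truth in scaled count units (n_pixels, F)
``noise_free``              noise-free count sinograms (m_s, F)
``expected``                expected (scaled) sinograms (m_s, F)
``background``              background means r (m_s, F)
``noisy``                   Poisson realizations (R, m_s, F)
``schedule/starts``         frame starts [s]; NPZ key ``schedule_starts``
``schedule/durations``      frame durations [s]
``seeds``                   per-realization seeds (R,)
``results/<name>``          optional named output arrays
attrs: ``schema_version``, ``scale``, ``config`` (YAML echo)
==========================  ==========================================
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .config import RunConfig
from .kinetics import FrameSchedule
from .phantom import Phantom
from .simulate import SimulatedDataset

__all__ = ["SchemaError", "save_dataset", "load_dataset", "export_nifti"]

SCHEMA_VERSION = "1"
_REQUIRED = (
    "labels",
    "truth_activity",
    "truth_scaled",
    "noise_free",
    "expected",
    "background",
    "noisy",
    "schedule/starts",
    "schedule/durations",
    "seeds",
)


class SchemaError(RuntimeError):
    """Raised when a container file is missing required members or has an
    incompatible schema version."""


def _is_h5(path: Path) -> bool:
    return path.suffix.lower() in (".h5", ".hdf5")


def save_dataset(dataset: SimulatedDataset, path: str | Path) -> None:
    """Write a dataset container; format chosen by extension (.h5/.npz)."""
    path = Path(path)
    arrays = {
        "labels": dataset.phantom.label_grid,
        "truth_activity": dataset.truth_activity,
        "truth_scaled": dataset.truth_scaled,
        "noise_free": dataset.noise_free,
        "expected": dataset.expected,
        "background": dataset.background,
        "noisy": dataset.noisy,
        "schedule/starts": np.asarray(dataset.schedule.starts),
        "schedule/durations": np.asarray(dataset.schedule.durations),
        "seeds": np.asarray(dataset.seeds, dtype=np.int64),
    }
    for name, arr in dataset.results.items():
        arrays[f"results/{name}"] = arr

    if _is_h5(path):
        with h5py.File(path, "w") as f:
            f.attrs["schema_version"] = SCHEMA_VERSION
            f.attrs["scale"] = dataset.scale
            f.attrs["config"] = dataset.config.to_yaml()
            for key, arr in arrays.items():
                f.create_dataset(key, data=arr)
    else:
        flat = {key.replace("/", "__"): arr for key, arr in arrays.items()}
        np.savez(
            path,
            __schema_version__=np.bytes_(SCHEMA_VERSION),
            __scale__=np.float64(dataset.scale),
            __config__=np.bytes_(dataset.config.to_yaml().encode()),
            **flat,
        )


def load_dataset(path: str | Path) -> SimulatedDataset:
    """Read a dataset container written by :func:`save_dataset`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_h5(path):
        with h5py.File(path, "r") as f:
            version = f.attrs.get("schema_version")
            if version != SCHEMA_VERSION:
                raise SchemaError(
                    f"unsupported schema version {version!r}; expected {SCHEMA_VERSION!r}"
                )
            for key in _REQUIRED:
                if key not in f:
                    raise SchemaError(f"container is missing required member {key!r}")
            arrays = {key: np.asarray(f[key]) for key in _REQUIRED}
            results = {}
            if "results" in f:
                results = {name: np.asarray(f["results"][name]) for name in f["results"]}
            scale = float(f.attrs["scale"])
            config = RunConfig.from_yaml(str(f.attrs["config"]))
    else:
        with np.load(path) as f:
            if "__schema_version__" not in f:
                raise SchemaError("not a dataset container: missing schema version")
            version = bytes(f["__schema_version__"]).decode()
            if version != SCHEMA_VERSION:
                raise SchemaError(
                    f"unsupported schema version {version!r}; expected {SCHEMA_VERSION!r}"
                )
            for key in _REQUIRED:
                if key.replace("/", "__") not in f:
                    raise SchemaError(f"container is missing required member {key!r}")
            arrays = {key: f[key.replace("/", "__")] for key in _REQUIRED}
            results = {
                name.split("__", 1)[1]: f[name]
                for name in f.files
                if name.startswith("results__")
            }
            scale = float(f["__scale__"])
            config = RunConfig.from_yaml(bytes(f["__config__"]).decode())

    phantom = Phantom(label_grid=arrays["labels"])
    schedule = FrameSchedule(
        starts=tuple(arrays["schedule/starts"]),
        durations=tuple(arrays["schedule/durations"]),
    )
    return SimulatedDataset(
        phantom=phantom,
        schedule=schedule,
        truth_activity=arrays["truth_activity"],
        truth_scaled=arrays["truth_scaled"],
        noise_free=arrays["noise_free"],
        expected=arrays["expected"],
        background=arrays["background"],
        noisy=arrays["noisy"],
        scale=scale,
        seeds=tuple(int(s) for s in arrays["seeds"]),
        config=config,
        results=results,
    )


def export_nifti(
    images: np.ndarray, side: int, path: str | Path, pixel_size: float = 1.0
) -> None:
    """Export an (n_pixels, F) image stack as a 4-D NIfTI-1 volume."""
    import nibabel as nib

    vol = np.asarray(images).reshape(side, side, 1, -1).astype(np.float32)
    affine = np.diag([pixel_size, pixel_size, 1.0, 1.0])
    nib.save(nib.Nifti1Image(vol, affine), str(path))
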