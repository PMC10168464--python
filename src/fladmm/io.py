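"""File I/O: float TIFF / CSV arrays, JSON geometry sidecars, YAML configs,
run manifests.

Arrays are stored as 32-bit float on disk (single-page TIFF, or row-major
CSV with no header) while all in-memory computation is double precision.
Every array written gets a JSON sidecar at ``<path>.json`` recording the
shape and, when supplied, the grid/scan geometry needed to re-create the
operators exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .geometry import ImageGrid, ScanGeometry
from .solvers import SolverConfig

__all__ = [
    "write_image",
    "read_image",
    "sidecar_path",
    "write_sidecar",
    "read_sidecar",
    "geometry_from_sidecar",
    "grid_from_sidecar",
    "load_solver_config",
    "solver_config_to_dict",
    "RunManifest",
]

_CONFIG_KEYS = {
    "model",
    "n_outer",
    "n_inner",
    "beta",
    "beta1",
    "beta2",
    "alpha",
    "epsilon",
    "t",
    "safety_factor",
    "seed",
    "early_stop_tol",
    "log_every",
}


def write_image(path: str | Path, values: np.ndarray) -> None:
    """Write a 2D array as float32 TIFF (``.tif``/``.tiff``) or CSV."""
    path = Path(path)
    values = np.asarray(values, dtype=np.float32)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, values)
    elif path.suffix.lower() == ".csv":
        np.savetxt(path, values, delimiter=",", fmt="%.9g")
    else:
        raise ValueError(f"unsupported array format {path.suffix!r} (use .tif/.tiff/.csv)")


def read_image(path: str | Path) -> np.ndarray:
    """Read a 2D array written by :func:`write_image`; returns float64."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        values = tifffile.imread(path)
    elif path.suffix.lower() == ".csv":
        values = np.loadtxt(path, delimiter=",", ndmin=2)
    else:
        raise ValueError(f"unsupported array format {path.suffix!r} (use .tif/.tiff/.csv)")
    return np.asarray(values, dtype=float)


def sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".json")


def write_sidecar(
    path: str | Path,
    shape: tuple[int, int],
    grid: ImageGrid | None = None,
    geom: ScanGeometry | None = None,
) -> None:
    """Record array shape plus optional grid/scan geometry next to ``path``."""
    meta: dict = {"shape": list(shape)}
    if grid is not None:
        meta["grid"] = {
            "n_x": grid.n_x,
            "n_y": grid.n_y,
            "pixel_size": grid.pixel_size,
            "center_row": grid.center_row,
            "center_col": grid.center_col,
        }
    if geom is not None:
        meta["geometry"] = {
            "n_bins": geom.n_bins,
            "n_angles": geom.n_angles,
            "angles": geom.angles.tolist(),
            "bin_length": geom.bin_length,
            "detector_offsets": geom.detector_offsets.tolist(),
        }
    sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_sidecar(path: str | Path) -> dict:
    return json.loads(sidecar_path(path).read_text())


def grid_from_sidecar(meta: dict) -> ImageGrid:
    g = meta["grid"]
    return ImageGrid(
        n_x=g["n_x"],
        n_y=g["n_y"],
        pixel_size=g["pixel_size"],
        center_row=g["center_row"],
        center_col=g["center_col"],
    )


def geometry_from_sidecar(meta: dict) -> ScanGeometry:
    g = meta["geometry"]
    return ScanGeometry(
        n_bins=g["n_bins"],
        n_angles=g["n_angles"],
        angles=np.asarray(g["angles"]),
        bin_length=g["bin_length"],
        detector_offsets=np.asarray(g["detector_offsets"]),
    )


def load_solver_config(path: str | Path) -> SolverConfig:
    """Parse a YAML solver config; unknown keys and bad values raise ValueError."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping of solver keys")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "model" not in raw or "n_outer" not in raw:
        raise ValueError("config must set at least 'model' and 'n_outer'")
    try:
        return SolverConfig(**raw)
    except TypeError as exc:  # bad key combination
        raise ValueError(str(exc)) from exc


def solver_config_to_dict(cfg: SolverConfig) -> dict:
    return {k: v for k, v in asdict(cfg).items() if v is not None}


@dataclass
class RunManifest:
    """Everything needed to replay a reconstruction run exactly."""

    command: str
    config: dict
    inputs: dict
    outputs: dict
    seed: int
    package_version: str = ""
    created: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
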