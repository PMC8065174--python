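"""Configuration files, serialization, and run manifests.

Configs are YAML mappings validated against a strict per-command schema:
unknown keys are errors, not warnings, so a typo cannot silently fall back
to a default.  Every run writes its resolved config next to its outputs
together with a manifest (command, config hash, package version) so that
any result file can be traced to the exact parameters that produced it.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dopo_core import Trajectory
from .reduced_dynamics import PhaseDiagram, PolarTrajectory

__all__ = [
    "RunConfig",
    "ResultBundle",
    "ConfigError",
    "load_config",
    "write_trajectory_csv",
    "write_trajectory_hdf5",
    "write_polar_csv",
    "write_phase_diagram",
]

CSV_FLOAT_FMT = "%.9g"  # 9 significant digits in CSV; HDF5 keeps full doubles


class ConfigError(ValueError):
    """Configuration problem, reported with the offending field path."""


# command -> {key: (type, default)}; None default means required
_SCHEMAS: dict = {
    "simulate": {
        "p_tilde": ((int, float, list), 1.0),
        "i_ext_tilde": ((int, float, list), 0.0),
        "n_neurons": (int, 1),
        "dt": ((int, float), 1e-2),
        "duration": ((int, float), 100.0),
        "method": (str, "rk4"),
        "record_stride": (int, 1),
        "init_noise_amplitude": ((int, float), 1e-3),
        "pump_ramp": ((list, type(None)), None),  # [start, stop] in P~
        "bias_ramp": ((list, type(None)), None),
    },
    "phase-diagram": {
        "p_tilde_range": (list, [-0.5, 3.5]),
        "i_tilde_range": (list, [0.0, 0.0]),
        "resolution": (list, [25, 1]),
        "dt": ((int, float), 1e-2),
        "duration": ((int, float), 200.0),
        "record_stride": (int, 5),
    },
    "sync-experiment": {
        "n_clusters": (int, 4),
        "cluster_size": (int, 15),
        "j_k_list": (list, [0.0, 0.025, 0.05, 0.075]),
        "pump_centers": (list, [0.5, 1.0, 1.5, 2.0]),
        "pump_half_spread": ((int, float), 0.15),
        "inter_edges_per_pair": (int, 2),
        "dt": ((int, float), 1e-2),
        "duration": ((int, float), 400.0),
        "record_stride": (int, 10),
    },
    "anneal": {
        "j_k_list": (list, [0.25]),
        "p_start": ((int, float), -0.5),
        "p_end": ((int, float), 3.2),
        "duration": ((int, float), 500.0),
        "n_trials": (int, 20),
        "dt": ((int, float), 1e-2),
        "record_stride": (int, 10),
        "oracle": (bool, True),
    },
    "gen-instance": {
        "n": (int, 16),
        "density": ((int, float), 0.5),
        "weight_scheme": (str, "pm1"),
    },
    "stability": {
        "p_tilde": ((int, float), 1.0),
        "i_ext_tilde": ((int, float), 0.0),
    },
}


@dataclass
class RunConfig:
    command: str
    params: dict
    seed: int = 0
    outdir: str = "."
    format: str = "csv"

    def resolved(self) -> dict:
        return {
            "command": self.command,
            "seed": self.seed,
            "outdir": str(self.outdir),
            "format": self.format,
            "params": self.params,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _validate(command: str, raw: dict) -> dict:
    if command not in _SCHEMAS:
        raise ConfigError(f"unknown command {command!r}")
    schema = _SCHEMAS[command]
    params = {}
    for key, val in raw.items():
        if key not in schema:
            raise ConfigError(f"{command}: unknown config key {key!r}")
        expected, _ = schema[key]
        if not isinstance(val, expected):
            raise ConfigError(
                f"{command}.{key}: expected {expected}, got {type(val).__name__}"
            )
        params[key] = val
    for key, (_, default) in schema.items():
        params.setdefault(key, default)
    return params


def load_config(
    command: str,
    path=None,
    overrides: dict | None = None,
    seed: int = 0,
    outdir: str = ".",
    fmt: str = "csv",
) -> RunConfig:
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        raw.update(loaded)
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    params = _validate(command, raw)
    if fmt not in ("csv", "hdf5"):
        raise ConfigError(f"format must be csv or hdf5, got {fmt!r}")
    return RunConfig(command=command, params=params, seed=seed, outdir=outdir, format=fmt)


@dataclass
class ResultBundle:
    config: RunConfig
    files: list = field(default_factory=list)
    manifest_path: Path | None = None

    def add(self, path) -> Path:
        self.files.append(Path(path))
        return Path(path)

    def finalize(self) -> Path:
        outdir = Path(self.config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cfg_path = outdir / "config.resolved.yaml"
        with cfg_path.open("w") as fh:
            yaml.safe_dump(self.config.resolved(), fh, sort_keys=True)
        self.files.append(cfg_path)
        missing = [str(p) for p in self.files if not Path(p).exists()]
        if missing:
            raise RuntimeError(f"manifest references missing files: {missing}")
        from . import __version__

        manifest = {
            "command": self.config.command,
            "config_hash": self.config.config_hash(),
            "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "version": __version__,
            "files": [str(Path(p).name) for p in self.files],
        }
        self.manifest_path = outdir / "manifest.json"
        self.manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
        return self.manifest_path


# ---------------------------------------------------------------------------
# Writers


def write_coupling_csv(J: np.ndarray, path) -> None:
    """Dense coupling matrix as CSV (full precision, no header)."""
    np.savetxt(path, np.asarray(J, dtype=float), delimiter=",", fmt="%.17g")


def read_coupling_csv(path) -> np.ndarray:
    J = np.loadtxt(path, delimiter=",", ndmin=2)
    return J


def write_trajectory_csv(traj: Trajectory, path) -> None:
    traj.to_dataframe().to_csv(path, index=False, float_format=CSV_FLOAT_FMT)


def write_trajectory_hdf5(traj: Trajectory, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=traj.times)
        fh.create_dataset("v", data=traj.v)
        fh.create_dataset("w", data=traj.w)
        if traj.pump is not None:
            fh.create_dataset("pump", data=traj.pump)
        if traj.bias is not None:
            fh.create_dataset("bias", data=traj.bias)


def read_trajectory_hdf5(path) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as fh:
        return Trajectory(
            times=fh["times"][:],
            v=fh["v"][:],
            w=fh["w"][:],
            pump=fh["pump"][:] if "pump" in fh else None,
            bias=fh["bias"][:] if "bias" in fh else None,
        )


def write_polar_csv(polar: PolarTrajectory, path) -> None:
    n, T = polar.theta.shape
    df = pd.DataFrame(
        {
            "time": np.repeat(polar.times, n),
            "neuron": np.tile(np.arange(n), T),
            "theta": polar.theta.T.ravel(),
        }
    )
    if polar.R is not None:
        df["R"] = polar.R.T.ravel()
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FMT)


def write_phase_diagram(diagram: PhaseDiagram, csv_path, json_path) -> None:
    diagram.to_dataframe().to_csv(csv_path, index=False, float_format=CSV_FLOAT_FMT)
    payload = {
        "ah_boundary": [[float(a), float(b)] for a, b in diagram.ah_boundary],
        "snlc_boundary": [[float(a), float(b)] for a, b in diagram.snlc_boundary],
    }
    Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
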