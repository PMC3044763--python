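"""Configuration, serialization and run manifests.

Human-edited inputs are YAML (scenario configs), field data travels in
HDF5 (self-describing arrays, lossless round-trip), time series export to
CSV, and every run can emit a JSON manifest carrying the resolved
parameters, seed, code version, domain checksum and conservation
residuals — enough to re-execute the run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Union

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .domains import ShapeSpec
from .experiments import Scenario, Snapshot, Trajectory
from .kinetics import IntegrinState, ModelParams

__all__ = [
    "load_config",
    "save_config",
    "write_outputs",
    "read_outputs",
    "psi_series_csv",
    "write_manifest",
]

_SHAPE_KEYS = {"kind", "stair_steps"}
_SCENARIO_KEYS = {
    "name",
    "shape",
    "resolution",
    "initial",
    "seeds",
    "snapshot_interval",
    "record_interval",
    "t_total",
    "params",
}
_PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParams)}


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")


def load_config(path: Union[str, Path]) -> Scenario:
    """Read and validate a scenario config; defaults fill missing keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return scenario_from_dict(raw)


def scenario_from_dict(raw: dict) -> Scenario:
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    _check_keys(raw, _SCENARIO_KEYS, "scenario")
    shape_raw = raw.get("shape", {"kind": "square"})
    if isinstance(shape_raw, str):
        shape_raw = {"kind": shape_raw}
    _check_keys(shape_raw, _SHAPE_KEYS, "shape")
    shape = ShapeSpec(**shape_raw)
    params_raw = raw.get("params", {})
    _check_keys(params_raw, _PARAM_KEYS, "params")
    params = ModelParams(**params_raw)
    kw = {}
    for key in ("resolution", "initial", "snapshot_interval", "record_interval", "t_total"):
        if key in raw:
            kw[key] = raw[key]
    if "seeds" in raw:
        kw["seeds"] = tuple(int(s) for s in raw["seeds"])
    return Scenario(
        name=raw.get("name", shape.kind), shape=shape, params=params, **kw
    )


def scenario_to_dict(scenario: Scenario) -> dict:
    shape = {"kind": scenario.shape.kind}
    if scenario.shape.kind == "stair":
        shape["stair_steps"] = scenario.shape.stair_steps
    out = {
        "name": scenario.name,
        "shape": shape,
        "initial": scenario.initial,
        "seeds": list(scenario.seeds),
        "snapshot_interval": scenario.snapshot_interval,
        "record_interval": scenario.record_interval,
        "params": scenario.params.to_dict(),
    }
    if scenario.resolution is not None:
        out["resolution"] = scenario.resolution
    if scenario.t_total is not None:
        out["t_total"] = scenario.t_total
    return out


def save_config(scenario: Scenario, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=True)


def write_outputs(traj: Trajectory, path: Union[str, Path]) -> None:
    """Lossless HDF5 dump of a trajectory (series, snapshots, final state)."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = 1
        f.attrs["code_version"] = __version__
        f.attrs["seed"] = traj.seed
        f.attrs["conservation_max"] = traj.conservation_max
        f.attrs["force_balance_max"] = traj.force_balance_max
        f.attrs["wall_time"] = traj.wall_time
        f.attrs["scenario_yaml"] = yaml.safe_dump(scenario_to_dict(traj.scenario))
        f.create_dataset("times", data=traj.times)
        f.create_dataset("psi_mean", data=traj.psi_mean)
        f.create_dataset("global_oop_n", data=traj.global_oop_n)
        if traj.final_state is not None:
            g = f.create_group("final_state")
            _write_state(g, traj.final_state)
        snaps = f.create_group("snapshots")
        for i, s in enumerate(traj.snapshots):
            g = snaps.create_group(f"{i:05d}")
            g.attrs["time"] = s.time
            _write_state(g.create_group("state"), s.state)
            for name in ("director_n", "density_n", "oop_n", "psi"):
                g.create_dataset(name, data=getattr(s, name))


def _write_state(g: h5py.Group, state: IntegrinState) -> None:
    g.attrs["time"] = state.time
    for name in ("rho_f", "rho_p", "rho_n"):
        g.create_dataset(name, data=getattr(state, name))


def _read_state(g: h5py.Group) -> IntegrinState:
    return IntegrinState(
        rho_f=g["rho_f"][:],
        rho_p=g["rho_p"][:],
        rho_n=g["rho_n"][:],
        time=float(g.attrs["time"]),
    )


def read_outputs(path: Union[str, Path]) -> Trajectory:
    """Read a trajectory written by :func:`write_outputs`."""
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ValueError(f"cannot read trajectory file {path}: {exc}") from exc
    with f:
        version = int(f.attrs.get("format_version", -1))
        if version != 1:
            raise ValueError(f"unsupported trajectory format version {version}")
        scenario = scenario_from_dict(yaml.safe_load(f.attrs["scenario_yaml"]))
        snapshots = []
        for key in sorted(f["snapshots"]):
            g = f["snapshots"][key]
            snapshots.append(
                Snapshot(
                    time=float(g.attrs["time"]),
                    state=_read_state(g["state"]),
                    director_n=g["director_n"][:],
                    density_n=g["density_n"][:],
                    oop_n=g["oop_n"][:],
                    psi=g["psi"][:],
                )
            )
        return Trajectory(
            scenario=scenario,
            seed=int(f.attrs["seed"]),
            times=f["times"][:],
            psi_mean=f["psi_mean"][:],
            global_oop_n=f["global_oop_n"][:],
            snapshots=snapshots,
            final_state=_read_state(f["final_state"]) if "final_state" in f else None,
            conservation_max=float(f.attrs["conservation_max"]),
            force_balance_max=float(f.attrs["force_balance_max"]),
            wall_time=float(f.attrs["wall_time"]),
        )


def psi_series_csv(traj: Trajectory, path: Union[str, Path]) -> None:
    """CSV export of the psi_mean and global-OOP time series."""
    pd.DataFrame(
        {
            "time": traj.times,
            "psi_mean": traj.psi_mean,
            "global_oop_n": traj.global_oop_n,
        }
    ).to_csv(path, index=False, float_format="%.12g")


def write_manifest(traj: Trajectory, path: Union[str, Path]) -> None:
    domain = traj.domain
    checksum = None
    if domain is not None:
        h = hashlib.sha256()
        h.update(domain.occupancy.tobytes())
        h.update(np.float64(domain.spacing).tobytes())
        checksum = h.hexdigest()
    manifest = {
        "code_version": __version__,
        "scenario": scenario_to_dict(traj.scenario),
        "seed": traj.seed,
        "domain_checksum": checksum,
        "n_points": None if domain is None else domain.n_points,
        "conservation_max": traj.conservation_max,
        "force_balance_max": traj.force_balance_max,
        "wall_time_s": traj.wall_time,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
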