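"""File formats: flat key-value configs and tabular text outputs.

Configuration files are flat ``key = value`` lines grouped in
``[model]``, ``[domain]`` and ``[run]`` sections.  All tabular outputs
are headered comma-separated text (gzip-transparent on read and write):

* trajectory: ``t,id,x,y,theta,v`` — one row per agent per snapshot
* summary:    ``t,S1,S2,mean_speed[,mean_abs_vorticity]``
* observations: ``density,observable,value``
"""

from __future__ import annotations

import configparser
import dataclasses

import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .model import (
    Domain,
    ModelParams,
    ParticleState,
    SimulationConfig,
    validate_config,
)

__all__ = [
    "write_config",
    "read_config",
    "write_trajectory",
    "read_trajectory",
    "write_summary",
    "read_summary",
    "read_observations",
    "write_observations",
]

_MODEL_FIELDS = [f.name for f in dataclasses.fields(ModelParams)]
_RUN_FIELDS = [
    "n_particles",
    "n_steps",
    "seed",
    "init_orientation",
    "init_orientation_angle",
    "init_speed",
    "init_speed_scale",
    "record_every",
]


def write_config(config: SimulationConfig, path) -> None:
    cp = configparser.ConfigParser()
    cp.optionxform = str  # keys are case-sensitive (R vs r)
    cp["model"] = {
        name: repr(getattr(config.params, name))
        for name in _MODEL_FIELDS
        if getattr(config.params, name) is not None
    }
    cp["domain"] = {"L": repr(config.domain.L), "periodic": repr(config.domain.periodic)}
    cp["run"] = {name: repr(getattr(config, name)) for name in _RUN_FIELDS}
    with open(path, "w") as fh:
        cp.write(fh)


def _parse_value(raw: str, target_type):
    raw = raw.strip()
    if target_type is bool:
        return raw.lower() in ("true", "1", "yes")
    if target_type is int:
        return int(raw)
    if target_type is float:
        return float(raw)
    return raw.strip("'\"")


def read_config(path) -> SimulationConfig:
    """Parse and validate a flat key-value config file."""
    cp = configparser.ConfigParser()
    cp.optionxform = str
    read = cp.read(path)
    if not read:
        raise FileNotFoundError(path)

    params_kwargs = {}
    field_types = {f.name: f for f in dataclasses.fields(ModelParams)}
    for key, raw in cp["model"].items():
        if key not in field_types:
            raise ValueError(f"unknown model key {key!r}")
        tt = str if key == "g_mode" else float
        params_kwargs[key] = _parse_value(raw, tt)
    domain = Domain(
        L=_parse_value(cp["domain"].get("L", "32.0"), float),
        periodic=_parse_value(cp["domain"].get("periodic", "True"), bool),
    )
    run_kwargs = {}
    run_types = {
        "n_particles": int,
        "n_steps": int,
        "seed": int,
        "record_every": int,
        "init_orientation_angle": float,
        "init_speed_scale": float,
        "init_orientation": str,
        "init_speed": str,
    }
    for key, raw in cp["run"].items():
        if key not in run_types:
            raise ValueError(f"unknown run key {key!r}")
        run_kwargs[key] = _parse_value(raw, run_types[key])

    config = SimulationConfig(
        params=ModelParams(**params_kwargs), domain=domain, **run_kwargs
    )
    return validate_config(config)


def write_trajectory(traj: Trajectory, path) -> None:
    frames = []
    for s in traj.states:
        n = s.n
        frames.append(
            pd.DataFrame(
                {
                    "t": np.full(n, s.t),
                    "id": np.arange(n),
                    "x": s.positions[:, 0],
                    "y": s.positions[:, 1],
                    "theta": s.orientations,
                    "v": s.speeds,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def read_trajectory(path, domain_L: float, config_hash: str = "", seed: int = -1) -> Trajectory:
    """Rebuild a Trajectory from a ``t,id,x,y,theta,v`` table."""
    df = pd.read_csv(path)
    states = []
    for t, grp in df.groupby("t", sort=True):
        grp = grp.sort_values("id")
        states.append(
            ParticleState(
                t=float(t),
                positions=grp[["x", "y"]].to_numpy(),
                orientations=np.mod(grp["theta"].to_numpy(), 2 * np.pi),
                speeds=grp["v"].to_numpy(),
            )
        )
    return Trajectory(states=states, config_hash=config_hash, seed=seed)


def write_summary(rows, path) -> None:
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_summary(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_observations(path) -> pd.DataFrame:
    """Read a ``density,observable,value`` observation table."""
    df = pd.read_csv(path)
    missing = [c for c in ("density", "observable", "value") if c not in df.columns]
    if missing:
        raise ValueError(f"observation table misses columns {missing}")
    return df.astype({"density": float, "value": float})


def write_observations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
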