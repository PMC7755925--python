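"""Scripted computational experiments: sweeps, regime maps, bacteria scenario.

Canonical parameter sets are shipped as named presets:

* ``polar_order``    — negative angular sensitivity; Vicsek-like global
  polar alignment (beta_theta = -0.25 snapshot variant: ``polar_snapshot``).
* ``vortex``         — strongly positive angular sensitivity with speed
  homogenization; transient vortex structures.
* ``order_transition`` — base protocol for sensitivity sweeps
  (N = 1000, R = 3, angular noise std 0.01, beta_v = 0, epsilon = 0, g = 1,
  1000 steps); sweep beta_theta negative for the polar transition,
  positive for the nematic one.
* ``orientation_histogram`` — same protocol with zero noise, used for
  the bimodal orientation distribution of the anti-aligning regime.
* ``bacteria``       — swarming of spherical bacteria: long interaction
  radius R = 10, noise std 1e-4, epsilon = 0.008, beta_v = -20,
  beta_theta = 5, g = 1/v, 500 steps; density is set via n_particles.

The box side defaults to L = 32 for the N = 1000 protocols (mean density
about 1, so a radius-3 neighborhood holds roughly 28 agents — the
medium-range information-spread regime where ordering occurs); the
bacteria preset uses L = 16 so densities can be scanned at tractable N.

Ensemble seeds derive from a master seed through
``numpy.random.SeedSequence([master_seed, index])`` so ensembles are
reproducible and extensible realization by realization.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import run_simulation
from .model import Domain, GMode, ModelParams, SimulationConfig, validate_config
from .observables import mean_abs_vorticity, order_parameters, vorticity_field

__all__ = [
    "SweepSpec",
    "RegimeMap",
    "preset",
    "PRESET_NAMES",
    "derive_seed",
    "ensemble_configs",
    "sweep_sensitivity",
    "regime_map",
    "bacteria_scenario",
]


def derive_seed(master_seed: int, index: int) -> int:
    """Deterministic per-realization seed from (master, counter)."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def ensemble_configs(
    base: SimulationConfig, realizations: int, master_seed: int, offset: int = 0
) -> List[SimulationConfig]:
    return [
        dataclasses.replace(base, seed=derive_seed(master_seed, offset + k))
        for k in range(realizations)
    ]


def preset(name: str, **overrides) -> SimulationConfig:
    """Build a named scenario configuration; keyword overrides are applied
    to the top-level config fields (use ``params=...`` to replace the
    parameter block wholesale, or ``beta_theta=...`` etc. for single
    parameter overrides)."""
    if name in ("polar_order", "polar_snapshot"):
        params = ModelParams(
            beta_theta=-0.25, beta_v=-5.0, R=3.0,
            noise_std_theta=0.01, noise_std_v=0.01, epsilon=0.0, g_mode=GMode.UNIT,
        )
        cfg = SimulationConfig(params=params, domain=Domain(L=32.0),
                               n_particles=1000, n_steps=1000, record_every=1000)
    elif name in ("vortex", "vortex_snapshot"):
        params = ModelParams(
            beta_theta=18.0, beta_v=-5.0, R=3.0,
            noise_std_theta=0.01, noise_std_v=0.01, epsilon=0.0, g_mode=GMode.UNIT,
        )
        cfg = SimulationConfig(params=params, domain=Domain(L=32.0),
                               n_particles=1000, n_steps=1000, record_every=1000)
    elif name == "order_transition":
        params = ModelParams(
            beta_theta=0.0, beta_v=0.0, R=3.0,
            noise_std_theta=0.01, noise_std_v=0.0, epsilon=0.0, g_mode=GMode.UNIT,
        )
        cfg = SimulationConfig(params=params, domain=Domain(L=32.0),
                               n_particles=1000, n_steps=1000, record_every=1000)
    elif name == "orientation_histogram":
        params = ModelParams(
            beta_theta=18.0, beta_v=0.0, R=3.0,
            noise_std_theta=0.0, noise_std_v=0.0, epsilon=0.0, g_mode=GMode.UNIT,
        )
        cfg = SimulationConfig(params=params, domain=Domain(L=32.0),
                               n_particles=1000, n_steps=1000, record_every=1000)
    elif name == "bacteria":
        params = ModelParams(
            beta_theta=5.0, beta_v=-20.0, R=10.0,
            noise_std_theta=1e-4, noise_std_v=1e-4, epsilon=0.008,
            g_mode=GMode.INVERSE_SPEED,
        )
        cfg = SimulationConfig(params=params, domain=Domain(L=16.0),
                               n_particles=256, n_steps=500, record_every=500)
    else:
        raise ValueError(f"unknown preset {name!r}")

    param_fields = {f.name for f in dataclasses.fields(ModelParams)}
    param_overrides = {k: v for k, v in overrides.items() if k in param_fields}
    config_overrides = {k: v for k, v in overrides.items() if k not in param_fields}
    if param_overrides:
        cfg = dataclasses.replace(
            cfg, params=dataclasses.replace(cfg.params, **param_overrides)
        )
    if config_overrides:
        cfg = dataclasses.replace(cfg, **config_overrides)
    return validate_config(cfg)


PRESET_NAMES = (
    "polar_order",
    "vortex",
    "order_transition",
    "orientation_histogram",
    "bacteria",
)


@dataclass
class SweepSpec:
    """One-parameter sweep over an ensemble-averaged observable."""

    parameter: str  # a ModelParams field name, e.g. "beta_theta"
    values: Sequence[float]
    base: SimulationConfig
    realizations: int = 10
    master_seed: int = 0
    reducers: Dict[str, Callable] = field(
        default_factory=lambda: {
            "S1": lambda st, dom: order_parameters(st.orientations).s1,
            "S2": lambda st, dom: order_parameters(st.orientations).s2,
        }
    )

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.size == 0:
            raise ValueError("sweep grid must be non-empty")
        if vals.size > 1 and not (
            np.all(np.diff(vals) > 0) or np.all(np.diff(vals) < 0)
        ):
            raise ValueError("sweep grid must be strictly monotone")


def _ensemble_finals(base, realizations, master_seed, reducers, offset=0):
    rows = []
    for k, cfg in enumerate(
        ensemble_configs(base, realizations, master_seed, offset)
    ):
        traj = run_simulation(cfg)
        st = traj.final_state
        row = {name: fn(st, cfg.domain) for name, fn in reducers.items()}
        row["seed"] = cfg.seed
        rows.append(row)
    return pd.DataFrame(rows)


def sweep_sensitivity(spec: SweepSpec) -> pd.DataFrame:
    """Ensemble mean +- sd of each reducer along the parameter grid.

    Per-grid-value realization seeds derive from the master seed and a
    running counter, so the whole sweep is reproducible.
    """
    rows = []
    for gi, value in enumerate(spec.values):
        base = dataclasses.replace(
            spec.base,
            params=dataclasses.replace(spec.base.params, **{spec.parameter: value}),
        )
        finals = _ensemble_finals(
            base,
            spec.realizations,
            spec.master_seed,
            spec.reducers,
            offset=gi * spec.realizations,
        )
        row = {spec.parameter: value}
        for name in spec.reducers:
            row[f"{name}_mean"] = float(finals[name].mean())
            row[f"{name}_sd"] = float(finals[name].std(ddof=1)) if len(finals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RegimeMap:
    """Order parameters and pattern flags on a (beta_theta, R) grid."""

    beta_theta_values: np.ndarray
    R_values: np.ndarray
    s1: np.ndarray  # (len(beta), len(R)) ensemble means
    s2: np.ndarray
    threshold: float
    flags: np.ndarray  # pattern present: S1 > tau or S2 > tau


def regime_map(
    beta_theta_values,
    R_values,
    base: SimulationConfig,
    realizations: int = 5,
    master_seed: int = 0,
    threshold: Optional[float] = None,
) -> RegimeMap:
    """Map the ordered-pattern region of the (beta_theta, R) plane.

    The literal "nonzero order" criterion is never exact in a finite
    system; the default threshold is 3 / sqrt(N), three times the
    disordered-state noise floor of the order parameters.
    """
    beta_theta_values = np.asarray(beta_theta_values, dtype=float)
    R_values = np.asarray(R_values, dtype=float)
    if threshold is None:
        threshold = 3.0 / np.sqrt(base.n_particles)
    s1 = np.zeros((len(beta_theta_values), len(R_values)))
    s2 = np.zeros_like(s1)
    reducers = {
        "S1": lambda st, dom: order_parameters(st.orientations).s1,
        "S2": lambda st, dom: order_parameters(st.orientations).s2,
    }
    counter = 0
    for i, bt in enumerate(beta_theta_values):
        for j, R in enumerate(R_values):
            cfg = dataclasses.replace(
                base, params=dataclasses.replace(base.params, beta_theta=bt, R=R)
            )
            finals = _ensemble_finals(
                cfg, realizations, master_seed, reducers, offset=counter
            )
            counter += realizations
            s1[i, j] = finals["S1"].mean()
            s2[i, j] = finals["S2"].mean()
    return RegimeMap(
        beta_theta_values=beta_theta_values,
        R_values=R_values,
        s1=s1,
        s2=s2,
        threshold=float(threshold),
        flags=(s1 > threshold) | (s2 > threshold),
    )


def bacteria_scenario(
    densities,
    realizations: int = 50,
    master_seed: int = 0,
    base: Optional[SimulationConfig] = None,
    vorticity_bin_size: float = 2.0,
    keep_speed_samples: bool = True,
) -> tuple:
    """Per-density ensemble means of speed and |vorticity| for the
    spherical-bacteria swarming scenario.

    Returns ``(predictions, speed_samples)``: a DataFrame with columns
    (density, observable, pred_mean, pred_sd) ready for the chi-square
    stage, and a dict density -> pooled final-speed sample for
    distribution checks.
    """
    densities = np.asarray(densities, dtype=float)
    if densities.size < 1:
        raise ValueError("density grid must contain at least 1 value")
    if base is None:
        base = preset("bacteria")
    rows = []
    speed_samples = {}
    counter = 0
    for rho in densities:
        n = int(round(rho * base.domain.L**2))
        if n < 2:
            raise ValueError(f"density {rho} yields fewer than 2 agents")
        cfg = dataclasses.replace(
            base,
            n_particles=n,
            params=dataclasses.replace(base.params, rho_bar=None),
        )
        cfg = validate_config(cfg)
        speeds_mean, vort = [], []
        pooled = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # R >= L/2 degeneracy is intended here
            for sub in ensemble_configs(cfg, realizations, master_seed, counter):
                traj = run_simulation(sub)
                st = traj.final_state
                speeds_mean.append(float(st.speeds.mean()))
                field_ = vorticity_field(st, cfg.domain, vorticity_bin_size)
                vort.append(mean_abs_vorticity(field_))
                if keep_speed_samples:
                    pooled.append(st.speeds)
        counter += realizations
        for name, vals in (("speed", speeds_mean), ("vorticity", vort)):
            vals = np.asarray(vals)
            rows.append(
                {
                    "density": float(rho),
                    "observable": name,
                    "pred_mean": float(vals.mean()),
                    "pred_sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                }
            )
        if keep_speed_samples:
            speed_samples[float(rho)] = np.concatenate(pooled)
    return pd.DataFrame(rows), speed_samples
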