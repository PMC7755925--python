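"""Euler–Maruyama integration of the entropy-gradient Langevin system.

Per step (synchronous update, all gradients evaluated on the pre-step
state):

    theta_n <- wrap(theta_n + beta_theta * dS_theta * dt + g(v_n) * eta_theta)
    v_n     <- | v_n + beta_v * dS_v * dt - epsilon * psi(rho_n) * v_n * dt + eta_v |
    r_n     <- wrap(r_n + v_n * (cos theta_n, sin theta_n) * dt)

with ``eta_alpha ~ Normal(0, noise_std_alpha**2)`` per-step increments,
``psi(rho) = rho - rho_bar`` the density-dependent friction, and the
position advanced with the pre-update heading and speed.  Speeds are
reflected at zero (absolute value), matching the half-normal support.
``g`` modulates only the angular noise: ``g = 1`` or ``g = 1/max(v, v_min)``.

Noise stream order is fixed: one ``(N, 2)`` standard-normal block per
step, agent-major, angular noise before speed noise.  Identical
(config, seed) pairs therefore reproduce bit-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .model import (
    Domain,
    InitOrientation,
    InitSpeed,
    ModelParams,
    ParticleState,
    SimulationConfig,
    validate_config,
    wrap_angle,
)
from .neighbors import build_neighbor_index
from .statmech import compute_all_stats

__all__ = ["Trajectory", "g_noise_modulation", "friction", "step", "run_simulation"]


def g_noise_modulation(v, params: ModelParams):
    """Angular-noise modulation ``g(v)``: 1, or ``1/max(v, v_min)``."""
    v = np.asarray(v, dtype=float)
    if params.g_mode == "unit":
        out = np.ones_like(v)
    else:
        out = 1.0 / np.maximum(v, params.v_min)
    return float(out) if v.ndim == 0 else out


def friction(rho, params: ModelParams):
    """Density-dependent friction ``psi(rho) = rho - rho_bar``.

    Negative in underdense regions (anti-friction), positive in
    overdense ones.
    """
    rho_bar = params.rho_bar if params.rho_bar is not None else 0.0
    out = np.asarray(rho, dtype=float) - rho_bar
    return float(out) if np.ndim(rho) == 0 else out


def step(
    state: ParticleState,
    params: ModelParams,
    domain: Domain,
    rng: np.random.Generator,
) -> ParticleState:
    """Advance the system by one Euler–Maruyama step."""
    index = build_neighbor_index(state, params.R, domain)
    stats = compute_all_stats(state, index, params)

    theta = state.orientations
    v = state.speeds
    dt = params.dt

    # angular entropy gradient (see statmech for the closed form)
    num = np.cos(theta) * stats.vbar_y - np.sin(theta) * stats.vbar_x
    one_minus_sq = (1.0 - stats.s1_clipped) * (1.0 + stats.s1_clipped)
    ratio = stats.s1_clipped / np.maximum(stats.s1_raw, params.s1_clip)
    grad_theta = -2.0 * num * ratio / (stats.n_area**2 * one_minus_sq)

    grad_v = v / (stats.n_area * stats.sigma_sq)
    psi = stats.rho - (params.rho_bar if params.rho_bar is not None else 0.0)

    eta = rng.standard_normal((state.n, 2))
    eta_theta = params.noise_std_theta * eta[:, 0]
    eta_v = params.noise_std_v * eta[:, 1]

    g = g_noise_modulation(v, params)
    new_theta = wrap_angle(theta + params.beta_theta * grad_theta * dt + g * eta_theta)
    new_v = np.abs(
        v + params.beta_v * grad_v * dt - params.epsilon * psi * v * dt + eta_v
    )
    new_pos = domain.wrap_positions(
        state.positions
        + v[:, None] * np.column_stack((np.cos(theta), np.sin(theta))) * dt
    )

    if not (
        np.all(np.isfinite(new_theta))
        and np.all(np.isfinite(new_v))
        and np.all(np.isfinite(new_pos))
    ):
        raise FloatingPointError(
            "non-finite state after update (t = %.6g); check parameters" % state.t
        )
    return ParticleState(
        t=state.t + dt, positions=new_pos, orientations=new_theta, speeds=new_v
    )


@dataclass
class Trajectory:
    """Recorded snapshots of one simulation run."""

    states: List[ParticleState]
    config_hash: str
    seed: int

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.states])

    @property
    def final_state(self) -> ParticleState:
        return self.states[-1]

    def __len__(self) -> int:
        return len(self.states)


def initial_state(config: SimulationConfig, rng: np.random.Generator) -> ParticleState:
    """Draw the initial condition: positions uniform in the box,
    orientations and speeds per the configured schemes."""
    n = config.n_particles
    L = config.domain.L
    positions = rng.uniform(0.0, L, size=(n, 2))
    if config.init_orientation == InitOrientation.UNIFORM_RANDOM:
        orientations = rng.uniform(0.0, 2.0 * np.pi, size=n)
    else:
        orientations = np.full(n, wrap_angle(config.init_orientation_angle))
    scale = config.init_speed_scale
    if config.init_speed == InitSpeed.UNIFORM:
        speeds = rng.uniform(0.0, scale, size=n)
    elif config.init_speed == InitSpeed.HALF_NORMAL:
        speeds = np.abs(rng.normal(0.0, scale, size=n))
    else:
        speeds = np.full(n, scale)
    return ParticleState(t=0.0, positions=positions, orientations=orientations, speeds=speeds)


def run_simulation(config: SimulationConfig) -> Trajectory:
    """Run a full simulation; fully reproducible from (config, seed)."""
    config = validate_config(config)
    rng = np.random.default_rng(config.seed)
    state = initial_state(config, rng)
    states = [state]
    for k in range(config.n_steps):
        state = step(state, config.params, config.domain, rng)
        if (k + 1) % config.record_every == 0 or k + 1 == config.n_steps:
            states.append(state)
    return Trajectory(states=states, config_hash=config.config_hash(), seed=config.seed)
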