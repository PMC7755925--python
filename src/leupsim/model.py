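"""Core state, parameter and configuration types for the LEUP particle model.

The model describes ``N`` self-propelled agents on a periodic square box.
Each agent carries a position ``r_n`` (box units), a heading ``theta_n``
(radians, stored wrapped to ``[0, 2*pi)``) and a nonnegative speed ``v_n``.
Agents reorient and accelerate along the gradient of the differential
entropy of the orientation / speed distribution of their radius-``R``
neighborhood, with coupling strengths ``beta_theta`` and ``beta_v`` (the
angular and radial sensitivities).  Negative sensitivity drives agents
toward local entropy minima (alignment / speed homogenization), positive
sensitivity toward entropy maxima.

This module holds only data containers and validation; dynamics live in
:mod:`leupsim.dynamics`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Domain",
    "ParticleState",
    "ModelParams",
    "SimulationConfig",
    "ConfigError",
    "validate_config",
    "wrap_angle",
    "GMode",
    "InitOrientation",
    "InitSpeed",
]

TWO_PI = 2.0 * math.pi


class ConfigError(ValueError):
    """Raised when a configuration value is inconsistent or out of range."""


# enums are plain string constants: they round-trip through flat config files
class GMode:
    """Angular-noise modulation g(v): constant or inverse-speed."""

    UNIT = "unit"
    INVERSE_SPEED = "inverse_speed"
    ALL = (UNIT, INVERSE_SPEED)


class InitOrientation:
    UNIFORM_RANDOM = "uniform_random"
    FIXED = "fixed"
    ALL = (UNIFORM_RANDOM, FIXED)


class InitSpeed:
    UNIFORM = "uniform"
    HALF_NORMAL = "half_normal"
    CONSTANT = "constant"
    ALL = (UNIFORM, HALF_NORMAL, CONSTANT)


def wrap_angle(angle):
    """Wrap an angle (scalar or array) to the interval ``[0, 2*pi)``.

    The result is congruent to ``angle`` modulo ``2*pi``.  Non-finite
    input raises ``ValueError``.
    """
    arr = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("wrap_angle requires finite input")
    wrapped = np.mod(arr, TWO_PI)
    # np.mod can return 2*pi itself for tiny negative inputs; fold it back
    wrapped = np.where(wrapped >= TWO_PI, wrapped - TWO_PI, wrapped)
    if np.isscalar(angle) or arr.ndim == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class Domain:
    """Periodic square simulation box of side ``L``.

    Only fully periodic boxes are supported; positions are stored in
    ``[0, L)`` on each axis.
    """

    L: float
    periodic: bool = True

    def __post_init__(self):
        if not (self.L > 0):
            raise ConfigError("L must be positive")
        if not self.periodic:
            raise ConfigError("only periodic domains are supported")

    def wrap_positions(self, positions: np.ndarray) -> np.ndarray:
        """Fold positions into ``[0, L)`` on each axis."""
        return np.mod(positions, self.L)

    def contains(self, positions: np.ndarray) -> bool:
        return bool(np.all((positions >= 0) & (positions < self.L)))


@dataclass
class ParticleState:
    """Positions, orientations and speeds of all agents at one instant."""

    t: float
    positions: np.ndarray  # (N, 2)
    orientations: np.ndarray  # (N,), radians in [0, 2*pi)
    speeds: np.ndarray  # (N,), >= 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        self.speeds = np.asarray(self.speeds, dtype=float)
        n = len(self.positions)
        if n < 1:
            raise ValueError("state must contain at least one agent")
        if self.positions.shape != (n, 2):
            raise ValueError("positions must have shape (N, 2)")
        if self.orientations.shape != (n,) or self.speeds.shape != (n,):
            raise ValueError("orientations and speeds must have shape (N,)")
        if np.any(self.orientations < 0) or np.any(self.orientations >= TWO_PI):
            raise ValueError("orientations must lie in [0, 2*pi)")
        if np.any(self.speeds < 0):
            raise ValueError("speeds must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.speeds)

    @property
    def complex_velocity(self) -> np.ndarray:
        """Normalized complex velocity ``z_n = exp(i theta_n)``."""
        return np.exp(1j * self.orientations)

    @property
    def velocities(self) -> np.ndarray:
        """Cartesian velocities ``v_n * (cos theta_n, sin theta_n)``, shape (N, 2)."""
        return self.speeds[:, None] * np.column_stack(
            (np.cos(self.orientations), np.sin(self.orientations))
        )

    def copy(self) -> "ParticleState":
        return ParticleState(
            t=self.t,
            positions=self.positions.copy(),
            orientations=self.orientations.copy(),
            speeds=self.speeds.copy(),
        )


@dataclass
class ModelParams:
    """All coefficients of the Langevin dynamics.

    Parameters
    ----------
    beta_theta : float
        Angular sensitivity.  Negative values drive each agent toward the
        local entropy minimum (parallel alignment with the neighborhood
        mean heading); positive values toward the maximum (anti-parallel).
    beta_v : float
        Radial (speed) sensitivity, coupling to the half-normal speed
        entropy of the neighborhood.
    R : float
        Interaction radius; neighbors are agents at distance <= R.
    noise_std_theta, noise_std_v : float
        Standard deviation of the *per-step* Gaussian noise increment on
        the heading / speed.  Relates to a diffusion coefficient by
        ``noise_std = sqrt(2 * D * dt)``; only the per-step std is stored.
    epsilon : float
        Proportionality constant of the density-dependent friction
        ``-epsilon * (rho_n - rho_bar) * v_n``.
    rho_bar : float or None
        Global mean density; when None it is filled as ``N / L**2`` by
        :func:`validate_config`.
    g_mode : str
        Angular-noise modulation: ``"unit"`` (g = 1) or
        ``"inverse_speed"`` (g = 1 / max(v, v_min)).
    dt : float
        Euler–Maruyama step.
    v_min : float
        Speed floor used by the inverse-speed noise modulation.
    s1_clip : float
        Regularization bound: the local polar order is clipped to
        ``[s1_clip, 1 - s1_clip]`` before taking logarithms, bounding the
        divergence of the logarithmic entropy potential.
    """

    beta_theta: float = 0.0
    beta_v: float = 0.0
    R: float = 3.0
    noise_std_theta: float = 0.01
    noise_std_v: float = 0.0
    epsilon: float = 0.0
    rho_bar: Optional[float] = None
    g_mode: str = GMode.UNIT
    dt: float = 0.1
    v_min: float = 0.01
    s1_clip: float = 1e-6


@dataclass
class SimulationConfig:
    """A complete, reproducible simulation specification."""

    params: ModelParams = field(default_factory=ModelParams)
    domain: Domain = field(default_factory=lambda: Domain(L=32.0))
    n_particles: int = 1000
    n_steps: int = 1000
    seed: int = 0
    init_orientation: str = InitOrientation.UNIFORM_RANDOM
    init_orientation_angle: float = 0.0
    init_speed: str = InitSpeed.UNIFORM
    init_speed_scale: float = 1.0
    record_every: int = 1

    def config_hash(self) -> str:
        """Stable hash of every field except the seed (provenance tag)."""
        payload = repr(
            (
                dataclasses.astuple(self.params),
                (self.domain.L, self.domain.periodic),
                self.n_particles,
                self.n_steps,
                self.init_orientation,
                self.init_orientation_angle,
                self.init_speed,
                self.init_speed_scale,
                self.record_every,
            )
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _require(cond: bool, message: str):
    if not cond:
        raise ConfigError(message)


def validate_config(config: SimulationConfig) -> SimulationConfig:
    """Validate a configuration and fill derived defaults.

    Returns a new, normalized :class:`SimulationConfig`; the input is not
    modified.  ``rho_bar`` is filled as ``N / L**2`` when unset.  Raises
    :class:`ConfigError` naming the offending field otherwise.
    """
    p = config.params
    d = config.domain
    _require(d.L > 0, "L must be positive")
    _require(p.R > 0, "R must be positive")
    _require(p.dt > 0, "dt must be positive")
    _require(p.noise_std_theta >= 0, "noise_std_theta must be nonnegative")
    _require(p.noise_std_v >= 0, "noise_std_v must be nonnegative")
    _require(p.epsilon >= 0, "epsilon must be nonnegative")
    _require(p.v_min > 0, "v_min must be positive")
    _require(0 < p.s1_clip < 1, "s1_clip must lie in (0, 1)")
    _require(p.g_mode in GMode.ALL, f"g_mode must be one of {GMode.ALL}")
    _require(config.n_particles >= 1, "n_particles must be at least 1")
    _require(config.n_steps >= 0, "n_steps must be nonnegative")
    _require(config.record_every >= 1, "record_every must be at least 1")
    _require(
        config.init_orientation in InitOrientation.ALL,
        f"init_orientation must be one of {InitOrientation.ALL}",
    )
    _require(
        config.init_speed in InitSpeed.ALL,
        f"init_speed must be one of {InitSpeed.ALL}",
    )
    _require(config.init_speed_scale > 0, "init_speed_scale must be positive")
    if p.rho_bar is not None:
        _require(p.rho_bar >= 0, "rho_bar must be nonnegative")

    rho_bar = p.rho_bar
    if rho_bar is None:
        rho_bar = config.n_particles / d.L**2

    params = dataclasses.replace(p, rho_bar=rho_bar)
    return dataclasses.replace(config, params=params)
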