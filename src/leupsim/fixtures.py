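"""Deterministic synthetic particle states for testing the analysis stack.

Every fixture is a valid :class:`~leupsim.model.ParticleState` with a
known analytic property (perfect order, zero polar order, rigid-body
rotation, exact sampling distributions), so each observable can be
tested without running the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Domain, ParticleState, wrap_angle

__all__ = ["FixtureSpec", "make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = (
    "ALIGNED",
    "ANTIPARALLEL_PAIRS",
    "RIGID_ROTATION",
    "UNIFORM_RANDOM",
    "WRAPPED_CAUCHY_SAMPLE",
    "RAYLEIGH_SPEEDS",
)


@dataclass
class FixtureSpec:
    """Recipe for a synthetic state; same (spec, seed) -> identical state."""

    name: str
    size: int = 100
    angle: float = 0.0  # common heading / distribution mean mu
    angular_velocity: float = 1.0  # rigid-rotation rate
    gamma: float = 1.0  # wrapped-Cauchy concentration
    sigma: float = 1.0  # Rayleigh scale
    speed: float = 1.0  # common speed where headings are prescribed
    seed: int = 0


def make_fixture(spec: FixtureSpec, domain: Domain) -> ParticleState:
    """Materialize a fixture state inside ``domain``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    if n < 1:
        raise ValueError("fixture size must be at least 1")
    positions = rng.uniform(0.0, domain.L, size=(n, 2))
    speeds = np.full(n, float(spec.speed))

    if spec.name == "ALIGNED":
        orientations = np.full(n, wrap_angle(spec.angle))
    elif spec.name == "ANTIPARALLEL_PAIRS":
        half = n // 2
        orientations = np.concatenate(
            (
                np.full(half, wrap_angle(spec.angle)),
                np.full(n - half, wrap_angle(spec.angle + np.pi)),
            )
        )
    elif spec.name == "RIGID_ROTATION":
        # tangential velocities around the box center: v = omega x r
        center = domain.L / 2.0
        dx = positions[:, 0] - center
        dy = positions[:, 1] - center
        vx = -spec.angular_velocity * dy
        vy = spec.angular_velocity * dx
        orientations = np.mod(np.arctan2(vy, vx), 2 * np.pi)
        speeds = np.hypot(vx, vy)
    elif spec.name == "UNIFORM_RANDOM":
        orientations = rng.uniform(0.0, 2 * np.pi, size=n)
    elif spec.name == "WRAPPED_CAUCHY_SAMPLE":
        if spec.gamma <= 0:
            raise ValueError("gamma must be positive")
        # wrapping a linear Cauchy(mu, gamma) sample yields the wrapped
        # Cauchy with first circular moment exp(-gamma)
        u = rng.uniform(0.0, 1.0, size=n)
        orientations = np.mod(
            spec.angle + spec.gamma * np.tan(np.pi * (u - 0.5)), 2 * np.pi
        )
    elif spec.name == "RAYLEIGH_SPEEDS":
        orientations = rng.uniform(0.0, 2 * np.pi, size=n)
        speeds = rng.rayleigh(spec.sigma, size=n)
    else:
        raise ValueError(f"unknown fixture name {spec.name!r}")

    return ParticleState(
        t=0.0, positions=positions, orientations=orientations, speeds=speeds
    )
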