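"""Closed-form statistical mechanics of the neighborhood distributions.

Neighborhood orientations are modeled as wrapped-Cauchy distributed with
concentration ``gamma`` and mean ``mu``; neighborhood speeds as
half-normal with scale ``sigma``.  Their differential entropies have the
closed forms

    S_angular(gamma)   = ln(2*pi) + ln(1 - exp(-2*gamma))
    S_speed(sigma**2)  = 0.5 * ln(pi * sigma**2 / 2) + 0.5

``gamma`` is tied to the local polar order ``S1`` of the neighborhood by
``gamma = -ln(S1)`` (a property of the wrapped Cauchy: the modulus of its
first circular moment is ``exp(-gamma)``), and ``sigma**2`` is estimated
as the neighborhood mean of squared speeds (the half-normal maximum
likelihood scale).

Conventions (they make the entropy gradients non-trivial):

* the *local polar order* ``S1`` entering ``gamma`` includes the focal
  agent's own orientation — otherwise the angular entropy would not
  depend on ``theta_n`` and the reorientation force would vanish;
* the *mean-heading sums* ``vbar_x, vbar_y`` exclude the focal agent, so
  the entropy is stationary exactly at ``theta_n = theta_bar`` (minimum,
  parallel to the neighbors' mean heading) and ``theta_bar + pi``
  (maximum, anti-parallel);
* ``sigma**2`` includes the focal agent's speed.

Because the entropies are logarithmic potentials they diverge as the
neighborhood becomes perfectly ordered or perfectly still; ``S1`` is
clipped to ``[s1_clip, 1 - s1_clip]`` and ``sigma**2`` floored at 1e-12.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import ModelParams, ParticleState, wrap_angle
from .neighbors import NeighborIndex, local_densities

__all__ = [
    "NeighborhoodStats",
    "FreeEnergyResult",
    "wrapped_cauchy_pdf",
    "angular_entropy",
    "speed_entropy",
    "gamma_from_polar_order",
    "neighborhood_stats",
    "angular_entropy_gradient",
    "speed_entropy_gradient",
    "angular_entropy_gradients",
    "speed_entropy_gradients",
    "classify_entropy_extrema",
    "helmholtz_free_energy",
]

LN_2PI = math.log(2.0 * math.pi)
SIGMA_SQ_FLOOR = 1e-12


def wrapped_cauchy_pdf(theta, mu, gamma):
    """Wrapped-Cauchy density on ``[0, 2*pi)``.

    ``sinh(gamma) / (2*pi * (cosh(gamma) - cos(theta - mu)))``; requires
    ``gamma > 0``.  Approaches the uniform density ``1/(2*pi)`` as
    ``gamma -> inf`` and a delta at ``mu`` as ``gamma -> 0+``.
    """
    if not np.all(np.asarray(gamma) > 0):
        raise ValueError("gamma must be positive")
    theta = np.asarray(theta, dtype=float)
    return np.sinh(gamma) / (2.0 * np.pi * (np.cosh(gamma) - np.cos(theta - mu)))


def angular_entropy(gamma):
    """Differential entropy of the wrapped Cauchy: ``ln(2*pi) + ln(1 - e^{-2*gamma})``.

    Strictly increasing in ``gamma``; tends to ``ln(2*pi)`` (uniform) as
    ``gamma -> inf`` and diverges to ``-inf`` as ``gamma -> 0+`` (callers
    must clip first).
    """
    g = np.asarray(gamma, dtype=float)
    if not np.all(g > 0):
        raise ValueError("gamma must be positive")
    out = LN_2PI + np.log1p(-np.exp(-2.0 * g))
    return float(out) if np.ndim(gamma) == 0 else out


def speed_entropy(sigma_sq):
    """Differential entropy of the half-normal: ``0.5*ln(pi*sigma^2/2) + 0.5``."""
    s2 = np.asarray(sigma_sq, dtype=float)
    if not np.all(s2 > 0):
        raise ValueError("sigma_sq must be positive")
    out = 0.5 * np.log(np.pi * s2 / 2.0) + 0.5
    return float(out) if np.ndim(sigma_sq) == 0 else out


def gamma_from_polar_order(s1, s1_clip: float = 1e-6):
    """Concentration ``gamma = -ln(S1)`` with ``S1`` clipped away from 0 and 1.

    ``s1`` must lie in ``[0, 1]``; the clip keeps the result finite and
    positive for the boundary cases of total disorder (``S1 = 0``) and
    perfect alignment (``S1 = 1``).
    """
    arr = np.asarray(s1, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("polar order must lie in [0, 1]")
    out = -np.log(np.clip(arr, s1_clip, 1.0 - s1_clip))
    return float(out) if np.ndim(s1) == 0 else out


@dataclass
class NeighborhoodStats:
    """Per-agent local quantities feeding the entropy gradients."""

    n_area: int  # agents in the circular neighborhood, focal included
    vbar_x: float  # sum of cos(theta_m) over neighbors, focal excluded
    vbar_y: float  # sum of sin(theta_m) over neighbors, focal excluded
    theta_bar: float  # mean neighbor heading atan2(vbar_y, vbar_x)
    s1_local: float  # local polar order, focal included, clipped
    gamma: float  # -ln(s1_local)
    sigma_sq: float  # mean squared speed, focal included, floored
    rho: float  # local density (focal counted)
    degenerate: bool  # True when the agent has no neighbors


@dataclass
class FreeEnergyResult:
    """Helmholtz free energy of the weakly interacting steady state."""

    value: float  # total F (nan when invalid)
    per_cell: float
    valid: bool
    reason: str
    beta_theta: float
    gamma_n: float
    n_cells: int


class _AllStats:
    """Vectorized neighborhood statistics for every agent at once."""

    __slots__ = (
        "n_area",
        "vbar_x",
        "vbar_y",
        "s1_raw",
        "s1_clipped",
        "gamma",
        "sigma_sq",
        "rho",
    )

    def __init__(self, state: ParticleState, index: NeighborIndex, params: ModelParams):
        cos_t = np.cos(state.orientations)
        sin_t = np.sin(state.orientations)
        sq_v = state.speeds**2
        counts = index.counts
        row = np.repeat(np.arange(state.n), counts)

        vbar_x = np.bincount(row, weights=cos_t[index.indices], minlength=state.n)
        vbar_y = np.bincount(row, weights=sin_t[index.indices], minlength=state.n)
        sum_sq = np.bincount(row, weights=sq_v[index.indices], minlength=state.n)

        n_area = counts + 1
        cx = vbar_x + cos_t
        cy = vbar_y + sin_t
        s1_raw = np.sqrt(cx**2 + cy**2) / n_area
        s1_clipped = np.clip(s1_raw, params.s1_clip, 1.0 - params.s1_clip)

        self.n_area = n_area
        self.vbar_x = vbar_x
        self.vbar_y = vbar_y
        self.s1_raw = s1_raw
        self.s1_clipped = s1_clipped
        self.gamma = -np.log(s1_clipped)
        self.sigma_sq = np.maximum((sum_sq + sq_v) / n_area, SIGMA_SQ_FLOOR)
        self.rho = local_densities(index)


def compute_all_stats(
    state: ParticleState, index: NeighborIndex, params: ModelParams
) -> _AllStats:
    return _AllStats(state, index, params)


def neighborhood_stats(
    state: ParticleState, n: int, index: NeighborIndex, params: ModelParams
) -> NeighborhoodStats:
    """Neighborhood statistics of a single agent (see module conventions)."""
    nb = index.neighbors(n)
    cos_nb = np.cos(state.orientations[nb])
    sin_nb = np.sin(state.orientations[nb])
    vbar_x = float(cos_nb.sum())
    vbar_y = float(sin_nb.sum())
    n_area = len(nb) + 1
    cx = vbar_x + math.cos(state.orientations[n])
    cy = vbar_y + math.sin(state.orientations[n])
    s1_raw = math.hypot(cx, cy) / n_area
    s1 = min(max(s1_raw, params.s1_clip), 1.0 - params.s1_clip)
    sigma_sq = max(
        float((state.speeds[nb] ** 2).sum() + state.speeds[n] ** 2) / n_area,
        SIGMA_SQ_FLOOR,
    )
    return NeighborhoodStats(
        n_area=n_area,
        vbar_x=vbar_x,
        vbar_y=vbar_y,
        theta_bar=math.atan2(vbar_y, vbar_x) % (2.0 * math.pi),
        s1_local=s1,
        gamma=-math.log(s1),
        sigma_sq=sigma_sq,
        rho=n_area / (math.pi * index.R**2),
        degenerate=len(nb) == 0,
    )


def _angular_gradient_arrays(stats: _AllStats, theta: np.ndarray, s1_clip: float):
    """d/d theta_n of the neighborhood angular entropy, vectorized.

    Chain rule dS/dgamma * dgamma/dS1 * dS1/dtheta_n with
    dS/dgamma = 2 e^{-2 gamma} / (1 - e^{-2 gamma}),  dgamma/dS1 = -1/S1,
    dS1/dtheta_n = (cos(theta_n) vbar_y - sin(theta_n) vbar_x) / (N_A^2 S1).
    With gamma = -ln(S1) the product collapses to
    -2 (cos vbar_y - sin vbar_x) / (N_A^2 (1 - S1^2)), evaluated on the
    clipped S1 (zero derivative inside the clipped region is approximated
    by clipping both occurrences of S1).
    """
    num = np.cos(theta) * stats.vbar_y - np.sin(theta) * stats.vbar_x
    s1c = stats.s1_clipped
    one_minus_sq = (1.0 - s1c) * (1.0 + s1c)
    ratio = s1c / np.maximum(stats.s1_raw, s1_clip)
    return -2.0 * num * ratio / (stats.n_area**2 * one_minus_sq)


def angular_entropy_gradients(
    state: ParticleState, index: NeighborIndex, params: ModelParams
) -> np.ndarray:
    """Analytic ``dS(Theta_n | theta_n)/d theta_n`` for every agent."""
    stats = _AllStats(state, index, params)
    return _angular_gradient_arrays(stats, state.orientations, params.s1_clip)


def speed_entropy_gradients(
    state: ParticleState, index: NeighborIndex, params: ModelParams
) -> np.ndarray:
    """Analytic ``dS(V_n | v_n)/d v_n = v_n / (N_A sigma^2)`` for every agent."""
    stats = _AllStats(state, index, params)
    return state.speeds / (stats.n_area * stats.sigma_sq)


def angular_entropy_gradient(
    state: ParticleState, n: int, index: NeighborIndex, params: ModelParams
) -> float:
    """Single-agent angular entropy gradient (zero for isolated agents)."""
    grads = angular_entropy_gradients(state, index, params)
    return float(grads[n])


def speed_entropy_gradient(
    state: ParticleState, n: int, index: NeighborIndex, params: ModelParams
) -> float:
    grads = speed_entropy_gradients(state, index, params)
    return float(grads[n])


def classify_entropy_extrema(stats: NeighborhoodStats):
    """Headings extremizing the neighborhood angular entropy.

    The entropy is minimal when the focal agent is parallel to the mean
    neighbor heading (``theta_min = theta_bar``, the Vicsek-like aligned
    state) and maximal anti-parallel (``theta_max = theta_bar + pi``).
    Raises for degenerate neighborhoods where the neighbor headings
    cancel and no mean orientation exists.
    """
    if stats.degenerate or math.hypot(stats.vbar_x, stats.vbar_y) < 1e-12:
        raise ValueError("no well-defined mean orientation")
    theta_min = stats.theta_bar
    return wrap_angle(theta_min), wrap_angle(theta_min + math.pi)


def helmholtz_free_energy(
    beta_theta: float, gamma_n: float, n_cells: int = 1
) -> FreeEnergyResult:
    """Closed-form Helmholtz free energy of the weakly interacting steady state.

    Per cell: ``(1 - 1/beta) ln(gamma_n) + ln(4*pi) + ln(1 - beta)/beta``.
    Well-defined only for ``beta_theta < 1`` — no steady state exists at
    or above 1.  At ``beta_theta = 0`` the singular coefficients are
    replaced by their finite parts (``ln(1 - beta)/beta -> -1`` and the
    ``gamma`` coefficient by 1); for ``gamma_n = 1`` this is the true
    ``beta -> 0`` limit, elsewhere a regularized value.
    """
    if gamma_n <= 0:
        raise ValueError("gamma_n must be positive")
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    if beta_theta >= 1:
        return FreeEnergyResult(
            value=math.nan,
            per_cell=math.nan,
            valid=False,
            reason="free energy undefined for beta_theta >= 1 (no steady state)",
            beta_theta=beta_theta,
            gamma_n=gamma_n,
            n_cells=n_cells,
        )
    if beta_theta == 0.0:
        per_cell = math.log(gamma_n) + math.log(4.0 * math.pi) - 1.0
    else:
        per_cell = (
            (1.0 - 1.0 / beta_theta) * math.log(gamma_n)
            + math.log(4.0 * math.pi)
            + math.log1p(-beta_theta) / beta_theta
        )
    return FreeEnergyResult(
        value=n_cells * per_cell,
        per_cell=per_cell,
        valid=True,
        reason="",
        beta_theta=beta_theta,
        gamma_n=gamma_n,
        n_cells=n_cells,
    )
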