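"""Macroscopic observables: order parameters, vorticity, distribution checks.

The polar order parameter ``S1 = |<e^{i theta}>|`` measures global
parallel alignment; the nematic order parameter ``S2 = |<e^{2 i theta}>|``
measures alignment along a single axis regardless of direction.  Both lie
in [0, 1]; perfect polar order implies perfect nematic order but not
conversely.

The vorticity ``omega = curl(v_mean) . k`` (twice the local angular
velocity) is estimated by binning agent velocities onto a square grid
and taking periodic central finite differences of the bin means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats as sps

from .model import Domain, ParticleState, SimulationConfig

__all__ = [
    "OrderParameters",
    "VorticityField",
    "order_parameters",
    "vorticity_field",
    "mean_abs_vorticity",
    "orientation_histogram",
    "peak_separation",
    "PeakSeparation",
    "rayleigh_fit_check",
    "ensemble_summary",
    "summarize_state",
]


@dataclass(frozen=True)
class OrderParameters:
    s1: float  # polar order, in [0, 1]
    s2: float  # nematic order, in [0, 1]
    area: str = "global"


def order_parameters(orientations, area: str = "global") -> OrderParameters:
    """Moduli of the first and second moments of ``e^{i theta}``."""
    theta = np.asarray(orientations, dtype=float)
    if theta.size == 0:
        raise ValueError("order_parameters requires at least one orientation")
    z = np.exp(1j * theta)
    return OrderParameters(
        s1=float(abs(z.mean())), s2=float(abs((z**2).mean())), area=area
    )


@dataclass
class VorticityField:
    """Binned mean-velocity field and its curl on a periodic grid."""

    v_mean: np.ndarray  # (nx, ny, 2) bin-mean velocities (empty bins filled)
    omega: np.ndarray  # (nx, ny) vorticity
    bin_size: float
    empty_mask: np.ndarray  # (nx, ny) True where the bin held no agents
    mean_speed: float  # population mean speed of the binned state


def _fill_empty_bins(grid: np.ndarray, empty: np.ndarray) -> np.ndarray:
    """Fill empty bins by iterative periodic nearest-neighbor averaging."""
    filled = grid.copy()
    todo = empty.copy()
    while todo.any():
        have = ~todo
        acc = np.zeros_like(filled)
        cnt = np.zeros(todo.shape, dtype=float)
        for axis in (0, 1):
            for shift in (-1, 1):
                acc += np.where(
                    np.roll(have, shift, axis=axis)[..., None],
                    np.roll(filled, shift, axis=axis),
                    0.0,
                )
                cnt += np.roll(have, shift, axis=axis)
        ready = todo & (cnt > 0)
        if not ready.any():  # fully empty field cannot be filled
            break
        filled[ready] = acc[ready] / cnt[ready][..., None]
        todo &= ~ready
    return filled


def vorticity_field(
    state: ParticleState, domain: Domain, bin_size: float
) -> VorticityField:
    """Estimate the vorticity of the coarse-grained velocity field.

    Velocities ``v_n (cos theta_n, sin theta_n)`` are averaged per grid
    bin; ``omega = d v_y/d x - d v_x/d y`` via periodic central
    differences.  Bins without agents are filled by nearest-neighbor
    interpolation and reported in ``empty_mask``.
    """
    L = domain.L
    n_bins = int(L / bin_size)
    if n_bins < 3:
        raise ValueError("bin_size yields fewer than 3 bins per axis")
    h = L / n_bins

    ix = np.minimum((state.positions[:, 0] // h).astype(int), n_bins - 1)
    iy = np.minimum((state.positions[:, 1] // h).astype(int), n_bins - 1)
    flat = ix * n_bins + iy
    vel = state.velocities
    counts = np.bincount(flat, minlength=n_bins * n_bins)
    sums = np.column_stack(
        [np.bincount(flat, weights=vel[:, k], minlength=n_bins * n_bins) for k in (0, 1)]
    )
    empty = (counts == 0).reshape(n_bins, n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        v_mean = (sums / np.maximum(counts, 1)[:, None]).reshape(n_bins, n_bins, 2)
    v_mean = _fill_empty_bins(v_mean, empty)

    # periodic central differences; axis 0 is x, axis 1 is y
    dvy_dx = (np.roll(v_mean[..., 1], -1, axis=0) - np.roll(v_mean[..., 1], 1, axis=0)) / (2 * h)
    dvx_dy = (np.roll(v_mean[..., 0], -1, axis=1) - np.roll(v_mean[..., 0], 1, axis=1)) / (2 * h)
    omega = dvy_dx - dvx_dy
    return VorticityField(
        v_mean=v_mean,
        omega=omega,
        bin_size=h,
        empty_mask=empty,
        mean_speed=float(state.speeds.mean()),
    )


def mean_abs_vorticity(field: VorticityField, normalized: bool = True) -> float:
    """Mean of ``|omega|`` over occupied bins.

    With ``normalized=True`` (default) the mean is divided by the
    population mean speed, making the observable comparable across
    densities and speed scales.
    """
    keep = ~field.empty_mask
    if not keep.any():
        raise ValueError("all bins are empty")
    value = float(np.abs(field.omega[keep]).mean())
    if normalized:
        if field.mean_speed <= 0:
            raise ValueError("mean speed is zero; cannot normalize vorticity")
        value /= field.mean_speed
    return value


def orientation_histogram(orientations, n_bins: int = 36):
    """Circular histogram density of orientations on ``[0, 2*pi)``.

    Returns ``(densities, bin_edges)``; densities integrate to 1.
    """
    theta = np.asarray(orientations, dtype=float)
    if theta.size == 0:
        raise ValueError("orientation_histogram requires data")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    dens, edges = np.histogram(
        np.mod(theta, 2 * np.pi), bins=n_bins, range=(0.0, 2 * np.pi), density=True
    )
    return dens, edges


@dataclass
class PeakSeparation:
    separation: Optional[float]  # circular distance between the two main peaks
    unimodal: bool
    peak_angles: List[float]


def peak_separation(
    histogram, min_prominence_frac: float = 0.1
) -> PeakSeparation:
    """Circular distance between the two highest peaks of a histogram.

    The histogram counts are smoothed with a circular 3-bin moving
    average; peaks are circular local maxima with prominence at least
    ``min_prominence_frac`` of the highest smoothed value.  Fewer than
    two such peaks flags the distribution unimodal.
    """
    dens, edges = histogram
    dens = np.asarray(dens, dtype=float)
    nb = len(dens)
    centers = 0.5 * (edges[:-1] + edges[1:])
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(np.concatenate((dens[-1:], dens, dens[:1])), kernel, "same")[1:-1]

    tiled = np.concatenate((smooth, smooth, smooth))
    peaks, props = signal.find_peaks(
        tiled, prominence=min_prominence_frac * smooth.max()
    )
    main = peaks[(peaks >= nb) & (peaks < 2 * nb)] - nb
    if len(main) < 2:
        angle = [float(centers[main[0]])] if len(main) else []
        return PeakSeparation(separation=None, unimodal=True, peak_angles=angle)
    top2 = main[np.argsort(smooth[main])[::-1][:2]]
    a, b = centers[top2[0]], centers[top2[1]]
    d = abs(a - b) % (2 * np.pi)
    d = min(d, 2 * np.pi - d)
    return PeakSeparation(
        separation=float(d), unimodal=False, peak_angles=[float(a), float(b)]
    )


def rayleigh_fit_check(speeds):
    """Maximum-likelihood Rayleigh scale and a one-sample KS p-value.

    ``sigma_hat = sqrt(mean(v^2) / 2)``; the KS test is against
    Rayleigh(sigma_hat) with location 0.  Requires >= 50 nonnegative
    samples.
    """
    v = np.asarray(speeds, dtype=float)
    if v.size < 50:
        raise ValueError("need at least 50 speed samples")
    if np.any(v < 0):
        raise ValueError("speeds must be nonnegative")
    sigma_hat = math.sqrt(float((v**2).mean()) / 2.0)
    if sigma_hat == 0.0:
        return sigma_hat, 0.0
    result = sps.kstest(v, "rayleigh", args=(0.0, sigma_hat))
    return sigma_hat, float(result.pvalue)


def summarize_state(
    state: ParticleState, domain: Domain, vorticity_bin_size: Optional[float] = None
) -> dict:
    """Scalar observables of one snapshot: t, S1, S2, mean speed, mean |omega|."""
    op = order_parameters(state.orientations)
    row = {
        "t": state.t,
        "S1": op.s1,
        "S2": op.s2,
        "mean_speed": float(state.speeds.mean()),
    }
    if vorticity_bin_size is not None:
        field = vorticity_field(state, domain, vorticity_bin_size)
        row["mean_abs_vorticity"] = mean_abs_vorticity(field)
    return row


def ensemble_summary(
    configs: Sequence[SimulationConfig],
    reducers: Optional[dict] = None,
    vorticity_bin_size: Optional[float] = None,
) -> pd.DataFrame:
    """Run an ensemble of configs differing only in seed; aggregate finals.

    Returns a DataFrame with one row per observable carrying the mean
    and standard deviation over realizations at the final recorded
    snapshot.  ``reducers`` maps extra observable names to callables
    ``f(state, domain) -> float``.
    """
    from .dynamics import run_simulation  # deferred: avoids module cycle

    if len(configs) < 2:
        raise ValueError("an ensemble needs at least 2 realizations")
    ref = configs[0].config_hash()
    for c in configs[1:]:
        if c.config_hash() != ref:
            raise ValueError("ensemble configs differ in more than the seed")

    rows = []
    for c in configs:
        traj = run_simulation(c)
        row = summarize_state(traj.final_state, c.domain, vorticity_bin_size)
        if reducers:
            for name, fn in reducers.items():
                row[name] = fn(traj.final_state, c.domain)
        row["seed"] = c.seed
        rows.append(row)
    per_seed = pd.DataFrame(rows)
    observables = [c for c in per_seed.columns if c not in ("seed", "t")]
    agg = per_seed[observables].agg(["mean", "std"]).T.reset_index()
    agg.columns = ["observable", "mean", "sd"]
    agg.attrs["per_seed"] = per_seed
    return agg
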