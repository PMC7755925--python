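"""Periodic-geometry neighbor queries.

Fixed-radius neighbor search on the periodic box via a vectorized cell
list: the box is tiled by ``m x m`` square cells of side ``>= R`` and each
agent's candidates are gathered from the 3 x 3 block of cells around its
own, then filtered by minimum-image distance.  When fewer than three
cells fit per axis the query degenerates (correctly) to all-pairs.

Neighbor sets exclude the focal agent; the distance threshold is
inclusive (``<= R``) with direct floating-point comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import Domain, ParticleState

__all__ = [
    "NeighborIndex",
    "minimum_image_displacement",
    "build_neighbor_index",
    "local_density",
]


def minimum_image_displacement(p, q, domain: Domain) -> np.ndarray:
    """Shortest displacement ``q - p`` on the periodic box.

    Each component of the result lies in ``[-L/2, L/2)``.  Positions must
    lie inside the box.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    L = domain.L
    if np.any(p < 0) or np.any(p >= L) or np.any(q < 0) or np.any(q >= L):
        raise ValueError("positions must lie in [0, L) on each axis")
    d = q - p
    d -= L * np.floor(d / L + 0.5)
    return d


@dataclass
class NeighborIndex:
    """CSR-style radius-R neighbor sets for all agents.

    ``indices[indptr[n]:indptr[n + 1]]`` are the neighbors of agent ``n``
    (focal agent excluded).  Sets are symmetric by construction.
    """

    indptr: np.ndarray  # (N + 1,)
    indices: np.ndarray  # (total pairs * 2,)
    R: float

    @property
    def n_agents(self) -> int:
        return len(self.indptr) - 1

    @property
    def counts(self) -> np.ndarray:
        """Number of neighbors of each agent (focal excluded)."""
        return np.diff(self.indptr)

    def neighbors(self, n: int) -> np.ndarray:
        return self.indices[self.indptr[n] : self.indptr[n + 1]]

    def as_sets(self) -> list:
        return [set(self.neighbors(n).tolist()) for n in range(self.n_agents)]


def _candidate_pairs_cell_list(pos: np.ndarray, R: float, L: float):
    """Directed candidate pairs (i, j) from the 3x3 cell neighborhood."""
    n = len(pos)
    m = int(L // R)
    cell_side = L / m
    cx = np.minimum((pos[:, 0] // cell_side).astype(np.int64), m - 1)
    cy = np.minimum((pos[:, 1] // cell_side).astype(np.int64), m - 1)

    cid = cx * m + cy
    order = np.argsort(cid, kind="stable")
    counts = np.bincount(cid, minlength=m * m)
    starts = np.concatenate(([0], np.cumsum(counts)))

    all_i = []
    all_j = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            ncid = ((cx + dx) % m) * m + (cy + dy) % m
            cnt = counts[ncid]
            total = int(cnt.sum())
            if total == 0:
                continue
            rep_i = np.repeat(np.arange(n), cnt)
            block_start = np.repeat(starts[ncid], cnt)
            csum = np.concatenate(([0], np.cumsum(cnt)))
            within = np.arange(total) - np.repeat(csum[:-1], cnt)
            all_i.append(rep_i)
            all_j.append(order[block_start + within])
    return np.concatenate(all_i), np.concatenate(all_j)


def build_neighbor_index(
    state: ParticleState, R: float, domain: Domain
) -> NeighborIndex:
    """Build the radius-``R`` neighbor index for every agent.

    Equivalent to brute-force all-pairs thresholding at minimum-image
    distance ``<= R``.  Emits a warning when ``R >= L/2`` (every pair is
    then within one image; the query is still correct).
    """
    if R <= 0:
        raise ValueError("R must be positive")
    L = domain.L
    if R >= L / 2:
        warnings.warn(
            "R >= L/2: neighbor query degenerates to all-pairs", stacklevel=2
        )
    pos = state.positions
    n = state.n

    if int(L // R) >= 3 and n > 1:
        i, j = _candidate_pairs_cell_list(pos, R, L)
    else:
        i, j = np.divmod(np.arange(n * n), n)

    d = pos[j] - pos[i]
    d -= L * np.floor(d / L + 0.5)
    keep = (i != j) & (d[:, 0] ** 2 + d[:, 1] ** 2 <= R * R)
    i = i[keep]
    j = j[keep]

    order = np.argsort(i, kind="stable")
    indices = j[order]
    counts = np.bincount(i, minlength=n)
    indptr = np.concatenate(([0], np.cumsum(counts)))
    return NeighborIndex(indptr=indptr, indices=indices, R=float(R))


def local_density(
    state: ParticleState, n: int, R: float, domain: Domain, index: NeighborIndex = None
) -> float:
    """Local density around agent ``n``: ``(|neighbors| + 1) / (pi R^2)``.

    The focal agent is counted (a cell contributes to its own crowding)
    even though it is excluded from the stored neighbor sets.
    """
    if index is None:
        index = build_neighbor_index(state, R, domain)
    return (len(index.neighbors(n)) + 1) / (np.pi * R**2)


def local_densities(index: NeighborIndex) -> np.ndarray:
    """Vectorized local densities for every agent (focal counted)."""
    return (index.counts + 1) / (np.pi * index.R**2)
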