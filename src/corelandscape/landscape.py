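"""Population-based free-energy landscapes: binning, Boltzmann inversion,
basin detection and minimax barrier analysis.

Relative state populations N_i are converted to free energies via
E_i = -ln(N_i / N_max) in units of k_BT (Boltzmann inversion, no
pseudocounts; the energy reference is the most populated bin).  Empty
bins are masked and treated as impassable, so a barrier computed across
a sparsely sampled ridge is honestly a lower bound.  Basins are
catchments of local minima under 8-connectivity; the barrier between two
basins is the minimax path energy (the lowest ridge crossing) minus the
starting basin's minimum energy.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .surface import ParticleSet

__all__ = [
    "LandscapeGrid",
    "Basin",
    "BarrierResult",
    "bin_particles",
    "boltzmann_invert",
    "find_basins",
    "find_barrier",
    "assign_states",
    "DegenerateBinningError",
]

_NEIGHBORS8 = [
    (di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)
]


class DegenerateBinningError(ValueError):
    pass


@dataclass
class LandscapeGrid:
    """Binned particle counts and (optionally) inverted energies."""

    bin_edges_q1: np.ndarray
    bin_edges_q2: np.ndarray
    counts: np.ndarray  # (n1, n2) int
    energies: np.ndarray | None = None  # k_BT, NaN on empty bins

    @property
    def empty_mask(self) -> np.ndarray:
        return self.counts == 0

    @property
    def n_particles(self) -> int:
        return int(self.counts.sum())


@dataclass
class Basin:
    """An 8-connected catchment of one local minimum."""

    label: int
    member_bins: set = field(default_factory=set)
    minimum_bin: tuple[int, int] = (0, 0)
    minimum_energy: float = np.nan
    count: int = 0
    fraction: float = np.nan


@dataclass
class BarrierResult:
    """Directional barrier heights over the lowest connecting ridge."""

    saddle_energy: float
    saddle_bin: tuple[int, int] | None
    barrier_from_a: float
    barrier_from_b: float
    lower_bound: bool  # True when no populated path connects the basins


def _digitize(coords: np.ndarray, edges_q1: np.ndarray, edges_q2: np.ndarray):
    """Right-open bins, last bin closed (np.histogram2d semantics)."""
    i = np.searchsorted(edges_q1, coords[:, 0], side="right") - 1
    j = np.searchsorted(edges_q2, coords[:, 1], side="right") - 1
    i = np.clip(i, 0, len(edges_q1) - 2)
    j = np.clip(j, 0, len(edges_q2) - 2)
    inside = (
        (coords[:, 0] >= edges_q1[0])
        & (coords[:, 0] <= edges_q1[-1])
        & (coords[:, 1] >= edges_q2[0])
        & (coords[:, 1] <= edges_q2[-1])
    )
    return i, j, inside


def bin_particles(
    particles: ParticleSet, n_bins: tuple[int, int] = (30, 30)
) -> LandscapeGrid:
    """Histogram particle mode coordinates on an (n1, n2) grid.

    Edges span the observed coordinate range exactly; counts sum to n.
    """
    if particles.n == 0:
        raise ValueError("particle set is empty")
    if n_bins[0] < 2 or n_bins[1] < 2:
        raise ValueError("need at least 2x2 bins")
    q = particles.mode_coords
    for k, name in enumerate(("q1", "q2")):
        if np.ptp(q[:, k]) == 0:
            raise DegenerateBinningError(
                f"coordinate {name} has zero variance; landscape binning "
                "needs spread along both mode coordinates (check the mode "
                "projections or reduce the dimensionality of the analysis)"
            )
    counts, e1, e2 = np.histogram2d(q[:, 0], q[:, 1], bins=n_bins)
    return LandscapeGrid(e1, e2, counts.astype(int))


def boltzmann_invert(grid: LandscapeGrid) -> LandscapeGrid:
    """Fill energies E_i = -ln(N_i / N_max) (k_BT); empty bins become NaN."""
    if grid.counts.sum() == 0:
        raise ValueError("no non-empty bins to invert")
    nmax = grid.counts.max()
    with np.errstate(divide="ignore"):
        e = -np.log(grid.counts / nmax)
    e[grid.empty_mask] = np.nan
    grid.energies = e
    return grid


def _require_energies(grid: LandscapeGrid) -> np.ndarray:
    if grid.energies is None:
        raise ValueError("energies not filled; run boltzmann_invert first")
    return grid.energies


def find_basins(grid: LandscapeGrid) -> list[Basin]:
    """Watershed assignment of every non-empty bin to a local minimum.

    Bins are visited in order of increasing energy; a bin with no
    already-assigned lower-or-equal neighbor seeds a new basin, otherwise
    it joins the basin of its steepest (lowest-energy) assigned neighbor.
    Ties break deterministically on bin index.
    """
    e = _require_energies(grid)
    n1, n2 = e.shape
    filled = [
        (e[i, j], i, j) for i in range(n1) for j in range(n2) if np.isfinite(e[i, j])
    ]
    if not filled:
        raise ValueError("no non-empty bins")
    filled.sort()
    assignment: dict[tuple[int, int], int] = {}
    basins: list[Basin] = []
    for energy, i, j in filled:
        best = None
        for di, dj in _NEIGHBORS8:
            ni, nj = i + di, j + dj
            if (ni, nj) in assignment and e[ni, nj] <= energy:
                key = (e[ni, nj], ni, nj)
                if best is None or key < best[0]:
                    best = (key, assignment[(ni, nj)])
        if best is None:
            label = len(basins)
            basins.append(
                Basin(label=label, minimum_bin=(i, j), minimum_energy=energy)
            )
        else:
            label = best[1]
        assignment[(i, j)] = label
        basins[label].member_bins.add((i, j))
        basins[label].count += int(grid.counts[i, j])
    total = grid.n_particles
    for b in basins:
        b.fraction = b.count / total
    return basins


def find_barrier(grid: LandscapeGrid, basin_a: Basin, basin_b: Basin) -> BarrierResult:
    """Minimax barrier between two basins over 8-connected non-empty paths.

    barrier(a->b) = [min over paths of the path's maximum energy] minus the
    energy of basin a's minimum.  When no populated path exists, the
    result carries ``lower_bound=True`` and uses the maximum observed
    energy as the ridge estimate ("barrier at least this high").
    """
    e = _require_energies(grid)
    if basin_a.minimum_bin == basin_b.minimum_bin:
        return BarrierResult(basin_a.minimum_energy, basin_a.minimum_bin, 0.0, 0.0, False)

    start = basin_a.minimum_bin
    goal = basin_b.minimum_bin
    best = np.full(e.shape, np.inf)
    best[start] = e[start]
    heap = [(e[start], start)]
    argmax_bin = {start: start}
    while heap:
        ridge, (i, j) = heapq.heappop(heap)
        if ridge > best[i, j]:
            continue
        if (i, j) == goal:
            saddle_bin = argmax_bin[(i, j)]
            return BarrierResult(
                saddle_energy=ridge,
                saddle_bin=saddle_bin,
                barrier_from_a=ridge - basin_a.minimum_energy,
                barrier_from_b=ridge - basin_b.minimum_energy,
                lower_bound=False,
            )
        for di, dj in _NEIGHBORS8:
            ni, nj = i + di, j + dj
            if 0 <= ni < e.shape[0] and 0 <= nj < e.shape[1] and np.isfinite(e[ni, nj]):
                cand = max(ridge, e[ni, nj])
                if cand < best[ni, nj]:
                    best[ni, nj] = cand
                    argmax_bin[(ni, nj)] = (
                        (ni, nj) if e[ni, nj] >= ridge else argmax_bin[(i, j)]
                    )
                    heapq.heappush(heap, (cand, (ni, nj)))
    ridge = float(np.nanmax(e))
    return BarrierResult(
        saddle_energy=ridge,
        saddle_bin=None,
        barrier_from_a=ridge - basin_a.minimum_energy,
        barrier_from_b=ridge - basin_b.minimum_energy,
        lower_bound=True,
    )


def assign_states(
    particles: ParticleSet,
    grid: LandscapeGrid,
    basins: list[Basin],
    compression_threshold: float = 6.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Label each particle with its bin's basin; summarize basin fractions.

    A basin counts as "compressed" when its minimum lies at an absolute
    compression coordinate of at least ``compression_threshold`` (half the
    full 12 A compression range by default); the summary reports those
    basins' combined mass under ``is_compressed``.
    """
    e = _require_energies(grid)
    bin_to_basin = {}
    for b in basins:
        for ij in b.member_bins:
            bin_to_basin[ij] = b.label
    i, j, inside = _digitize(particles.mode_coords, grid.bin_edges_q1, grid.bin_edges_q2)
    labels = np.empty(particles.n, dtype=int)
    for k in range(particles.n):
        key = (int(i[k]), int(j[k]))
        if not inside[k] or key not in bin_to_basin:
            raise RuntimeError(
                "internal consistency error: particle falls in an empty bin "
                "of the grid built from the same particle set"
            )
        labels[k] = bin_to_basin[key]

    centers_q2 = 0.5 * (grid.bin_edges_q2[:-1] + grid.bin_edges_q2[1:])
    rows = []
    for b in basins:
        q2_min = centers_q2[b.minimum_bin[1]]
        rows.append(
            {
                "basin": b.label,
                "minimum_q1_bin": b.minimum_bin[0],
                "minimum_q2_bin": b.minimum_bin[1],
                "minimum_energy_kBT": b.minimum_energy,
                "count": b.count,
                "fraction": b.fraction,
                "is_compressed": bool(abs(q2_min) >= compression_threshold),
            }
        )
    return labels, pd.DataFrame(rows)
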