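"""Free-energy-surface and trajectory analysis.

Operations on regular CV-grid free-energy surfaces: basin detection by
persistence merging, the minimax (lowest free-energy) path between basins,
barrier heights, population-weighted basin free-energy differences, plus
per-selection RMSD/RMSF trajectory statistics.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .geometry import (Configuration, optimal_align, apply_superposition,
                       msd_after_alignment)

__all__ = [
    "Axis",
    "FESGrid",
    "Basin",
    "find_minima",
    "lowest_free_energy_path",
    "barrier_height",
    "basin_delta_f",
    "rmsd_series",
    "rmsf",
]


@dataclass
class Axis:
    """One CV grid dimension: [lo, hi) split into n equal bins, values at centers."""

    lo: float
    hi: float
    n: int
    label: str = ""

    @property
    def width(self) -> float:
        return (self.hi - self.lo) / self.n

    def centers(self) -> np.ndarray:
        return self.lo + (np.arange(self.n) + 0.5) * self.width


@dataclass
class FESGrid:
    """Free energy (kJ/mol) on a regular CV grid, minimum-referenced.

    Unvisited cells are NaN.  ``values`` has one axis per CV dimension.
    """

    axes: list[Axis]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(ax.n for ax in self.axes):
            raise ValueError("grid values shape does not match axes")
        vis = np.isfinite(self.values)
        if not vis.any():
            raise ValueError("FES has no visited cells")

    @property
    def visited(self) -> np.ndarray:
        return np.isfinite(self.values)

    def shifted_to_zero(self) -> "FESGrid":
        vmin = np.nanmin(self.values)
        return FESGrid(self.axes, self.values - vmin)

    def cell_coords(self, cell) -> np.ndarray:
        return np.array([ax.lo + (i + 0.5) * ax.width
                         for ax, i in zip(self.axes, cell)])

    def neighbors(self, cell):
        """Orthogonally adjacent visited cells."""
        for d in range(len(self.axes)):
            for step in (-1, 1):
                nb = list(cell)
                nb[d] += step
                if 0 <= nb[d] < self.axes[d].n:
                    nb = tuple(nb)
                    if np.isfinite(self.values[nb]):
                        yield nb


@dataclass
class Basin:
    """A metastable basin: its minimum and the connected cells within a depth."""

    label: str
    min_cell: tuple
    min_coords: np.ndarray
    f_min: float
    cells: list = field(default_factory=list)


def find_minima(fes: FESGrid, depth_threshold: float = 2.5) -> list[Basin]:
    """Detect basins as persistent local minima of the surface.

    Cells are flooded in order of increasing F with union-find merging; a
    local minimum survives as a separate basin only if the ridge connecting
    it to a deeper minimum lies at least ``depth_threshold`` kJ/mol above it
    (one default contour step).  Basin member cells are the orthogonally
    connected cells within ``depth_threshold`` of the basin minimum.
    Returned sorted by basin minimum, labelled 'A', 'B', ...
    """
    cells = [tuple(c) for c in np.argwhere(fes.visited)]
    cells.sort(key=lambda c: (fes.values[c], c))
    parent: dict = {}
    comp_min: dict = {}

    def root(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    basin_minima = []
    for c in cells:
        roots = {root(nb) for nb in fes.neighbors(c) if nb in parent}
        parent[c] = c
        if not roots:
            comp_min[c] = c
            continue
        roots = sorted(roots, key=lambda r: (fes.values[comp_min[r]], comp_min[r]))
        deepest = roots[0]
        for r in roots[1:]:
            persistence = fes.values[c] - fes.values[comp_min[r]]
            if persistence >= depth_threshold:
                basin_minima.append(comp_min[r])  # sealed: survives as a basin
            parent[r] = deepest
        parent[c] = deepest
    # remaining components (incl. the global minimum / disconnected regions)
    for r in {root(c) for c in parent}:
        basin_minima.append(comp_min[r])
    basin_minima = sorted(set(basin_minima), key=lambda c: (fes.values[c], c))

    basins = []
    for i, mc in enumerate(basin_minima):
        label = chr(ord("A") + i) if i < 26 else f"B{i}"
        fmin = float(fes.values[mc])
        members = _flood_below(fes, mc, fmin + depth_threshold)
        basins.append(Basin(label=label, min_cell=mc,
                            min_coords=fes.cell_coords(mc), f_min=fmin,
                            cells=members))
    return basins


def _flood_below(fes: FESGrid, start, level):
    seen = {start}
    stack = [start]
    while stack:
        c = stack.pop()
        for nb in fes.neighbors(c):
            if nb not in seen and fes.values[nb] < level:
                seen.add(nb)
                stack.append(nb)
    return sorted(seen)


def lowest_free_energy_path(fes: FESGrid, a: Basin, b: Basin) -> list:
    """Minimax path between two basin minima on the visited grid.

    Among all orthogonally connected cell paths this minimizes the maximum F
    encountered; ties are broken by smaller total F along the path.  Raises
    if the basins are not connected through visited cells.
    """
    start, goal = a.min_cell, b.min_cell
    if start == goal:
        return [start]
    best = {start: (fes.values[start], fes.values[start])}
    prev = {}
    heap = [(fes.values[start], fes.values[start], start)]
    while heap:
        mx, tot, c = heapq.heappop(heap)
        if (mx, tot) > best.get(c, (np.inf, np.inf)):
            continue
        if c == goal:
            break
        for nb in fes.neighbors(c):
            key = (max(mx, fes.values[nb]), tot + fes.values[nb])
            if key < best.get(nb, (np.inf, np.inf)):
                best[nb] = key
                prev[nb] = c
                heapq.heappush(heap, (key[0], key[1], nb))
    if goal not in prev and goal != start:
        raise ValueError("basins are not connected through visited cells")
    path = [goal]
    while path[-1] != start:
        path.append(prev[path[-1]])
    return path[::-1]


def barrier_height(fes: FESGrid, a: Basin, b: Basin,
                   temperature: float | None = None):
    """Free-energy barrier from basin ``a`` to ``b`` along the minimax path.

    Returns (barrier_kJ, barrier_kBT) with the latter None unless a
    temperature is given.  The barrier is max F along the path minus F at the
    starting basin minimum, so forward and backward barriers differ by the
    basin offset.
    """
    path = lowest_free_energy_path(fes, a, b)
    fmax = max(fes.values[c] for c in path)
    barrier = float(fmax - fes.values[a.min_cell])
    in_kbt = barrier / (KB * temperature) if temperature is not None else None
    return barrier, in_kbt


def basin_delta_f(fes: FESGrid, a: Basin, b: Basin, temperature: float) -> float:
    """Population-weighted basin free-energy difference F_a - F_b, in k_BT.

    Computed as -ln(sum_a exp(-F/kT) / sum_b exp(-F/kT)) over member cells;
    negative when basin ``a`` is the more populated (lower) one.  Using
    populations rather than point minima accounts for basins of very
    different widths.
    """
    if not a.cells or not b.cells:
        raise ValueError("basins have no member cells")
    kt = KB * temperature
    fa = np.array([fes.values[c] for c in a.cells])
    fb = np.array([fes.values[c] for c in b.cells])
    la = _logsumexp(-fa / kt)
    lb = _logsumexp(-fb / kt)
    return float(-(la - lb))


def _logsumexp(x):
    m = np.max(x)
    return m + np.log(np.exp(x - m).sum())


# ---------------------------------------------------------------------------
# trajectory statistics


def _as_coords(traj) -> np.ndarray:
    if isinstance(traj, np.ndarray):
        return traj
    return np.stack([f.coords if isinstance(f, Configuration) else np.asarray(f)
                     for f in traj])


def rmsd_series(traj, reference: Configuration, align_idx=None,
                measure_idx=None) -> np.ndarray:
    """Per-frame RMSD (nm) to a reference after alignment on ``align_idx``.

    Follows the per-domain convention of aligning on the stable selection
    (e.g. the core) and measuring the mobile one.
    """
    coords = _as_coords(traj)
    out = np.empty(len(coords))
    for i, c in enumerate(coords):
        frame = reference.with_coords(c)
        out[i] = np.sqrt(msd_after_alignment(frame, reference,
                                             align_idx, measure_idx))
    return out


def rmsf(traj, selection=None, align_idx=None,
         reference: Configuration | None = None) -> np.ndarray:
    """Per-particle root-mean-square fluctuation (nm) about the mean structure.

    Every frame is aligned on ``align_idx`` (against the time-mean structure,
    obtained by one alignment-average pass), then fluctuations are taken
    about the per-particle time means.
    """
    coords = _as_coords(traj)
    if len(coords) < 2:
        raise ValueError("rmsf needs at least 2 frames")
    template = reference if reference is not None else Configuration(coords[0])
    sel = template.resolve(selection)

    def align_all(ref_coords):
        ref = template.with_coords(ref_coords)
        out = np.empty_like(coords)
        for i, c in enumerate(coords):
            sup = optimal_align(template.with_coords(c), ref, align_idx)
            out[i] = apply_superposition(c, sup)
        return out

    aligned = align_all(template.coords if reference is not None else coords[0])
    aligned = align_all(aligned.mean(axis=0))
    mean = aligned.mean(axis=0)
    fluct = ((aligned - mean) ** 2).sum(axis=2).mean(axis=0)
    return np.sqrt(fluct[sel])
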