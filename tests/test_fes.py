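"""Free-energy-surface analysis and trajectory-statistics tests."""

import itertools

import numpy as np
import pytest

from pathmetad.constants import KB
from pathmetad.fes import (Axis, Basin, FESGrid, barrier_height,
                           basin_delta_f, find_minima,
                           lowest_free_energy_path, rmsd_series, rmsf)
from pathmetad.geometry import Configuration

from conftest import random_rotation


def grid1d(values, lo=0.0, hi=1.0, label="s"):
    return FESGrid([Axis(lo, hi, len(values), label)], np.asarray(values,
                                                                  float))


def gaussian_wells(centers, depths, n=40):
    """2-D surface with designed Gaussian wells on [0,1]^2."""
    x = np.linspace(0, 1, n)
    xx, yy = np.meshgrid(x, x, indexing="ij")
    f = np.zeros_like(xx)
    for (cx, cy), d in zip(centers, depths):
        f -= d * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 0.08 ** 2))
    f -= f.min()
    return FESGrid([Axis(0, 1, n, "x"), Axis(0, 1, n, "y")], f)


class TestFindMinima:
    def test_single_well(self):
        fes = gaussian_wells([(0.5, 0.5)], [10.0])
        basins = find_minima(fes, 2.5)
        assert len(basins) == 1
        assert np.allclose(basins[0].min_coords, [0.5, 0.5], atol=0.03)

    def test_two_designed_wells(self):
        fes = gaussian_wells([(0.25, 0.3), (0.75, 0.7)], [12.0, 9.0])
        basins = find_minima(fes, 2.5)
        assert len(basins) == 2
        assert np.allclose(basins[0].min_coords, [0.25, 0.3], atol=0.03)
        assert np.allclose(basins[1].min_coords, [0.75, 0.7], atol=0.03)
        assert basins[0].f_min < basins[1].f_min
        assert basins[0].label == "A"

    def test_merge_limit_gives_single_basin(self):
        fes = gaussian_wells([(0.25, 0.3), (0.75, 0.7)], [12.0, 9.0])
        basins = find_minima(fes, depth_threshold=1e4)
        assert len(basins) == 1

    def test_shallow_ripples_are_merged(self):
        x = np.linspace(-np.pi, np.pi, 100)
        f = 5 * (1 - np.cos(x)) + 0.3 * np.sin(9 * x)  # ripple << threshold
        basins = find_minima(grid1d(f - f.min()), 2.5)
        assert len(basins) == 1

    def test_members_are_connected_and_contain_minimum(self):
        fes = gaussian_wells([(0.3, 0.4), (0.7, 0.6)], [10.0, 8.0])
        for b in find_minima(fes, 2.5):
            assert b.min_cell in b.cells
            member = set(b.cells)
            seen = {b.min_cell}
            stack = [b.min_cell]
            while stack:
                c = stack.pop()
                for nb in fes.neighbors(c):
                    if nb in member and nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            assert seen == member


def minimax_oracle(fes, start, goal):
    """Threshold connectivity: smallest level h such that start and goal are
    connected through visited cells with F <= h."""
    values = sorted({fes.values[tuple(c)] for c in np.argwhere(fes.visited)})
    for h in values:
        seen = set()
        if fes.values[start] > h:
            continue
        stack = [start]
        seen.add(start)
        while stack:
            c = stack.pop()
            if c == goal:
                return h
            for nb in fes.neighbors(c):
                if nb not in seen and fes.values[nb] <= h:
                    seen.add(nb)
                    stack.append(nb)
    raise AssertionError("not connected")


class TestLowestFreeEnergyPath:
    def test_flat_surface_path_max_zero(self):
        fes = grid1d(np.zeros(10))
        a = Basin("A", (0,), np.array([0.05]), 0.0, [(0,)])
        b = Basin("B", (9,), np.array([0.95]), 0.0, [(9,)])
        path = lowest_free_energy_path(fes, a, b)
        assert max(fes.values[c] for c in path) == 0.0
        assert len(path) == 10

    def test_two_channels_picks_lower_saddle(self):
        # 3x3 with two routes between corners; saddles 5 vs 9
        vals = np.array([[0.0, 9.0, 0.0],
                         [5.0, 99.0, 5.0],
                         [0.0, 5.0, 0.0]])
        fes = FESGrid([Axis(0, 1, 3, "x"), Axis(0, 1, 3, "y")], vals)
        a = Basin("A", (0, 0), np.zeros(2), 0.0, [(0, 0)])
        b = Basin("B", (0, 2), np.zeros(2), 0.0, [(0, 2)])
        path = lowest_free_energy_path(fes, a, b)
        assert max(fes.values[c] for c in path) == 5.0
        assert (1, 0) in path or (2, 1) in path

    def test_1d_barrier_is_saddle_value(self):
        f = np.array([0.0, 2.0, 7.0, 3.0, 1.0])
        fes = grid1d(f)
        a = Basin("A", (0,), np.array([0.1]), 0.0, [(0,)])
        b = Basin("B", (4,), np.array([0.9]), 1.0, [(4,)])
        path = lowest_free_energy_path(fes, a, b)
        assert max(fes.values[c] for c in path) == 7.0

    def test_disconnected_regions_error(self):
        f = np.array([0.0, np.nan, 1.0])
        fes = grid1d(f)
        a = Basin("A", (0,), np.array([0.0]), 0.0, [(0,)])
        b = Basin("B", (2,), np.array([1.0]), 1.0, [(2,)])
        with pytest.raises(ValueError, match="connected"):
            lowest_free_energy_path(fes, a, b)

    def test_matches_exhaustive_threshold_oracle(self, rng):
        """Minimax value equals the threshold-connectivity oracle on 100
        random surfaces up to 6x6 (with random unvisited holes)."""
        for trial in range(100):
            nx, ny = rng.integers(2, 7, size=2)
            vals = rng.uniform(0, 10, size=(nx, ny))
            # punch holes but keep corners
            holes = rng.random(vals.shape) < 0.15
            holes[0, 0] = holes[-1, -1] = False
            vals[holes] = np.nan
            fes = FESGrid([Axis(0, 1, nx, "x"), Axis(0, 1, ny, "y")], vals)
            start, goal = (0, 0), (nx - 1, ny - 1)
            a = Basin("A", start, np.zeros(2), vals[start], [start])
            b = Basin("B", goal, np.zeros(2), vals[goal], [goal])
            try:
                oracle = minimax_oracle(fes, start, goal)
            except AssertionError:
                with pytest.raises(ValueError):
                    lowest_free_energy_path(fes, a, b)
                continue
            path = lowest_free_energy_path(fes, a, b)
            assert max(fes.values[c] for c in path) == pytest.approx(oracle)
            # path is orthogonally connected over visited cells
            for c1, c2 in zip(path, path[1:]):
                assert sum(abs(i - j) for i, j in zip(c1, c2)) == 1


class TestBarriers:
    def make_two_basin_fes(self):
        f = np.array([2.5, 0.5, 2.0, 10.0, 4.0, 0.0, 3.0])
        fes = grid1d(f)
        basins = find_minima(fes, 2.0)
        return fes, basins

    def test_barrier_and_kbt_conversion(self):
        fes, basins = self.make_two_basin_fes()
        a, b = basins[0], basins[1]
        kj, kbt = barrier_height(fes, a, b, temperature=300.0)
        assert kj == pytest.approx(10.0 - a.f_min)
        assert kbt == pytest.approx(kj / (KB * 300.0))
        # 10 kJ/mol is very nearly 4 kBT at 300 K
        assert 10.0 / (KB * 300.0) == pytest.approx(4.01, abs=0.01)

    def test_zero_barrier_to_self(self):
        fes, basins = self.make_two_basin_fes()
        a = basins[0]
        assert barrier_height(fes, a, a)[0] == 0.0

    def test_forward_backward_difference_is_basin_offset(self):
        fes, basins = self.make_two_basin_fes()
        a, b = basins[0], basins[1]
        fwd = barrier_height(fes, a, b)[0]
        bwd = barrier_height(fes, b, a)[0]
        assert fwd - bwd == pytest.approx(b.f_min - a.f_min)

    def test_barrier_invariant_under_constant_shift(self):
        f = np.array([0.0, 2.0, 8.0, 1.0, 0.5])
        fes1 = grid1d(f)
        fes2 = FESGrid(fes1.axes, f + 5.0)
        a = Basin("A", (0,), np.array([0.1]), f[0], [(0,)])
        b = Basin("B", (4,), np.array([0.9]), f[4], [(4,)])
        a2 = Basin("A", (0,), np.array([0.1]), f[0] + 5, [(0,)])
        b2 = Basin("B", (4,), np.array([0.9]), f[4] + 5, [(4,)])
        assert barrier_height(fes1, a, b)[0] == pytest.approx(
            barrier_height(fes2, a2, b2)[0])


class TestBasinDeltaF:
    def test_identical_basins_zero(self):
        fes = grid1d([0.0, 1.0, 0.0])
        a = Basin("A", (0,), np.array([0.0]), 0.0, [(0,)])
        assert basin_delta_f(fes, a, a, 300.0) == 0.0

    def test_single_cell_arithmetic(self):
        """F = 0 vs 2.5 kJ/mol at 300 K differ by very nearly 1 kBT."""
        fes = grid1d([0.0, 5.0, 2.5])
        a = Basin("A", (0,), np.array([0.0]), 0.0, [(0,)])
        b = Basin("B", (2,), np.array([0.8]), 2.5, [(2,)])
        df = basin_delta_f(fes, a, b, 300.0)
        assert df == pytest.approx(-2.5 / (KB * 300.0), abs=1e-12)
        assert abs(df) == pytest.approx(1.0, abs=0.01)

    def test_population_weighting_favors_wide_basins(self):
        # same minimum depth, one basin twice as wide -> lower by kT ln 2
        f = np.array([0.0, 0.0, 8.0, 0.0, 8.0])
        fes = grid1d(f)
        wide = Basin("A", (0,), np.array([0.0]), 0.0, [(0,), (1,)])
        narrow = Basin("B", (3,), np.array([0.6]), 0.0, [(3,)])
        assert basin_delta_f(fes, wide, narrow, 300.0) == pytest.approx(
            -np.log(2.0))

    def test_empty_members_rejected(self):
        fes = grid1d([0.0, 1.0])
        a = Basin("A", (0,), np.array([0.0]), 0.0, [])
        b = Basin("B", (1,), np.array([1.0]), 1.0, [(1,)])
        with pytest.raises(ValueError):
            basin_delta_f(fes, a, b, 300.0)


class TestTrajectoryStats:
    def test_rmsd_zero_for_copies_and_rigid_motions(self, rng):
        ref = Configuration(rng.normal(size=(6, 3)))
        frames = [ref.coords]
        for _ in range(4):
            frames.append(ref.coords @ random_rotation(rng).T
                          + rng.normal(size=3))
        out = rmsd_series(np.stack(frames), ref)
        assert np.all(out < 1e-10)

    def test_hinge_rmsd_matches_block_displacement(self, hinge_pair):
        """Aligning on the static core, the rotated-block RMSD equals the
        hand-computed mean displacement of the block points."""
        a, b = hinge_pair
        core, block = a.selections["core"], a.selections["block"]
        out = rmsd_series(b.coords[None], a, align_idx=core,
                          measure_idx=block)
        expected = np.sqrt(((a.coords[block] - b.coords[block]) ** 2).sum()
                           / len(block))
        assert out[0] == pytest.approx(expected, abs=1e-10)

    def test_rmsf_static_trajectory_zero(self, rng):
        ref = Configuration(rng.normal(size=(5, 3)))
        traj = np.repeat(ref.coords[None], 6, axis=0)
        assert np.allclose(rmsf(traj), 0.0, atol=1e-12)

    def test_rmsf_recovers_isotropic_jitter(self, rng):
        """Free particles with per-coordinate std sigma show
        rmsf = sigma*sqrt(3) within 3 SE; aligned-core particles less."""
        sigma = 0.05
        base = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.3, 0.9, 0],
                         [0.2, 0.1, 0.8], [1.2, 1.1, 0.2], [0.7, -0.8, 0.5]])
        n = 10000
        traj = np.repeat(base[None], n, axis=0)
        core = np.arange(3)
        free = np.arange(3, 6)
        traj[:, free] += rng.normal(0, sigma, size=(n, 3, 3))
        out = rmsf(traj, align_idx=core)
        se = sigma * np.sqrt(3) / np.sqrt(2 * n)
        for j in free:
            assert out[j] == pytest.approx(sigma * np.sqrt(3), abs=5 * se)
        assert out[core].max() < out[free].min()

    def test_rmsf_needs_two_frames(self, rng):
        with pytest.raises(ValueError):
            rmsf(rng.normal(size=(1, 4, 3)))
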