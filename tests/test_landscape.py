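"""Binning, Boltzmann inversion, basins and minimax barriers."""

import itertools

import numpy as np
import pytest

import corelandscape as cl
from corelandscape.landscape import DegenerateBinningError, LandscapeGrid
from corelandscape.surface import ParticleSet


def grid_from_energies(energies, scale=100_000, exact=True):
    """Synthetic grid whose counts realize the given energy pattern.

    With ``exact`` the energies are installed verbatim (masked bins NaN),
    so path/basin logic can be tested free of count rounding.
    """
    e = np.asarray(energies, dtype=float)
    counts = np.zeros(e.shape, dtype=int)
    finite = np.isfinite(e)
    counts[finite] = np.maximum(np.round(scale * np.exp(-e[finite])), 1).astype(int)
    g = LandscapeGrid(
        np.arange(e.shape[0] + 1.0), np.arange(e.shape[1] + 1.0), counts
    )
    cl.boltzmann_invert(g)
    if exact:
        g.energies = np.where(finite, e, np.nan)
    return g


def brute_force_minimax(energies, start, goal):
    """Oracle: exhaustive enumeration of simple 8-connected paths."""
    e = np.asarray(energies, dtype=float)
    n1, n2 = e.shape
    best = [np.inf]

    def neighbors(ij):
        i, j = ij
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                ni, nj = i + di, j + dj
                if 0 <= ni < n1 and 0 <= nj < n2 and np.isfinite(e[ni, nj]):
                    yield ni, nj

    def dfs(ij, ridge, visited):
        ridge = max(ridge, e[ij])
        if ridge >= best[0]:
            return
        if ij == goal:
            best[0] = ridge
            return
        for nb in neighbors(ij):
            if nb not in visited:
                dfs(nb, ridge, visited | {nb})

    dfs(start, -np.inf, {start})
    return best[0]


class TestBinning:
    def test_four_corner_particles_two_by_two(self):
        pts = ParticleSet(np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]]))
        grid = cl.bin_particles(pts, (2, 2))
        assert np.array_equal(grid.counts, [[1, 1], [1, 1]])
        assert grid.bin_edges_q1[0] == 0.0 and grid.bin_edges_q1[-1] == 1.0

    def test_counts_conserved(self):
        rng = np.random.default_rng(5)
        pts = ParticleSet(rng.normal(size=(777, 2)))
        for bins in [(2, 2), (7, 13), (30, 30)]:
            assert cl.bin_particles(pts, bins).n_particles == 777

    def test_uniform_counts_within_multinomial_bounds(self):
        rng = np.random.default_rng(7)
        n = 100_000
        pts = ParticleSet(rng.random(size=(n, 2)))
        grid = cl.bin_particles(pts, (10, 10))
        expected = n / 100
        sigma = np.sqrt(n * 0.01 * 0.99)
        assert np.all(np.abs(grid.counts - expected) < 4 * sigma)

    def test_zero_variance_coordinate_rejected(self):
        pts = ParticleSet(np.column_stack([np.zeros(10), np.arange(10.0)]))
        with pytest.raises(DegenerateBinningError, match="q1"):
            cl.bin_particles(pts, (5, 5))


class TestBoltzmannInversion:
    def test_closed_form_two_bin_ratio(self):
        g = LandscapeGrid(
            np.arange(3.0), np.arange(2.0), np.array([[1000], [368]])
        )
        cl.boltzmann_invert(g)
        assert g.energies[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert g.energies[1, 0] == pytest.approx(-np.log(368 / 1000), abs=1e-12)
        assert g.energies[1, 0] == pytest.approx(0.9997, abs=5e-4)

    def test_uniform_counts_flat_energy(self):
        g = LandscapeGrid(np.arange(4.0), np.arange(4.0), np.full((3, 3), 42))
        cl.boltzmann_invert(g)
        assert np.allclose(g.energies, 0.0)

    def test_barrier_scale_population(self):
        """A population ratio of exp(-5.6) inverts to a 5.6 k_BT energy."""
        n_max = 1_000_000
        g = LandscapeGrid(
            np.arange(3.0),
            np.arange(2.0),
            np.array([[n_max], [round(n_max * np.exp(-5.6))]]),
        )
        cl.boltzmann_invert(g)
        assert g.energies[1, 0] == pytest.approx(5.6, abs=1e-3)

    def test_forward_inverse_consistency(self):
        """exp(-E) renormalized over non-empty bins reproduces counts/N."""
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 500, size=(8, 8))
        g = cl.boltzmann_invert(
            LandscapeGrid(np.arange(9.0), np.arange(9.0), counts)
        )
        p = np.exp(-np.nan_to_num(g.energies, nan=np.inf))
        p /= p.sum()
        np.testing.assert_allclose(p, counts / counts.sum(), atol=1e-12)
        assert np.all(np.isnan(g.energies[counts == 0]))

    def test_empty_grid_rejected(self):
        g = LandscapeGrid(np.arange(3.0), np.arange(3.0), np.zeros((2, 2), int))
        with pytest.raises(ValueError):
            cl.boltzmann_invert(g)


class TestBasins:
    def test_single_well_single_basin(self):
        q = np.arange(-2.0, 2.5, 0.5)
        e = np.add.outer(q**2, q**2)
        basins = cl.find_basins(grid_from_energies(e))
        assert len(basins) == 1
        assert basins[0].fraction == pytest.approx(1.0)

    def test_two_well_surface_two_basins(self):
        q = np.linspace(0, 1, 12)
        e = np.minimum.outer((q - 0.2) ** 2 * 50, (q - 0.8) ** 2 * 50)
        e = np.add.outer(np.zeros_like(q), np.minimum((q - 0.2) ** 2, (q - 0.8) ** 2) * 50)
        basins = cl.find_basins(grid_from_energies(e))
        mins = sorted(b.minimum_bin[1] for b in basins if b.fraction > 0.05)
        assert len(mins) == 2

    def test_every_nonempty_bin_assigned_once(self):
        rng = np.random.default_rng(12)
        e = rng.uniform(0, 4, size=(6, 6))
        e[rng.random((6, 6)) < 0.2] = np.inf
        grid = grid_from_energies(e)
        basins = cl.find_basins(grid)
        seen = set()
        for b in basins:
            assert not (b.member_bins & seen)
            seen |= b.member_bins
        assert len(seen) == int(np.isfinite(grid.energies).sum())


class TestBarrier:
    def test_worked_example_directional_barriers(self):
        e = np.array([[0.0, 3.0, 9.0], [9.0, 2.0, 9.0], [9.0, 4.0, 1.0]])
        grid = grid_from_energies(e)
        basins = {b.minimum_bin: b for b in cl.find_basins(grid)}
        res = cl.find_barrier(grid, basins[(0, 0)], basins[(2, 2)])
        assert res.saddle_energy == pytest.approx(2.0, abs=1e-6)
        assert res.barrier_from_a == pytest.approx(2.0, abs=1e-6)
        assert res.barrier_from_b == pytest.approx(1.0, abs=1e-6)
        assert not res.lower_bound

    def test_same_basin_zero_barrier(self):
        e = np.add.outer(np.arange(3.0) ** 2, np.arange(3.0) ** 2)
        grid = grid_from_energies(e)
        b = cl.find_basins(grid)[0]
        assert cl.find_barrier(grid, b, b).barrier_from_a == 0.0

    def test_matches_brute_force_on_small_grids(self):
        """Exhaustive-path oracle equivalence on all masked grids up to 4x4."""
        rng = np.random.default_rng(20220311)
        for trial in range(40):
            n1, n2 = rng.integers(2, 5, size=2)
            e = rng.uniform(0, 6, size=(n1, n2)).round(2)
            e[0, 0] = 0.0
            e[n1 - 1, n2 - 1] = 0.1
            mask = rng.random((n1, n2)) < 0.15
            mask[0, 0] = mask[n1 - 1, n2 - 1] = False
            e[mask] = np.inf
            grid = grid_from_energies(e)
            basins = {b.minimum_bin: b for b in cl.find_basins(grid)}
            if (0, 0) not in basins or (n1 - 1, n2 - 1) not in basins:
                continue
            res = cl.find_barrier(grid, basins[(0, 0)], basins[(n1 - 1, n2 - 1)])
            oracle = brute_force_minimax(
                grid.energies, (0, 0), (n1 - 1, n2 - 1)
            )
            if np.isinf(oracle):
                assert res.lower_bound
            else:
                assert res.saddle_energy == pytest.approx(oracle, abs=1e-9)

    def test_invariance_and_monotonicity(self):
        e = np.array([[0.0, 3.0, 9.0], [9.0, 2.0, 9.0], [9.0, 4.0, 1.0]])
        grid = grid_from_energies(e)
        basins = {b.minimum_bin: b for b in cl.find_basins(grid)}
        base = cl.find_barrier(grid, basins[(0, 0)], basins[(2, 2)]).barrier_from_a

        shifted = grid_from_energies(e + 2.0, scale=1_000_000)
        sb = {b.minimum_bin: b for b in cl.find_basins(shifted)}
        res = cl.find_barrier(shifted, sb[(0, 0)], sb[(2, 2)])
        assert res.barrier_from_a == pytest.approx(base, abs=1e-3)

        higher = e.copy()
        higher[1, 1] = 3.5  # raise the on-path saddle bin
        hg = grid_from_energies(higher)
        hb = {b.minimum_bin: b for b in cl.find_basins(hg)}
        assert (
            cl.find_barrier(hg, hb[(0, 0)], hb[(2, 2)]).barrier_from_a
            >= base - 1e-9
        )

    def test_disconnected_reports_lower_bound(self):
        e = np.array([[0.0, np.inf], [np.inf, 1.0]])
        grid = grid_from_energies(e)
        # diagonal neighbors are 8-connected; sever them by masking fully
        e2 = np.array(
            [[0.0, np.inf, 2.0], [np.inf, np.inf, np.inf], [3.0, np.inf, 1.0]]
        )
        grid = grid_from_energies(e2)
        basins = {b.minimum_bin: b for b in cl.find_basins(grid)}
        res = cl.find_barrier(grid, basins[(0, 0)], basins[(2, 2)])
        assert res.lower_bound
        assert res.saddle_energy == pytest.approx(np.nanmax(grid.energies))


class TestAssignStates:
    def test_single_well_full_fraction(self):
        rng = np.random.default_rng(2)
        pts = ParticleSet(rng.normal(0, 0.3, size=(2000, 2)))
        grid = cl.boltzmann_invert(cl.bin_particles(pts, (12, 12)))
        basins = cl.find_basins(grid)
        labels, summary = cl.assign_states(pts, grid, basins)
        assert summary["fraction"].sum() == pytest.approx(1.0, abs=1e-9)
        assert summary["fraction"].max() > 0.95

    def test_truth_labels_recovered_away_from_saddle(self, surface):
        pts = cl.sample_particles(surface, 30_000, seed=99)
        grid = cl.boltzmann_invert(cl.bin_particles(pts, (30, 30)))
        basins = cl.find_basins(grid)
        labels, summary = cl.assign_states(pts, grid, basins)
        # map recovered major basins onto generator labels via their minima
        big = summary.sort_values("fraction", ascending=False).head(3)
        # particles in low-energy regions (away from the saddle) must agree
        # with the generator's truth label for >= 99% of particles
        i = np.searchsorted(grid.bin_edges_q1, pts.mode_coords[:, 0]) - 1
        j = np.searchsorted(grid.bin_edges_q2, pts.mode_coords[:, 1]) - 1
        i = np.clip(i, 0, grid.counts.shape[0] - 1)
        j = np.clip(j, 0, grid.counts.shape[1] - 1)
        low_e = np.nan_to_num(grid.energies, nan=np.inf)[i, j] < 3.0
        truth_names = pts.truth_basin[low_e]
        recovered = labels[low_e]
        # build the label correspondence by majority vote
        agree = 0
        for lab in np.unique(recovered):
            names, counts = np.unique(truth_names[recovered == lab], return_counts=True)
            agree += counts.max()
        assert agree / len(recovered) >= 0.99

    def test_compressed_state_flagged_separately(self, surface):
        pts = cl.sample_particles(surface, 30_000, seed=41)
        grid = cl.boltzmann_invert(cl.bin_particles(pts, (30, 30)))
        basins = cl.find_basins(grid)
        _labels, summary = cl.assign_states(pts, grid, basins)
        comp = summary[summary["is_compressed"]]
        assert comp["fraction"].sum() == pytest.approx(0.07, abs=0.01)
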