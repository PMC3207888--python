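"""Density accumulation, bulk normalization, MDHS extraction, correlation."""

import numpy as np
import pytest

from hydrosite.density_map import (
    SHELL_BULK,
    SHELL_FIRST,
    DensityGrid,
    HydrationSite,
    accumulate_density,
    extract_mdhs,
    map_correlation,
    sites_near_atoms,
)
from hydrosite.io_formats import Trajectory
from hydrosite.structcore import Atom, Structure
from hydrosite.synthetic_data import generate_hydration_trajectory, make_scaffold


def _static_water_trajectory(water_pos, n_frames=20):
    scaffold = make_scaffold(3, center=(1.5, 1.5, 1.5), spacing=0.2)
    atoms = list(scaffold.atoms)
    serial0 = max(a.serial for a in atoms)
    atoms.append(Atom(serial0 + 1, "OW", "O", "SOL", 99, "W", np.asarray(water_pos)))
    # a far-away bulk water supplies the bulk-shell counts
    atoms.append(Atom(serial0 + 2, "OW", "O", "SOL", 100, "W", (1.5, 1.5, 2.2)))
    topo = Structure(id="static", atoms=atoms)
    coords = np.repeat(topo.coords()[None], n_frames, axis=0)
    return Trajectory(topology=topo, coordinates=coords,
                      times=np.arange(n_frames, dtype=float), dt=1.0)


class TestAccumulate:
    def test_fixed_water_fills_single_voxel(self):
        pos = (1.5, 1.9, 1.5)
        traj = _static_water_trajectory(pos)
        grid = accumulate_density(traj)
        nz = np.argwhere(grid.raw_counts > 0)
        assert len(nz) == 2  # the fixed water and the bulk marker
        ijk = tuple(np.floor((np.asarray(pos) - grid.origin) / grid.step + 0.5).astype(int))
        assert np.allclose(grid.voxel_center(ijk), pos, atol=grid.step / 2 + 1e-9)
        assert grid.raw_counts[ijk] == traj.n_frames
        assert grid.raw_counts.sum() == 2 * traj.n_frames

    def test_count_conservation(self, benchmark_run):
        grid = benchmark_run["grid"]
        assert grid.raw_counts.sum() == grid.raw_counts[grid.raw_counts > 0].sum()
        assert int(grid.raw_counts.sum()) > 0

    def test_shells_partition_and_are_half_open(self, benchmark_run):
        grid = benchmark_run["grid"]
        labels = np.unique(grid.shell_mask)
        assert set(labels.tolist()) <= {0, 1, 2}
        from scipy.spatial import cKDTree

        ref = benchmark_run["trajectory"].topology
        tree = cKDTree(np.array([a.position for a in ref.protein_heavy_atoms]))
        centers = grid.voxel_centers()
        d, _ = tree.query(centers[::97])
        mask = grid.shell_mask.reshape(-1)[::97]
        assert np.all(mask[d < 0.6] == SHELL_FIRST)
        assert np.all(mask[(d >= 0.6) & (d < 0.8)] == SHELL_BULK)
        assert np.all(mask[d >= 0.8] == 0)

    def test_ideal_gas_first_shell_density_is_bulk(self):
        """Homogeneous fixture: mean first-shell relative density is 1
        within 3 sigma of the counting error."""
        from hydrosite.pipeline_cli import ideal_gas_spec

        traj, _ = generate_hydration_trajectory(ideal_gas_spec(seed=3, n_frames=3000))
        grid = accumulate_density(traj)
        fs = grid.shell_mask == SHELL_FIRST
        cf = grid.raw_counts[fs].sum()
        cb = grid.raw_counts[grid.shell_mask == SHELL_BULK].sum()
        sigma = np.sqrt(1 / cf + 1 / cb)
        assert grid.relative_density[fs].mean() == pytest.approx(1.0, abs=3 * sigma)

    def test_zero_bulk_counts_raises(self):
        traj = _static_water_trajectory((1.5, 1.9, 1.5))
        # drop the bulk marker water by moving it on top of the site
        traj.coordinates[:, -1] = (1.5, 1.9, 1.5)
        with pytest.raises(ValueError, match="bulk"):
            accumulate_density(traj)

    def test_planted_site_relative_density_exceeds_iso_level(self, benchmark_run):
        """Planted sites show up far above the 2.8 site-calling level, and
        the grid value agrees with a direct count in a small ball."""
        grid = benchmark_run["grid"]
        traj = benchmark_run["trajectory"]
        truth = benchmark_run["truth"]
        spec = benchmark_run["spec"]
        w0 = len(spec.scaffold.atoms)
        waters = traj.coordinates[:, w0:, :]
        for site in truth.site_positions:
            ijk = np.floor((site - grid.origin) / grid.step + 0.5).astype(int)
            block = grid.relative_density[
                ijk[0] - 1 : ijk[0] + 2, ijk[1] - 1 : ijk[1] + 2, ijk[2] - 1 : ijk[2] + 2
            ]
            assert block.max() > 2.8
            # oracle: counts within a 0.05 nm ball over expected bulk counts
            d = np.linalg.norm(waters - site, axis=2)
            n_ball = int((d <= 0.05).sum())
            v_ball = 4 / 3 * np.pi * 0.05**3
            expected_bulk = grid.bulk_density * v_ball * traj.n_frames
            assert n_ball / expected_bulk > 2.8


def _uniform_grid(value=1.0, dims=(6, 6, 6)):
    return DensityGrid(
        origin=np.zeros(3), step=0.05, dims=dims,
        raw_counts=np.ones(dims, dtype=np.int64),
        relative_density=np.full(dims, float(value)),
        shell_mask=np.full(dims, SHELL_FIRST, dtype=np.uint8),
        n_frames_used=10, bulk_density=33.0,
    )


class TestExtract:
    def test_single_spike(self):
        g = _uniform_grid()
        g.relative_density[3, 3, 3] = 5.0
        sites = extract_mdhs(g, threshold=2.8)
        assert len(sites) == 1
        assert np.allclose(sites[0].position, g.voxel_center((3, 3, 3)))
        assert sites[0].peak_relative_density == 5.0

    def test_uniform_grid_no_sites(self):
        assert extract_mdhs(_uniform_grid(), threshold=2.8) == []

    def test_tie_goes_to_smallest_index(self):
        g = _uniform_grid()
        g.relative_density[2, 2, 2] = 4.0
        g.relative_density[2, 2, 3] = 4.0  # touching, equal: one site only
        sites = extract_mdhs(g, threshold=2.8)
        assert len(sites) == 1
        assert np.allclose(sites[0].position, g.voxel_center((2, 2, 2)))

    def test_nearby_peaks_merged_keeping_higher(self):
        g = _uniform_grid(dims=(8, 8, 8))
        g.relative_density[2, 2, 2] = 4.0
        g.relative_density[2, 2, 3] = 3.0  # within 0.1 nm merge radius
        sites = extract_mdhs(g, threshold=2.8)
        assert len(sites) == 1
        assert sites[0].peak_relative_density == 4.0

    def test_well_separated_planted_sites_recovered(self, benchmark_run):
        sites = benchmark_run["sites"]
        truth = benchmark_run["truth"]
        found = np.array([s.position for s in sites])
        for planted in truth.site_positions:
            d = np.linalg.norm(found - planted, axis=1).min()
            assert d <= 0.05  # within one voxel

    def test_sites_lie_in_first_shell(self, benchmark_run):
        grid = benchmark_run["grid"]
        for s in benchmark_run["sites"]:
            ijk = tuple(np.floor((s.position - grid.origin) / grid.step + 0.5).astype(int))
            assert grid.shell_mask[ijk] == SHELL_FIRST

    def test_sorted_by_descending_peak(self, benchmark_run):
        peaks = [s.peak_relative_density for s in benchmark_run["sites"]]
        assert peaks == sorted(peaks, reverse=True)


class TestCorrelation:
    def test_self_correlation_is_one(self):
        g = _uniform_grid()
        rng = np.random.default_rng(0)
        g.relative_density = rng.uniform(0, 4, size=g.dims)
        assert map_correlation(g, g, threshold=1.0) == pytest.approx(1.0)

    def test_matches_textbook_pearson_on_hand_values(self):
        a = _uniform_grid(dims=(2, 2, 2))
        b = _uniform_grid(dims=(2, 2, 2))
        av = np.array([3.0, 4.0, 5.0, 2.9, 3.5, 4.2, 3.1, 5.5]).reshape(2, 2, 2)
        bv = np.array([2.8, 4.4, 4.9, 3.0, 3.2, 4.0, 3.3, 5.1]).reshape(2, 2, 2)
        a.relative_density, b.relative_density = av, bv
        x, y = av.ravel(), bv.ravel()
        hand = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert map_correlation(a, b, threshold=2.8) == pytest.approx(hand, abs=1e-12)

    def test_symmetry_and_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        a, b = _uniform_grid(), _uniform_grid()
        a.relative_density = rng.uniform(0, 4, size=a.dims)
        b.relative_density = rng.uniform(0, 4, size=b.dims)
        r = map_correlation(a, b, threshold=1.0)
        assert map_correlation(b, a, threshold=1.0) == pytest.approx(r)
        a2, b2 = _uniform_grid(), _uniform_grid()
        a2.relative_density = 3.0 * a.relative_density
        b2.relative_density = 3.0 * b.relative_density
        assert map_correlation(a2, b2, threshold=3.0) == pytest.approx(r)

    def test_independent_fixtures_uncorrelated(self):
        """Two independent homogeneous fixtures: |r| < 0.2 over >= 100
        qualifying voxels."""
        from hydrosite.pipeline_cli import ideal_gas_spec

        grids = []
        for seed in (21, 22):
            traj, _ = generate_hydration_trajectory(ideal_gas_spec(seed=seed, n_frames=2000))
            grids.append(accumulate_density(traj))
        # a threshold far below bulk keeps virtually every voxel in the
        # union, so no selection artifact biases the null correlation
        mask = (grids[0].relative_density >= 0.2) | (grids[1].relative_density >= 0.2)
        assert mask.sum() >= 100
        assert abs(map_correlation(grids[0], grids[1], threshold=0.2)) < 0.2

    def test_geometry_mismatch_raises(self):
        a = _uniform_grid(dims=(6, 6, 6))
        b = _uniform_grid(dims=(5, 6, 6))
        with pytest.raises(ValueError, match="geometr"):
            map_correlation(a, b, threshold=1.0)

    def test_degenerate_voxel_set_raises(self):
        a, b = _uniform_grid(), _uniform_grid()
        with pytest.raises(ValueError, match="threshold"):
            map_correlation(a, b, threshold=50.0)


class TestSitesNearAtoms:
    def _atom(self, pos, serial=1):
        return Atom(serial, "H", "H", "ALA", 2, "A", np.asarray(pos))

    def test_boundary_inclusive(self):
        site = HydrationSite(position=np.zeros(3), peak_relative_density=3.0)
        near = self._atom((0.30, 0, 0))
        far = self._atom((0.36, 0, 0), serial=2)
        flags = sites_near_atoms([site], [near, far], cutoff=0.35)
        assert flags.tolist() == [True, False]

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        sites = [
            HydrationSite(position=p, peak_relative_density=3.0)
            for p in rng.uniform(0, 1.5, size=(20, 3))
        ]
        atoms = [self._atom(p, serial=i + 1) for i, p in enumerate(rng.uniform(0, 1.5, size=(30, 3)))]
        got = sites_near_atoms(sites, atoms, cutoff=0.3)
        want = [
            any(np.linalg.norm(s.position - a.position) <= 0.3 for s in sites)
            for a in atoms
        ]
        assert got.tolist() == want
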