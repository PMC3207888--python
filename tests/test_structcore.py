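"""Rigid superposition, RMSD/RMSF and neighbour queries."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from hydrosite.io_formats import Trajectory
from hydrosite.structcore import (
    Atom,
    Structure,
    backbone_rmsf,
    is_backbone,
    kabsch_superpose,
    mean_pairwise_rmsd,
    neighbor_within,
)
from hydrosite.synthetic_data import make_scaffold

RNG = np.random.default_rng(1234)


def _random_points(n, rng=RNG, scale=1.0):
    return rng.uniform(-scale, scale, size=(n, 3))


def rmsd_oracle(mobile, reference):
    """Brute-force minimal RMSD over rigid motions: rotation-vector search.

    Translation is optimal at matched centroids; the rotation is found by
    multi-start local minimisation over rotation vectors.
    """
    m = mobile - mobile.mean(axis=0)
    r = reference - reference.mean(axis=0)

    def cost(rv):
        diff = m @ Rotation.from_rotvec(rv).as_matrix().T - r
        return np.sqrt((diff**2).sum() / len(m))

    best = np.inf
    for start in np.array(
        [[0, 0, 0]] + [v for v in np.ndindex(3, 3, 3)], dtype=float
    ) * (np.pi / 1.5) - np.pi:
        res = minimize(cost, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identity(self):
        pts = _random_points(5)
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sup.apply(pts), pts, atol=1e-12)

    def test_recovers_applied_rigid_motion(self):
        pts = _random_points(6)
        rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        shift = np.array([1.0, 2.0, 3.0])
        moved = pts @ rot90.T + shift
        sup = kabsch_superpose(pts, moved)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(sup.rotation, rot90, atol=1e-9)
        assert np.allclose(sup.translation, shift, atol=1e-9)
        # and the inverse motion maps back
        back = kabsch_superpose(moved, pts)
        assert np.allclose(back.rotation @ rot90, np.eye(3), atol=1e-9)

    def test_matches_numerical_minimization(self):
        mobile = np.array(
            [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
        )
        reference = mobile.copy()
        reference[3] += np.array([0.1, 0.0, 0.0])
        got = kabsch_superpose(mobile, reference).rmsd
        assert got == pytest.approx(rmsd_oracle(mobile, reference), abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_oracle_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        assert kabsch_superpose(a, b).rmsd == pytest.approx(rmsd_oracle(a, b), abs=1e-6)

    def test_count_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            kabsch_superpose(_random_points(4), _random_points(5))

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match="at least 3"):
            kabsch_superpose(_random_points(2), _random_points(2))

    def test_collinear_raises(self):
        line = np.outer(np.arange(4.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line)

    def test_rotation_proper_on_reflective_input(self):
        # a near-planar set whose best improper alignment would reflect
        rng = np.random.default_rng(7)
        a = rng.normal(size=(6, 3))
        a[:, 2] *= 1e-4
        b = a.copy()
        b[:, 0] *= -1  # mirrored
        sup = kabsch_superpose(a, b)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_symmetry_and_rigid_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 8, 3))
        r_ab = kabsch_superpose(a, b).rmsd
        assert r_ab == pytest.approx(kabsch_superpose(b, a).rmsd, abs=1e-10)
        common = Rotation.random(rng=np.random.default_rng(seed + 99)).as_matrix()
        shift = rng.normal(size=3)
        assert kabsch_superpose(
            a @ common.T + shift, b @ common.T + shift
        ).rmsd == pytest.approx(r_ab, abs=1e-9)


class TestMeanPairwiseRmsd:
    def test_identical_copies_zero(self, scaffold):
        copies = [scaffold, scaffold, scaffold]
        assert mean_pairwise_rmsd(copies) == pytest.approx(0.0, abs=1e-12)

    def test_two_structures_equals_pairwise(self, scaffold):
        rng = np.random.default_rng(5)
        rot = Rotation.random(rng=rng).as_matrix()
        moved = Structure(
            id="m",
            atoms=[
                Atom(a.serial, a.name, a.element, a.residue_name, a.residue_index,
                     a.chain, a.position @ rot.T + rng.normal(scale=0.01, size=3))
                for a in scaffold.atoms
            ],
        )
        via_mean = mean_pairwise_rmsd([scaffold, moved])
        bb = [a for a in scaffold.atoms if is_backbone(a)]
        bb_m = [a for a in moved.atoms if is_backbone(a)]
        direct = kabsch_superpose(
            np.array([a.position for a in bb]), np.array([a.position for a in bb_m])
        ).rmsd
        assert via_mean == pytest.approx(direct, abs=1e-12)

    def test_unmatched_atom_raises_with_name(self, scaffold):
        truncated = Structure(id="t", atoms=scaffold.atoms[:-2])
        with pytest.raises(ValueError, match="residue"):
            mean_pairwise_rmsd([scaffold, truncated])


class TestNeighborWithin:
    def test_inclusive_boundary(self):
        q = [[0.0, 0.0, 0.0]]
        assert neighbor_within(q, [[0.349, 0.0, 0.0]], 0.35)
        assert not neighbor_within(q, [[0.351, 0.0, 0.0]], 0.35)
        assert neighbor_within(q, [[0.35, 0.0, 0.0]], 0.35)  # d == cutoff kept

    def test_empty_inputs(self):
        assert neighbor_within(np.empty((0, 3)), _random_points(5), 0.3) == []
        with pytest.raises(ValueError):
            neighbor_within(_random_points(2), _random_points(2), 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_all_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        q = rng.uniform(0, 2, size=(n, 3))
        t = rng.uniform(0, 2, size=(n, 3))
        got = {(i, j) for i, j, _ in neighbor_within(q, t, 0.3)}
        want = {
            (i, j)
            for i in range(n)
            for j in range(n)
            if np.linalg.norm(q[i] - t[j]) <= 0.3
        }
        assert got == want


class TestBackboneRmsf:
    def _trajectory(self, coords_per_frame, topo):
        n = len(coords_per_frame)
        return Trajectory(
            topology=topo,
            coordinates=np.asarray(coords_per_frame),
            times=np.arange(n, dtype=float),
            dt=1.0,
        )

    def test_static_trajectory_zero(self, scaffold):
        traj = self._trajectory([scaffold.coords()] * 5, scaffold)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in backbone_rmsf(traj).values())

    def test_two_point_distribution(self, scaffold):
        # two atoms alternate by +/-d along the axis joining them: the
        # optimal fit stays the identity and each RMSF equals d exactly
        base = scaffold.coords()
        d = 0.05
        frames = []
        for sign in (1, -1, 1, -1):
            c = base.copy()
            c[0, 0] += sign * d  # first residue N
            c[-2, 0] -= sign * d  # last residue C (same x-axis row)
            frames.append(c)
        rmsf = backbone_rmsf(self._trajectory(frames, scaffold))
        first_res = scaffold.atoms[0].residue_index
        # residue value averages its 4 backbone atoms; only N moved
        assert rmsf[first_res] == pytest.approx(d / 4, rel=1e-6)

    def test_isotropic_jitter_matches_analytic(self):
        # per-axis sigma -> 3D RMSF sigma*sqrt(3), within 2 % at 10k frames;
        # the per-frame fit absorbs 6 of the 3N noise DOF, so use enough
        # atoms (120) that the resulting deflation is < 1 %
        topo = make_scaffold(30, center=(0, 0, 0), spacing=0.5, with_hydrogens=False)
        rng = np.random.default_rng(42)
        sigma = 0.02
        base = topo.coords()
        frames = base[None] + rng.normal(0, sigma, size=(10_000, *base.shape))
        rmsf = backbone_rmsf(self._trajectory(frames, topo))
        for v in rmsf.values():
            assert v == pytest.approx(sigma * np.sqrt(3), rel=0.02)

    def test_empty_selection_raises(self, scaffold):
        traj = self._trajectory([scaffold.coords()] * 3, scaffold)
        with pytest.raises(ValueError, match="empty selection"):
            backbone_rmsf(traj, selection=lambda a: False)
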