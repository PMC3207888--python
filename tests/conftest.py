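"""Shared fixtures: synthetic systems sized for fast, reproducible checks."""

from __future__ import annotations

import numpy as np
import pytest

from hydrosite.io_formats import Trajectory
from hydrosite.structcore import Atom, Structure
from hydrosite.synthetic_data import generate_hydration_trajectory, make_scaffold


@pytest.fixture()
def scaffold() -> Structure:
    return make_scaffold(4, center=(1.5, 1.5, 1.5), spacing=0.2)


@pytest.fixture(scope="session")
def benchmark_run():
    """The default planted-site benchmark, computed once per session."""
    from hydrosite.density_map import accumulate_density, extract_mdhs
    from hydrosite.pipeline_cli import default_benchmark_spec

    spec = default_benchmark_spec(seed=11)
    traj, truth = generate_hydration_trajectory(spec)
    grid = accumulate_density(traj)
    sites = extract_mdhs(grid, threshold=2.8)
    return {"spec": spec, "trajectory": traj, "truth": truth, "grid": grid, "sites": sites}


def single_residue_topology(center=(1.0, 1.0, 1.0)) -> Structure:
    """One-residue protein plus one water, for hand-built trajectories."""
    c = np.asarray(center)
    atoms = [
        Atom(1, "N", "N", "ALA", 2, "A", c + (-0.12, 0, 0)),
        Atom(2, "CA", "C", "ALA", 2, "A", c + (0, 0.06, 0)),
        Atom(3, "C", "C", "ALA", 2, "A", c + (0.12, 0, 0)),
        Atom(4, "O", "O", "ALA", 2, "A", c + (0.14, 0.10, 0.06)),
        Atom(5, "OW", "O", "SOL", 3, "W", c + (2.0, 0, 0)),
    ]
    return Structure(id="toy", atoms=atoms)


def toy_trajectory(occupied: np.ndarray, dt: float = 10.0) -> Trajectory:
    """A trajectory whose single water is in/out of the residue shell.

    ``occupied`` is a boolean series; in-shell frames place the water
    0.2 nm from the residue centre, others 2 nm away.
    """
    topo = single_residue_topology()
    c = np.array([1.0, 1.0, 1.0])
    n = len(occupied)
    coords = np.repeat(topo.coords()[None, :, :], n, axis=0)
    inside = c + np.array([0.0, 0.2, 0.0])
    outside = c + np.array([2.0, 0.0, 0.0])
    for f, occ in enumerate(occupied):
        coords[f, 4] = inside if occ else outside
    return Trajectory(
        topology=topo, coordinates=coords, times=np.arange(n) * dt, dt=dt
    )
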