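"""Bulk-normalized water-density grids and hydration-site extraction.

The space around the protein is divided on a regular 3D grid (default
step 0.05 nm).  For each trajectory frame the protein is superposed onto a
reference structure, the same rigid motion is applied to the water
oxygens, and each oxygen is binned into its voxel.  Voxels are labelled by
the distance from their centre to the nearest protein heavy atom of the
reference: the first hydration shell reaches 0.6 nm, the bulk reference
shell spans 0.6-0.8 nm.  Densities are expressed relative to the mean
density observed in the bulk shell, so 1.0 means bulk-like water and the
filtered local maxima of the relative density are the hydration sites
(MDHS).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .io_formats import Trajectory
from .structcore import Atom, Structure, is_backbone, kabsch_superpose, neighbor_within

__all__ = [
    "DensityGrid",
    "HydrationSite",
    "SHELL_OUTSIDE",
    "SHELL_FIRST",
    "SHELL_BULK",
    "accumulate_density",
    "extract_mdhs",
    "map_correlation",
    "sites_near_atoms",
]

SHELL_OUTSIDE = 0
SHELL_FIRST = 1
SHELL_BULK = 2


@dataclass
class DensityGrid:
    """Regular 3D grid of bulk-normalized water-oxygen density."""

    origin: np.ndarray  # nm, centre of voxel (0,0,0)
    step: float  # nm
    dims: tuple[int, int, int]
    raw_counts: np.ndarray  # per-voxel observation counts
    relative_density: np.ndarray  # ratio to bulk density
    shell_mask: np.ndarray  # SHELL_* labels
    n_frames_used: int
    bulk_density: float  # waters per nm^3

    def voxel_centers(self) -> np.ndarray:
        idx = np.indices(self.dims).reshape(3, -1).T
        return self.origin + idx * self.step

    def voxel_center(self, index: Sequence[int]) -> np.ndarray:
        return self.origin + np.asarray(index) * self.step

    def same_geometry(self, other: "DensityGrid") -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.origin, other.origin, atol=1e-9)
            and abs(self.step - other.step) < 1e-12
        )


@dataclass(frozen=True)
class HydrationSite:
    """A filtered local maximum of the relative water density."""

    position: np.ndarray  # nm, voxel centre
    peak_relative_density: float
    support_voxels: int = 1


def _grid_geometry(
    protein_xyz: np.ndarray, step: float, pad: float
) -> tuple[np.ndarray, tuple[int, int, int]]:
    lo = protein_xyz.min(axis=0) - pad
    hi = protein_xyz.max(axis=0) + pad
    dims = tuple(int(np.floor((hi[k] - lo[k]) / step)) + 1 for k in range(3))
    return lo, dims


def accumulate_density(
    trajectory: Trajectory,
    reference: Structure | None = None,
    step: float = 0.05,
    first_shell: float = 0.6,
    bulk_shell_outer: float = 0.8,
    align: bool = True,
) -> DensityGrid:
    """Accumulate bulk-normalized water-oxygen density over a trajectory.

    Per frame, the protein backbone is superposed onto the reference
    structure (default: the trajectory topology) and the same motion is
    applied to the water oxygens, which are then binned on the grid.
    Shell labels are assigned at voxel centres from the distance ``d`` to
    the nearest protein heavy atom of the reference: first shell
    ``d < first_shell``, bulk shell ``first_shell <= d < bulk_shell_outer``
    (half-open intervals, so the labels partition space).  The bulk
    density is the mean count density over bulk-shell voxels and
    normalizes the whole grid.
    """
    if not (0 < first_shell < bulk_shell_outer):
        raise ValueError("need 0 < first_shell < bulk_shell_outer")
    topo = trajectory.topology
    if reference is None:
        reference = topo
    ref_heavy = reference.protein_heavy_atoms
    if not ref_heavy:
        raise ValueError("reference structure has no protein heavy atoms")
    ref_heavy_xyz = np.array([a.position for a in ref_heavy])

    bb_idx = [i for i, a in enumerate(topo.atoms) if is_backbone(a)]
    ref_bb = {(a.residue_index, a.name): a.position for a in reference.atoms if is_backbone(a)}
    matched = [(i, ref_bb[(topo.atoms[i].residue_index, topo.atoms[i].name)])
               for i in bb_idx if (topo.atoms[i].residue_index, topo.atoms[i].name) in ref_bb]
    if align and len(matched) < 3:
        raise ValueError("fewer than 3 backbone atoms matched between topology and reference")
    fit_idx = np.array([i for i, _ in matched], dtype=int)
    fit_ref = np.array([p for _, p in matched])

    wat_idx = np.array(
        [i for i, a in enumerate(topo.atoms) if a.is_water_oxygen], dtype=int
    )
    if wat_idx.size == 0:
        raise ValueError("trajectory contains no water oxygens")

    origin, dims = _grid_geometry(ref_heavy_xyz, step, pad=bulk_shell_outer + 2 * step)
    counts = np.zeros(dims, dtype=np.int64)
    n_binned = 0
    flat_chunks: list[np.ndarray] = []

    for f in range(trajectory.n_frames):
        xyz = trajectory.coordinates[f]
        if align:
            sup = kabsch_superpose(xyz[fit_idx], fit_ref)
            waters = sup.apply(xyz[wat_idx])
        else:
            waters = xyz[wat_idx]
        ijk = np.floor((waters - origin) / step + 0.5).astype(np.int64)
        ok = np.all((ijk >= 0) & (ijk < np.asarray(dims)), axis=1)
        ijk = ijk[ok]
        flat_chunks.append(np.ravel_multi_index((ijk[:, 0], ijk[:, 1], ijk[:, 2]), dims))
        n_binned += int(ok.sum())
        if len(flat_chunks) >= 4096:
            counts.flat += np.bincount(
                np.concatenate(flat_chunks), minlength=counts.size
            ).astype(np.int64)
            flat_chunks.clear()
    if flat_chunks:
        counts.flat += np.bincount(
            np.concatenate(flat_chunks), minlength=counts.size
        ).astype(np.int64)

    assert counts.sum() == n_binned, "count conservation violated"

    tree = cKDTree(ref_heavy_xyz)
    centers = origin + np.indices(dims).reshape(3, -1).T * step
    d, _ = tree.query(centers)
    d = d.reshape(dims)
    shell = np.full(dims, SHELL_OUTSIDE, dtype=np.uint8)
    shell[d < first_shell] = SHELL_FIRST
    shell[(d >= first_shell) & (d < bulk_shell_outer)] = SHELL_BULK

    n_bulk_vox = int((shell == SHELL_BULK).sum())
    bulk_counts = int(counts[shell == SHELL_BULK].sum())
    if bulk_counts == 0:
        raise ValueError(
            "no water observations in the bulk shell; use a longer trajectory "
            "or wider shells"
        )
    voxel_volume = step**3
    n_frames = trajectory.n_frames
    bulk_density = bulk_counts / (n_frames * n_bulk_vox * voxel_volume)
    relative = counts / (n_frames * voxel_volume * bulk_density)

    return DensityGrid(
        origin=np.asarray(origin),
        step=step,
        dims=dims,
        raw_counts=counts,
        relative_density=relative,
        shell_mask=shell,
        n_frames_used=n_frames,
        bulk_density=float(bulk_density),
    )


_NEIGHBOR_OFFSETS = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
     if (i, j, k) != (0, 0, 0)]
)


def extract_mdhs(
    grid: DensityGrid, threshold: float = 2.8, merge_radius: float = 0.1
) -> list[HydrationSite]:
    """Extract hydration sites as filtered local density maxima.

    A first-shell voxel is a peak iff its relative density is at least
    ``threshold`` and exceeds all 26 neighbours; an exact tie between
    neighbouring voxels is awarded to the lexicographically smallest voxel
    index.  Peaks closer than ``merge_radius`` are merged keeping the
    higher peak.  Sites are returned sorted by descending peak density.
    """
    rd = grid.relative_density
    cand = np.argwhere((grid.shell_mask == SHELL_FIRST) & (rd >= threshold))
    peaks: list[tuple[tuple[int, int, int], float]] = []
    dims = np.asarray(grid.dims)
    for ijk in cand:
        v = rd[tuple(ijk)]
        is_peak = True
        for off in _NEIGHBOR_OFFSETS:
            n = ijk + off
            if np.any(n < 0) or np.any(n >= dims):
                continue
            nv = rd[tuple(n)]
            if nv > v or (nv == v and tuple(n) < tuple(ijk)):
                is_peak = False
                break
        if is_peak:
            peaks.append((tuple(int(x) for x in ijk), float(v)))

    # Merge peaks closer than merge_radius, keeping the higher one
    # (ties: lexicographically smaller index wins).
    peaks.sort(key=lambda p: (-p[1], p[0]))
    kept: list[tuple[tuple[int, int, int], float]] = []
    for ijk, v in peaks:
        pos = grid.voxel_center(ijk)
        if any(
            np.linalg.norm(pos - grid.voxel_center(kijk)) < merge_radius
            for kijk, _ in kept
        ):
            continue
        kept.append((ijk, v))

    sites = []
    thr_mask = rd >= threshold
    for ijk, v in kept:
        support = _connected_support(thr_mask, ijk)
        sites.append(
            HydrationSite(
                position=grid.voxel_center(ijk),
                peak_relative_density=v,
                support_voxels=support,
            )
        )
    return sites


def _connected_support(mask: np.ndarray, seed: tuple[int, int, int]) -> int:
    """Size of the 26-connected above-threshold component containing seed."""
    from scipy import ndimage

    labels, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    return int((labels == labels[seed]).sum())


def map_correlation(grid_a: DensityGrid, grid_b: DensityGrid, threshold: float) -> float:
    """Pearson correlation of two density maps above a threshold.

    Computed over the union of voxels where either grid's relative
    density reaches ``threshold``.  The grids must share origin, step and
    dimensions.
    """
    if not grid_a.same_geometry(grid_b):
        raise ValueError("grid geometries differ; resample before correlating")
    mask = (grid_a.relative_density >= threshold) | (grid_b.relative_density >= threshold)
    n = int(mask.sum())
    if n < 2:
        raise ValueError(f"only {n} voxels reach the threshold; correlation undefined")
    r, _ = pearsonr(grid_a.relative_density[mask], grid_b.relative_density[mask])
    return float(r)


def sites_near_atoms(
    sites: Sequence[HydrationSite], atoms: Sequence[Atom], cutoff: float = 0.35
) -> np.ndarray:
    """Per-atom boolean: is any hydration site within cutoff (inclusive)?"""
    flags = np.zeros(len(atoms), dtype=bool)
    if not sites or not atoms:
        return flags
    pairs = neighbor_within(
        np.array([a.position for a in atoms]),
        np.array([s.position for s in sites]),
        cutoff,
    )
    for i, _, _ in pairs:
        flags[i] = True
    return flags
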