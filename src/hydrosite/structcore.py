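"""Core structure model and rigid-body geometry.

Atoms and structures are stored in nanometres.  The module provides the
geometric primitives shared by every analysis stage: least-squares rigid
superposition (Kabsch), pairwise backbone RMSD over structure ensembles,
fixed-radius neighbour queries, and per-residue backbone RMSF over a
trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Structure",
    "Superposition",
    "WATER_RESIDUE_NAMES",
    "WATER_OXYGEN_NAMES",
    "BACKBONE_ATOM_NAMES",
    "is_backbone",
    "kabsch_superpose",
    "mean_pairwise_rmsd",
    "neighbor_within",
    "backbone_rmsf",
]

#: Residue names recognised as water (crystallographic and MD conventions).
WATER_RESIDUE_NAMES = frozenset({"HOH", "WAT", "SOL", "TIP3", "TIP"})
#: Atom names recognised as the water oxygen.
WATER_OXYGEN_NAMES = frozenset({"O", "OW", "OH2"})
#: Protein backbone heavy atoms.
BACKBONE_ATOM_NAMES = ("N", "CA", "C", "O")


@dataclass
class Atom:
    """A single atom.

    Positions are in nm.  ``residue_index`` follows author numbering (for
    the reference protein the chain starts with an alanine at position 2).
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom serial {self.serial}")
        if not self.element:
            raise ValueError(f"empty element for atom serial {self.serial}")

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_RESIDUE_NAMES

    @property
    def is_water_oxygen(self) -> bool:
        return self.is_water and self.name in WATER_OXYGEN_NAMES

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class Structure:
    """An ordered collection of atoms, optionally one model of an ensemble."""

    id: str
    atoms: list[Atom] = field(default_factory=list)
    model_number: int | None = None

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(serials) != len(set(serials)):
            raise ValueError(f"duplicate atom serials in structure {self.id!r}")

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self, atoms: Sequence[Atom] | None = None) -> np.ndarray:
        pool = self.atoms if atoms is None else atoms
        if not pool:
            return np.empty((0, 3))
        return np.array([a.position for a in pool])

    @property
    def protein_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_water]

    @property
    def protein_heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_water and a.element != "H"]

    @property
    def water_oxygens(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_water_oxygen]

    def select(self, predicate: Callable[[Atom], bool]) -> list[Atom]:
        return [a for a in self.atoms if predicate(a)]

    def residue_atoms(self, residue_index: int, heavy_only: bool = True) -> list[Atom]:
        out = [a for a in self.atoms if not a.is_water and a.residue_index == residue_index]
        if heavy_only:
            out = [a for a in out if a.element != "H"]
        return out

    def protein_residue_indices(self) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            if not a.is_water:
                seen.setdefault(a.residue_index, None)
        return list(seen)


@dataclass(frozen=True)
class Superposition:
    """A proper rigid motion ``x -> R @ x + t`` and the RMSD it attains."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        det = float(np.linalg.det(self.rotation))
        if abs(det - 1.0) > 1e-9:
            raise ValueError(f"rotation determinant {det} is not +1")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def is_backbone(atom: Atom) -> bool:
    """True for the protein backbone heavy atoms N, CA, C, O."""
    return not atom.is_water and atom.name in BACKBONE_ATOM_NAMES


def _as_points(x: Iterable, label: str) -> np.ndarray:
    arr = np.asarray(list(x) if not isinstance(x, np.ndarray) else x, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"{label} must be an (n, 3) coordinate array")
    return arr


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation ``R`` and translation ``t`` minimising
    ``sum_i |R m_i + t - r_i|^2`` over all rigid motions (Kabsch, via SVD
    with a determinant sign correction so the rotation is never a
    reflection), together with the minimal RMSD.

    Raises
    ------
    ValueError
        If the point counts differ, fewer than 3 points are given, or the
        point sets are degenerate (all points collinear or coincident).
    """
    m = _as_points(mobile, "mobile")
    r = _as_points(reference, "reference")
    if m.shape != r.shape:
        raise ValueError(f"point count mismatch: mobile {m.shape[0]} vs reference {r.shape[0]}")
    n = m.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")

    mc = m.mean(axis=0)
    rc = r.mean(axis=0)
    dm = m - mc
    dr = r - rc

    # Degeneracy: rank < 2 means collinear/coincident points and an
    # underdetermined rotation.
    if min(np.linalg.matrix_rank(dm, tol=1e-10), np.linalg.matrix_rank(dr, tol=1e-10)) < 2:
        raise ValueError("degenerate point set: points are collinear or coincident")

    h = dm.T @ dr
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    # Orthonormalise against accumulated round-off so det == 1 within 1e-9.
    uu, _, vv = np.linalg.svd(rot)
    rot = uu @ vv

    trans = rc - rot @ mc
    diff = dm @ rot.T - dr
    rmsd = float(np.sqrt((diff * diff).sum() / n))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd)


def _matched_coords(
    structures: Sequence[Structure], selection: Callable[[Atom], bool]
) -> list[np.ndarray]:
    """Match selected atoms across structures by (residue_index, atom name)."""
    keyed: list[dict[tuple[int, str], Atom]] = []
    for s in structures:
        d: dict[tuple[int, str], Atom] = {}
        for a in s.select(selection):
            d.setdefault((a.residue_index, a.name), a)
        keyed.append(d)
    common = set(keyed[0])
    for d in keyed[1:]:
        common &= set(d)
    if not common:
        raise ValueError("selection yields no atoms common to all structures")
    for s, d in zip(structures, keyed):
        missing = sorted(set(d) - common)
        if missing:
            ri, name = missing[0]
            raise ValueError(
                f"structure {s.id!r}: atom (residue {ri}, {name!r}) "
                "has no counterpart in every structure"
            )
    keys = sorted(common)
    return [np.array([d[k].position for k in keys]) for d in keyed]


def mean_pairwise_rmsd(
    structures: Sequence[Structure],
    selection: Callable[[Atom], bool] = is_backbone,
    strict: bool = True,
) -> float:
    """Mean of the superposed RMSD over all unordered structure pairs.

    Atoms are matched across structures by ``(residue_index, name)``.  With
    ``strict=True`` any selected atom missing from some structure raises;
    with ``strict=False`` only the atoms common to all structures enter.
    """
    if len(structures) < 2:
        raise ValueError("need at least 2 structures")
    if strict:
        coords = _matched_coords(structures, selection)
    else:
        keyed = []
        for s in structures:
            d = {}
            for a in s.select(selection):
                d.setdefault((a.residue_index, a.name), a)
            keyed.append(d)
        common = set(keyed[0])
        for d in keyed[1:]:
            common &= set(d)
        if not common:
            raise ValueError("selection yields no atoms common to all structures")
        keys = sorted(common)
        coords = [np.array([d[k].position for k in keys]) for d in keyed]
    vals = []
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            vals.append(kabsch_superpose(coords[i], coords[j]).rmsd)
    return float(np.mean(vals))


def neighbor_within(
    queries: np.ndarray, targets: np.ndarray, cutoff: float
) -> list[tuple[int, int, float]]:
    """All (query, target) pairs with distance <= cutoff (inclusive).

    Returns each qualifying pair exactly once as ``(i, j, distance)``,
    sorted by query index then target index.  Empty inputs give an empty
    list.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    q = np.asarray(queries, dtype=float).reshape(-1, 3)
    t = np.asarray(targets, dtype=float).reshape(-1, 3)
    if q.size == 0 or t.size == 0:
        return []
    tree = cKDTree(t)
    out: list[tuple[int, int, float]] = []
    for i, hits in enumerate(tree.query_ball_point(q, cutoff)):
        for j in sorted(hits):
            d = float(np.linalg.norm(q[i] - t[j]))
            out.append((i, int(j), d))
    return out


def backbone_rmsf(trajectory, selection: Callable[[Atom], bool] = is_backbone) -> dict[int, float]:
    """Per-residue RMSF of selected atoms about their time-average positions.

    Every frame is first superposed onto the trajectory's topology
    (reference) coordinates using the selected atoms; the RMSF of each atom
    is then the root-mean-square deviation from its mean position, and
    residue values are the average over that residue's selected atoms.
    Returns ``{residue_index: rmsf_nm}``.
    """
    topo = trajectory.topology
    sel = [i for i, a in enumerate(topo.atoms) if selection(a)]
    if not sel:
        raise ValueError("empty selection")
    if trajectory.n_frames < 2:
        raise ValueError("need at least 2 frames for RMSF")
    ref = topo.coords()[sel]
    fitted = np.empty((trajectory.n_frames, len(sel), 3))
    for f in range(trajectory.n_frames):
        xyz = trajectory.coordinates[f][sel]
        sup = kabsch_superpose(xyz, ref)
        fitted[f] = sup.apply(xyz)
    mean_pos = fitted.mean(axis=0)
    per_atom = np.sqrt(((fitted - mean_pos) ** 2).sum(axis=2).mean(axis=0))
    per_res: dict[int, list[float]] = {}
    for k, idx in enumerate(sel):
        per_res.setdefault(topo.atoms[idx].residue_index, []).append(float(per_atom[k]))
    return {ri: float(np.mean(v)) for ri, v in per_res.items()}
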