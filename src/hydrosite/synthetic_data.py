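"""Synthetic systems with known ground truth.

Three generators emulate the statistical structure the hydration analysis
assumes: (i) a trajectory of a rigid protein scaffold with bound waters at
planted sites (exponential dwell/off times tuned to a target occupancy)
plus diffusing bulk waters at uniform density; (ii) an ensemble of aligned
"crystal" structures sharing the scaffold, with conserved waters planted in
a chosen number of structures plus uniform decoy waters; (iii) a table of
hydrated hydrogens derived from planted sites plus optional spurious hits.

All generators draw from ``numpy.random.default_rng`` (PCG64), so equal
seeds give bit-identical output within this implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import EphogsyEntry, Trajectory
from .structcore import Atom, Structure

__all__ = [
    "SiteSpec",
    "HydrationSpec",
    "GroundTruth",
    "make_scaffold",
    "generate_hydration_trajectory",
    "generate_crystal_ensemble",
    "generate_ephogsy_table",
]

#: Default excluded-volume radius around scaffold atoms, nm.
DEFAULT_EXCLUSION_RADIUS = 0.15


@dataclass(frozen=True)
class SiteSpec:
    """A planted hydration site."""

    position: tuple[float, float, float]
    mean_dwell: float  # ps
    occupancy: float  # long-run bound fraction in [0, 1]
    jitter_sigma: float = 0.02  # nm, per-axis Gaussian spread while bound

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.occupancy >= 1.0:
            raise ValueError(
                "occupancy 1 is infeasible with a finite off-period model"
            )
        if self.mean_dwell <= 0:
            raise ValueError("mean_dwell must be positive")


@dataclass
class HydrationSpec:
    """Specification of a synthetic hydration trajectory."""

    box_edge: float  # nm, cubic box [0, box_edge]^3
    n_frames: int
    dt: float  # ps
    scaffold: Structure
    sites: Sequence[SiteSpec] = ()
    n_bulk_waters: int = 0
    bulk_step_sigma: float = 0.1  # nm per frame, per axis
    exclusion_radius: float = DEFAULT_EXCLUSION_RADIUS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.box_edge <= 0 or self.n_frames < 1 or self.dt <= 0:
            raise ValueError("box_edge, n_frames and dt must be positive")
        for s in self.sites:
            if not np.all((np.asarray(s.position) >= 0) & (np.asarray(s.position) <= self.box_edge)):
                raise ValueError(f"site {s.position} outside the box")


@dataclass
class GroundTruth:
    """What the generator actually planted."""

    site_positions: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    #: per site: list of (start_ps, end_ps, water_id), clipped to the run.
    dwell_intervals: list[list[tuple[float, float, int]]] = field(default_factory=list)
    #: per ensemble water: {(structure_id, water_serial): conserved?}
    conserved_flags: dict[tuple[str, int], bool] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Scaffold


_RESIDUE_TEMPLATE = (
    # (atom name, element, offset from residue centre, nm)
    ("N", "N", (-0.12, 0.00, 0.00)),
    ("H", "H", (-0.12, -0.10, 0.00)),
    ("CA", "C", (0.00, 0.06, 0.00)),
    ("C", "C", (0.12, 0.00, 0.00)),
    ("O", "O", (0.14, 0.10, 0.06)),
)


def make_scaffold(
    n_residues: int,
    center: Sequence[float],
    spacing: float = 0.4,
    with_hydrogens: bool = True,
    chain: str = "A",
) -> Structure:
    """A rigid mini-protein: residues along a line with N/H/CA/C/O atoms.

    Residue numbering starts at 2 (author numbering of the reference
    protein, whose first modelled residue is an alanine at position 2).
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    center = np.asarray(center, dtype=float)
    atoms: list[Atom] = []
    serial = 1
    half = (n_residues - 1) / 2.0
    for i in range(n_residues):
        c = center + np.array([(i - half) * spacing, 0.0, 0.0])
        for name, element, off in _RESIDUE_TEMPLATE:
            if element == "H" and not with_hydrogens:
                continue
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=element,
                    residue_name="ALA",
                    residue_index=i + 2,
                    chain=chain,
                    position=c + np.asarray(off),
                )
            )
            serial += 1
    return Structure(id="scaffold", atoms=atoms)


# ---------------------------------------------------------------------------
# Trajectory generator


def _fold(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (triangle-wave fold)."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    return lo + span - np.abs(span - y)


def _sample_intervals(
    rng: np.random.Generator, mean_on: float, mean_off: float, duration: float
) -> list[tuple[float, float]]:
    """Alternating exponential on/off intervals covering [0, duration]."""
    p_on = mean_on / (mean_on + mean_off)
    t = 0.0
    on = bool(rng.random() < p_on)
    out: list[tuple[float, float]] = []
    while t < duration:
        length = float(rng.exponential(mean_on if on else mean_off))
        if on:
            out.append((t, min(t + length, duration)))
        t += length
        on = not on
    return out


def _random_walk(
    rng: np.random.Generator,
    start: np.ndarray,
    n_frames: int,
    step_sigma: float,
    box_edge: float,
    scaffold_tree: cKDTree | None,
    exclusion: float,
) -> np.ndarray:
    """Reflected random walk, optionally excluded from the scaffold zone."""
    n_waters = start.shape[0]
    if scaffold_tree is None or exclusion <= 0:
        steps = rng.normal(0.0, step_sigma, size=(n_frames, n_waters, 3))
        steps[0] = 0.0
        return _fold(start[None, :, :] + np.cumsum(steps, axis=0), 0.0, box_edge)
    pos = np.empty((n_frames, n_waters, 3))
    pos[0] = start
    steps = rng.normal(0.0, step_sigma, size=(n_frames, n_waters, 3))
    for f in range(1, n_frames):
        prop = _fold(pos[f - 1] + steps[f], 0.0, box_edge)
        d, _ = scaffold_tree.query(prop)
        bad = d < exclusion
        prop[bad] = pos[f - 1][bad]  # reject steps entering the exclusion zone
        pos[f] = prop
    return pos


def _uniform_outside(
    rng: np.random.Generator,
    n: int,
    box_edge: float,
    scaffold_tree: cKDTree | None,
    exclusion: float,
) -> np.ndarray:
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        cand = rng.uniform(0.0, box_edge, size=(max(n - filled, 16), 3))
        if scaffold_tree is not None and exclusion > 0:
            d, _ = scaffold_tree.query(cand)
            cand = cand[d >= exclusion]
        take = min(len(cand), n - filled)
        out[filled : filled + take] = cand[:take]
        filled += take
    return out


def generate_hydration_trajectory(spec: HydrationSpec) -> tuple[Trajectory, GroundTruth]:
    """Generate a trajectory with planted hydration sites and bulk waters.

    Each site is occupied during exponential(mean_dwell) intervals
    separated by exponential off-periods with mean
    ``mean_dwell * (1 - occupancy) / occupancy``, so the long-run occupied
    fraction equals the requested occupancy.  While bound, the site's
    dedicated water sits at the site position plus per-axis Gaussian
    jitter; while unbound it joins the bulk.  Bulk waters perform a
    reflected Gaussian random walk, excluded from within
    ``exclusion_radius`` of scaffold atoms.
    """
    rng = np.random.default_rng(spec.seed)
    n_frames, dt = spec.n_frames, spec.dt
    duration = n_frames * dt
    times = np.arange(n_frames) * dt

    scaffold_xyz = spec.scaffold.coords()
    tree = cKDTree(scaffold_xyz) if len(scaffold_xyz) and spec.exclusion_radius > 0 else None

    n_site = len(spec.sites)
    n_waters = n_site + spec.n_bulk_waters
    truth = GroundTruth(
        site_positions=np.array([s.position for s in spec.sites]).reshape(n_site, 3),
        dwell_intervals=[[] for _ in range(n_site)],
    )

    water_xyz = np.zeros((n_frames, n_waters, 3))
    if n_waters:
        start = _uniform_outside(rng, n_waters, spec.box_edge, tree, spec.exclusion_radius)
        water_xyz[:] = _random_walk(
            rng, start, n_frames, spec.bulk_step_sigma, spec.box_edge, tree,
            spec.exclusion_radius,
        )

    for k, site in enumerate(spec.sites):
        if site.occupancy == 0.0:
            continue
        mean_off = site.mean_dwell * (1.0 - site.occupancy) / site.occupancy
        intervals = _sample_intervals(rng, site.mean_dwell, mean_off, duration)
        pos = np.asarray(site.position)
        for (a, b) in intervals:
            lo = int(np.ceil(a / dt))
            hi = int(np.ceil(b / dt))  # frames with a <= t < b
            if hi <= lo:
                continue
            jitter = rng.normal(0.0, site.jitter_sigma, size=(hi - lo, 3))
            water_xyz[lo:hi, k, :] = pos + jitter
            truth.dwell_intervals[k].append((a, b, k))

    # Assemble topology: scaffold atoms then one-oxygen water residues.
    atoms = [
        Atom(a.serial, a.name, a.element, a.residue_name, a.residue_index, a.chain, a.position)
        for a in spec.scaffold.atoms
    ]
    serial0 = max((a.serial for a in atoms), default=0)
    res0 = max((a.residue_index for a in atoms), default=0)
    for w in range(n_waters):
        atoms.append(
            Atom(
                serial=serial0 + 1 + w,
                name="OW",
                element="O",
                residue_name="SOL",
                residue_index=res0 + 1 + w,
                chain="W",
                position=water_xyz[0, w],
            )
        )
    topo = Structure(id="synthetic", atoms=atoms)

    coords = np.empty((n_frames, len(atoms), 3))
    coords[:, : len(spec.scaffold.atoms), :] = scaffold_xyz[None, :, :]
    coords[:, len(spec.scaffold.atoms) :, :] = water_xyz
    traj = Trajectory(topology=topo, coordinates=coords, times=times, dt=dt)
    return traj, truth


# ---------------------------------------------------------------------------
# Crystal-ensemble generator


def _anchored_scaffold(
    base: Structure, site_positions: np.ndarray, contact_cutoff: float = 0.36
) -> Structure:
    """Ensure every planted site has a scaffold N/O/S atom within reach.

    Sites farther than the contact cutoff from every polar scaffold atom
    get an extra anchor residue carrying a single carbonyl-like oxygen
    0.28 nm away.
    """
    atoms = list(base.atoms)
    polar = np.array([a.position for a in atoms if a.element in ("N", "O", "S")])
    serial = max(a.serial for a in atoms)
    res = max(a.residue_index for a in atoms)
    for pos in site_positions:
        d = np.linalg.norm(polar - pos, axis=1).min() if len(polar) else np.inf
        if d > contact_cutoff - 0.05:
            serial += 1
            res += 1
            anchor = np.asarray(pos) + np.array([0.28, 0.0, 0.0])
            atoms.append(
                Atom(serial, "O", "O", "GLY", res, "A", anchor)
            )
    return Structure(id=base.id, atoms=atoms)


def generate_crystal_ensemble(
    n_structures: int,
    conserved_sites: Sequence[tuple[Sequence[float], int]],
    decoys_per_structure: int,
    noise_sigma: float,
    seed: int,
    scaffold: Structure | None = None,
    box_edge: float = 4.0,
    min_support: int | None = None,
) -> tuple[list[Structure], GroundTruth]:
    """Generate aligned structures with planted conserved and decoy waters.

    Each structure shares a rigid scaffold.  Every conserved site places a
    water at ``position + N(0, noise_sigma)`` in exactly ``support``
    randomly chosen structures; decoy waters are uniform in the box and at
    least 0.45 nm from every conserved site.  Ground-truth conservation
    flags follow the majority rule ``support >= min_support`` (default
    ``floor(n/2) + 1``, the "2 of 3" rule for three structures).
    """
    if n_structures < 2:
        raise ValueError("need at least 2 structures")
    for pos, support in conserved_sites:
        if not (0 < support <= n_structures):
            raise ValueError(f"support {support} outside 1..{n_structures}")
    if noise_sigma >= 0.1:
        raise ValueError("noise_sigma must stay below 0.1 nm (half the cluster radius)")
    if min_support is None:
        min_support = n_structures // 2 + 1
    rng = np.random.default_rng(seed)

    site_pos = np.array([np.asarray(p, dtype=float) for p, _ in conserved_sites]).reshape(-1, 3)
    if scaffold is None:
        scaffold = make_scaffold(6, center=[box_edge / 2] * 3, spacing=0.4)
    scaffold = _anchored_scaffold(scaffold, site_pos)

    chosen = [
        sorted(rng.choice(n_structures, size=support, replace=False).tolist())
        for _, support in conserved_sites
    ]

    structures: list[Structure] = []
    truth = GroundTruth(site_positions=site_pos)
    for s in range(n_structures):
        sid = f"synth{s:02d}"
        atoms = [
            Atom(a.serial, a.name, a.element, a.residue_name, a.residue_index, a.chain, a.position)
            for a in scaffold.atoms
        ]
        serial = max(a.serial for a in atoms)
        res = max(a.residue_index for a in atoms)
        for k, ((_, support), members) in enumerate(zip(conserved_sites, chosen)):
            if s in members:
                serial += 1
                res += 1
                pos = site_pos[k] + rng.normal(0.0, noise_sigma, size=3)
                atoms.append(Atom(serial, "O", "O", "HOH", res, "W", pos))
                truth.conserved_flags[(sid, serial)] = support >= min_support
        placed = 0
        attempts = 0
        while placed < decoys_per_structure:
            attempts += 1
            if attempts > 1000 * max(decoys_per_structure, 1):
                raise ValueError("cannot place decoys: box too crowded")
            cand = rng.uniform(0.0, box_edge, size=3)
            if len(site_pos) and np.linalg.norm(site_pos - cand, axis=1).min() < 0.45:
                continue
            serial += 1
            res += 1
            atoms.append(Atom(serial, "O", "O", "HOH", res, "W", cand))
            truth.conserved_flags[(sid, serial)] = False
            placed += 1
        structures.append(Structure(id=sid, atoms=atoms))
    return structures, truth


# ---------------------------------------------------------------------------
# Signal-table generator


def generate_ephogsy_table(
    structure: Structure,
    truth: GroundTruth,
    hit_noise: float,
    seed: int,
    cutoff: float = 0.35,
) -> list[EphogsyEntry]:
    """Derive a hydrated-hydrogen table from planted sites plus noise.

    Hydrogens within ``cutoff`` of a true site get a normalised intensity
    drawn from Uniform(0.3, 1.0); a fraction ``hit_noise`` of the other
    hydrogens get a spurious Uniform(0.05, 0.3) intensity; the rest are
    absent from the table.
    """
    rng = np.random.default_rng(seed)
    hydrogens = [a for a in structure.atoms if a.is_hydrogen and not a.is_water]
    if not hydrogens:
        raise ValueError("structure has no hydrogens")
    entries: list[EphogsyEntry] = []
    sites = np.asarray(truth.site_positions).reshape(-1, 3)
    for h in hydrogens:
        near = len(sites) > 0 and float(np.linalg.norm(sites - h.position, axis=1).min()) <= cutoff
        if near:
            entries.append(
                EphogsyEntry(h.residue_index, h.name, float(rng.uniform(0.3, 1.0)), "noe")
            )
        elif hit_noise > 0 and rng.random() < hit_noise:
            entries.append(
                EphogsyEntry(h.residue_index, h.name, float(rng.uniform(0.05, 0.3)), "ambiguous")
            )
    return entries
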