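"""Readers and writers for structures, trajectories, density grids and tables.

Coordinates are nm everywhere inside the package; PDB and OpenDX files are
written in Angstrom at the format boundary.  PDB parsing and writing go
through gemmi; OpenDX grids through GridDataFormats; tables through pandas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
from gridData import Grid

from .structcore import Atom, Structure

__all__ = [
    "Trajectory",
    "EphogsyEntry",
    "read_structures",
    "write_structures",
    "read_trajectory",
    "write_trajectory",
    "write_density_dx",
    "read_density_dx",
    "write_bfactor_projection",
    "read_ephogsy_table",
    "write_ephogsy_table",
]

NM_PER_ANGSTROM = 0.1

log = logging.getLogger(__name__)

EPHOGSY_COLUMNS = ["residue_index", "atom_name", "intensity", "mechanism_flag"]
EPHOGSY_MECHANISMS = ("noe", "exchange", "ambiguous")


@dataclass
class Trajectory:
    """Time-stamped coordinate frames over a fixed topology.

    ``coordinates`` has shape (n_frames, n_atoms, 3) in nm; ``times`` is in
    ps and strictly increasing.  Frames earlier than
    ``equilibration_discard`` are dropped at read time, before any
    analysis.
    """

    topology: Structure
    coordinates: np.ndarray
    times: np.ndarray
    dt: float
    equilibration_discard: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[0] != self.times.shape[0]:
            raise ValueError("times and coordinate frames disagree in count")
        if self.coordinates.shape[1] != len(self.topology):
            raise ValueError(
                f"topology has {len(self.topology)} atoms but frames have "
                f"{self.coordinates.shape[1]}"
            )
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def duration(self) -> float:
        """Covered time span in ps, counting each frame as one dt of sampling."""
        return float(self.times[-1] - self.times[0] + self.dt) if self.n_frames else 0.0


@dataclass(frozen=True)
class EphogsyEntry:
    """One experimentally hydrated hydrogen with its normalised intensity."""

    residue_index: int
    atom_name: str
    intensity: float
    mechanism_flag: str = "noe"

    def __post_init__(self) -> None:
        if not (0.0 <= self.intensity <= 1.0):
            raise ValueError(f"intensity {self.intensity} outside [0, 1]")
        if self.mechanism_flag not in EPHOGSY_MECHANISMS:
            raise ValueError(f"unknown mechanism flag {self.mechanism_flag!r}")
        if not self.atom_name.startswith("H") and self.atom_name not in ("HN",):
            raise ValueError(f"{self.atom_name!r} is not a hydrogen name")


# ---------------------------------------------------------------------------
# PDB structures


def _validate_pdb_lines(path: Path) -> None:
    # gemmi tolerates short coordinate records; fail loudly instead.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM") and len(line.rstrip("\n")) < 54:
                raise ValueError(f"{path}: truncated {rec} record at line {lineno}")


def _convert_model(model: gemmi.Model, struct_id: str, model_number: int | None) -> Structure:
    atoms: list[Atom] = []
    best_alt: dict[tuple[str, int, str, str], int] = {}
    for chain in model:
        for res in chain:
            for at in res:
                key = (chain.name, res.seqid.num, res.name, at.name)
                pos = np.array([at.pos.x, at.pos.y, at.pos.z]) * NM_PER_ANGSTROM
                atom = Atom(
                    serial=at.serial,
                    name=at.name,
                    element=at.element.name or at.name[0],
                    residue_name=res.name,
                    residue_index=res.seqid.num,
                    chain=chain.name,
                    position=pos,
                    occupancy=float(at.occ),
                    b_factor=float(at.b_iso),
                )
                # Alternate locations: keep the highest occupancy; ties keep
                # the first encountered.
                if key in best_alt:
                    prev = best_alt[key]
                    if atom.occupancy > atoms[prev].occupancy:
                        atoms[prev] = atom
                else:
                    best_alt[key] = len(atoms)
                    atoms.append(atom)
    return Structure(id=struct_id, atoms=atoms, model_number=model_number)


def read_structures(path: str | Path, format: str = "pdb") -> list[Structure]:
    """Read a (possibly multi-model) PDB file into one Structure per MODEL.

    HETATM waters are retained as solvent atoms.  Alternate locations keep
    the highest-occupancy conformer.  Raises on truncated coordinate
    records (with the line number) and on files without atoms.
    """
    if format != "pdb":
        raise ValueError(f"unsupported structure format {format!r}")
    path = Path(path)
    _validate_pdb_lines(path)
    st = gemmi.read_pdb(str(path))
    base = st.name or path.stem
    out = []
    multi = len(st) > 1
    for model in st:
        num = int(model.num) if hasattr(model, "num") else None
        sid = f"{base}#{num}" if multi else base
        out.append(_convert_model(model, sid, num))
    out = [s for s in out if len(s)]
    if not out:
        raise ValueError(f"{path}: no atoms found")
    n_solvent = sum(len(s.water_oxygens) for s in out)
    log.debug("%s: %d model(s), %d solvent oxygen(s)", path, len(out), n_solvent)
    return out


def _to_gemmi(
    models: Sequence[tuple[Structure, np.ndarray | None]], name: str
) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    for k, (struct, coords) in enumerate(models, start=1):
        model = gemmi.Model(k)
        chains: dict[str, gemmi.Chain] = {}
        last_res_key: dict[str, tuple[int, str]] = {}
        for i, a in enumerate(struct.atoms):
            ch = chains.get(a.chain)
            if ch is None:
                ch = gemmi.Chain(a.chain or "A")
                chains[a.chain] = ch
            key = (a.residue_index, a.residue_name)
            if last_res_key.get(a.chain) != key:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_index, " ")
                res.het_flag = "H" if a.is_water else "A"
                ch.add_residue(res)
                last_res_key[a.chain] = key
            res = ch[-1]
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            xyz = a.position if coords is None else coords[i]
            ga.pos = gemmi.Position(*(np.asarray(xyz) / NM_PER_ANGSTROM))
            ga.occ = a.occupancy
            ga.b_iso = a.b_factor
            ga.serial = a.serial
            res.add_atom(ga)
        for ch in chains.values():
            model.add_chain(ch)
        st.add_model(model)
    st.setup_entities()
    return st


def write_structures(
    structures: Structure | Sequence[Structure],
    path: str | Path,
    remarks: Sequence[str] = (),
) -> Path:
    """Write one or more Structures as a (multi-model) PDB file."""
    if isinstance(structures, Structure):
        structures = [structures]
    path = Path(path)
    st = _to_gemmi([(s, None) for s in structures], path.stem)
    text = st.make_pdb_string()
    if remarks:
        header = "".join(f"REMARK 999 {r}\n" for r in remarks)
        text = header + text
    path.write_text(text)
    return path


# ---------------------------------------------------------------------------
# Trajectories


def read_trajectory(
    topology: str | Path,
    coords: str | Path | None = None,
    format: str = "pdb",
    dt: float | None = None,
    equilibration_discard: float = 0.0,
) -> Trajectory:
    """Read a trajectory from a multi-model PDB (or XTC/DCD via MDAnalysis).

    For multi-model PDB input the models are the frames and ``dt`` (ps)
    must be supplied -- PDB carries no timestamps and none are guessed.
    Frames with time earlier than ``equilibration_discard`` (ps) are
    dropped.
    """
    topology = Path(topology)
    if format == "pdb":
        models = read_structures(topology if coords is None else Path(coords))
        topo = models[0]
        counts = {len(m) for m in models}
        if len(counts) > 1:
            raise ValueError(f"frame atom counts differ across models: {sorted(counts)}")
        xyz = np.array([m.coords() for m in models])
        if dt is None:
            raise ValueError("multi-model PDB has no timestamps; dt must be given")
        times = np.arange(len(models)) * dt
    elif format in ("xtc", "dcd"):
        import MDAnalysis as mda

        u = mda.Universe(str(topology), str(coords))
        topo = read_structures(topology)[0]
        frames, times_l = [], []
        for ts in u.trajectory:
            frames.append(ts.positions * NM_PER_ANGSTROM)
            times_l.append(ts.time)
        xyz = np.array(frames)
        times = np.asarray(times_l, dtype=float)
        if dt is not None:
            times = np.arange(len(frames)) * dt
        elif times.size > 1 and np.all(np.diff(times) > 0):
            dt = float(times[1] - times[0])
        else:
            raise ValueError("trajectory carries no usable timestamps; supply dt")
    else:
        raise ValueError(f"unsupported trajectory format {format!r}")

    if xyz.shape[1] != len(topo):
        raise ValueError(
            f"atom count mismatch: topology {len(topo)} vs frames {xyz.shape[1]}"
        )
    keep = times >= equilibration_discard
    if not np.any(keep):
        raise ValueError("equilibration discard removes every frame")
    return Trajectory(
        topology=topo,
        coordinates=xyz[keep],
        times=times[keep],
        dt=float(dt),
        equilibration_discard=equilibration_discard,
    )


def write_trajectory(trajectory: Trajectory, path: str | Path) -> Path:
    """Write a trajectory as a multi-model PDB (one MODEL per frame)."""
    path = Path(path)
    models = [(trajectory.topology, trajectory.coordinates[f]) for f in range(trajectory.n_frames)]
    st = _to_gemmi(models, path.stem)
    path.write_text(st.make_pdb_string())
    return path


# ---------------------------------------------------------------------------
# OpenDX density grids


def write_density_dx(grid, path: str | Path) -> Path:
    """Export a DensityGrid's relative density as an OpenDX scalar field.

    Origin and grid step are written in Angstrom for molecular viewers.
    Data ordering follows the OpenDX "gridpositions counts" convention
    (z fastest-varying, then y, then x), which GridDataFormats implements.
    """
    if grid.n_frames_used == 0 or not np.any(grid.raw_counts):
        raise ValueError("refusing to write an empty density grid")
    path = Path(path)
    g = Grid(
        grid.relative_density.astype(float),
        origin=np.asarray(grid.origin) / NM_PER_ANGSTROM,
        delta=[grid.step / NM_PER_ANGSTROM] * 3,
    )
    g.export(str(path), file_format="dx")
    return path


def read_density_dx(path: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read an OpenDX scalar field; returns (values, origin_nm, step_nm)."""
    g = Grid(str(path))
    deltas = np.atleast_1d(np.unique(np.round(np.diag(np.atleast_2d(g.delta)), 9)))
    if deltas.size != 1:
        raise ValueError("anisotropic grid steps are not supported")
    return g.grid, np.asarray(g.origin) * NM_PER_ANGSTROM, float(deltas[0]) * NM_PER_ANGSTROM


# ---------------------------------------------------------------------------
# B-factor projection

#: Values are printed in ps divided by this factor to fit the B column.
BFACTOR_SCALE = 10.0
BFACTOR_MAX = 999.99


def write_bfactor_projection(
    structure: Structure,
    per_residue: Mapping[int, float],
    path: str | Path,
    scale: float = BFACTOR_SCALE,
) -> Path:
    """Write a PDB whose B-factor column carries a per-residue value.

    Every atom of a residue gets ``value / scale`` clamped to
    [0, 999.99]; residues without a value get the sentinel 0.00.  The
    scaling is recorded in a REMARK header so the file is
    self-describing.
    """
    for ri, v in per_residue.items():
        if not np.isfinite(v):
            raise ValueError(f"non-finite value for residue {ri}")
    proj = Structure(
        id=structure.id,
        atoms=[
            Atom(
                serial=a.serial,
                name=a.name,
                element=a.element,
                residue_name=a.residue_name,
                residue_index=a.residue_index,
                chain=a.chain,
                position=a.position,
                occupancy=a.occupancy,
                b_factor=float(
                    np.clip(per_residue.get(a.residue_index, 0.0) / scale, 0.0, BFACTOR_MAX)
                ),
            )
            for a in structure.atoms
        ],
        model_number=structure.model_number,
    )
    return write_structures(
        proj,
        path,
        remarks=[f"B-FACTOR COLUMN = PER-RESIDUE VALUE (PS) / {scale:g}, CLAMPED TO [0, {BFACTOR_MAX}]"],
    )


# ---------------------------------------------------------------------------
# Tables


def read_ephogsy_table(path: str | Path) -> list[EphogsyEntry]:
    """Read a TSV of hydrated hydrogens (header row required)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EPHOGSY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        EphogsyEntry(
            residue_index=int(row.residue_index),
            atom_name=str(row.atom_name),
            intensity=float(row.intensity),
            mechanism_flag=str(row.mechanism_flag),
        )
        for row in df.itertuples(index=False)
    ]


def write_ephogsy_table(entries: Iterable[EphogsyEntry], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [(e.residue_index, e.atom_name, e.intensity, e.mechanism_flag) for e in entries],
        columns=EPHOGSY_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path
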