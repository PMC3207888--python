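"""Concordance between hydration sites and experimentally hydrated hydrogens.

An NMR hydration experiment of the ePHOGSY family reports protein
hydrogens that receive magnetisation from water.  The analysis here asks,
for each reported hydrogen, whether a computed hydration site lies within
0.35 nm, and aggregates to residues: a residue with signals is concordant
when at least one of its reported hydrogens has a vicinal site; a residue
without signals is concordant when none of its hydrogens does.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .density_map import HydrationSite, sites_near_atoms
from .io_formats import EphogsyEntry
from .structcore import Atom, Structure

__all__ = ["ConcordanceReport", "hydrogen_concordance", "residue_concordance"]

#: Side-chain heavy atoms bearing exchangeable hydrogens, used as proxy
#: positions when a structure carries no explicit hydrogens.
_EXCHANGEABLE_SIDECHAIN = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "CYS": ("SG",),
    "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2"),
    "ASN": ("ND2",), "GLN": ("NE2",), "TRP": ("NE1",),
}


@dataclass
class ConcordanceReport:
    """Per-hydrogen and per-residue agreement between sites and signals."""

    per_hydrogen: list[tuple[int, str, float, bool]]  # residue, atom, intensity, vicinal
    per_residue: list[tuple[int, bool, bool]]  # residue, has_signal, mdhs_positive
    agreement_fraction: float
    proxy_note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.agreement_fraction <= 1.0):
            raise ValueError("agreement fraction outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.per_residue, columns=["residue_index", "has_signal", "mdhs_positive"]
        )

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            if self.proxy_note:
                fh.write(f"# {self.proxy_note}\n")
            fh.write(f"# agreement_fraction\t{self.agreement_fraction:.6f}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)
        return path


def _resolve(entries: Sequence[EphogsyEntry], structure: Structure) -> list[Atom]:
    atom_map = {(a.residue_index, a.name): a for a in structure.atoms if not a.is_water}
    resolved, missing = [], []
    for e in entries:
        a = atom_map.get((e.residue_index, e.atom_name))
        if a is None:
            missing.append(f"residue {e.residue_index} atom {e.atom_name}")
        else:
            resolved.append(a)
    if missing:
        raise ValueError("unresolvable hydrogens: " + "; ".join(missing))
    return resolved


def hydrogen_concordance(
    entries: Sequence[EphogsyEntry],
    structure: Structure,
    sites: Sequence[HydrationSite],
    cutoff: float = 0.35,
) -> np.ndarray:
    """Per-entry boolean: is a hydration site within cutoff of the hydrogen?

    Every entry must resolve to an atom of the structure; unresolvable
    hydrogens raise (listing them) rather than being silently skipped.
    """
    atoms = _resolve(entries, structure)
    return sites_near_atoms(sites, atoms, cutoff)


def _residue_probe_atoms(structure: Structure, residue_index: int) -> tuple[list[Atom], bool]:
    """Hydrogens of a residue, or proxy heavy atoms when there are none.

    Crystal structures usually lack hydrogens; in that case proximity is
    evaluated from the bonded heavy atoms (backbone N for the amide
    hydrogen, exchangeable side-chain N/O/S) with the cutoff unchanged.
    """
    res_atoms = [a for a in structure.atoms if not a.is_water and a.residue_index == residue_index]
    hydrogens = [a for a in res_atoms if a.is_hydrogen]
    if hydrogens:
        return hydrogens, False
    resname = res_atoms[0].residue_name if res_atoms else ""
    proxy_names = ("N",) + _EXCHANGEABLE_SIDECHAIN.get(resname, ())
    return [a for a in res_atoms if a.name in proxy_names], True


def residue_concordance(
    entries: Sequence[EphogsyEntry],
    structure: Structure,
    sites: Sequence[HydrationSite],
    cutoff: float = 0.35,
) -> ConcordanceReport:
    """Residue-level agreement between hydration sites and signals.

    A residue with at least one table entry has a signal; its site status
    is positive when any of its reported hydrogens lies within the cutoff
    of a site.  A residue without entries is site-positive when any of its
    hydrogens (or proxy heavy atoms, see ``_residue_probe_atoms``) lies
    within the cutoff.  The agreement fraction is the share of protein
    residues whose signal and site status coincide.
    """
    vicinal = hydrogen_concordance(entries, structure, sites, cutoff)
    per_hydrogen = [
        (e.residue_index, e.atom_name, e.intensity, bool(v))
        for e, v in zip(entries, vicinal)
    ]

    by_residue: dict[int, list[bool]] = {}
    for (ri, _, _, v) in per_hydrogen:
        by_residue.setdefault(ri, []).append(v)

    used_proxy = False
    per_residue: list[tuple[int, bool, bool]] = []
    n_agree = 0
    residues = structure.protein_residue_indices()
    for ri in residues:
        if ri in by_residue:
            has_signal = True
            positive = any(by_residue[ri])
        else:
            has_signal = False
            probes, proxy = _residue_probe_atoms(structure, ri)
            used_proxy = used_proxy or proxy
            positive = bool(sites_near_atoms(sites, probes, cutoff).any()) if probes else False
        per_residue.append((ri, has_signal, positive))
        n_agree += int(has_signal == positive)

    return ConcordanceReport(
        per_hydrogen=per_hydrogen,
        per_residue=per_residue,
        agreement_fraction=n_agree / len(residues) if residues else 0.0,
        proxy_note=(
            "signal-free residues probed via exchangeable-H-bearing heavy atoms "
            "(no explicit hydrogens in structure)"
            if used_proxy
            else ""
        ),
    )
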