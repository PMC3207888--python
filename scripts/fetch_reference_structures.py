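#!/usr/bin/env python
"""One-time download of the five Sso7d reference structures from RCSB.

Fetches 1BF4, 1BNZ, 1C8C (X-ray, protein-DNA complexes) and 1JIC, 1SSO
(solution NMR, model 1 only) and writes stripped copies to
``data/reference/<id>.pdb``: protein ATOM records (standard amino acids)
plus crystallographic waters.  DNA chains, hydrogens and other models are
dropped to keep the files small.  After this script has run once, the
five-structure RMSD check in the test suite and the acceptance script
pick the files up automatically.

Requires network access; everything else in this repository works offline.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

import gemmi

OUT_DIR = Path(__file__).resolve().parent.parent / "data" / "reference"
ENTRIES = ("1bf4", "1bnz", "1c8c", "1jic", "1sso")
URL = "https://files.rcsb.org/download/{pid}.pdb"

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def strip(structure: gemmi.Structure) -> gemmi.Structure:
    out = gemmi.Structure()
    out.name = structure.name
    model = structure[0]  # model 1 (the representative NMR conformer)
    new_model = gemmi.Model(1)
    for chain in model:
        new_chain = gemmi.Chain(chain.name)
        for res in chain:
            if res.name not in AMINO_ACIDS and res.name != "HOH":
                continue
            new_res = gemmi.Residue()
            new_res.name = res.name
            new_res.seqid = res.seqid
            new_res.het_flag = res.het_flag
            for atom in res:
                if atom.element.name == "H":
                    continue
                new_res.add_atom(atom)
            if len(new_res):
                new_chain.add_residue(new_res)
        if len(new_chain):
            new_model.add_chain(new_chain)
    out.add_model(new_model)
    out.setup_entities()
    return out


def main() -> None:
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    for pid in ENTRIES:
        dest = OUT_DIR / f"{pid}.pdb"
        if dest.exists():
            print(f"{pid}: already present, skipping")
            continue
        print(f"{pid}: downloading ...")
        raw, _ = urllib.request.urlretrieve(URL.format(pid=pid.upper()))
        st = gemmi.read_pdb(raw)
        stripped = strip(st)
        dest.write_text(stripped.make_pdb_string())
        print(f"{pid}: wrote {dest} ({dest.stat().st_size // 1024} kB)")


if __name__ == "__main__":
    main()
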