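"""Conserved crystallographic waters across aligned structures.

A water position counts as conserved when, after rigid alignment of the
protein heavy atoms, waters from enough independent structures fall
within a common sphere of 0.2 nm radius.  Candidate waters are first
restricted to those in polar contact with the protein (within 0.36 nm of
a nitrogen, oxygen or sulfur atom).  The "common sphere" rule is realised
by a deterministic greedy clustering: the unassigned water with the most
cross-structure neighbours seeds a cluster (sphere centred on the seed),
each other structure contributes at most its nearest in-sphere water, and
clusters reaching the support threshold (default: a majority of the
structures, i.e. 2 of 3) are kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structcore import Atom, Structure, kabsch_superpose

__all__ = ["ConservedWater", "filter_contact_waters", "find_conserved_waters"]

POLAR_ELEMENTS = ("N", "O", "S")


@dataclass
class ConservedWater:
    """A cross-structure water cluster in the reference frame."""

    centroid: np.ndarray  # nm
    members: list[tuple[str, int]]  # (structure id, water serial)
    support: int  # distinct structures represented

    def __post_init__(self) -> None:
        sids = [s for s, _ in self.members]
        if len(sids) != len(set(sids)):
            raise ValueError("a cluster may hold at most one water per structure")
        if self.support != len(set(sids)):
            raise ValueError("support must equal the number of member structures")


def filter_contact_waters(structure: Structure, contact_cutoff: float = 0.36) -> list[Atom]:
    """Water oxygens within the contact cutoff of a protein N, O or S atom.

    The rule names nitrogen, oxygen and sulfur only: a water that is close
    to a carbon but far from every polar atom is dropped.
    """
    polar = np.array(
        [a.position for a in structure.protein_atoms if a.element in POLAR_ELEMENTS]
    ).reshape(-1, 3)
    out = []
    for w in structure.water_oxygens:
        if len(polar) and np.linalg.norm(polar - w.position, axis=1).min() <= contact_cutoff:
            out.append(w)
    return out


def _align_onto_first(structures: Sequence[Structure]) -> list[dict]:
    """Superpose every structure's waters into the frame of the first.

    Protein heavy atoms matched by (residue_index, atom name) across all
    structures drive the alignment; waters never participate.
    """
    keyed = []
    for s in structures:
        d = {}
        for a in s.protein_heavy_atoms:
            d.setdefault((a.residue_index, a.name), a)
        keyed.append(d)
    common = set(keyed[0])
    for d in keyed[1:]:
        common &= set(d)
    if len(common) < 3:
        raise ValueError("no matchable protein core across the structures")
    keys = sorted(common)
    ref = np.array([keyed[0][k].position for k in keys])
    out = []
    for si, (s, d) in enumerate(zip(structures, keyed)):
        mob = np.array([d[k].position for k in keys])
        sup = kabsch_superpose(mob, ref)
        out.append({"structure": s, "index": si, "superposition": sup})
    return out


def find_conserved_waters(
    structures: Sequence[Structure],
    contact_cutoff: float = 0.36,
    cluster_radius: float = 0.2,
    min_support: int | None = None,
) -> list[ConservedWater]:
    """Identify conserved water positions across aligned structures.

    Default ``min_support`` is a majority of the input structures
    (``floor(n/2) + 1``), which reduces to the "at least 2 out of 3" rule
    for three structures.

    The greedy clustering is deterministic: seeds are chosen by the
    largest cross-structure neighbour count within ``cluster_radius``,
    ties broken by lowest structure position in the input list, then
    lowest water serial; each other structure contributes at most its
    nearest water inside the seed-centred sphere; the centroid is
    recomputed once from the members; assigned waters leave the pool.
    """
    if len(structures) < 2:
        raise ValueError("need at least 2 structures")
    n = len(structures)
    if min_support is None:
        min_support = n // 2 + 1

    aligned = _align_onto_first(structures)

    # candidate waters: (struct_pos, serial, aligned position)
    cands: list[tuple[int, int, np.ndarray]] = []
    for entry in aligned:
        s: Structure = entry["structure"]
        sup = entry["superposition"]
        for w in filter_contact_waters(s, contact_cutoff):
            cands.append((entry["index"], w.serial, sup.apply(w.position[None, :])[0]))

    unassigned = list(range(len(cands)))
    clusters: list[ConservedWater] = []
    while unassigned:
        # neighbour counts: waters of OTHER structures within the radius
        best = None
        for ci in unassigned:
            si, serial, pos = cands[ci]
            count = sum(
                1
                for cj in unassigned
                if cj != ci
                and cands[cj][0] != si
                and np.linalg.norm(cands[cj][2] - pos) <= cluster_radius
            )
            key = (-count, si, serial)
            if best is None or key < best[0]:
                best = (key, ci)
        seed_idx = best[1]
        s_si, s_serial, s_pos = cands[seed_idx]

        members = [seed_idx]
        for other in range(n):
            if other == s_si:
                continue
            nearest = None
            for cj in unassigned:
                if cands[cj][0] != other:
                    continue
                d = float(np.linalg.norm(cands[cj][2] - s_pos))
                if d <= cluster_radius and (nearest is None or d < nearest[0]):
                    nearest = (d, cj)
            if nearest is not None:
                members.append(nearest[1])

        centroid = np.mean([cands[m][2] for m in members], axis=0)
        support = len({cands[m][0] for m in members})
        if support >= min_support:
            clusters.append(
                ConservedWater(
                    centroid=centroid,
                    members=[(structures[cands[m][0]].id, cands[m][1]) for m in members],
                    support=support,
                )
            )
        for m in members:
            unassigned.remove(m)
    clusters.sort(key=lambda c: (-c.support, c.members[0]))
    return clusters
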