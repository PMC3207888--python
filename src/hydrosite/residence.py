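"""Water residence times per residue: intervals, means, classes, profiles.

A water "resides" on a residue while its oxygen stays within a shell
cutoff of any heavy atom of that residue.  Maximal runs of consecutive
occupied frames form occupancy intervals; runs separated by at most
``gap_tolerance`` absent frames are merged, and runs touching the first
or last frame are flagged censored (their true length is unknown).  The
mean residence time tau of a residue is the arithmetic mean of its
uncensored interval lengths.  Tau values are clustered into the four
classes short (tau < 100 ps), intermediate (100 <= tau < 300 ps), long
(300 <= tau < 1000 ps) and very long (tau >= 1000 ps), and distribution
profiles bin values into 100 ps bins over 0-1000 ps plus one open bin
from 1000 ps onward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import Trajectory

__all__ = [
    "OccupancyInterval",
    "ResidenceRecord",
    "ResidenceProfile",
    "TAU_CLASS_EDGES",
    "classify_tau",
    "occupancy_intervals",
    "site_occupancy_intervals",
    "residence_record",
    "residence_table",
    "residence_profile",
    "halves_convergence",
]

#: Class boundaries in ps: short / intermediate / long / very_long.
TAU_CLASS_EDGES = (100.0, 300.0, 1000.0)
TAU_CLASS_NAMES = ("short", "intermediate", "long", "very_long")

#: Profile bin edges: 100 ps bins over 0-1000 ps, then one open bin.
PROFILE_EDGES = tuple(float(x) for x in range(0, 1001, 100)) + (np.inf,)


@dataclass(frozen=True)
class OccupancyInterval:
    """A maximal run of frames during which one water occupies one shell."""

    residue_index: int
    water_id: int
    start: float  # ps
    end: float  # ps (exclusive; length = end - start)
    censored: bool

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class ResidenceRecord:
    """Per-residue mean residence time and class label."""

    residue_index: int
    tau: float  # ps; NaN when no uncensored interval exists
    n_intervals: int
    class_label: str

    @property
    def defined(self) -> bool:
        return np.isfinite(self.tau)


@dataclass(frozen=True)
class ResidenceProfile:
    """Histogram of residence times over the fixed 11-bin layout."""

    bin_edges: tuple[float, ...]
    bin_counts: tuple[int, ...]

    @property
    def frequencies(self) -> np.ndarray:
        total = sum(self.bin_counts)
        if total == 0:
            return np.zeros(len(self.bin_counts))
        return np.asarray(self.bin_counts, dtype=float) / total


def classify_tau(tau: float, edges: Sequence[float] = TAU_CLASS_EDGES) -> str:
    """Class label for a mean residence time, half-open boundaries.

    Exactly 100 ps is intermediate, 300 ps is long, 1000 ps is very long.
    """
    if not np.isfinite(tau):
        return "undefined"
    for edge, name in zip(edges, TAU_CLASS_NAMES):
        if tau < edge:
            return name
    return TAU_CLASS_NAMES[-1]


def _runs_from_bool(occ: np.ndarray, gap_tolerance: int) -> list[tuple[int, int]]:
    """Maximal runs of True, merging gaps of at most gap_tolerance Falses.

    Returns (first_frame, last_frame) pairs, inclusive.
    """
    idx = np.flatnonzero(occ)
    if idx.size == 0:
        return []
    runs: list[tuple[int, int]] = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if i - prev - 1 <= gap_tolerance:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    return runs


def occupancy_intervals(
    trajectory: Trajectory,
    residue_index: int,
    shell_cutoff: float = 0.35,
    gap_tolerance: int = 1,
) -> list[OccupancyInterval]:
    """Occupancy intervals of every water on one residue's shell.

    Per water oxygen, frames where the oxygen lies within ``shell_cutoff``
    (inclusive) of any heavy atom of the residue are collected; maximal
    runs separated by at most ``gap_tolerance`` absent frames are merged
    into one interval.  An interval touching the first or last frame is
    censored.  Distances are taken within each frame, so no prior
    superposition is required.
    """
    topo = trajectory.topology
    res_idx = np.array(
        [
            i
            for i, a in enumerate(topo.atoms)
            if not a.is_water and a.residue_index == residue_index and a.element != "H"
        ],
        dtype=int,
    )
    if res_idx.size == 0:
        raise ValueError(f"unknown residue index {residue_index}")
    wat_idx = np.array([i for i, a in enumerate(topo.atoms) if a.is_water_oxygen], dtype=int)
    if wat_idx.size == 0:
        return []

    n_frames = trajectory.n_frames
    occupied = np.zeros((n_frames, wat_idx.size), dtype=bool)
    # chunked broadcast keeps memory bounded for long trajectories
    chunk = max(1, int(4e6 / max(1, wat_idx.size * res_idx.size)))
    for f0 in range(0, n_frames, chunk):
        f1 = min(f0 + chunk, n_frames)
        w = trajectory.coordinates[f0:f1, wat_idx, None, :]
        r = trajectory.coordinates[f0:f1, None, res_idx, :]
        d2 = ((w - r) ** 2).sum(axis=-1).min(axis=-1)
        occupied[f0:f1] = d2 <= shell_cutoff**2

    dt = trajectory.dt
    t0 = float(trajectory.times[0])
    out: list[OccupancyInterval] = []
    for w in range(wat_idx.size):
        for first, last in _runs_from_bool(occupied[:, w], gap_tolerance):
            out.append(
                OccupancyInterval(
                    residue_index=residue_index,
                    water_id=int(wat_idx[w]),
                    start=t0 + first * dt,
                    end=t0 + (last + 1) * dt,
                    censored=(first == 0) or (last == n_frames - 1),
                )
            )
    out.sort(key=lambda iv: (iv.start, iv.water_id))
    return out


def site_occupancy_intervals(
    trajectory: Trajectory,
    site_position,
    shell_cutoff: float = 0.35,
    gap_tolerance: int = 1,
) -> list[OccupancyInterval]:
    """Occupancy intervals around a fixed point instead of a residue.

    Useful for computing residence times of individual hydration sites;
    the site position stands in for the residue's heavy atoms and the
    returned intervals carry residue_index -1.
    """
    import numpy as _np

    pos = _np.asarray(site_position, dtype=float).reshape(1, 3)
    topo = trajectory.topology
    wat_idx = _np.array([i for i, a in enumerate(topo.atoms) if a.is_water_oxygen], dtype=int)
    if wat_idx.size == 0:
        return []
    d2 = ((trajectory.coordinates[:, wat_idx, :] - pos[None]) ** 2).sum(axis=-1)
    occupied = d2 <= shell_cutoff**2
    dt = trajectory.dt
    t0 = float(trajectory.times[0])
    n_frames = trajectory.n_frames
    out: list[OccupancyInterval] = []
    for w in range(wat_idx.size):
        for first, last in _runs_from_bool(occupied[:, w], gap_tolerance):
            out.append(
                OccupancyInterval(
                    residue_index=-1,
                    water_id=int(wat_idx[w]),
                    start=t0 + first * dt,
                    end=t0 + (last + 1) * dt,
                    censored=(first == 0) or (last == n_frames - 1),
                )
            )
    out.sort(key=lambda iv: (iv.start, iv.water_id))
    return out


def residence_record(
    intervals: Iterable[OccupancyInterval], include_censored: bool = False
) -> ResidenceRecord:
    """Summarise one residue's intervals into a mean tau and class label.

    Censored intervals are excluded from the mean by default: that is
    unbiased for dwells much shorter than the trajectory and conservative
    (under-estimating) for very long ones.  ``include_censored=True``
    includes them for sensitivity analysis.
    """
    intervals = list(intervals)
    residues = {iv.residue_index for iv in intervals}
    if len(residues) > 1:
        raise ValueError(f"intervals span multiple residues: {sorted(residues)}")
    used = intervals if include_censored else [iv for iv in intervals if not iv.censored]
    if not used:
        ri = intervals[0].residue_index if intervals else -1
        return ResidenceRecord(ri, float("nan"), 0, "undefined")
    tau = float(np.mean([iv.length for iv in used]))
    return ResidenceRecord(used[0].residue_index, tau, len(used), classify_tau(tau))


def residence_table(
    trajectory: Trajectory,
    residue_indices: Sequence[int] | None = None,
    shell_cutoff: float = 0.35,
    gap_tolerance: int = 1,
    include_censored: bool = False,
) -> list[ResidenceRecord]:
    """Residence records for a set of residues (default: all protein residues)."""
    if residue_indices is None:
        residue_indices = trajectory.topology.protein_residue_indices()
    _check_stride(trajectory)
    return [
        residence_record(
            occupancy_intervals(trajectory, ri, shell_cutoff, gap_tolerance),
            include_censored=include_censored,
        )
        for ri in residue_indices
    ]


def _check_stride(trajectory: Trajectory, min_ratio: float = 5.0) -> None:
    # Heuristic guard: tau recovery degrades once the frame spacing is not
    # well below the dwell times of interest (shortest class edge).
    if trajectory.dt * min_ratio > TAU_CLASS_EDGES[0]:
        warnings.warn(
            f"frame spacing {trajectory.dt} ps is coarse relative to the "
            f"shortest residence class (<{TAU_CLASS_EDGES[0]:g} ps); "
            "short dwells may be missed",
            stacklevel=3,
        )


def residence_profile(values_or_intervals: Iterable) -> ResidenceProfile:
    """Histogram residence times into the fixed 11-bin layout.

    Accepts interval objects, residence records (their tau), or plain
    numbers.  A value exactly on a bin edge goes to the upper bin,
    matching the inclusive-lower class convention.
    """
    vals: list[float] = []
    for item in values_or_intervals:
        if isinstance(item, OccupancyInterval):
            vals.append(item.length)
        elif isinstance(item, ResidenceRecord):
            if item.defined:
                vals.append(item.tau)
        else:
            vals.append(float(item))
    if not vals:
        raise ValueError("nothing to profile")
    edges = np.asarray(PROFILE_EDGES[:-1])
    # digitize with right=False: value == edge lands in the upper bin
    which = np.digitize(vals, edges, right=False) - 1
    counts = np.bincount(which, minlength=len(PROFILE_EDGES) - 1)
    return ResidenceProfile(PROFILE_EDGES, tuple(int(c) for c in counts))


def _subtrajectory(trajectory: Trajectory, frame_slice: slice) -> Trajectory:
    return Trajectory(
        topology=trajectory.topology,
        coordinates=trajectory.coordinates[frame_slice],
        times=trajectory.times[frame_slice],
        dt=trajectory.dt,
        equilibration_discard=trajectory.equilibration_discard,
    )


def halves_convergence(
    trajectory: Trajectory,
    shell_cutoff: float = 0.35,
    gap_tolerance: int = 1,
) -> tuple[ResidenceProfile, ResidenceProfile, float]:
    """Compare residence-time profiles from the two halves of a trajectory.

    The trajectory is split at its midpoint time and the interval
    computation repeated independently on each half; uncensored interval
    lengths from all protein residues are pooled into profiles.  Returns
    both profiles and the maximum absolute difference of normalized bin
    frequencies -- a small value indicates the sampling has converged.
    """
    if trajectory.n_frames < 4:
        raise ValueError("need at least 4 frames")
    mid = trajectory.n_frames // 2
    profiles = []
    for half in (slice(0, mid), slice(mid, None)):
        sub = _subtrajectory(trajectory, half)
        lengths: list[float] = []
        for ri in sub.topology.protein_residue_indices():
            for iv in occupancy_intervals(sub, ri, shell_cutoff, gap_tolerance):
                if not iv.censored:
                    lengths.append(iv.length)
        profiles.append(residence_profile(lengths))
    disc = float(np.max(np.abs(profiles[0].frequencies - profiles[1].frequencies)))
    return profiles[0], profiles[1], disc
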