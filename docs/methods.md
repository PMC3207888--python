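# Methods

`hydrosite` computes four complementary views of protein hydration from
structural data: bulk-normalized water-density maps with hydration sites
(MDHS), per-residue water residence times, conserved crystallographic
waters, and concordance between hydration sites and NMR-detected hydrated
hydrogens. This note records the models, the parameters that matter, the
numerical conventions, and what the synthetic benchmarks do and do not
demonstrate.

All lengths are nanometres internally (PDB and OpenDX files are written in
Ångström at the format boundary); times are picoseconds.

## Density maps and hydration sites

The space around the protein is discretised on a regular grid (step
`grid_step`, default **0.05 nm**). For every trajectory frame the protein
backbone (N, CA, C, O) is superposed onto a reference structure by
least-squares rigid-body fitting (Kabsch, SVD with a determinant sign
correction so the motion is never a reflection), the same motion is
applied to the water oxygens, and each oxygen is binned into its voxel.

Voxels are labelled by the distance *d* from the voxel centre to the
nearest protein heavy atom of the reference — the simplest reproducible
reading of "distance from the protein surface":

* first hydration shell: *d* < 0.6 nm,
* bulk reference shell: 0.6 ≤ *d* < 0.8 nm (half-open intervals, so the
  labels partition space and nothing is double-counted).

The bulk density is the mean count density over bulk-shell voxels;
dividing every voxel by it yields the **relative density** (1.0 =
bulk-like water). Whether one regards the raw quantity as time-averaged
voxel occupancy or total counts is immaterial: the two differ by the
constant `n_frames × voxel volume`, which cancels in the ratio.

**MDHS extraction.** A first-shell voxel is a site peak iff its relative
density is at least the iso-level (default **2.8**; 2.0 is kept as a
separate rendering level) and exceeds all 26 neighbours; exact ties go to
the lexicographically smallest voxel index so extraction is deterministic.
Peaks closer than 0.1 nm (two voxels) are merged keeping the higher one —
sub-voxel jitter should not split one physical site. Sites are reported
sorted by descending peak density, with the size of the surrounding
26-connected above-threshold component as a support measure.

**Map correlation** is the Pearson coefficient of relative density over
the union of voxels where either map reaches a threshold. Note a
statistical property of this estimator: when the threshold sits near the
bulk mean, the union-selection itself induces negative correlation
between *independent* maps (a voxel that is low in one map enters the
union only if it is high in the other). Null checks should therefore use
thresholds far below bulk, where essentially all voxels qualify.

## Residence times

A water occupies a residue's shell while its oxygen is within
`residence_shell` (default **0.35 nm**, matching the proximity cutoff used
throughout) of any heavy atom of the residue; distances are evaluated
within each frame, so no prior superposition is required. Maximal runs of
occupied frames form intervals; runs separated by at most `gap_tolerance`
absent frames (default 1) are merged, absorbing single-frame imaging
jitter. An interval touching the first or last frame is **censored** —
its true length is unknown — and excluded from the mean by default. That
estimator is unbiased for dwells much shorter than the trajectory and
conservative (under-estimating) for dwells comparable to it; a switch
includes censored intervals for sensitivity analysis.

The mean residence time τ of a residue is classified as short (τ <
100 ps), intermediate (100 ≤ τ < 300 ps), long (300 ≤ τ < 1000 ps) or
very long (τ ≥ 1000 ps); boundaries are half-open with the inclusive
lower edge, and exactly the same convention drives the distribution
profile (100 ps bins over 0–1000 ps plus one open bin from 1000 ps).
Convergence is assessed by repeating the computation independently on the
two halves of the trajectory and reporting the maximum absolute
difference of normalized bin frequencies; the profiles pool uncensored
interval lengths across residues so the comparison has stable statistics
even on small systems.

Two sources of bias of the frame-counted estimator are worth knowing:
dwells shorter than the frame spacing dt can be missed entirely, which
inflates the conditional mean of *detected* intervals by roughly dt/2τ;
and gap-merging inflates τ when genuine off-periods are comparable to
dt·(gap_tolerance+1). Recovery guarantees therefore require dt ≲ τ/25 and
are benchmarked with gap merging off; a warning is emitted when the frame
spacing is coarse relative to the shortest residence class.

## Conserved waters

Candidate waters are those within `contact_cutoff` (**0.36 nm**) of a
protein nitrogen, oxygen or sulfur atom — the rule deliberately names
polar atoms only, so a water close to carbon alone is dropped. After
aligning all structures onto the first by their shared protein heavy
atoms (matched by residue index and atom name; waters never drive the
alignment), waters from different structures falling within a common
sphere of `cluster_radius` (**0.2 nm**) are clustered greedily:

1. seed from the unassigned water with the most cross-structure
   neighbours within the radius (ties: lowest structure position in the
   input list, then lowest serial);
2. each *other* structure contributes at most its nearest water inside
   the seed-centred sphere;
3. the centroid is recomputed once from the members; assigned waters
   leave the pool.

Clusters are kept when they span at least `min_support` structures;
the default is a majority, `floor(n/2) + 1`, which reduces to the
"at least 2 out of 3" rule for three structures. The sphere is centred
on the seed water rather than a free centroid — the alternative reading;
with positional noise well below the radius the two coincide, and the
seed-centred rule makes the procedure deterministic and order-free.

## Concordance with hydrated-hydrogen tables

NMR hydration experiments of the ePHOGSY family report protein hydrogens
receiving magnetisation from water. Each table row carries a residue
index, a hydrogen name, a normalized intensity in [0, 1] and a mechanism
flag (direct NOE / exchange / ambiguous). Intensity is carried through
but never thresholded: signal presence is presence of a row, since
relayed transfer pathways preclude a quantitative distance
interpretation.

A reported hydrogen is concordant when a hydration site lies within
`proximity_cutoff` (**0.35 nm**, inclusive). Residues aggregate as: a
residue with signals is site-positive if any of its reported hydrogens is
vicinal; a residue without signals is site-positive if any of its
hydrogens is. When the structure carries no explicit hydrogens (X-ray),
proximity is evaluated from the bonded heavy atoms — backbone N for the
amide hydrogen and the exchangeable-hydrogen-bearing side-chain N/O/S
atoms — with the cutoff unchanged, and the report header records that
convention. The agreement fraction is the share of protein residues
whose signal and site status coincide.

## Synthetic study conditions

The generators produce data with the statistical structure the analysis
assumes, with known ground truth:

* **Trajectories** — a rigid scaffold (the method assumes no major
  backbone rearrangement, so the generator tests it in its validity
  regime) plus planted sites with exponential dwell and off periods.
  Off-period means are `mean_dwell·(1−occupancy)/occupancy`, making the
  long-run occupied fraction equal the requested occupancy; memoryless
  dwells keep every recovery check analytically tractable. Bound waters
  jitter around the site (per-axis σ, default 0.02 nm); unbound and bulk
  waters perform a reflected Gaussian random walk excluded from a radius
  around scaffold atoms (default 0.15 nm). All draws come from a seeded
  PCG64 generator: equal seeds give bit-identical output within this
  implementation (cross-implementation reproducibility is statistical,
  not bit-level).
* **Structure ensembles** — a shared scaffold with conserved waters
  planted (position + Gaussian noise, σ < half the cluster radius) in a
  chosen number of structures, plus uniform decoy waters kept ≥ 0.45 nm
  from every planted site.
* **Signal tables** — hydrogens within 0.35 nm of a planted site receive
  Uniform(0.3, 1.0) intensities; a chosen fraction of the remaining
  hydrogens receive spurious Uniform(0.05, 0.3) intensities.

Benchmark sizing (chosen once, as the package's standard conditions): the
site-recovery system uses a 6-residue scaffold in a 3 nm box, three sites
at occupancy 0.9, 250 bulk waters and 17 000 frames, giving ≈ 20 expected
counts per bulk voxel so the 2.8 iso-level lies ~10 σ into the Poisson
tail and false peaks are vanishingly rare. The normalization fixture uses
the same geometry with no sites and frame-independent water positions —
i.e. exactly the homogeneous Poisson point process against which the
"relative density = 1.00 within counting error" expectation is derived.
The τ-recovery systems place ten isolated single-residue shells with one
site each (occupancy 0.5) and use an excluded-volume radius (0.45 nm)
larger than the residence shell, so the planted dwell intervals are the
only occupancy events; trajectory lengths are chosen to yield ≈ 600–1500
uncensored intervals, keeping the 3σ sampling band inside the 10%
recovery tolerance.

What passing these benchmarks does **not** show: the generator has no
protein flexibility, no water–water structure, no realistic diffusion
constants and no hydrogen-bond geometry, so recovery on it validates the
*estimators* (binning, normalization, peak logic, interval accounting,
clustering, aggregation rules), not the physics of any particular force
field or the values reported for any real protein. Reproducing published
trajectory-scale numbers (e.g. a cross-map correlation of ~0.7 between
two 100 ns simulations) is out of scope by design.

## Numerical conventions and degenerate inputs

* Distance cutoffs are inclusive (d ≤ cutoff) throughout, making boundary
  behaviour exact and testable.
* Superposition requires ≥ 3 non-collinear points per set and raises on
  degenerate input; the returned rotation always has determinant +1
  within 1e-9.
* Atom matching across structures is by (residue index, atom name);
  alternate locations keep the highest-occupancy conformer (ties: first
  encountered); NMR ensembles contribute model 1 unless another is
  selected.
* Multi-model PDB trajectories carry no timestamps; the frame spacing dt
  must be supplied — it is never guessed. Frames before the equilibration
  discard (default 100 ps) are dropped before any analysis.
* An empty bulk shell (no observations) is an error advising longer
  trajectories or wider shells, not a silent division by zero.
* B-factor projections write value/10 clamped to [0, 999.99] into the
  B column (the scaling is recorded in a REMARK); residues without a
  value get 0.00.
* OpenDX export follows the standard "gridpositions counts" ordering
  (z fastest, then y, then x) with origin and deltas in Å.

## Known limitations

* Residence times are computed per residue (and optionally against site
  positions); no multi-exponential survival fitting is attempted.
* The greedy common-sphere clustering is deterministic but, like all
  greedy schemes, not globally optimal; it is validated by exact
  agreement with an independent naive implementation on randomized small
  instances rather than by an optimality proof.
* Solvent species other than water, mmCIF input, and compressed
  trajectory writing are unsupported.
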