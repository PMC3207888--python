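# hydrosite

Protein hydration analysis from molecular-dynamics ensembles and
experimental structures: water-density maps and hydration sites,
per-residue water residence times, conserved crystallographic waters, and
concordance with NMR-detected hydrated hydrogens.

## The problem

How water organises at a protein surface shapes where ligands, nucleic
acids and other proteins can bind: stable hydration sites shield surface
patches, while sparsely hydrated regions often coincide with interaction
hot spots. `hydrosite` is for structural biologists and simulators who
want to turn an MD trajectory (or a set of crystal/NMR structures) into a
quantitative hydration landscape and compare it with experiment.

## What it computes

**MD hydration sites (MDHS).** Water-oxygen positions from every frame
are binned on a 3D grid (step 0.05 nm) after superposing the protein onto
a reference (Kabsch least-squares fit). Voxels are labelled by distance
*d* to the nearest protein heavy atom: first hydration shell
(*d* < 0.6 nm) and bulk reference shell (0.6 ≤ *d* < 0.8 nm). Densities
are normalized by the bulk-shell mean, so ρ_rel = 1 means bulk-like
water, and hydration sites are the filtered local maxima with
ρ_rel ≥ 2.8.

**Residence times.** For each residue, maximal runs of frames during
which a water oxygen stays within 0.35 nm of the residue's heavy atoms
form occupancy intervals; τ is the mean length of uncensored intervals,
classified as short (τ < 100 ps), intermediate (100 ≤ τ < 300 ps), long
(300 ≤ τ < 1000 ps) or very long (τ ≥ 1000 ps), with 100 ps distribution
profiles and a half-trajectory convergence check.

**Conserved waters.** Across aligned structures, waters within 0.36 nm of
a protein N/O/S atom that fall into a common 0.2 nm sphere in at least a
majority of the structures (2 of 3 by default) are reported as conserved
clusters.

**Concordance.** Given a table of hydrogens with water-transfer NMR
signals (ePHOGSY-style), each hydrogen is checked for a hydration site
within 0.35 nm, and agreement is aggregated per residue.

A seeded synthetic-data module generates trajectories with planted
hydration sites (exponential dwell times, set occupancies), structure
ensembles with planted conserved waters, and matching signal tables — all
with known ground truth, so every estimator is validated by recovery.

## Worked example

Run the built-in recovery benchmark (three planted sites at occupancy
0.9 in a 3 nm box, plus dwell-time, conserved-water and concordance
systems):

```python
from hydrosite.pipeline_cli import run_synthetic_benchmark
import json
print(json.dumps(run_synthetic_benchmark(seed=7), indent=2, sort_keys=True))
```

prints

```json
{
  "concordance_agreement": 1.0,
  "conserved_expected": 2.0,
  "conserved_found": 2.0,
  "n_sites_found": 3.0,
  "site_max_position_error_nm": 0.004999999999999893,
  "site_precision": 1.0,
  "site_recall": 1.0,
  "tau_rel_error_dwell_1500ps": 0.05044921875,
  "tau_rel_error_dwell_300ps": 0.00810256410256405,
  "tau_rel_error_dwell_50ps": 0.002493638676844796
}
```

meaning: all three planted hydration sites were recovered with no false
positives and peak positions within 0.005 nm of the truth (one tenth of a
voxel); planted mean dwell times of 50/300/1500 ps were recovered within
0.2–5 % relative error; both plantable conserved waters (supports 3 and
2 of 3 structures) were found while the support-1 decoy was rejected; and
a noise-free signal table agreed with the planted sites at every residue.

The same stages run from the shell on your own data:

```bash
hydrosite run-all --trajectory traj.pdb --dt 0.2 \
    --ensemble crystals.pdb --signals ephogsy.tsv --out-dir out/
```

which writes `density.dx` (OpenDX, for PyMOL/ChimeraX iso-surfaces),
`sites.tsv`/`sites.pdb`, `residence.tsv` and a τ-coloured
`tau_bfactor.pdb`, `conserved.tsv`/`conserved.pdb`, `concordance.tsv`,
and a `manifest.json` recording the config, input checksums and seed.
`hydrosite synth` writes the synthetic fixtures; `hydrosite benchmark`
reproduces the metrics above. See `docs/methods.md` for the model and
every tunable parameter.

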