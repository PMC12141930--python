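# muscledti

Skeletal-muscle diffusion-tensor analysis: phantom simulation, tensor
fitting, streamline fascicle reconstruction, architecture metrics, and
interlimb deficit statistics.

## The problem

Muscles affected by hemiparetic cerebral palsy (HCP) undergo secondary
structural change — atrophy, shortened fascicles, extracellular-matrix
proliferation — that contributes to weakness in the affected arm.
Diffusion tensor imaging (DTI) can measure both the macrostructure
(muscle volume, fascicle length and pennation angle via tractography)
and the microstructure (water diffusivity) of forearm flexors
non-invasively, and interlimb percent deficits in these measures can be
related to the interlimb deficit in grip strength.

This package implements that analysis chain as a tested, reusable
pipeline.  Because clinical cohorts of this kind are not publicly
shareable, every stage is exercised against **synthetic ground truth**:
unipennate muscle phantoms with closed-form architecture, and simulated
bilateral cohorts with injected deficits, so that what the statistics
recover can be compared with what was put in.

## What it computes

* **Tensor stage** — per-voxel diffusion tensor by two-pass weighted
  linear least squares on the log signal, and the standard scalars
  FA = √(3/2)·‖λ−MD‖/‖λ‖, MD = (λ₁+λ₂+λ₃)/3, AD = λ₁,
  RD = (λ₂+λ₃)/2, averaged over all muscle voxels.
* **Tractography stage** — every muscle voxel seeds a bidirectional
  streamline (step 0.5 mm, turning cap 90°, FA floor 0) that stops at
  the muscle boundary; anatomical filters (boundary contact, length
  bounds, aponeurosis-to-deep endpoint pairing) select valid fascicles.
* **Architecture stage** — fascicle count, arc lengths (raw and
  normalized to bone length), pennation angle against the local
  aponeurosis plane, and

      PCSA = volume · cos(μ_pennation) / μ_length

  with μ the mean (median/mode variants available), plus volume-weighted
  aggregation across muscles.
* **Statistics stage** — per-participant percent deficits
  PD = (reference − other)/reference × 100; linear mixed-effects models
  `value ~ group × arm` with random intercepts for age bin, sex and
  participant; Pearson correlations of each PD with the grip-strength
  PD; and the integrated model `PD_grip ~ PD_volume + PD_MD` with
  marginal r².
* **Generators** — slab phantoms (12-direction b = 400 s/mm² scheme,
  10 b = 0 volumes, 1.25 × 1.25 × 6.5 mm³ voxels, Rician noise with
  3-average magnitude averaging) and bilateral cohorts (14 HCP + 16 TD;
  27% / 4.5% volume deficits, 9.3% MD deficit, grip-deficit weights
  1.27 and 0.843).

## Worked example

```bash
python analysis/03_architecture_recovery.py
```

recovers the architecture of three noiseless phantoms (60 × 20 × 13 mm
slab, fibers at 0°/15°/30° to the aponeurosis):

```
 theta_deg  n_valid  n_raw  length_mm  length_true_mm  length_err_pct  pennation_deg  pcsa_mm2  pcsa_true_mm2
       0.0     1536   1536  59.999999       60.000000        0.000002            0.0 260.000004     260.000000
      15.0      288   1536  50.228142       50.228143        0.000002           15.0 300.000007     300.000000
      30.0      928   1536  25.999999       26.000000        0.000004           30.0 519.615261     519.615242
```

Each row is one phantom: all 1536 voxels are seeded, the endpoint-pair
filter keeps only fascicles spanning deep surface to aponeurosis, and
the recovered mean length (thickness/sin θ), pennation and PCSA match
the closed forms to numerical precision.  `analysis/05_cohort_statistics.py`
runs the statistical stage on a simulated cohort and reports, over
repeated cohorts, mean recovered percent deficits of 26.9% (volume,
injected 27%) and 9.3% (MD, injected 9.3%), with the integrated model
explaining ≈ 0.61 of the grip-deficit variance at the generator weights.

The same pipeline is scriptable end-to-end:

```bash
muscledti run-all --out run1 --seed 7
```

writes the simulated DWI (NIfTI + FSL bval/bvec), scalar maps,
tractograms (.trk and TSV), architecture summary, cohort table and
statistics JSON, plus a manifest with a checksum per output.

## Layout

```
src/muscledti/   library: phantom, gradients, tensor, tracking,
                 architecture, cohort, stats, io, config, pipeline,
                 cli, validation
analysis/        numbered narrative drivers writing tables to results/
tests/           pytest suite (unit, property and acceptance tests)
scripts/         acceptance.py
docs/methods.md  models, assumptions, parameter choices, limitations
```
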