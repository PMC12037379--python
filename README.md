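# siscom — quantitative subtraction ictal SPECT for epileptogenic-zone localization

In pharmacoresistant focal epilepsy, surgical resection of the
epileptogenic zone (EZ) is the most effective route to seizure freedom,
and localizing the EZ is the central pre-surgical problem. A perfusion
SPECT scan acquired during a seizure (ictal) shows focal hyperperfusion
at the seizure onset zone; a scan at rest (interictal) does not.
**SISCOM** (Subtraction Ictal SPECT COregistered to MRI) turns this
contrast into a statistical map:

1. rigidly coregister the interictal scan to the ictal scan by mutual-information
   maximization;
2. scale both scans so the whole-brain mean intensity is 100
   (proportional global normalization);
3. subtract voxel by voxel, `d = ictal − interictal`;
4. z-score the difference over all brain voxels,
   `z = (d − μ_d) / σ_d`;
5. keep voxels with `z > 2` (hyperperfusion; a two-sided mode also keeps
   `z < −2`), and group them into 3-D connected clusters.

The candidate EZ is then read off the cluster map by four criteria: the
cluster containing the **highest-intensity voxel**, or the **1st / 2nd /
3rd largest cluster** by voxel count. Against a reference EZ region
(resection area with good surgical outcome), each candidate is
**concordant** (overlaps the reference), **partially concordant** (within
an adjacency radius, default 10 mm) or **discordant**.

This package provides, for researchers comparing SISCOM platforms or
validating pipelines without access to patient data:

- the full pipeline (`siscom.pipeline.run_siscom`) over NIfTI-1 volumes;
- a synthetic phantom generator with exact ground truth (known rigid
  misalignment, known focus and propagation blobs) so every stage is
  testable end to end;
- the agreement statistics used to compare two analysis platforms on a
  20-patient temporal-lobe-epilepsy cohort — Cohen's kappa with
  poor (< 0.40) / moderate (0.40–0.75) / excellent (> 0.75) bands, exact
  and normal-approximation Mann–Whitney, Fisher's exact test, Spearman's
  rho — plus that cohort's published per-patient tables packaged as CSV
  fixtures, with every recomputable summary statistic re-derived from
  them.

## Worked example

Simulate a phantom pair (left temporal focus, 30 % hyperperfusion, 5 %
noise) and run the pipeline:

```sh
siscom simulate --out demo --seed 7
siscom run --ictal demo/ictal.nii.gz --interictal demo/interictal.nii.gz \
           --ez-mask demo/ez_mask.nii.gz --ez-side left --out demo/out
```

`demo/out/report.json` then contains (abridged):

```
mu_d -0.0000  sigma_d 13.3973  mask_voxels 103871  n_significant 2359
clusters:  highest_intensity 6.98   n_clusters 1600
           vol1_mm3 9126.0  vol2_mm3 162.0  vol3_mm3 162.0
labels:    highest_intensity C (0.0 mm)   cluster1 C (0.0 mm)
           cluster2 D (68.5 mm)           cluster3 D (89.4 mm)
registration: translation (-0.009, -0.006, 0.025) mm, final MI 1.907 nats
```

Reading: the difference map was z-scored over 103 871 brain voxels; the
implanted focus is recovered as the largest cluster (9 126 mm³, peak
z = 6.98) and is concordant with the ground-truth EZ mask by both the
highest-intensity and largest-cluster criteria, while the small residual
noise clusters are discordant. The recovered registration is within
hundredths of a millimetre of the (identity) truth for this aligned pair.

Replicate the packaged 20-patient study tables:

```sh
siscom replicate
```

prints one PASS/FAIL line per published summary (mean age 42.5 y, SPM
mean highest intensity 3.7, 70 % sensitivity for both platforms by the
largest-cluster criterion, SPM-vs-Analyze kappa 0.0179 "poor", ...) and
exits 0 only if all of them reproduce.

The `analysis/` directory holds the same experiments as numbered
narrative scripts (phantom simulation, registration validation, phantom
cohort study, table replication) writing their tables under `results/`.

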