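# Methods

## Pipeline model

The package implements ictal–interictal subtraction SPECT analysis
(SISCOM) as a deterministic pipeline over scalar 3-D volumes. All
volumes are reoriented to RAS+ at load, voxel indices are 0-based, world
coordinates are millimetres, and every derived map lives on the ictal
grid (registration direction: moving = interictal, fixed = ictal).

**Brain mask.** Voxels brighter than `f x mean(all voxels)` (default
`f = 0.125`), restricted to the largest 26-connected component, then one
pass of 1-voxel morphological closing. The z statistics are computed
over the intersection of the two scans' masks, further restricted to
voxels actually covered by the resampled interictal scan, so
out-of-field zeros never enter `μ_d`/`σ_d`.

**Rigid registration.** 6-parameter rigid body (3 translations mm,
3 extrinsic x-y-z Euler rotations) about the fixed brain's center of
mass, maximizing mutual information of a 64-bin joint histogram with
intensities clipped to the [1st, 99th] percentile. The search is
Powell's method at two levels (≈6 mm grid, then full resolution with
every 2nd in-mask voxel), followed by a small-step Powell polish.
Two numerical details matter and were found necessary:

- *metric smoothing* (default 1 voxel Gaussian on both images): with
  voxel-wise independent noise, trilinear resampling at a misaligned
  pose low-pass filters the moving image's noise and spuriously
  *raises* MI, biasing rotations by several degrees; smoothing both
  images removes the bias;
- *consistent binning*: the moving histogram range is estimated from
  the in-mask samples at the initial pose. Estimating it over a
  different voxel population bins the marginals inconsistently, and the
  MI optimum moves away from the true alignment.

If the optimized MI does not exceed MI at identity, the identity
transform is returned with a `degraded` flag. Registration is fully
deterministic (no random restarts by default).

**Normalization, subtraction, z-scoring.** Proportional scaling to an
in-mask mean of 100 (the conventional global value); subtraction on the
common grid; z-scores use the in-mask sample mean and SD with
denominator n−1 (at ~10⁵ brain voxels the n vs n−1 choice is
numerically irrelevant but is fixed for reproducibility). The whole
chain is invariant to positive rescaling of either raw input.
Significance is *strict* exceedance `z > t` (default `t = 2`),
positive-only by default (ictal hyperperfusion defines the EZ), with a
two-sided mode.

**Clusters.** Connected components per sign class, default 26-
connectivity (configurable 6/18); no minimum cluster size (published
per-patient tables contain sub-voxel-scale entries, so source pipelines
evidently kept single-voxel clusters). Ranking uses voxel count with
ties broken by higher peak z then lexicographic peak index; volumes are
reported in mm³. The highest-intensity criterion returns the cluster
containing the global peak z; "highest-intensity cluster" and
"highest-intensity voxel" coincide under this definition.

**Concordance.** A candidate cluster is concordant with the reference
EZ mask if they share ≥ 1 voxel; otherwise the minimum Euclidean
boundary distance in world mm decides partially-concordant
(≤ adjacency radius) vs discordant. The adjacency radius quantifies
"adjacent or very close"; no number exists in the source description,
so the default is 10 mm ≈ one smoothing-kernel width, and the radius is
a logged parameter of every run. For group statistics, partially
concordant and discordant merge into one non-concordant class.

## Statistics layer

- **Cohen's kappa** (own implementation): unweighted, from the observed
  cross-tabulation; bands poor < 0.40, moderate 0.40–0.75 (inclusive),
  excellent > 0.75; undefined (distinct error) when chance agreement
  is 1.
- **Mann–Whitney U** (own implementation): midranks for ties; exact mode
  enumerates all `C(n, n1)` group assignments (feasible at study sizes)
  with the two-sided p defined by `|U − n1 n2/2|`; the
  normal-approximation mode is tie-corrected (via scipy). Both modes
  are exposed because the published group comparison does not state its
  convention; on the packaged tables the approximation reproduces the
  published p = 0.0252 exactly and the exact mode gives 0.0200 — both
  significant at α = 5 %.
- **Fisher's exact** and **Spearman's rho** delegate to scipy.stats
  (two-sided hypergeometric sum; rho on midranks with t-approximation
  p), with an exact permutation option for Spearman at n ≤ 9.

## Study-table replication

The cohort's per-patient tables (demographics/pathology/outcome,
per-method cluster metrics, per-criterion concordance labels) ship as
CSV fixtures. `replicate_study` recomputes every recoverable summary —
means/medians/SDs (denominator n−1), per-criterion concordant counts
and sensitivities, the between-platform kappa on binarized
highest-intensity labels, and the hippocampal-sclerosis vs
other-pathology cluster-count comparison — and compares each with its
printed value at the printed rounding. Integer counts must match
exactly; real-valued summaries may additionally differ by one unit in
the last printed digit, because they are recomputed from per-patient
entries that are themselves rounded (e.g. the largest-cluster volume SD
recomputes to 16 798.45 from entries printed to 0.1 mm³ against a
printed 16 798.5). Two published quantities are reported as
non-replicable rather than checked: the mean *total* cluster volume
(totals over all clusters are not recoverable from the printed top-3
columns, and the source reports it in mm³ for one platform and voxels
for the other) and per-rank mean cluster intensities (not printed per
patient).

## Synthetic phantoms

The generator emulates a reconstructed perfusion study, not raw
emission data: an ellipsoidal brain (default semi-axes 65 x 80 x 60 mm
on a 64 x 64 x 56 grid at 3 mm) with internal structure shared by both
frames — a posteriorly offset white-matter core at 60 % gray intensity,
two paramedian low-intensity ventricles, and a brighter infero-posterior
cerebellum-like lobe. The internal asymmetry is deliberate: a bare
ellipsoid is nearly rotation-invariant and cannot constrain MI-based
rotation estimates. The ictal frame multiplies a spherical focus
(default radius 12 mm at (−42, −15, −8) mm, i.e. left mesial-temporal)
and any propagation blobs by `1 + amplitude/100`; both frames are
smoothed to SPECT-like resolution (default FWHM 8 mm, matching typical
reconstruction filtering); the interictal frame is rigidly moved by the
specified misalignment; white Gaussian noise (default SD 5 % of the
in-brain mean) is added last. Defaults — 30 % focal hyperperfusion,
5 % noise, 8 mm resolution, 20-subject cohorts with randomized focus
side — represent a clearly localizing ictal study.

What the phantoms do *not* emulate: anatomical cortical geometry,
Poisson emission statistics and reconstruction-correlated noise
(additive Gaussian noise post-smoothing is voxel-wise independent),
attenuation/scatter artifacts, and physiological between-session
perfusion drift. Passing phantom tests therefore demonstrates the
correctness of the numerics (registration recovery, z-map calibration,
cluster extraction, concordance logic) under a known ground truth — not
clinical sensitivity on real patients, which the packaged study tables
address separately.

Phantom problem sizes used by the test suite and the acceptance script
(20 registration phantoms, 50- and 20-subject cohorts, 8–15 null
phantoms) were chosen as the smallest batches at which the measured
rates are stable; the null |z| > 2 exceedance is compared with the
Gaussian value 2(1 − Φ(2)) = 4.55 % as a mean over phantoms.

## Known limitations

- The registration accuracy targets (1 mm / 1°) are validated on
  phantoms with SPECT-like smoothness; pathologically flat or symmetric
  images can still leave rotations weakly determined.
- The concordance rule is geometric (mask overlap / boundary distance);
  the source study's judgments were made at the lobe level by experts,
  so the packaged labels are consumed as data, never recomputed.
- Analyze-platform intensities in the packaged tables are 8-bit display
  values (~245–255); they are treated as opaque fixture data since the
  display mapping is not stated.
- No inference is attached to cluster extent (no multiple-comparison
  correction): the method is a plain z-subtraction, by design.
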