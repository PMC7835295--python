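# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic experiments do and do not show.

## Synthetic cohort model

No public archive of prospective prostate-cancer PSMA PET scans exists, so
the pipeline is exercised on phantoms that reproduce the *statistical
structure* of such a cohort rather than its anatomy.

Each subject carries a latent aggressiveness score `a ~ N(0, 1)` that
drives both the images and the outcome labels:

* **Tumor** — an ellipsoid (volume drawn log-uniformly from 1–15 mL, mild
  random anisotropy) with mean uptake `base_suv · (1 + 0.35·a)`,
  `base_suv ~ U(5, 12)` SUV. Heterogeneity is a multiplicative lognormal
  Gaussian random field, spectrally synthesised by Gaussian-smoothing white
  noise (correlation length 8 mm), with amplitude
  `0.35 · exp(0.8·a)`. The log-linear amplitude coupling keeps the
  texture–aggressiveness relation monotone and strictly positive over the
  whole latent range; a linear coupling clips at zero for low `a` and
  erases discrimination in the lower tail. The field has unit mean so the
  target mean uptake is preserved.
* **Confounder** — a 15 mm-radius bladder at 30 SUV, placed 15 mm from the
  tumor surface, outside the delineation constraint mask, to exercise the
  bladder-exclusion logic (background guard, mask-constrained growth).
* **Acquisition** — isotropic Gaussian blur of 7 mm FWHM (typical
  whole-body PET resolution) applied to the whole scene, then additive
  Gaussian noise (SD 0.1 SUV) as a post-reconstruction noise
  approximation; Poisson/sinogram-level simulation is out of scope.
  Default grid: 4 mm voxels, matching common reconstruction settings.
* **Labels** — each binary endpoint is Bernoulli with
  `logit p = b0 + b1·a`. `b0` is calibrated by Gauss–Hermite quadrature so
  the expected prevalence matches the cohort targets: lymph-node
  involvement 13.9% (10/72 surgically staged), any metastasis 18.4%,
  Gleason ≥ 8 26.8%, extracapsular extension 50.7%. `b1 = 0` makes labels
  independent of the images (the null condition).

Both mean uptake and heterogeneity were deliberately made informative:
in the emulated setting, standard PET metrics alone predict outcomes
(AUC ≈ 0.7–0.8) and texture adds on top, so a generator in which uptake is
pure noise would not represent the intended conditions. Couplings were
chosen once so the latent score is recoverable from images and then frozen.

**What the phantoms do not emulate:** anatomy and attenuation, multifocal
disease, nodal lesions, reconstruction artefacts, scanner-specific or
spatially-variant PSFs, inter-scanner harmonisation. Passing tests show the
*pipeline* behaves correctly under known ground truth; they do not certify
clinical performance on patient data.

## Partial-volume correction and calibration

Richardson–Lucy deconvolution with an isotropic Gaussian PSF: a FWHM
parameterisation implies no particular kernel shape, and an isotropic
Gaussian is the standard post-reconstruction choice. Iteration starts from
the observed image, runs 10 steps, guards the ratio with ε = 1e-12 and uses
reflective boundaries (which conserve flux for interior objects to <1%, a
tested invariant). Since the Gaussian is symmetric, the mirrored kernel in
the RL update equals the kernel itself.

PSF calibration deconvolves a six-sphere NEMA NU2-style phantom
(10/13/17/22/28/37 mm, 10:1 sphere:background) over a candidate FWHM grid
and picks the FWHM whose post-PVC recovery coefficients best match a target
curve (sum of squared deviations). The recovery statistic is the **mean
within the 50%-of-maximum isocontour** around each sphere. This choice is
load-bearing: max-based recovery overshoots under RL ringing (biasing the
argmin to too-small FWHMs) and whole-mask mean recovery increases
monotonically with candidate FWHM (argmin escapes to the grid edge); the
A50 mean yields a unique interior argmin at the generating FWHM
(recovered to ±1 mm on noiseless phantoms, a tested property). Target
recovery curves are configuration inputs, not constants, since published
harmonisation bands are scanner-programme specific.

## Delineation

The threshold is the standard background-corrected relative form
`T = f·(SUV_peak − bkg) + bkg`. Decisions where conventions vary:

* SUV_peak uses a 1 mL sphere (≈12.4 mm diameter, EANM convention),
  evaluated by exhaustive sphere-mean search over the constraint mask;
  ties broken by lowest linear voxel index; spheres clip at grid edges
  with a warning.
* Background is the mean of a 2-voxel dilation shell around the constraint
  mask, excluding shell voxels above 2.5× the shell median — the guard that
  keeps bladder spill-over out of the estimate. Shell thickness and guard
  factor are configurable.
* Region growth takes the 26-connected component of `{SUV ≥ T}` (inclusive
  inequality) containing the peak centre, intersected with the constraint
  mask. If the peak-centre voxel itself falls below `T` (possible because
  the peak is a sphere mean), the hottest above-threshold voxel seeds the
  component instead.

Nesting across the 50–70% sweep and whole-voxel translation equivariance
are tested invariants.

## Feature set

The 480-feature decomposition is 50 intensity (18 intensity statistics,
2 peaks, 23 intensity-histogram, 7 intensity-volume-histogram), 22
morphology, and 408 texture features: GLCM 25 × 6 aggregations,
GLRLM 16 × 6, GLSZM/GLDZM 16 × 3 each, NGTDM 5 × 3, NGLDM 17 × 3.
Definitions follow the IBSI reference nomenclature. Conventions chosen
where the standard leaves room:

* discretization: fixed 0.25 SUV bins anchored at the VOI minimum; the
  maximum clamps into the top bin; a constant VOI is a single level.
* IVH features use continuous intensities (not the discretized levels);
  `V_f` counts voxels with intensity fraction ≥ f (inclusive); the IVH
  area under the curve equals the mean intensity fraction exactly.
* GLCM: symmetric, Chebyshev distance 1; 2D aggregation averages matrices
  over slices without voxel-count weighting; empty matrices (single-voxel
  slices) are skipped in averages.
* GLRLM merged aggregations accumulate the effective voxel count
  (voxels × merged directions) for the run-percentage denominator.
* GLDZM distance is city-block steps to the VOI border (border voxel = 1;
  the array edge counts as border); zones share the GLSZM connectivity
  (26 in 3D, 8 in 2D).
* NGLDM: coarseness α = 0; dependence count = 1 + number of equal-level
  in-VOI Chebyshev-1 neighbours.
* morphology uses a marching-cubes mesh at the 0.5 iso-level (volumes,
  surface area, densities), PCA axes of the voxel point cloud (axis
  lengths 4√λ), and the Thomsen approximation for the enclosing-ellipsoid
  surface (relative error ≈ 1%). Degenerate single-voxel VOIs fall back to
  voxel surrogates and are flagged.
* features undefined on degenerate VOIs (zero variance, single level) are
  emitted as 0 with a flag rather than dropped, keeping tables rectangular.

Every matrix family is verified against independent brute-force oracles
(pair enumeration, line walking, flood fill, neighbour scans) on small
random VOIs, and 3D-merged features are checked invariant under 90°
grid rotations.

## Cross-validation pipeline

`RadiomicsForest.fit()` runs repeated stratified k-fold cross-validation
(defaults: 5 folds × 50 repeats, re-randomised per repeat) around a
random forest (default 1000 trees). Inside each training fold, in order:
z-scoring (constant columns get SD 1), dimension reduction (none / PCA
retaining 95% variance / RFE dropping the lowest-importance 10% per step
with the retained size chosen by inner-CV AUC / ANOVA top-10-percentile),
SMOTE (minority oversampled to the majority count by k-NN interpolation,
k = 5), then a randomized search over tree depth {2, 4, 6, 8, ∞} and split
criterion {gini, entropy} (10 draws, 3-fold inner CV scored by AUC; inner
fold counts and draw counts are configuration defaults, not reported
values). The held-out fold enters no fit — a guard test verifies that
scrambling test-fold labels leaves the held-out predictions bit-identical.
Single-class test folds (possible with ~10 positives) are excluded from
AUC aggregation and counted. Forest importances are mean-decrease-in-
impurity, normalised to sum to 1; PCA fits report no feature-space
importances. All randomness fans out deterministically from one seed via
`SeedSequence.spawn`.

## Inference

* **Permutation test** — labels shuffled once per permutation, the same
  pipeline re-run (10× repeated 5-fold by default; scaled down in tests),
  p = plain fraction of permutation mean AUCs ≥ the actual mean AUC (no
  +1 smoothing, so p = 0 is attainable and the granularity is 1/n_perm).
* **DeLong** — placement-value (structural-component) variance, two-sided
  normal p; identical score vectors (zero variance) give p = 1 with a
  defined rather than undefined result. Model comparison applies the test
  per fold cell on matched partitions (same pipeline seed) and reports the
  median p, a deliberately conservative scheme.
* **ICC** — two-way mixed model, absolute agreement, single measurement,
  from the ANOVA mean squares; categories poor/moderate/good/excellent at
  0.5/0.75/0.9 with boundary values assigned upward (the conventional
  open intervals leave boundaries unassigned). Cross-checked against an
  independent statistical package in the tests.

## Scaled experiment sizes

The repository's tests and the acceptance script run everything at sizes a
single CPU handles in minutes, as a deliberate design choice: phantom grids
36×36×28 at 4 mm, cohorts of 40–200 subjects, forests of 25–200 trees,
2–8 repeats, 20–40 permutations with ~20 meta-replicates. The acceptance
recovery experiments use n = 200 subjects with effect sizes β₁ ∈ {0, 5}
on PVC images at the 50% threshold with no dimension reduction: at β₁ = 0
the cross-validated mean AUC calibrates to 0.5, at β₁ = 5 the pipeline
recovers the coupling (AUC ≈ 0.8–0.9 across seeds). Full-scale settings
(1000 trees, 50 repeats, 100 permutations) remain the library defaults.

One caveat the experiments exposed: because radiomic features are strongly
inter-correlated (a handful of effective dimensions), the *dataset-level*
null distribution of the cross-validated AUC has heavy tails — a single
independent label draw can align with a dominant feature direction by
chance and yield a genuine (not leaked) CV AUC well away from 0.5. The
acceptance script therefore reports the null level averaged over three
independent label draws on one extracted cohort, whose expectation is
exactly 0.5; permutation-based inference is unaffected since it compares
against the same dataset's permutation distribution.

## Known limitations

* The exact 480-item feature list of the original analysis is not public;
  the 50/22/408 family decomposition here matches the printed counts under
  IBSI definitions but individual features may differ from the original
  tool's selection.
* The background-adaptation formula and shell definition behind the
  published delineation method are not printed; the implementations here
  are documented conventions, configurable where they are decisions.
* Cross-validated AUCs on synthetic cohorts are not comparable in absolute
  terms to the clinical cohort's values; only structural and qualitative
  behaviour (null calibration, signal recovery, PVC/threshold effects) is
  meaningful.
* SMOTE is applied after dimension reduction and before hyperparameter
  search; the inner search oversamples inner-training splits only.
* The "best configuration by mean AUC" summary is optimistic (no
  selection-corrected inference), and is flagged as such in the report.
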