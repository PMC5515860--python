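# Methods

This note documents the models, parameter choices and numerical decisions
behind `aslperf`, and what the synthetic-phantom validation does and does
not establish about real data.

## Perfusion model and quantification

The acquisition emulated and inverted is a PICORE QUIPSS-II pulsed ASL
sequence: a tag slab inverts arterial water, a saturation cut at TI1 fixes
the temporal width of the labeled bolus, and slices are read out starting
at TI2 in ascending order. Under the QUIPSS-II assumptions (bolus fully
delivered before readout, no outflow, label relaxing with the T1 of blood)
the difference signal of a voxel in slice *s* is

ΔM = 2 · α · M0_blood · f · TI1 · exp(−TI2_s / T1b) / 6000,

with *f* the CBF in mL/100 g tissue/min, TI1 in seconds, and
TI2_s = TI2 + s·slice_duration. The quantifier inverts this closed form.
No transit-delay term beyond the QUIPSS-II timing assumptions is modeled,
and no multi-delay fitting is attempted.

**Constants** (`QuantConstants`, shared by the phantom's forward model and
the quantifier so round-trip tests exercise one set of numbers, not two
copies):

| constant | default | unit | rationale |
|---|---|---|---|
| α (inversion efficiency) | 0.95 | — | standard pulsed-labeling value at 3 T |
| T1 of blood | 1664 | ms | standard arterial-blood T1 at 3 T |
| M0_CSF → M0_blood ratio | 0.76 | — | see below |
| unit factor | 6000 | s·mL/(min·100 g) | 100 g × 60 s/min |

The full CSF-to-blood magnetization conversion involves proton-density and
T2*/TE decay terms of both compartments; this implementation collapses the
chain into the single dimensionless ratio 0.76. All constants are
overridable in configuration and echoed in every map's provenance sidecar.

**Surround subtraction.** ΔM at control *k* is c_k − (t_{k−1} + t_{k+1})/2
in acquisition order, which cancels any linearly drifting signal component
exactly. The first/last control of the run has one neighbor and falls back
to simple subtraction, keeping all n_pairs estimates; with a nonzero drift
*b* per volume this leaves a bias of b/n_pairs on the mean ΔM (≈0.6% of
the gray-matter signal at defaults), visible in the round-trip bias
measurements and accepted in exchange for not discarding a pair.

**Calibration.** M0_CSF is the *median* of the reference scan inside the
CSF mask — robust to partial-volume contamination at the mask edge. The
minimum-contrast field is the average of the two repetitions, smoothed at
6 mm FWHM and normalized to unit mean over the brain mask, so the division
preserves brain-mean signal; field values below 0.05 invalidate the voxel
instead of being divided. The CSF reference scan is treated as acquired
coil-corrected (its simulated counterpart carries no coil modulation); the
field is divided out of the mean difference volume only.

**Tag/control ordering** is tag-first by default and configurable — the
interleaving convention differs between sites and the difference operation
handles either.

## Partial-volume correction and conditioning

CBF_corr = CBF_uncorr / (GM + 0.4·WM). The 0.4 white-matter weight and its
implied 2.5:1 gray/white perfusion ratio are one constant (`WM_WEIGHT`);
CSF is assumed to have zero flow. Voxels whose denominator falls below
ε = 0.1 (CSF-dominated) are removed from the validity mask rather than
divided — the correction otherwise amplifies noise without bound in
near-pure-CSF voxels.

Stage order is fixed and asserted from provenance logs: **PVC → smooth →
clip → resample → screen**.

- *Smoothing*: 4 mm FWHM Gaussian, masked renormalized convolution
  (smoothed masked map divided by smoothed mask). This avoids rim
  attenuation where the kernel overlaps the mask edge, leaves constants
  invariant exactly, and preserves the masked mean to first order.
- *Clipping*: negative intensities replaced with 0 (idempotent).
- *Resampling*: trilinear to a 3 mm isotropic grid; all µL volumes
  downstream are computed as voxel count × |det(affine)| and never
  hard-coded. The phantom generates directly on the 3 mm analysis grid, so
  atlas registration is an identity pass-through in this pipeline.
- *Screening*: "values deviating by more than 3 SD of the mean" is
  interpreted at the **session level** by default — a map is excluded when
  its within-mask mean deviates more than 3 cohort SDs from the cohort
  mean of means (single pass; a zero-SD cohort excludes nothing). The
  sentence is ambiguous about the screening unit, so a voxel-level variant
  (per-map 3-SD voxel exclusion) is available behind `level="voxel"`.

## Group statistics

Per-subject Hungry − Fed difference maps are compared between groups by a
per-voxel linear model (intercept + group indicator + covariates, scanner
as a fixed effect). Without covariates the group *t* equals the textbook
pooled two-sample *t* — asserted to 1e-10 against a closed-form oracle.

**Cluster-extent randomization.** For each relabeling of group membership
the t-map is recomputed, binarized two-sided at voxel p < 0.001, and the
maximum face-connected (6-neighbor) cluster size inside the search ROI
recorded; k_min is the smallest extent whose null exceedance probability
is ≤ 0.05. Choices:

- *Scheme*: label permutation (not sign-flipping) — natural for a
  two-group between-subject contrast. Exhaustive enumeration replaces
  sampling when the number of distinct relabelings is ≤ 20,000; fewer
  distinct relabelings than 1/cluster_p triggers a warning plus exact
  enumeration. Relabelings that make the covariate collinear with the
  permuted group indicator leave the group effect unidentified and are
  dropped from the null.
- *Connectivity*: faces only — the conservative default of cluster
  simulation tools.
- *Sign handling*: voxel tests are two-sided; clusters are extracted and
  reported per sign.
- *Determinism*: the seed is mandatory in configuration and echoed in all
  outputs; the Monte-Carlo SE of the exceedance estimate is reported
  (zero under exhaustive enumeration).

The hypothalamus is too small for cluster inference and is tested on its
whole-ROI mean with a pooled *t*. Cohen's *d* is computed on
anatomical-ROI averages (not on significant clusters) to avoid
non-independence inflation.

## Behavioral association

Huber robust regression of ratings on regional CBF by iteratively
reweighted least squares: weights min(1, c·s/|r|) with c = 1.345 (95%
Gaussian efficiency), scale s = median|r|/0.6745 re-estimated per
iteration, convergence when coefficients move < 1e-8. The slope standard
error is the weighted-least-squares one at the final weights
(σ² (XᵀWX)⁻¹ with σ² = Σw·r²/(n−2)) and p-values use the t distribution
with n − 2 df — a pragmatic convention; robust-SE conventions differ
between implementations and no numerical agreement with any particular
published t-value is claimed. An exact fit (zero residual scale) reports
t = ∞, p = 0. The scan covers group × condition × region cells and applies
Bonferroni correction p_adj = min(1, 6·p) for the family of 2 conditions ×
3 regions; secondary clinical covariates reuse the same operation with
their own family size.

## The digital phantom

The phantom generates what the pipeline consumes — tag/control series, a
CSF reference scan, two minimum-contrast repetitions, tissue fractions,
ROI masks, a session manifest with ratings — with exact serialized ground
truth. It emulates:

- **Geometry**: concentric ellipsoidal tissue bands (white-matter core,
  gray-matter band, CSF rim and central ventricle) on the 3 mm analysis
  grid, 24×24×12 voxels by default. Boundaries are smoothed to create
  genuine partial-volume voxels; the ventricle core is forced to pure CSF
  (exact calibration) and the four ROI boxes to pure gray matter (exact
  effect arithmetic). Three multi-voxel search ROIs and one ≤5-voxel
  structure tested whole-ROI are placed disjointly in the gray-matter
  band; overlap raises a configuration error.
- **Acquisition**: 20 tag/control pairs (40 volumes), TR 2500 ms,
  TI1 600 ms, TI2 1600 ms. The slice readout schedule is not part of the
  emulated protocol's public description, so it is configuration with a
  documented default — ascending order, 45 ms per slice — rather than a
  guessed "true" value. Default grids use 12 slices so the synthetic
  volumes stay small; the slice-timing rule is exercised identically at
  any slice count.
- **Signal**: control = static tissue signal × coil field + linear drift
  + white thermal noise (SD 2 signal units, ≈0.5% of the static signal);
  tag = control − ΔM × coil field with ΔM from the shared forward model.
  The coil field is a random second-order polynomial with ±20% amplitude,
  normalized to unit brain mean. M0_CSF defaults to 1200 signal units.
- **Population**: 16 controls and 21 patients by default, alternating
  between two scanner labels within group (exercising the covariate).
  Tissue CBF defaults to 60 (GM) and 24 (WM) mL/100 g/min — the 2.5:1
  ratio the PVC assumes. Each subject carries a baseline GM-CBF shift
  (SD 5 mL/100 g/min, realistic inter-individual spread) that is stable
  across conditions, so it cancels in Hungry − Fed contrasts while giving
  the behavioral association a predictor with variance. Hungry − Fed
  offsets are planted per ROI and group — by default +8/−8 (ventral
  striatum, prefrontal ROI) and +6/−6 (insula) mL/100 g/min for
  controls/patients, zero in the hypothalamus — reproducing the
  opposite-signed group response pattern. An optional per-subject jitter
  of the planted offsets defaults to 0 so truth remains exactly
  reconstructible from configuration.
- **Ratings**: 0–7 Likert hunger ratings, rating = clamp(center +
  slope·(ROI CBF − reference) + noise). The planted link defaults to
  slope −0.1 per mL/100 g/min with noise SD 0.5, attached to the hungry
  patients' insula; all other cells carry condition centers only
  (hungry 5.0, fed 1.5).

**What the phantom does not emulate** — and hence what passing tests do
not establish about real data: anatomy (the geometry is schematic), head
motion beyond linear drift, physiological noise structure (cardiac or
respiratory fluctuations, temporally correlated noise), transit-delay
heterogeneity, k-space/SENSE reconstruction artifacts, segmentation error
(fractions are supplied, not estimated), and registration error (all
volumes share one grid). The validation demonstrates that the *analysis*
is correct and calibrated under its own model assumptions, not that those
assumptions hold in any given acquisition.

## Validation experiments and problem sizes

The experiments in `aslperf.experiments` (used by the test suite and the
reproduction script) run at these sizes, chosen to give tight Monte-Carlo
error while keeping the full suite interactive:

- round-trip bias: 20 single-subject default-noise phantoms; noiseless
  recovery is exact to ~1e-13 relative (floating-point only).
- oracle agreement: 1000 random cohorts (GLM vs pooled *t*), 100 random
  fits (Huber c→∞ vs OLS).
- cluster FWER: 200 null cohorts, scaled to 10 subjects per group,
  6 pairs, a 16×16×8 grid and 1000 permutations per cohort; the full
  quantify→PVC→contrast path runs on each.
- effect direction: 20 default-condition cohorts, 1000 permutations each.
- association: 50 planted-slope and 100 null cohorts; regional CBF enters
  at ground-truth resolution in these replicates (the sensitivity of the
  scan to imaging noise is exercised separately through the full-pipeline
  driver), ratings carry their configured noise.

## Known limitations

- The surround-subtraction endpoint convention trades a small,
  quantified drift bias for retaining every pair.
- The session-level interpretation of quality screening is a choice;
  both readings are implemented but only one can be the default.
- Huber p-values use an n−2-df t reference; for n < ~15 this is only an
  approximation to the randomization distribution of the robust slope.
- The mean-preservation of masked smoothing is exact only for constant
  maps; for structured maps it holds to ~2% at the default kernel.
- The phantom's rating clamp attenuates planted slopes when the operating
  point sits near the 0/7 bounds; defaults keep ratings comfortably
  interior.
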