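# Methods

`meningrad` implements a radiographic analysis of meningioma WHO grade from
contrast-enhanced T1 MRI: radiomic feature extraction inside a tumor
segmentation, univariate screening of semantic (radiologist-scored binary)
and radiomic (computed continuous) features against grade, and random-forest
grade classification validated on a temporally held-out subset.  Because no
patient imaging is distributed, every stage is exercised on a synthetic
phantom cohort whose statistical structure encodes the grade-dependent
phenotype the analysis assumes.

## Preprocessing

Tumor intensities are winsorized at mean ± 3 SD computed over the mask
foreground (the tumor is the analysis substrate; background air/skull values
would corrupt the statistics), then image and mask are resampled to an
isotropic 3 mm lattice — trilinear for the image, nearest-neighbor for the
mask — so distance-1 texture offsets mean the same physical distance for
every patient.  Winsorizing rather than excluding voxels keeps the grid
dense for the filter bank.  No further intensity normalization is applied:
all texture features are computed on a range-relative discretization and the
rank-based statistics downstream are invariant to monotone intensity maps.
Note that winsorizing is a single pass; re-applying it re-estimates the
statistics on clipped data and may clip further, so the operation is a fixed
point only for volumes already inside the band.

## Filter bank

Nineteen channels: the original volume, eight subbands of a single-level
undecimated (stationary) 3D wavelet transform, and ten
Laplacian-of-Gaussian (LoG) responses.

* **Wavelet.** Coiflet-1, orthonormal, one decomposition level — the
  convention of the radiomic-signature literature this feature set follows.
  Subband labels map letters to axes: `HHL` = high-pass x, high-pass y,
  low-pass z.  The transform is undecimated, so every subband retains the
  input grid.
* **LoG.** σ runs 0.5–5.0 mm in 0.5 mm steps (`LoGk` ↔ σ = 0.5·k mm, so
  `LoG4` = 2.0 mm, `LoG5` = 2.5 mm).  Second derivatives are taken per axis
  in voxel units and divided by spacing², giving responses in mm⁻² that are
  invariant to grid resolution; a wide kernel truncation (8σ) keeps the DC
  response numerically zero.  Scales below half the largest voxel spacing
  are computed but flagged with a warning (under-resolved).

Both filters use symmetric (mirror) boundary extension to avoid wrap-around
artifacts in anatomical volumes.

## Radiomic features

Texture features are computed on an equal-width discretization of the
masked intensities into Ng = 32 levels spanning the foreground range,
recomputed per channel (filter responses have their own ranges).  A constant
foreground maps to level 1.

* **GLCM** (cluster prominence, difference entropy, inverse difference
  normalized): distance-1 co-occurrence over the 13 unique 3D directions,
  symmetrized and normalized per direction, features averaged across
  directions.  IDN normalizes |i−j| by Ng.
* **GLRLM** (run-length non-uniformity, short-run low-gray-level emphasis):
  maximal collinear runs within the mask, same 13 directions,
  feature-level averaging.
* **GLSZM** (high/low-intensity large-area emphasis, low-intensity
  small-area emphasis): connected zones of equal level under
  26-connectivity; direction-free.
* **First order**: median, mean, minimum, and population skewness
  (m₃/m₂^{3/2}; defined as 0 for a constant foreground).
* **Shape**: volume (voxel count × voxel volume), spherical disproportion
  (isosurface area over the area of the equal-volume sphere, from marching
  cubes at the 0.5 level — voxel-face counting was rejected because it
  overestimates a sphere's area by a constant factor), and maximum axial
  diameter (largest in-plane distance between foreground voxel centers over
  axial slices).

The default 15-feature analysis panel pairs channels with features
(`HHL Skewness` … `HHH High Intensity Large Area Emp.`); names without a
channel prefix refer to the original channel.  The full feature-space
inventory enumerates 55 intensity/texture names per channel × 19 channels
plus 10 shape names (1,055 total); it is a catalogue of the space the panel
was selected from, and only the panel features are computed numerically.

Every texture feature is validated against naive full-enumeration oracles
(voxel-pair loops, run walks, BFS flood fills) to 1e-10 on random tiny
volumes, and against closed-form degenerate cases.

## Univariate statistics

* Binary features: conditional-maximum-likelihood odds ratio under the
  noncentral hypergeometric model, exact 95% CI by test inversion, Fisher's
  exact two-sided p.  Zero-margin tables report OR undefined with p = 1;
  infinite ORs are reported symbolically with the exact one-sided bound.
* Continuous features: Mann–Whitney AUC (midranks; positives = high grade,
  so AUC > 0.5 means higher values predict high grade — note some published
  presentations report |AUC − 0.5| folded above 0.5 instead), Noether's
  asymptotic test of AUC = 0.5 with the tie-corrected null variance of the
  rank statistic, and a Hanley–McNeil normal-approximation CI.  Exact
  numeric parity with any particular statistics package is not claimed.
* Multiplicity: Benjamini–Hochberg within each analysis family (10 semantic
  tests; 15 radiomic tests; all 150 semantic × radiomic association cells;
  each atypia screen separately).
* The atypia sub-analysis restricts to grade-I patients and relabels by
  presence of any atypical histologic feature, reusing both screens.

## Multivariate models

Patients are split temporally: after sorting by surgery date (ties broken
by patient id for order-invariance), the earliest ⌊0.75·n⌋ train — for
n = 175 this reproduces the 131/44 partition.  Radiomic feature selection
sees training rows only, enforced by an audited split plan that refuses
validation ids: columns are taken in decreasing variance order and dropped
when |Spearman ρ| with a kept column exceeds 0.90, then the top 15 survivors
by variance are retained.  The radiographic model reuses this panel rather
than re-selecting.

Six random forests (clinical, location, semantic, radiomic, radiographic =
location + semantic + radiomic, combined = all): 500 trees, with the
per-split predictor count tuned by an inner 5-fold stratified CV repeated 3
times over a small grid ({√p, 0.33p, 0.5p}); inner-CV forests use 60 trees
to keep tuning cheap, the winner is refit with 500.  Validation metrics:
rank AUC with Noether p against chance, sensitivity/specificity at the 0.5
class-probability threshold (probability exactly 0.5 counts as a positive
call), Hanley–McNeil CI.  Model pairs are compared by bootstrap (1,000
patient resamples; Δ = AUC_A − AUC_B; two-sided p by doubling the smaller
add-one-smoothed tail, so the resolution floor is ≈ 2/(B+1); single-class
resamples are skipped and counted).

## Synthetic phantom cohort

Defaults are the study conditions: 175 patients, 41% high-grade prevalence,
median age 57 (range 22–89), 62% female, 7% radiation-induced, five-level
location, surgery dates uniform over 2003–2014, atypia prevalence 33% among
grade-I patients.

Each phantom is a star-convex body on a 64³ grid at 1 mm spacing: a
spherical base radius modulated along each ray by a smooth random field of
relative amplitude `irregularity`.  Interior signal is
`base_intensity · (1 + heterogeneity · h)` with h a 3 mm
Gaussian-correlated unit-variance field — this produces the flat bright and
dark zones the size-zone features respond to — plus independent voxel
noise; an optional central hypointense core (relative intensity 0.35)
occupies `necrosis_fraction` of the volume, and hyperintense foci (relative
intensity 1.8, radius 2.5 mm) model hemorrhage.

Grade effects:

* The ten semantic flags are independent Bernoulli draws given grade, with
  high-grade probabilities derived from low-grade baselines by a logit
  shift matching the target odds ratios (heterogeneity 7.95, cystic 7.53,
  necrosis/hemorrhage 6.60, sinus invasion 2.91, mass effect 2.31, midline
  shift 1.39, bone invasion 1.00, multifocality 0.89, spiculation 0.47,
  hyperostosis 0.35).  Baselines are chosen for clinical plausibility (the
  rare-event features — cystic 1%, necrosis/hemorrhage 4% — are kept rare,
  which reproduces the wide exact CIs those features show).
* Tumor radius is grade-shifted by 1.4 mm at SD 2.0 mm, placing the
  volume-for-grade AUC near the reported 0.69; the irregularity gap
  (0.10 → 0.12 at SD 0.04) places the spherical-disproportion AUC near the
  reported 0.61.
* Heterogeneity amplitude carries the flag effect (+0.25) plus a direct
  grade shift (+0.08): the radiologist's flag binarizes a continuous trait,
  so the texture stream retains grade information complementary to the
  semantic stream — this is what lets the combined radiographic model beat
  either stream alone, the analysis's central claim.
* Necrotic cores / hemorrhagic foci appear only when the
  necrosis/hemorrhage flag is set; atypia shifts grade-I base intensity by
  −8 so the atypia screen has a recoverable intensity signal.

A null configuration (`EffectConfig.null()`) zeroes every contrast and is
used to probe FDR validity.

**Tabular simulator.** Replicate-level studies (200-cohort FDR probe,
20-cohort recovery and model-ordering studies) draw the same
grade-conditional patient parameters but map phantom traits to panel
features through an analytic linear response model with unit Gaussian
noise, instead of rendering volumes.  Rank-based statistics depend only on
the dependence structure, which the response model preserves; loadings were
set so the per-feature AUC ladder approximates the reported univariate
magnitudes.  Rendering ~10⁵ volumes for these studies would add runtime but
no information.  The paired-phantom monotonicity study and the single
demonstration cohort in `scripts/acceptance.py` use fully rendered volumes.

* Location is a categorical draw with a mild grade-conditional mix
  (skull-base tumors benign-leaning, convexity tumors high-grade-leaning;
  marginals ≈ 13/30/22/32/3%), so a location-only classifier performs above
  chance, as observed in the study population.

What the phantoms do **not** emulate: MRI physics (bias fields, Gibbs
ringing, coil profiles), anatomy (skull, brain parenchyma — the location
covariate has no imaging correlate), inter-feature correlation of the
semantic flags beyond grade, and scanner heterogeneity.  Passing tests therefore
demonstrate the correctness and statistical validity of the machinery under
the assumed generative structure, not clinical performance on real cohorts;
the reported patient-cohort AUCs/ORs are not reproducible without the data.

## Numerical and design notes

* Spherical disproportion in the paired-phantom monotonicity study is
  measured on the native-resolution mask: shape is a property of the
  segmentation, and on the 3 mm lattice the surface perturbation is
  under-resolved (marching-cubes mesh noise then dominates the contrast).
* The winsorization band example {0,0,0,0,100} is a fixed point (μ = 20,
  σ = 40 ⇒ band reaches 140); a genuine outlier needs to exceed μ + 3σ.
* A parity checkerboard has difference entropy exactly 0: each distance-1
  direction sees a single |i−j| value.  Width-2 stripes are the minimal
  DE > 0 pattern.
* Degenerate inputs: empty or single-voxel masks, single-class label
  vectors, zero-margin tables, all-tied scores, and constant feature
  columns all raise typed errors or return flagged results rather than
  NaNs.
* All randomness flows through `numpy.random.Generator` seeded from
  explicit arguments; the full pipeline is byte-reproducible under a fixed
  seed.
* Study sizes in the test suite and acceptance script (200 oracle volumes,
  200 null cohorts at n = 100, 20 recovery/ordering cohorts at n = 175,
  8 phantom pairs, one rendered demonstration cohort at n = 175) are the
  package's chosen desk-scale defaults; every study function takes explicit
  size arguments.
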