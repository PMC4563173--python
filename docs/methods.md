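# Methods

## Model and assumptions

The quantification rests on three imaging assumptions: (i) compact
(cortical) bone shows the highest Hounsfield values on CT while the
trabecular compartment in its cavity is markedly lower, so a single HU
feature separates the two; (ii) bone marrow resides in the trabecular
compartment; (iii) PET tracer uptake inside trabecular bone is bimodal —
high in hematopoietically active red marrow, low in fatty yellow marrow —
so a patient-specific SUV cut can split the two without a fixed,
scanner-dependent threshold.

### Compartment classifier

The voxel classifier is a two-class, one-dimensional Gaussian linear
discriminant with pooled within-class variance. For class k ∈ {C, T} with
mean μ_k and pooled variance σ² (unbiased, N−2 denominator), the
discriminant function is d_k(HV) = α_k + β_k·HV with β_k = μ_k/σ² and
α_k = −μ_k²/(2σ²); the linear score adds the log class prior,
L_k = d_k + log p_k. Posteriors are the softmax of the two scores, computed
as the logistic of L_C − L_T so that p_C + p_T = 1 exactly in floating
point and no exponential can overflow. The larger posterior decides the
voxel; an exact tie goes to cortical, which is the conservative direction —
it can only shrink, never inflate, the marrow-bearing compartment. With
equal priors the decision boundary is the midpoint of the class means,
which the test suite checks in closed form.

A training set is a list of HU values labelled C or T (in practice drawn
from labelled voxels; `sample_training_voxels` emulates that draw from
label masks). Training sets with fewer than two samples in either class, or
with zero pooled variance, are rejected: the boundary would be undefined.
The classifier is a scikit-learn estimator (`HounsfieldDiscriminant`), so
it composes with sklearn model selection; the rest of the pipeline is
function-shaped because nothing else is naturally fit/predict.

### Bone extraction

The classifier needs a bone mask to operate on. Voxels at or above
`hu_threshold` (default 100 HU — above soft tissue, below essentially all
mineralised bone) are kept and a morphological closing with an ellipsoidal
element of physical radius `closing_radius_mm` (default 3 mm, converted to
voxels per axis) recaptures trabecular interiors whose noisy HU dips below
the threshold. The mask is padded before closing so the operation behaves
identically at the volume border and stays extensive (output ⊇ threshold
mask). Isolated supra-threshold noise in soft tissue survives extraction
and is classified trabecular (its HU is far below cortical); that is
exactly what the islanding step removes.

### Islanding

Connected components of the trabecular mask with fewer than P voxels
(default P = 10, exposed as `--min-island`) under 26-neighbourhood
connectivity (faces, edges, corners; 6 and 18 also supported) are treated
as spurious. Removed voxels are re-assigned to cortical rather than
deleted, so cortical ∪ trabecular = bone remains a partition throughout.
The fast path uses `scipy.ndimage.label`; the test suite checks it against
a brute-force flood-fill oracle over random grids, all connectivities and
several P.

### Marrow threshold and volumetry

The red-marrow threshold is SUV_vert − k·SD_vert over the trabecular voxels
inside the vertebral (thoracic + lumbar) ROI, pooled across vertebrae, with
the sample (n−1) standard deviation; k defaults to 2.5 and is exposed as
`--k` for sensitivity analyses. Red marrow is strictly above the threshold;
a voxel exactly at it counts as yellow. A negative threshold (possible for
dispersed vertebral activity, since the formula subtracts 2.5 SDs) is legal
and classifies every analyzed voxel as red; it warns rather than errors.
Because the threshold is computed from the same SUV field it cuts, a purely
multiplicative SUV calibration error cancels; the test suite asserts this
equivariance.

Volumes are voxel counts times the voxel volume, reported in ml. RBV + YBV
equals the analyzed-region volume exactly at the voxel-count level (the ml
figures only add float rounding). The optional skull exclusion removes the
skull ROI from the analyzed region: the classifier labels the brain as
trabecular (it sits inside the cranial shell at soft-tissue HU), which is
harmless for proliferation tracers with negligible brain uptake but
contaminates glucose-tracer studies.

### Classifier evaluation

Repeated leave-one-out cross-validation: each of 50 repetitions draws 1000
labelled voxels without replacement, refits the discriminant on each n−1
subset and classifies the held-out sample; accuracy, sensitivity,
specificity and precision (cortical = positive class) are averaged over
repetitions. The per-fold refit uses exact mean/sum-of-squares downdates
(O(n) per repetition instead of O(n²)); the tests verify fold-for-fold
agreement with literal refitting. Folds whose remainder loses a class or
has zero pooled variance are skipped and counted.

## SUV conversion

Body-weight SUV: SUV = C/(D/W) with C the activity concentration in Bq/ml,
D the injected activity in Bq and W the body weight in g, tissue density
taken as 1 g/ml. Decay correction of D to scan time (factor 2^(−t/T½),
T½ = 109.77 min for ¹⁸F) is a flag, default on, referenced to injection
time — scanner conventions differ, so explicit is safer. DICOM SUV
metadata is read when present but always overridable. Masks live on the CT
grid; a PET volume with different geometry is resampled trilinearly onto
the CT grid before masking (nearest-neighbour is mandatory for labels).

## The synthetic phantom

The phantom emulates the assumptions above, not anatomy: each bone is a
geometric primitive (cylinder/box/ellipsoid) rasterized as a cortical shell
of stated physical thickness around a trabecular core; HU and SUV are drawn
per tissue from normal distributions; PET is Gaussian-blurred
(`blur_fwhm_mm`, default 4 mm) as a crude partial-volume surrogate. The
red/yellow split inside each bone is an axial slab chosen to hit the
requested per-bone red fraction to rasterization granularity — spatially
coherent, so blur and islanding see realistic interfaces rather than
salt-and-pepper marrow. Elements may not overlap (ground truth stays
unambiguous) and everything is deterministic given the seed.

The reference phantom (96×96×220 voxels at 2 mm, ~2.0 M voxels, generated
in well under a second) is a stylised whole body: seven vertebral
cylinders (15 mm radius, 2.5 mm shell), a pelvic box, two femoral shafts
and a skull ellipsoid. Default tissue parameters: HU means 1200/150/40
(SDs 50/50/20) for cortical/trabecular/soft tissue; SUV means 2.0/0.4/0.1
(SDs 0.2/0.1/0.05) for red/yellow/background. Per-bone red fractions
(vertebrae 1.0, pelvis 0.75, long bones and skull 0.25) reflect the adult
distribution — axial skeleton active, peripheral skeleton converted to
fatty marrow — and put the global red fraction near 0.60. Making the
vertebrae fully red is load-bearing: the vertebral statistics then describe
the red population alone, and mean − 2.5·SD lands between the red and
yellow SUV modes, which is the regime the threshold formula presumes.

What the phantom does not emulate: Poisson counting noise (Gaussian noise
is sufficient to exercise the statistics), CT beam hardening and partial
volume (CT is left unblurred, so compartment classification on the phantom
is essentially noise-free at the default 21-SD class separation),
anatomy-shaped bones, respiratory motion, or inter-patient variability.
Passing the recovery tests therefore shows the chain is correct and
well-conditioned under its own assumptions — not that those assumptions
hold on any particular scanner.

## Cohort statistics

OLS regressions (slope, intercept, R² = 1 − SS_res/SS_tot, two-sided slope
p from t with n−2 df), paired t-tests (two-sided; zero-variance differences
are flagged undefined rather than raised), one-way ANOVA (with exactly two
groups the equivalent pooled t is also reported, F = t²; the fully
degenerate all-constant case is defined as F = 0), and Devine ideal body
weight (M: 50 kg, F: 45.5 kg, + 0.906 kg/cm above 152.4 cm, floored at the
base). All tests are two-sided at α = 0.05 by convention; no
multiple-testing correction is applied. The implementations delegate to
scipy/statsmodels-grade routines and are cross-checked against independent
reference computations in the tests.

## Numerical and design choices

- Pooled-variance denominator N−2; vertebral SD denominator n−1.
- Posterior computation via the logistic of the score difference
  (overflow-safe; normalization exact).
- Tie rules: posterior tie → cortical; SUV exactly at threshold → yellow.
- Connectivity semantics follow `scipy.ndimage.generate_binary_structure`
  ranks 1/2/3 for 6/18/26.
- One master seed; phantom noise, training draws and LOOCV sampling use
  independently derived streams so stages are individually reproducible.
  Reports contain no timestamps and serialize deterministically.
- Problem sizes in the tests (reference phantom at 2 mm, 10-seed recovery
  sweeps, 50×1000 LOOCV) were chosen so the whole suite runs in well under
  a minute on one CPU while keeping every estimate's sampling error an
  order of magnitude below the tolerances being asserted.

## Known limitations

- Inputs must be co-registered; no registration is performed.
- No partial-volume correction; on real data the cortical/trabecular
  boundary blurs and both compartments are overestimated at their
  interface.
- The classifier is single-feature by design; pathologies that shift HU
  (sclerotic metastases, contrast agents) violate its assumptions.
- Vertebral/spine/skull ROIs are inputs, not computed.
- The phantom's simplifications above bound what green tests imply about
  clinical data.
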