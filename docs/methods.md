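# Methods

This note documents the models and procedures implemented in `hipshape`,
the synthetic study conditions, and the numerical conventions, in the order
the pipeline runs them.

## Synthetic hip surrogates

Real inputs to this kind of analysis are corresponded bone surfaces from CT
segmentation and group-wise registration. The package replaces them with
parametric surrogates whose geometry *realises the requested diagnostic
angles exactly by construction*, so the angle-measurement code can be
validated against analytic ground truth rather than against another
implementation.

All coordinates are millimetres in a right-handed frame: x subject-left →
right, y posterior → anterior, z inferior → superior (coronal plane x–z,
axial plane x–y). A hip is built in local (lateral, anterior, superior)
coordinates and mirrored for the left side, so left and right are separate
corresponded families ("mirrored parameterisation, stored unmirrored").

Each **pelvis** (1200 points) comprises:

* an acetabular cup: a two-layer spherical cap centred on the femoral head
  centre, radius = head radius + 2 mm, whose angular extent per azimuth is
  interpolated through four anchors — the anterior extent equals AASA, the
  posterior extent PASA, the superior extent 90° + CE, and the inferior
  extent is fixed at 55°. The rim ring therefore passes exactly through
  the anterior-sector, lateral-rim and posterior-sector landmark
  directions;
* a medial acetabular-roof landmark placed so the roof chord to the
  lateral rim makes exactly the AI angle with the transverse axis;
* two vertical wall-edge lines whose anterior→posterior chord makes
  exactly the AcAV angle with the sagittal axis. Version is carried by a
  separate landmark pair from the sector angles: AASA and PASA fix the
  *directions* of the sector rim points at the head centre, which
  over-determines the wall-edge chord if the same two points must also
  realise an independently drawn AcAV — with two pairs, all five cup
  angles are exact and independent for every realistic draw;
* pubic symphysis and an inferior pubic ramus leaving the midline at half
  the pubic-arch angle (the main sexually dimorphic feature);
* an iliac sheet carrying the anterior superior iliac spine (ASIS), an
  ischial plate, and an ischial-spine bump whose prominence grows as
  anteversion decreases (prominence = max(0, κ·(20.1° − AcAV)),
  κ = 0.35 mm/°), reproducing the prominent-ischial-spine appearance of
  retroverted acetabula without inventing an uncited quantitative law;
* two layers separated by the bone-thickness parameter wherever the
  structure is a plate or shell.

Each **femur** (800 points) comprises a head sphere sampled on a fixed
golden-angle direction set, a neck at the neck-shaft angle (default 127°)
and a shaft. Dysplastic heads are deformed by a smooth cam-like radial bump
on the anterosuperior-lateral aspect; the bump's support is disjoint from
the medial articular region used for sphere fitting, so the fitted head
centre is exact at any asphericity (as it is for the well-covered articular
surface in vivo). Subluxation shifts the whole hip complex laterally.

**Pose and noise.** Jitter is a subject-level rigid transform (whole
pelvis+femur assembly; up to ±5° per axis, ±10 mm) plus a per-femur
rotation about its own head centre (up to ±8°), mimicking patient
positioning and leg rotation — per-hemipelvis jitter would be anatomically
impossible. Isotropic Gaussian point noise (default sd 0.4 mm, the scale of
CT segmentation error) is applied last. Ground-truth angles are recorded
before jitter and noise; HASA ≡ AASA + PASA by construction.

**Cohort sampling.** The default configuration is the study condition: 75
subjects, 50 female. Dysplasia category per subject: 50% unilateral (random
side), 30% bilateral, 20% neither. Angle draws per hip share a
subject-level component (intraclass correlation `side_icc = 0.3` between
sides) with the side-level remainder drawn from the exact truncated
conditional by inverse-CDF sampling, so stratum bounds always hold:

| angle | split | distributions (mean, sd, degrees) |
|---|---|---|
| CE | dysplasia | dysplastic (14.5, 5.0) truncated < 25; normal (28, 3.5) truncated ≥ 25 |
| AI | dysplasia | dysplastic (18, 6); normal (8, 4) |
| AcAV | sex only | female (22.1, 5.0); male (16.2, 4.1) |
| AASA | sex + shift | female (47.7, 8.9); male (52.7, 8.4); −4 dysplastic / +4.9 normal |
| PASA | sex + shift | female (92.1, 8.2); male (86.0, 6.9); −3 dysplastic / +3.7 normal |

The CE/AI strata were chosen so the mixture marginals approximate the
published whole-cohort values (e.g. AI: 0.55·18 + 0.45·8 = 13.5); the
sector-angle shifts are prevalence-weighted to zero so the per-sex
marginals are preserved. AcAV is deliberately independent of dysplasia —
version is treated as a separate morphological axis. `side_icc = 0.3`
keeps substantial between-side correlation while remaining consistent with
the published detectability of the sex difference in anteversion at n = 74
(at markedly higher ICC the subject-level error stratum grows until that
effect is no longer reliably significant at α = 10⁻⁴). Sex effects beyond
the angles: pubic arch 95° (F) vs 72° (M) (sd 6°), cortical thickness
4.2 vs 5.6 mm (sd 0.5), global scale 1.00 vs 1.06 (sd 0.035), femur length
410 vs 450 mm (sd 15). The dysplasia continuum couples asphericity
(0.006/°) and lateral subluxation (0.15 mm/°) linearly to the CE deficit
below 25°.

Seeding: one master seed; per-subject seeds by a counter-based
`SeedSequence` split, so generation is order-independent and bitwise
reproducible. Infeasible draws (e.g. AASA + PASA ≥ 360°, collapsing cup
anchors) are resampled up to 100 times before a generation error.

**What the surrogates do not emulate** — and hence what passing tests do
not show about real data: cortical/trabecular anatomy, smooth continuous
bone surfaces (the surrogate is a union of parametric patches),
registration/correspondence error (correspondence is exact by
construction), scanner artefacts, and population covariance structure
beyond the effects listed above. In particular, classification AUCs on
surrogates say that the *pipeline* recovers planted effects, not that real
hips are this separable.

## Angle measurement

The manual radiographic measurements being emulated are defined on
standardised supine scans. Here every subject carries its own anatomical
frame built from the anterior-pelvic-plane landmarks: lateral axis along
the inter-head line (own head centre minus contralateral), superior axis
from the symphysis→ASIS direction orthogonalised to it, anterior axis from
the symphysis offset orthogonalised to both. This makes all six angles
exactly invariant to whole-subject rigid pose and global scale (the
pipeline still measures after alignment, where the convention also pins
the axial/coronal planes). Definitions, with signs chosen to be positive
for normal anatomy on either side:

* CE = ∠(superior axis, head centre → lateral rim) in the coronal plane;
* AI = ∠(transverse axis, medial roof → lateral rim) in the coronal plane;
* AcAV = ∠(sagittal axis, posterior → anterior wall edge) in the axial
  plane; smaller = more retroverted;
* AASA / PASA = ∠(ray to contralateral head centre, ray to anterior /
  posterior sector rim point) at the head centre in the axial plane;
  HASA = AASA + PASA (enforced at construction of every `AngleSet`);
* head centre = algebraic least-squares sphere fit (linear formulation,
  solving ‖p‖² = 2c·p + (r² − ‖c‖²)) on the articular head region.

The medial-roof landmark convention (a fixed chord from the lateral rim)
is a package choice; whether the original manual AI used the weight-bearing
sourcil or the full roof is not determinable from angle values alone.
Dysplasia is classified as CE strictly below 25°.

## Alignment

GPA of the combined left+right pelvis follows the geometric-morphometrics
convention: with scaling enabled, every shape is first normalised to the
*mean input centroid size* (keeping millimetre units meaningful for
displacement maps, and making "size removal" exact: every aligned pelvis
has the same centroid size), then rotations/translations are iterated
against the evolving mean, bootstrapped from the first subject. Each
half-step is exact coordinate descent on Σᵢ‖xᵢ − x̄‖², so the objective is
monotone non-increasing; convergence is a relative mean-shape change below
1e-7 (cap 100 iterations; the result is returned with a warning if the cap
is hit). The converged alignment is invariant, up to a global similarity,
to subject ordering.

The pelvis similarity is then applied to the femurs, head centres are
fitted, and femur pose correction iterates per side, separately for left
and right: superpose each femur onto the current mean with rotation and
translation only, translate it back so its head centre returns to the
initial (post-GPA) position, re-average, until the maximum per-point
displacement between iterations is below 1e-5 mm. Head-centre preservation
holds to numerical precision (< 1e-6 mm) and every pose transform has
scale exactly 1. Pose variability is thereby removed from the model while
the head position relative to the acetabulum — a diagnostic signal
(subluxation) — is retained; joint shape+pose modelling is out of scope.

## Point-distribution model

PCA uses the dual (small-matrix) trick via SVD of the centred data matrix;
eigenvalues follow the 1/(n−1) sample-covariance convention. Modes with
λ < 1e-10·λ₁ are dropped as rank noise, and each mode's sign is fixed by
making its largest-magnitude component positive, so stored models and
tests are reproducible despite eigenvector sign ambiguity. Three models
are built per cohort: combined (both pelves + both femurs), left-side and
right-side pelvis+femur. Mode perturbations x̄ + c√λₖ·pₖ and per-point
displacement maps (Euclidean displacement normalised by its maximum, with
a degenerate flag for identical shapes) support visualisation and the
localisation checks.

## Regression and evaluation

Discriminating directions are regressions of an outcome on the leading
mode scores: ridge-penalised logistic regression (default penalty 1e-4 on
the coefficients, intercept unpenalised — ~28 predictors on ~75 subjects
can separate perfectly, so some regularisation is required for a finite
optimum) or ordinary least squares for angles. The default mode count is
the smallest explaining 95% of variance. `shape_along_direction` solves
the fitted model for a requested probability or angle value and
reconstructs the shape at that point of the line through the mean, so
projecting the returned shape back through the model recovers the target
exactly.

Leave-one-out evaluation refits only the regression per fold; the mode
basis stays fixed from the full model (the basis is a property of the
cohort's variance structure, and the published mode counts are tied to the
full model). The stricter alternative that rebuilds the PCA basis per fold
is implemented (`loo_evaluate_rebuilt_basis`, config flag
`refit_basis_per_fold`) but off by default. Classification is scored by
AUC (rank statistic, ties counted half); angle prediction by the central
95% empirical interval of held-out residuals. Folds whose training labels
collapse to a single class are flagged and excluded with a warning. For
the sex model there is one observation per subject (combined model
scores); dysplasia models use one observation per hip on the matching
side's model.

## Cohort statistics

`summarize_angles` reports mean/sd (n−1) per angle, total and by sex,
combining sides. `mixed_anova` implements the split-plot decomposition for
the design: within-subject factor side, between-subject factors sex and
dysplasia, interactions side×sex and side×dysplasia, no between-factor
interaction. Between-subject effects are Type-II F tests in an additive
linear model on subject side-averages; within-subject effects are computed
on side differences — the intercept of a sum-coded additive model tests
the side main effect, Type-II F tests give the interactions. For a
balanced two-level within factor these are the classical exact F tests
(verified against an independent mixed-ANOVA implementation on balanced
single-factor designs, and calibrated to uniform null p-values by
simulation). Dysplasia enters the between stratum per subject — dysplastic
if either hip is, with "both" exposed as an alternative coding since
unilateral subjects make the choice genuinely ambiguous. Subjects missing
one side are excluded and counted. No installed package provides a
split-plot ANOVA with two between-subject factors, hence the in-package
implementation on explicit design matrices.

## Problem sizes and determinism

The shipped study conditions are deliberately compact: 1200 + 800 points
per side keeps a full 75-subject pipeline (generation → alignment → three
PDMs → all leave-one-out evaluations) at roughly ten seconds on one CPU
while leaving displacement maps smooth. Simulation-based checks use 200
replicate cohorts for the anteversion power analysis, 500 for the type-I
rate and 1000 for null-calibration KS tests, all on the shape-free
angle-sampling fast path. Every random quantity derives from a single
master seed; reports are byte-identical across runs at a fixed seed.

## Known limitations

* Surrogate realism is limited to the features listed above; AI and AcAV
  are carried by few points (one roof landmark, 18 wall points), so their
  shape-regression predictability is weaker than CE's — a property of the
  surrogate, not of the method.
* The GPA mean is a Fréchet-style arithmetic mean in the aligned frame,
  appropriate for the small rotations produced by pose jitter; very large
  pose differences would need a proper rotation averaging.
* The split-plot F tests assume homoscedastic Gaussian errors; per-sex
  variance differences in the generator are mild but make the dysplasia
  type-I rate only approximately nominal in unbalanced designs.
* The ridge penalty makes logistic coefficients (and hence discriminating
  directions) shrink slightly toward zero; direction *orientation*, the
  quantity that is visualised and tested, is insensitive to this at the
  default penalty.
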