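# Methods

This note documents the models, numerical choices and limitations of
`bctrisk` the way a maintainer would want them recorded. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate convention

Everything image-related uses one frame: axis 0 runs left→right (x),
axis 1 posterior→anterior (y), axis 2 inferior→superior (z); the
"frontal plane" is x–z. World coordinates are `origin + index*spacing`
(mm), sampled at voxel centers. Thick sections ("slabs") and the
femoral-neck cylinder use half-open membership along their axis
(`-t/2 <= d < t/2`), so a 10 mm slab on a 1 mm grid samples exactly ten
voxel layers and segment lengths add exactly; a closed interval would
double-count both boundary layers.

## Trait extraction

**Resampling.** Volumes are resampled to isotropic 1 mm voxels by
trilinear interpolation (`scipy.ndimage.map_coordinates`, order 1,
nearest-edge padding); output shape is `round(extent/target)` per axis.

**Femoral head localization.** Heads are found as the two dominant
maxima of the Euclidean distance transform of the bone mask (density ≥
0.2 g/cm³ or HU ≥ 200), each refined to the centroid of the surrounding
thresholded ball; the second search suppresses a 2.2-radius
neighborhood of the first. The EDT value at the center estimates the
head radius (used to place the upper muscle section). With hints, each
hint is refined to the local bone centroid. Ordering is by x (left
first), so mirror-image volumes give mirror-image results.

**Sections.** The gluteus maximus section is the 10-mm transverse slab
rotated about the anterior–posterior axis so its mid-plane contains both
head centers; the rotation angle is `atan(Δz/Δx)` of the centers. The
medius/minimus section is parallel, displaced superiorly along the slab
normal by `offset × head diameter`. The displacement default is 1.5
diameters; 1.0 is an equally citable convention for this measurement,
so the offset is a config knob (`medius_offset_diameters`) rather than
a hard-coded constant, and we do not guess which was intended.

**Muscle segmentation.** The shipped segmenter is a deliberate
geometric stand-in for a trained network: voxels inside the section
whose HU falls in the skeletal-muscle window (default −30..100 HU at
the assumed 50 keV effective energy), reduced to the connected
component containing an atlas-prior seed placed relative to the
detected head center (lateral component signed away from the
mid-sagittal plane). This presumes muscle separated from other
in-window tissue by fat planes and moderate fat infiltration (voxels
with fat fraction ≳0.5 leave the window); both assumptions hold on the
phantoms by construction and approximately in gluteal anatomy. An
optional median prefilter (`segmentation_median_size`, default off)
exists for noise regimes that overlap the window edges; it biases the
boundary by ~half a voxel, which is why it is off by default.
Cross-sectional area = component volume / slab thickness.

**Posterior fat thickness.** From each head center the posterior ray is
walked to the first air voxel (HU < −400); the thickness is the
contiguous run of fat voxels (−250..−60 HU) immediately inside that
boundary, i.e. between the muscle–fat and fat–skin interfaces. Trait =
lower of the two sides. A ray that exits the grid before reaching air
raises, which `measure_all_traits` converts to a missing-trait flag.

**Intramuscular fat.** Per-voxel fat fraction
`f = (Hm − H′)/(Hm − Hf)` clamped to [0,1], with
`H′ = H − contrast_offset` when a contrast flag is set; trait = 100 ×
mean over the medius+minimus mask, averaged over sides. Defaults
`Hm = +60`, `Hf = −120` HU; the true pure-tissue constants at 50 keV
are scanner-calibration specific, so both are config. The fraction is
affine in HU between the endpoints, and the mask mean is invariant to
voxel order. The intravenous-contrast correction is reduced to this
single configurable offset.

**Bone compartments.** Cortical = ROI voxels with density ≥ 1.0 g/cm³
*or* within 2 mm of the periosteal surface (EDT of the femur mask; ties
at exactly 2 mm are cortical); trabecular = remainder; the trait is the
ratio of compartment mean densities. The proximal-femur ROI is bounded
by axial planes supplied by the caller (phantoms pass head-center
offsets of −45..−5 mm). Femoral neck volume counts bone voxels inside a
caller-supplied cylinder (the same region used for the neck BMD
T-score); the left side is used, nominally. Left/right combination
rules overall: minimum for muscle area and fat thickness, mean for
intramuscular fat.

**Missing traits.** `measure_all_traits` converts constituent errors to
per-trait missing flags instead of aborting; downstream,
`impute_missing_traits` fills flagged values from sex- and age-based
regressions fitted on the random sample, keeping the imputed flag.

## Phantoms

The phantom voxelizes analytic solids: two shelled spheres (heads, 24 mm
radius, 3 mm cortical shell at 1.2 g/cm³ over a 0.3 g/cm³ core), two
shelled neck cylinders (13 mm × 35 mm, capped ends so every periosteal
surface carries cortical density), three ellipsoidal gluteal muscles per
side with a 2 mm fascial fat sheath, a posterior subcutaneous fat slab
whose contiguous thickness along the posterior ray equals the spec
value exactly, and air behind the skin. Bone HU = 1000 × density
(configurable affine); muscle HU mixes the pure endpoints by the spec
fat fraction; the background compartment sits at 120 HU, outside the
muscle window, standing in for the semantic discrimination a learned
segmenter provides. Gaussian HU noise and a contrast offset are
optional.

Ground truth is closed form and independent of voxelization: hip width
from the spec centers; fat thickness from the slab construction; maximus
area as the slab average `πab(1 − (u1²+u1u2+u2²)/(3c²))`; medius/minimus
fat as the volume-weighted fat fraction; neck volume `πr²L`; ratio =
trabecular/cortical density (exact whenever cortical density ≥ the
1.0 g/cm³ rule threshold, as in all defaults). Recovery tolerances
asserted on the noise-free default phantom: hip width and fat thickness
within one voxel, areas/volumes within 3%, fat fraction within 0.5
points, ratio within 2%.

What the phantom does **not** emulate: partial-volume blur, beam
hardening, reconstruction kernels, metal artifacts, anatomic shape
variation, or muscle boundaries defined by anything subtler than fat
planes. Passing phantom tests therefore demonstrates correctness of the
measurement geometry and arithmetic, not robustness to real scans.

## Cohort simulation

Per sex, ages are drawn once from a common Beta(1.2, 2.5) shape mapped
to 65–95 yr and coded at 90 (mirroring identity-protection coding), so
the sexes are age-matched in distribution. Traits follow a Gaussian
copula: standardized strength loads on standardized age with the
configured R² (sign negative), and each trait solves a 2×2 system so
its correlations with age and strength hit the per-sex R² targets
(defaults: the published per-sex univariate values). Infeasible target
combinations (non-positive residual variance) raise. Marginals are
truncated to physiologic ranges; strength and T-score marginals follow
published population characteristics (3460±860 N women, 4570±1120 N
men; hip T −1.5±1.1 / −0.7±1.2, which reproduce the published 18%/6.2%
osteoporosis rates under normality), while the six trait marginals are
realistic defaults chosen once (they are not published). The male
hip-width mean sits close to the female mean so the pooled
hip-width–strength R² stays near its weak per-sex values, whereas the
large FN-volume sex gap correctly makes its pooled correlation with
strength much stronger than within either sex — matching the published
pooled-versus-per-sex R² pattern.

Outcomes are logistic in the eight covariates with per-SD coefficients
(defaults: strength −0.8, FN volume +0.45, intramuscular fat +0.4,
ratio −0.35, muscle area −0.35, age +0.3, hip width +0.25, fat
thickness −0.2; signs fixed by the risk directions, magnitudes are
simulation choices). The per-sex intercept is solved by root finding so
the population 5-yr rate equals the configured base rate (5.8% women,
3.4% men). Late fractures in (5,10] yr occur at 0.6× the 5-yr
probability; non-fracture dropouts (15%) get follow-up < 5 yr; 8% are
treated ≥180 d. FRAX is a monotone map of the true logit plus clinical
noise, with its additive constant solved so the per-sex 3%-positive
rate hits the configured targets (34.6% women, 20.0% men). The
case-cohort sample keeps all fracture cases plus a random subcohort of
equal size per sex, giving ≈1:1 fracture:control ratios; site labels
0–11 and 12–27 define the development/validation split.

The simulated functional form is the same logistic family the risk
model fits — by design, enabling parameter-recovery tests; the
simulation therefore cannot detect misspecification bias.

## Risk model and calibration

Fits use `statsmodels.Logit` (Newton, tol 1e-10; convex, hence
deterministic); perfect separation or non-convergence raises. Selection
criteria use Wald p-values at exactly 1e-4; R² screening uses the
squared Pearson correlation in the random sample (pooled sexes, as the
published pooled columns are single numbers). Calibration solves the
per-sex offset by bisection on [−50, 50] logit units to interval 1e-8,
then takes the bracket endpoint with the smaller rate error; the match
is within 1/n up to ties in the empirical score distribution. Degenerate
targets (0 or 1) pin the offset at the bracket bound with a warning.
Scores are kept continuous for all statistics and rounded half-up to
integers only for display; ties at a threshold are positive in the
printed inequality direction (≤ −2.5 for T-scores, ≥ otherwise).

Z-score references are per-sex OLS age regressions fitted on
random-sample records, excluding age-coded-90 records and records with
any imputed trait; Z = (value − predicted)/residual SE, reported signed,
with a per-trait adverse-direction flag for display. References with
near-zero residual SE are flagged degenerate and refuse to produce Z.
References are pooled across race/ethnicity.

## Evaluation statistics

AUC uses the tie-corrected Mann–Whitney formulation via placement
values; its CI and the paired comparison use DeLong's covariance of
placements, with two-sided normal p. The implementation is hand-written
(no installed package exposes the paired test) and is checked three
independent ways in the suite: exhaustive pair enumeration at n ≤ 50, a
10,000-rep stratified bootstrap of the variance, and the pROC reference
implementation through Rscript. Identical score vectors short-circuit
to difference 0, p 1. Sensitivity/specificity CIs are the binomial
normal approximation `p ± 1.96√(p(1−p)/n)` truncated to [0,1]; the DOR
CI is a log-odds Wald interval with Haldane–Anscombe 0.5 correction
when a cell is zero (no method is printed for the published DOR CIs, so
this is a package choice). An empty class yields NaN metrics with an
`undefined` flag, never a silent zero.

Outcome recoding (horizon 2 or 5 yr): treated ≥180 d excluded; fracture
beyond the horizon recoded to control if in the random sample, excluded
otherwise; non-fracture with follow-up short of the horizon dropped.
The ledger counts are asserted to partition the input.

## Effectiveness arithmetic

`PPV = S·PopFR/TestPR` and `preventable/1000 = S·PopFR·E·1000`, with
E = 0.53 fixed (no uncertainty propagation) and the stated assumption
that all positive-testing patients are treated. PopFR comes from
untreated random-sample patients excluding dropouts; TestPR from the
whole random sample at baseline (dropouts included — future status is
unknown at testing time); S from the validation set. Display rounding
is half-up (1 decimal for percentages, integer for counts); internal
arithmetic is unrounded, and the identity `PPV·TestPR = S·PopFR` holds
pre-rounding on every report row. Risk classes compare 1-decimal
rounded PPVs against the FRAX 3.0%/4.5% reference PPVs of the same
stratum, ties classifying upward. In the worked-example deck, rows
whose printed outputs used unrounded internal sensitivities differ from
printed-input recomputation by one display unit; the deck flags these
(`exact=False`) and they are reported, not "fixed".

## Problem sizes

Chosen as the package's own defaults: the standard phantom is a
200×150×190 grid at 1 mm. Cohort simulations default to 5000 women /
2200 men source populations; the parameter-recovery check uses 20 seeds
at 24000/10500 source per sex, giving ≈2700 patients per
development/validation split; null-uniformity checks use 500 seeds of
n = 120; the bootstrap oracle uses 10,000 replicates at n = 30.

## Known limitations

* The muscle segmenter is a threshold stand-in; real scans need a
  semantic segmenter (the measurement interfaces accept any mask).
* Finite-element femoral strength and FRAX internals are inputs, not
  computed; the density↔HU map is a configurable affine, not a scanner
  calibration.
* The simulated cohort shares the fitted model's functional form and
  carries no covariate measurement error.
* Survival analysis is deliberately absent: outcomes are binary at a
  2- or 5-yr horizon, with dropouts handled by the recoding rules.
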