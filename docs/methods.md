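# Methods

## Scope and data model

The package quantifies breast composition from pendant-breast spiral CT:
per-voxel tissue classification, quadrant partition, the three composition
features (BTV, MGV, PBD), age-group statistics, and two single-regressor
age models. All grids are isotropic Hounsfield-unit volumes with a fixed
axis convention: axis 0 runs from the chest wall (slice 0) toward the
nipple, so the "most posterior" slice of a prone acquisition is the
highest-index tissue-bearing slice; axis 1 is image rows (smaller row =
upper breast), axis 2 is image columns (patient-right to patient-left by
default). NIfTI is the on-disk format; DICOM ingestion is out of scope.

## Segmentation

1. **Body mask.** `HU > air_threshold` (default −500 HU, midway between
   air and fat and many noise SDs from both), reduced to the largest
   26-connected component, interior holes filled.
2. **Skin.** Body voxels within `skin_thickness` (default 1.5 mm) of
   non-body space, via a Euclidean distance transform with the voxel size
   as sampling — equivalent to subtracting the erosion of the body by a
   Euclidean ball, and resolution independent. The nipple, a surface
   structure, falls entirely in this class. Image borders are treated as
   body continuation (the chest continues beyond the field of view), so
   the chest-wall cut face grows no spurious skin.
3. **Chest structures**, gated to the first `chest_extent` (default 0.15)
   fraction of slices: ribs are voxels ≥ `rib_threshold` (150 HU, far
   above soft tissue, far below cortical bone); pectoralis muscle is the
   union of soft-tissue-dense components (HU ≥ 0) touching slice 0;
   skin-fold flaps are the tissue components left disconnected from the
   main breast after muscle and rib removal. The gate exists because no
   anatomical prior distinguishes a fold from breast tissue far from the
   chest wall.
4. **Gland vs adipose — adaptive region growing.** The interior HU
   histogram is split by Otsu's threshold; the fat and gland reference
   means are the medians of the two sides (robust to partial-volume
   tails). If the two medians are closer than `min_class_separation`
   (40 HU; fat and fibroglandular tissue are ~140 HU apart, so anything
   below this indicates a single population) the interior is declared
   gland-free with a warning rather than an error. Otherwise every
   interior voxel gets a glandular fraction
   `g = clamp((HU − μ_fat)/(μ_gland − μ_fat), 0, 1)`; voxels with
   `g ≥ seed_fraction` (0.8) are seeds; each sweep accepts all
   26-connected neighbours with `g ≥ max(floor_fraction, α·(1 − D_t))`
   where `D_t` is the mean glandular fraction of the region grown so far —
   the running average breast density. `D_t` is recomputed per sweep;
   growth stops when a sweep adds nothing and `D_t` moved less than
   `convergence_tol` (1e-4), or after `max_iterations` (50). The procedure
   is deterministic. On a clean two-tissue breast the region mean stays
   high, the adaptive term stays below the floor, and the result reduces
   to thresholding at `g ≥ floor_fraction` (0.25) restricted to seeded
   components — the test suite checks exactly this, plus equality with a
   set-based brute-force sweep implementation on small grids.

   Parameter defaults (seed 0.8, floor 0.25, α 0.5) were chosen so that
   seeds are unambiguous gland, the floor sits below the 0.5 partial-volume
   midpoint (slightly generous gland, compensating the erosion of thin
   structures), and the adaptive term only bites when the grown region's
   density collapses — i.e. when growth is leaking into fat.

## Quadrants

The nipple is the rounded centre of mass of skin voxels in the last
skin-bearing slice. The row plane and column plane through it partition
adipose∪gland voxels into UOQ/UIQ/LOQ/LIQ. Tie rules are fixed: voxels on
the row plane are "upper", on the column plane "outer"; each affects at
most a one-voxel sheet. The outer (lateral) side at low column index is
`(laterality == right) == (columns run right-to-left)`; both inputs are
explicit because image orientation is a per-scanner convention. No central
region is modelled (the four-quadrant scheme has none).

## Composition features

BTV and MGV are voxel counts × voxel volume (cm³); whole-breast values
equal the sum over quadrants exactly because the partition covers the
tissue voxels. PBD is reported two ways: `pbd_hu` (primary) is 100 × the
mean glandular fraction over the region's tissue voxels, which respects
partial volume; `pbd_volumetric` is 100·MGV/BTV, the binary ratio. They
coincide in the binary-image limit (tested). HU references for `pbd_hu`
default to the mean HU of 2-voxel-eroded adipose and gland cores, which
strips partial-volume shells without requiring scanner calibration; fixed
values can be supplied. Known limitation: under HU noise the clamping at
0 and 1 biases `pbd_hu` upward (≈ +σ·φ(0)/(μ_gland−μ_fat) per pure-fat
voxel, a few points at σ = 15 HU); the noiseless recovery tests are
therefore the reference for accuracy claims, and fixed references plus
unclamped averaging would be the remedy for noisy production data.

## Cohort statistics and regression

The analysis unit is the breast examination, grouped into seven five-year
bins (40–74 years); records outside the range are excluded with a logged
count, never silently. Summaries use sample SDs (n−1). Group differences
use the pooled-variance Student t-test (two-sided; Welch available behind
a flag), computable from raw values or from (mean, SD, n) summaries —
both paths agree to 1e-10 by test.

Age models: logarithmic `y = a·ln(age) + b` for BTV, multiplicative
inverse `y = a/age + b` for MGV and PBD, solved in closed form from the
weighted normal equations. Weights are frequency (count) weights: an
integer-weighted fit is identical — standard errors included — to the fit
on the row-replicated data (`df = Σw − 2`). Coefficient p-values use the
t distribution with that df. `RSE = sqrt(SSE/(n − 2))` with one regressor.
When only a demographics table is available, the within/between identity
`SSE = Σ_g [(n_g−1)·SD_g² + n_g·(mean_g − ŷ(age_g))²]` reconstructs the
raw-data SSE exactly if ages are constant within groups; with ±1–2 year
in-group SDs it is an approximation, evaluated at the group mean age.
Whether the published models were fitted to individuals or to the seven
group means is ambiguous in the source description; both modes exist here,
and reproduction runs use the count-weighted group-mean fit, documented as
an approximation of the individual-level fit (it lands within ~5% on the
slopes and ~0.5% on the reconstructed RSEs).

## Phantom generator

The phantom emulates the acquisition geometry, not the physics: no photon
transport, detector model, or reconstruction artifacts. Geometry, at
0.3 mm isotropic voxels on a 192×200×200 grid by default: a pectoral slab
(muscle, 16 slices) at the chest end; a half-ellipsoid breast
(45×24×24 mm semiaxes — a scaled-down pendant breast that fits a ~6 cm
field; real breasts are larger, the morphology and contrast are what
matter for testing) attached to the slab; a 1.5 mm skin layer defined as
the air-adjacent surface of *all* tissue (breast, chest wall, fold —
anatomically, skin covers the thoracic wall too) by the same EDT rule the
segmenter uses; a 4 mm spherical nipple cap at the breast tip, guaranteeing
skin in the last tissue-bearing slice; two rib cylinders inside the slab
(700 HU); and an optional skin-fold flap attached to the chest wall beside
the breast with a ≥2 mm air gap.

Every primitive carries an anti-aliased sub-voxel inside-fraction
(analytic inside/outside plus 4³ deterministic sub-voxel sampling in a
surface band), so boundary voxels get partial-volume HU by linear mixing
and the per-voxel true glandular fraction — hence the true PBD — is well
defined. Voxelized volumes converge to the analytic ellipsoid volumes as
the voxel shrinks (tested: a threefold refinement cuts the error by far
more than half).

Glandular tissue is a union of ellipsoidal inclusions. The quadrant
weights (defaulting to the published quadrant MGV shares 34/21/26/18,
normalized) allocate the gland volume budget per quadrant
deterministically; component centres are rejection-sampled inside the
quadrant's interior, clear of the dividing planes and of other components,
and all semiaxes are rescaled together until the true gland volume lands
within 5% of the target. HU reference means are literature-typical values
(fat −100, gland +40, skin +30, muscle +45, rib +700, air −1000 HU) —
no calibration for the source scanner is published, so these are package
defaults, configurable per spec. HU noise defaults to 15 HU, a realistic
magnitude for photon-counting breast CT at this voxel size; recovery
criteria in the tests use noiseless phantoms so that they measure
algorithmic fidelity rather than noise response.

What passing phantom tests does *not* show: robustness to reconstruction
artifacts, bias fields, anatomical variability (lesions, implants,
heterogeneous skin thickness) or positioning error — real scans exercise
all of these.

The cohort simulator draws integer ages (uniform per bin when bin counts
are pinned, uniform over 40–74 otherwise), evaluates the configured mean
curves — defaulting to the published models BTV = 290 ln(age) − 554,
MGV = 4885/age − 26, PBD = 1237/age − 8.4 — adds independent Gaussian
noise with the published residual standard errors (386, 67 cm³, 13%) as
default SDs, and truncates to physical ranges (volumes ≥ 0, MGV ≤ BTV,
PBD ∈ [0, 100]). Truncation tilts the conditional means where the curves
approach zero (chiefly MGV at older ages), which biases refitted slopes
by a fraction of their single-fit standard error; recovery tests therefore
compare against the spread of replicate estimates rather than the standard
error of their mean.

## Numerical choices and degenerate inputs

* All randomness flows from a single integer seed per spec
  (`numpy.random.default_rng`); equal seeds give bit-identical phantoms.
* Degenerate inputs fail fast with explicit errors: all-air volumes, skin
  thickness consuming the interior, constant-age regression designs,
  gland targets beyond the interior capacity, grids too small for the
  requested geometry.
* A unimodal interior histogram (no gland) is a warning state with an
  empty gland mask, not an error — fully fatty breasts are legitimate.
* Zero-variance t-tests: equal means → (t=0, p=1); unequal → (±inf, 0).
* Shares of a zero denominator (e.g. MGV shares of a gland-free breast)
  are reported missing, and excluded from share averaging with a logged
  count.

## Problem sizes used in the checks

Reproduction of the published regression quantities runs on the packaged
seven-row demographics table (n = 1033 grouped examinations). Image
recovery runs on one full-geometry noiseless phantom (192×200×200 voxels)
plus a 128×120×120 phantom shared across the unit tests; coefficient
recovery simulates 200 cohorts of n = 1033. These sizes keep the whole
suite in the tens of seconds on one CPU while matching the study's tabular
dimensions exactly; only the image grids are scaled-down stand-ins.
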