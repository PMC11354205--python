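# Methods

This note documents the models, defaults and numerical choices behind
`qctscreen`, and what the synthetic experiments do and do not demonstrate.

## Measurement model

Trabecular vBMD is measured per vertebra as
`vBMD = f(HU_rep)`, where `f` is a phantom-calibrated conversion equation and
`HU_rep` is the trimmed-median HU of an elliptic-cylinder ROI inside the
vertebral body. The combined L1–2 value is the unweighted mean of the
available per-vertebra values (a single-vertebra result is flagged, not
silently promoted).

### ROI construction

Per vertebra, on the mid-slice of the central-third slab of its axial extent:

| parameter | default | rationale |
|---|---|---|
| erosion radius | 3 mm | exceeds typical cortical shell thickness (~2 mm), so the eroded region — and hence the ROI — cannot touch the shell; specified in mm and converted to per-axis voxel radii (rounded half-up) so behaviour is spacing-invariant |
| anterior fraction kept | 2/3 | the basivertebral vein enters the posterior-central body; excluding the posterior third of the eroded cross-section keeps the ROI clear of the channel |
| ellipse scale | 0.8 | the second-moment (equivalent) ellipse of the eroded anterior region, scaled down for margin; shrunk further by factors of 0.95 until every ellipse voxel lies inside the region |
| slab | central third of the body height | samples the mid-body trabecular compartment, away from the endplates |
| minimum ROI size | 50 voxels | below this the trimmed median is too unstable to report |

Voxel indices are 0-based; slab and extent ranges are half-open; mm positions
come from voxel centers (index + 0.5) × spacing and the NIfTI affine.

### Representative HU

The ROI's HU values are sorted and `floor(trim/2 · n)` values are removed
from **each** tail (default trim 1 %); the median of the remainder is
`HU_rep`. The trim guards against high-HU degenerative calcification inside
the ROI; symmetric trimming also sheds low-HU vein/partial-volume voxels and
leaves the median unchanged for symmetric noise. A one-tailed (upper) mode is
available by configuration. `floor` is used for the per-tail count; with the
median as the final statistic the floor/round/ceil choice is immaterial for
any realistic ROI size.

## Calibration

Per acquisition protocol (vendor / kVp / kernel class), a three-insert
phantom scan yields per-insert-per-slice trimmed-median HU samples — the same
operator as the patient measurement, so one representative-HU definition
serves both. Six regression families are fitted by least squares (density as
a function of HU): linear, quadratic, power (`a·HU^b`), logarithmic
(`a + b·ln HU`), exponential (`a·e^{b·HU}`), and Theil–Sen robust linear
(median of pairwise slopes). Log-linearizable families are initialized from
the linearized least-squares fit and refined with `scipy.optimize.curve_fit`.

Fitting per slice rather than on three aggregate means keeps the design
over-determined, so the in-sample RMSE is a meaningful noise measure and the
quadratic cannot trivially interpolate. The lowest-RMSE candidate wins;
candidates that are not monotone over the HU domain (observed range ± 50 HU)
are flagged and lose ties, since a BMD conversion must be order-preserving.
If even the best RMSE **exceeds** 5.0 mg/cc (strictly — exactly 5.0 passes),
a recalibration signal is returned instead of a model. Models are keyed by
protocol; applying a model to a volume with a different protocol key is an
error, never a silent fallback. RMSE is computed in-sample; with 60 rows and
at most 3 parameters the optimism is negligible at the 5.0 mg/cc scale.

## Segmentation reference implementation

The rule-based path thresholds at 250 HU (selecting the cortical shell),
applies a morphological closing with an **in-plane** disk of radius 2 voxels,
fills holes per axial slice, and keeps 3-D 26-connected components of at
least 200 voxels. Closing and filling are deliberately in-plane: an in-plane
closing seals small gaps in the cortical ring (noise, thin-shell dropouts)
but cannot bridge adjacent vertebrae across the 4 mm disc space, which a 3-D
ball of the same radius would do at 1 mm spacing. Instance ordering is by
centroid along the superior axis (most superior = L1), with ties broken by
size then lexicographic centroid so labeling never depends on component
discovery order; components whose axial extents overlap by more than half of
the shorter extent raise an ambiguous-ordering error rather than guessing.

The contract assumes the first (most superior) lumbar object is L1; scans
where that assumption fails (transitional anatomy, cropped fields of view
that clip L1) are out of scope for the reference implementation and are the
reason the cohort model carries a missing-L1 exclusion flag.

## Synthetic data: what it emulates, and what it does not

The generator paints, on a 1 mm isotropic grid by default (orientation stored
explicitly as per-axis anatomical codes, never assumed):

* **Vertebral bodies** — elliptic cylinders (AP/RL aspect 0.85) stacked along
  the superior axis with 4 mm disc gaps; a cortical shell (default 2 mm,
  500 HU) enclosing a trabecular core painted at
  `HU = slope·density + intercept` (defaults 1, 0 — the affine family the
  calibration must recover, making recovery tests exact in expectation);
  a basivertebral-vein channel (2 mm radius cylinder at 30 HU) entering the
  posterior-central body at mid-height, running from the inner shell boundary
  to 22 % of the AP diameter so the whole channel stays inside the posterior
  third; optional calcification spheres (1.5 mm, 800 HU) inside the core;
  soft tissue at 40 HU and air at −1000 HU; optional additive Gaussian noise.
  Every voxel belongs to exactly one class, and the class map ships with the
  ground truth so tests can intersect ROIs with the true shell/vein/core.
* **Phantom** — soft-tissue-equivalent body (35 HU) with three 9 mm-radius
  cylindrical inserts at the configured densities.
* **Cohorts** — ages uniform over 5-year bins; sex Bernoulli(0.5); true vBMD
  drawn as a sex-specific median-age curve plus Gaussian spread (σ =
  20 mg/cm³). The default curves are piecewise-linear anchors at bin
  midpoints chosen to reproduce the canonical screening-cohort pattern —
  female plateau near 165 mg/cm³ through the forties, steep post-menopausal
  decline crossing below the male curve after 50; male peak near 151 with a
  gradual decline — with a running minimum applied after age 50 so the median
  curve is monotone non-increasing there. Exclusion flags are assigned to
  exactly the requested numbers of participants.

Not emulated: posterior elements (pedicles, processes), ribs, scanner physics
(beam hardening, scatter, kernel texture), inter-vendor HU bias (exposed as
slope/intercept per protocol key instead of hard-coded physics), spatially
correlated noise, degenerative deformity, and fractures. Passing tests
therefore demonstrate that the *measurement chain* is correct given a
contract-conforming mask and an affine HU–density relationship with
independent noise; they do not validate segmentation of real anatomy or
robustness to reconstruction artifacts — those require a trained segmenter
and scanner data behind the same interfaces.

The bundled standard population (`synthetic_standard_population.csv`) is a
smooth synthetic age pyramid for an aging population, **not** a census table;
reports always carry the provenance label of whatever standard they used, and
real analyses should supply their own weights CSV.

## Epidemiology conventions

* ACR QCT cut-offs: < 80 osteoporosis, 80–120 osteopenia (both boundaries
  inclusive in osteopenia, matching the printed intervals), > 120 normal.
* Age bins: 5-year bins from 20, open-ended 85+.
* Quartiles: linear interpolation ("type 7"), recorded in report metadata.
* Display rounding: one decimal, half-up; internal values stay unrounded.
* A record with both exclusion flags is counted once, under missing-L1
  (flowchart order).
* Prevalence over an empty denominator is reported as undefined, never 0 %.
* Direct standardization renormalizes weights over the bins the cohort
  actually covers (with a warning), so either a 50+-only or an all-adult
  weight table can be supplied.

## Problem sizes

The default demo pipeline images 40 participants (96×96 in-plane grids, two
vertebrae each, σ = 10 HU), calibrates on a 20-slice phantom at σ = 5 HU, and
completes in a few seconds; the test suite's randomized-vertebra safety sweep
uses 50 single-vertebra volumes. These sizes were chosen as the smallest at
which the statistical claims under test (standard errors of trimmed medians
and regression RMSEs) are comfortably resolved.

## Known limitations

* The rule-based segmenter assumes a closed cortical ring per slice; severe
  cortical thinning or lytic defects would leak the per-slice fill.
* The ROI is a straight elliptic cylinder; it does not follow endplate tilt.
* No confidence intervals on prevalence estimates.
* Cross-scanner harmonization beyond per-protocol calibration models, and
  phantomless (internal) calibration, are out of scope.
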