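# Methods

## The quality-assurance problem

A multicenter SABR trial asks every participating radiation-oncology
department to treat the same kinds of lesions with the same protocol.
Before enrollment, a dummy run distributes a small set of benchmark
cases; each center contours the targets, prescribes a dose, and builds a
plan. The QA office then needs two quantitative answers: *how much do
the centers disagree about where the tumor is* (phase 1), and *do their
plans satisfy the protocol's dose constraints* (phase 2). `sabrqa`
implements both analyses on an internal voxel representation, with a
synthetic-phantom generator standing in for the clinical DICOM data that
such exercises can never release.

## Geometry model

All structures live on one axis-aligned voxel lattice per case
(`VoxelGrid`: shape, spacing in mm, origin in mm; index (0,0,0) at the
origin). Structures are binary occupancy arrays; doses are non-negative
scalar fields on the same lattice. Submissions arriving on different
lattices are expected to be resampled at ingest — nearest-neighbor for
masks, trilinear for doses (`read_rtstruct` / `read_rtdose`) — so every
metric is evaluated on a single grid. Volumes are reported in cc, doses
in Gy, percentages on the 0–100 scale.

## Phase 1: contour agreement

* **Summed volumes.** Cases may contain several lesions; agreement is
  assessed on the union ("sum") of each center's GTVs and PTVs against
  the union of the reference panel's. This is a pooled-voxel Dice, not a
  mean of per-lesion Dice values: a missed lesion dilutes the union
  score rather than contributing a separate zero.
* **Empty-mask conventions.** Two empty masks score DSC 1.0 (vacuous
  agreement, flagged with a warning); an empty submission against a
  non-empty reference scores 0.0. Published dummy-run tables contain
  exact 0.000 entries for centers that effectively missed the target, so
  no outlier exclusion is applied anywhere.
* **ICC(2,1).** Two-way random-effects, absolute-agreement, single-
  measure intraclass correlation from the ANOVA decomposition
  `(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)`. The mean squares
  are returned alongside the coefficient for audit. A ratings matrix
  with zero total variance (all cells equal) is defined as ICC 1.0 with
  a warning; the zero test is relative to machine epsilon because a
  constant matrix leaves O(1e-31) residues in floating point. The
  ratings layout (what constitutes a subject and a rater) is a caller
  decision: both cases × pairwise-DSC values and cases × per-center
  reference DSCs are supported, since published reports rarely state the
  layout.
* **Bootstrap CI.** Non-parametric percentile ("relative frequency
  distribution") bootstrap, default 1,000 replicates, no bias
  correction. The resampling unit defaults to the *axial slice* of the
  union support region: slices preserve within-slice spatial correlation
  (voxel-level resampling would be wildly anticonservative for smooth
  3D masks) and reproduce CI widths of realistic scale on phantoms. A
  voxel-column unit is available as an alternative. Replicates with an
  empty denominator are dropped; if all are empty the CI degenerates to
  (0, 0) with a warning. Everything is driven by a `numpy` Generator
  seed, so CIs are bit-reproducible.

## Phase 2: plan compliance

* **DVH metrics.** Dmax, D(v cc) (minimum dose of the hottest v cc,
  converging to Dmax as v → 0), V(d Gy) and cumulative DVH curves are
  computed from voxel doses sampled at mask voxel centers. On coarse
  grids D(v cc) snaps to whole voxels (ceiling rule: the hottest
  ⌈v/voxel⌉ voxels).
* **Conformity/fall-off indices.** R50% = volume of the half-
  prescription isodose cloud divided by the PTV volume; D2cm = maximum
  dose at ≥ 20 mm from the PTV surface as % of prescription, with the
  distance taken from an exact 3D Euclidean distance transform of the
  PTV complement (anisotropic spacing respected); high-dose spillage =
  volume above 105% of prescription outside the PTV, as % of PTV volume.
  When one prescription covers several PTV components, the union is the
  denominator and the full isodose cloud the numerator — which is
  exactly why multi-target plans blow through R50%/D2cm limits and why
  the exemption policy exists.
* **Grading.** The boundary is compliant. A violation is *minor* up to a
  tolerance margin beyond the limit and *major* past it. The margin is
  1 Gy for dose-type limits and 3 *percentage points* for %-scale
  volume metrics; for absolute cc (and ratio) limits the single "3% in
  volume" rule is read as 3% relative, since one number has to serve
  two unit families. PTV coverage uses an explicit 5-point band
  (≥ 95% compliant, ≥ 90% minor, below major) via a per-constraint
  margin override.
* **Exemptions.** Under the `multi-ptv` policy, R50%/D2cm deviation
  records whose prescription target has ≥ 2 connected components
  (`scipy.ndimage.label`) are marked exempt — kept in the report,
  excluded from tallies — reproducing with/without-exemption views of
  the same review. Granularity is per prescription (per dose cloud),
  not per plan. The binary rule is a declared simplification of
  protocols that exempt "to some extent".
* **PTV-EVAL.** PTV minus the union of OARs (optionally expanded by a
  margin), used for the coverage metric when a plan declares it. An
  empty PTV-EVAL yields a warning and undefined coverage.
* **Constraint table.** The numeric limits of any specific trial live in
  protocol documents that are not redistributable; the package ships
  explicit defaults (small bowel Dmax 30 Gy and D120cc 15 Gy, duodenum
  Dmax 24 Gy and D10cc 18 Gy, coverage ≥ 95%, R50 ≤ 4, D2cm ≤ 50% TD,
  spillage ≤ 15%) in `fixtures/default_constraints.yaml`, overridable by
  a YAML file of the same shape. "Small bowel 120 cc" is modeled as a
  dose-at-volume constraint (D120cc ≤ limit), the reading that grades
  naturally with the 1 Gy margin.

## Synthetic cohorts

The generator's job is to reproduce the *statistical structure* of a
dummy run, not anatomy.

* **Archetypes.** Four benchmark cases spanning the difficulty range:
  `NODAL` (one ellipsoidal ~165 cc PTV), `LUNG_MULTI` (five nodules with
  PTVs of 3, 10.5, 7.5, 5 and 6.5 cc — three of these are the scales a
  published exercise prints, the other two fill the stated 3–10 cc
  range), `LIVER_RIND` (a 3 mm shell on the upper cap of a liver-scale
  sphere, PTV ~49 cc), and `PERITONEAL_MULTI` (two 16 cc blobs plus one
  544 cc blob abutting a bowel-like tube OAR). Default prescriptions:
  35 Gy/10, 40 Gy/5, 24 Gy/3, 35 Gy/10 respectively. PTV = GTV expanded
  isotropically by 5 mm (configurable; trial-specific margins are not
  public). Per-seed jitter (±3–5% radii, ±2–3 mm centers) keeps PTV
  volumes within ±20% of the nominal scale on the default lattice; GTV
  radii carry a +0.4·h rasterization compensation so small nodules hit
  their volume after dilation. Positional offsets scale with grid extent
  so smaller lattices keep lesions inside the field of view (the
  peritoneal archetype needs ≥ ~190 mm extent to avoid clipping).
* **Default lattice.** 128³ voxels at 2 mm isotropic — large enough that
  the 2 cm D2cm shell is 10 voxels while keeping any single-case
  computation around a second. Tests and the acceptance experiments use
  32–64 voxel grids; those sizes are the package's chosen problem scale
  and are stated with each experiment's `n`.
* **Contour perturbation.** An institutional variant is the reference
  warped by a Gaussian-smoothed random displacement field (correlation
  length `deformation_scale_mm`, default 8 mm) plus a signed
  morphological adjustment (dilation or erosion at 0.25× the
  displacement magnitude, emulating systematic over-/under-segmentation).
  The displacement magnitude is tuned by bisection against the measured
  Dice: guaranteed within ±0.05 of the target (internal tolerance
  0.02), typically ±0.01–0.03 mean absolute error. Target 1.0 returns a
  copy; target 0.0 translates the structure beyond its bounding box
  (clipped at the grid edge if needed). Unreachable targets raise an
  error reporting the best achieved Dice. Near-zero published DSC
  entries are emulated by such gross-mismatch schedule entries, not
  modeled mechanistically — published tables give no cause for them.
* **Dose fields.** `synth_dose` builds a plateau of TD × hotspot/100
  inside the PTV union falling linearly to zero over `falloff_mm`
  outside, as a function of distance from the PTV surface. The
  center-to-center Euclidean distance transform overshoots the distance
  to the smooth surface underlying a voxelized structure by ~h/4 on
  average (boundary voxel centers straddle the surface), so that offset
  is subtracted; with it, the analytic sphere phantom (16 mm radius,
  16 mm fall-off) reproduces the continuum R50% of (24/16)³ = 3.375
  within ~2% on a 2 mm grid. R50, D2cm and Dmax of any generated plan
  are therefore known in closed form, which is what makes the compliance
  engine testable.
* **What the generator does not emulate.** CT appearance, organ motion,
  deformable anatomy, planning-system dose algorithms, and the *causes*
  of inter-observer disagreement (it dials only its magnitude). Passing
  tests demonstrate that the statistics and the rule engine are correct
  on fields with known truth — not that any particular clinical cohort
  would reach a given agreement level.

## Fixture tables

Per-center tables from a published 10-center dummy-run exercise are
transcribed as CSV fixtures (`table1`–`table4`, plus a center roster
recording who evaluated the hardest case on PTV-EVAL). They are test
*inputs*: the package recomputes every printed mean, SD and percentage
from the per-center cells. Two transcription notes: one case's printed
summary cell (35.700 (4.398)) is inconsistent with its own per-center
cells, which are stored verbatim (the recomputed row gives 35.200
(4.131)); and ungraded deviation marks are stored as grade
`deviation`, distinct from `minor`/`major`, since tallies only need
deviation-vs-none. Rounding everywhere follows the printed convention:
half-up, 3 decimals for DSC and Gy, 1 decimal for percentages
(`decimal`-based, since numpy rounds half-to-even).

## Numerical choices and edge cases

* Sample SD uses the n−1 denominator and is undefined (reported empty)
  for n = 1.
* `d_cc(v)` errors if v exceeds the structure volume; OAR constraints
  clamp the requested volume to the organ volume instead, so a small
  phantom organ can still be graded against a 120 cc-style rule.
* `d2cm_pct` requires grid spacing ≤ shell/5 and at least one voxel at
  the shell distance; both failure modes raise informative errors.
* Bisection in the perturbation engine brackets by geometric expansion
  (×1.8, up to 12 steps) before bisecting (default 30 iterations).
* RTSTRUCT rasterization is slice-wise polygon filling with the even-odd
  rule (contours on one slice XOR together, so holes subtract);
  round-trips preserve ≥ 0.99 Dice and volumes within 2% on convex
  phantoms. RTDOSE round-trips are exact to the 32-bit scaling quantum.

## Known limitations

* The overall-mean aggregation and the ICC inputs of any given published
  exercise are generally not recoverable from its printed tables; the
  package computes ICC(2,1) of whatever ratings matrix it is handed and
  reports the fixture-matrix value (0.661 GTV / 0.425 PTV for the
  packaged tables) without claiming equivalence to numbers computed
  from unpublished pairwise data.
* Exemption logic is binary per prescription; protocols that scale
  limits for multi-target plans instead of waiving them need a custom
  constraint table.
* The bootstrap unit (slices) is a modeling choice; published reports
  rarely state theirs, and voxel-level resampling would give much
  narrower intervals.
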