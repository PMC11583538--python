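# Methods

## Problem and model

Post-therapy pneumonitis (PTP) is delineated on a follow-up diagnostic CT,
while the dose distribution exists on the planning CT. The package maps the
PTP region into the planning frame, weights the planned dose biologically,
and summarizes how the pneumonitis volume is distributed over dose levels.

**Coordinates.** All physical coordinates are millimetres on LPS patient
axes; volumes are stored `values[i, j, k]` with the voxel centre at
`origin + index · spacing` and a voxel covering the half-open cube around its
centre. This matches DICOM patient space and makes voxel inclusion
unambiguous.

**EQD2.** The planned total dose `D` per voxel, delivered in `N` equal
fractions (fraction dose `d = D/N`), is converted to the equivalent dose in
2-Gy fractions under the linear-quadratic model:

    EQD2 = D · (d + α/β) / (2 + α/β)

with `α/β = 3 Gy` (normal lung) by default. At 2 Gy per fraction the
conversion is the identity for any α/β. The per-voxel `d = D/N` assumes one
plan delivered in equal fractions; boosts and replans are out of scope.

**Dose levels and thresholds.** "At least x Gy" is implemented as
`dose ≥ x`. The three dose levels are LD `[0, 20)`, ID `[20, 40)` and HD
`[40, ∞)` Gy, so exactly 20 Gy is ID (and counts toward V20) and exactly
40 Gy is HD. LD + ID + HD = 100% by construction.

**DVH and AUC.** The cumulative DVH is evaluated on edges `0, w, 2w, …`
(default `w = 0.1 Gy`) past the maximum in-mask dose; the value at edge `D`
is the percentage of in-mask voxels with dose ≥ `D`. The AUC is the
trapezoidal integral of that curve (Gy·%). By the layer-cake identity
AUC/100 equals the mean in-mask dose to within one bin width — this is used
as a standing cross-check.

**Stage order.** Registration → PTP warp → GTV subtraction → dose resampling
to the planning CT grid → EQD2 → metrics. EQD2 always precedes every metric,
and GTV subtraction always precedes DVH extraction, so results are
reproducible under one canonical ordering. Total-lung metrics (MLD, V20) are
computed on the EQD2 grid by default (a config switch selects physical dose)
and the lung mask excludes the GTV, consistent with the PTP handling.

## Registration

Classic additive Thirion demons, multi-resolution, with the displacement
field on the fixed (planning) grid: fixed point + vector = corresponding
moving point, so the pneumonitis mask lands directly in the frame of the
dose grid. Per iteration the update at each voxel is

    δ = −(m∘φ − f) ∇f / (|∇f|² + (m∘φ − f)²/K),   K = (mean voxel spacing)²

step-limited to `max_step_mm`, added to the field, then Gaussian-smoothed.
The `K` normalization is the standard intensity/geometry scaling: it gives
the update millimetre units and a bounded step of `√K/2` per iteration;
without it the raw quotient mixes HU² with HU²/mm² and caps steps at ~0.5,
too small to recover multi-millimetre deformations in a realistic iteration
budget. CT intensities are clamped to [−1000, 1000] HU first, because bone
and metal extremes destabilize the forces.

Defaults: 3 pyramid levels, 50 iterations/level, field smoothing σ = 3 mm,
max step 2 mm, convergence when the mean update drops below 0.005 mm. Two of
these were revised during phantom validation: with σ = 2 mm the coarse
levels "explain" an appearing opacity by dragging the surrounding anatomy
(a spurious ~1.7 mm field inside the pneumonitis region), and with a loose
tolerance the finest level converges immediately and never corrects it.
Field smoothing is floored at one voxel per level so coarse levels stay
regularized. Masks are warped as trilinearly interpolated 0/1 indicator
fields thresholded at 0.5 — robust to resampling, and bit-exact identity
under the zero field.

The mean-squared intensity residual is reported per level. On clean inputs
(intensity constancy holds) it decreases monotonically; on images with an
appearing lesion the global MSE is *not* minimized by the true field —
erasing the lesion lowers MSE — so residuals there are diagnostics, not an
objective to be forced. (An experiment that kept the per-level best-MSE
field degraded mask accuracy and was rejected.)

Whether this matches any specific clinical implementation of the demons
family cannot be claimed; parameters of treatment-planning systems are not
published.

## Resampling

Dose grids rarely share the CT geometry. `resample_to_grid` evaluates the
source at target voxel centres with a cubic B-spline (default), which is
exact for constant and affine fields at interior points and has an order of
magnitude less bias than trilinear on smooth penumbras — trilinear's
systematic chord bias (~0.1–0.5 Gy on a clinical penumbra) is enough to
flip whole near-threshold voxel shells between dose levels. Trilinear
(`order=1`) remains available. Target voxels outside the source extent are
set to 0 Gy and counted: pneumonitis regularly extends beyond the exported
dose grid, and that truncation must be explicit. The per-patient log always
reports the fraction of pneumonitis voxels outside the dose grid. Small
negative spline undershoots are clamped to zero before EQD2 conversion.

## Rasterization

A voxel is inside a planar contour iff its centre is inside the polygon by
the even-odd (crossing-number) rule; multiple polygons on one slice combine
by exclusive-or, which supports holes. The crossing test is half-open, so a
point on a shared edge belongs to exactly one of two adjacent polygons.
Volume of a 20 mm sphere converges to `4πr³/3` within 5% at 1 mm spacing.

## Statistics

Numeric variables: two-sided Mann-Whitney-U; exact enumeration when
`n + m ≤ 20` and tie-free, otherwise the normal approximation with tie and
continuity correction (scipy's implementation behind the package's surface).
Categorical variables: Pearson chi-square without continuity correction.
These choices are defensible defaults; clinical statistics packages differ
in their option sets, so exact agreement with any given analysis cannot be
promised. Summary tables report mean, sample SD (n−1), median, min and max
per group; p-values are suppressed when any group has fewer than 5 patients
(configurable), mirroring how very small matched subgroups are reported
descriptively only. No multiple-testing correction is applied — with ~10
partially correlated variables at α = 0.05, a null cohort flags at least one
"significant" variable in a substantial minority of realizations; the
per-test type-I rate is what is calibrated (5% ± 1.5% over 1000 null
cohorts).

Matched pairs minimize the total absolute PTV difference by optimal
assignment (Hungarian method), exact at cohort scale, one-to-one, with ties
broken toward ascending patient id by an infinitesimal index perturbation.

## Synthetic phantoms

The phantom is an analytic scene — body and lung ellipsoids, a tumor sphere,
HU palette air −1000 / lung −700 / soft tissue 40 / tumor 60 / pneumonitis
opacity −300 (ground-glass-like contrast; test constants, not clinical
claims) — sampled at 64×64×48 voxels of 2.5 mm. The planning CT is the
scene; the follow-up CT is the scene observed through a Gaussian-bump
displacement (default peak 6 mm, σ 22 mm) plus the added opacity and
independent Gaussian HU noise (default SD 20). Because the scene is
analytic, the follow-up image is evaluated exactly at displaced points (no
resampling error), and the exact forward field solves `u(x) = −w(x + u(x))`
by fixed-point iteration, which contracts because the folding check enforces
`det(I + ∇w) > 0`.

Dose is a spherical logistic falloff around the PTV (prescription 60 Gy in
30 fractions; 20–80% penumbra width 10 mm) exported on its own 2 mm grid
with non-integer offsets, so resampling is always exercised. The
pneumonitis region is the union of an in-field lobe and an out-of-field
lobe, clipped to the lung interior with a 3 mm margin — an opacity touching
the pleural wall creates a genuine appearance-change confound that
intensity-driven registration cannot resolve, which is a real limitation,
not a test artifact. The out-lobe placement and size are calibrated by a
2-D grid scan so the HD fraction of the (GTV-excluded) region meets the
requested overlap; the response is non-monotone because of lung clipping,
so no bisection. The achievable range with default geometry is roughly
0.34–0.70; extreme targets clamp and the truth records what was realized
(at 1.0, the shortfall is penumbra leakage plus lobe geometry). Phantom
centres sit off-lattice: a perfectly grid-aligned sphere puts a degenerate
shell of equal-radius voxels exactly at a dose threshold, which any
sub-0.1-Gy interpolation difference flips en masse.

What the phantoms do *not* emulate: realistic anatomy and texture,
breathing motion, CT artifacts, multi-plan dose, inter-observer contour
variability. Passing phantom tests therefore demonstrates algorithmic
correctness and self-consistency, not clinical registration accuracy on
real image quality.

**Simulated cohorts** sample per-patient fractionation (definitive
54–66 Gy at 1.8–2 Gy/fraction, ~65% of patients; palliative 30–50.4 Gy at
1.8–3 Gy), PTV volumes (log-normal, clipped to 90–1200 cm³), and a
pneumonitis sphere whose in-field share θ ~ N(0.45, 0.18) controls its dose
exposure; metrics are computed by the real dosimetry chain on a 24³ grid of
5 mm voxels (sizes chosen so a 1000-cohort calibration stays desk-scale).
An `effect` in Gy·% shifts θ in the ICI group by `effect / (100 · 55)` —
AUC ≈ 100 × mean EQD2 and the exposure lever spans ≈ 55 Gy — so the
expected AUC separation is approximately the requested effect. Onset days
are drawn from one pooled distribution (mean 87 d, SD 55 d) for both groups
so that `effect = 0` is a true null for every summarized variable; grades
are 1/2/3 with probabilities 0.65/0.25/0.10 in both groups.

## Numerical choices and degenerate inputs

- DVH bin width 0.1 Gy by default; AUC integrates to just past the max
  in-mask dose (the curve is zero beyond).
- An empty pneumonitis mask after GTV subtraction yields an
  evaluable-but-empty record: lung metrics and PTV survive, dose metrics
  are absent, and the overlap fraction is logged (cases with large
  GTV–pneumonitis overlap stay in the cohort, flagged).
- CSV outputs use fixed column order, fixed row ordering and `%.6f`
  formatting, so identical inputs reproduce byte-identical files.
- Verification problem sizes: 64×64×48 phantom (≈ 200k voxels), 200 random
  DVH fields of ≤ 10³ voxels, 1000 null cohorts for type-I calibration, 50
  matching instances with groups of ≤ 6.

## Known limitations

- Single-frame axis-aligned DICOM geometry only (no gantry-tilted or
  oblique acquisitions); fraction counts come from metadata, and re-planned
  or multi-course patients are rejected.
- The demons variant is classic and mono-modal; image-quality differences
  between planning and follow-up CT degrade it in ways the phantoms do not
  capture.
- Exact-vs-asymptotic MWU switching follows sample size and ties, which may
  differ from any specific statistics package's defaults.
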