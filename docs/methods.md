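# Methods

This note documents the models implemented in `artdose`, the defaults they
run with, and what the synthetic experiments can and cannot show.

## Geometry and grids

All objects live on regular voxel grids (axes x, y, z; millimetre world
coordinates; `origin` is the center of voxel (0,0,0)). The default
experiment grid is 64³ voxels at 4 mm isotropic spacing — a 256 mm cube
holding a schematic thorax: an elliptic-cylinder body (semi-axes
118 × 95 mm), two lung ellipsoids (52 × 60 × 112 mm, centers ±62 mm
lateral), an ellipsoidal heart, and tubular esophagus and spinal cord. The
GTV is a sphere centered in one lung; CTV = GTV + 6 mm, PTV = CTV + 6 mm
(Euclidean margin expansion on the voxel lattice, boundary-inclusive,
clipped to the body). The 4 mm spacing is the coarsest resolution at which
the full volume range of the cohort (≈100–500 cm³ tumors plus margins)
fits the 64³ field of view; unit tests that need sub-percent volume
accuracy use 1–2.5 mm grids on a proportionally smaller thorax.

A consequence of the 4 mm grid worth knowing: the idealized plan's 95%
isodose shell (≈2.6 mm wide, see below) is sub-voxel, so the planning-time
conformity index saturates at 1.0 rather than the ≈0.87 typical of clinical
plans. Conformity *differences* between arms — the quantity the experiment
measures — remain well resolved.

## Tumor regression

Per-fraction GTV volumes follow geometric decay at a per-patient rate drawn
from N(1.1%, 0.4%) (truncated at 0). By default the decay is modulated by a
weekly shrinkage profile (−1.6, −6.7, −9.6, −11.9, −7.4, −5.1, −3.4 percent
for weeks 1–7), distributed geometrically over the five fractions of each
week; per-patient heterogeneity scales the log-profile by the ratio of the
drawn rate to the 1.1% mean. The compounded profile leaves ≈64–66% of the
planning volume after six weeks — the observed clinical regime — whereas
the pure geometric model (the `weekly_profile=None` branch) leaves 71.8%
after 30 fractions; both interpretations are exposed because per-day
percentages do not uniquely determine compounding. A linear (non-compounding)
variant is also available.

Between planning CT and first fraction (a ~7.5-day interval) each patient
progresses with probability 0.5, by a factor drawn uniformly from
[+6.6%, +12.1%]; non-progressors start unchanged. This reproduces the
clinical facts directly (half the cohort progressing, with that range)
rather than assuming a single cohort-wide growth value.

Fraction indices equal treatment days; weekend gaps are ignored.

## Anatomy per fraction

Shrinkage is isotropic about the GTV centroid (no shape information is
available to justify anything richer). The fraction-k GTV is rasterized by
sampling the trilinearly interpolated *signed-distance field* of the
planning GTV at the inversely scaled position — volume-accurate to
sub-voxel level, unlike thresholding an interpolated binary mask, which
biases volumes outward by a sizable fraction of a voxel.

The deformation field (DVF) uses the pull-back convention: a planning-frame
point x corresponds to fraction-frame position x + u(x), with
u(x) = (s − 1)(x − c) inside the planning GTV (s = cube root of the volume
ratio, c = centroid) and a smooth cosine taper to zero 40 mm beyond the GTV
surface. The radial map is monotone (hence invertible) for the contraction
magnitudes that occur here. Organs at risk are passively displaced by the
field (first-order inverse: sample the planning mask at y − u(y)); targets
are re-derived by margin expansion on the adaptation images (fractions
1, 5, 10, …), matching weekly target adaptation. Whether organs deform
with the tumor in clinical registrations is not observable from reports;
passive displacement is an explicit assumption.

Residual setup error is i.i.d. Gaussian per axis with 1.5 mm standard
deviation per fraction — a typical post-IGRT residual; its magnitude is a
free simulator parameter, and on the default cohort the delivery
degradation is dominated by shrinkage, not by setup noise.

One master seed drives everything: cohort parameters and per-patient
streams are spawned from it (`numpy` SeedSequence), so a run is a pure
function of its configuration.

## Dose model

VMAT inverse optimization is replaced by a deterministic conformal shape —
this is the largest acknowledged simplification. The total-course dose is
the prescription P inside the PTV; outside, P · max(exp(−d²/2σ²), b) within
the body and zero beyond it, where d is the Euclidean distance transform to
the PTV on the voxel grid (d = 0 inside), σ = 8 mm is the penumbra scale
and b = 0.08 the relative body bath. PTV-mean = P holds exactly and
D95(PTV) = P, satisfying the clinical "mean = prescription, D95 ≥ 95%"
normalization with margin. The stand-in preserves the causal chain the
experiment measures — a smaller PTV means less dose to surrounding lung —
but has no coverage-vs-sparing trade-off knob beyond σ and b; constraint
conflicts a clinical optimizer would negotiate are reported (warnings, or
per-constraint pass/fail tables via `check_constraints`) rather than
resolved.

Re-optimization with background: at an adaptation the per-fraction target
becomes p = (P − mean background over the *current* PTV) / remaining
fractions, and the conformal shape around the current PTV is rescaled to
PTV-mean p. With static anatomy the accumulated PTV-mean telescopes to P
exactly, which is what makes the degenerate-course equivalence of the three
arms a machine-precision identity rather than an approximation.

## Accumulation

Dose is intensive: warping is pull-back trilinear resampling
(output(x) = fraction dose at x + u(x) + setup shift), with no Jacobian or
energy rescaling, and out-of-grid samples contribute zero (grids are sized
so this never clips dose in the experiments). Accumulation is the voxel-wise
sum; the aPlan background is kept in the planning frame throughout and
pushed to the current frame with the fixed-point inverse of the DVF when a
plan is adapted. Push-forward splatting was rejected because it creates
holes/overlaps for contracting fields.

## Evaluation

D_x% uses the descending integer rank ceil(x·N/100) with no interpolation
(exactly testable against brute-force selection); V_xGy counts boundary
voxels as covered. gEUD winsorizes to [D99%, D1%] before the power mean
when clipping is requested — winsorization rather than voxel removal keeps
N and the a = 1 mean-dose identity approximately intact (lung gEUD ≈ MLD).
The evaluation lung is both lungs minus the GTV. CI's isodose threshold
defaults to 0.95 · P because plan normalization makes the 95% isodose the
coverage surface; it is configurable. All metrics for all arms are
evaluated on the planning-frame structures; for aPlan the conformity index
is additionally reported against the final adapted PTV (`PTV/ci_adapted`),
since either anchor is defensible and neither is asserted as canonical.
Spinal-cord response parameters are literature estimates by analogy to the
optic nerve and should be read accordingly.

## Statistics

Arms are compared per metric with the two-sided Wilcoxon signed-rank test:
zero differences dropped, mid-ranks for ties, and the exact null
distribution of the positive-rank sum computed by dynamic programming for
n ≤ 25 (the n = 10 cohort always uses the exact distribution); the normal
approximation with tie correction covers larger n. Identical arms are
flagged as such instead of erroring the whole comparison table.

## Default experiment and problem sizes

Ten patients whose planning GTV volumes and prescriptions are the printed
values of the reference clinical cohort (99.7–496.8 cm³; 60/64/66 Gy in
2 Gy fractions), simulated at 64³ × 4 mm with weekly adaptation blocks
(initial plan for fraction 1; adapt on the fraction-1 image for fractions
2–5; then every fifth fraction). For cohort sizes other than ten, GTV
volumes are drawn log-uniformly from [100, 500] cm³ and prescriptions from
{60, 66} Gy. The full three-arm experiment runs in roughly a minute on one
CPU; these sizes were chosen so the whole pipeline stays interactive while
keeping the clinical volume range, fractionation and adaptation cadence.

## What the phantom does and does not show

The generator reproduces the *structure* of the clinical situation —
volume range, regression dynamics, weekly adaptation cadence, deformable
accumulation — but not CT physics (no Hounsfield units or CB-CT artifacts),
respiratory motion, nodal targets, density changes, or optimizer trade-offs.
Passing tests therefore demonstrate that the adaptation/accumulation logic
produces the expected *directional* effects (delivered worse than planned;
adaptation recovers lung dose and conformity, with the lung benefiting more
than heart, esophagus or cord), not that any particular patient's absolute
dose numbers would be reproduced. Absolute lung doses here are lower than
typical clinical values because the schematic phantom has no nodal disease
and an idealized falloff.

## Numerical notes

- Margin expansion and PTV distances use `scipy.ndimage`
  distance transforms with physical sampling; masks are closed sets
  (boundary centers at exactly the margin distance are included).
- gEUD is computed in the log domain, stable for |a| up to the 25 used here;
  a cold spot (zero dose) with negative `a` returns 0 with a warning.
- The DVF inverse uses three fixed-point iterations, ample for the smooth,
  small-magnitude contraction fields generated here.
- Trilinear warping is a convex combination: it never creates negative dose
  and never exceeds the input maximum; with identity fields it is exact at
  machine precision, which the accumulation-conservation test exercises.
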