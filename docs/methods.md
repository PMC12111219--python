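# Methods

This note records the models behind `hydrolens`, the defaults and why,
and what the synthetic data do and do not establish.

## Expansion factors and AUC

Expansion factors are plain ratios: LEF = wet diameter / dry diameter,
REF = wet sagittal depth / dry sagittal depth (dimensionless, ≥ 1 for
swelling gels).  Off-grid timepoints are read by linear interpolation —
the minimal assumption between tracked frames; no extrapolation outside
the recorded range.  AUC over a window [t₀, t₁] (hours) is the
trapezoid rule with interpolated endpoints, which makes AUC exactly
additive over adjacent windows.  Group summaries use the sample
standard deviation (n−1), matching the "mean ± sd" convention for
five-sample lab groups.

The paired comparison integrates cumulative exposure windows
[0, 17 h] vs [0, 24 h] by default (both windows are configurable).
Differences are taken as (24 h − 17 h), so continued swelling is
*positive*; reports that adopt the opposite sign convention simply
negate.  For a factor that never drops below its starting value the
cumulative AUC necessarily grows, which is why every group's exact
Wilcoxon p lands on the two-sided enumeration floor 2/2⁵ = 0.0625 at
n = 5 — a structural property, not an artefact.

Gravimetric water content is 100·(M₁−M₀)/M₁ with M₀ the dry and M₁ the
swollen mass; *mass swelling* is the same quantity on the fractional
scale.  (The verbal gloss "mass increase over initial mass" would be
(M₁−M₀)/M₀, but the published per-group values are consistent with the
(M₁−M₀)/M₁ column formula, so that is the single implemented formula,
exposed under both names.)

## Exact small-sample inference

`wilcoxon_signed_rank_exact` drops zero differences (classic
convention; the study's data contain none), mid-ranks tied magnitudes,
and computes the null distribution of W = Σ ranks of positive
differences by dynamic programming over the 2ⁿ sign assignments (ranks
doubled internally so half-integer mid-ranks stay on an integer
lattice).  The two-sided p is min(1, 2·min(P(W≤w), P(W≥w))).  No
normal approximation is ever used; enumeration is capped at n = 30,
far above the study's n = 5.

The Hodges–Lehmann estimate is the median of the n(n+1)/2 Walsh
averages (dᵢ+dⱼ)/2, i ≤ j.  Its CI takes the k-th smallest/largest
Walsh averages with k the largest value whose one-sided null tail
P(W ≤ k−1) stays within α/2 — the standard distribution-free
order-statistic interval.  At n = 5 a two-sided 95% level is not
achievable (the widest interval reaches 1 − 2/2⁵ = 93.75%); rather than
silently interpolating, the result carries `achieved_coverage` and a
`coverage_met` flag.

The between-group test is the textbook pooled two-sample t-test
computed from (mean, sd, n) summaries, df = n₁+n₂−2, with a Welch
variant behind a flag.  Pooled is the default because "two-sample
t-test" without qualification conventionally means the equal-variance
form.  Published summaries are rounded to 3–4 digits, so p-values
recomputed from them can differ from full-precision p-values by a small
factor; tests treat order-of-magnitude agreement as the honest check.

## Refractometry

The bench model is Snell's law at an air–gel interface,
n_gel = sin θ_air / sin θ_gel with n_air = 1 and θ measured from the
normal (incidence fixed at 60° in the study).  The forward model
θ_gel = arcsin(sin θ_air / n) and the inversion round-trip to machine
precision; observations violating 0 < θ_gel ≤ θ_air < 90° (a ray
bending *away* from the normal entering a denser medium) are rejected
at construction.

## Lens power simulation

**Power model.**  In-air paraxial thick-lens (lensmaker) formula,
P = F₁ + F₂ − (t/n)F₁F₂, F₁ = (n−1)/r₁, F₂ = −(n−1)/r₂, with the
meniscus sign convention: both apex radii positive, centres of
curvature behind the lens.  This is the simplest model consistent with
"effective central curvature + refractive index" inputs; the module
boundary allows an on-eye variant (tear lens, cornea) to be added, but
that is out of scope here.  Designing for a target power inverts the
formula in closed form for F₁ (it is linear); targets requiring
F₁ ≤ 0 are infeasible as meniscus designs and reported as such rather
than silently dropped.

**Geometry.**  Optical axis = z, apex at the origin, spherical-cap sag
z(x) = R − √(R²−x²) ≥ 0.  Defaults: back apex radius 8.6 mm (the
classic base curve), wet centre thickness 0.5 mm (a deliberately high
nominal value that makes thickness effects visible), wet optic-zone
diameter 8 mm, target grid −20…20 D in 0.25 D steps (the stated range;
the step is ours).  All lengths in mm; conversion to metres happens
only inside the power formulas.

**Swelling chain.**  Per target: (1) build wet profiles with the
manufacturer index; (2) scale isotropically by 1/SF to the dry state;
(3) re-swell x by LEF and z by REF (24 h group means by default — the
later, more equilibrated timepoint; 17 h selectable); centre thickness
scales axially by REF/SF.  Sag and thickness are scaled independently;
whether the original analysis also scaled the back-vertex position is
unknowable from the published description, so this choice is stated
rather than hidden.

**Circle fitting.**  Effective central curvatures come from an
algebraic least-squares (Kåsa) circle fit constrained to centre on the
symmetry axis — the constraint removes the degeneracy of shallow caps
and reduces the fit to a 2-parameter linear solve.  For an
anisotropically scaled sphere the fitted radius tends to the apex
value a²R/b as the fit chord narrows; over a finite chord it sits
between the apex and mid-zone curvature.  The fit chord (default: the
central 8 mm of the swollen zone, clipped to the available zone)
therefore materially affects anisotropic results and is a first-class
configuration knob, not a buried constant.

**ISO bands.**  ±0.25 D for |P| ≤ 10 D, ±0.5 D for 10 < |P| ≤ 20 D,
±1.0 D beyond.

**What this simulation does and does not reproduce.**  With the
bundled measured values the error curves are monotone in target power
and every material exceeds its ISO tolerance somewhere on the grid;
C38/C55/C58 (large index or scale mismatch) violate it over ~90% of
targets with extreme errors of ≈2.3–3.8 D, while C77/C67 stay within
roughly ±0.55 D.  Published curves for these materials show larger
magnitudes (up to ±6…±10 D); those depend on an unpublished fit-zone
width and thickness handling and are not derivable from the stated
inputs, so this package asserts bound- and trend-type properties, not
pointwise curve reproduction.

## LiDAR transparency processing

Normalisation divides by the mean over the first 10 min (the
"baseline"); the published description does not define its
normalisation, and baseline-relative scaling is chosen because it is
invariant to the sensor's absolute offset.  Filtering is a 4th-order
Butterworth low-pass applied forward and backward (zero phase;
effective order 8) in second-order sections — numerically necessary at
the default cutoff of 1/(2·3600) Hz ≈ 1.4×10⁻⁴ Hz on 1 Hz data, which
preserves ≥ 30-min hydration features while killing sensor jitter.
Endpoints use the filter routine's reflective padding.

Segmentation takes the global minimum as the end of the growth dip, the
subsequent global maximum as the transparency peak, and the first time
after the peak at which the slope magnitude stays below 0.01 per hour
over a trailing 1 h window as equilibrium onset.  The slope threshold
is a heuristic and exposed in the API.  Traces without a dip-then-peak
of at least 0.01 normalised amplitude raise a structure-not-found
error instead of returning arbitrary boundaries.

## Synthetic data generator

**Swelling.**  factor(t) = 1 + (plateau − 1 − creep·24)·(1 − e^(−t/τ))
+ creep·t + ε, ε ~ N(0, σ²) i.i.d.  The saturating-plus-creep form is a
modelling choice (the source material describes the shape only
qualitatively: fast rise within ~8 h, then slow ongoing swelling); it
has exactly two shape parameters, so for the Contaflex preset they are
solved per group/direction from the two published anchors — the
noiseless curve passes *exactly* through the 17 h and 24 h means, and
σ is the published 24 h sd.  τ defaults to 2.5 h, putting ~96% of the
saturating rise inside the first 8 h.  Sampling is a 1-min grid over
0–24 h, mirroring once-a-minute image capture.

**Masses.**  m₁ = m₀/(1 − wc/100) + noise with m₀ = 0.3 g; the noise
sd is propagated from the published water-content sd via
dm₁/dwc = m₀/(1−wc)².  Draws pushing m₁ below m₀ are clipped to m₀ and
flagged.  **Refraction.**  Forward Snell at the published 17 h index
plus 0.5° Gaussian angle noise (a realistic imaged-beam reading error;
the instrument itself resolves 0.01°).  **LiDAR.**  A C1
piecewise-cubic dip–rise–plateau template with zero-slope knots at
(0 h, 1), (2 h, 0.85), (9 h, 1.08), (12.5 h, 1.02) — so the global
minimum and maximum sit exactly at the nominal dip and peak times and
the ground truth returned with the trace is exact — plus 0.005
Gaussian noise at 1 Hz over 15 h.

**RNG discipline.**  Every draw comes from
`default_rng([seed, group, sample, channel])`; a fixed seed yields
byte-identical cohorts and each channel is independently reproducible.

**What passing tests show.**  Parameter recovery on these cohorts
demonstrates that the extraction/inference chain is unbiased and exact
in the noiseless limit *under the generator's assumptions*: i.i.d.
Gaussian noise on the factor scale, no temporal autocorrelation of
tracking errors, no drift, no inter-channel correlation.  Real tracked
video exhibits autocorrelated noise and occasional edge-detection
glitches; nothing here certifies robustness to those.

## Numerical choices and degenerate inputs

Strictly increasing time grids, positive dimensions and dry references
are enforced at construction.  Interpolation is exact on grid points;
AUC windows must be non-degenerate (t₀ < t₁).  The circle fit requires
≥ 3 distinct non-collinear points.  Zero differences in the Wilcoxon
test raise a degenerate-data error when nothing remains.  Equal-summary
zero-variance t-tests are degenerate, not p = NaN.  Dataset CSVs are
parsed with round-trip float precision so write→read→analyse is
bit-identical to in-memory analysis; reports are JSON with sorted keys,
so identical inputs give byte-identical reports.

## Known limitations

* Optic zone only: no peripheral curves, aspherics, torics, wavefront
  or on-eye (tear lens) optics; paraxial power only.
* The published large-magnitude HL medians for AUC comparisons
  (≈ −10³, unexplained units) are out of scope; this package reports HL
  estimates in factor·hours with its own documented sign convention.
* LiDAR output is a relative transparency indicator; no absolute
  transmittance calibration.
* Material constants are stored exactly as published (including the
  C77 17 h index sitting slightly above C67's, against the overall
  trend); no re-derivation or smoothing.
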