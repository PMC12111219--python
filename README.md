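# hydrolens

Hydration analysis for soft contact-lens hydrogels: swelling-factor
extraction and small-sample inference, Snell's-law refractometry,
LiDAR transparency-signal processing, and a wet/dry lens-geometry
simulation that converts swell-factor and refractive-index mismatches
into optical power errors checked against ISO tolerance bands.

## The problem

Soft contact lenses are lathed **dry** and swell when hydrated.
Manufacturers publish a single isotropic *swell factor* SF to convert
target wet dimensions into dry lathing dimensions, but real hydrogels
expand anisotropically: the **linear expansion factor**
LEF = wet diameter / dry diameter differs from the **radial expansion
factor** REF = wet sagittal depth / dry sagittal depth, and the hydrated
refractive index differs from the published value.  `hydrolens`
quantifies what those mismatches do to the delivered optical power.

The package ships the measured constants of five Contaflex (group-I
polymacon) materials with nominal water contents 38–77% (C38, C55, C58,
C67, C77) and targets lab scientists and lens designers who need to

* turn tracked dimension-vs-time series into expansion-factor series,
  timepoint summaries and trapezoidal AUCs;
* compare paired 17 h vs 24 h measurements with the **exact Wilcoxon
  signed-rank test** (full enumeration of sign assignments — no normal
  approximation at n = 5) and the **Hodges–Lehmann estimator** (median
  of Walsh averages) with its distribution-free order-statistic CI;
* recover refractive indices from laser refraction angles via Snell's
  law, n = sin θ_air / sin θ_gel;
* simulate the manufacturing chain per target power P ∈ [−20, 20] D:
  design a wet meniscus lens (back apex radius 8.6 mm, thick-lens power
  P = F₁ + F₂ − (t/n)F₁F₂ with F₁ = (n−1)/r₁, F₂ = −(n−1)/r₂), shrink
  it by 1/SF to the dry state, re-swell with measured LEF (lateral) and
  REF (axial), fit axis-centred circles to the swollen surfaces, and
  recompute the power with the measured index;
* process LiDAR transparency traces: baseline normalisation, zero-phase
  (forward–backward) Butterworth low-pass filtering, and segmentation
  into growth / transparency / equilibrium phases.

A synthetic-cohort generator reproduces the study's structure (5 groups
× 5 samples, saturating swelling kinetics anchored to the published
17 h/24 h group means, mass pairs, refraction angles, dip–rise–plateau
LiDAR traces) so the entire chain is testable without instrument data.

## Worked example

```sh
hydrolens generate --out ds --seed 3     # synthetic 5x5 cohort
hydrolens analyze ds --out report.json   # full swelling analysis
hydrolens simulate-power --out powsim    # power-error curves
```

The last command prints, for the five bundled materials:

```
C38: max |error| 3.760 D, ISO-compliant fraction 0.068
C55: max |error| 2.506 D, ISO-compliant fraction 0.106
C58: max |error| 2.291 D, ISO-compliant fraction 0.112
C67: max |error| 0.545 D, ISO-compliant fraction 0.907
C77: max |error| 0.547 D, ISO-compliant fraction 0.901
```

i.e. for C38 the lens delivered after realistic anisotropic swelling
misses the target by up to 3.76 D at the ±20 D extremes, and only 6.8%
of target powers stay within the ISO tolerance (±0.25 D up to ±10 D,
±0.5 D up to ±20 D).  `report.json` contains, per group, LEF/REF means
± sd at 17 h and 24 h, the paired AUC comparison (each group's exact
Wilcoxon p is 0.0625 — the two-sided floor 2/2⁵ at n = 5 when hydration
grows in every sample — with a positive Hodges–Lehmann median
difference and its achieved-coverage-flagged CI), the C38-vs-C58
two-sample t-test (here t = −15.3, p = 3.3 × 10⁻⁷), gravimetric water
contents and recovered refractive indices.

The same computations are available as a library:

```python
import hydrolens as hl

c77 = hl.get_material("C77")          # SF 1.66, LEF(24h) 1.563, n(24h) 1.372
curve = hl.power_error_curve(c77)     # -20..20 D grid
print(curve.max_abs_error())          # 0.547 D
```

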