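# Methods

## Dose model

`brachyverify` implements the TG-43U1 general 2D formalism for a single
line source stepped through applicator channels. The dose rate from one
dwell is the product of five factors: the air-kerma strength on the
treatment day S_k (U = cGy·cm²·h⁻¹), the dose-rate constant Λ
(cGy·h⁻¹·U⁻¹), the geometry-function ratio G_L(r,θ)/G_L(1 cm, 90°), the
radial dose function g_L(r), and the 2D anisotropy function F(r,θ). The
point dose is the sum of rate × dwell-time over all dwells, with dwell
times stored in seconds and divided by 3600 at the multiply; doses are
reported in cGy.

Water-equivalent geometry is assumed throughout: no heterogeneity,
shielding or applicator-attenuation corrections, no 3D dose grids, and
no 1D (point-source) fallback.

### Geometry

A dwell is a center plus a unit orientation. From a 4×4 transform matrix
the orientation is the normalized third column and the center the fourth
column; from DICOM channel geometry (which stores positions only) the
orientation at dwell *j* is the normalized central difference
P(j+1) − P(j−1) along the channel, with forward/backward differences at
the ends and a configurable default axis for single-dwell channels. This
is the physical tangent of the source train.

β is computed as |atan2(ρ, z−L/2) − atan2(ρ, z+L/2)| in the plane
spanned by the source axis (z) and the point (ρ the perpendicular
distance). The two-argument arctangent avoids the acos round-off that an
angle-between-vectors formulation suffers near the poles. The on-axis
closed form (r² − L²/4)⁻¹ is applied whenever sin θ < 10⁻⁶, at θ ≈ 180°
as well as θ ≈ 0° by the mirror symmetry of the segment, and demands
r > L/2.

All internal math is in centimetres. Plan files (DICOM and the text
dialect) carry millimetres, converted once at the I/O boundary.

### Fitted dosimetric functions

g_L(r) = h·rⁱ/(1 + j·rᵏ) and F(r,θ) = k(r) + a(r)u^e(r)/(1+b(r)u^e(r)) +
a′(r)(1−u)^e′(r)/(1+b′(r)(1−u)^e′(r)) with u = θ/180°, each coefficient
itself a three-term radial fit c₁r^c₂ + c₃r + c₄. The package ships the
published fit parameters for the GammaMed Plus HDR ¹⁹²Ir source; absent
table entries are exactly zero, and a zero exponent is read as a
constant term (c₁·r⁰ = c₁ for all r > 0). Other sources are loaded from
YAML documents with the same schema, so extending the tool is a matter
of supplying a new parameter file.

The fractional-power terms of F diverge at the exact poles, where the
fit was never intended to be evaluated; θ is therefore clamped to
[0.05°, 179.95°] and the clamp is reported as a `clamped-theta` warning
on the affected contributions. F is reported as fitted — it is not
clamped to be non-negative — so a pathological parameter set shows up in
the numbers rather than being masked.

### Physical constants (defaults, overridable)

The paper-grade fit parameters fully determine g_L and F; the remaining
constants default to published consensus data for the GammaMed Plus
source and are ordinary configuration fields an institution should set
to its own TPS values:

| parameter | default | unit |
|---|---|---|
| active length L | 0.35 | cm |
| dose-rate constant Λ | 1.118 | cGy·h⁻¹·U⁻¹ |
| half-life | 73.83 | days |
| validity window r_min–r_max | 0.2 – 10 | cm |
| fit deviations Δg, ΔF | 0.5, 0.9 | % |
| guard capsule radius | 0.05 | cm |

The validity window reflects the radial extent of the Monte Carlo data
behind the fits; evaluations outside it are computed (the functions are
analytic everywhere) but flagged `near-window`/`far-field` in the
result, since fit accuracy is not established there. The window is a
judgement call and is configurable per source document.

### Decay

Both calibration and treatment dates are taken at midnight, so the
elapsed time is a whole-day count and S_k(t) = S_k,cal·2^(−Δt/T½).
Sub-day decay of ¹⁹²Ir is below 0.5% and therefore below the acceptance
band's resolution; if agreement with a TPS that uses fractional-hour
decay were required, this day-count rule is the piece to change.

## Verification judgement

D_diff% = 100·(D_indep − D_TPS)/D_TPS is compared with a symmetric band
±√(Δg² + ΔF²) obtained by linear error propagation from the average
relative deviations of the two fitted functions; with the shipped
deviations this is ±1.03%. The boundary is inclusive: a difference
exactly equal to the band passes, the conventional reading of "within
tolerance". The band is per-source configuration, so a different source
model carries its own deviations and hence its own band.

A point inside a source's guard capsule (perpendicular distance to the
active segment below 0.05 cm, or collinear with r ≤ L/2) is a fatal
near-source condition: the formalism has no meaningful value there, so
the point is reported FAIL with the diagnosis and the offending dwell
index instead of a number that would be garbage. Out-of-window radii and
clamped θ are warnings only — they flag reduced fit accuracy, not an
unusable geometry — and are printed prominently in the report so a
reviewer checks the point location before blaming the plan.

## Synthetic plans

The generator stands in for patient plans, which are not distributable.
It emulates the geometry of gynaecological HDR applicators: a straight
tandem (one channel along +z, dwells at a fixed step) or a tandem-ovoid
layout (a tandem plus two short lateral channels tilted 15° toward the
axis). Dwell times are drawn uniformly from 10–30 s; the calibration is
40 700 U with a 14-day calibration-to-treatment gap. Four verification
points follow the classical pattern: point A left/right 2 cm lateral at
the tandem tip level, a bladder point 2 cm anterior and a rectum point
2.5 cm posterior of the mid-tandem. Stored "TPS" doses are the engine's
own output, optionally multiplied by a configurable bias so failure
modes can be exercised deterministically.

What passing on these plans shows: the full pipeline (file round trip,
decay, geometry, fitted functions, summation, comparison, reporting) is
self-consistent and behaves correctly under controlled perturbations.
What it does not show: agreement with a real TPS's table-interpolated
dose, which depends on clinical plan data and the TPS's own dosimetric
tables; the clinical-scale statistics of such comparisons are outside
the scope of a desk-scale test suite.

## Numerical choices

- Collinearity tolerance sin θ < 10⁻⁶; θ clamp 0.05°; orientation unit
  norm enforced to 10⁻⁹.
- β via atan2 differences (quadrant-safe), never acos.
- All pass/fail comparisons use full double precision; percentages are
  rounded to two decimals only for display.
- The reference normalization G_L(r₀,θ₀) is evaluated by the same code
  path as the numerator, so the ratio is exactly 1 at the reference
  point by construction.
- Problem sizes in the test and acceptance runs (10⁴ random geometries
  for the point-source limit, 10⁵ draws for the constant-anisotropy
  property, 100 seeded plans end to end) were chosen as the smallest
  sizes that exercise the full input ranges; all complete in seconds.

## Known limitations

- Single source model shipped; other line sources need their own fit
  parameters and deviations.
- DICOM reading covers HDR brachy application setups with cumulative
  dwell weights; plans with per-dwell transform matrices in private
  attributes are carried faithfully only by the text dialect.
- The dwell-time recovery treats every cumulative-weight interval as a
  dwell at its starting control point. TPS exports that encode dwells as
  paired control points (position repeated, weight increasing on the
  second of the pair) yield interleaved zero-time dwells that do not
  change any dose, but consumers counting dwells should be aware.
- No secondary legacy tolerance (e.g. ±5%) is applied; the band is the
  single configurable gate.
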