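# brachyverify

Independent second-check dose verification for high-dose-rate (HDR)
brachytherapy plans.

Before an HDR treatment is delivered, the dose computed by the treatment
planning system (TPS) at a handful of named reference points — point A
left/right, bladder, rectum in gynaecological work — should be confirmed
by an independent calculation. `brachyverify` performs that second
check: it reads the plan's dwell geometry (positions, orientations,
dwell times), the source calibration, and the verification points,
recomputes each point dose with the AAPM TG-43U1 2D line-source
formalism, and judges the relative difference against an
error-propagated acceptance band.

## The calculation

The dose rate at distance *r* and polar angle *θ* from one dwell of a
line source with active length *L* is

```
Ḋ(r,θ) = S_k · Λ · [G_L(r,θ) / G_L(r₀,θ₀)] · g_L(r) · F(r,θ)
```

with the reference point r₀ = 1 cm, θ₀ = 90°, S_k the air-kerma strength
on the treatment day (decayed from calibration as S_k·2^(−Δt/T½) with a
whole-day Δt), Λ the dose-rate constant, and the geometry function

```
G_L(r,θ) = β / (L·r·sinθ)        off axis,
G_L(r,0) = (r² − L²/4)⁻¹         on the long axis,
```

where β is the angle the source tips subtend at the point. Instead of
interpolating the TPS's stored tables, the radial dose function g_L(r) =
h·rⁱ/(1 + j·rᵏ) and the 2D anisotropy function F(r,θ) are evaluated from
published analytic fits to Monte Carlo data; parameters for the GammaMed
Plus HDR ¹⁹²Ir source ship built in. The point dose is Σᵢ Ḋᵢ·tᵢ over all
dwells, and the relative difference against the TPS is

```
D_diff% = 100% · (D_indep − D_TPS) / D_TPS .
```

The average deviations of the fitted g_L (0.5%) and F (0.9%) from the
Monte Carlo data combine in quadrature to the default acceptance band
±√(0.5² + 0.9²) = ±1.03%. Points that sit inside a source's guard
capsule fail with a near-source diagnosis; points outside the fits'
validity window (0.2–10 cm by default) carry near/far warnings, mirroring
the two ways a second check legitimately disagrees with a TPS.

## Worked example

Generate a synthetic straight-tandem plan (5 dwells, 0.5 cm steps, four
classical verification points whose stored TPS doses are the engine's
own output) and verify it:

```
$ brachyverify generate --out demo.yaml --seed 42
wrote demo.yaml (5 dwells, 4 points)
$ brachyverify verify --plan demo.yaml
```

```
Plan:            synthetic-straight-tandem-seed42
Source model:    GammaMedPlus-Ir192
Sk (calibration): 40700.00 U on 2022-04-01
Sk (treatment):   35687.13 U on 2022-04-15
Acceptance band:  +/-1.03 %
Dwells:           5
------------------------------------------------------------------------
Point 'point-A-left': PASS
  D_indep = 224.0485 cGy
  D_TPS   = 224.0485 cGy
  D_diff  = +0.00 % (band +/-1.03 %)
  per-dwell contributions (cGy):
    dwell   0 ch 1:    34.526300  (r=  2.828 cm, theta=  45.00 deg, t=25.5 s)
    ...
Summary: 4/4 points PASS
```

The header shows the air-kerma strength decayed from the calibration day
to the treatment day (40700 U → 35687.13 U over 14 days of the 73.83-day
¹⁹²Ir half-life). Each point lists the independent dose, the TPS dose,
their relative difference, and the per-dwell breakdown (distance, polar
angle, dwell time). The command exits 0 when all points pass, 1 when any
fails, and 2 on input errors. A plan biased away from the engine's dose
(`generate --bias 2`) fails at the ±1.03% band with a −1.96% difference.

DICOM RT Plan files (`.dcm`) are read directly; `show-source` prints the
built-in source parameters. Plans can also be built in code — see
`brachyverify.generate_synthetic_plan`, `read_plan_text`,
`read_rtplan_dicom` and `verify_plan`.

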