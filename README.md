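# glucoloop

Blood-glucose dynamics after a meal, and how to control them with
proportional insulin infusion.

`glucoloop` is a small scientific Python library + CLI for researchers and
students working on glucose homeostasis and artificial-pancreas control
strategies.  It implements:

- a **three-variable ODE model** of blood glucose *x* (mmol/L), insulin *y*
  (mU/L) and glucagon *z*:

  ```
  dx/dt = I(t) − E(x) − δ·x·y + ε·z
  dy/dt = β·b(x, x₀) − λ·y            b(x, x₀) = max(0, x − x₀)
  dz/dt = α·exp(−β·b(x, x₀)/m) − γ·z
  ```

  with a Gamma-profile meal inflow `I(t) = w·Gamma(t; a, k)` and a saturating
  glucose-based expenditure `E(x) = q·(1 − exp(−p·(x − x₀)))`;

- its **quasi-steady-state (QSS) reduction**: insulin and glucagon turn over
  in minutes while glucose moves over hours, so the fast equations can be
  replaced by their equilibria, leaving one nonlinear ODE

  ```
  dx/dt = I(t; w, a, k) − E(x) − ω·b(x, x₀)·x + σ·exp(−b(x, x₀)/n)
  ```

  in the lumped, identifiable parameters ω = δβ/λ, n = m/β, σ = αε/γ;

- **parameter fitting**: bounded multi-start nonlinear least squares for
  (a, k, ω, σ) on a measured glucose profile, with exact gradients from
  forward sensitivity equations;

- **closed-loop control**: proportional infusion u(t) = ρ·b(x, x₀), which
  in the reduced equation simply raises the effective uptake to ω + κρ
  (κ = δ/λ); gain selection for a target peak, long-acting/cutoff/adaptive
  variants, and the κ-calibration experiment that identifies the insulin
  resistance R = 1/δ from a repeated meal with a probe infusion;

- **PRCC / eFAST global sensitivity analysis** of the meal peak and the
  baseline;

- a **synthetic-data generator** emulating averaged multi-subject
  meal-tolerance measurements (needed because the original averaged
  clinical profiles are not publicly deposited).

## Worked example

```python
import dataclasses
import glucoloop as gl

healthy = gl.get_preset("healthy_fitted")    # ω=8.30, σ=382, n=1.75, x₀=3
meal = gl.FITTED_MEAL                        # w=280.3 mmol (50.5 g), shape 4.11, rate 5.69/h

print(round(gl.baseline(healthy), 2))        # 4.76   resting glucose, mmol/L

diabetic = gl.get_preset("diabetic_omega2")  # β-cell failure: ω drops to 2
tr = gl.simulate(diabetic, meal)
print(round(tr.peak_value, 1))               # 12.8   post-meal peak, mmol/L

rho = gl.gain_for_target_omega(2.0, 4.0, diabetic.kappa)
ctl = gl.simulate(diabetic, meal, control=gl.ControlPolicy(rho=rho))
print(round(rho, 2), round(ctl.peak_value, 1))  # 8.3  9.7
```

The numbers mean: a healthy fitted subject rests at ~4.8 mmol/L; with
β-cell function cut to ~a quarter (ω = 2) the same 50.5 g carbohydrate meal
would spike glucose to 12.8 mmol/L; an infusion gain ρ ≈ 8.3 mU/h per
mmol/L of glucose excess doubles the effective uptake (ω_eff = 4) and caps
the peak at 9.7 mmol/L.

The same is available from the shell:

```bash
glucoloop simulate --preset diabetic_omega2 --out diabetic.csv
glucoloop control  --preset diabetic_omega2 --target-peak 10 --out controlled.csv
glucoloop synth    --seed 1 --out profile.csv
glucoloop fit      --data profile.csv --meal-w 280.3 --seed 0 --out fit.json
```

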