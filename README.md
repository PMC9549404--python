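# voripk

Population pharmacokinetics of voriconazole in talaromycosis, with
CRP-guided initial dosing.

Voriconazole trough concentrations in patients with *Talaromyces
marneffei* infection are highly variable, and inflammation — measured by
C-reactive protein (CRP) — suppresses the CYP-mediated clearance of the
drug. `voripk` implements the full analysis pipeline behind a published
population-PK study of this population: a one-compartment nonlinear
mixed-effects model with an exponential CRP covariate on clearance,

    CL_i (L/h) = 4.34 · e^(−0.135 · CRP_i/43.6) · e^(η_CL,i),   η_CL ~ N(0, 1.01)
    V_i  (L)   = 97.4 · e^(η_V,i),                              η_V  ~ N(0, 0.0973)
    Ka = 1.1 h⁻¹ (fixed),  F = 95.1%,   Y = f·(1+ε₁) + ε₂

together with everything needed to estimate, validate, and use it:

- **kinetics** — closed-form one-compartment solutions (oral first-order
  absorption, 1-h zero-order IV infusion) with exact superposition over
  dosing histories;
- **estimation** — a FOCE-type Laplace marginal-likelihood objective with
  inner empirical-Bayes Newton steps, OFV-based model comparison, RSE,
  shrinkage, and CWRES diagnostics;
- **covariate selection** — stepwise forward (ΔOFV > 3.84) / backward
  (ΔOFV > 6.63) screening over linear/proportional/power/exponential
  relations;
- **validation** — subject-resampling bootstrap, visual predictive checks,
  goodness-of-fit tables, and the post-hoc EBE-clearance-vs-CRP analyses;
- **dosing simulation** — Monte Carlo probability of target attainment
  (PTA) of the trough against the 1.0–5.5 mg/L therapeutic window,
  stratified at CRP 96 mg/L, reproducing the study's loading-dose (C24)
  and steady-state maintenance tables and its recommendations
  (CRP ≤ 96: 250/100 mg q12h; CRP > 96: 200/75 mg q12h);
- **synthetic cohort** — a generator matched to the study design
  (69 patients, ~233 sparse samples, mixed IV/oral label regimens,
  two-site covariate distributions, Hardy–Weinberg CYP2C19 genotypes,
  LLOQ 0.2 mg/L), since the original data are not public.

It is aimed at pharmacometricians and methods-minded readers who want a
transparent, fully tested re-implementation of this kind of analysis in
scientific Python rather than NONMEM.

## Worked example

Simulate a study-like cohort, fit it, and ask for the CRP-stratified
dose recommendation:

```python
import voripk as v

cohort = v.generate_cohort(seed=1)          # 69 subjects, ~233 samples
fit = v.fit(cohort, v.final_model())        # Ka fixed at 1.1 1/h
print(f"OFV {fit.ofv:.1f}  CL {fit.est.theta['cl']:.2f} L/h  "
      f"V {fit.est.theta['v']:.1f} L  "
      f"IIV_CL {100*fit.est.omega2['cl']**0.5:.0f}%CV")

res = v.simulate_troughs(v.make_regimen(250, 100, "iv"), v.CRP1,
                         v.final_model(), n=1000, seed=1)
print(f"PTA {100*res.p_in_range:.1f}%  >5.5 mg/L {100*res.p_above:.1f}%  "
      f"mean trough {res.trough_mean:.2f} mg/L")
```

which prints (seed 1):

```
OFV 613.5  CL 4.92 L/h  V 103.6 L  IIV_CL 78%CV
PTA 58.3%  >5.5 mg/L 9.9%  mean trough 2.41 mg/L
```

The fitted clearance and volume recover the generating values (4.34 L/h,
97.4 L) within the wide sampling scatter this sparse 69-subject design
allows (the study's own clearance RSE is 18.6%). The simulated
steady-state trough for the recommended CRP-1 regimen attains the
1.0–5.5 mg/L window in ~58% of subjects with ~10% overshoot — the
irreducible consequence of the 100% inter-individual variability in
clearance.

The same stages are available from a shell:

```bash
voripk simulate-data --n 69 --seed 1 --out data.csv
voripk fit data.csv --out model.yaml
voripk pta --model model.yaml --n 1000 --seed 1 --outdir pta/
voripk recommend
voripk run-all --outdir run/ --seed 1
```

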