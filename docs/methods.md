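# Methods

## The model

Voriconazole concentration–time data are described by a one-compartment
model with first-order absorption and first-order elimination. For
individual *i*,

    CL_i = θ_CL · exp(θ_CRP · CRP_i / 43.6) · exp(η_CL,i)
    V_i  = θ_V · exp(η_V,i)
    Ka   = 1.1 h⁻¹ (fixed)
    F    = θ_F (oral doses only; IV bioavailability is 1 by definition)

with η ~ N(0, ω²) independently per parameter (diagonal Ω — no CL–V
correlation is modeled) and a combined residual-error model
Y = f·(1+ε₁) + ε₂, ε₁ ~ N(0, σ_prop²), ε₂ ~ N(0, σ_add²). The default
parameter values are the published final estimates: θ_CL = 4.34 L/h,
θ_CRP = −0.135 (CRP centered at 43.6 mg/L), θ_V = 97.4 L, θ_F = 0.951,
ω²_CL = 1.01 (IIV 100.5 %CV), ω²_V = 0.0973 (31.2 %CV), σ_prop = 0.071,
σ_add = 0.373 mg/L. The exponential covariate form is e^(θ·x/x̃), i.e.
the multiplier at the median is e^θ, matching the published equation; the
printed e^1.01 and e^0.0973 factors in that equation are the η terms
(their variances), not fixed multipliers — a fixed e^1.01 would
contradict the reported typical clearance.

Concentration profiles are evaluated analytically (superposition of
closed-form single-dose solutions; zero-order input for 1-h infusions,
first-order gut absorption for oral doses). Near the removable
singularity Ka → k = CL/V the oral solution switches to its analytic
limit when |Ka − k| < 10⁻⁸·Ka. The ODE integrator exists only in the
test suite, as an independent oracle.

## Estimation

The marginal likelihood is approximated by a Laplace expansion around
each subject's empirical-Bayes η mode, with the residual variance
evaluated at the η-dependent prediction (the "interaction" of FOCE-I).
The objective is −2·log-likelihood with all constants kept, so ΔOFV
between nested models is χ²-calibrated; no attempt is made to reproduce
any particular software's additive constant. Inner η optimization is a
damped Newton iteration (finite-difference derivatives, step cap 4 in η
space, stopping at gradient ∞-norm < 10⁻⁶ or relative objective change
< 10⁻⁸). The outer problem runs Nelder–Mead on log-transformed
structural and variance parameters (covariate coefficients on the
natural scale) in restart rounds — a fresh simplex around the incumbent
recovers progress lost to simplex collapse on the long θ_CL/θ_CRP ridge
created by the uncentered exponential covariate. η variances initialized
at zero are treated as absent (pure fixed-effects subproblem), which
also provides the cheap exact-likelihood path used by several
calibration tests. Standard errors come from a finite-difference Hessian
of the OFV (Cov = 2·H⁻¹); η-shrinkage is 100·(1 − SD(η̂)/ω).

Observations below the 0.2 mg/L quantitation limit are flagged at
generation and dropped (with a logged count) at estimation; the study's
observed minimum (0.23 mg/L) suggests no likelihood-based BLQ handling
was needed, and none is implemented.

Covariate screening follows stepwise selection: forward inclusion at
ΔOFV > 3.84 (χ², df 1, p < 0.05), backward elimination at ΔOFV > 6.63
(p < 0.01), candidate relations linear / proportional / power /
exponential with continuous covariates centered at their medians. A
two-structure comparison harness (linear vs Michaelis–Menten
elimination, the latter by numeric ODE) reports the ΔOFV at the same
3.84 gate; Ka and F are carried over from the linear fit there, since
absorption is not the quantity under test.

## Validation machinery

*Bootstrap*: subject-level resampling with replacement, dataset size
preserved; a replicate counts as successful if the optimizer converges
with finite, positive estimates; reports medians and 2.5–97.5
percentiles and is flagged invalid if more than half the replicates
fail. *VPC*: replicate datasets simulated under each subject's own
dosing and sampling design; observed 5/50/95th percentiles per
time-after-dose bin (nominal-grid edges, sparse bins merged leftward)
against the simulated 95% bands. *CWRES*: residuals decorrelated by the
FOCE-linearized covariance G Ω Gᵀ + diag(v) around the η mode (Cholesky
whitening). *Post-hoc*: OLS of EBE clearance on CRP and a Mann–Whitney
comparison split at 96 mg/L.

## Dosing simulation

Monte Carlo per regimen × CRP stratum: draw CRP from the stratum rule,
draw η, evaluate the trough analytically, add residual error (negative
draws truncated at zero and counted), classify against the threshold
pair. Loading regimens are assessed at exactly 24 h (C24, categories
<1 / 1–5 / >5 mg/L as printed); maintenance regimens at the first trough
eligible under the study's steady-state rule — after the 5th maintenance
dose following the loading day, i.e. 84 h for q12h maintenance starting
at 24 h — against 1.0–5.5 mg/L. Both threshold pairs are configuration
values. This 84-h evaluation follows the study's stated steady-state
definition; by 84 h the accumulation factor is within ~10% of its
asymptote, and the choice is configurable.

CRP strata are CRP-1 = (0.9, 96] and CRP-2 = (96, 207.7] mg/L (observed
range). The within-stratum CRP sampling rule is not given by the study;
the default draws from a lognormal moment-matched to the pooled cohort
summary (mean 77.8, SD 58 mg/L) truncated to the stratum, with uniform
and fixed-representative modes available for sensitivity analysis. The
simulated PTA is dominated by the 100.5% IIV, so the rule shifts
in-range probabilities by only ~1–2 points; it mainly affects the CRP-2
stratum, where the reproduced loading-day PTA sits 4–5 points below the
printed one under every rule tried.

The PTA result records the full simulated trough sample plus both the
median and the arithmetic mean. The printed steady-state trough
statistic is reported as the mean: the published probability columns
(P(<1.0) ≈ 30%) place the distribution's median near 1.9 mg/L, which is
incompatible with the printed 2.5–2.7 mg/L values, while the simulated
mean reproduces them within ±0.4 mg/L.

The label-dose comparator uses per-replicate body weights (two-site
mixture) with IV 6→4 mg/kg q12h or oral 400→200 mg q12h, halved below
40 kg.

## Synthetic cohort

The generator emulates the study design, not any individual patient:
69 subjects split 35/34 across two sites; regimen mix 50 IV-loading /
4 oral-loading / 1 mixed / 3 + 11 non-loading; label dosing by body
weight; 1–9 samples per subject (pmf with mean ≈3.4 and median 4, so 69
subjects yield ≈233 samples) of which 0–2 are steady-state pre-dose
troughs (≈75 expected); remaining samples fall on the nominal 0.5–12 h
post-dose grid of a dosing occasion drawn from any treatment day (only
troughs are restricted to steady state, as in the sampling protocol).
Continuous covariates are truncated lognormals moment-matched to each
site's published mean/SD and clipped to the observed range; binaries are
Bernoulli at the observed frequencies; CRP is drawn once per subject and
held constant (no within-subject CRP trajectory is modeled). CYP2C19
genotypes are drawn under Hardy–Weinberg equilibrium with allele
frequencies solved from the cohort phenotype split (f(*1) = √(30/69) ≈
0.659; f(*2)+f(*3) = √(8/69) ≈ 0.341, apportioned at the *2:*3 ratio
typical of southern Chinese cohorts). Concentrations below 0.2 mg/L are
flagged, not deleted.

What passing tests on these cohorts do **not** show: robustness to
model misspecification (the generator and the estimator share the
structural model), time-varying CRP, adherence or drop-out, or any
real-data idiosyncrasy — the study data are not public, so parameter
recovery is the strongest attainable end-to-end check.

## Numerical choices and problem sizes

Residual variances are floored at 10⁻¹²; η excursions beyond ±15 are
rejected as infeasible; non-positive-definite inner Hessians are ridge
regularized. The test suite scales simulation sizes to what the
properties need: likelihood-ratio calibration uses 200 replicates of a
24-subject fixed-effects design (median ΔOFV vs the χ²(1) median
0.455); PTA checks run 20 000 Monte Carlo replicates per cell so the
comparison with printed values is not dominated by simulation noise
(the tolerances are unchanged); the full-design recovery experiment is
a single seeded 69-subject cohort with ~233 observations. The
sparse-design sampling distribution of the typical-clearance estimate
is wide (the study's own RSE is 18.6%, and the uncentered covariate
parametrization ties the intercept to the CRP coefficient, itself at
65% RSE), so single-replicate recovery scatters accordingly; the
volume of distribution is much tighter (7–8%).

## Known limitations

- One-compartment linear kinetics only (the study's selected structure);
  the Michaelis–Menten harness exists for model comparison, not dosing.
- Diagonal Ω; no inter-occasion variability; no time-varying covariates.
- The Laplace objective is an approximation; ω²_CL on very sparse
  designs can be noticeably underestimated in individual replicates.
- Dose recommendations reproduce the study's simulation framework; they
  are not clinical guidance.
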