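# Methods

## Scope and intent

The package reimplements a population PK/PD analysis of once-daily
subcutaneous anakinra in children: an allometrically scaled
one-compartment PK model, a CRP turnover model with Emax inhibition and a
two-class responder/resistance mixture, sequential SAEM estimation, VPC
and NPDE diagnostics, and a dose calculator targeting a mean steady-state
concentration. Since the original patient-level data are not public,
everything is validated against synthetic cohorts generated at the
published population estimates, plus analytic consequences of the printed
model.

## Structural models

**PK.** After a subcutaneous dose D the one-compartment
first-order-absorption solution is superposed over the dose history; for a
regular schedule the geometric sums are evaluated in closed form, so
finite regimens and the steady-state profile cost the same. When
|Ka − ke|/Ka < 1e-8 (ke = CL/V), the solution switches to the analytic
degenerate limit `D·Ka·t/V·e^{−Ka·t}` per dose to avoid catastrophic
cancellation; tests pin the switch by continuity against the regular
branch and an ODE oracle. Times are in hours, concentrations in mg/L.

**PD.** CRP obeys `dR/dt = k_tr·R0·(1 − I(t)) − k_tr·R` with inhibition
`I = C/(C50+C)` for responders and `I = e^{−k_resi·t}·C/(C50+C)` for the
resistance class; at C = 0 both reduce to the pre-treatment equilibrium
R = R0. The fitted model uses each subject's constant mean steady-state
exposure, so both classes integrate exactly:

- responders: `R(t) = R0(1−I) + R0·I·e^{−k_tr t}`,
- resistance: `R(t) = R0 − k_tr·R0·I·(e^{−k_resi t} − e^{−k_tr t})/(k_tr − k_resi)`
  (with the `t·e^{−k_tr t}` limit when the two rates collide).

The resistance-class nadir falls at `ln(k_tr/k_resi)/(k_tr − k_resi)`
(≈58 days at the reference estimates) independent of the exposure level.
PD time runs in days from the first dose; the resistance clock is assumed
to start at treatment start. A numerically integrated variant driven by a
time-varying concentration profile is provided as an oracle/extension.
Note a deliberate consequence of Emax concavity: a fluctuating once-daily
profile averaging 0.4 mg/L yields slightly *less* average inhibition than
a constant 0.4 mg/L (Jensen's inequality), so residual CRP sits ~20%
higher in relative terms while fractional suppression agrees within a few
percent of baseline; the tests assert the latter, scale-stable quantity.

`C90` is implemented as the analytic 9×C50 (the often-quoted "≈10×C50" is
a rounding, documented here rather than coded).

## Reference parameter values

`reference_pk_params()` / `reference_pd_params()` carry the published
population estimates used as generating truth throughout: CL/F
6.24 L/h/70 kg (β 0.47), V/F 65.2 L/70 kg (β 0.76), Ka 0.38 h⁻¹, ω_CL
0.28, γ_V 0.47, additive residual SD 0.072 mg/L, LOQ 0.04 mg/L; CRP
baselines 141 (responders) and 37.9 mg/L (resistance class), k_tr
0.042 d⁻¹, C50 0.03 mg/L, k_resi 0.0048 d⁻¹, responder proportion 0.37,
ω_R0(RESI) 0.79, ω_ktr 0.81. The published PD residual SD of 0.39 for
proportional error on log10-transformed CRP is ambiguous about its scale;
it is read here as a natural-log-scale SD, i.e. 0.39/ln 10 ≈ 0.169 on the
log10 scale on which the model is fitted (configurable in the generator).
Only the resistance-class baseline carries between-subject variability,
matching the published variability table; the responder baseline is a
pure fixed effect.

## Synthetic cohorts

The generator emulates the study design rather than any individual
patients. Bodyweights are log-uniform over the design range — this
reproduces the reported right-skew (median ≈ 21 kg over 4.3–83 kg) with
no extra shape parameters. Ages are a monotone growth-curve map of weight
with 20% log-normal scatter clipped to the design range; they are carried
as covariates but play no role in the final model (bodyweight removed the
age effect). Dosing is 2 mg/kg once daily capped at 100 mg. PK sampling
occasions default to treatment days 2 and 28 with draws from a
0.5–24 h post-dose grid — a stand-in, as the observed sampling-time
design is only reported graphically. CRP is sampled on days
0, 14, 30, 60, 90, 120, 180, 270, 360, 400 (follow-up "to ~400 days").

Simulated PK observations add N(0, σ²) noise, truncate at zero for
physical plausibility, and flag anything below the LOQ as left-censored
with DV = LOQ. Each subject's latent truth (random effects, class, Css)
travels in a sidecar structure that estimation never reads.

What the generator does **not** emulate: dropout, dose adjustments,
adherence gaps, assay batch effects, or any real covariate correlation
beyond the weight–age map. Passing recovery tests therefore demonstrate
estimator correctness under the model's own assumptions, not robustness
to real-data violations of them.

## SAEM estimator

Latent variables: per-subject log CL (between-subject), per-occasion
log V (between-occasion), censored concentration values, and for the PD
stage the mixture label plus per-subject log baseline (resistance class
only) and log k_tr. Each observation's prediction uses the V of its own
occasion applied to the entire dose history; with a ~7 h half-life the
carryover across occasions weeks apart is negligible, and generator and
fitter share the same prediction code so the convention is internally
consistent.

E-step: per subject (or occasion), one independent proposal from the
population prior followed by two adaptive random-walk Metropolis steps,
on 2 parallel chains; censored values are Gibbs-imputed from the
truncated residual distribution (equivalent to the M3 left-censored
likelihood — the reported log-likelihood integrates the exact normal left
tail). The mixture label is drawn from its exact full conditional; a
responder's unused baseline latent is refreshed from its prior, which
keeps the label move a valid Gibbs step.

M-step: the Gaussian-linear parts are exact exponential-family updates of
stochastically averaged sufficient statistics — the allometric regressions
of log CL and log V on log(BW/70), the random-effect variances, the
residual variance and the mixture proportion. Fixed effects that enter
the mean nonlinearly and carry no random effect (Ka; responder baseline,
C50, k_resi) are updated by conditional least squares on the current
latent draws (bounded Brent in 1-D, Nelder-Mead otherwise) with the same
step-size damping. If a random-effect variance is held at zero, its
location parameters automatically join the conditional-least-squares
update, since the latent regression then carries no information — this is
what makes the noise-free degenerate checks exact.

Schedules: 300 exploration iterations (step size 1, variances annealed —
prevented from contracting faster than 5% per iteration) then 100
smoothing iterations with step size 1/k. Random-walk scales adapt toward
~30% acceptance during exploration only. Initial values come from naive
pooled statistics (clearance from dose rate over mean concentration with
a log-log regression on weight; baseline split at the geometric-mean
first CRP). All stochastic pieces run off a single seed in the settings.

Likelihood: per-subject importance sampling (300 Student-t(5) draws
centered on the conditional posterior from a post-fit sampling pass);
for the PD mixture the class is marginalized exactly, which also yields
each subject's posterior responder probability (tie at 0.5 → responder).
AIC = −2LL + 2p, BIC = −2LL + p·log(N subjects). Standard errors come
from per-subject score vectors (central finite differences of the
subject-level importance-sampling log-likelihoods with common random
numbers), with the Fisher information approximated by the sum of score
outer products; a Louis-type stochastic approximation would be the
heavier alternative and is not needed for the package's claims.

Sequential fitting: `fit_pd` accepts the PK stage as a fitted result
(empirical-Bayes clearances), as population parameters (allometric
clearance at each subject's weight), or as an explicit clearance map;
subject exposure is Css = daily dose/(24·CL). How the original analysis
computed individual Css is unreported; empirical-Bayes clearances are the
default recommendation here.

## Diagnostics

VPC: equal-count time bins (default 6; empty bins merged and counted),
observed 5th/50th/95th percentiles against the median and central 90%
band of those percentiles across replicate simulations on the original
design. PK bins on time after the last dose; PD on days since start
(log10 scale). NPDE: per subject, observations are decorrelated with the
inverse Cholesky factor of the empirical simulation covariance
(ridge-regularized and flagged if singular), ranked within the
decorrelated simulations with a mid-offset tie rule, and mapped through
the standard-normal quantile; calibration is tested with a t-test (mean
0), a chi-square variance test (variance 1) and Shapiro–Wilk normality.
Censored observations are excluded from the NPDE (they were 4/148 in the
study). The replicate count defaults to 1000 (unreported in the original
analysis).

## Dosing

`dose_for_target_css` inverts the exposure relation with the typical
allometric clearance (an individual clearance hook exists; the published
weight–dose curve is a population recommendation). Band edges are exactly
10 and 50 kg with the lower edge belonging to the 2 mg/kg rule — the
source ranges carry no boundary convention, so one was chosen and
documented. The default target Css of 0.4 mg/L is the smallest value on
the published 0.02–0.40 grid whose responder steady state is ≤10 mg/L.

## Problem sizes and numerical choices

Recovery experiments use 200 subjects × 3 samples (PK) and 100 subjects
× 10 CRP observations (PD), three seeds each, matching the package's
stated validation design; each SAEM fit takes seconds. Closed forms are
verified against `solve_ivp` oracles at 1e-6 relative tolerance.
Variance floors of 1e-10 guard degenerate updates; the mixture proportion
is clamped to [0.5/N, 1−0.5/N] during estimation. Grid-search likelihood
cross-checks use a plain prior-sampling Monte-Carlo marginal likelihood
(`pk_marginal_loglik`), deliberately independent of the SAEM path.

## Known limitations

- Candidate structural alternatives (two-compartment, nonlinear
  elimination, transit absorption) are out of scope by design; only a
  generic model-comparison operation (LRT/AIC/BIC) is provided.
- The covariate search is represented by the single allometric-vs-none
  comparison, not a general screening procedure.
- The per-occasion V convention approximates the dose history before the
  current occasion (see above); exact per-dose occasion bookkeeping would
  matter only for drugs with half-lives approaching the occasion spacing.
- Importance-sampling log-likelihoods carry Monte-Carlo noise of order a
  few hundredths per subject; AIC/BIC differences of interest here are
  orders of magnitude larger.
- The NPDE excludes censored observations rather than imputing them.
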