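# anakinra-pkpd

Population pharmacokinetic–pharmacodynamic modelling of subcutaneous
anakinra (recombinant IL-1 receptor antagonist) in children and
adolescents treated for systemic-onset juvenile idiopathic arthritis
(SJIA) and autoinflammatory syndromes, with dose individualization to a
target steady-state exposure.

The package is aimed at pharmacometricians and methodologists: it couples
a synthetic-cohort generator that reproduces the statistical structure of
a sparse pediatric study with a from-scratch SAEM estimator, so every
stage of the analysis — simulation, nonlinear mixed-effects estimation,
diagnostics, dose translation — is testable end to end without any
patient-level data.

## The model

**Pharmacokinetics.** One-compartment disposition with first-order
subcutaneous absorption. The identifiable parameters are the apparent
clearance CL/F and volume V/F (bioavailability F is folded in) and the
absorption rate constant Ka. Both disposition parameters scale
allometrically with bodyweight, with exponents estimated from data:

    CL/F = TV(CL) · (BW/70)^β_CL        V/F = TV(V) · (BW/70)^β_V

Between-subject variability acts log-normally on CL/F (SD ω_CL),
between-occasion variability on V/F (SD γ_V); the residual error on
concentrations is additive, and observations below the assay limit of
quantification (0.04 mg/L) enter the likelihood as left-censored.

**Pharmacodynamics.** C-reactive protein (CRP, R) follows an
indirect-response (turnover) model whose production rate k_TR·R₀ is
inhibited by drug concentration C through an Emax term:

    dR/dt = k_TR · R₀ · (1 − C/(C₅₀+C)) − k_TR · R          (responders)
    dR/dt = k_TR · R₀ · (1 − e^{−k_RESI·t} · C/(C₅₀+C)) − k_TR · R

The second form multiplies the inhibition by an empirical resistance
function, describing subjects whose CRP dips and then re-increases; a
mixture model assigns each subject to one class with estimated proportion
p_RESP. Because the fitted model drives the turnover equation with each
subject's constant mean steady-state concentration Css =
daily dose/(24·CL/F), both trajectories have exact closed forms.

**Estimation.** Stochastic approximation EM (SAEM) with
Metropolis-within-Gibbs sampling of the individual random effects, the
censored concentrations, and the latent mixture labels — no linearization
of the model. The stages run sequentially: PK first, then CRP with the PK
stage fixed. Model evaluation uses visual predictive checks and
normalized prediction distribution errors (NPDE).

**Dosing.** Inverting the exposure relation gives the daily dose reaching
a target Css: `dose = target · CL/F(BW) · 24`. A target of 0.4 mg/L
(well above C₉₀ = 9·C₅₀) drives responder steady-state CRP to 10 mg/L or
below, and the per-kg dose curve motivates a three-band rule: 3 mg/kg/day
under 10 kg, 2 mg/kg/day from 10–50 kg, flat 100 mg/day above 50 kg.

## Worked example

Simulate a study-sized cohort (87 children, 4.3–83 kg, once-daily
2 mg/kg subcutaneous dosing capped at 100 mg, sparse sampling) at the
published population estimates, refit it, and derive a dose:

```python
import anakinra_pkpd as ap
from anakinra_pkpd import cohort

design = cohort.study_pk_design(seed=1)          # 87 children, 4.3-83 kg
subjects = cohort.simulate_pk_dataset(design, ap.reference_pk_params())
fit = ap.fit_pk(subjects, ap.default_pk_init(subjects), ap.SaemSettings(seed=1))
print(fit.summary())

rec = ap.dose_for_target_css(20.0, target_css=0.4)
print(f"20 kg child -> {rec.daily_dose:.1f} mg/day "
      f"({rec.dose_per_kg:.2f} mg/kg/day); band: {rec.band}")
```

which prints

```
Parameter           Estimate   RSE (%)
tv_cl                  6.258         7
beta_cl                0.421        12
tv_v                   62.35        17
beta_v                0.7596        10
ka                     0.346        12
omega_cl              0.3029        15
gamma_v               0.4747        11
sigma_add            0.06684        19
-2LL -53.56  AIC -37.56  BIC -17.84  (p=8, N=87)

20 kg child -> 33.2 mg/day (1.66 mg/kg/day); band: 10-50 kg: 2 mg/kg/day
```

The refit recovers the generating values (typical CL/F 6.24 L/h/70 kg,
V/F 65.2 L, Ka 0.38 h⁻¹) to within the sampling noise of an 87-subject
sparse design, and the exact dose for a 20 kg child (1.66 mg/kg/day)
sits inside the 2 mg/kg band, as the banded rule intends.

The same pipeline is available from the shell:

```sh
anakinra-pkpd simulate --out out --kind both
anakinra-pkpd fit-pk  --data out/pk_dataset.csv --out out
anakinra-pkpd fit-pd  --data out/pd_dataset.csv --out out
anakinra-pkpd dose    --bw 20 --target-css 0.4
```

## Layout

- `anakinra_pkpd.models` — closed-form PK/PD structural models, exposure metrics
- `anakinra_pkpd.cohort` — synthetic study populations and replicate simulation
- `anakinra_pkpd.fit` — SAEM estimation, model comparison (LRT/AIC/BIC)
- `anakinra_pkpd.diagnostics` — VPC and NPDE with calibration tests
- `anakinra_pkpd.dosing` — Css-targeted dose calculator and bodyweight bands
- `anakinra_pkpd.io` / `anakinra_pkpd.cli` — NONMEM-style CSV dialect, config, CLI

See `docs/methods.md` for modelling assumptions, numerical choices and
known limitations.
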