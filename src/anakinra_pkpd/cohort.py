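"""Virtual study populations for the anakinra PK/PD analysis.

The generator reproduces the statistical structure the estimation stage
assumes: once-daily subcutaneous dosing at a per-kg dose capped at 100 mg,
log-normal between-subject variability on CL/F and between-occasion
variability on V/F, additive residual error with left-censoring at the
assay LOQ, and a two-class CRP response (responders vs delayed resistance)
with log-normal variability on the resistance-class baseline and on the
turnover rate.  Defaults mirror the study that motivated the package: 87
PK subjects weighing 4.3-83 kg with sparse sampling, and 22 CRP subjects
followed for about 400 days.

Bodyweights are drawn log-uniformly over the design range, which
reproduces the right-skewed weight distribution (median ~20 kg) without
extra shape parameters.  Ages are a deterministic growth-curve map of
weight with log-normal scatter, clipped to the design range — a stand-in,
since only ranges and medians are known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import models
from .data import PD, PK, PKDesign, PDDesign, SubjectData
from .models import PopPDParams, PopPKParams, RESI, RESP

__all__ = [
    "CohortDesign",
    "study_pk_design",
    "study_pd_design",
    "draw_covariates",
    "simulate_pk_dataset",
    "simulate_pd_dataset",
    "simulate_pk_observations",
    "simulate_pd_observations",
]

#: default CRP sampling days (follow-up to ~400 days)
DEFAULT_PD_TIMES = (0.0, 14.0, 30.0, 60.0, 90.0, 120.0, 180.0, 270.0, 360.0, 400.0)

#: default candidate post-dose PK sampling times (h)
DEFAULT_PK_TIMES = (0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)


@dataclass(frozen=True)
class CohortDesign:
    """Study design for a simulated cohort.

    ``occasion_days`` are the treatment days (0-based) on which PK sampling
    occasions take place; ``pk_samples_per_subject`` concentrations are
    spread round-robin over the occasions.  ``pd_noise_log10`` is the
    residual SD applied on the log10 CRP scale (default: the published
    natural-log-scale SD 0.39 divided by ln 10).
    """

    n_subjects: int = 87
    bw_range: tuple[float, float] = (4.3, 83.0)
    age_range: tuple[float, float] = (0.73, 21.0)
    dose_per_kg: float = 2.0
    dose_cap: float = 100.0
    n_occasions: int = 2
    occasion_days: tuple[int, ...] = (2, 28)
    pk_sample_times: tuple[float, ...] = DEFAULT_PK_TIMES
    pk_samples_per_subject: int = 2
    pd_sample_times: tuple[float, ...] = DEFAULT_PD_TIMES
    pd_noise_log10: float = 0.39 / math.log(10.0)
    p_male: float = 0.6
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        lo, hi = self.bw_range
        if not (0 < lo < hi <= 200):
            raise ValueError("bw_range must satisfy 0 < min < max <= 200")
        if self.dose_per_kg <= 0 or self.dose_cap <= 0:
            raise ValueError("doses must be positive")
        if len(self.occasion_days) < self.n_occasions:
            raise ValueError("occasion_days must cover n_occasions")
        if self.pk_samples_per_subject < 1:
            raise ValueError("pk_samples_per_subject must be at least 1")


def study_pk_design(**overrides) -> CohortDesign:
    """The PK study conditions: 87 children, 4.3-83 kg, 2 mg/kg/day."""
    return replace(CohortDesign(), **overrides) if overrides else CohortDesign()


def study_pd_design(**overrides) -> CohortDesign:
    """The CRP substudy conditions: 22 SJIA children, 10-83 kg, ~400 days."""
    base = CohortDesign(
        n_subjects=22,
        bw_range=(10.0, 83.0),
        age_range=(2.26, 16.8),
    )
    return replace(base, **overrides) if overrides else base


def draw_covariates(design: CohortDesign, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the covariate table (id, bodyweight, age, sex) for a cohort.

    Log-uniform bodyweights over ``bw_range``; ages follow a crude
    allometric growth map of weight with 20% log-normal scatter, clipped to
    ``age_range``.  Reproducible from ``design.seed``.
    """
    rng = np.random.default_rng(design.seed) if rng is None else rng
    lo, hi = design.bw_range
    bw = np.exp(rng.uniform(np.log(lo), np.log(hi), size=design.n_subjects))
    age = 2.5 * (bw / 10.0) ** 1.3 * np.exp(rng.normal(0.0, 0.2, size=design.n_subjects))
    age = np.clip(age, *design.age_range)
    sex = np.where(rng.random(design.n_subjects) < design.p_male, "M", "F")
    return pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:03d}" for i in range(design.n_subjects)],
            "bw": bw,
            "age": age,
            "sex": sex,
        }
    )


def _dose_amount(design: CohortDesign, bw: float) -> float:
    return float(min(design.dose_per_kg * bw, design.dose_cap))


def simulate_pk_dataset(
    design: CohortDesign, pk: PopPKParams, rng: np.random.Generator | None = None
) -> list[SubjectData]:
    """Simulate a sparse-sampling PK dataset under the population model.

    Per subject i, ``CL_i = tv_cl*(BW/70)**beta_cl * exp(eta_i)`` with
    ``eta_i ~ N(0, omega_cl^2)``; per occasion k,
    ``V_ik = tv_v*(BW/70)**beta_v * exp(phi_ik)`` with
    ``phi_ik ~ N(0, gamma_v^2)``.  Observations are the one-compartment
    prediction plus additive N(0, sigma_add^2) noise, truncated below at 0;
    values under the LOQ are flagged left-censored and carry DV = LOQ.
    """
    rng = np.random.default_rng(design.seed) if rng is None else rng
    cov = draw_covariates(design, rng)
    subjects: list[SubjectData] = []
    grid = np.asarray(design.pk_sample_times, dtype=float)
    occ_days = design.occasion_days[: design.n_occasions]
    last_day = max(occ_days)
    dose_times = np.arange(0.0, (last_day + 1) * 24.0, 24.0)
    for _, row in cov.iterrows():
        amount = _dose_amount(design, row.bw)
        eta = rng.normal(0.0, pk.omega_cl)
        phi = rng.normal(0.0, pk.gamma_v, size=design.n_occasions)
        cl_i = pk.cl_at(row.bw) * np.exp(eta)
        v_ik = pk.v_at(row.bw) * np.exp(phi)
        obs_t, obs_occ, preds = [], [], []
        for j in range(design.pk_samples_per_subject):
            k = j % design.n_occasions
            t_post = grid[rng.integers(grid.size)]
            t_abs = occ_days[k] * 24.0 + t_post
            n_given = int(np.floor(t_abs / 24.0)) + 1
            n_given = min(n_given, dose_times.size)
            s_last = t_abs - (n_given - 1) * 24.0
            pred = models._conc_multi(amount, 24.0, n_given, s_last, pk.ka, cl_i, v_ik[k])
            obs_t.append(t_abs)
            obs_occ.append(k + 1)
            preds.append(float(pred))
        preds = np.asarray(preds)
        y = np.maximum(preds + rng.normal(0.0, pk.sigma_add, size=preds.size), 0.0)
        cens = y < pk.loq
        dv = np.where(cens, pk.loq, y)
        order = np.argsort(obs_t, kind="stable")
        subjects.append(
            SubjectData(
                subject_id=row.subject_id,
                bw=float(row.bw),
                age=float(row.age),
                sex=str(row.sex),
                dose_times=dose_times,
                dose_amounts=np.full(dose_times.size, amount),
                obs_times=np.asarray(obs_t)[order],
                obs_values=dv[order],
                obs_types=np.asarray([PK] * len(obs_t), dtype=object),
                obs_cens=cens[order],
                obs_lloq=np.full(len(obs_t), pk.loq),
                obs_occ=np.asarray(obs_occ, dtype=int)[order],
                truth={
                    "eta_cl": float(eta),
                    "phi_v": [float(p) for p in phi],
                    "cl": float(cl_i),
                    "v": [float(v) for v in v_ik],
                    "pred": [float(p) for p in preds[order]],
                    "seed": design.seed,
                },
            )
        )
    return subjects


def simulate_pd_dataset(
    design: CohortDesign,
    pk: PopPKParams,
    pd_params: PopPDParams,
    rng: np.random.Generator | None = None,
) -> list[SubjectData]:
    """Simulate a two-class CRP dataset under the turnover/mixture model.

    Each subject is a responder with probability ``p_resp``.  The
    resistance-class baseline and the turnover rate are perturbed
    log-normally; each subject's constant exposure is
    ``Css_i = daily_dose / (24 * CL_i)`` with CL_i drawn from the PK model
    (including its between-subject variability).  Observed CRP carries
    additive noise on the log10 scale (SD ``design.pd_noise_log10``).
    """
    rng = np.random.default_rng(design.seed) if rng is None else rng
    cov = draw_covariates(design, rng)
    times = np.asarray(design.pd_sample_times, dtype=float)
    last_dose_day = int(np.ceil(times.max()))
    dose_times = np.arange(0.0, (last_dose_day + 1) * 24.0, 24.0)
    subjects: list[SubjectData] = []
    for _, row in cov.iterrows():
        amount = _dose_amount(design, row.bw)
        eta_cl = rng.normal(0.0, pk.omega_cl)
        cl_i = pk.cl_at(row.bw) * np.exp(eta_cl)
        css = amount / (24.0 * cl_i)
        is_resp = rng.random() < pd_params.p_resp
        eta_r0 = rng.normal(0.0, pd_params.omega_r0_resi)
        eta_ktr = rng.normal(0.0, pd_params.omega_ktr)
        r0_i = pd_params.r0_resp if is_resp else pd_params.r0_resi * np.exp(eta_r0)
        ktr_i = pd_params.k_tr * np.exp(eta_ktr)
        group = RESP if is_resp else RESI
        crp = models._crp_values(times, css, r0_i, ktr_i, pd_params, group)
        ylog = np.log10(crp) + rng.normal(0.0, design.pd_noise_log10, size=times.size)
        subjects.append(
            SubjectData(
                subject_id=row.subject_id,
                bw=float(row.bw),
                age=float(row.age),
                sex=str(row.sex),
                dose_times=dose_times,
                dose_amounts=np.full(dose_times.size, amount),
                obs_times=times.copy(),
                obs_values=10.0 ** ylog,
                obs_types=np.asarray([PD] * times.size, dtype=object),
                obs_cens=np.zeros(times.size, dtype=bool),
                obs_lloq=np.full(times.size, np.nan),
                obs_occ=np.ones(times.size, dtype=int),
                truth={
                    "group": group,
                    "eta_cl": float(eta_cl),
                    "eta_r0": float(eta_r0) if not is_resp else 0.0,
                    "eta_ktr": float(eta_ktr),
                    "css": float(css),
                    "r0": float(r0_i),
                    "k_tr": float(ktr_i),
                    "seed": design.seed,
                },
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# replicate simulation on an existing design (VPC / NPDE engines)
# ---------------------------------------------------------------------------

def simulate_pk_observations(
    design: PKDesign, pk: PopPKParams, rng: np.random.Generator, n_rep: int
) -> np.ndarray:
    """Replicate concentration matrices (n_rep, n_obs) on a fixed design.

    Redraws all random effects and residual noise while keeping times,
    doses, occasions and covariates of the original dataset; used by the
    visual predictive check and NPDE.  Values are truncated at 0 but not
    censored — callers decide how to treat the LOQ.
    """
    cl_typ = pk.cl_at(design.bw)
    v_typ = pk.v_at(design.bw)
    out = np.empty((n_rep, design.n_obs))
    for r in range(n_rep):
        eta = rng.normal(0.0, pk.omega_cl, size=design.n_subj)
        phi = rng.normal(0.0, pk.gamma_v, size=design.n_occ)
        cl_obs = (cl_typ * np.exp(eta))[design.subj_idx]
        v_obs = (v_typ[design.occ_subj] * np.exp(phi))[design.occ_idx]
        pred = design.predict(cl_obs, v_obs, pk.ka)
        out[r] = np.maximum(pred + rng.normal(0.0, pk.sigma_add, size=design.n_obs), 0.0)
    return out


def simulate_pd_observations(
    design: PDDesign,
    pd_params: PopPDParams,
    rng: np.random.Generator,
    n_rep: int,
    noise_log10: float | None = None,
) -> np.ndarray:
    """Replicate log10-CRP matrices (n_rep, n_obs) on a fixed design.

    Conditions on each subject's fitted constant Css (the sequential-fit
    convention) and redraws mixture membership, baselines, turnover rates
    and residual noise.
    """
    sd = pd_params.sigma_pd if noise_log10 is None else noise_log10
    out = np.empty((n_rep, design.n_obs))
    for r in range(n_rep):
        is_resp = rng.random(design.n_subj) < pd_params.p_resp
        r0 = np.where(
            is_resp,
            pd_params.r0_resp,
            pd_params.r0_resi * np.exp(rng.normal(0.0, pd_params.omega_r0_resi, design.n_subj)),
        )
        ktr = pd_params.k_tr * np.exp(rng.normal(0.0, pd_params.omega_ktr, design.n_subj))
        css_obs = design.css[design.subj_idx]
        r0_obs = r0[design.subj_idx]
        ktr_obs = ktr[design.subj_idx]
        resp_obs = is_resp[design.subj_idx]
        crp_resp = models._crp_values(design.t, css_obs, r0_obs, ktr_obs, pd_params, RESP)
        crp_resi = models._crp_values(design.t, css_obs, r0_obs, ktr_obs, pd_params, RESI)
        crp = np.where(resp_obs, crp_resp, crp_resi)
        out[r] = np.log10(np.maximum(crp, 1e-12)) + rng.normal(0.0, sd, size=design.n_obs)
    return out
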