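"""Shared fixtures: reference parameter sets and the (expensive) synthetic
parameter-recovery experiments, run once per session."""

from __future__ import annotations

import numpy as np
import pytest

import anakinra_pkpd as ap
from anakinra_pkpd import cohort


@pytest.fixture(scope="session")
def pk_ref() -> ap.PopPKParams:
    return ap.reference_pk_params()


@pytest.fixture(scope="session")
def pd_ref() -> ap.PopPDParams:
    return ap.reference_pd_params()


def pk_recovery_design(seed: int) -> cohort.CohortDesign:
    """The PK recovery conditions: 200 subjects, 4.3-83 kg log-uniform,
    2 mg/kg once daily capped at 100 mg, 3 samples over 2 occasions."""
    return cohort.study_pk_design(n_subjects=200, pk_samples_per_subject=3, seed=seed)


def pd_recovery_design(seed: int) -> cohort.CohortDesign:
    """The PD recovery conditions: 100 subjects, 10 CRP samples to 400 days."""
    return cohort.study_pd_design(n_subjects=100, seed=seed)


@pytest.fixture(scope="session")
def pk_recovery(pk_ref):
    """Three-seed PK recovery experiment at the study's scale."""
    runs = []
    for design_seed, fit_seed in ((101, 201), (102, 202), (103, 203)):
        subs = cohort.simulate_pk_dataset(pk_recovery_design(design_seed), pk_ref)
        fit = ap.fit_pk(subs, ap.default_pk_init(subs), ap.SaemSettings(seed=fit_seed))
        runs.append((subs, fit))
    return runs


@pytest.fixture(scope="session")
def pd_recovery(pk_ref, pd_ref):
    """Three-seed PD mixture recovery experiment, PK stage fixed at truth."""
    runs = []
    for design_seed, fit_seed in ((301, 401), (302, 402), (303, 403)):
        subs = cohort.simulate_pd_dataset(pd_recovery_design(design_seed), pk_ref, pd_ref)
        fit = ap.fit_pd(subs, pk_ref, ap.default_pd_init(subs), ap.SaemSettings(seed=fit_seed))
        runs.append((subs, fit))
    return runs


@pytest.fixture(scope="session")
def allometric_comparison(pk_ref):
    """Full allometric fit vs covariate-free fit on bodyweight-driven data."""
    subs = cohort.simulate_pk_dataset(
        cohort.study_pk_design(n_subjects=80, pk_samples_per_subject=3, seed=77), pk_ref
    )
    init = ap.default_pk_init(subs)
    full = ap.fit_pk(subs, init, ap.SaemSettings(seed=501))
    null = ap.fit_pk(
        subs, init, ap.SaemSettings(seed=502, fix={"beta_cl": 0.0, "beta_v": 0.0})
    )
    return full, null


def median_param(fits, name: str) -> float:
    return float(np.median([getattr(f.params, name) for f in fits]))
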