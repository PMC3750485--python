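"""Subject-level data containers and vectorized design matrices.

``SubjectData`` is the exchange format between the cohort generator, the
dataset I/O layer and the estimation machinery: one subject's covariates,
dosing events (hours) and observations (hours for drug concentrations,
days for CRP) with censoring flags and occasion labels.  Latent simulation
truth, when present, travels in a side ``truth`` dict and is never read by
the estimators.

``PKDesign``/``PDDesign`` flatten a list of subjects into numpy arrays so
that model predictions for every observation can be computed in one
vectorized pass; both the SAEM fitters and the simulation-based
diagnostics (VPC, NPDE) operate on these.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .models import KA_KE_SWITCH_TOL

PK = "PK"
PD = "PD"


@dataclass
class SubjectData:
    """One subject's covariates, dosing history and observations."""

    subject_id: str
    bw: float
    age: float
    sex: str
    dose_times: np.ndarray      # hours since first dose
    dose_amounts: np.ndarray    # mg
    obs_times: np.ndarray       # hours (PK rows) or days (PD rows)
    obs_values: np.ndarray      # mg/L
    obs_types: np.ndarray       # "PK" | "PD"
    obs_cens: np.ndarray        # bool, left-censored at lloq
    obs_lloq: np.ndarray        # mg/L (nan when not censored)
    obs_occ: np.ndarray         # occasion index (int, 1-based)
    truth: dict | None = None   # latent simulation truth; never fitted

    def __post_init__(self) -> None:
        self.dose_times = np.asarray(self.dose_times, dtype=float)
        self.dose_amounts = np.asarray(self.dose_amounts, dtype=float)
        self.obs_times = np.asarray(self.obs_times, dtype=float)
        self.obs_values = np.asarray(self.obs_values, dtype=float)
        self.obs_types = np.asarray(self.obs_types, dtype=object)
        self.obs_cens = np.asarray(self.obs_cens, dtype=bool)
        self.obs_lloq = np.asarray(self.obs_lloq, dtype=float)
        self.obs_occ = np.asarray(self.obs_occ, dtype=int)
        if not self.bw > 0:
            raise ValueError(f"subject {self.subject_id}: bodyweight must be positive")
        if np.any(self.dose_amounts < 0):
            raise ValueError(f"subject {self.subject_id}: negative dose amount")
        if np.any(np.diff(self.dose_times) < 0):
            raise ValueError(f"subject {self.subject_id}: dose times not sorted")
        if np.any(self.obs_cens & ~np.isfinite(self.obs_lloq)):
            raise ValueError(
                f"subject {self.subject_id}: censored observation without an LLOQ"
            )

    def mask(self, obs_type: str) -> np.ndarray:
        return self.obs_types == obs_type

    @property
    def daily_dose(self) -> float:
        """Administered dose rate in mg/day, assuming a regular schedule."""
        if self.dose_times.size == 0:
            return 0.0
        if self.dose_times.size == 1:
            return float(self.dose_amounts[0])
        tau = float(np.median(np.diff(self.dose_times)))
        return float(np.median(self.dose_amounts) * 24.0 / tau)


def dataset_fingerprint(subjects: list[SubjectData]) -> str:
    """Stable digest of ids, observation times and values (truth excluded)."""
    h = hashlib.sha256()
    for s in subjects:
        h.update(str(s.subject_id).encode())
        for arr in (s.obs_times, s.obs_values, s.dose_times, s.dose_amounts):
            h.update(np.round(np.asarray(arr, dtype=float), 9).tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# PK design matrix
# ---------------------------------------------------------------------------

@dataclass
class PKDesign:
    """Flattened PK observations with padded dose-history matrices."""

    n_subj: int
    subject_ids: list[str]
    bw: np.ndarray            # (n_subj,)
    x: np.ndarray             # (n_subj,) log(bw/70)
    subj_idx: np.ndarray      # (n_obs,) observation -> subject
    occ_idx: np.ndarray       # (n_obs,) observation -> global occasion
    occ_subj: np.ndarray      # (n_occ,) global occasion -> subject
    n_occ: int
    y: np.ndarray             # (n_obs,) observed concentration (lloq if censored)
    cens: np.ndarray          # (n_obs,) bool
    lloq: np.ndarray          # (n_obs,)
    u: np.ndarray             # (n_obs, dmax) time since each prior dose (h)
    amt: np.ndarray           # (n_obs, dmax) dose amounts
    dose_mask: np.ndarray     # (n_obs, dmax) valid-dose mask

    @property
    def n_obs(self) -> int:
        return self.y.size

    def predict(self, cl_obs: np.ndarray, v_obs: np.ndarray, ka: float) -> np.ndarray:
        """Concentration for every observation given per-observation CL, V.

        Superposes the one-compartment first-order-absorption solution over
        each observation's full dose history (each observation uses the V of
        its own occasion for the whole history; with a ~7 h half-life the
        contribution of earlier occasions is negligible).
        """
        ke = (cl_obs / v_obs)[:, None]
        diff = ka - ke
        degen = np.abs(diff) < KA_KE_SWITCH_TOL * ka
        safe = np.where(degen, 1.0, diff)
        e_ke = np.exp(-ke * self.u)
        e_ka = np.exp(-ka * self.u)
        per_dose = self.amt * ka / (v_obs[:, None] * safe) * (e_ke - e_ka)
        limit = self.amt * ka * self.u * e_ka / v_obs[:, None]
        per_dose = np.where(degen, limit, per_dose)
        return np.maximum((per_dose * self.dose_mask).sum(axis=1), 0.0)


def build_pk_design(subjects: list[SubjectData]) -> PKDesign:
    subs = [s for s in subjects if np.any(s.mask(PK))]
    if not subs:
        raise ValueError("dataset contains no PK observations")
    if any(s.dose_times.size == 0 for s in subs):
        bad = [s.subject_id for s in subs if s.dose_times.size == 0]
        raise ValueError(f"subjects without dosing records: {bad}")
    dmax = 1
    rows: list[tuple] = []
    occ_key_to_idx: dict[tuple, int] = {}
    occ_subj: list[int] = []
    for i, s in enumerate(subs):
        m = s.mask(PK)
        for t, yv, cv, lq, occ in zip(
            s.obs_times[m], s.obs_values[m], s.obs_cens[m], s.obs_lloq[m], s.obs_occ[m]
        ):
            prior = s.dose_times <= t + 1e-9
            dmax = max(dmax, int(prior.sum()))
            key = (i, int(occ))
            if key not in occ_key_to_idx:
                occ_key_to_idx[key] = len(occ_subj)
                occ_subj.append(i)
            rows.append((i, occ_key_to_idx[key], t, yv, cv, lq, prior))
    n_obs = len(rows)
    u = np.zeros((n_obs, dmax))
    amt = np.zeros((n_obs, dmax))
    mask = np.zeros((n_obs, dmax), dtype=bool)
    subj_idx = np.zeros(n_obs, dtype=int)
    occ_idx = np.zeros(n_obs, dtype=int)
    y = np.zeros(n_obs)
    cens = np.zeros(n_obs, dtype=bool)
    lloq = np.full(n_obs, np.nan)
    for j, (i, oc, t, yv, cv, lq, prior) in enumerate(rows):
        s = subs[i]
        nd = int(prior.sum())
        u[j, :nd] = t - s.dose_times[prior]
        amt[j, :nd] = s.dose_amounts[prior]
        mask[j, :nd] = True
        subj_idx[j] = i
        occ_idx[j] = oc
        y[j] = yv
        cens[j] = cv
        lloq[j] = lq
    bw = np.array([s.bw for s in subs])
    return PKDesign(
        n_subj=len(subs),
        subject_ids=[s.subject_id for s in subs],
        bw=bw,
        x=np.log(bw / 70.0),
        subj_idx=subj_idx,
        occ_idx=occ_idx,
        occ_subj=np.asarray(occ_subj, dtype=int),
        n_occ=len(occ_subj),
        y=y,
        cens=cens,
        lloq=lloq,
        u=u,
        amt=amt,
        dose_mask=mask,
    )


# ---------------------------------------------------------------------------
# PD design matrix
# ---------------------------------------------------------------------------

@dataclass
class PDDesign:
    """Flattened CRP observations with per-subject constant exposure."""

    n_subj: int
    subject_ids: list[str]
    bw: np.ndarray
    daily_dose: np.ndarray    # (n_subj,) mg/day
    css: np.ndarray           # (n_subj,) mg/L, from the PK stage
    subj_idx: np.ndarray      # (n_obs,)
    t: np.ndarray             # (n_obs,) days since treatment start
    ylog: np.ndarray          # (n_obs,) log10 observed CRP
    first_obs: np.ndarray     # (n_subj,) index of each subject's earliest obs

    @property
    def n_obs(self) -> int:
        return self.ylog.size


def build_pd_design(subjects: list[SubjectData], cl_by_subject: dict[str, float]) -> PDDesign:
    subs = [s for s in subjects if np.any(s.mask(PD))]
    if not subs:
        raise ValueError("dataset contains no PD observations")
    missing = [s.subject_id for s in subs if s.subject_id not in cl_by_subject]
    if missing:
        raise ValueError(f"no clearance supplied for subjects: {missing}")
    subj_idx, t, ylog = [], [], []
    for i, s in enumerate(subs):
        m = s.mask(PD)
        if np.any(s.obs_values[m] <= 0):
            raise ValueError(f"subject {s.subject_id}: non-positive CRP observation")
        subj_idx.extend([i] * int(m.sum()))
        t.extend(s.obs_times[m])
        ylog.extend(np.log10(s.obs_values[m]))
    subj_idx = np.asarray(subj_idx, dtype=int)
    t = np.asarray(t, dtype=float)
    ylog = np.asarray(ylog, dtype=float)
    daily = np.array([s.daily_dose for s in subs])
    cl = np.array([cl_by_subject[s.subject_id] for s in subs])
    first = np.zeros(len(subs), dtype=int)
    for i in range(len(subs)):
        idx = np.flatnonzero(subj_idx == i)
        first[i] = idx[np.argmin(t[idx])]
    return PDDesign(
        n_subj=len(subs),
        subject_ids=[s.subject_id for s in subs],
        bw=np.array([s.bw for s in subs]),
        daily_dose=daily,
        css=daily / (24.0 * cl),
        subj_idx=subj_idx,
        t=t,
        ylog=ylog,
        first_obs=first,
    )
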