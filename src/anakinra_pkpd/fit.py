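"""SAEM estimation of the population PK and PD models.

Maximum-likelihood estimation of nonlinear mixed-effects models by
stochastic approximation EM with MCMC sampling of the individual random
effects (and, for the PD model, of the latent responder/resistant class),
without any linearization of the model.  The two stages run sequentially:
the PK model is fitted first and its individual clearances define each
subject's constant steady-state exposure for the CRP stage.

Implementation outline
----------------------
* Latent variables: per-subject log CL (between-subject), per-occasion
  log V (between-occasion) for PK; mixture label, log baseline (resistance
  class) and log turnover rate for PD.  Left-censored concentrations are
  treated as additional latent variables and Gibbs-imputed from the
  truncated residual distribution, which is equivalent to integrating the
  normal left tail below the LOQ into the likelihood (the M3 convention);
  the reported log-likelihood uses the exact left-tail probability.
* E-step: Metropolis-within-Gibbs transitions per subject/occasion — one
  independent proposal from the population prior plus adaptive random-walk
  proposals — run on ``n_chains`` parallel chains.
* M-step: the Gaussian-linear parts (allometric regressions of log CL and
  log V on log bodyweight, random-effect variances, residual variance and
  the mixture proportion) are exact exponential-family updates of
  stochastically averaged sufficient statistics; fixed effects that enter
  the mean nonlinearly and carry no random effect (ka; r0_resp, c50,
  k_resi) are updated by conditional least squares on the current latent
  draws with the same stochastic-approximation damping.  Variance updates
  are annealed (kept from collapsing) during the exploration phase.
* Likelihood: per-subject importance sampling around the conditional
  posterior (Student-t proposals built from a post-fit conditional
  sampling pass); for the PD mixture, the class is marginalized exactly,
  which also yields each subject's posterior responder probability.
* Standard errors: per-subject score vectors by central finite differences
  of the subject importance-sampling log-likelihoods with common random
  numbers; the Fisher information is approximated by the sum of score
  outer products.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from types import SimpleNamespace

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, logit, logsumexp, ndtr, ndtri
from scipy.stats import chi2, norm, t as student_t

from .data import (
    PD,
    PK,
    SubjectData,
    build_pd_design,
    build_pk_design,
    dataset_fingerprint,
)
from .models import PopPDParams, PopPKParams, RESI, RESP, _crp_values, allometric_value

__all__ = [
    "SaemSettings",
    "FitResult",
    "ModelComparison",
    "fit_pk",
    "fit_pd",
    "compare_models",
    "default_pk_init",
    "default_pd_init",
    "pk_marginal_loglik",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class SaemSettings:
    """SAEM run configuration.

    Two phases: ``n_burnin`` exploration iterations (step size 1, annealed
    variances) and ``n_smooth`` smoothing iterations (step size
    ``1/(k - n_burnin)``).  ``fix`` maps parameter names (natural scale,
    e.g. ``{"beta_cl": 0.0}``) to values held constant during estimation —
    the mechanism behind the covariate-free comparison model and the
    single-class PD fit (``{"p_resp": 1.0}``).
    """

    n_burnin: int = 300
    n_smooth: int = 100
    n_chains: int = 2
    rw_transitions: int = 2
    seed: int = 1234
    fix: dict = field(default_factory=dict)
    compute_se: bool = True
    ll_draws: int = 300
    eb_transitions: int = 300
    eb_keep: int = 150
    annealing: float = 0.95

    def __post_init__(self) -> None:
        if self.n_burnin < 1 or self.n_smooth < 1 or self.n_chains < 1:
            raise ValueError("iteration and chain counts must be positive")


@dataclass
class FitResult:
    """Population fit output: estimates, uncertainty, fit metrics, posteriors."""

    model: str                      # "pk" | "pd"
    params: PopPKParams | PopPDParams
    rse: dict                       # relative standard errors, % of estimate
    minus2ll: float
    aic: float
    bic: float
    n_params: int
    n_subjects: int
    trace: pd.DataFrame             # per-iteration parameter trajectory
    eb: pd.DataFrame                # per-subject empirical-Bayes summaries
    eb_occ: pd.DataFrame | None
    posterior_resp: pd.Series | None
    converged: bool
    flags: list
    seed: int
    n_iter: tuple
    fingerprint: str

    def summary(self) -> str:
        """Plain-text estimate table (estimate + RSE%)."""
        lines = [f"{'Parameter':<16}{'Estimate':>12}{'RSE (%)':>10}"]
        for name, val in vars(self.params).items():
            if name == "loq":
                continue
            rse = self.rse.get(name, float("nan"))
            rse_s = f"{rse:.0f}" if np.isfinite(rse) else "-"
            lines.append(f"{name:<16}{val:>12.4g}{rse_s:>10}")
        lines.append(
            f"-2LL {self.minus2ll:.2f}  AIC {self.aic:.2f}  BIC {self.bic:.2f}"
            f"  (p={self.n_params}, N={self.n_subjects})"
        )
        if self.flags:
            lines.append("flags: " + "; ".join(self.flags))
        return "\n".join(lines)


@dataclass(frozen=True)
class ModelComparison:
    """AIC/BIC deltas and, for nested fits, the likelihood-ratio test."""

    delta_aic: float
    delta_bic: float
    lrt_stat: float | None
    lrt_df: int | None
    lrt_pvalue: float | None


def compare_models(fit_a: FitResult, fit_b: FitResult, nested: bool = False) -> ModelComparison:
    """Compare two fits of the same dataset.

    Deltas are ``fit_a - fit_b`` (negative favors ``fit_a``).  With
    ``nested=True`` the fit with fewer parameters is taken as the null and
    the LRT statistic is the difference of the two -2LL values, referred to
    a chi-square with df = difference in parameter count.
    """
    if fit_a.fingerprint != fit_b.fingerprint:
        raise ValueError("fits were obtained on different datasets")
    out = ModelComparison(
        delta_aic=fit_a.aic - fit_b.aic,
        delta_bic=fit_a.bic - fit_b.bic,
        lrt_stat=None,
        lrt_df=None,
        lrt_pvalue=None,
    )
    if nested:
        null, alt = (
            (fit_a, fit_b) if fit_a.n_params <= fit_b.n_params else (fit_b, fit_a)
        )
        stat = max(null.minus2ll - alt.minus2ll, 0.0)
        df = alt.n_params - null.n_params
        pval = float(chi2.sf(stat, df)) if df > 0 else float("nan")
        out = replace(out, lrt_stat=stat, lrt_df=df, lrt_pvalue=pval)
    return out


# ---------------------------------------------------------------------------
# naive initial estimates
# ---------------------------------------------------------------------------

def default_pk_init(subjects: list[SubjectData]) -> PopPKParams:
    """Naive pooled initial values for the PK model.

    Per-subject clearance from the steady-state relation dose rate /
    (24 * mean concentration), then a log-log regression on bodyweight for
    the typical value and exponent; V from a nominal elimination rate of
    0.1 1/h; ka started at 0.5 1/h.
    """
    cls, xs, lloqs = [], [], []
    for s in subjects:
        m = s.mask(PK)
        if not np.any(m) or s.daily_dose <= 0:
            continue
        keep = m & ~s.obs_cens
        vals = s.obs_values[keep]
        lloqs.extend(s.obs_lloq[m][np.isfinite(s.obs_lloq[m])])
        if vals.size == 0 or np.mean(vals) <= 0:
            continue
        cls.append(s.daily_dose / (24.0 * np.mean(vals)))
        xs.append(math.log(s.bw / 70.0))
    loq = float(np.median(lloqs)) if lloqs else 0.04
    if len(cls) >= 3 and np.ptp(xs) > 1e-6:
        slope, intercept = np.polyfit(xs, np.log(cls), 1)
        beta_cl = float(np.clip(slope, 0.0, 1.5))
        tv_cl = float(np.exp(intercept))
    elif cls:
        tv_cl, beta_cl = float(np.exp(np.mean(np.log(cls)))), 0.75
    else:
        tv_cl, beta_cl = 5.0, 0.75
    tv_cl = float(np.clip(tv_cl, 1e-3, 1e3))
    return PopPKParams(
        tv_cl=tv_cl,
        beta_cl=beta_cl,
        tv_v=tv_cl / 0.1,
        beta_v=1.0,
        ka=0.5,
        omega_cl=0.3,
        gamma_v=0.3,
        sigma_add=0.1,
        loq=loq,
    )


def default_pd_init(subjects: list[SubjectData]) -> PopPDParams:
    """Naive initial values for the CRP mixture model.

    Subjects are provisionally split at the geometric-mean baseline CRP:
    the high-baseline group seeds the responder baseline, the low-baseline
    group the resistance baseline and the split fraction the mixture
    proportion.
    """
    base = []
    for s in subjects:
        m = s.mask(PD)
        if np.any(m):
            i = np.argmin(s.obs_times[m])
            base.append(s.obs_values[m][i])
    base = np.asarray(base, dtype=float)
    base = base[base > 0]
    if base.size == 0:
        raise ValueError("dataset contains no CRP observations")
    thr = float(np.exp(np.mean(np.log(base))))
    high, low = base[base >= thr], base[base < thr]
    r0_resp = float(np.median(high)) if high.size else float(np.median(base) * 2)
    r0_resi = float(np.median(low)) if low.size else float(np.median(base) / 2)
    p0 = float(np.clip(high.size / base.size, 0.1, 0.9))
    return PopPDParams(
        r0_resp=max(r0_resp, 1.0),
        r0_resi=max(r0_resi, 1.0),
        k_tr=0.03,
        c50=0.05,
        k_resi=0.01,
        p_resp=p0,
        omega_r0_resi=0.5,
        omega_ktr=0.5,
        sigma_pd=0.2,
    )


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _step_size(k: int, n_burnin: int) -> float:
    return 1.0 if k <= n_burnin else 1.0 / (k - n_burnin)


def _trunc_normal_below(rng, upper, loc, scale):
    """Draw from N(loc, scale^2) truncated above at ``upper`` (vectorized)."""
    p_hi = np.clip(ndtr((upper - loc) / scale), 1e-300, 1.0)
    u = np.clip(rng.random(np.shape(loc)) * p_hi, 1e-300, 1.0)
    return loc + scale * np.clip(ndtri(u), -37.0, 37.0)


def _solve_allometric(n, sx, sxx, s1, s2, fix_mu, fix_beta):
    """Least-squares intercept/slope of latent log-params on log(BW/70)."""
    if fix_mu is not None and fix_beta is not None:
        return fix_mu, fix_beta
    if fix_beta is not None:
        return (s1 - fix_beta * sx) / n, fix_beta
    if fix_mu is not None:
        return fix_mu, (s2 - fix_mu * sx) / max(sxx, 1e-12)
    det = n * sxx - sx * sx
    if abs(det) < 1e-12:
        return s1 / n, 0.0
    mu = (sxx * s1 - sx * s2) / det
    beta = (n * s2 - sx * s1) / det
    return mu, beta


def _variance_update(prev, hat, gamma_anneal, annealing):
    hat = max(hat, 1e-10)
    if annealing is not None:
        hat = max(hat, annealing * prev)
    return hat


def _is_proposal(rng, loc, scale, m, df=5):
    """Student-t importance draws and their log-density, shape (m, *loc.shape)."""
    scale = np.maximum(scale, 1e-8)
    draws = loc + scale * rng.standard_t(df, size=(m,) + np.shape(loc))
    logq = student_t.logpdf((draws - loc) / scale, df) - np.log(scale)
    return draws, logq


# ---------------------------------------------------------------------------
# PK stage
# ---------------------------------------------------------------------------

class _PKTheta(SimpleNamespace):
    pass


def _pk_theta_from(params: PopPKParams) -> _PKTheta:
    return _PKTheta(
        mu_cl=math.log(params.tv_cl),
        beta_cl=params.beta_cl,
        mu_v=math.log(params.tv_v),
        beta_v=params.beta_v,
        log_ka=math.log(params.ka),
        omega2=params.omega_cl**2,
        gamma2=params.gamma_v**2,
        sigma2=params.sigma_add**2,
        loq=params.loq,
    )


def _pk_theta_to_params(th: _PKTheta) -> PopPKParams:
    return PopPKParams(
        tv_cl=math.exp(th.mu_cl),
        beta_cl=th.beta_cl,
        tv_v=math.exp(th.mu_v),
        beta_v=th.beta_v,
        ka=math.exp(th.log_ka),
        omega_cl=math.sqrt(max(th.omega2, 0.0)),
        gamma_v=math.sqrt(max(th.gamma2, 0.0)),
        sigma_add=math.sqrt(max(th.sigma2, 0.0)),
        loq=th.loq,
    )


_PK_FIX_SETTERS = {
    "tv_cl": lambda th, v: setattr(th, "mu_cl", math.log(v)),
    "beta_cl": lambda th, v: setattr(th, "beta_cl", float(v)),
    "tv_v": lambda th, v: setattr(th, "mu_v", math.log(v)),
    "beta_v": lambda th, v: setattr(th, "beta_v", float(v)),
    "ka": lambda th, v: setattr(th, "log_ka", math.log(v)),
    "omega_cl": lambda th, v: setattr(th, "omega2", float(v) ** 2),
    "gamma_v": lambda th, v: setattr(th, "gamma2", float(v) ** 2),
    "sigma_add": lambda th, v: setattr(th, "sigma2", float(v) ** 2),
}

_PK_PARAM_NAMES = list(_PK_FIX_SETTERS)


def _apply_pk_fix(th: _PKTheta, fix: dict) -> None:
    for name, val in fix.items():
        if name not in _PK_FIX_SETTERS:
            raise ValueError(f"unknown PK parameter in fix: {name!r}")
        _PK_FIX_SETTERS[name](th, val)


def _pk_prior_means(th, design):
    return th.mu_cl + th.beta_cl * design.x, th.mu_v + th.beta_v * design.x[design.occ_subj]


def _pk_pred(design, z, w, ka):
    return design.predict(np.exp(z)[design.subj_idx], np.exp(w)[design.occ_idx], ka)


def _pk_sweep(ch, design, th, rng, adapt: bool) -> None:
    """One Metropolis-within-Gibbs sweep over censored values, z and w."""
    sigma = math.sqrt(th.sigma2)
    ka = math.exp(th.log_ka)
    mz, mw = _pk_prior_means(th, design)
    cens = design.cens

    if cens.any():
        ch["y"][cens] = _trunc_normal_below(
            rng, design.lloq[cens], ch["pred"][cens], sigma
        )

    def resid_ll(pred):
        return -0.5 * ((ch["y"] - pred) / sigma) ** 2

    def subj_sum(vals):
        return np.bincount(design.subj_idx, weights=vals, minlength=design.n_subj)

    def occ_sum(vals):
        return np.bincount(design.occ_idx, weights=vals, minlength=design.n_occ)

    def try_z(z_prop, extra_cur, extra_prop):
        pred_prop = _pk_pred(design, z_prop, ch["w"], ka)
        delta = subj_sum(resid_ll(pred_prop)) - subj_sum(resid_ll(ch["pred"]))
        delta += extra_prop - extra_cur
        acc = np.log(rng.random(design.n_subj)) < delta
        ch["z"] = np.where(acc, z_prop, ch["z"])
        ch["pred"] = np.where(acc[design.subj_idx], pred_prop, ch["pred"])
        return acc.mean()

    def try_w(w_prop, extra_cur, extra_prop):
        pred_prop = _pk_pred(design, ch["z"], w_prop, ka)
        delta = occ_sum(resid_ll(pred_prop)) - occ_sum(resid_ll(ch["pred"]))
        delta += extra_prop - extra_cur
        acc = np.log(rng.random(design.n_occ)) < delta
        ch["w"] = np.where(acc, w_prop, ch["w"])
        ch["pred"] = np.where(acc[design.occ_idx], pred_prop, ch["pred"])
        return acc.mean()

    zero = 0.0
    if th.omega2 > 0:
        # independent proposal from the population prior
        z_prop = mz + math.sqrt(th.omega2) * rng.standard_normal(design.n_subj)
        try_z(z_prop, zero, zero)
        for _ in range(ch["n_rw"]):
            z_prop = ch["z"] + ch["dz"] * rng.standard_normal(design.n_subj)
            rate = try_z(
                z_prop,
                -0.5 * (ch["z"] - mz) ** 2 / th.omega2,
                -0.5 * (z_prop - mz) ** 2 / th.omega2,
            )
            if adapt:
                ch["dz"] = float(np.clip(ch["dz"] * math.exp(0.4 * (rate - 0.3)), 1e-3, 5.0))
    else:
        ch["z"] = mz.copy()
        ch["pred"] = _pk_pred(design, ch["z"], ch["w"], ka)

    if th.gamma2 > 0:
        w_prop = mw + math.sqrt(th.gamma2) * rng.standard_normal(design.n_occ)
        try_w(w_prop, zero, zero)
        for _ in range(ch["n_rw"]):
            w_prop = ch["w"] + ch["dw"] * rng.standard_normal(design.n_occ)
            rate = try_w(
                w_prop,
                -0.5 * (ch["w"] - mw) ** 2 / th.gamma2,
                -0.5 * (w_prop - mw) ** 2 / th.gamma2,
            )
            if adapt:
                ch["dw"] = float(np.clip(ch["dw"] * math.exp(0.4 * (rate - 0.3)), 1e-3, 5.0))
    else:
        ch["w"] = mw.copy()
        ch["pred"] = _pk_pred(design, ch["z"], ch["w"], ka)


def _pk_subject_ll_matrix(design, th, z_draws, w_draws):
    """Observed-data log-likelihood terms per (draw, subject).

    Censored observations contribute the exact normal left-tail probability
    below their LOQ.  Returns (m, n_subj) log p(y_i | latent draw).
    """
    sigma = math.sqrt(th.sigma2)
    ka = math.exp(th.log_ka)
    m = z_draws.shape[0]
    out = np.empty((m, design.n_subj))
    cens = design.cens
    for i in range(m):
        pred = _pk_pred(design, z_draws[i], w_draws[i], ka)
        res = (design.y - pred) / sigma
        ll = -0.5 * res**2 - math.log(sigma) - 0.5 * _LOG_2PI
        if cens.any():
            tail = np.log(np.clip(ndtr((design.lloq[cens] - pred[cens]) / sigma), 1e-300, 1.0))
            ll[cens] = tail
        out[i] = np.bincount(design.subj_idx, weights=ll, minlength=design.n_subj)
    return out


def _pk_importance_ll(design, th, prop, rng, n_draws):
    """Per-subject IS log-likelihood and the draws used (for the scores)."""
    z_loc, z_sd, w_loc, w_sd = prop
    if th.omega2 > 0:
        z_draws, z_logq = _is_proposal(rng, z_loc, np.maximum(z_sd, 0.05) * 1.3, n_draws)
    else:
        mz, _ = _pk_prior_means(th, design)
        z_draws = np.tile(mz, (n_draws, 1))
        z_logq = np.zeros_like(z_draws)
    if th.gamma2 > 0:
        w_draws, w_logq = _is_proposal(rng, w_loc, np.maximum(w_sd, 0.05) * 1.3, n_draws)
    else:
        _, mw = _pk_prior_means(th, design)
        w_draws = np.tile(mw, (n_draws, 1))
        w_logq = np.zeros_like(w_draws)
    ll = _pk_ll_from_draws(design, th, z_draws, w_draws, z_logq, w_logq)
    return ll, (z_draws, w_draws, z_logq, w_logq)


def _pk_ll_from_draws(design, th, z_draws, w_draws, z_logq, w_logq):
    mz, mw = _pk_prior_means(th, design)
    lw = _pk_subject_ll_matrix(design, th, z_draws, w_draws)
    if th.omega2 > 0:
        lw += norm.logpdf(z_draws, mz, math.sqrt(th.omega2)) - z_logq
    if th.gamma2 > 0:
        wq = norm.logpdf(w_draws, mw, math.sqrt(th.gamma2)) - w_logq
        # occasion terms roll up to their subject
        for i in range(w_draws.shape[0]):
            lw[i] += np.bincount(design.occ_subj, weights=wq[i], minlength=design.n_subj)
    return logsumexp(lw, axis=0) - math.log(z_draws.shape[0])


def fit_pk(
    dataset: list[SubjectData],
    init: PopPKParams | None = None,
    settings: SaemSettings | None = None,
) -> FitResult:
    """Fit the allometric one-compartment PK model by SAEM.

    Estimates tv_cl, beta_cl, tv_v, beta_v, ka, omega_cl, gamma_v and
    sigma_add (any subset can be held fixed via ``settings.fix``).
    Left-censored observations enter through the exact left-tail
    likelihood.  Non-convergence and non-identifiability are flagged on
    the result, not raised.
    """
    settings = settings or SaemSettings()
    init = init or default_pk_init(dataset)
    design = build_pk_design(dataset)
    fingerprint = dataset_fingerprint(dataset)
    rng = np.random.default_rng(settings.seed)
    th = _pk_theta_from(init)
    _apply_pk_fix(th, settings.fix)
    flags: list[str] = []

    n_free = len(_PK_PARAM_NAMES) - len([k for k in settings.fix if k in _PK_FIX_SETTERS])

    if design.cens.all():
        flags.append("non-identifiable: all observations are left-censored")
        empty = pd.DataFrame()
        return FitResult(
            model="pk", params=init, rse={}, minus2ll=float("nan"),
            aic=float("nan"), bic=float("nan"), n_params=n_free,
            n_subjects=design.n_subj, trace=empty, eb=empty, eb_occ=None,
            posterior_resp=None, converged=False, flags=flags,
            seed=settings.seed, n_iter=(settings.n_burnin, settings.n_smooth),
            fingerprint=fingerprint,
        )

    # chain state
    mz, mw = _pk_prior_means(th, design)
    chains = []
    for _ in range(settings.n_chains):
        z = mz + (0.1 * rng.standard_normal(design.n_subj) if th.omega2 > 0 else 0.0)
        w = mw + (0.1 * rng.standard_normal(design.n_occ) if th.gamma2 > 0 else 0.0)
        y = design.y.copy()
        y[design.cens] = design.lloq[design.cens] * 0.5
        chains.append(
            {
                "z": z, "w": w, "y": y,
                "pred": _pk_pred(design, z, w, math.exp(th.log_ka)),
                "dz": 0.3, "dw": 0.3, "n_rw": settings.rw_transitions,
            }
        )

    sx, sxx = design.x.sum(), (design.x**2).sum()
    x_occ = design.x[design.occ_subj]
    sxo, sxxo = x_occ.sum(), (x_occ**2).sum()
    S = dict.fromkeys(["z", "zx", "zz", "w", "wx", "ww", "rss"], 0.0)
    n_iter = settings.n_burnin + settings.n_smooth
    trace_rows = []

    for k in range(1, n_iter + 1):
        gamma = _step_size(k, settings.n_burnin)
        anneal = settings.annealing if k <= settings.n_burnin else None
        for ch in chains:
            _pk_sweep(ch, design, th, rng, adapt=k <= settings.n_burnin)

        # --- conditional least squares for fixed effects without a live
        # random effect: always ka; also the CL (resp. V) typical value and
        # exponent when their variability is held at zero, since the latent
        # regression then carries no information about them ---
        direct: list[str] = []
        if "ka" not in settings.fix:
            direct.append("log_ka")
        if th.omega2 == 0.0:
            if "tv_cl" not in settings.fix:
                direct.append("mu_cl")
            if "beta_cl" not in settings.fix:
                direct.append("beta_cl")
        if th.gamma2 == 0.0:
            if "tv_v" not in settings.fix:
                direct.append("mu_v")
            if "beta_v" not in settings.fix:
                direct.append("beta_v")
        if direct:
            def rss_of(vec):
                t2 = _PKTheta(**vars(th))
                for name, val in zip(direct, vec):
                    setattr(t2, name, val)
                mz2, mw2 = _pk_prior_means(t2, design)
                tot = 0.0
                for ch in chains:
                    z = mz2 if t2.omega2 == 0.0 else ch["z"]
                    w = mw2 if t2.gamma2 == 0.0 else ch["w"]
                    pred = _pk_pred(design, z, w, math.exp(t2.log_ka))
                    tot += float(((ch["y"] - pred) ** 2).sum())
                return tot

            x0 = np.array([getattr(th, name) for name in direct])
            if len(direct) == 1:
                res = minimize_scalar(
                    lambda v: rss_of([v]),
                    bounds=(x0[0] - 1.0, x0[0] + 1.0),
                    method="bounded",
                    options={"xatol": 2e-3, "maxiter": 25},
                )
                new = np.array([res.x])
            else:
                res = minimize(rss_of, x0, method="Nelder-Mead",
                               options={"maxiter": 60, "xatol": 1e-4, "fatol": 1e-10})
                new = res.x
            for name, val in zip(direct, new):
                setattr(th, name, getattr(th, name) + gamma * (val - getattr(th, name)))
        ka = math.exp(th.log_ka)

        # --- sufficient statistics (chain-averaged) ---
        stat = dict.fromkeys(S, 0.0)
        for ch in chains:
            ch["pred"] = _pk_pred(design, ch["z"], ch["w"], ka)
            stat["z"] += ch["z"].sum()
            stat["zx"] += (ch["z"] * design.x).sum()
            stat["zz"] += (ch["z"] ** 2).sum()
            stat["w"] += ch["w"].sum()
            stat["wx"] += (ch["w"] * x_occ).sum()
            stat["ww"] += (ch["w"] ** 2).sum()
            stat["rss"] += ((ch["y"] - ch["pred"]) ** 2).sum()
        for key in S:
            S[key] += gamma * (stat[key] / settings.n_chains - S[key])

        # --- exact M-step for the Gaussian-linear parts (only while the
        # corresponding random effect is live; otherwise the direct
        # conditional-LS update above owns these parameters) ---
        fix = settings.fix
        if th.omega2 > 0:
            th.mu_cl, th.beta_cl = _solve_allometric(
                design.n_subj, sx, sxx, S["z"], S["zx"],
                math.log(fix["tv_cl"]) if "tv_cl" in fix else None,
                fix.get("beta_cl"),
            )
        if th.gamma2 > 0:
            th.mu_v, th.beta_v = _solve_allometric(
                design.n_occ, sxo, sxxo, S["w"], S["wx"],
                math.log(fix["tv_v"]) if "tv_v" in fix else None,
                fix.get("beta_v"),
            )
        if "omega_cl" not in fix:
            m = th.mu_cl + th.beta_cl * design.x
            hat = (
                S["zz"] / design.n_subj
                - 2.0 * (th.mu_cl * S["z"] + th.beta_cl * S["zx"]) / design.n_subj
                + float(np.mean(m**2))
            )
            th.omega2 = _variance_update(th.omega2, hat, gamma, anneal)
        if "gamma_v" not in fix:
            m = th.mu_v + th.beta_v * x_occ
            hat = (
                S["ww"] / design.n_occ
                - 2.0 * (th.mu_v * S["w"] + th.beta_v * S["wx"]) / design.n_occ
                + float(np.mean(m**2))
            )
            th.gamma2 = _variance_update(th.gamma2, hat, gamma, anneal)
        if "sigma_add" not in fix:
            th.sigma2 = _variance_update(th.sigma2, S["rss"] / design.n_obs, gamma, anneal)

        p = _pk_theta_to_params(th)
        trace_rows.append({name: getattr(p, name) for name in _PK_PARAM_NAMES})

    trace = pd.DataFrame(trace_rows)
    trace.index.name = "iteration"
    converged = _trace_converged(trace, settings.n_smooth)
    if not converged:
        flags.append("convergence questionable: parameters drifting in smoothing phase")

    # --- conditional sampling pass at the final estimates ---
    keep_from = settings.eb_transitions - settings.eb_keep
    z_samp, w_samp = [], []
    for j in range(settings.eb_transitions):
        for ch in chains:
            _pk_sweep(ch, design, th, rng, adapt=False)
            if j >= keep_from:
                z_samp.append(ch["z"].copy())
                w_samp.append(ch["w"].copy())
    z_samp = np.asarray(z_samp)
    w_samp = np.asarray(w_samp)
    z_mean, z_sd = z_samp.mean(axis=0), z_samp.std(axis=0)
    w_mean, w_sd = w_samp.mean(axis=0), w_samp.std(axis=0)

    ll_subj, draws = _pk_importance_ll(
        design, th, (z_mean, z_sd, w_mean, w_sd), rng, settings.ll_draws
    )
    minus2ll = -2.0 * float(ll_subj.sum())
    aic = minus2ll + 2.0 * n_free
    bic = minus2ll + n_free * math.log(design.n_subj)

    params = _pk_theta_to_params(th)
    mz, mw = _pk_prior_means(th, design)
    eb = pd.DataFrame(
        {
            "subject_id": design.subject_ids,
            "bw": design.bw,
            "eta_cl": z_mean - mz,
            "eta_cl_sd": z_sd,
            "cl": np.exp(z_mean),
        }
    )
    eb_occ = pd.DataFrame(
        {
            "subject_id": [design.subject_ids[i] for i in design.occ_subj],
            "phi_v": w_mean - mw,
            "phi_v_sd": w_sd,
            "v": np.exp(w_mean),
        }
    )

    rse: dict = {name: float("nan") for name in _PK_PARAM_NAMES}
    if settings.compute_se:
        try:
            rse.update(_pk_standard_errors(design, th, draws, settings.fix))
        except Exception as exc:  # pragma: no cover - defensive
            flags.append(f"standard errors unavailable: {exc}")

    return FitResult(
        model="pk", params=params, rse=rse, minus2ll=minus2ll, aic=aic, bic=bic,
        n_params=n_free, n_subjects=design.n_subj, trace=trace, eb=eb,
        eb_occ=eb_occ, posterior_resp=None, converged=converged, flags=flags,
        seed=settings.seed, n_iter=(settings.n_burnin, settings.n_smooth),
        fingerprint=fingerprint,
    )


def _trace_converged(trace: pd.DataFrame, n_smooth: int, tol: float = 0.05) -> bool:
    tail = trace.iloc[-n_smooth:]
    half = len(tail) // 2
    if half < 5:
        return True
    a = tail.iloc[:half].median()
    b = tail.iloc[half:].median()
    denom = np.maximum(np.abs(a), 1e-6)
    return bool((np.abs(b - a) / denom).max() < tol)


def _pk_standard_errors(design, th, draws, fix):
    z_draws, w_draws, z_logq, w_logq = draws
    free = []
    if "tv_cl" not in fix:
        free.append("log_tv_cl")
    if "beta_cl" not in fix:
        free.append("beta_cl")
    if "tv_v" not in fix:
        free.append("log_tv_v")
    if "beta_v" not in fix:
        free.append("beta_v")
    if "ka" not in fix:
        free.append("log_ka")
    if "omega_cl" not in fix and th.omega2 > 0:
        free.append("log_omega_cl")
    if "gamma_v" not in fix and th.gamma2 > 0:
        free.append("log_gamma_v")
    if "sigma_add" not in fix:
        free.append("log_sigma_add")

    def with_perturbation(name, h):
        t2 = _PKTheta(**vars(th))
        if name == "log_tv_cl":
            t2.mu_cl += h
        elif name == "beta_cl":
            t2.beta_cl += h
        elif name == "log_tv_v":
            t2.mu_v += h
        elif name == "beta_v":
            t2.beta_v += h
        elif name == "log_ka":
            t2.log_ka += h
        elif name == "log_omega_cl":
            t2.omega2 *= math.exp(2 * h)
        elif name == "log_gamma_v":
            t2.gamma2 *= math.exp(2 * h)
        elif name == "log_sigma_add":
            t2.sigma2 *= math.exp(2 * h)
        return t2

    h = 1e-3
    scores = np.empty((design.n_subj, len(free)))
    for j, name in enumerate(free):
        lp = _pk_ll_from_draws(design, with_perturbation(name, h), z_draws, w_draws, z_logq, w_logq)
        lm = _pk_ll_from_draws(design, with_perturbation(name, -h), z_draws, w_draws, z_logq, w_logq)
        scores[:, j] = (lp - lm) / (2 * h)
    values = {
        "log_tv_cl": math.exp(th.mu_cl), "beta_cl": th.beta_cl,
        "log_tv_v": math.exp(th.mu_v), "beta_v": th.beta_v,
        "log_ka": math.exp(th.log_ka),
        "log_omega_cl": math.sqrt(th.omega2), "log_gamma_v": math.sqrt(th.gamma2),
        "log_sigma_add": math.sqrt(th.sigma2),
    }
    rse = {}
    fisher = scores.T @ scores
    cov = np.linalg.pinv(fisher)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    for j, name in enumerate(free):
        if name.startswith("log_"):
            rse[name.removeprefix("log_")] = 100.0 * se[j]
        else:
            val = values[name]
            rse[name] = 100.0 * se[j] / abs(val) if val != 0 else float("inf")
    return rse


def pk_marginal_loglik(
    dataset: list[SubjectData],
    params: PopPKParams,
    n_mc: int = 2000,
    seed: int = 0,
) -> float:
    """Monte-Carlo marginal log-likelihood under the PK model.

    Plain prior sampling of the random effects (no importance proposal),
    intended as an independent likelihood oracle for small datasets and for
    grid searches; censored observations contribute the exact left-tail
    probability.
    """
    design = build_pk_design(dataset)
    th = _pk_theta_from(params)
    rng = np.random.default_rng(seed)
    mz, mw = _pk_prior_means(th, design)
    z = mz + math.sqrt(th.omega2) * rng.standard_normal((n_mc, design.n_subj))
    w = mw + math.sqrt(th.gamma2) * rng.standard_normal((n_mc, design.n_occ))
    lw = _pk_subject_ll_matrix(design, th, z, w)
    return float((logsumexp(lw, axis=0) - math.log(n_mc)).sum())


# ---------------------------------------------------------------------------
# PD stage
# ---------------------------------------------------------------------------

class _PDTheta(SimpleNamespace):
    pass


def _pd_theta_from(params: PopPDParams) -> _PDTheta:
    return _PDTheta(
        log_r0_resp=math.log(params.r0_resp),
        mu_r0=math.log(params.r0_resi),
        mu_ktr=math.log(params.k_tr),
        log_c50=math.log(params.c50),
        log_kresi=math.log(params.k_resi),
        p=params.p_resp,
        omega_r0_2=params.omega_r0_resi**2,
        omega_ktr_2=params.omega_ktr**2,
        sigma2=params.sigma_pd**2,
    )


def _pd_theta_to_params(th: _PDTheta) -> PopPDParams:
    return PopPDParams(
        r0_resp=math.exp(th.log_r0_resp),
        r0_resi=math.exp(th.mu_r0),
        k_tr=math.exp(th.mu_ktr),
        c50=math.exp(th.log_c50),
        k_resi=math.exp(th.log_kresi),
        p_resp=min(max(th.p, 0.0), 1.0),
        omega_r0_resi=math.sqrt(max(th.omega_r0_2, 0.0)),
        omega_ktr=math.sqrt(max(th.omega_ktr_2, 0.0)),
        sigma_pd=math.sqrt(max(th.sigma2, 0.0)),
    )


_PD_FIX_SETTERS = {
    "r0_resp": lambda th, v: setattr(th, "log_r0_resp", math.log(v)),
    "r0_resi": lambda th, v: setattr(th, "mu_r0", math.log(v)),
    "k_tr": lambda th, v: setattr(th, "mu_ktr", math.log(v)),
    "c50": lambda th, v: setattr(th, "log_c50", math.log(v)),
    "k_resi": lambda th, v: setattr(th, "log_kresi", math.log(v)),
    "p_resp": lambda th, v: setattr(th, "p", float(v)),
    "omega_r0_resi": lambda th, v: setattr(th, "omega_r0_2", float(v) ** 2),
    "omega_ktr": lambda th, v: setattr(th, "omega_ktr_2", float(v) ** 2),
    "sigma_pd": lambda th, v: setattr(th, "sigma2", float(v) ** 2),
}

_PD_PARAM_NAMES = list(_PD_FIX_SETTERS)


def _pd_curve_log10(design, r0_obs, ktr_obs, resp_obs, c50, kresi):
    """log10 CRP predictions for every observation, both classes merged."""
    ns = SimpleNamespace(c50=c50, k_resi=kresi)
    resp = _crp_values(design.t, design.css[design.subj_idx], r0_obs, ktr_obs, ns, RESP)
    resi = _crp_values(design.t, design.css[design.subj_idx], r0_obs, ktr_obs, ns, RESI)
    crp = np.where(resp_obs, resp, resi)
    return np.log10(np.maximum(crp, 1e-12))


def _pd_pred(design, th, g, u, v):
    r0_obs = np.where(g, math.exp(th.log_r0_resp), np.exp(u))[design.subj_idx]
    ktr_obs = np.exp(v)[design.subj_idx]
    return _pd_curve_log10(
        design, r0_obs, ktr_obs, g[design.subj_idx],
        math.exp(th.log_c50), math.exp(th.log_kresi),
    )


def _pd_class_ll(design, th, u, v, as_resp: bool):
    """Per-subject residual log-likelihood forcing every subject's class."""
    g = np.full(design.n_subj, as_resp)
    pred = _pd_pred(design, th, g, u, v)
    sigma = math.sqrt(th.sigma2)
    ll = -0.5 * ((design.ylog - pred) / sigma) ** 2 - math.log(sigma) - 0.5 * _LOG_2PI
    return np.bincount(design.subj_idx, weights=ll, minlength=design.n_subj)


def _pd_sweep(ch, design, th, rng, adapt: bool, single_class: bool) -> None:
    sigma_r0 = math.sqrt(max(th.omega_r0_2, 1e-12))
    sigma_ktr = math.sqrt(max(th.omega_ktr_2, 1e-12))

    if not single_class:
        # exact Gibbs draw of the latent class given the random effects
        ll_resp = _pd_class_ll(design, th, ch["u"], ch["v"], True)
        ll_resi = _pd_class_ll(design, th, ch["u"], ch["v"], False)
        p = np.clip(th.p, 1e-6, 1.0 - 1e-6)
        log_odds = math.log(p) - math.log1p(-p) + ll_resp - ll_resi
        uu = rng.random(design.n_subj)
        ch["g"] = (np.log(uu) - np.log1p(-uu)) < log_odds
        # a responder's baseline latent is prior-only: refresh from the prior
        n_resp = int(ch["g"].sum())
        if n_resp and th.omega_r0_2 > 0:
            ch["u"][ch["g"]] = th.mu_r0 + sigma_r0 * rng.standard_normal(n_resp)

    def subj_sum(vals):
        return np.bincount(design.subj_idx, weights=vals, minlength=design.n_subj)

    def resid_ll(pred):
        return -0.5 * ((design.ylog - pred) / th.sigma2**0.5) ** 2

    pred_cur = _pd_pred(design, th, ch["g"], ch["u"], ch["v"])

    def try_move(u_prop, v_prop, extra):
        nonlocal pred_cur
        pred_prop = _pd_pred(design, th, ch["g"], u_prop, v_prop)
        delta = subj_sum(resid_ll(pred_prop)) - subj_sum(resid_ll(pred_cur)) + extra
        acc = np.log(rng.random(design.n_subj)) < delta
        ch["u"] = np.where(acc, u_prop, ch["u"])
        ch["v"] = np.where(acc, v_prop, ch["v"])
        pred_cur = np.where(acc[design.subj_idx], pred_prop, pred_cur)
        return acc.mean()

    if not single_class and th.omega_r0_2 > 0:
        # independent prior proposal for the resistance baseline
        u_prop = th.mu_r0 + sigma_r0 * rng.standard_normal(design.n_subj)
        try_move(u_prop, ch["v"], 0.0)
        for _ in range(ch["n_rw"]):
            u_prop = ch["u"] + ch["du"] * rng.standard_normal(design.n_subj)
            extra = (-0.5 * (u_prop - th.mu_r0) ** 2 + 0.5 * (ch["u"] - th.mu_r0) ** 2) / max(
                th.omega_r0_2, 1e-12
            )
            rate = try_move(u_prop, ch["v"], extra)
            if adapt:
                ch["du"] = float(np.clip(ch["du"] * math.exp(0.4 * (rate - 0.3)), 1e-3, 5.0))
    elif not single_class:
        ch["u"] = np.full(design.n_subj, th.mu_r0)

    if th.omega_ktr_2 > 0:
        v_prop = th.mu_ktr + sigma_ktr * rng.standard_normal(design.n_subj)
        try_move(ch["u"], v_prop, 0.0)
        for _ in range(ch["n_rw"]):
            v_prop = ch["v"] + ch["dv"] * rng.standard_normal(design.n_subj)
            extra = (-0.5 * (v_prop - th.mu_ktr) ** 2 + 0.5 * (ch["v"] - th.mu_ktr) ** 2) / max(
                th.omega_ktr_2, 1e-12
            )
            rate = try_move(ch["u"], v_prop, extra)
            if adapt:
                ch["dv"] = float(np.clip(ch["dv"] * math.exp(0.4 * (rate - 0.3)), 1e-3, 5.0))
    else:
        ch["v"] = np.full(design.n_subj, th.mu_ktr)


def _resolve_cl(dataset, pk_stage) -> dict:
    """Per-subject clearance from the PK stage, whatever form it takes."""
    if isinstance(pk_stage, FitResult):
        if pk_stage.model != "pk":
            raise ValueError("pk_stage FitResult must come from fit_pk")
        return dict(zip(pk_stage.eb["subject_id"], pk_stage.eb["cl"]))
    if isinstance(pk_stage, PopPKParams):
        return {
            s.subject_id: allometric_value(pk_stage.tv_cl, pk_stage.beta_cl, s.bw)
            for s in dataset
        }
    return dict(pk_stage)


def fit_pd(
    dataset: list[SubjectData],
    pk_stage: FitResult | PopPKParams | dict,
    init: PopPDParams | None = None,
    settings: SaemSettings | None = None,
) -> FitResult:
    """Fit the CRP turnover/mixture model by SAEM, PK stage held fixed.

    ``pk_stage`` supplies each subject's clearance — a PK ``FitResult``
    (empirical-Bayes clearances), a ``PopPKParams`` (population allometric
    clearance at the subject's bodyweight) or an explicit id->CL mapping —
    from which the constant exposure ``Css = daily_dose/(24*CL)`` is
    computed.  CRP is fitted on the log10 scale.  Fixing ``p_resp`` to 1
    drops the resistance class and its parameters from estimation.
    """
    settings = settings or SaemSettings()
    init = init or default_pd_init(dataset)
    cl_map = _resolve_cl(dataset, pk_stage)
    design = build_pd_design(dataset, cl_map)
    fingerprint = dataset_fingerprint(dataset)
    rng = np.random.default_rng(settings.seed)
    th = _pd_theta_from(init)
    for name, val in settings.fix.items():
        if name not in _PD_FIX_SETTERS:
            raise ValueError(f"unknown PD parameter in fix: {name!r}")
        _PD_FIX_SETTERS[name](th, val)
    flags: list[str] = []
    single_class = settings.fix.get("p_resp") == 1.0
    if single_class:
        th.p = 1.0

    # degenerate-mixture check on the provisional baseline split
    if not single_class:
        base = 10.0 ** design.ylog[design.first_obs]
        thr = math.sqrt(math.exp(th.log_r0_resp) * math.exp(th.mu_r0))
        n_hi = int((base >= thr).sum())
        if min(n_hi, design.n_subj - n_hi) < 2:
            warnings.warn(
                "degenerate mixture: fewer than 2 subjects per class at initialization",
                stacklevel=2,
            )
            flags.append("degenerate mixture at initialization")

    if single_class:
        est_names = ["r0_resp", "k_tr", "c50", "omega_ktr", "sigma_pd"]
    else:
        est_names = list(_PD_PARAM_NAMES)
    n_free = len([n for n in est_names if n not in settings.fix])

    chains = []
    for _ in range(settings.n_chains):
        chains.append(
            {
                "g": np.full(design.n_subj, True)
                if single_class
                else rng.random(design.n_subj) < th.p,
                "u": th.mu_r0 + 0.1 * rng.standard_normal(design.n_subj),
                "v": th.mu_ktr + 0.1 * rng.standard_normal(design.n_subj),
                "du": 0.4, "dv": 0.4, "n_rw": settings.rw_transitions,
            }
        )

    S = dict.fromkeys(["resp", "nresi", "u", "uu", "v", "vv", "rss"], 0.0)
    n_iter = settings.n_burnin + settings.n_smooth
    trace_rows = []
    nl_free = [n for n in ("r0_resp", "c50", "k_resi") if n not in settings.fix]
    if single_class and "k_resi" in nl_free:
        nl_free.remove("k_resi")

    for k in range(1, n_iter + 1):
        gamma = _step_size(k, settings.n_burnin)
        anneal = settings.annealing if k <= settings.n_burnin else None
        for ch in chains:
            _pd_sweep(ch, design, th, rng, adapt=k <= settings.n_burnin, single_class=single_class)

        # --- nonlinear fixed effects by conditional least squares ---
        if nl_free:
            cur = {"r0_resp": th.log_r0_resp, "c50": th.log_c50, "k_resi": th.log_kresi}

            def rss_of(vec):
                trial = dict(cur)
                trial.update(dict(zip(nl_free, vec)))
                t2 = _PDTheta(**vars(th))
                t2.log_r0_resp, t2.log_c50, t2.log_kresi = (
                    trial["r0_resp"], trial["c50"], trial["k_resi"],
                )
                tot = 0.0
                for ch in chains:
                    pred = _pd_pred(design, t2, ch["g"], ch["u"], ch["v"])
                    tot += float(((design.ylog - pred) ** 2).sum())
                return tot

            x0 = np.array([cur[n] for n in nl_free])
            res = minimize(rss_of, x0, method="Nelder-Mead",
                           options={"maxiter": 40, "xatol": 1e-3, "fatol": 1e-6})
            new = dict(zip(nl_free, res.x))
            if "r0_resp" in new:
                th.log_r0_resp += gamma * (new["r0_resp"] - th.log_r0_resp)
            if "c50" in new:
                th.log_c50 += gamma * (new["c50"] - th.log_c50)
            if "k_resi" in new:
                th.log_kresi += gamma * (new["k_resi"] - th.log_kresi)

        # --- sufficient statistics ---
        stat = dict.fromkeys(S, 0.0)
        for ch in chains:
            resi = ~ch["g"]
            stat["resp"] += float(ch["g"].sum())
            stat["nresi"] += float(resi.sum())
            stat["u"] += float(ch["u"][resi].sum())
            stat["uu"] += float((ch["u"][resi] ** 2).sum())
            stat["v"] += float(ch["v"].sum())
            stat["vv"] += float((ch["v"] ** 2).sum())
            pred = _pd_pred(design, th, ch["g"], ch["u"], ch["v"])
            stat["rss"] += float(((design.ylog - pred) ** 2).sum())
        for key in S:
            S[key] += gamma * (stat[key] / settings.n_chains - S[key])

        # --- exact M-step updates ---
        fix = settings.fix
        if "p_resp" not in fix:
            lo = 0.5 / design.n_subj
            th.p = float(np.clip(S["resp"] / design.n_subj, lo, 1.0 - lo))
        if not single_class:
            n_resi = max(S["nresi"], 1e-6)
            if "r0_resi" not in fix:
                th.mu_r0 = S["u"] / n_resi
            if "omega_r0_resi" not in fix:
                hat = S["uu"] / n_resi - (S["u"] / n_resi) ** 2
                th.omega_r0_2 = _variance_update(th.omega_r0_2, hat, gamma, anneal)
        if "k_tr" not in fix:
            th.mu_ktr = S["v"] / design.n_subj
        if "omega_ktr" not in fix:
            hat = S["vv"] / design.n_subj - (S["v"] / design.n_subj) ** 2
            th.omega_ktr_2 = _variance_update(th.omega_ktr_2, hat, gamma, anneal)
        if "sigma_pd" not in fix:
            th.sigma2 = _variance_update(th.sigma2, S["rss"] / design.n_obs, gamma, anneal)

        p = _pd_theta_to_params(th)
        trace_rows.append({name: getattr(p, name) for name in _PD_PARAM_NAMES})

    trace = pd.DataFrame(trace_rows)
    trace.index.name = "iteration"
    converged = _trace_converged(trace, settings.n_smooth)
    if not converged:
        flags.append("convergence questionable: parameters drifting in smoothing phase")

    # --- conditional pass for EB summaries and IS proposals ---
    keep_from = settings.eb_transitions - settings.eb_keep
    g_samp, u_samp, v_samp = [], [], []
    for j in range(settings.eb_transitions):
        for ch in chains:
            _pd_sweep(ch, design, th, rng, adapt=False, single_class=single_class)
            if j >= keep_from:
                g_samp.append(ch["g"].copy())
                u_samp.append(ch["u"].copy())
                v_samp.append(ch["v"].copy())
    g_samp = np.asarray(g_samp)
    u_samp = np.asarray(u_samp)
    v_samp = np.asarray(v_samp)

    ll_subj, post_resp, draws = _pd_importance_ll(
        design, th, g_samp, u_samp, v_samp, rng, settings.ll_draws, single_class
    )
    minus2ll = -2.0 * float(ll_subj.sum())
    aic = minus2ll + 2.0 * n_free
    bic = minus2ll + n_free * math.log(design.n_subj)

    params = _pd_theta_to_params(th)
    eb = pd.DataFrame(
        {
            "subject_id": design.subject_ids,
            "bw": design.bw,
            "css": design.css,
            "p_resp": post_resp,
            "eta_ktr": v_samp.mean(axis=0) - th.mu_ktr,
            "eta_r0_resi": u_samp.mean(axis=0) - th.mu_r0,
            "group": np.where(post_resp >= 0.5, RESP, RESI),
        }
    )

    rse: dict = {name: float("nan") for name in _PD_PARAM_NAMES}
    if settings.compute_se:
        try:
            rse.update(_pd_standard_errors(design, th, draws, settings.fix, single_class))
        except Exception as exc:  # pragma: no cover - defensive
            flags.append(f"standard errors unavailable: {exc}")

    return FitResult(
        model="pd", params=params, rse=rse, minus2ll=minus2ll, aic=aic, bic=bic,
        n_params=n_free, n_subjects=design.n_subj, trace=trace, eb=eb,
        eb_occ=None, posterior_resp=pd.Series(post_resp, index=design.subject_ids),
        converged=converged, flags=flags, seed=settings.seed,
        n_iter=(settings.n_burnin, settings.n_smooth), fingerprint=fingerprint,
    )


def _pd_importance_ll(design, th, g_samp, u_samp, v_samp, rng, n_draws, single_class):
    """Per-subject log-likelihood with the latent class marginalized exactly.

    ``L_i = p * E_resp_i + (1-p) * E_resi_i`` where each class integral is
    importance-sampled around the class-conditional posterior of the random
    effects; the same integrals give the posterior responder probability.
    """
    p = 1.0 if single_class else float(np.clip(th.p, 1e-9, 1.0 - 1e-9))
    sd_u = math.sqrt(max(th.omega_r0_2, 1e-12))
    sd_v = math.sqrt(max(th.omega_ktr_2, 1e-12))

    def class_stats(samples, mask_samples, prior_mu, prior_sd):
        loc = np.empty(design.n_subj)
        sd = np.empty(design.n_subj)
        for i in range(design.n_subj):
            vals = samples[mask_samples[:, i], i]
            if vals.size >= 5:
                loc[i], sd[i] = vals.mean(), max(vals.std(), 0.05 * prior_sd + 1e-6)
            else:
                loc[i], sd[i] = prior_mu, prior_sd
        return loc, sd

    resp_mask = g_samp
    resi_mask = ~g_samp
    v_loc_resp, v_sd_resp = class_stats(v_samp, resp_mask, th.mu_ktr, max(sd_v, 1e-3))
    v_loc_resi, v_sd_resi = class_stats(v_samp, resi_mask, th.mu_ktr, max(sd_v, 1e-3))
    u_loc, u_sd = class_stats(u_samp, resi_mask, th.mu_r0, max(sd_u, 1e-3))

    def class_integral(as_resp, u_loc_c, u_sd_c, v_loc_c, v_sd_c):
        if th.omega_ktr_2 > 0:
            v_draws, v_logq = _is_proposal(rng, v_loc_c, v_sd_c * 1.3, n_draws)
            v_prior = norm.logpdf(v_draws, th.mu_ktr, sd_v)
        else:
            v_draws = np.tile(np.full(design.n_subj, th.mu_ktr), (n_draws, 1))
            v_logq = np.zeros_like(v_draws)
            v_prior = np.zeros_like(v_draws)
        if not as_resp and th.omega_r0_2 > 0:
            u_draws, u_logq = _is_proposal(rng, u_loc_c, u_sd_c * 1.3, n_draws)
            u_prior = norm.logpdf(u_draws, th.mu_r0, sd_u)
        else:
            u_draws = np.tile(np.full(design.n_subj, th.mu_r0), (n_draws, 1))
            u_logq = np.zeros_like(u_draws)
            u_prior = np.zeros_like(u_draws)
        lw = np.empty((n_draws, design.n_subj))
        for m in range(n_draws):
            lw[m] = _pd_class_ll(design, th, u_draws[m], v_draws[m], as_resp)
        lw += v_prior - v_logq
        if not as_resp:
            lw += u_prior - u_logq
        return (
            logsumexp(lw, axis=0) - math.log(n_draws),
            (u_draws, u_logq, v_draws, v_logq),
        )

    ll_resp, draws_resp = class_integral(True, u_loc, u_sd, v_loc_resp, v_sd_resp)
    if single_class:
        return ll_resp, np.ones(design.n_subj), (draws_resp, None)
    ll_resi, draws_resi = class_integral(False, u_loc, u_sd, v_loc_resi, v_sd_resi)
    both = np.stack([ll_resp + math.log(p), ll_resi + math.log1p(-p)])
    ll = logsumexp(both, axis=0)
    post_resp = np.exp(both[0] - ll)
    return ll, post_resp, (draws_resp, draws_resi)


def _pd_ll_from_draws(design, th, draws, single_class):
    draws_resp, draws_resi = draws

    def class_ll(as_resp, pack):
        u_draws, u_logq, v_draws, v_logq = pack
        sd_u = math.sqrt(max(th.omega_r0_2, 1e-12))
        sd_v = math.sqrt(max(th.omega_ktr_2, 1e-12))
        n_draws = v_draws.shape[0]
        lw = np.empty((n_draws, design.n_subj))
        for m in range(n_draws):
            lw[m] = _pd_class_ll(design, th, u_draws[m], v_draws[m], as_resp)
        if th.omega_ktr_2 > 0:
            lw += norm.logpdf(v_draws, th.mu_ktr, sd_v) - v_logq
        if not as_resp and th.omega_r0_2 > 0:
            lw += norm.logpdf(u_draws, th.mu_r0, sd_u) - u_logq
        return logsumexp(lw, axis=0) - math.log(n_draws)

    ll_resp = class_ll(True, draws_resp)
    if single_class:
        return ll_resp
    p = float(np.clip(th.p, 1e-9, 1.0 - 1e-9))
    ll_resi = class_ll(False, draws_resi)
    return logsumexp(
        np.stack([ll_resp + math.log(p), ll_resi + math.log1p(-p)]), axis=0
    )


def _pd_standard_errors(design, th, draws, fix, single_class):
    free = []
    candidates = [
        ("r0_resp", "log_r0_resp"), ("r0_resi", "mu_r0"), ("k_tr", "mu_ktr"),
        ("c50", "log_c50"), ("k_resi", "log_kresi"), ("p_resp", "logit_p"),
        ("omega_r0_resi", "log_or0"), ("omega_ktr", "log_oktr"), ("sigma_pd", "log_sig"),
    ]
    for natural, internal in candidates:
        if natural in fix:
            continue
        if single_class and natural in ("r0_resi", "k_resi", "p_resp", "omega_r0_resi"):
            continue
        free.append((natural, internal))

    def perturbed(internal, h):
        t2 = _PDTheta(**vars(th))
        if internal == "log_r0_resp":
            t2.log_r0_resp += h
        elif internal == "mu_r0":
            t2.mu_r0 += h
        elif internal == "mu_ktr":
            t2.mu_ktr += h
        elif internal == "log_c50":
            t2.log_c50 += h
        elif internal == "log_kresi":
            t2.log_kresi += h
        elif internal == "logit_p":
            t2.p = float(expit(logit(np.clip(th.p, 1e-9, 1 - 1e-9)) + h))
        elif internal == "log_or0":
            t2.omega_r0_2 *= math.exp(2 * h)
        elif internal == "log_oktr":
            t2.omega_ktr_2 *= math.exp(2 * h)
        elif internal == "log_sig":
            t2.sigma2 *= math.exp(2 * h)
        return t2

    h = 1e-3
    scores = np.empty((design.n_subj, len(free)))
    for j, (_, internal) in enumerate(free):
        lp = _pd_ll_from_draws(design, perturbed(internal, h), draws, single_class)
        lm = _pd_ll_from_draws(design, perturbed(internal, -h), draws, single_class)
        scores[:, j] = (lp - lm) / (2 * h)
    fisher = scores.T @ scores
    cov = np.linalg.pinv(fisher)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    rse = {}
    for j, (natural, internal) in enumerate(free):
        if internal == "logit_p":
            se_nat = se[j] * th.p * (1.0 - th.p)
            rse[natural] = 100.0 * se_nat / th.p if th.p > 0 else float("inf")
        else:
            rse[natural] = 100.0 * se[j]
    return rse
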