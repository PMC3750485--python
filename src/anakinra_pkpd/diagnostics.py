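"""Simulation-based model evaluation: visual predictive checks and NPDE.

Both tools re-simulate the fitted dataset many times under the candidate
population parameters, keeping the original design (times, doses,
covariates, occasions) and redrawing every random quantity.

The VPC compares observed percentiles (5th/50th/95th) per time bin with
the distribution of the same percentiles across replicate simulations.
The normalized prediction distribution errors decorrelate each subject's
observation vector with the inverse Cholesky factor of the empirical
simulation covariance, rank the decorrelated observations within the
decorrelated simulations, and map the ranks through the standard-normal
quantile function; under a correct model the NPDE are iid N(0, 1), which
is checked by a t-test on the mean, a chi-square variance test and a
Shapiro-Wilk normality test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular
from scipy.special import ndtri

from .cohort import simulate_pd_observations, simulate_pk_observations
from .data import SubjectData, build_pd_design, build_pk_design
from .fit import _resolve_cl
from .models import PopPDParams, PopPKParams

__all__ = ["VPCSummary", "NPDEReport", "vpc", "npde"]

PERCENTILES = (5.0, 50.0, 95.0)


@dataclass
class VPCSummary:
    """Binned observed percentiles with simulated percentile bands."""

    table: pd.DataFrame   # one row per (bin, percentile)
    n_bins: int
    n_rep: int
    seed: int
    merged_bins: int      # empty bins merged into neighbors

    def coverage(self) -> float:
        """Fraction of (bin, percentile) cells whose observed value falls
        inside the central 90% simulated band."""
        t = self.table
        inside = (t["observed"] >= t["sim_lo"]) & (t["observed"] <= t["sim_hi"])
        return float(inside.mean())


@dataclass
class NPDEReport:
    """Per-observation NPDE values and the three calibration tests."""

    npde: np.ndarray
    mean: float
    mean_pvalue: float
    variance: float
    variance_pvalue: float
    normality_pvalue: float
    n_rep: int
    seed: int
    ridged: bool          # empirical covariance needed ridge regularization

    def summary(self) -> str:
        return (
            f"NPDE n={self.npde.size}, replicates={self.n_rep}\n"
            f"mean     {self.mean:+.4f}  (t-test p={self.mean_pvalue:.3f})\n"
            f"variance {self.variance:.4f}  (chi-square p={self.variance_pvalue:.3f})\n"
            f"normality (Shapiro-Wilk) p={self.normality_pvalue:.3f}"
            + ("\nwarning: simulation covariance ridge-regularized" if self.ridged else "")
        )


def _binned_percentiles(times, values, edges):
    rows = []
    for b in range(len(edges) - 1):
        m = (times >= edges[b]) & (times <= edges[b + 1] if b == len(edges) - 2 else times < edges[b + 1])
        if not np.any(m):
            continue
        for q in PERCENTILES:
            rows.append((b, q, float(np.percentile(values[m], q))))
    return rows


def _design_for(dataset, params, model, pk_stage):
    if model == "PK":
        design = build_pk_design(dataset)
        times = np.min(np.where(design.dose_mask, design.u, np.inf), axis=1)  # time after last dose
        observed = design.y
        keep = ~design.cens
        return design, times, observed, keep
    if model == "PD":
        if pk_stage is None:
            raise ValueError("PD diagnostics require pk_stage for the exposure")
        design = build_pd_design(dataset, _resolve_cl(dataset, pk_stage))
        return design, design.t, design.ylog, np.ones(design.n_obs, dtype=bool)
    raise ValueError("model must be 'PK' or 'PD'")


def _simulate(design, params, model, rng, n_rep):
    if model == "PK":
        return simulate_pk_observations(design, params, rng, n_rep)
    return simulate_pd_observations(design, params, rng, n_rep)


def vpc(
    dataset: list[SubjectData],
    params: PopPKParams | PopPDParams,
    model: str = "PK",
    n_rep: int = 200,
    seed: int = 0,
    n_bins: int = 6,
    pk_stage=None,
) -> VPCSummary:
    """Visual predictive check on equal-count time bins.

    Simulates ``n_rep`` replicates of the dataset under ``params`` and
    summarizes, per bin, the observed 5th/50th/95th percentiles against the
    median and central 90% band of the same percentiles across replicates.
    PK uses time after the last dose as the binning axis and the
    concentration scale; PD uses days since treatment start and the log10
    CRP scale.  Bins left empty by the equal-count construction are merged
    into their neighbors and counted in ``merged_bins``.
    """
    if n_rep < 100:
        raise ValueError("vpc requires n_rep >= 100")
    design, times, observed, keep = _design_for(dataset, params, model, pk_stage)
    rng = np.random.default_rng(seed)
    sims = _simulate(design, params, model, rng, n_rep)

    # equal-count bin edges on the observation times
    qs = np.linspace(0, 100, n_bins + 1)
    edges = np.unique(np.percentile(times[keep], qs))
    merged = (n_bins + 1) - edges.size
    obs_rows = _binned_percentiles(times[keep], observed[keep], edges)

    sim_percentiles: dict[tuple[int, float], list[float]] = {}
    for r in range(n_rep):
        for b, q, val in _binned_percentiles(times[keep], sims[r][keep], edges):
            sim_percentiles.setdefault((b, q), []).append(val)

    rows = []
    for b, q, obs_val in obs_rows:
        band = np.asarray(sim_percentiles[(b, q)])
        rows.append(
            {
                "bin": b,
                "t_lo": edges[b],
                "t_hi": edges[b + 1],
                "percentile": q,
                "observed": obs_val,
                "sim_median": float(np.median(band)),
                "sim_lo": float(np.percentile(band, 5)),
                "sim_hi": float(np.percentile(band, 95)),
            }
        )
    table = pd.DataFrame(rows)
    return VPCSummary(
        table=table, n_bins=edges.size - 1, n_rep=n_rep, seed=seed, merged_bins=merged
    )


def npde(
    dataset: list[SubjectData],
    params: PopPKParams | PopPDParams,
    model: str = "PK",
    n_rep: int = 1000,
    seed: int = 0,
    pk_stage=None,
) -> NPDEReport:
    """Normalized prediction distribution errors with calibration tests.

    Censored observations are excluded.  Singular empirical simulation
    covariances are ridge-regularized (and flagged).  Rank ties use the
    mid-offset convention (count of smaller + 0.5) so the normal quantile
    is always finite.
    """
    if n_rep < 500:
        raise ValueError("npde requires n_rep >= 500")
    design, _, observed, keep = _design_for(dataset, params, model, pk_stage)
    rng = np.random.default_rng(seed)
    sims = _simulate(design, params, model, rng, n_rep)

    npde_vals = []
    ridged = False
    for i in range(design.n_subj):
        idx = np.flatnonzero((design.subj_idx == i) & keep)
        if idx.size == 0:
            continue
        y = observed[idx]
        sim = sims[:, idx]                       # (n_rep, n_i)
        mu = sim.mean(axis=0)
        cov = np.cov(sim, rowvar=False).reshape(idx.size, idx.size)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            ridged = True
            cov = cov + 1e-8 * np.eye(idx.size) * max(np.trace(cov) / idx.size, 1e-12)
            chol = np.linalg.cholesky(cov)
        y_dec = solve_triangular(chol, y - mu, lower=True)
        sim_dec = solve_triangular(chol, (sim - mu).T, lower=True).T
        # mid-offset rank -> uniform -> standard normal
        pde = ((sim_dec < y_dec).sum(axis=0) + 0.5) / (n_rep + 1.0)
        npde_vals.append(ndtri(pde))
    npde_arr = np.concatenate(npde_vals)
    n = npde_arr.size

    mean = float(npde_arr.mean())
    t_res = stats.ttest_1samp(npde_arr, 0.0)
    var = float(npde_arr.var(ddof=1))
    chi_stat = (n - 1) * var
    var_p = 2.0 * min(
        stats.chi2.cdf(chi_stat, n - 1), stats.chi2.sf(chi_stat, n - 1)
    )
    shapiro_p = float(stats.shapiro(npde_arr).pvalue) if n >= 3 else float("nan")
    return NPDEReport(
        npde=npde_arr,
        mean=mean,
        mean_pvalue=float(t_res.pvalue),
        variance=var,
        variance_pvalue=float(var_p),
        normality_pvalue=shapiro_p,
        n_rep=n_rep,
        seed=seed,
        ridged=ridged,
    )
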