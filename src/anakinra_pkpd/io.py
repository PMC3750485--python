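"""Dataset file dialect, run configuration and report writers.

The dataset is a single NONMEM-convention CSV holding both stages (a TYPE
column separates drug-concentration rows from CRP rows, so the sequential
fit can share subjects).  Columns, comma-separated, UTF-8:

    ID, TIME, AMT, DV, EVID, TYPE, CENS, LLOQ, BW, AGE, SEX, OCC

Dose rows have EVID=1 and AMT>0 (TIME in hours); observation rows have
EVID=0 and either a DV or CENS=1 with the LLOQ filled in.  PK observation
times are hours since the first dose, PD observation times are days —
each row's TYPE declares its clock.  Rows are sorted by ID then TIME
within each type.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

import yaml

from .data import PD, PK, SubjectData

__all__ = [
    "COLUMNS",
    "DatasetError",
    "RunConfig",
    "read_dataset",
    "write_dataset",
    "write_truth",
    "read_truth",
    "load_config",
    "save_config",
]

COLUMNS = ["ID", "TIME", "AMT", "DV", "EVID", "TYPE", "CENS", "LLOQ", "BW", "AGE", "SEX", "OCC"]


class DatasetError(ValueError):
    """Malformed dataset file; message carries the offending line numbers."""


@dataclass
class RunConfig:
    """Run configuration echoed (with its hash) into every output."""

    seed: int = 1234
    n_burnin: int = 300
    n_smooth: int = 100
    n_chains: int = 2
    blq_method: str = "censored"       # left-censored likelihood (M3-equivalent)
    pd_noise_scale: str = "ln"         # how the published 0.39 residual SD is read
    vpc_reps: int = 200
    npde_reps: int = 1000
    outdir: str = "out"

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


def write_dataset(subjects: list[SubjectData], path) -> None:
    """Write subjects to the dataset CSV dialect (truth is NOT written)."""
    rows = []
    for s in subjects:
        for t, amt in zip(s.dose_times, s.dose_amounts):
            rows.append(
                dict(ID=s.subject_id, TIME=t, AMT=amt, DV="", EVID=1, TYPE=PK,
                     CENS=0, LLOQ="", BW=s.bw, AGE=s.age, SEX=s.sex, OCC=1)
            )
        for t, dv, typ, cens, lloq, occ in zip(
            s.obs_times, s.obs_values, s.obs_types, s.obs_cens, s.obs_lloq, s.obs_occ
        ):
            rows.append(
                dict(ID=s.subject_id, TIME=t, AMT="", DV=dv, EVID=0, TYPE=typ,
                     CENS=int(cens), LLOQ=lloq if np.isfinite(lloq) else "",
                     BW=s.bw, AGE=s.age, SEX=s.sex, OCC=int(occ))
            )
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)


def read_dataset(path) -> list[SubjectData]:
    """Read and validate a dataset CSV; errors report 1-based line numbers."""
    frame = pd.read_csv(path, dtype={"ID": str, "TYPE": str, "SEX": str})
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetError(f"missing mandatory columns: {missing}")
    frame["_line"] = np.arange(2, len(frame) + 2)  # header is line 1

    problems = []
    obs = frame[frame["EVID"] == 0]
    bad_cens = obs[(obs["CENS"] == 1) & ~np.isfinite(obs["LLOQ"].astype(float))]
    problems += [f"line {ln}: CENS=1 without LLOQ" for ln in bad_cens["_line"]]
    bad_dv = obs[(obs["CENS"] != 1) & ~np.isfinite(obs["DV"].astype(float))]
    problems += [f"line {ln}: observation without DV" for ln in bad_dv["_line"]]
    doses = frame[frame["EVID"] == 1]
    bad_amt = doses[~(doses["AMT"].astype(float) > 0)]
    problems += [f"line {ln}: dose row with AMT<=0" for ln in bad_amt["_line"]]
    bad_type = frame[~frame["TYPE"].isin([PK, PD])]
    problems += [f"line {ln}: TYPE must be PK or PD" for ln in bad_type["_line"]]
    for sid, grp in frame.groupby("ID", sort=False):
        if grp["BW"].nunique() > 1:
            problems.append(f"subject {sid}: BW not constant")
        for typ in (PK, PD):
            sub = grp[(grp["EVID"] == 0) & (grp["TYPE"] == typ)]
            if np.any(np.diff(sub["TIME"].to_numpy(dtype=float)) < 0):
                problems.append(f"subject {sid}: {typ} observation times not sorted")
    if problems:
        raise DatasetError("; ".join(problems))

    subjects = []
    for sid, grp in frame.groupby("ID", sort=False):
        d = grp[grp["EVID"] == 1].sort_values("TIME")
        o = grp[grp["EVID"] == 0]
        lloq = o["LLOQ"].astype(float).to_numpy()
        cens = o["CENS"].to_numpy() == 1
        dv = o["DV"].astype(float).to_numpy()
        dv = np.where(cens, lloq, dv)  # censored rows carry DV = LLOQ
        subjects.append(
            SubjectData(
                subject_id=str(sid),
                bw=float(grp["BW"].iloc[0]),
                age=float(grp["AGE"].iloc[0]),
                sex=str(grp["SEX"].iloc[0]),
                dose_times=d["TIME"].to_numpy(dtype=float),
                dose_amounts=d["AMT"].to_numpy(dtype=float),
                obs_times=o["TIME"].to_numpy(dtype=float),
                obs_values=dv,
                obs_types=o["TYPE"].to_numpy(dtype=object),
                obs_cens=cens,
                obs_lloq=np.where(np.isfinite(lloq), lloq, np.nan),
                obs_occ=o["OCC"].to_numpy(dtype=int),
            )
        )
    return subjects


def write_truth(subjects: list[SubjectData], path, extra: dict | None = None) -> None:
    """Sidecar JSON with generating parameters and latent truth per subject."""
    payload = {
        "extra": extra or {},
        "subjects": {s.subject_id: (s.truth or {}) for s in subjects},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_truth(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def attach_meta(path, cfg: RunConfig) -> None:
    """Append a sidecar meta file recording seed and config hash."""
    meta = Path(str(path) + ".meta.json")
    with open(meta, "w", encoding="utf-8") as fh:
        json.dump({"seed": cfg.seed, "config_sha": cfg.digest(), "config": asdict(cfg)}, fh, indent=1)


def save_fit(fit, path) -> None:
    """Machine-readable fit results (estimates, RSEs, metrics, EB tables)."""
    payload = {
        "model": fit.model,
        "params": {k: (None if v is None else float(v)) for k, v in vars(fit.params).items()},
        "rse_percent": {k: _jsonable(v) for k, v in fit.rse.items()},
        "minus2ll": _jsonable(fit.minus2ll),
        "aic": _jsonable(fit.aic),
        "bic": _jsonable(fit.bic),
        "n_params": fit.n_params,
        "n_subjects": fit.n_subjects,
        "converged": bool(fit.converged),
        "flags": list(fit.flags),
        "seed": fit.seed,
        "n_iter": list(fit.n_iter),
        "fingerprint": fit.fingerprint,
        "eb": fit.eb.to_dict(orient="list"),
        "eb_occ": fit.eb_occ.to_dict(orient="list") if fit.eb_occ is not None else None,
        "posterior_resp": (
            {str(k): float(v) for k, v in fit.posterior_resp.items()}
            if fit.posterior_resp is not None
            else None
        ),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def load_fit(path) -> dict:
    """Load a saved fit; 'params' is rebuilt as the proper parameter object."""
    from .models import PopPDParams, PopPKParams

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    cls = PopPKParams if payload["model"] == "pk" else PopPDParams
    payload["params"] = cls(**payload["params"])
    payload["eb"] = pd.DataFrame(payload["eb"])
    if payload.get("eb_occ"):
        payload["eb_occ"] = pd.DataFrame(payload["eb_occ"])
    return payload


def _jsonable(v):
    v = float(v)
    return v if np.isfinite(v) else None
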