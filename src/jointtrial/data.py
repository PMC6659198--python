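"""Trial data containers, validation, and design-matrix construction.

A trial is a pair of tables: a long-format longitudinal table (one row per
visit) and a survival table (one row per subject, right-censored event time).
Times are in years with 0 at randomization throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

LONG_COLUMNS = ["subject_id", "time_years", "outcome_value", "fortasyn", "bmmse", "site"]
SURV_COLUMNS = ["subject_id", "event_time_years", "event_indicator", "fortasyn", "bmmse", "site"]


class SchemaError(ValueError):
    """Raised when an input table violates the trial data schema."""


@dataclass
class TrialDataset:
    """Paired longitudinal and survival tables for one (real or simulated) trial.

    Attributes
    ----------
    longitudinal : DataFrame with columns ``LONG_COLUMNS``.
    survival : DataFrame with columns ``SURV_COLUMNS``.
    truth : optional dict with the generating parameters and per-subject
        random effects, present only for simulated trials.
    """

    longitudinal: pd.DataFrame
    survival: pd.DataFrame
    truth: dict | None = None

    def validate(self) -> "TrialDataset":
        """Check schema and cross-table invariants; raise SchemaError on failure."""
        for cols, df, name in (
            (LONG_COLUMNS, self.longitudinal, "longitudinal"),
            (SURV_COLUMNS, self.survival, "survival"),
        ):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise SchemaError(f"{name} table missing columns: {missing}")
        surv = self.survival
        long = self.longitudinal
        if surv["subject_id"].duplicated().any():
            dup = surv.loc[surv["subject_id"].duplicated(), "subject_id"].tolist()
            raise SchemaError(f"duplicate subject ids in survival table: {dup[:5]}")
        long_ids = set(long["subject_id"])
        surv_ids = set(surv["subject_id"])
        only_long = sorted(long_ids - surv_ids, key=str)
        only_surv = sorted(surv_ids - long_ids, key=str)
        if only_long or only_surv:
            raise SchemaError(
                f"subject ids do not match across tables: only in longitudinal "
                f"{only_long[:5]}, only in survival {only_surv[:5]}"
            )
        if (surv["event_time_years"] <= 0).any():
            bad = surv.loc[surv["event_time_years"] <= 0, "subject_id"].tolist()
            raise SchemaError(f"non-positive event times for subjects {bad[:5]}")
        if not surv["event_indicator"].isin([0, 1]).all():
            raise SchemaError("event_indicator must be 0 or 1")
        if not surv["fortasyn"].isin([0, 1]).all() or not long["fortasyn"].isin([0, 1]).all():
            raise SchemaError("fortasyn must be 0 or 1")
        merged = long.merge(
            surv, on="subject_id", suffixes=("", "_surv"), validate="many_to_one"
        )
        late = merged["time_years"] > merged["event_time_years"] + 1e-9
        if late.any():
            bad = merged.loc[late, "subject_id"].unique().tolist()
            raise SchemaError(
                f"{int(late.sum())} longitudinal rows after follow-up end for subjects {bad[:5]}"
            )
        for c in ("fortasyn", "bmmse", "site"):
            diff = merged[c] != merged[f"{c}_surv"]
            if c == "bmmse":
                diff = ~np.isclose(merged[c].astype(float), merged[f"{c}_surv"].astype(float))
            if diff.any():
                bad = merged.loc[diff, "subject_id"].unique().tolist()
                raise SchemaError(f"covariate '{c}' inconsistent across tables for {bad[:5]}")
        return self

    @property
    def n_subjects(self) -> int:
        return len(self.survival)

    @property
    def n_events(self) -> int:
        return int(self.survival["event_indicator"].sum())

    def write(self, directory: str | Path) -> None:
        """Write longitudinal.csv, survival.csv and an optional truth.json sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        # %.17g keeps the write->read round trip bit-exact for float64
        self.longitudinal.to_csv(directory / "longitudinal.csv", index=False,
                                 float_format="%.17g")
        self.survival.to_csv(directory / "survival.csv", index=False,
                             float_format="%.17g")
        if self.truth is not None:
            with open(directory / "truth.json", "w") as fh:
                json.dump(_jsonable(self.truth), fh, indent=1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class TrialDesign:
    """Numeric arrays derived from a TrialDataset for likelihood evaluation.

    Subjects are ordered as in the survival table. Longitudinal rows are
    sorted by (subject, time) and grouped contiguously; ``obs_subject`` maps
    each row to its subject index. ``bmmse`` is mean-centred (centre stored in
    ``bmmse_center``) so the intercept refers to an average-MMSE subject.
    """

    subject_ids: np.ndarray
    site_levels: list
    bmmse_center: float
    # longitudinal rows
    obs_subject: np.ndarray  # (N,) int
    t_obs: np.ndarray        # (N,)
    y_obs: np.ndarray        # (N,)
    X: np.ndarray            # (N, p_x) fixed-effects design
    n_obs_per_subject: np.ndarray  # (n,)
    # per-subject covariates / survival
    fortasyn: np.ndarray     # (n,)
    bmmse_c: np.ndarray      # (n,) centred
    site_code: np.ndarray    # (n,) int, 0 = reference
    event_time: np.ndarray   # (n,)
    event: np.ndarray        # (n,) 0/1
    W: np.ndarray            # (n, p_w) survival covariate design
    surv_names: list = field(default_factory=list)
    x_names: list = field(default_factory=list)
    # trajectory fixed design split: m_i(t) = (XP @ beta + b0) + (XQ @ beta + b1) t
    XP: np.ndarray = None    # (n, p_x)
    XQ: np.ndarray = None    # (n, p_x)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def p_x(self) -> int:
        return self.X.shape[1]

    @property
    def p_w(self) -> int:
        return self.W.shape[1]

    @property
    def obs_offsets(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum(self.n_obs_per_subject)[:-1]]).astype(int)


def longitudinal_design_row(fortasyn, bmmse_c, site_code, n_sites, t):
    """Fixed-effects design row [1, t, fortasyn, fortasyn*t, bmmse, site contrasts]."""
    row = [1.0, t, fortasyn, fortasyn * t, bmmse_c]
    row += [1.0 if site_code == s else 0.0 for s in range(1, n_sites)]
    return np.asarray(row)


def build_design(dataset: TrialDataset, include_bmmse_in_survival: bool = True) -> TrialDesign:
    """Construct the numeric design arrays shared by all model fits."""
    dataset.validate()
    surv = dataset.survival.reset_index(drop=True)
    long = dataset.longitudinal.copy()

    subject_ids = surv["subject_id"].to_numpy()
    order = {sid: i for i, sid in enumerate(subject_ids)}
    long["_idx"] = long["subject_id"].map(order)
    long = long.sort_values(["_idx", "time_years"], kind="mergesort").reset_index(drop=True)

    site_levels = sorted(pd.unique(surv["site"]), key=str)
    n_sites = len(site_levels)
    site_map = {lv: i for i, lv in enumerate(site_levels)}
    site_code = surv["site"].map(site_map).to_numpy()
    obs_site_code = long["site"].map(site_map).to_numpy()

    bmmse_center = float(surv["bmmse"].mean())
    bmmse_c = surv["bmmse"].to_numpy(dtype=float) - bmmse_center
    obs_bmmse_c = long["bmmse"].to_numpy(dtype=float) - bmmse_center

    t_obs = long["time_years"].to_numpy(dtype=float)
    y_obs = long["outcome_value"].to_numpy(dtype=float)
    f_obs = long["fortasyn"].to_numpy(dtype=float)
    obs_subject = long["_idx"].to_numpy(dtype=int)

    N = len(long)
    p_x = 5 + (n_sites - 1)
    X = np.zeros((N, p_x))
    X[:, 0] = 1.0
    X[:, 1] = t_obs
    X[:, 2] = f_obs
    X[:, 3] = f_obs * t_obs
    X[:, 4] = obs_bmmse_c
    for s in range(1, n_sites):
        X[:, 4 + s] = (obs_site_code == s).astype(float)
    x_names = ["Intercept", "Time", "Fortasyn", "Time:Fortasyn", "Bmmse"] + [
        f"Site[{site_levels[s]}]" for s in range(1, n_sites)
    ]

    fortasyn = surv["fortasyn"].to_numpy(dtype=float)
    event_time = surv["event_time_years"].to_numpy(dtype=float)
    event = surv["event_indicator"].to_numpy(dtype=float)

    cols = [fortasyn]
    surv_names = ["Fortasyn"]
    if include_bmmse_in_survival:
        cols.append(bmmse_c)
        surv_names.append("Bmmse")
    for s in range(1, n_sites):
        cols.append((site_code == s).astype(float))
        surv_names.append(f"Site[{site_levels[s]}]")
    W = np.column_stack(cols)

    n = len(surv)
    XP = np.zeros((n, p_x))
    XQ = np.zeros((n, p_x))
    XP[:, 0] = 1.0
    XP[:, 2] = fortasyn
    XP[:, 4] = bmmse_c
    for s in range(1, n_sites):
        XP[:, 4 + s] = (site_code == s).astype(float)
    XQ[:, 1] = 1.0
    XQ[:, 3] = fortasyn

    n_obs = np.bincount(obs_subject, minlength=n)
    if (n_obs == 0).any():
        raise SchemaError("every subject needs at least one longitudinal row")

    return TrialDesign(
        subject_ids=subject_ids,
        site_levels=site_levels,
        bmmse_center=bmmse_center,
        obs_subject=obs_subject,
        t_obs=t_obs,
        y_obs=y_obs,
        X=X,
        n_obs_per_subject=n_obs,
        fortasyn=fortasyn,
        bmmse_c=bmmse_c,
        site_code=site_code,
        event_time=event_time,
        event=event,
        W=W,
        surv_names=surv_names,
        x_names=x_names,
        XP=XP,
        XQ=XQ,
    )
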