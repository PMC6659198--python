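"""Readers, validators and text reporting for trial data and fits."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data import LONG_COLUMNS, SURV_COLUMNS, SchemaError, TrialDataset
from .joint import JointFit
from .longitudinal import LMMFit


def read_trial(longitudinal_path, survival_path) -> TrialDataset:
    """Read and validate the two CSV tables into a TrialDataset.

    Raises SchemaError on missing columns, non-numeric fields, orphan subject
    ids or visits after the follow-up time.
    """
    long = _read_csv(longitudinal_path, LONG_COLUMNS, "longitudinal")
    surv = _read_csv(survival_path, SURV_COLUMNS, "survival")
    for col in ("time_years", "outcome_value", "bmmse"):
        _require_numeric(long, col, "longitudinal")
    for col in ("event_time_years", "event_indicator", "bmmse"):
        _require_numeric(surv, col, "survival")
    return TrialDataset(longitudinal=long, survival=surv).validate()


def _read_csv(path, columns, name) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{name} file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table {path} missing columns {missing}")
    return df


def _require_numeric(df, col, name):
    vals = pd.to_numeric(df[col], errors="coerce")
    if vals.isna().any():
        rows = df.index[vals.isna()].tolist()
        raise SchemaError(f"non-numeric values in {name} column '{col}' at rows {rows[:5]}")
    df[col] = vals


def wald_pvalues(estimates, ses) -> np.ndarray:
    """Two-sided Wald p-values with a standard-normal reference."""
    z = np.asarray(estimates, dtype=float) / np.asarray(ses, dtype=float)
    return 2 * stats.norm.sf(np.abs(z))


def lmm_coefficient_table(fit: LMMFit) -> pd.DataFrame:
    est = fit.params.fixed_vector()
    se = fit.fixed_se()
    return pd.DataFrame({
        "term": fit.x_names, "estimate": est, "se": se,
        "p_value": wald_pvalues(est, se),
    })


# rows of the Table-style report: all natural-scale parameters with Wald tests
def joint_coefficient_table(fit: JointFit) -> pd.DataFrame:
    est = fit._natural()
    if fit.vcov is not None:
        se = np.sqrt(np.clip(np.diag(fit.vcov), 0, None))
    else:
        se = np.full(len(est), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = wald_pvalues(est, se)
    return pd.DataFrame({
        "term": fit.param_names, "estimate": est, "se": se, "p_value": p,
    })


def write_fit_report(fit: JointFit, path) -> None:
    """Structured text report: coefficient table plus fit summary."""
    path = Path(path)
    table = joint_coefficient_table(fit)
    with open(path, "w") as fh:
        table.to_csv(fh, index=False, float_format="%.6g")
        fh.write(f"# loglik,{fit.loglik:.6f}\n")
        fh.write(f"# aic,{fit.aic:.6f}\n")
        fh.write(f"# bic,{fit.bic:.6f}\n")
        fh.write(f"# n_subjects,{fit.n_subjects}\n")
        fh.write(f"# n_events,{fit.n_events}\n")
        fh.write(f"# converged,{fit.converged}\n")


def write_curve(curve, path) -> None:
    curve.to_frame().to_csv(path, index=False, float_format="%.17g")
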