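"""Direct / indirect / total intervention hazard-ratio decomposition.

Under the current-value association the hazard ratio between an otherwise
identical test and control subject factorizes as

    HR(t) = exp{gamma1 + alpha (beta2 + beta3 t)}
          = exp(gamma1) * exp(alpha beta2) * exp(alpha beta3 t),

i.e. a constant direct effect not mediated by the trajectory, a constant
indirect effect from the baseline group difference, and a time-varying
indirect effect from the diverging trajectories. Percentile confidence bands
come from a cluster (subject-level) bootstrap with full joint refits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TrialDataset, build_design
from .joint import JointFit, JointSpec, fit_joint
from .survival import VALUE, VALUE_SLOPE, fit_piecewise_ph


@dataclass
class HazardRatioCurve:
    """Hazard-ratio components of the intervention effect on a time grid."""

    time_grid: np.ndarray
    direct: float                      # exp(gamma1)
    indirect_constant: float           # exp(alpha * beta2)
    indirect_timevarying: np.ndarray   # exp(alpha * beta3 * t)
    total: np.ndarray                  # product of the three
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    n_boot: int = 0
    n_failed: int = 0
    cox_reference: float | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time": self.time_grid,
            "direct": self.direct,
            "indirect_constant": self.indirect_constant,
            "indirect_timevarying": self.indirect_timevarying,
            "total": self.total,
        })
        if self.lower is not None:
            df["lower"] = self.lower
            df["upper"] = self.upper
        return df


DEFAULT_TIME_GRID = np.linspace(0.0, 2.0, 101)


def _decomposition_coefficients(fit: JointFit):
    if fit.spec.association_type != VALUE:
        raise ValueError(
            "the direct/indirect decomposition is defined for the current-value "
            f"association, not {fit.spec.association_type!r}"
        )
    return fit.survival.gamma_fortasyn, fit.survival.alpha_value, \
        fit.mixed.beta2, fit.mixed.beta3


def decompose(fit: JointFit, time_grid=None) -> HazardRatioCurve:
    """Evaluate the hazard-ratio components from the fit's point estimates."""
    gamma1, alpha, beta2, beta3 = _decomposition_coefficients(fit)
    t = np.asarray(DEFAULT_TIME_GRID if time_grid is None else time_grid, dtype=float)
    direct = float(np.exp(gamma1))
    ind_const = float(np.exp(alpha * beta2))
    ind_tv = np.exp(alpha * beta3 * t)
    return HazardRatioCurve(
        time_grid=t, direct=direct, indirect_constant=ind_const,
        indirect_timevarying=ind_tv, total=direct * ind_const * ind_tv,
    )


def total_hr(fit: JointFit, t) -> np.ndarray:
    gamma1, alpha, beta2, beta3 = _decomposition_coefficients(fit)
    return np.exp(gamma1 + alpha * (beta2 + beta3 * np.asarray(t, dtype=float)))


def association_hr(fit: JointFit, delta: float) -> float:
    """exp(alpha1 * delta): hazard ratio for a ``delta``-unit increase in the
    current trajectory value."""
    if fit.spec.association_type not in (VALUE, VALUE_SLOPE):
        raise ValueError("association_hr needs a value or value_slope fit")
    return float(np.exp(fit.survival.alpha_value * delta))


def slope_hr(fit: JointFit, delta: float) -> float:
    """exp(alpha2 * delta): hazard ratio for a ``delta``-unit increase in the
    trajectory slope, holding the current value fixed."""
    if fit.spec.association_type != VALUE_SLOPE:
        raise ValueError("slope_hr needs a value_slope fit")
    return float(np.exp(fit.survival.alpha_slope * delta))


def auc_hr(fit: JointFit, delta: float) -> float:
    """exp(alpha3 * delta): hazard ratio for a ``delta``-unit increase in the
    cumulative trajectory (AUC)."""
    if fit.spec.association_type != "auc":
        raise ValueError("auc_hr needs an auc fit")
    return float(np.exp(fit.survival.alpha_auc * delta))


class BootstrapError(RuntimeError):
    pass


def resample_subjects(dataset: TrialDataset, rng: np.random.Generator) -> TrialDataset:
    """Cluster bootstrap: resample whole subjects with replacement, keeping
    each subject's longitudinal rows and survival row intact. Resampled
    copies get fresh ids so the id-uniqueness invariant holds."""
    surv = dataset.survival.reset_index(drop=True)
    ids = surv["subject_id"].to_numpy()
    pick = rng.integers(0, len(ids), size=len(ids))
    long_by_id = {sid: g for sid, g in dataset.longitudinal.groupby("subject_id", sort=False)}
    long_parts = []
    surv_parts = surv.iloc[pick].copy()
    new_ids = [f"B{k:04d}" for k in range(len(pick))]
    surv_parts["subject_id"] = new_ids
    for k, j in enumerate(pick):
        g = long_by_id[ids[j]].copy()
        g["subject_id"] = new_ids[k]
        long_parts.append(g)
    return TrialDataset(
        longitudinal=pd.concat(long_parts, ignore_index=True),
        survival=surv_parts.reset_index(drop=True),
    )


def bootstrap_bands(dataset: TrialDataset, spec: JointSpec, time_grid=None,
                    n_boot: int = 200, seed: int = 0,
                    base_fit: JointFit | None = None,
                    max_failure_rate: float = 0.2) -> HazardRatioCurve:
    """Pointwise 95% percentile bands for the total intervention HR.

    Each replicate resamples subjects with replacement and refits the joint
    model, warm-started at the full-data estimates. Replicates that fail to
    converge are dropped and counted; more than ``max_failure_rate`` failures
    aborts with diagnostics. Deterministic given ``seed``.
    """
    if n_boot < 50:
        raise ValueError("n_boot must be at least 50")
    t = np.asarray(DEFAULT_TIME_GRID if time_grid is None else time_grid, dtype=float)
    if base_fit is None:
        base_fit = fit_joint(dataset, spec, compute_se=False)
    curve = decompose(base_fit, t)

    rng = np.random.default_rng(seed)
    curves = []
    n_failed = 0
    for _ in range(n_boot):
        boot = resample_subjects(dataset, rng)
        try:
            refit = fit_joint(boot, spec, init=base_fit, compute_se=False)
            if not refit.converged:
                raise RuntimeError("refit did not converge")
            curves.append(total_hr(refit, t))
        except Exception:
            n_failed += 1
    if n_failed > max_failure_rate * n_boot:
        raise BootstrapError(
            f"{n_failed}/{n_boot} bootstrap refits failed (limit "
            f"{max_failure_rate:.0%}); the model may be too unstable at this "
            "sample size"
        )
    reps = np.array(curves)
    curve.lower = np.percentile(reps, 2.5, axis=0)
    curve.upper = np.percentile(reps, 97.5, axis=0)
    curve.n_boot = n_boot
    curve.n_failed = n_failed
    return curve


def cox_reference_effect(dataset: TrialDataset, include_bmmse: bool = False,
                         n_intervals: int = 7) -> float:
    """Conventional time-fixed intervention hazard ratio exp(gamma1_hat) from
    a proportional-hazards model with arm (+ optional baseline MMSE) and site
    but no trajectory term."""
    design = build_design(dataset, include_bmmse_in_survival=include_bmmse)
    ph = fit_piecewise_ph(design=design, n_intervals=n_intervals)
    return float(np.exp(ph.params.gamma_fortasyn))


def plot_decomposition(curve: HazardRatioCurve, path=None):
    """Line plot of the separate components (dashed direct, solid indirect
    constant, dot-dashed indirect time-varying)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    t = curve.time_grid
    ax.axhline(1.0, color="0.8", lw=0.8)
    ax.plot(t, np.full_like(t, curve.direct), "--", label="direct exp(gamma1)")
    ax.plot(t, np.full_like(t, curve.indirect_constant), "-",
            label="indirect constant exp(alpha*beta2)")
    ax.plot(t, curve.indirect_timevarying, "-.",
            label="indirect time-varying exp(alpha*beta3*t)")
    ax.set_xlabel("years since randomization")
    ax.set_ylabel("hazard ratio (test vs control)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_total(curve: HazardRatioCurve, path=None):
    """Total intervention HR with optional bootstrap band and Cox reference."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    t = curve.time_grid
    ax.axhline(1.0, color="0.8", lw=0.8)
    if curve.lower is not None:
        ax.fill_between(t, curve.lower, curve.upper, color="0.85",
                        label=f"95% band ({curve.n_boot} bootstrap)")
    ax.plot(t, curve.total, "-", label="joint model total HR")
    if curve.cox_reference is not None:
        ax.plot(t, np.full_like(t, curve.cox_reference), "--",
                label="time-fixed PH model")
    ax.set_xlabel("years since randomization")
    ax.set_ylabel("hazard ratio (test vs control)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
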