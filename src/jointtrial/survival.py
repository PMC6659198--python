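"""Piecewise-exponential proportional-hazards sub-model.

The baseline hazard is piecewise constant on intervals defined by interior
knots: lambda0(t) = exp(log_lambda0[q]) for t in [k_{q-1}, k_q), with the
last interval extending to infinity. Knots default to equally spaced
quantiles of observed event times. The time-fixed-covariates-only fit
supplies initial values for the joint model and the conventional
constant-hazard-ratio reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

VALUE, VALUE_SLOPE, AUC = "value", "value_slope", "auc"
ASSOCIATION_TYPES = (VALUE, VALUE_SLOPE, AUC)


@dataclass
class SurvivalParams:
    """Baseline hazard, direct-effect and association coefficients.

    Exactly one association configuration may be active: {alpha_value},
    {alpha_value, alpha_slope}, or {alpha_auc}; all-None is allowed for the
    covariates-only model used for initial values.
    """

    knots: np.ndarray
    log_lambda0: np.ndarray
    gamma_fortasyn: float = 0.0
    gamma_bmmse: float | None = None
    gamma_site: np.ndarray = field(default_factory=lambda: np.zeros(0))
    alpha_value: float | None = None
    alpha_slope: float | None = None
    alpha_auc: float | None = None

    def __post_init__(self):
        self.knots = np.atleast_1d(np.asarray(self.knots, dtype=float))
        self.log_lambda0 = np.atleast_1d(np.asarray(self.log_lambda0, dtype=float))
        self.gamma_site = np.atleast_1d(np.asarray(self.gamma_site, dtype=float))
        if self.knots.size and (np.any(np.diff(self.knots) <= 0) or np.any(self.knots <= 0)):
            raise ValueError("knots must be strictly increasing and positive")
        if len(self.log_lambda0) != len(self.knots) + 1:
            raise ValueError("need len(knots)+1 baseline-hazard values")
        if self.alpha_slope is not None and self.alpha_value is None:
            raise ValueError("slope association requires alpha_value (current value) too")
        if self.alpha_auc is not None and self.alpha_value is not None:
            raise ValueError("auc association excludes the value association")

    @property
    def association_type(self) -> str | None:
        if self.alpha_auc is not None:
            return AUC
        if self.alpha_slope is not None:
            return VALUE_SLOPE
        if self.alpha_value is not None:
            return VALUE
        return None

    @property
    def n_intervals(self) -> int:
        return len(self.log_lambda0)


def baseline_hazard(params: SurvivalParams, t):
    """lambda0(t); intervals are half-open [k_{q-1}, k_q) so the right
    interval owns each knot."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    q = np.searchsorted(params.knots, t, side="right")
    out = np.exp(params.log_lambda0[q])
    return out if out.ndim else float(out)


def interval_bounds(params: SurvivalParams, T):
    """Clip the baseline intervals to [0, T].

    Returns (t1, t2) arrays of shape T.shape + (Q,); empty pieces have
    t2 <= t1.
    """
    T = np.asarray(T, dtype=float)
    lo = np.concatenate([[0.0], params.knots])
    hi = np.concatenate([params.knots, [np.inf]])
    t1 = np.minimum(lo, T[..., None])
    t2 = np.minimum(hi, T[..., None])
    return t1, np.maximum(t2, t1)


def cumulative_baseline_hazard(params: SurvivalParams, T):
    """Integral of lambda0 over [0, T]; continuous and piecewise linear in T."""
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError("T must be non-negative")
    t1, t2 = interval_bounds(params, T)
    out = np.sum(np.exp(params.log_lambda0) * (t2 - t1), axis=-1)
    return out if out.ndim else float(out)


def _exposure_matrix(params: SurvivalParams, T):
    t1, t2 = interval_bounds(params, T)
    return t2 - t1  # (n, Q)


def _event_interval(params: SurvivalParams, T):
    return np.searchsorted(params.knots, T, side="right")


def piecewise_loglik(params: SurvivalParams, event_time, event, W, gamma=None):
    """Log-likelihood of the covariates-only piecewise-exponential model.

    ``gamma`` defaults to the coefficient vector implied by ``params``
    (fortasyn, optional bmmse, site contrasts) matching columns of W.
    """
    if gamma is None:
        gamma = _gamma_vector(params, W.shape[1])
    eta = W @ gamma
    Delta = _exposure_matrix(params, event_time)
    lam = np.exp(params.log_lambda0)
    Lambda = (Delta * lam) @ np.ones(len(lam)) * np.exp(eta)
    qev = _event_interval(params, event_time)
    return float(np.sum(event * (params.log_lambda0[qev] + eta)) - np.sum(Lambda))


def _gamma_vector(params: SurvivalParams, p_w: int):
    g = [params.gamma_fortasyn]
    if params.gamma_bmmse is not None:
        g.append(params.gamma_bmmse)
    g.extend(params.gamma_site)
    g = np.asarray(g, dtype=float)
    if len(g) != p_w:
        raise ValueError(f"gamma length {len(g)} does not match design width {p_w}")
    return g


def choose_knots(event_times, n_intervals: int = 7):
    """Interior knots at equally spaced quantiles of observed event times;
    duplicates dropped."""
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise ValueError("no events observed: cannot place baseline-hazard knots")
    if n_intervals < 2:
        return np.zeros(0)
    qs = np.arange(1, n_intervals) / n_intervals
    knots = np.unique(np.quantile(event_times, qs))
    return knots[(knots > 0) & (knots < event_times.max())]


def fit_piecewise_ph(
    survival: pd.DataFrame | None = None,
    include_bmmse: bool = False,
    n_intervals: int = 7,
    design=None,
    W=None,
    event_time=None,
    event=None,
    surv_names=None,
) -> "PiecewisePHFit":
    """ML fit of the piecewise-exponential PH model with time-fixed covariates.

    Accepts either a survival DataFrame (schema of TrialDataset.survival) or
    pre-built arrays. Intervals with no events are merged into their left
    neighbour. Used for joint-fit initial values and as the conventional
    Cox-style reference effect.
    """
    if design is not None:
        W = design.W
        event_time, event = design.event_time, design.event
        surv_names = design.surv_names
    elif survival is not None:
        from .data import TrialDataset, build_design

        long = survival.rename(columns={"event_time_years": "time_years"}).copy()
        long["outcome_value"] = 0.0
        long["time_years"] = 0.0
        ds = TrialDataset(longitudinal=long[
            ["subject_id", "time_years", "outcome_value", "fortasyn", "bmmse", "site"]
        ], survival=survival)
        d = build_design(ds, include_bmmse_in_survival=include_bmmse)
        W, event_time, event, surv_names = d.W, d.event_time, d.event, d.surv_names
    if event.sum() == 0:
        raise ValueError("zero events: cannot fit the survival sub-model")

    knots = choose_knots(event_time[event == 1], n_intervals)
    # merge intervals containing no events
    while True:
        edges = np.concatenate([[0.0], knots, [np.inf]])
        counts, _ = np.histogram(event_time[event == 1], bins=edges)
        if (counts > 0).all() or len(knots) == 0:
            break
        first_empty = int(np.argmin(counts > 0))
        drop = first_empty - 1 if first_empty == len(knots) else first_empty
        knots = np.delete(knots, drop)

    Q = len(knots) + 1
    p_w = W.shape[1]

    base = SurvivalParams(knots=knots, log_lambda0=np.zeros(Q))
    Delta = _exposure_matrix(base, event_time)
    qev = _event_interval(base, event_time)
    d_q = np.array([np.sum(event[qev == q]) for q in range(Q)])

    def negll_grad(xi):
        loglam, gamma = xi[:Q], xi[Q:]
        eta = W @ gamma
        mu = np.exp(eta)[:, None] * Delta * np.exp(loglam)[None, :]  # (n, Q)
        ll = np.sum(event * (loglam[qev] + eta)) - mu.sum()
        g_lam = d_q - mu.sum(axis=0)
        g_gam = W.T @ (event - mu.sum(axis=1))
        return -ll, -np.concatenate([g_lam, g_gam])

    rate0 = max(event.sum() / np.sum(event_time), 1e-8)
    x0 = np.concatenate([np.full(Q, np.log(rate0)), np.zeros(p_w)])
    res = optimize.minimize(negll_grad, x0, jac=True, method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 500})
    xi = res.x
    H = _numerical_hessian(lambda v: negll_grad(v)[0], xi)
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov = np.full((len(xi), len(xi)), np.nan)

    names = surv_names or [f"w{j}" for j in range(p_w)]
    gamma = xi[Q:]
    kw = dict(knots=knots, log_lambda0=xi[:Q], gamma_fortasyn=float(gamma[0]))
    j = 1
    if "Bmmse" in names:
        kw["gamma_bmmse"] = float(gamma[names.index("Bmmse")])
        j += 1
    kw["gamma_site"] = gamma[j:]
    params = SurvivalParams(**kw)
    return PiecewisePHFit(
        params=params, gamma=gamma, vcov=vcov, loglik=float(-res.fun),
        converged=bool(res.success), names=names, n_events=int(event.sum()),
    )


@dataclass
class PiecewisePHFit:
    params: SurvivalParams
    gamma: np.ndarray
    vcov: np.ndarray           # (Q+p_w) x (Q+p_w), order [log lambda0, gamma]
    loglik: float
    converged: bool
    names: list
    n_events: int

    def gamma_se(self) -> np.ndarray:
        Q = self.params.n_intervals
        return np.sqrt(np.diag(self.vcov)[Q:])


def _numerical_hessian(f, x, h=1e-5):
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * steps[i] * steps[j])
    return H
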