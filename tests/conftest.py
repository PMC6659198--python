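import numpy as np
import pytest

import jointtrial as jt


@pytest.fixture(scope="session")
def trial_311():
    """Default two-arm trial at the emulated study size."""
    return jt.simulate_trial(jt.default_config(n_subjects=311, seed=11))


@pytest.fixture(scope="session")
def sim_spec():
    """Joint-fit settings used for the simulation studies: 9 quadrature
    points per dimension and 5 baseline intervals (quadrature-stability and
    oracle tests justify the reduced grid)."""
    return jt.JointSpec(association_type="value", quadrature_points=9,
                        n_baseline_intervals=5)


@pytest.fixture(scope="session")
def value_fit_311(trial_311, sim_spec):
    fit = jt.fit_joint(trial_311, sim_spec)
    assert fit.converged
    return fit


@pytest.fixture(scope="session")
def small_trial():
    return jt.simulate_trial(jt.default_config(n_subjects=80, seed=21))


def make_fit(gamma1=0.0, alpha=0.0, beta2=0.0, beta3=0.0, association="value",
             alpha_slope=None, alpha_auc=None):
    """Assemble a JointFit directly from coefficients (for worked examples)."""
    mixed = jt.MixedModelParams(
        beta0=0.0, beta1=0.0, beta2=beta2, beta3=beta3, beta4=0.0,
        beta_site=np.zeros(0), D=np.eye(2), sigma=1.0,
    )
    kw = {}
    if association == "value":
        kw["alpha_value"] = alpha
    elif association == "value_slope":
        kw.update(alpha_value=alpha, alpha_slope=alpha_slope)
    else:
        kw["alpha_auc"] = alpha_auc
    surv = jt.SurvivalParams(
        knots=np.zeros(0), log_lambda0=np.zeros(1), gamma_fortasyn=gamma1, **kw
    )
    spec = jt.JointSpec(association_type=association)
    return jt.JointFit(
        mixed=mixed, survival=surv, spec=spec, loglik=0.0, aic=0.0, bic=0.0,
        n_subjects=1, n_obs=1, n_events=0, converged=True,
        theta=np.zeros(1), param_names=["x"],
    )
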