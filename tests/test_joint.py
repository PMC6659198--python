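"""Joint-likelihood checks: hazard algebra, cumulative-hazard integration
oracles, quadrature correctness and stability, gradient validity, and the
fitting fixed point."""

from dataclasses import replace

import numpy as np
import pytest

import jointtrial as jt
from jointtrial.data import build_design
from jointtrial.joint import JointLikelihood, _init_values
from jointtrial.longitudinal import SubjectCovariates


def mixed_zero(**kw):
    base = dict(beta0=0.0, beta1=0.0, beta2=0.0, beta3=0.0, beta4=0.0,
                beta_site=np.zeros(2), D=np.eye(2), sigma=1.0)
    base.update(kw)
    return jt.MixedModelParams(**base)


def surv_params(**kw):
    base = dict(knots=np.zeros(0), log_lambda0=np.zeros(1),
                gamma_bmmse=0.0, gamma_site=np.zeros(2))
    base.update(kw)
    return jt.SurvivalParams(**base)


class TestHazard:
    def test_zero_coefficients_give_baseline(self):
        p = surv_params(knots=np.array([1.0]), log_lambda0=np.log([2.0, 5.0]),
                        alpha_value=0.0)
        cov = SubjectCovariates(fortasyn=1, bmmse=3.0, site=2)
        spec = jt.JointSpec(association_type="value")
        assert jt.hazard(mixed_zero(), p, spec, cov, (0.5, -0.5), 0.5) == pytest.approx(2.0)
        assert jt.hazard(mixed_zero(), p, spec, cov, (0.5, -0.5), 1.5) == pytest.approx(5.0)

    def test_value_association_hand_example(self):
        # trajectory value 2 with the printed association coefficient 0.701
        p = surv_params(alpha_value=0.701)
        cov = SubjectCovariates(fortasyn=0)
        out = jt.hazard(mixed_zero(), p, jt.JointSpec("value"), cov, (2.0, 0.0), 1.0)
        assert out == pytest.approx(np.exp(1.402), abs=1e-3)
        assert out == pytest.approx(4.063, abs=1e-3)

    def test_value_slope_nests_value(self):
        rng = np.random.default_rng(41)
        for _ in range(100):
            m = mixed_zero(beta0=rng.normal(), beta1=rng.normal(), beta3=rng.normal())
            a1 = rng.normal()
            pv = surv_params(alpha_value=a1, gamma_fortasyn=rng.normal())
            pvs = replace(pv, alpha_slope=0.0)
            cov = SubjectCovariates(fortasyn=int(rng.random() < 0.5))
            b = rng.normal(size=2)
            t = rng.uniform(0, 2)
            hv = jt.hazard(m, pv, jt.JointSpec("value"), cov, b, t)
            hvs = jt.hazard(m, pvs, jt.JointSpec("value_slope"), cov, b, t)
            assert hv == pytest.approx(hvs, rel=1e-12)

    def test_missing_association_parameter_raises(self):
        with pytest.raises(ValueError, match="alpha_value"):
            jt.hazard(mixed_zero(), surv_params(alpha_auc=1.0), jt.JointSpec("value"),
                      SubjectCovariates(fortasyn=0), (0, 0), 1.0)


class TestCumulativeHazard:
    def test_constant(self):
        p = surv_params(log_lambda0=np.array([np.log(2.0)]), alpha_value=0.0)
        out = jt.cumulative_hazard(mixed_zero(), p, jt.JointSpec("value"),
                                   SubjectCovariates(fortasyn=0), (0, 0), 1.5)
        assert out == pytest.approx(3.0)

    @pytest.mark.parametrize("assoc", ["value", "value_slope", "auc"])
    def test_matches_dense_trapezoid(self, assoc):
        rng = np.random.default_rng(43)
        spec = jt.JointSpec(assoc)
        for _ in range(25):
            m = mixed_zero(beta0=rng.normal(), beta1=rng.normal(0, 0.5),
                           beta2=rng.normal(0, 0.3), beta3=rng.normal(0, 0.3))
            kw = dict(knots=np.array([0.7, 1.4]), log_lambda0=rng.normal(size=3),
                      gamma_fortasyn=rng.normal(0, 0.3))
            if assoc == "value":
                kw["alpha_value"] = rng.normal(0, 0.5)
            elif assoc == "value_slope":
                kw.update(alpha_value=rng.normal(0, 0.5), alpha_slope=rng.normal(0, 0.5))
            else:
                kw["alpha_auc"] = rng.normal(0, 0.5)
            p = surv_params(**kw)
            cov = SubjectCovariates(fortasyn=int(rng.random() < 0.5))
            b = rng.normal(size=2) * 0.5
            T = rng.uniform(0.3, 2.0)
            ours = jt.cumulative_hazard(m, p, spec, cov, b, T)
            # trapezoid per baseline interval (the hazard jumps at the knots)
            edges = np.concatenate([[0.0], p.knots[p.knots < T], [T]])
            grid = 0.0
            for lo, hi in zip(edges[:-1], edges[1:]):
                s = np.linspace(lo, hi, max(int((hi - lo) / 1e-5), 2) + 1)
                lam_q = jt.baseline_hazard(p, (lo + hi) / 2)
                rel = jt.hazard(m, p, spec, cov, b, s) / jt.baseline_hazard(p, s)
                grid += np.trapezoid(lam_q * rel, s)
            assert ours == pytest.approx(grid, rel=1e-6)

    def test_auc_with_zero_alpha_reduces_to_baseline_integral(self):
        p = surv_params(knots=np.array([1.0]), log_lambda0=np.log([2.0, 3.0]),
                        alpha_auc=0.0)
        out = jt.cumulative_hazard(mixed_zero(beta0=4.0), p, jt.JointSpec("auc"),
                                   SubjectCovariates(fortasyn=0), (1.0, 1.0), 2.0)
        assert out == pytest.approx(5.0, rel=1e-12)


class TestSubjectLoglik:
    def test_reduces_to_longitudinal_marginal_when_no_survival_info(self):
        from scipy import stats

        m = jt.default_mixed()
        p = surv_params(alpha_value=0.0, log_lambda0=np.array([-30.0]))
        spec = jt.JointSpec("value", quadrature_points=15)
        rng = np.random.default_rng(47)
        t = np.array([0.0, 0.5, 1.0])
        cov = SubjectCovariates(fortasyn=1, bmmse=0.5, site=1)
        b_true = rng.multivariate_normal([0, 0], m.D)
        y = jt.trajectory_value(m, cov, b_true, t) + rng.normal(0, m.sigma, 3)
        sub = dict(y=y, t=t, cov=cov, T=1e-9, delta=0)
        ll = jt.subject_loglik(m, p, spec, sub)
        Z = np.column_stack([np.ones_like(t), t])
        V = Z @ m.D @ Z.T + m.sigma**2 * np.eye(3)
        oracle = stats.multivariate_normal.logpdf(
            y, mean=jt.trajectory_value(m, cov, (0, 0), t), cov=V
        )
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_degenerate_D_gives_plugin_likelihood(self):
        m = mixed_zero(beta0=1.0, beta1=0.5, D=np.eye(2) * 1e-12, sigma=0.7)
        p = surv_params(alpha_value=0.4, gamma_fortasyn=0.2, log_lambda0=np.array([-1.0]))
        spec = jt.JointSpec("value", quadrature_points=15)
        t = np.array([0.0, 1.0])
        cov = SubjectCovariates(fortasyn=1)
        y = np.array([1.1, 1.4])
        sub = dict(y=y, t=t, cov=cov, T=1.8, delta=1)
        ll = jt.subject_loglik(m, p, spec, sub)
        resid = y - jt.trajectory_value(m, cov, (0, 0), t)
        plug = (-len(y) / 2 * np.log(2 * np.pi * m.sigma**2)
                - resid @ resid / (2 * m.sigma**2)
                + np.log(jt.hazard(m, p, spec, cov, (0, 0), 1.8))
                - jt.cumulative_hazard(m, p, spec, cov, (0, 0), 1.8))
        assert ll == pytest.approx(plug, abs=1e-6)

    @pytest.mark.parametrize("assoc,n_draws",
                             [("value", 30_000), ("value_slope", 30_000),
                              ("auc", 10_000)])
    def test_matches_monte_carlo(self, assoc, n_draws):
        """Quadrature vs plain Monte-Carlo integration at modest draw counts
        (the 1e6-draw study-scale check lives in the acceptance suite)."""
        m = jt.default_mixed()
        surv = jt.default_survival(3, assoc)
        spec = jt.JointSpec(assoc, quadrature_points=15)
        ds = jt.simulate_trial(jt.default_config(
            n_subjects=5, seed=53, association_type=assoc, true_survival=surv))
        design = build_design(ds, True)
        rng = np.random.default_rng(59)
        draws = rng.multivariate_normal([0, 0], m.D, size=n_draws)
        for i in range(5):
            lo = design.obs_offsets[i]
            hi = lo + design.n_obs_per_subject[i]
            cov = SubjectCovariates(int(design.fortasyn[i]), float(design.bmmse_c[i]),
                                    int(design.site_code[i]))
            sub = dict(y=design.y_obs[lo:hi], t=design.t_obs[lo:hi], cov=cov,
                       T=design.event_time[i], delta=design.event[i])
            ll = jt.subject_loglik(m, surv, spec, sub)
            f = _integrand(m, surv, spec, sub, draws)
            mc, se = f.mean(), f.std() / np.sqrt(len(f))
            assert abs(np.exp(ll) - mc) < 3 * se


def _integrand(m, surv, spec, sub, draws):
    """Joint density of one subject's data given each random-effects draw."""
    y, t, cov, T, delta = sub["y"], sub["t"], sub["cov"], sub["T"], sub["delta"]
    vals = np.empty(len(draws))
    s2 = m.sigma**2
    for k, b in enumerate(draws):
        resid = y - jt.trajectory_value(m, cov, b, t)
        ll = -len(y) / 2 * np.log(2 * np.pi * s2) - resid @ resid / (2 * s2)
        ll -= jt.cumulative_hazard(m, surv, spec, cov, b, T)
        if delta:
            ll += np.log(jt.hazard(m, surv, spec, cov, b, T))
        vals[k] = np.exp(ll)
    return vals


@pytest.mark.parametrize("assoc", ["value", "value_slope", "auc"])
def test_analytic_gradient_matches_finite_differences(assoc):
    cfg = jt.default_config(n_subjects=30, seed=61, association_type=assoc,
                            true_survival=jt.default_survival(3, assoc))
    ds = jt.simulate_trial(cfg)
    spec = jt.JointSpec(assoc, quadrature_points=7, legendre_points=7,
                        n_baseline_intervals=3)
    design = build_design(ds, True)
    mixed0, surv0, knots, modes, covs = _init_values(design, spec, None)
    like = JointLikelihood(design, spec, knots, modes, covs)
    rng = np.random.default_rng(67)
    theta = like.packer.pack(mixed0, surv0) + 0.02 * rng.standard_normal(like.packer.n_params)
    _, g = like.loglik_and_grad(theta)
    for j in range(len(theta)):
        e = np.zeros_like(theta)
        e[j] = 1e-6 * max(1.0, abs(theta[j]))
        lp, _ = like.loglik_and_grad(theta + e, with_grad=False)
        lm, _ = like.loglik_and_grad(theta - e, with_grad=False)
        fd = (lp - lm) / (2 * e[j])
        assert g[j] == pytest.approx(fd, rel=1e-4, abs=1e-5)


class TestFitting:
    def test_fixed_point_and_score(self, small_trial):
        spec = jt.JointSpec("value", quadrature_points=7, n_baseline_intervals=3)
        fit = jt.fit_joint(small_trial, spec, compute_se=False)
        refit = jt.fit_joint(small_trial, spec, init=fit, compute_se=False)
        assert abs(refit.loglik - fit.loglik) < 1e-6
        # score check: numerical gradient at the optimum is ~0
        design = build_design(small_trial, True)
        from jointtrial.longitudinal import empirical_bayes_modes

        modes, covs = empirical_bayes_modes(fit.mixed, design)
        like = JointLikelihood(design, spec, fit.survival.knots, modes, covs)
        theta = like.packer.pack(fit.mixed, fit.survival)
        res = jt.fit_joint(small_trial, spec, init=fit, compute_se=False)
        th = res.theta
        like2 = JointLikelihood(design, spec, res.survival.knots,
                                *empirical_bayes_modes(res.mixed, design))
        g = np.zeros_like(th)
        for j in range(len(th)):
            e = np.zeros_like(th)
            e[j] = 1e-5 * max(1.0, abs(th[j]))
            lp, _ = like2.loglik_and_grad(th + e, with_grad=False)
            lm, _ = like2.loglik_and_grad(th - e, with_grad=False)
            g[j] = (lp - lm) / (2 * e[j])
        assert np.max(np.abs(g)) < 1e-3
        del like, theta

    def test_loglik_invariant_to_relabelling(self, small_trial):
        m = jt.default_mixed()
        s = jt.default_survival()
        spec = jt.JointSpec("value", quadrature_points=7)
        ll0 = jt.joint_loglik(small_trial, spec, m, s)
        rng = np.random.default_rng(71)
        long = small_trial.longitudinal.sample(frac=1, random_state=3).reset_index(drop=True)
        surv = small_trial.survival.sample(frac=1, random_state=4).reset_index(drop=True)
        relabel = {sid: f"Z{i:03d}" for i, sid in
                   enumerate(rng.permutation(surv.subject_id.unique()))}
        shuffled = jt.TrialDataset(
            longitudinal=long.assign(subject_id=long.subject_id.map(relabel)),
            survival=surv.assign(subject_id=surv.subject_id.map(relabel)),
        )
        ll1 = jt.joint_loglik(shuffled, spec, m, s)
        assert abs(ll0 - ll1) < 1e-6

    def test_quadrature_stability(self, trial_311, value_fit_311):
        m, s = value_fit_311.mixed, value_fit_311.survival
        lls = [
            jt.joint_loglik(trial_311, jt.JointSpec("value", quadrature_points=q), m, s)
            for q in (15, 25)
        ]
        assert abs(lls[0] - lls[1]) < 1e-3

    def test_separability_when_no_association(self):
        truth_surv = surv_params(alpha_value=0.0, gamma_fortasyn=0.2,
                                 gamma_bmmse=-0.1, log_lambda0=np.array([-1.2]))
        cfg = jt.default_config(n_subjects=200, seed=73, true_survival=truth_surv)
        ds = jt.simulate_trial(cfg)
        lmm = jt.fit_lmm(ds)
        spec = jt.JointSpec("value", quadrature_points=9, n_baseline_intervals=3)
        joint = jt.fit_joint(ds, spec)
        diffs = np.abs(joint.mixed.fixed_vector() - lmm.params.fixed_vector())
        ses = lmm.fixed_se()
        assert np.mean(diffs / ses) < 0.5

    def test_empirical_bayes_modes_returned(self, small_trial):
        spec = jt.JointSpec("value", quadrature_points=7, n_baseline_intervals=3)
        fit = jt.fit_joint(small_trial, spec, compute_se=False, compute_eb=True)
        assert fit.empirical_bayes.shape == (small_trial.n_subjects, 2)
        assert np.isfinite(fit.empirical_bayes).all()


class TestInformationCriteria:
    def test_formula(self):
        fit = _dummy_fit(loglik=-100.0, p=10, n=100)
        aic, bic = jt.information_criteria(fit)
        assert aic == pytest.approx(220.0)
        assert bic == pytest.approx(200 + 10 * np.log(100))

    def test_nesting_loglik(self, small_trial):
        spec_v = jt.JointSpec("value", quadrature_points=7, n_baseline_intervals=3)
        fit_v = jt.fit_joint(small_trial, spec_v, compute_se=False)
        spec_vs = jt.JointSpec("value_slope", quadrature_points=7, n_baseline_intervals=3)
        init = (fit_v.mixed, replace(fit_v.survival, alpha_slope=0.0))
        fit_vs = jt.fit_joint(small_trial, spec_vs, init=init, compute_se=False)
        assert fit_vs.loglik >= fit_v.loglik - 1e-6


def _dummy_fit(loglik, p, n):
    return jt.JointFit(
        mixed=mixed_zero(), survival=surv_params(alpha_value=0.0),
        spec=jt.JointSpec("value"), loglik=loglik, aic=np.nan, bic=np.nan,
        n_subjects=n, n_obs=n, n_events=0, converged=True,
        theta=np.zeros(p), param_names=[f"p{i}" for i in range(p)],
    )
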