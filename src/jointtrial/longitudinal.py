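"""Linear mixed sub-model for the longitudinal outcome.

The subject-specific trajectory is

    m_i(t) = beta0 + beta1*t + beta2*arm_i + beta3*arm_i*t
             + beta4*bmmse_i + beta_site'site_i + b_i0 + b_i1*t,

with (b_i0, b_i1) ~ N(0, D) shared with the survival sub-model and
residuals eps ~ N(0, sigma^2). Fitting is by maximum likelihood (not REML)
so that estimates sit on the same scale as the joint likelihood they
initialize. D is parameterized by its log-Cholesky factor during
optimization to stay positive definite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .data import TrialDataset, TrialDesign, build_design


class CovariateError(ValueError):
    """Unknown or incomplete subject covariates."""


@dataclass
class SubjectCovariates:
    """Baseline covariates of one subject; ``site`` is a 0-based level index
    (0 = reference site)."""

    fortasyn: int
    bmmse: float = 0.0
    site: int = 0


@dataclass
class MixedModelParams:
    """Fixed effects, random-effects covariance and residual s.d. of the
    longitudinal sub-model.

    ``beta_site`` holds reference-coded site contrasts (length n_sites - 1).
    """

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    beta4: float
    beta_site: np.ndarray
    D: np.ndarray
    sigma: float

    def __post_init__(self):
        self.beta_site = np.atleast_1d(np.asarray(self.beta_site, dtype=float))
        self.D = np.asarray(self.D, dtype=float)
        self.validate()

    def validate(self):
        if self.D.shape != (2, 2):
            raise ValueError("D must be 2x2")
        if not np.allclose(self.D, self.D.T):
            raise ValueError("D must be symmetric")
        try:
            np.linalg.cholesky(self.D)
        except np.linalg.LinAlgError as err:
            raise ValueError("D must be positive definite") from err
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")

    @property
    def n_sites(self) -> int:
        return len(self.beta_site) + 1

    def fixed_vector(self) -> np.ndarray:
        return np.concatenate(
            [[self.beta0, self.beta1, self.beta2, self.beta3, self.beta4], self.beta_site]
        )

    @classmethod
    def from_fixed_vector(cls, beta, D, sigma) -> "MixedModelParams":
        beta = np.asarray(beta, dtype=float)
        return cls(
            beta0=beta[0], beta1=beta[1], beta2=beta[2], beta3=beta[3], beta4=beta[4],
            beta_site=beta[5:], D=D, sigma=sigma,
        )


@dataclass
class LMMFit:
    """Maximum-likelihood fit of the longitudinal sub-model."""

    params: MixedModelParams
    vcov_fixed: np.ndarray
    loglik: float
    converged: bool
    empirical_bayes: np.ndarray       # (n, 2) posterior modes of (b0, b1)
    eb_cov: np.ndarray                # (n, 2, 2) posterior covariances
    x_names: list = field(default_factory=list)

    def fixed_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov_fixed))


def _site_contrast(params: MixedModelParams, site: int) -> float:
    if site < 0 or site >= params.n_sites:
        raise CovariateError(f"unknown site level index {site} (model has {params.n_sites} sites)")
    return 0.0 if site == 0 else float(params.beta_site[site - 1])


def trajectory_parts(params: MixedModelParams, cov: SubjectCovariates, random_effects):
    """Return (P, Q) with m_i(t) = P + Q t."""
    b0, b1 = random_effects
    P = (
        params.beta0
        + params.beta2 * cov.fortasyn
        + params.beta4 * cov.bmmse
        + _site_contrast(params, cov.site)
        + b0
    )
    Q = params.beta1 + params.beta3 * cov.fortasyn + b1
    return P, Q


def trajectory_value(params: MixedModelParams, cov: SubjectCovariates, random_effects, t):
    """Error-free trajectory m_i(t); linear in t for a fixed subject."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    P, Q = trajectory_parts(params, cov, random_effects)
    return P + Q * t


def trajectory_slope(params: MixedModelParams, cov: SubjectCovariates, random_effects):
    """d/dt m_i(t) = beta1 + beta3*fortasyn + b_i1 (constant in t)."""
    _, Q = trajectory_parts(params, cov, random_effects)
    return Q


def trajectory_auc(params: MixedModelParams, cov: SubjectCovariates, random_effects, t):
    """Cumulative trajectory integral_0^t m_i(s) ds = P t + Q t^2 / 2."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    P, Q = trajectory_parts(params, cov, random_effects)
    return P * t + Q * t**2 / 2.0


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def chol_from_u(u) -> np.ndarray:
    """Lower-triangular Cholesky factor from the log-Cholesky vector
    (log c11, c21, log c22)."""
    return np.array([[np.exp(u[0]), 0.0], [u[1], np.exp(u[2])]])


def u_from_D(D) -> np.ndarray:
    C = np.linalg.cholesky(D)
    return np.array([np.log(C[0, 0]), C[1, 0], np.log(C[1, 1])])


def _groups(design: TrialDesign):
    """Group subjects by visit count for batched per-subject linear algebra."""
    offsets = design.obs_offsets
    n_obs = design.n_obs_per_subject
    out = []
    for ni in np.unique(n_obs):
        idx = np.flatnonzero(n_obs == ni)
        rows = (offsets[idx][:, None] + np.arange(ni)[None, :]).ravel()
        Y = design.y_obs[rows].reshape(len(idx), ni)
        T = design.t_obs[rows].reshape(len(idx), ni)
        Xg = design.X[rows].reshape(len(idx), ni, design.p_x)
        Z = np.stack([np.ones_like(T), T], axis=2)  # (g, ni, 2)
        out.append((idx, Y, T, Xg, Z))
    return out


def _profile_pieces(groups, D, sigma2):
    """Per-group V^{-1}, log|V| and GLS accumulators for fixed variance params."""
    A = 0.0
    c = 0.0
    logdet_sum = 0.0
    Vinvs = []
    for idx, Y, T, Xg, Z in groups:
        ni = Y.shape[1]
        V = np.einsum("gia,ab,gjb->gij", Z, D, Z) + sigma2 * np.eye(ni)
        Vinv = np.linalg.inv(V)
        sign, logdet = np.linalg.slogdet(V)
        logdet_sum += logdet.sum()
        A = A + np.einsum("gip,gij,gjq->pq", Xg, Vinv, Xg)
        c = c + np.einsum("gip,gij,gj->p", Xg, Vinv, Y)
        Vinvs.append(Vinv)
    return A, c, logdet_sum, Vinvs


def marginal_loglik(params: MixedModelParams, dataset_or_design) -> float:
    """Marginal normal log-likelihood of the longitudinal data under ``params``.

    Integrates the random effects analytically: per subject,
    y_i ~ N(X_i beta, Z_i D Z_i' + sigma^2 I).
    """
    design = (
        dataset_or_design
        if isinstance(dataset_or_design, TrialDesign)
        else build_design(dataset_or_design)
    )
    beta = params.fixed_vector()
    groups = _groups(design)
    ll = 0.0
    N = 0
    for idx, Y, T, Xg, Z in groups:
        ni = Y.shape[1]
        N += Y.size
        V = np.einsum("gia,ab,gjb->gij", Z, params.D, Z) + params.sigma**2 * np.eye(ni)
        Vinv = np.linalg.inv(V)
        sign, logdet = np.linalg.slogdet(V)
        r = Y - Xg @ beta
        quad = np.einsum("gi,gij,gj->", r, Vinv, r)
        ll += -0.5 * (logdet.sum() + quad)
    return float(ll - 0.5 * N * np.log(2 * np.pi))


def empirical_bayes_modes(params: MixedModelParams, design: TrialDesign):
    """Longitudinal-only posterior modes/covariances of (b0, b1) per subject.

    The posterior is Gaussian: cov = (Z'Z/sigma^2 + D^{-1})^{-1},
    mean = cov @ Z'r / sigma^2 with r the fixed-effect residual.
    """
    beta = params.fixed_vector()
    Dinv = np.linalg.inv(params.D)
    s2 = params.sigma**2
    n = design.n_subjects
    modes = np.zeros((n, 2))
    covs = np.zeros((n, 2, 2))
    resid = design.y_obs - design.X @ beta
    for idx, Y, T, Xg, Z in _groups(design):
        ZtZ = np.einsum("gia,gib->gab", Z, Z)
        prec = ZtZ / s2 + Dinv
        cov = np.linalg.inv(prec)
        r = Y - np.einsum("gip,p->gi", Xg, beta)
        rhs = np.einsum("gia,gi->ga", Z, r) / s2
        mu = np.einsum("gab,gb->ga", cov, rhs)
        modes[idx] = mu
        covs[idx] = cov
    del resid
    return modes, covs


def fit_lmm(
    dataset_or_design,
    fixed_variance: tuple | None = None,
    start: MixedModelParams | None = None,
) -> LMMFit:
    """Fit the linear mixed sub-model by maximum likelihood.

    Profiles the fixed effects out of the marginal normal likelihood and
    optimizes the 4 variance parameters (log-Cholesky of D, log sigma) by
    quasi-Newton. ``fixed_variance=(D, sigma)`` skips the variance
    optimization and returns the GLS fixed effects for those values
    (useful for degenerate-D checks).
    """
    design = (
        dataset_or_design
        if isinstance(dataset_or_design, TrialDesign)
        else build_design(dataset_or_design)
    )
    groups = _groups(design)
    N = len(design.y_obs)

    # rank check on the pooled fixed-effects design
    rank = np.linalg.matrix_rank(design.X)
    if rank < design.p_x:
        u, s, vt = np.linalg.svd(design.X, full_matrices=False)
        bad = [design.x_names[i] for i in np.argsort(np.abs(vt[-1]))[::-1][:2]]
        raise ValueError(f"rank-deficient longitudinal design; near-collinear columns: {bad}")

    def negloglik(phi):
        D = chol_from_u(phi[:3]) @ chol_from_u(phi[:3]).T
        sigma2 = np.exp(2 * phi[3])
        A, c, logdet_sum, Vinvs = _profile_pieces(groups, D, sigma2)
        beta = np.linalg.solve(A, c)
        quad = 0.0
        for (idx, Y, T, Xg, Z), Vinv in zip(groups, Vinvs):
            r = Y - np.einsum("gip,p->gi", Xg, beta)
            quad += np.einsum("gi,gij,gj->", r, Vinv, r)
        ll = -0.5 * (N * np.log(2 * np.pi) + logdet_sum + quad)
        return -ll

    if fixed_variance is not None:
        D, sigma = fixed_variance
        D = np.asarray(D, dtype=float)
        A, c, logdet_sum, Vinvs = _profile_pieces(groups, D, sigma**2)
        beta = np.linalg.solve(A, c)
        params = MixedModelParams.from_fixed_vector(beta, D, sigma)
        ll = marginal_loglik(params, design)
        modes, covs = empirical_bayes_modes(params, design)
        return LMMFit(params, np.linalg.inv(A), ll, True, modes, covs, design.x_names)

    if start is not None:
        phi0 = np.concatenate([u_from_D(start.D), [np.log(start.sigma)]])
    else:
        # crude start: pooled OLS residual variance split between levels
        beta_ols, *_ = np.linalg.lstsq(design.X, design.y_obs, rcond=None)
        s2 = max(np.var(design.y_obs - design.X @ beta_ols), 1e-4)
        phi0 = np.array([0.5 * np.log(s2 / 2), 0.0, 0.5 * np.log(s2 / 4), 0.5 * np.log(s2 / 2)])

    res = optimize.minimize(negloglik, phi0, method="BFGS", options={"gtol": 1e-6, "maxiter": 500})
    phi = res.x
    C = chol_from_u(phi[:3])
    D = C @ C.T
    sigma = float(np.exp(phi[3]))
    A, c, logdet_sum, Vinvs = _profile_pieces(groups, D, sigma**2)
    beta = np.linalg.solve(A, c)
    params = MixedModelParams.from_fixed_vector(beta, D, sigma)
    modes, covs = empirical_bayes_modes(params, design)
    return LMMFit(
        params=params,
        vcov_fixed=np.linalg.inv(A),
        loglik=float(-res.fun),
        converged=bool(res.success),
        empirical_bayes=modes,
        eb_cov=covs,
        x_names=design.x_names,
    )
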