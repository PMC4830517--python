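"""Maximum-likelihood linear mixed model for log1p-transformed claim counts.

The longitudinal sub-model is

    y_ij = m_i(t_ij) + eps_ij,   m_i(t) = (beta0 + b_i0) + (beta1 + b_i1) t,

with subject random effects b_i ~ N(0, D) (random intercept, optionally a
correlated random slope) and residuals eps_ij ~ N(0, sigma^2).  The random
effects are integrated analytically, and the marginal Gaussian likelihood
is maximised by quasi-Newton over log-standard-deviations and an
atanh-correlation so the search space is unconstrained.  ML (not REML) is
used throughout so that likelihood-ratio tests and AIC remain comparable
with the joint fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ._numdiff import numeric_hessian, safe_inverse
from .data import Cohort, Subject

logger = logging.getLogger(__name__)

_LOG_SD_MIN, _LOG_SD_MAX = -15.0, 5.0
_SIGMA_FLOOR = 1e-9


@dataclass
class MixedModelParams:
    """Estimates for the longitudinal sub-model (natural scale)."""

    beta: np.ndarray  # (beta0, beta1)
    sd_b0: float
    sigma: float
    sd_b1: float | None = None
    corr_b: float | None = None
    loglik: float = np.nan
    se: dict = field(default_factory=dict)
    n_subjects: int = 0
    n_obs: int = 0
    converged: bool = True
    message: str = ""

    @property
    def random_slope(self) -> bool:
        return self.sd_b1 is not None

    @property
    def dim(self) -> int:
        return 2 if self.random_slope else 1

    @property
    def D(self) -> np.ndarray:
        """Random-effects covariance, (dim x dim)."""
        if not self.random_slope:
            return np.array([[self.sd_b0**2]])
        cov = self.corr_b * self.sd_b0 * self.sd_b1
        return np.array([[self.sd_b0**2, cov], [cov, self.sd_b1**2]])

    @property
    def n_params(self) -> int:
        return 4 if not self.random_slope else 6


def _grouped_data(cohort: Cohort):
    """Group subjects by identical occasion-time patterns for fast batching."""
    groups: dict[tuple, list[np.ndarray]] = {}
    for s in cohort.subjects:
        if not s.records:
            continue
        key = tuple(round(r.t, 12) for r in s.records)
        groups.setdefault(key, []).append(np.array([r.y for r in s.records]))
    out = []
    for key, ys in groups.items():
        t = np.array(key, dtype=float)
        out.append((t, np.vstack(ys)))
    return out


def _phi_to_D(phi: np.ndarray, random_slope: bool):
    if random_slope:
        sb0, sb1 = np.exp(phi[0]), np.exp(phi[1])
        rho = np.tanh(phi[2])
        sigma = np.exp(phi[3])
        D = np.array([[sb0**2, rho * sb0 * sb1], [rho * sb0 * sb1, sb1**2]])
    else:
        sb0 = np.exp(phi[0])
        sigma = np.exp(phi[1])
        D = np.array([[sb0**2]])
    return D, sigma


def _marginal_pieces(groups, D: np.ndarray, sigma: float, random_slope: bool):
    """Sufficient pieces of the marginal likelihood across pattern groups.

    Returns (sum_logdet, q, bvec, A, N) where q = sum_i y_i' V^-1 y_i,
    bvec = sum_i X' V^-1 y_i and A = sum_i X' V^-1 X for design X = (1, t).
    """
    sum_logdet = 0.0
    q = 0.0
    bvec = np.zeros(2)
    A = np.zeros((2, 2))
    N = 0
    for t, Y in groups:
        n_t = t.size
        m = Y.shape[0]
        X = np.column_stack([np.ones(n_t), t])
        Z = X[:, : (2 if random_slope else 1)]
        V = Z @ D @ Z.T + sigma**2 * np.eye(n_t)
        sign, logdet = np.linalg.slogdet(V)
        if sign <= 0:
            return None
        Vi = np.linalg.inv(V)
        sum_logdet += m * logdet
        Yv = Y @ Vi  # (m, n_t)
        q += float(np.sum(Yv * Y))
        ysum = Y.sum(axis=0)
        bvec += X.T @ (Vi @ ysum)
        A += m * (X.T @ Vi @ X)
        N += m * n_t
    return sum_logdet, q, bvec, A, N


def _profiled_nll(phi, groups, random_slope):
    D, sigma = _phi_to_D(phi, random_slope)
    pieces = _marginal_pieces(groups, D, max(sigma, _SIGMA_FLOOR), random_slope)
    if pieces is None:
        return 1e10, np.zeros(2)
    sum_logdet, q, bvec, A, N = pieces
    try:
        beta = np.linalg.solve(A, bvec)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros(2)
    rss = q - 2.0 * bvec @ beta + beta @ A @ beta
    nll = 0.5 * (sum_logdet + rss + N * np.log(2.0 * np.pi))
    if not np.isfinite(nll):
        return 1e10, beta
    return nll, beta


def _full_nll(theta, groups, random_slope):
    """Negative marginal log-likelihood at (beta, phi) jointly (for SEs)."""
    beta, phi = theta[:2], theta[2:]
    D, sigma = _phi_to_D(phi, random_slope)
    pieces = _marginal_pieces(groups, D, max(sigma, _SIGMA_FLOOR), random_slope)
    if pieces is None:
        return 1e10
    sum_logdet, q, bvec, A, N = pieces
    rss = q - 2.0 * bvec @ beta + beta @ A @ beta
    return 0.5 * (sum_logdet + rss + N * np.log(2.0 * np.pi))


def fit_lmm(
    cohort: Cohort,
    random_slope: bool = True,
    max_iter: int = 500,
    compute_se: bool = True,
) -> MixedModelParams:
    """ML fit of the linear mixed sub-model on a cohort.

    Requires at least two subjects with at least one record each.
    Deterministic given the data.  Standard errors come from the
    numerically differentiated observed information on the transformed
    scale, delta-method-mapped back to natural units.
    """
    groups = _grouped_data(cohort)
    n_sub = sum(Y.shape[0] for _, Y in groups)
    if n_sub < 2:
        raise ValueError("fit_lmm needs at least 2 subjects with records")
    n_obs = sum(Y.size for _, Y in groups)

    # pooled OLS for initial values
    all_t = np.concatenate([np.tile(t, Y.shape[0]) for t, Y in groups])
    all_y = np.concatenate([Y.ravel() for _, Y in groups])
    Xp = np.column_stack([np.ones_like(all_t), all_t])
    beta_ols, *_ = np.linalg.lstsq(Xp, all_y, rcond=None)
    resid_sd = max(np.std(all_y - Xp @ beta_ols), 1e-3)
    # the correlation is kept off the |corr| = 1 knife edge and the SDs off
    # exact zero: the boundary solutions there are statistically equivalent
    # (profile is flat) but produce degenerate posteriors downstream
    if random_slope:
        phi0 = np.array(
            [np.log(0.6 * resid_sd), np.log(0.1 * resid_sd), 0.0, np.log(0.7 * resid_sd)]
        )
        bounds = [
            (np.log(1e-3), _LOG_SD_MAX),
            (np.log(5e-4), _LOG_SD_MAX),
            (-1.832, 1.832),
            (np.log(1e-3), _LOG_SD_MAX),
        ]
    else:
        phi0 = np.array([np.log(0.6 * resid_sd), np.log(0.7 * resid_sd)])
        bounds = [(np.log(1e-3), _LOG_SD_MAX), (np.log(1e-3), _LOG_SD_MAX)]

    res = minimize(
        lambda p: _profiled_nll(p, groups, random_slope)[0],
        phi0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
    )
    nll, beta = _profiled_nll(res.x, groups, random_slope)
    D, sigma = _phi_to_D(res.x, random_slope)

    se: dict = {}
    if compute_se:
        theta_hat = np.concatenate([beta, res.x])
        H = numeric_hessian(lambda th: _full_nll(th, groups, random_slope), theta_hat)
        V, is_pd = safe_inverse(H)
        # delta method: natural = (b0, b1, sd_b0, [sd_b1, rho], sigma)
        if random_slope:
            jac = np.array(
                [1.0, 1.0, np.exp(res.x[0]), np.exp(res.x[1]), 1 - np.tanh(res.x[2]) ** 2,
                 np.exp(res.x[3])]
            )
            names = ["beta0", "beta1", "sd_b0", "sd_b1", "corr_b", "sigma"]
        else:
            jac = np.array([1.0, 1.0, np.exp(res.x[0]), np.exp(res.x[1])])
            names = ["beta0", "beta1", "sd_b0", "sigma"]
        sds = jac * np.sqrt(np.clip(np.diag(V), 0.0, None))
        se = dict(zip(names, sds))
        if not is_pd:
            se["_information_pd"] = False

    params = MixedModelParams(
        beta=beta,
        sd_b0=float(np.sqrt(D[0, 0])),
        sd_b1=float(np.sqrt(D[1, 1])) if random_slope else None,
        corr_b=float(D[0, 1] / np.sqrt(D[0, 0] * D[1, 1])) if random_slope else None,
        sigma=float(sigma),
        loglik=-float(nll),
        se=se,
        n_subjects=n_sub,
        n_obs=n_obs,
        converged=bool(res.success),
        message=str(res.message),
    )
    if not res.success:
        logger.warning("fit_lmm did not fully converge: %s", res.message)
    return params


def eb_posterior(params: MixedModelParams, subject: Subject):
    """Gaussian posterior (mean, covariance) of b given the subject's y only.

    A subject with no records gets the prior N(0, D).  In the
    noise-free limit (sigma -> 0) with enough distinct occasions the
    posterior concentrates on the subject's exact least-squares line.
    """
    d = params.dim
    D = params.D
    if not subject.records:
        return np.zeros(d), D.copy()
    t = np.array([r.t for r in subject.records])
    y = np.array([r.y for r in subject.records])
    Z = np.column_stack([np.ones_like(t), t])[:, :d]
    r = y - (params.beta[0] + params.beta[1] * t)
    if params.sigma < 1e-8 and np.linalg.matrix_rank(Z) >= d:
        mu, *_ = np.linalg.lstsq(Z, r, rcond=None)
        return mu, np.zeros((d, d))
    sig2 = max(params.sigma, 1e-8) ** 2
    # guard near-singular D (e.g. boundary sd estimates)
    Dr = D + 1e-12 * np.eye(d)
    prec = Z.T @ Z / sig2 + np.linalg.inv(Dr)
    Sigma = np.linalg.inv(prec)
    mu = Sigma @ (Z.T @ r) / sig2
    return mu, Sigma


def empirical_bayes(params: MixedModelParams, subject: Subject) -> np.ndarray:
    """Posterior mode (= mean) of the subject's random effects given y."""
    return eb_posterior(params, subject)[0]
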