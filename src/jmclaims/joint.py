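"""Joint likelihood of the longitudinal and survival processes.

The two sub-models share the subject random effects b_i:

    y_i(t)   = m_i(t) + eps_i(t),     m_i(t) = (b0+b_i0) + (b1+b_i1) t
    h_i(t)   = h0(t) exp{gamma' w_i + alpha F(m_i(t))}

with b_i ~ N(0, D), eps ~ N(0, sigma^2), h0 an exponentiated cubic
B-spline and F the recency-weighted cumulative effect.  Each subject's
likelihood contribution integrates the product of the longitudinal
density, the survival density and the random-effect prior over b_i;
the integral is evaluated by *pseudo-adaptive* Gauss-Hermite
quadrature, i.e. the Hermite grid is recentred and rescaled once at the
subject's empirical-Bayes posterior (from the separate longitudinal
fit) and then held fixed during optimisation.

Maximisation is direct quasi-Newton over an unconstrained
parametrisation (log standard deviations, atanh correlation); standard
errors come from the numerically differentiated observed information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import chi2

from ._numdiff import hessian_from_grad, safe_inverse
from ._quad import hermite_grid, legendre_01
from .data import Cohort, Subject
from .longitudinal import MixedModelParams, eb_posterior, fit_lmm
from .survival import (
    BaselineHazard,
    SurvivalParams,
    default_knots,
    fit_cox_separate,
    fit_parametric_ph,
    survival_frame,
)
from .weights import ASSOCIATION_MODES, WeightFunction, default_weight, kernel_moments

logger = logging.getLogger(__name__)

_BIG = 1e10


@dataclass
class JointModelParams:
    """All parameters of the joint model on the natural scale."""

    beta: np.ndarray
    sd_b0: float
    sigma: float
    gamma: np.ndarray
    alpha: np.ndarray  # length 1, or 2 in value-plus-slope mode
    baseline: BaselineHazard
    weight: WeightFunction
    sd_b1: float | None = None
    corr_b: float | None = None
    mode: str = "weighted-cumulative"
    covariate_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    # fixed offset subtracted from the association feature; absorbed into the
    # spline level, it decorrelates alpha from the baseline during fitting
    feature_center: float = 0.0

    @property
    def random_slope(self) -> bool:
        return self.sd_b1 is not None

    @property
    def dim(self) -> int:
        return 2 if self.random_slope else 1

    @property
    def D(self) -> np.ndarray:
        if not self.random_slope:
            return np.array([[self.sd_b0**2]])
        cov = self.corr_b * self.sd_b0 * self.sd_b1
        return np.array([[self.sd_b0**2, cov], [cov, self.sd_b1**2]])

    def longitudinal_view(self) -> MixedModelParams:
        return MixedModelParams(
            beta=self.beta.copy(),
            sd_b0=self.sd_b0,
            sd_b1=self.sd_b1,
            corr_b=self.corr_b,
            sigma=self.sigma,
        )


@dataclass
class FittedJointModel:
    params: JointModelParams
    loglik: float
    aic: float
    n_params: int
    n_subjects: int
    se: dict = field(default_factory=dict)
    vcov_transformed: np.ndarray | None = None
    theta_transformed: np.ndarray | None = None
    converged: bool = True
    message: str = ""
    n_ghq: int = 9
    information_pd: bool = True


# ---------------------------------------------------------------------------
# parameter packing


def _n_alpha(mode: str) -> int:
    return 2 if mode == "value-plus-slope" else 1


def _pack(params: JointModelParams) -> np.ndarray:
    """Natural -> unconstrained transformed vector."""
    parts = [params.beta[0], params.beta[1], np.log(params.sd_b0)]
    if params.random_slope:
        parts += [np.log(params.sd_b1), np.arctanh(np.clip(params.corr_b, -0.999999, 0.999999))]
    parts += [np.log(params.sigma)]
    parts += list(params.gamma)
    parts += list(np.atleast_1d(params.alpha))
    parts += list(params.baseline.coefs)
    return np.array(parts, dtype=float)


def _unpack(theta: np.ndarray, template: JointModelParams) -> JointModelParams:
    random_slope = template.random_slope
    k = 0
    beta = theta[k : k + 2]
    k += 2
    sd_b0 = float(np.exp(theta[k]))
    k += 1
    if random_slope:
        sd_b1 = float(np.exp(theta[k]))
        corr_b = float(np.tanh(theta[k + 1]))
        k += 2
    else:
        sd_b1, corr_b = None, None
    sigma = float(np.exp(theta[k]))
    k += 1
    gamma = theta[k : k + 3]
    k += 3
    na = _n_alpha(template.mode)
    alpha = theta[k : k + na]
    k += na
    coefs = theta[k:]
    baseline = BaselineHazard(
        knots=template.baseline.knots.copy(),
        boundary=template.baseline.boundary,
        coefs=coefs.copy(),
        degree=template.baseline.degree,
    )
    return JointModelParams(
        beta=beta.copy(),
        sd_b0=sd_b0,
        sd_b1=sd_b1,
        corr_b=corr_b,
        sigma=sigma,
        gamma=gamma.copy(),
        alpha=alpha.copy(),
        baseline=baseline,
        weight=template.weight,
        mode=template.mode,
        covariate_center=template.covariate_center.copy(),
        feature_center=template.feature_center,
    )


def _natural_jacobian(theta: np.ndarray, template: JointModelParams) -> np.ndarray:
    """Diagonal Jacobian d(natural)/d(transformed) for the delta method."""
    random_slope = template.random_slope
    jac = [1.0, 1.0, np.exp(theta[2])]
    k = 3
    if random_slope:
        jac += [np.exp(theta[3]), 1.0 - np.tanh(theta[4]) ** 2]
        k = 5
    jac += [np.exp(theta[k])]
    n_rest = theta.size - (k + 1)
    jac += [1.0] * n_rest
    return np.array(jac)


def _param_names(template: JointModelParams) -> list[str]:
    names = ["beta0", "beta1", "sd_b0"]
    if template.random_slope:
        names += ["sd_b1", "corr_b"]
    names += ["sigma", "gamma_sex", "gamma_age0", "gamma_sex_age0"]
    if template.mode == "value-plus-slope":
        names += ["alpha_value", "alpha_slope"]
    else:
        names += ["alpha"]
    names += [f"spline_{j}" for j in range(template.baseline.n_basis)]
    return names


# ---------------------------------------------------------------------------
# likelihood machinery


class _JointDesign:
    """Precomputed, parameter-independent arrays for the joint likelihood."""

    def __init__(
        self,
        cohort: Cohort,
        template: JointModelParams,
        lmm_for_modes: MixedModelParams,
        n_ghq: int = 9,
        n_outer: int = 7,
        n_inner: int = 15,
    ):
        self.template = template
        self.mode = template.mode
        d = template.dim
        self.d = d
        subs = cohort.subjects
        n = len(subs)
        self.n = n

        # longitudinal sufficient statistics per subject
        self.n_i = np.array([len(s.records) for s in subs], dtype=float)
        self.St = np.array([sum(r.t for r in s.records) for s in subs])
        self.Stt = np.array([sum(r.t**2 for r in s.records) for s in subs])
        self.Sy = np.array([sum(r.y for r in s.records) for s in subs])
        self.Sty = np.array([sum(r.t * r.y for r in s.records) for s in subs])
        self.Syy = np.array([sum(r.y**2 for r in s.records) for s in subs])

        # survival design
        self.T = np.array([s.t_obs for s in subs])
        self.delta = np.array([s.delta for s in subs], dtype=float)
        W_raw = survival_frame(cohort)[["sex", "age0", "sex_age0"]].to_numpy(dtype=float)
        self.W = W_raw - template.covariate_center

        x, wt = legendre_01(n_outer)
        self.outer_w = wt
        self.s_nodes = self.T[:, None] * x  # (n, n_outer)
        bh = template.baseline
        self.basis_T = bh.basis(self.T)  # (n, K)
        self.basis_s = bh.basis(np.minimum(self.s_nodes.ravel(), bh.boundary[1])).reshape(
            n, n_outer, -1
        )
        if self.mode == "weighted-cumulative":
            self.W0s, self.W1s = kernel_moments(template.weight, self.s_nodes, n_inner)
            self.W0T, self.W1T = kernel_moments(template.weight, self.T, n_inner)

        # pseudo-adaptive Gauss-Hermite grid per subject
        z, logw = hermite_grid(n_ghq, d)
        self.Q = z.shape[0]
        B = np.empty((n, self.Q, d))
        log_det = np.empty(n)
        for i, s in enumerate(subs):
            mu, Sig = eb_posterior(lmm_for_modes, s)
            mu = np.atleast_1d(mu)[:d]
            Sig = np.atleast_2d(Sig)[:d, :d]
            # inflate a floor so degenerate posteriors still spread nodes
            Sig = Sig + 1e-10 * np.eye(d)
            L = np.linalg.cholesky(Sig)
            B[i] = mu[None, :] + np.sqrt(2.0) * z @ L.T
            log_det[i] = np.log(np.diag(L)).sum()
        self.B = B
        self.log_norm = log_det + 0.5 * d * np.log(2.0)  # per-subject constant
        self.logw = logw  # (Q,)

    def loglik_vector(self, params: JointModelParams) -> np.ndarray:
        """Per-subject log-likelihood contributions."""
        d = self.d
        b0 = self.B[:, :, 0]
        b1 = self.B[:, :, 1] if d == 2 else np.zeros_like(b0)
        a = params.beta[0] + b0  # (n, Q)
        slope = params.beta[1] + b1

        sig2 = max(params.sigma, 1e-8) ** 2
        rss = (
            self.Syy[:, None]
            - 2.0 * (a * self.Sy[:, None] + slope * self.Sty[:, None])
            + a**2 * self.n_i[:, None]
            + 2.0 * a * slope * self.St[:, None]
            + slope**2 * self.Stt[:, None]
        )
        ll_y = -0.5 * self.n_i[:, None] * np.log(2.0 * np.pi * sig2) - 0.5 * rss / sig2

        # random-effect prior
        D = params.D + 1e-12 * np.eye(d)
        Dinv = np.linalg.inv(D)
        sign, logdetD = np.linalg.slogdet(D)
        if d == 2:
            quad = (
                Dinv[0, 0] * b0**2 + 2.0 * Dinv[0, 1] * b0 * self.B[:, :, 1] + Dinv[1, 1] * self.B[:, :, 1] ** 2
            )
        else:
            quad = Dinv[0, 0] * b0**2
        ll_b = -0.5 * d * np.log(2.0 * np.pi) - 0.5 * logdetD - 0.5 * quad

        # survival
        lp = self.W @ params.gamma  # (n,)
        logh0_s = self.basis_s @ params.baseline.coefs  # (n, n_outer)
        logh0_T = self.basis_T @ params.baseline.coefs  # (n,)
        fc = params.feature_center
        if self.mode == "weighted-cumulative":
            al = params.alpha[0]
            feat_s = al * (
                a[:, :, None] * self.W0s[:, None, :]
                + slope[:, :, None] * self.W1s[:, None, :]
                - fc
            )
            feat_T = al * (a * self.W0T[:, None] + slope * self.W1T[:, None] - fc)
        elif self.mode == "current-value":
            al = params.alpha[0]
            feat_s = al * (a[:, :, None] + slope[:, :, None] * self.s_nodes[:, None, :] - fc)
            feat_T = al * (a + slope * self.T[:, None] - fc)
        else:  # value-plus-slope
            a1, a2 = params.alpha
            feat_s = a1 * (
                a[:, :, None] + slope[:, :, None] * self.s_nodes[:, None, :] - fc
            ) + a2 * slope[:, :, None]
            feat_T = a1 * (a + slope * self.T[:, None] - fc) + a2 * slope

        log_integrand = logh0_s[:, None, :] + lp[:, None, None] + feat_s
        np.clip(log_integrand, -700.0, 700.0, out=log_integrand)
        Lam = self.T[:, None] * np.einsum("o,nqo->nq", self.outer_w, np.exp(log_integrand))
        ll_t = self.delta[:, None] * (logh0_T[:, None] + lp[:, None] + feat_T) - Lam

        total = ll_y + ll_b + ll_t + self.logw[None, :]
        ll_i = logsumexp(total, axis=1) + self.log_norm
        return ll_i

    def negloglik(self, theta: np.ndarray) -> float:
        params = _unpack(theta, self.template)
        with np.errstate(over="ignore", invalid="ignore"):
            ll = self.loglik_vector(params)
        val = -float(np.sum(ll))
        return val if np.isfinite(val) else _BIG

    def negloglik_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Value and analytic gradient on the transformed scale.

        The Hermite nodes are fixed (pseudo-adaptive), so the gradient is
        the softmax-weighted average of the per-node score contributions.
        """
        with np.errstate(over="ignore", invalid="ignore"):
            return self._negloglik_grad_impl(theta)

    def _negloglik_grad_impl(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        params = _unpack(theta, self.template)
        d = self.d
        rs = self.template.random_slope
        b0 = self.B[:, :, 0]
        b1 = self.B[:, :, 1] if d == 2 else np.zeros_like(b0)
        a = params.beta[0] + b0
        slope = params.beta[1] + b1

        sigma = max(params.sigma, 1e-8)
        sig2 = sigma**2
        r0 = self.Sy[:, None] - a * self.n_i[:, None] - slope * self.St[:, None]
        r1 = self.Sty[:, None] - a * self.St[:, None] - slope * self.Stt[:, None]
        rss = (
            self.Syy[:, None]
            - 2.0 * (a * self.Sy[:, None] + slope * self.Sty[:, None])
            + a**2 * self.n_i[:, None]
            + 2.0 * a * slope * self.St[:, None]
            + slope**2 * self.Stt[:, None]
        )
        ll_y = -0.5 * self.n_i[:, None] * np.log(2.0 * np.pi * sig2) - 0.5 * rss / sig2

        D = params.D + 1e-12 * np.eye(d)
        Dinv = np.linalg.inv(D)
        _, logdetD = np.linalg.slogdet(D)
        if d == 2:
            quad = Dinv[0, 0] * b0**2 + 2.0 * Dinv[0, 1] * b0 * b1 + Dinv[1, 1] * b1**2
        else:
            quad = Dinv[0, 0] * b0**2
        ll_b = -0.5 * d * np.log(2.0 * np.pi) - 0.5 * logdetD - 0.5 * quad

        lp = self.W @ params.gamma
        logh0_s = self.basis_s @ params.baseline.coefs
        logh0_T = self.basis_T @ params.baseline.coefs
        fc = params.feature_center
        if self.mode == "weighted-cumulative":
            al = params.alpha[0]
            F_s = (
                a[:, :, None] * self.W0s[:, None, :]
                + slope[:, :, None] * self.W1s[:, None, :]
                - fc
            )
            F_T = a * self.W0T[:, None] + slope * self.W1T[:, None] - fc
            feat_s, feat_T = al * F_s, al * F_T
            dfeat_s_db0, dfeat_T_db0 = al * self.W0s[:, None, :], al * self.W0T[:, None]
            dfeat_s_db1, dfeat_T_db1 = al * self.W1s[:, None, :], al * self.W1T[:, None]
        elif self.mode == "current-value":
            al = params.alpha[0]
            F_s = a[:, :, None] + slope[:, :, None] * self.s_nodes[:, None, :] - fc
            F_T = a + slope * self.T[:, None] - fc
            feat_s, feat_T = al * F_s, al * F_T
            ones_s = np.ones_like(self.s_nodes)[:, None, :]
            dfeat_s_db0, dfeat_T_db0 = al * ones_s, al * np.ones((self.n, 1))
            dfeat_s_db1 = al * self.s_nodes[:, None, :]
            dfeat_T_db1 = al * self.T[:, None]
        else:  # value-plus-slope
            a1, a2 = params.alpha
            m_s = a[:, :, None] + slope[:, :, None] * self.s_nodes[:, None, :] - fc
            m_T = a + slope * self.T[:, None] - fc
            feat_s = a1 * m_s + a2 * slope[:, :, None]
            feat_T = a1 * m_T + a2 * slope
            ones_s = np.ones_like(self.s_nodes)[:, None, :]
            dfeat_s_db0, dfeat_T_db0 = a1 * ones_s, a1 * np.ones((self.n, 1))
            dfeat_s_db1 = a1 * self.s_nodes[:, None, :] + a2
            dfeat_T_db1 = a1 * self.T[:, None] + a2

        log_integrand = logh0_s[:, None, :] + lp[:, None, None] + feat_s
        np.clip(log_integrand, -700.0, 700.0, out=log_integrand)
        E = np.exp(log_integrand)  # (n, Q, n_outer)
        wE = E * self.outer_w[None, None, :]
        Lam = self.T[:, None] * wE.sum(axis=2)
        ll_t = self.delta[:, None] * (logh0_T[:, None] + lp[:, None] + feat_T) - Lam

        total = ll_y + ll_b + ll_t + self.logw[None, :]
        M = total.max(axis=1, keepdims=True)
        expT = np.exp(total - M)
        denom = expT.sum(axis=1)
        ll_i = np.log(denom) + M[:, 0] + self.log_norm
        val = -float(np.sum(ll_i))
        if not np.isfinite(val):
            return _BIG, np.zeros_like(theta)
        P = expT / denom[:, None]  # (n, Q) softmax weights

        dT = self.delta[:, None]
        TwE = self.T[:, None, None] * wE  # d Lam / d(log-integrand at node o)

        # beta0, beta1 (longitudinal + survival channels)
        g_b0 = r0 / sig2 + dT * dfeat_T_db0 - (TwE * dfeat_s_db0).sum(axis=2)
        g_b1 = r1 / sig2 + dT * dfeat_T_db1 - (TwE * dfeat_s_db1).sum(axis=2)

        grad_parts = [np.sum(P * g_b0), np.sum(P * g_b1)]

        # D block (transformed scale)
        u0 = Dinv[0, 0] * b0 + (Dinv[0, 1] * b1 if d == 2 else 0.0)
        if d == 2:
            u1 = Dinv[1, 0] * b0 + Dinv[1, 1] * b1
            s0, s1, rho = params.sd_b0, params.sd_b1, params.corr_b
            c01 = rho * s0 * s1
            # d ll_b / d lsb0
            Dp = np.array([[2 * s0**2, c01], [c01, 0.0]])
            g = 0.5 * (u0**2 * Dp[0, 0] + 2 * u0 * u1 * Dp[0, 1] + u1**2 * Dp[1, 1]) - 0.5 * (
                Dinv * Dp
            ).sum()
            grad_parts.append(np.sum(P * g))
            Dp = np.array([[0.0, c01], [c01, 2 * s1**2]])
            g = 0.5 * (u0**2 * Dp[0, 0] + 2 * u0 * u1 * Dp[0, 1] + u1**2 * Dp[1, 1]) - 0.5 * (
                Dinv * Dp
            ).sum()
            grad_parts.append(np.sum(P * g))
            drho = (1.0 - rho**2) * s0 * s1
            Dp = np.array([[0.0, drho], [drho, 0.0]])
            g = 0.5 * (2 * u0 * u1 * Dp[0, 1]) - 0.5 * (Dinv * Dp).sum()
            grad_parts.append(np.sum(P * g))
        else:
            g = -1.0 + u0 * b0  # = -1 + b0^2/s0^2
            grad_parts.append(np.sum(P * g))

        # log sigma
        g_ls = -self.n_i[:, None] + rss / sig2
        grad_parts.append(np.sum(P * g_ls))

        # gamma: (delta - Lam) * w_j
        gmul = (P * (dT - Lam)).sum(axis=1)  # (n,)
        grad_parts.extend(list(self.W.T @ gmul))

        # alpha
        if self.mode in ("weighted-cumulative", "current-value"):
            g_al = dT * F_T - (TwE * F_s).sum(axis=2)
            grad_parts.append(np.sum(P * g_al))
        else:
            g_a1 = dT * m_T - (TwE * m_s).sum(axis=2)
            g_a2 = slope * (dT - Lam)
            grad_parts.append(np.sum(P * g_a1))
            grad_parts.append(np.sum(P * g_a2))

        # spline coefficients
        A = np.einsum("nq,nqo->no", P, TwE)  # (n, n_outer)
        g_c = self.basis_T.T @ self.delta - np.einsum("no,nok->k", A, self.basis_s)
        grad_parts.extend(list(g_c))

        grad = -np.array(grad_parts)
        if not np.all(np.isfinite(grad)):
            return _BIG, np.zeros_like(theta)
        return val, grad


# ---------------------------------------------------------------------------
# public operations


def subject_loglik(
    subject: Subject,
    params: JointModelParams,
    n_ghq: int = 9,
    n_outer: int = 7,
    n_inner: int = 15,
) -> float:
    """Log-likelihood contribution of a single subject under ``params``.

    The Gauss-Hermite grid is recentred at the subject's empirical-Bayes
    posterior computed from the longitudinal components of ``params``.
    """
    cohort = Cohort(subjects=[subject])
    design = _JointDesign(
        cohort, params, params.longitudinal_view(), n_ghq=n_ghq, n_outer=n_outer, n_inner=n_inner
    )
    return float(design.loglik_vector(params)[0])


def _default_template(
    cohort: Cohort,
    lmm: MixedModelParams,
    ph: SurvivalParams,
    weight: WeightFunction,
    mode: str,
) -> JointModelParams:
    na = _n_alpha(mode)
    return JointModelParams(
        beta=lmm.beta.copy(),
        sd_b0=lmm.sd_b0,
        sd_b1=lmm.sd_b1,
        corr_b=lmm.corr_b,
        sigma=lmm.sigma,
        gamma=ph.gamma.copy(),
        alpha=np.zeros(na),
        baseline=ph.baseline,
        weight=weight,
        mode=mode,
        covariate_center=ph.covariate_center.copy(),
    )


def fit_joint(
    cohort: Cohort,
    init: tuple[MixedModelParams, SurvivalParams] | None = None,
    mode: str = "weighted-cumulative",
    weight: WeightFunction | None = None,
    random_slope: bool = True,
    n_ghq: int = 9,
    knots: np.ndarray | None = None,
    n_interior: int = 5,
    compute_se: bool = True,
    maxiter: int = 400,
) -> FittedJointModel:
    """Maximise the joint likelihood by quasi-Newton with numerical derivatives.

    ``init`` supplies the separate fits used for starting values and for
    the pseudo-adaptive quadrature modes; when omitted they are computed
    here (ML mixed model; spline-baseline PH fit initialised at the Cox
    estimates).  Deterministic given data, initialisation and quadrature
    sizes.
    """
    if mode not in ASSOCIATION_MODES:
        raise ValueError(f"unknown association mode {mode!r}")
    if weight is None:
        weight = default_weight()
    cohort.validate()

    if init is None:
        lmm = fit_lmm(cohort, random_slope=random_slope, compute_se=False)
        cox = fit_cox_separate(cohort)
        ph = fit_parametric_ph(
            cohort, knots=knots, n_interior=n_interior, gamma_init=cox.gamma
        )
    else:
        lmm, ph = init
        if ph.baseline is None:
            ph = fit_parametric_ph(
                cohort, knots=knots, n_interior=n_interior, gamma_init=ph.gamma
            )
    if lmm.random_slope != random_slope:
        lmm = fit_lmm(cohort, random_slope=random_slope, compute_se=False)

    template = _default_template(cohort, lmm, ph, weight, mode)
    # centre the association feature at its empirical-Bayes cohort mean so the
    # alpha direction is decorrelated from the spline level
    T_all = np.array([s.t_obs for s in cohort.subjects])
    eb = np.array([eb_posterior(lmm, s)[0] for s in cohort.subjects])
    a_eb = lmm.beta[0] + eb[:, 0]
    sl_eb = lmm.beta[1] + (eb[:, 1] if lmm.random_slope else 0.0)
    if mode == "weighted-cumulative":
        W0T, W1T = kernel_moments(weight, T_all)
        template.feature_center = float(np.mean(a_eb * W0T + sl_eb * W1T))
    else:
        template.feature_center = float(np.mean(a_eb + sl_eb * T_all))
    theta0 = _pack(template)

    # Variance components are kept away from the degenerate corner (tiny SDs,
    # |corr| near 1) where the fixed pseudo-adaptive Hermite grid can no
    # longer resolve the prior and the likelihood approximation develops
    # spurious spikes.  The floors (SDs >= 0.005-0.01, |corr| <= 0.95) are far
    # below / above any plausible estimate on this data scale.
    p = theta0.size
    bounds = [(None, None)] * p
    bounds[2] = (np.log(0.01), 5.0)  # log sd_b0
    if random_slope:
        bounds[3] = (np.log(0.005), 5.0)  # log sd_b1
        bounds[4] = (-1.832, 1.832)  # atanh corr, |corr| <= 0.95
        bounds[5] = (np.log(0.01), 5.0)  # log sigma
    else:
        bounds[3] = (np.log(0.01), 5.0)  # log sigma

    # Pseudo-adaptive rounds: the Hermite grid is recentred at the
    # empirical-Bayes posteriors implied by the current longitudinal
    # parameters and held fixed within each optimisation; if the fitted
    # variance components move materially from the values that generated
    # the grid (e.g. a variance heading for its boundary), the grid is
    # rebuilt at the new estimates and the optimisation restarted there.
    theta_hat = theta0
    design = _JointDesign(cohort, template, lmm, n_ghq=n_ghq)
    for _round in range(5):
        # diagonal preconditioning: rescale coordinates by the initial
        # curvature so L-BFGS-B sees comparably scaled directions
        H0 = hessian_from_grad(lambda th: design.negloglik_grad(th)[1], theta_hat)
        t_ref = theta_hat.copy()
        scale = 1.0 / np.sqrt(np.clip(np.abs(np.diag(H0)), 1e-2, None))

        def scaled_obj(x, t_ref=t_ref, scale=scale, design=design):
            v, g = design.negloglik_grad(t_ref + scale * x)
            return v, g * scale

        sbounds = [
            (
                None if lo is None else (lo - t_ref[i]) / scale[i],
                None if hi is None else (hi - t_ref[i]) / scale[i],
            )
            for i, (lo, hi) in enumerate(bounds)
        ]
        res = minimize(
            scaled_obj,
            np.zeros(p),
            jac=True,
            method="L-BFGS-B",
            bounds=sbounds,
            options={"maxiter": maxiter, "maxfun": 10 * maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )
        theta_hat = t_ref + scale * res.x
        params_hat = _unpack(theta_hat, template)
        # verify the quadrature at the optimum: rebuild the grid from the
        # fitted longitudinal parameters and compare the likelihood there
        fresh = _JointDesign(cohort, template, params_hat.longitudinal_view(), n_ghq=n_ghq)
        ll_fit = -float(res.fun)
        ll_fresh = -fresh.negloglik(theta_hat)
        if abs(ll_fresh - ll_fit) < 0.05:
            break
        logger.debug(
            "regridding quadrature (round %d): loglik %.4f -> %.4f",
            _round + 1, ll_fit, ll_fresh,
        )
        design = fresh
    loglik = -float(design.negloglik(theta_hat))
    n_params = p
    aic = -2.0 * loglik + 2.0 * n_params

    se: dict = {}
    vcov = None
    information_pd = True
    if compute_se:
        H = hessian_from_grad(lambda th: design.negloglik_grad(th)[1], theta_hat)
        vcov, information_pd = safe_inverse(H)
        jac = _natural_jacobian(theta_hat, template)
        sds = jac * np.sqrt(np.clip(np.diag(vcov), 0.0, None))
        se = dict(zip(_param_names(template), sds))

    fitted = FittedJointModel(
        params=params_hat,
        loglik=loglik,
        aic=aic,
        n_params=n_params,
        n_subjects=len(cohort),
        se=se,
        vcov_transformed=vcov,
        theta_transformed=theta_hat,
        converged=bool(res.success),
        message=str(res.message),
        n_ghq=n_ghq,
        information_pd=information_pd,
    )
    if not res.success:
        logger.warning("fit_joint did not fully converge: %s", res.message)
    return fitted


def compare_weightings(
    cohort: Cohort,
    candidates: list[WeightFunction],
    mode: str = "weighted-cumulative",
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit one joint model per candidate kernel; rank ascending by AIC.

    Fit failures are recorded as NaN rows rather than aborting the
    comparison.  Fitted models are returned in the ``fit`` column.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate weight functions")
    fit_kwargs.setdefault("compute_se", False)
    rows = []
    for w in candidates:
        try:
            fit = fit_joint(cohort, mode=mode, weight=w, **fit_kwargs)
            rows.append(
                {
                    "family": w.family,
                    "rate": w.rate,
                    "normalize": w.normalize,
                    "loglik": fit.loglik,
                    "aic": fit.aic,
                    "fit": fit,
                }
            )
        except Exception as exc:  # noqa: BLE001 - table must survive per-candidate failures
            logger.warning("candidate %s failed: %s", w, exc)
            rows.append(
                {
                    "family": w.family,
                    "rate": w.rate,
                    "normalize": w.normalize,
                    "loglik": np.nan,
                    "aic": np.nan,
                    "fit": None,
                }
            )
    table = pd.DataFrame(rows).sort_values("aic", na_position="last").reset_index(drop=True)
    return table


def lrt_random_slope(fit_intercept_only, fit_with_slope) -> tuple[float, float]:
    """Boundary-corrected LRT for the random-slope variance component.

    The null value sigma_b1 = 0 lies on the edge of the parameter space,
    so the statistic 2 * (ll1 - ll0) is referred to the 50:50 mixture of
    chi-square(1) and chi-square(2).  Accepts any pair of fitted objects
    exposing ``loglik`` (nested, same data).
    """
    ll0 = getattr(fit_intercept_only, "loglik", fit_intercept_only)
    ll1 = getattr(fit_with_slope, "loglik", fit_with_slope)
    stat = 2.0 * (float(ll1) - float(ll0))
    if stat < -0.5:
        raise ValueError(
            f"negative LRT statistic {stat:.4g}: the larger model fit is worse; "
            "check convergence"
        )
    if stat < 0.0:
        # boundary fits can undershoot the nested model by a whisker
        logger.warning("clamping slightly negative LRT statistic %.4g to 0", stat)
    stat = max(stat, 0.0)
    if stat == 0.0:
        return 0.0, 1.0
    p = 0.5 * chi2.sf(stat, 1) + 0.5 * chi2.sf(stat, 2)
    return float(stat), float(p)
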