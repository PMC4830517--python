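"""Dynamic individualized survival prediction and prediction error.

Given a fitted joint model and a subject alive at time ``t`` with claim
history up to ``t``, the probability of surviving to a later time ``u``,

    pi(u | t) = Pr(T* >= u | T* > t, history, covariates),

is estimated by Monte Carlo: parameter vectors are drawn from the
asymptotic posterior N(theta_hat, V(theta_hat)) on the unconstrained
scale, a random-effect vector is drawn per parameter draw from
p(b | history, T* > t, theta) by Metropolis-Hastings, and each draw
contributes the conditional survival curve
exp(-(Lambda(u) - Lambda(t))).  Pointwise mean, median and 2.5/97.5%
quantiles over the draws are reported.  Predictions are capped at the
baseline-spline boundary: with no observed deaths beyond the study
window the hazard is unidentified there.

The prediction-error estimator with absolute loss averages, over the
subjects still at risk at ``t``, the discrepancy between survival
status at ``u`` and the predicted probability; subjects censored inside
(t, u) contribute through their own model-based continuation
probability rather than being dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from ._numdiff import numeric_hessian
from ._quad import composite_legendre_nodes, hermite_grid
from .data import Cohort, LongitudinalRecord, Subject
from .joint import FittedJointModel, JointModelParams, _n_alpha
from .survival import BaselineHazard, SurvivalParams
from .weights import kernel_moments

logger = logging.getLogger(__name__)


@dataclass
class SurvivalPrediction:
    """Grid of future times with Monte Carlo survival-probability summaries."""

    t: float
    u: np.ndarray
    mean: np.ndarray
    median: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    n_draws: int
    seed: int | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "u": self.u,
                "mean": self.mean,
                "median": self.median,
                "lower95": self.lower95,
                "upper95": self.upper95,
            }
        )


# ---------------------------------------------------------------------------
# parameter draws


def nearest_psd(M: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone by eigenvalue clipping."""
    M = 0.5 * (M + M.T)
    vals, vecs = np.linalg.eigh(M)
    return (vecs * np.clip(vals, 0.0, None)) @ vecs.T


def _theta_draw_matrix(fit: FittedJointModel, n_draws: int, rng: np.random.Generator):
    theta = fit.theta_transformed
    if theta is None:
        raise ValueError("fitted model lacks the transformed parameter vector")
    V = fit.vcov_transformed
    if V is None or not np.any(V):
        return np.tile(theta, (n_draws, 1))
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        logger.warning("vcov not positive definite; projecting to nearest PSD")
        Vp = nearest_psd(V)
        vals, vecs = np.linalg.eigh(Vp)
        L = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = rng.standard_normal((n_draws, theta.size))
    return theta[None, :] + z @ L.T


def sample_theta(
    fit: FittedJointModel, rng: np.random.Generator
) -> JointModelParams:
    """One draw from the asymptotic posterior N(theta_hat, V), mapped back."""
    from .joint import _unpack

    th = _theta_draw_matrix(fit, 1, rng)[0]
    return _unpack(th, fit.params)


def _unpack_batch(thetas: np.ndarray, template: JointModelParams) -> dict:
    """Vectorised version of the transformed -> natural mapping."""
    rs = template.random_slope
    k = 0
    out: dict[str, np.ndarray] = {}
    out["beta0"] = thetas[:, 0]
    out["beta1"] = thetas[:, 1]
    out["sd_b0"] = np.exp(thetas[:, 2])
    k = 3
    if rs:
        out["sd_b1"] = np.exp(thetas[:, 3])
        out["corr_b"] = np.tanh(thetas[:, 4])
        k = 5
    out["sigma"] = np.exp(thetas[:, k])
    k += 1
    out["gamma"] = thetas[:, k : k + 3]
    k += 3
    na = _n_alpha(template.mode)
    out["alpha"] = thetas[:, k : k + na]
    k += na
    out["coefs"] = thetas[:, k:]
    return out


# ---------------------------------------------------------------------------
# hazard machinery shared by sampling and curves


class _SubjectContext:
    """Cached subject-level quantities for prediction at condition time t."""

    def __init__(self, fit: FittedJointModel, subject: Subject, t: float,
                 n_outer: int = 7, n_inner: int = 15):
        p = fit.params
        self.fit = fit
        self.params = p
        self.d = p.dim
        self.t = float(t)
        self.tau = p.baseline.boundary[1]
        self.n_outer = n_outer
        self.n_inner = n_inner
        recs = [r for r in subject.records if r.t <= t + 1e-9]
        tt = np.array([r.t for r in recs])
        yy = np.array([r.y for r in recs])
        self.n_rec = tt.size
        self.St, self.Stt = tt.sum(), (tt**2).sum()
        self.Sy, self.Sty, self.Syy = yy.sum(), (tt * yy).sum(), (yy**2).sum()
        self.rec_t, self.rec_y = tt, yy
        self.w = np.array([subject.sex, subject.age0, subject.sex * subject.age0], dtype=float)
        self.w_centered = self.w - p.covariate_center

    # -- node caches -------------------------------------------------------
    def _nodes(self, times: np.ndarray):
        # composite rule split at the spline knots so the exponentiated
        # piecewise-cubic integrand is resolved to oracle accuracy
        bh = self.params.baseline
        s, wt = composite_legendre_nodes(times, bh.knots, n_points=self.n_outer)
        basis = bh.basis(np.minimum(s.ravel(), self.tau)).reshape(*s.shape, -1)
        if self.params.mode == "weighted-cumulative":
            W0, W1 = kernel_moments(self.params.weight, s, self.n_inner)
        else:
            W0 = W1 = None
        return s, wt, basis, W0, W1

    def lambda_batch(self, arrs: dict, b: np.ndarray, times: np.ndarray) -> np.ndarray:
        """Lambda(times) for each draw; arrs from _unpack_batch, b (L, d)."""
        times = np.asarray(times, dtype=float)
        s, wt, basis, W0, W1 = self._nodes(times)
        a = arrs["beta0"] + b[:, 0]  # (L,)
        slope = arrs["beta1"] + (b[:, 1] if self.d == 2 else 0.0)
        logh0 = np.einsum("mok,lk->lmo", basis, arrs["coefs"])
        lp = arrs["gamma"] @ self.w_centered  # (L,)
        mode = self.params.mode
        fc = self.params.feature_center
        if mode == "weighted-cumulative":
            feat = arrs["alpha"][:, 0, None, None] * (
                a[:, None, None] * W0[None] + slope[:, None, None] * W1[None] - fc
            )
        elif mode == "current-value":
            feat = arrs["alpha"][:, 0, None, None] * (
                a[:, None, None] + slope[:, None, None] * s[None] - fc
            )
        else:
            feat = arrs["alpha"][:, 0, None, None] * (
                a[:, None, None] + slope[:, None, None] * s[None] - fc
            ) + arrs["alpha"][:, 1, None, None] * slope[:, None, None]
        log_integrand = logh0 + lp[:, None, None] + feat
        np.clip(log_integrand, -700.0, 700.0, out=log_integrand)
        return np.einsum("mo,lmo->lm", wt, np.exp(log_integrand))

    def log_posterior_b(self, arrs: dict, b: np.ndarray) -> np.ndarray:
        """log p(b | history, T* > t, theta_l) up to a constant, per draw."""
        a = arrs["beta0"] + b[:, 0]
        slope = arrs["beta1"] + (b[:, 1] if self.d == 2 else 0.0)
        sig2 = np.maximum(arrs["sigma"], 1e-8) ** 2
        rss = (
            self.Syy
            - 2.0 * (a * self.Sy + slope * self.Sty)
            + a**2 * self.n_rec
            + 2.0 * a * slope * self.St
            + slope**2 * self.Stt
        )
        ll_y = -0.5 * self.n_rec * np.log(2.0 * np.pi * sig2) - 0.5 * rss / sig2
        # prior
        sd0 = arrs["sd_b0"]
        if self.d == 2:
            sd1 = arrs["sd_b1"]
            rho = arrs["corr_b"]
            det = (sd0 * sd1) ** 2 * (1 - rho**2) + 1e-300
            z0, z1 = b[:, 0] / sd0, b[:, 1] / sd1
            quad = (z0**2 - 2 * rho * z0 * z1 + z1**2) / np.maximum(1 - rho**2, 1e-12)
            ll_b = -np.log(2.0 * np.pi) - 0.5 * np.log(det) - 0.5 * quad
        else:
            ll_b = -0.5 * np.log(2.0 * np.pi * sd0**2) - 0.5 * (b[:, 0] / sd0) ** 2
        if self.t > 0:
            Lam_t = self.lambda_batch(arrs, b, np.array([self.t]))[:, 0]
        else:
            Lam_t = 0.0
        return ll_y + ll_b - Lam_t

    # -- posterior mode at theta_hat ---------------------------------------
    def posterior_mode(self, theta_params: JointModelParams | None = None):
        p = theta_params or self.params
        th = _pack_single(p)
        arrs = _unpack_batch(th[None, :], p)

        def neg(bv):
            return -float(self.log_posterior_b(arrs, np.asarray(bv)[None, :])[0])

        # start at the longitudinal-only empirical-Bayes mean (closed form)
        d = self.d
        if self.n_rec:
            Z = np.column_stack([np.ones(self.n_rec), self.rec_t])[:, :d]
            r = self.rec_y - (p.beta[0] + p.beta[1] * self.rec_t)
            sig2 = max(p.sigma, 1e-6) ** 2
            Dr = p.D + 1e-10 * np.eye(d)
            Sig = np.linalg.inv(Z.T @ Z / sig2 + np.linalg.inv(Dr))
            x0 = Sig @ (Z.T @ r) / sig2
        else:
            x0 = np.zeros(d)
        res = minimize(neg, x0, method="BFGS", options={"gtol": 1e-7})
        mode = res.x
        H = numeric_hessian(neg, mode, rel_step=1e-4)
        try:
            cov = np.linalg.inv(H)
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            cov = nearest_psd(np.linalg.pinv(H)) + 1e-10 * np.eye(self.d)
        return mode, cov


def _pack_single(params: JointModelParams) -> np.ndarray:
    from .joint import _pack

    return _pack(params)


# ---------------------------------------------------------------------------
# random-effect posterior sampling


def _sample_b_batch(
    ctx: _SubjectContext,
    arrs: dict,
    rng: np.random.Generator,
    n_mh: int = 25,
    mode: np.ndarray | None = None,
    prop_cov: np.ndarray | None = None,
) -> np.ndarray:
    """Final MH states of L parallel chains, one per parameter draw."""
    L = arrs["beta0"].size
    d = ctx.d
    sigma_hat = ctx.params.sigma
    if sigma_hat < 1e-10 and ctx.n_rec >= d:
        # degenerate limit: residual noise vanishes, the history pins b exactly
        Z = np.column_stack([np.ones(ctx.n_rec), ctx.rec_t])[:, :d]
        r = ctx.rec_y - (ctx.params.beta[0] + ctx.params.beta[1] * ctx.rec_t)
        b_exact, *_ = np.linalg.lstsq(Z, r, rcond=None)
        return np.tile(b_exact, (L, 1))

    if mode is None or prop_cov is None:
        mode, cov = ctx.posterior_mode()
        prop_cov = (2.4**2 / d) * cov
    Lp = np.linalg.cholesky(prop_cov + 1e-14 * np.eye(d))
    b = np.tile(mode, (L, 1))
    logp = ctx.log_posterior_b(arrs, b)
    n_accept = 0
    for _ in range(n_mh):
        prop = b + rng.standard_normal((L, d)) @ Lp.T
        logp_prop = ctx.log_posterior_b(arrs, prop)
        accept = np.log(rng.uniform(size=L)) < (logp_prop - logp)
        b = np.where(accept[:, None], prop, b)
        logp = np.where(accept, logp_prop, logp)
        n_accept += int(accept.sum())
    if n_accept == 0 and n_mh * L > 0:
        logger.warning("Metropolis-Hastings accepted no proposals (%d chains x %d steps)", L, n_mh)
    return b


def sample_b_posterior(
    fit: FittedJointModel,
    subject: Subject,
    t: float,
    theta: JointModelParams | None = None,
    rng: np.random.Generator | None = None,
    n_mh: int = 25,
) -> np.ndarray:
    """One MH draw from p(b | history up to t, T* > t, theta)."""
    rng = rng or np.random.default_rng()
    ctx = _SubjectContext(fit, subject, t)
    p = theta or fit.params
    arrs = _unpack_batch(_pack_single(p)[None, :], p)
    return _sample_b_batch(ctx, arrs, rng, n_mh=n_mh)[0]


# ---------------------------------------------------------------------------
# conditional survival and prediction


def conditional_survival(
    fit: FittedJointModel,
    subject: Subject,
    u: float,
    t: float,
    b: np.ndarray,
    theta: JointModelParams | None = None,
) -> float:
    """exp(-(Lambda(u) - Lambda(t))) for one random-effect vector."""
    if u < t:
        raise ValueError("u must be >= t")
    p = theta or fit.params
    ctx = _SubjectContext(fit, subject, t)
    arrs = _unpack_batch(_pack_single(p)[None, :], p)
    b = np.atleast_2d(np.asarray(b, dtype=float))
    Lam = ctx.lambda_batch(arrs, b, np.array([t, u]))
    return float(np.exp(-(Lam[0, 1] - Lam[0, 0])))


def predict_survival(
    fit: FittedJointModel,
    subject: Subject,
    t: float,
    u_grid: np.ndarray,
    n_draws: int = 200,
    rng: np.random.Generator | int | None = None,
    n_mh: int = 25,
) -> SurvivalPrediction:
    """Monte Carlo dynamic survival prediction for one subject alive at t."""
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    else:
        seed = None
        rng = rng or np.random.default_rng()
    tau = fit.params.baseline.boundary[1]
    if t >= tau:
        raise ValueError(f"conditioning time t={t} is at/beyond the baseline boundary {tau}")
    u_grid = np.asarray(u_grid, dtype=float)
    if np.any(u_grid < t):
        raise ValueError("all prediction times must satisfy u >= t")
    kept = u_grid <= tau + 1e-9
    if not np.all(kept):
        logger.warning("prediction horizon capped at the baseline boundary tau=%.3f", tau)
    u = u_grid[kept]

    ctx = _SubjectContext(fit, subject, t)
    thetas = _theta_draw_matrix(fit, n_draws, rng)
    arrs = _unpack_batch(thetas, fit.params)
    b = _sample_b_batch(ctx, arrs, rng, n_mh=n_mh)

    times = np.concatenate([[t], u])
    Lam = ctx.lambda_batch(arrs, b, times)  # (L, 1+m)
    S = np.exp(-(Lam[:, 1:] - Lam[:, [0]]))
    S = np.clip(S, 0.0, 1.0)
    # u == t is survival-to-now: exactly one
    S[:, np.isclose(u, t)] = 1.0

    return SurvivalPrediction(
        t=float(t),
        u=u,
        mean=S.mean(axis=0),
        median=np.median(S, axis=0),
        lower95=np.quantile(S, 0.025, axis=0),
        upper95=np.quantile(S, 0.975, axis=0),
        n_draws=n_draws,
        seed=seed,
    )


def update_prediction(
    fit: FittedJointModel,
    subject: Subject,
    new_record: LongitudinalRecord,
    t_new: float,
    u_grid: np.ndarray,
    rng: np.random.Generator | int | None = None,
    n_draws: int = 200,
    n_mh: int = 25,
) -> tuple[Subject, SurvivalPrediction]:
    """Append a new measurement and recompute the prediction at t_new."""
    last_t = subject.records[-1].t if subject.records else 0.0
    if new_record.t <= last_t:
        raise ValueError("new record time must exceed the last recorded occasion")
    if t_new < new_record.t:
        raise ValueError("t_new must be at or after the new record")
    updated = Subject(
        id=subject.id,
        sex=subject.sex,
        age0=subject.age0,
        t_obs=max(subject.t_obs, t_new),
        delta=subject.delta,
        records=subject.records + [new_record],
    )
    u = np.asarray(u_grid, dtype=float)
    u = u[u >= t_new]
    pred = predict_survival(fit, updated, t_new, u, n_draws=n_draws, rng=rng, n_mh=n_mh)
    return updated, pred


# ---------------------------------------------------------------------------
# deterministic plug-in probability and prediction error


def plugin_survival_probability(
    fit: FittedJointModel, subject: Subject, t: float, u: float, n_ghq: int = 9
) -> float:
    """Deterministic pi(u|t) at theta_hat.

    Integrates the conditional survival ratio over the exact posterior
    p(b | history, T* > t) with a Gauss-Hermite rule recentred at the
    posterior mode; no Monte Carlo noise.
    """
    if u < t:
        raise ValueError("u must be >= t")
    ctx = _SubjectContext(fit, subject, t)
    d = ctx.d
    arrs = _unpack_batch(_pack_single(fit.params)[None, :], fit.params)
    if fit.params.sigma < 1e-10 and ctx.n_rec >= d:
        b = _sample_b_batch(ctx, arrs, np.random.default_rng(0), n_mh=0)
        Lam = ctx.lambda_batch(arrs, b[:1], np.array([t, u]))
        return float(np.exp(-(Lam[0, 1] - Lam[0, 0])))
    mode, cov = ctx.posterior_mode()
    z, logw = hermite_grid(n_ghq, d)
    Lc = np.linalg.cholesky(cov + 1e-12 * np.eye(d))
    B = mode[None, :] + np.sqrt(2.0) * z @ Lc.T  # (Q, d)
    arrs_rep = {
        k: (np.repeat(v, B.shape[0], axis=0) if v.ndim > 1 else np.repeat(v, B.shape[0]))
        for k, v in arrs.items()
    }
    logpost = ctx.log_posterior_b(arrs_rep, B) + logw
    wts = np.exp(logpost - logsumexp(logpost))
    Lam = ctx.lambda_batch(arrs_rep, B, np.array([t, u]))
    S = np.exp(-(Lam[:, 1] - Lam[:, 0]))
    return float(np.clip(np.sum(wts * S), 0.0, 1.0))


def covariates_only_predictor(ph: SurvivalParams) -> Callable[[Subject, float, float], float]:
    """pi(u|t) from a spline-baseline PH model without longitudinal input."""
    if ph.baseline is None:
        raise ValueError("needs a parametric (spline-baseline) survival fit")

    def pi(subject: Subject, t: float, u: float) -> float:
        w = np.array([subject.sex, subject.age0, subject.sex * subject.age0], dtype=float)
        lp = float(ph.gamma @ (w - ph.covariate_center))
        tau = ph.baseline.boundary[1]

        def lam(tt):
            if tt <= 0:
                return 0.0
            s, wt = composite_legendre_nodes(np.array([tt]), ph.baseline.knots)
            h0 = np.exp(ph.baseline.log_hazard(np.minimum(s[0], tau)))
            return float(np.sum(wt[0] * h0) * np.exp(lp))

        return float(np.exp(-(lam(min(u, tau)) - lam(min(t, tau)))))

    return pi


def joint_model_predictor(
    fit: FittedJointModel, n_ghq: int = 9
) -> Callable[[Subject, float, float], float]:
    def pi(subject: Subject, t: float, u: float) -> float:
        return plugin_survival_probability(fit, subject, t, u, n_ghq=n_ghq)

    return pi


def prediction_error(
    fit_or_predictor,
    cohort: Cohort,
    t: float,
    u: float,
    loss: str = "absolute",
) -> tuple[float, int]:
    """Absolute-loss prediction error at horizon u using history up to t.

    Subjects at risk at ``t`` contribute |1{alive at u} - pi(u|t)| when
    their status at ``u`` is known.  A subject censored at c in (t, u)
    contributes the model-weighted decomposition

        pi(u|c) * |1 - pi(u|t)| + (1 - pi(u|c)) * |0 - pi(u|t)|,

    i.e. its own continuation probability splits it between the two
    outcomes.  Returns (estimate, risk-set size).
    """
    if loss != "absolute":
        raise ValueError("only the absolute loss is implemented")
    if u <= t:
        raise ValueError("horizon u must exceed base time t")
    if isinstance(fit_or_predictor, FittedJointModel):
        predictor = joint_model_predictor(fit_or_predictor)
    else:
        predictor = fit_or_predictor

    total = 0.0
    n_risk = 0
    for s in cohort.subjects:
        if s.t_obs <= t:
            continue
        n_risk += 1
        pi_u = predictor(s, t, u)
        if s.delta == 1 and s.t_obs <= u:
            total += abs(0.0 - pi_u)
        elif s.t_obs >= u:
            total += abs(1.0 - pi_u)
        else:  # censored inside (t, u)
            pi_cont = predictor(s, s.t_obs, u)
            total += pi_cont * abs(1.0 - pi_u) + (1.0 - pi_cont) * abs(0.0 - pi_u)
    if n_risk == 0:
        raise ValueError(f"no subjects at risk at t={t}")
    return total / n_risk, n_risk
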