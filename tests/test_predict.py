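"""Dynamic survival prediction and prediction-error estimation."""

import numpy as np
import pytest

import jmclaims as jm
from jmclaims.joint import FittedJointModel, JointModelParams, _pack
from jmclaims.predict import (
    _SubjectContext,
    _theta_draw_matrix,
    _unpack_batch,
    nearest_psd,
)
from jmclaims.simulate import SimulationConfig, simulate_cohort
from jmclaims.survival import BaselineHazard
from jmclaims.weights import WeightFunction

from conftest import make_subject


def _make_fit(vcov_scale=0.0, **overrides):
    """Hand-built fitted model with a constant-in-time spline baseline."""
    bh = BaselineHazard(
        knots=np.array([2.0, 4.0]), boundary=(0.0, 8.08),
        coefs=np.full(6, np.log(0.05)),
    )
    fields = dict(
        beta=np.array([0.32, 0.014]), sd_b0=0.33, sd_b1=0.05, corr_b=-0.2,
        sigma=0.47, gamma=np.array([-0.5, 0.09, 0.01]), alpha=np.array([1.462]),
        baseline=bh, weight=WeightFunction("exponential", 3.0),
        covariate_center=np.array([0.5, 74.0, 37.0]), feature_center=0.3,
    )
    fields.update(overrides)
    params = JointModelParams(**fields)
    theta = _pack(params)
    vcov = vcov_scale * np.eye(theta.size)
    return FittedJointModel(
        params=params, loglik=0.0, aic=0.0, n_params=theta.size, n_subjects=1,
        vcov_transformed=vcov, theta_transformed=theta,
    )


class TestSampleTheta:
    def test_zero_vcov_returns_point_estimate(self):
        fit = _make_fit(0.0)
        draw = jm.sample_theta(fit, np.random.default_rng(0))
        assert np.allclose(_pack(draw), fit.theta_transformed)

    def test_sample_covariance_matches_vcov(self):
        fit = _make_fit(0.0)
        rng = np.random.default_rng(1)
        p = fit.theta_transformed.size
        A = rng.standard_normal((p, p)) * 0.01
        fit.vcov_transformed = A @ A.T + 0.005 * np.eye(p)
        draws = _theta_draw_matrix(fit, 10_000, np.random.default_rng(2))
        S = np.cov(draws.T)
        V = fit.vcov_transformed
        assert np.linalg.norm(S - V, "fro") / np.linalg.norm(V, "fro") < 0.05

    def test_seed_reproducibility(self):
        fit = _make_fit(1e-4)
        d1 = _theta_draw_matrix(fit, 5, np.random.default_rng(7))
        d2 = _theta_draw_matrix(fit, 5, np.random.default_rng(7))
        assert np.array_equal(d1, d2)

    def test_nearest_psd_projection(self):
        M = np.array([[1.0, 0.0], [0.0, -0.5]])
        P = nearest_psd(M)
        assert np.all(np.linalg.eigvalsh(P) >= -1e-12)


class TestSampleBPosterior:
    def test_prior_limit_without_records(self):
        fit = _make_fit(0.0, alpha=np.array([0.0]))
        s = jm.Subject(id="a", sex=0, age0=72.0, t_obs=0.0, delta=0, records=[])
        ctx = _SubjectContext(fit, s, 0.0)
        arrs = _unpack_batch(np.tile(fit.theta_transformed, (4000, 1)), fit.params)
        from jmclaims.predict import _sample_b_batch

        b = _sample_b_batch(ctx, arrs, np.random.default_rng(3), n_mh=60)
        D = fit.params.D
        assert abs(b[:, 0].std() - np.sqrt(D[0, 0])) / np.sqrt(D[0, 0]) < 0.12
        assert abs(b[:, 1].std() - np.sqrt(D[1, 1])) / np.sqrt(D[1, 1]) < 0.12
        assert abs(b[:, 0].mean()) < 3 * np.sqrt(D[0, 0]) / np.sqrt(4000) * 3

    def test_zero_noise_concentrates_on_subject_line(self):
        fit = _make_fit(0.0, sigma=0.0)
        recs = [jm.LongitudinalRecord(t, None, 0.5 + 0.05 * t) for t in (0.0, 1.0, 2.0)]
        s = jm.Subject(id="a", sex=0, age0=72.0, t_obs=3.0, delta=0, records=recs)
        b = jm.sample_b_posterior(fit, s, 2.5, rng=np.random.default_rng(0))
        assert b[0] == pytest.approx(0.5 - 0.32, abs=1e-9)
        assert b[1] == pytest.approx(0.05 - 0.014, abs=1e-9)

    def test_single_record_posterior_matches_grid_density(self):
        """QQ agreement between MH draws and the grid-evaluated posterior."""
        fit = _make_fit(0.0)
        s = make_subject(series=((0.0, 3),), t_obs=2.0)
        ctx = _SubjectContext(fit, s, 1.0)
        arrs1 = _unpack_batch(fit.theta_transformed[None, :], fit.params)

        # marginal of b0 on a grid (integrate b1 numerically)
        g0 = np.linspace(-1.5, 1.5, 161)
        g1 = np.linspace(-0.3, 0.3, 161)
        B = np.array([[x0, x1] for x0 in g0 for x1 in g1])
        arrsN = {k: np.repeat(v, len(B), axis=0) for k, v in arrs1.items()}
        logp = ctx.log_posterior_b(arrsN, B).reshape(len(g0), len(g1))
        dens = np.exp(logp - logp.max())
        marg0 = np.trapezoid(dens, g1, axis=1)
        cdf = np.cumsum(marg0)
        cdf /= cdf[-1]

        arrs = _unpack_batch(np.tile(fit.theta_transformed, (4000, 1)), fit.params)
        from jmclaims.predict import _sample_b_batch

        draws = _sample_b_batch(ctx, arrs, np.random.default_rng(5), n_mh=60)[:, 0]
        for q in [0.1, 0.25, 0.5, 0.75, 0.9]:
            grid_q = np.interp(q, cdf, g0)
            mh_q = np.quantile(draws, q)
            assert abs(mh_q - grid_q) < 0.06, q


class TestConditionalSurvival:
    def test_now_equals_one(self):
        fit = _make_fit(0.0)
        s = make_subject()
        assert jm.conditional_survival(fit, s, 3.0, 3.0, np.zeros(2)) == pytest.approx(1.0)

    def test_constant_hazard_closed_form(self):
        # alpha = gamma = 0 and flat spline level log(0.05): pure exponential
        fit = _make_fit(0.0, alpha=np.array([0.0]), gamma=np.zeros(3))
        s = make_subject()
        val = jm.conditional_survival(fit, s, 7.0, 3.0, np.zeros(2))
        assert val == pytest.approx(np.exp(-0.05 * 4.0), rel=1e-10)

    def test_backward_horizon_rejected(self):
        fit = _make_fit(0.0)
        with pytest.raises(ValueError):
            jm.conditional_survival(fit, make_subject(), 2.0, 3.0, np.zeros(2))

    def test_matches_trapezoid_cumulative_hazard(self):
        fit = _make_fit(0.0)
        p = fit.params
        s = make_subject(sex=1, age0=75.0)
        b = np.array([0.2, 0.01])
        t, u = 2.0, 6.0
        val = jm.conditional_survival(fit, s, u, t, b)
        lamw = p.weight.rate
        a, sl = p.beta[0] + b[0], p.beta[1] + b[1]
        grid = np.linspace(0.0, u, 1_000_001)
        F = a * (1 - np.exp(-lamw * grid)) + sl * (grid - (1 - np.exp(-lamw * grid)) / lamw)
        w = np.array([1.0, 75.0, 75.0]) - p.covariate_center
        h = 0.05 * np.exp(p.gamma @ w + p.alpha[0] * (F - p.feature_center))
        Lam = np.trapezoid(h * (grid <= u), grid) - np.trapezoid(h * (grid <= t), grid)
        # trapezoid of the indicator-masked integrand: use cumulative form
        cum = np.concatenate([[0], np.cumsum((h[1:] + h[:-1]) / 2 * np.diff(grid))])
        Lam = np.interp(u, grid, cum) - np.interp(t, grid, cum)
        assert val == pytest.approx(np.exp(-Lam), rel=1e-6)


class TestPredictSurvival:
    def test_degenerate_configuration_zero_width_band(self):
        fit = _make_fit(0.0, sigma=0.0)
        recs = [jm.LongitudinalRecord(t, None, 0.5 + 0.05 * t) for t in (0.0, 1.0, 2.0)]
        s = jm.Subject(id="a", sex=0, age0=72.0, t_obs=3.0, delta=0, records=recs)
        pred = jm.predict_survival(fit, s, 2.5, np.linspace(2.5, 7.0, 8), n_draws=50, rng=0)
        assert np.allclose(pred.upper95 - pred.lower95, 0.0)
        assert np.allclose(pred.mean, pred.median)

    def test_band_ordering_and_monotone_median(self, joint_fit_500, cohort500):
        s = next(x for x in cohort500.subjects if x.t_obs > 6 and len(x.records) >= 5)
        pred = jm.predict_survival(joint_fit_500, s, 3.0, np.linspace(3.0, 8.0, 11),
                                   n_draws=150, rng=11)
        assert pred.median[0] == 1.0
        assert np.all(np.diff(pred.median) <= 1e-12)
        assert np.all(pred.lower95 <= pred.median + 1e-12)
        assert np.all(pred.median <= pred.upper95 + 1e-12)
        assert np.all((pred.lower95 >= 0) & (pred.upper95 <= 1))

    def test_rising_claims_lower_predicted_survival(self):
        """With a strongly positive association, new records showing rising
        claims pull the predicted survival down at a fixed horizon."""
        fit = _make_fit(0.0, alpha=np.array([3.0]))
        low = make_subject(series=((0.0, 1), (1.0, 1), (2.0, 1)), t_obs=3.0)
        pred_low = jm.predict_survival(fit, low, 2.5, np.array([2.5, 7.0]), n_draws=200, rng=1)
        high = make_subject(series=((0.0, 1), (1.0, 4), (2.0, 12)), t_obs=3.0)
        pred_high = jm.predict_survival(fit, high, 2.5, np.array([2.5, 7.0]), n_draws=200, rng=1)
        assert pred_high.median[-1] < pred_low.median[-1]

    def test_horizon_capped_at_boundary(self):
        fit = _make_fit(0.0)
        s = make_subject()
        pred = jm.predict_survival(fit, s, 2.0, np.array([2.0, 7.0, 9.5]), n_draws=20, rng=0)
        assert pred.u.max() <= 8.08 + 1e-9
        with pytest.raises(ValueError):
            jm.predict_survival(fit, s, 9.0, np.array([9.5]), n_draws=10, rng=0)


class TestUpdatePrediction:
    def test_consistent_update_moves_curve_less_than_extreme(self):
        fit = _make_fit(0.0, alpha=np.array([3.0]))
        base = make_subject(series=((0.0, 1), (1.0, 1)), t_obs=2.0)
        u_grid = np.array([3.0, 6.0])
        pred0 = jm.predict_survival(fit, base, 2.0, u_grid, n_draws=200, rng=4)
        _, pred_same = jm.update_prediction(
            fit, base, jm.LongitudinalRecord.from_count(2.0, 1), 3.0,
            np.array([3.0, 6.0]), rng=4, n_draws=200,
        )
        _, pred_jump = jm.update_prediction(
            fit, base, jm.LongitudinalRecord.from_count(2.0, 15), 3.0,
            np.array([3.0, 6.0]), rng=4, n_draws=200,
        )
        d_same = abs(pred_same.median[-1] - pred0.median[-1])
        d_jump = abs(pred_jump.median[-1] - pred0.median[-1])
        assert d_jump > d_same

    def test_grid_trimmed_and_conditions_on_survival(self):
        fit = _make_fit(0.0)
        base = make_subject(series=((0.0, 1), (1.0, 1)), t_obs=2.0)
        _, pred = jm.update_prediction(
            fit, base, jm.LongitudinalRecord.from_count(2.0, 2), 2.5,
            np.array([1.0, 2.5, 5.0]), rng=0, n_draws=20,
        )
        assert pred.u.min() >= 2.5
        assert pred.median[0] == 1.0

    def test_stale_record_rejected(self):
        fit = _make_fit(0.0)
        base = make_subject(series=((0.0, 1), (1.0, 1)), t_obs=2.0)
        with pytest.raises(ValueError):
            jm.update_prediction(fit, base, jm.LongitudinalRecord.from_count(0.5, 1),
                                 1.0, np.array([2.0]))


class TestPredictionError:
    @staticmethod
    def _toy_cohort():
        subs = [
            jm.Subject("a", 0, 70.0, 8.0, 0, []),   # alive past u
            jm.Subject("b", 1, 75.0, 6.5, 1, []),   # dies in window
            jm.Subject("c", 0, 80.0, 6.0, 0, []),   # censored in window
            jm.Subject("d", 1, 72.0, 4.9, 1, []),   # dead before t: not at risk
            jm.Subject("e", 0, 77.0, 7.4, 1, []),   # dies in window
            jm.Subject("f", 1, 84.0, 7.2, 0, []),   # censored in window
            jm.Subject("g", 0, 69.0, 7.05, 0, []),  # censored in window
            jm.Subject("h", 1, 71.0, 8.0, 0, []),   # alive past u
            jm.Subject("i", 0, 88.0, 5.5, 1, []),   # dies in window
            jm.Subject("j", 1, 66.0, 5.2, 0, []),   # censored in window
        ]
        return jm.Cohort(subjects=subs)

    def test_perfect_predictions_give_zero_error(self):
        cohort = self._toy_cohort()
        u = 7.5

        def oracle_pi(s, t, uu):
            if s.delta == 1 and s.t_obs <= uu:
                return 0.0
            return 1.0

        # restrict to subjects with known status (drop censored-in-window)
        known = jm.Cohort(
            subjects=[s for s in cohort.subjects
                      if s.t_obs >= u or (s.delta == 1)]
        )
        pe, _ = jm.prediction_error(oracle_pi, known, 5.0, u)
        assert pe == 0.0

    def test_coin_flip_prediction_without_censoring(self):
        subs = [jm.Subject(f"s{i}", 0, 70.0, 8.0 if i % 2 else 6.0, i % 2 == 0, [])
                for i in range(8)]
        cohort = jm.Cohort(subjects=subs)
        pe, n = jm.prediction_error(lambda s, t, u: 0.5, cohort, 5.0, 7.0)
        assert pe == pytest.approx(0.5)
        assert n == 8

    def test_matches_hand_coded_decomposition(self):
        """Same estimator, written out independently subject by subject."""
        cohort = self._toy_cohort()
        t, u = 5.0, 7.5

        def pi(s, tc, uu):
            # arbitrary deterministic predictor
            return float(np.exp(-0.04 * (uu - tc)) * (0.9 if s.sex else 1.0))

        pe, n_risk = jm.prediction_error(pi, cohort, t, u)

        total, n = 0.0, 0
        for s in cohort.subjects:
            if s.t_obs <= t:
                continue
            n += 1
            p_u = pi(s, t, u)
            if s.delta == 1 and s.t_obs <= u:
                total += p_u
            elif s.t_obs >= u:
                total += 1.0 - p_u
            else:
                p_c = pi(s, s.t_obs, u)
                total += p_c * (1.0 - p_u) + (1.0 - p_c) * p_u
        assert n_risk == n
        assert pe == pytest.approx(total / n, abs=1e-12)

    def test_empty_risk_set_rejected(self):
        cohort = jm.Cohort(subjects=[jm.Subject("a", 0, 70.0, 1.0, 1, [])])
        with pytest.raises(ValueError):
            jm.prediction_error(lambda s, t, u: 1.0, cohort, 5.0, 7.0)

    def test_joint_model_beats_covariates_only_benchmark(self):
        """With a strong association the joint predictor attains lower
        absolute-loss error than the covariates-only survival model in a
        majority of replicate cohorts."""
        wins = 0
        for rep in range(3):
            cfg = SimulationConfig(n_subjects=300, alpha=3.0, baseline_rate=2e-6)
            train = simulate_cohort(cfg, seed=500 + rep)
            test = simulate_cohort(cfg, seed=600 + rep)
            fit = jm.fit_joint(train, n_interior=1, compute_se=False, maxiter=400)
            ph = jm.fit_parametric_ph(train, n_interior=1)
            pe_joint, _ = jm.prediction_error(fit, test, 3.0, 6.0)
            pe_cov, _ = jm.prediction_error(
                jm.covariates_only_predictor(ph), test, 3.0, 6.0
            )
            wins += pe_joint < pe_cov
        assert wins >= 2
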