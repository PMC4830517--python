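"""Joint likelihood, its maximisation and model comparison."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import chi2, multivariate_normal

import jmclaims as jm
from jmclaims._quad import legendre_01
from jmclaims.joint import (
    JointModelParams,
    _JointDesign,
    lrt_random_slope,
    subject_loglik,
)
from jmclaims.longitudinal import fit_lmm
from jmclaims.simulate import SimulationConfig, simulate_cohort
from jmclaims.survival import BaselineHazard
from jmclaims.weights import WeightFunction, kernel_moments

from conftest import make_subject


@pytest.fixture
def toy_params():
    bh = BaselineHazard(
        knots=np.array([2.0, 4.0]), boundary=(0.0, 8.08),
        coefs=np.array([-3.0, -2.5, -3.0, -2.0, -2.5, -3.0]),
    )
    return JointModelParams(
        beta=np.array([0.32, 0.014]), sd_b0=0.33, sd_b1=0.05, corr_b=-0.2,
        sigma=0.47, gamma=np.array([-0.5, 0.09, 0.01]), alpha=np.array([1.2]),
        baseline=bh, weight=WeightFunction("exponential", 3.0),
        covariate_center=np.array([0.5, 74.0, 37.0]), feature_center=0.3,
    )


def _survival_terms(params, subject, b):
    """Independent (non-package-path) hazard pieces for one subject."""
    a = params.beta[0] + b[0]
    sl = params.beta[1] + b[1]
    x, wt = legendre_01(7)
    s = subject.t_obs * x
    W0, W1 = kernel_moments(params.weight, s)
    W0T, W1T = kernel_moments(params.weight, np.array([subject.t_obs]))
    wv = np.array([subject.sex, subject.age0, subject.sex * subject.age0])
    lp = params.gamma @ (wv - params.covariate_center)
    al = params.alpha[0]
    F = a * W0 + sl * W1 - params.feature_center
    Lam = subject.t_obs * np.sum(wt * np.exp(params.baseline.log_hazard(s) + lp + al * F))
    FT = a * W0T[0] + sl * W1T[0] - params.feature_center
    logh = params.baseline.log_hazard(np.array([subject.t_obs]))[0] + lp + al * FT
    return logh, Lam


class TestSubjectLoglik:
    def test_factorises_when_association_is_zero(self, toy_params, toy_subject):
        p0 = dataclasses.replace(toy_params, alpha=np.array([0.0]))
        ll = subject_loglik(toy_subject, p0, n_ghq=15)
        t = np.array([r.t for r in toy_subject.records])
        y = np.array([r.y for r in toy_subject.records])
        Z = np.column_stack([np.ones_like(t), t])
        V = Z @ p0.D @ Z.T + p0.sigma**2 * np.eye(t.size)
        ll_y = multivariate_normal.logpdf(y, mean=p0.beta[0] + p0.beta[1] * t, cov=V)
        logh, Lam = _survival_terms(p0, toy_subject, np.zeros(2))
        ll_t = toy_subject.delta * logh - Lam
        assert ll == pytest.approx(ll_y + ll_t, abs=1e-8)

    def test_no_records_reduces_to_marginal_survival(self, toy_params):
        s = jm.Subject(id="a", sex=1, age0=75.0, t_obs=4.0, delta=1, records=[])
        ll = subject_loglik(s, toy_params, n_ghq=25)
        # 2-D trapezoid integral of the survival density over the prior
        g0 = np.linspace(-8 * 0.33, 8 * 0.33, 301)
        g1 = np.linspace(-8 * 0.05, 8 * 0.05, 301)
        vals = np.empty((301, 301))
        for i, b0 in enumerate(g0):
            for j, b1 in enumerate(g1):
                logh, Lam = _survival_terms(toy_params, s, np.array([b0, b1]))
                lb = multivariate_normal.logpdf(
                    [b0, b1], mean=np.zeros(2), cov=toy_params.D
                )
                vals[i, j] = np.exp(logh - Lam + lb)
        oracle = np.trapezoid(np.trapezoid(vals, g1, axis=1), g0)
        assert np.exp(ll) == pytest.approx(oracle, rel=1e-5)

    def test_matches_tensor_grid_oracle(self, toy_params, toy_subject):
        ll = subject_loglik(toy_subject, toy_params, n_ghq=15)
        t = np.array([r.t for r in toy_subject.records])
        y = np.array([r.y for r in toy_subject.records])
        g0 = np.linspace(-8 * 0.33, 8 * 0.33, 201)
        g1 = np.linspace(-8 * 0.05, 8 * 0.05, 201)
        vals = np.empty((201, 201))
        for i, b0 in enumerate(g0):
            for j, b1 in enumerate(g1):
                m = (toy_params.beta[0] + b0) + (toy_params.beta[1] + b1) * t
                ly = np.sum(
                    -0.5 * np.log(2 * np.pi * toy_params.sigma**2)
                    - (y - m) ** 2 / (2 * toy_params.sigma**2)
                )
                logh, Lam = _survival_terms(toy_params, toy_subject, np.array([b0, b1]))
                lb = multivariate_normal.logpdf([b0, b1], mean=np.zeros(2), cov=toy_params.D)
                vals[i, j] = np.exp(ly + toy_subject.delta * logh - Lam + lb)
        oracle = np.trapezoid(np.trapezoid(vals, g1, axis=1), g0)
        assert abs(np.exp(ll) - oracle) / oracle < 1e-6


class TestFitJoint:
    def test_reference_fit_converges(self, joint_fit_500):
        fit = joint_fit_500
        assert fit.converged
        assert np.isfinite(fit.loglik)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)
        assert fit.se["alpha"] > 0
        assert fit.information_pd

    def test_reported_loglik_consistent_across_grids(self, cohort500, joint_fit_500):
        # evaluating the optimum on a grid built from the *separate* fit's
        # empirical-Bayes posteriors reproduces the reported log-likelihood:
        # the quadrature is stable between initial and final grids
        lmm = fit_lmm(cohort500, compute_se=False)
        design = _JointDesign(cohort500, joint_fit_500.params, lmm, n_ghq=9)
        ll_opt = -design.negloglik(joint_fit_500.theta_transformed)
        assert joint_fit_500.loglik == pytest.approx(ll_opt, abs=0.06)

    def test_optimum_is_stationary(self, cohort500, joint_fit_500):
        lmm = joint_fit_500.params.longitudinal_view()
        design = _JointDesign(cohort500, joint_fit_500.params, lmm, n_ghq=9)
        th = joint_fit_500.theta_transformed
        f0, g = design.negloglik_grad(th)
        # spot-check local optimality along each coordinate
        for i in range(th.size):
            for sgn in (+1, -1):
                e = np.zeros_like(th)
                e[i] = sgn * 1e-3 * max(1.0, abs(th[i]))
                assert design.negloglik(th + e) >= f0 - 5e-3

    def test_quadrature_stability_9_vs_15_nodes(self, small_cohort):
        fit = jm.fit_joint(small_cohort, n_interior=1, compute_se=False, maxiter=400)
        ll9 = sum(subject_loglik(s, fit.params, n_ghq=9) for s in small_cohort.subjects)
        ll15 = sum(subject_loglik(s, fit.params, n_ghq=15) for s in small_cohort.subjects)
        assert abs(ll9 - ll15) / len(small_cohort) < 1e-4

    def test_sensitivity_modes_fit(self, small_cohort):
        for mode in ("current-value", "value-plus-slope"):
            fit = jm.fit_joint(
                small_cohort, mode=mode, n_interior=1, compute_se=False, maxiter=400
            )
            assert np.isfinite(fit.loglik)
            n_alpha = 2 if mode == "value-plus-slope" else 1
            assert fit.params.alpha.size == n_alpha

    def test_unknown_mode_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            jm.fit_joint(small_cohort, mode="bogus")


class TestCompareWeightings:
    def test_duplicate_candidates_tie_and_aic_arithmetic(self, small_cohort):
        w = jm.default_weight()
        tab = jm.compare_weightings(
            small_cohort, [w, w], n_interior=1, maxiter=300
        )
        assert tab.aic.iloc[0] == pytest.approx(tab.aic.iloc[1], abs=1e-6)
        for _, row in tab.iterrows():
            k = row["fit"].n_params
            assert row["aic"] == pytest.approx(-2 * row["loglik"] + 2 * k)

    def test_needs_two_candidates(self, small_cohort):
        with pytest.raises(ValueError):
            jm.compare_weightings(small_cohort, [jm.default_weight()])


class TestLrtRandomSlope:
    def test_identical_logliks_give_null_result(self):
        stat, p = lrt_random_slope(-100.0, -100.0)
        assert stat == 0.0 and p == 1.0

    def test_mixture_reference_distribution(self):
        stat, p = lrt_random_slope(-100.0, -97.0)
        assert stat == pytest.approx(6.0)
        assert p == pytest.approx(0.5 * chi2.sf(6.0, 1) + 0.5 * chi2.sf(6.0, 2))

    def test_large_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            lrt_random_slope(-100.0, -103.0)

    def test_detects_slope_heterogeneity_in_longitudinal_fits(self):
        """At the reference slope SD (0.05) the boundary LRT on the mixed
        fits rejects in the majority of replicate cohorts."""
        hits = 0
        for rep in range(5):
            cohort = simulate_cohort(SimulationConfig(n_subjects=500, alpha=0.0), seed=400 + rep)
            f0 = fit_lmm(cohort, random_slope=False, compute_se=False)
            f1 = fit_lmm(cohort, random_slope=True, compute_se=False)
            _, p = lrt_random_slope(f0, f1)
            hits += p < 0.05
        assert hits >= 3
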