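"""Fixed-effect branch: trace summaries, moment estimators, bootstrap SE."""

import numpy as np
import pytest

from sparseherit.moments import (
    MomentVarianceEstimator,
    compute_d1_d2,
    fixed_se,
    h2_point,
    mom_estimate,
)
from sparseherit._utils import DegenerateDesignError


class TestD1D2:
    def test_identity_covariance_case(self):
        # columns scaled so S = (1/m) W'W = I exactly
        m2, nh = 100, 10
        rng = np.random.default_rng(0)
        W = np.linalg.qr(rng.standard_normal((m2, nh)))[0] * np.sqrt(m2)
        d1, d2 = compute_d1_d2(W)
        assert d1 == pytest.approx(1.0, abs=1e-12)
        assert d2 == pytest.approx(1.0 - nh / m2, abs=1e-12)

    def test_single_column_closed_form(self):
        rng = np.random.default_rng(1)
        w = rng.standard_normal(50)
        c = float(w @ w) / 50
        d1, d2 = compute_d1_d2(w[:, None])
        assert d1 == pytest.approx(c)
        assert d2 == pytest.approx(c**2 * (1 - 1 / 50))

    def test_matches_dense_trace_oracle(self):
        rng = np.random.default_rng(2)
        W = rng.standard_normal((20, 8))
        S = W.T @ W / 20
        d1_expected = np.trace(S) / 8
        d2_expected = np.trace(S @ S) / 8 - np.trace(S) ** 2 / (8 * 20)
        d1, d2 = compute_d1_d2(W)
        assert d1 == pytest.approx(d1_expected, abs=1e-10)
        assert d2 == pytest.approx(d2_expected, abs=1e-10)

    def test_gram_route_agrees_with_covariance_route(self):
        # wide matrix (n > m) exercises the Gram-form branch
        rng = np.random.default_rng(3)
        W = rng.standard_normal((15, 40))
        S = W.T @ W / 15
        d1, d2 = compute_d1_d2(W)
        assert d1 == pytest.approx(np.trace(S) / 40, abs=1e-10)
        assert d2 == pytest.approx(
            np.trace(S @ S) / 40 - np.trace(S) ** 2 / (40 * 15), abs=1e-10
        )

    def test_degenerate_design_rejected(self):
        with pytest.raises(DegenerateDesignError):
            compute_d1_d2(np.zeros((10, 3)))


class TestMomEstimate:
    def test_zero_phenotype_gives_zero_components(self):
        rng = np.random.default_rng(4)
        W = rng.standard_normal((20, 6))
        est = mom_estimate(np.zeros(20), W)
        assert est.tau2_hat == 0.0 and est.sigma_e2_hat == 0.0
        assert np.isnan(est.h2_raw)

    def test_linear_in_squared_norms_scale_equivariance(self):
        rng = np.random.default_rng(5)
        W = rng.standard_normal((40, 12))
        y = W[:, 0] + rng.standard_normal(40)
        base = mom_estimate(y, W)
        scaled = mom_estimate(3.0 * y, W)
        assert scaled.tau2_hat == pytest.approx(9 * base.tau2_hat, rel=1e-12)
        assert scaled.sigma_e2_hat == pytest.approx(9 * base.sigma_e2_hat, rel=1e-12)
        assert scaled.h2_raw == pytest.approx(base.h2_raw, rel=1e-12)

    def test_fixed_instance_matches_symbolic_evaluation(self):
        # 6x2 instance evaluated step by step, independent of the implementation
        W = np.array(
            [[1.0, 0.5], [-1.0, 1.5], [0.5, -0.5], [2.0, 0.0], [-0.5, -1.0], [0.0, 1.0]]
        )
        y = np.array([1.0, -2.0, 0.5, 1.5, -1.0, 0.5])
        m2, nh = 6, 2
        S = W.T @ W / m2
        d1 = np.trace(S) / nh
        d2 = np.trace(S @ S) / nh - np.trace(S) ** 2 / (nh * m2)
        yn = y @ y
        wyn = np.sum((W.T @ y) ** 2)
        c = d1 / (m2 * (m2 + 1) * d2)
        tau_expected = -nh * d1 * c * yn + c * wyn
        sig_expected = (1 + nh * d1**2 / ((m2 + 1) * d2)) * yn / m2 - c * wyn
        est = mom_estimate(y, W)
        assert est.tau2_hat == pytest.approx(tau_expected, rel=1e-12)
        assert est.sigma_e2_hat == pytest.approx(sig_expected, rel=1e-12)

    def test_literal_formula_differs_and_is_biased_up_in_sigma(self):
        # the literal printed sigma_e2 (1/n_hat total-variance factor) blows up
        # whenever n_hat << m2 — the reason the reference form is the default
        rng = np.random.default_rng(6)
        W = rng.standard_normal((200, 10))
        y = rng.standard_normal(200)
        ref = mom_estimate(y, W, formula="reference")
        lit = mom_estimate(y, W, formula="literal")
        assert lit.sigma_e2_hat > 5 * ref.sigma_e2_hat

    def test_components_sum_to_total_variance(self):
        # reference form: tau2 + sigma_e2 == ||y||^2 / m2 identically
        rng = np.random.default_rng(7)
        for m2, nh in [(50, 10), (30, 60)]:
            W = rng.standard_normal((m2, nh))
            y = W[:, 0] * 0.3 + rng.standard_normal(m2)
            est = mom_estimate(y, W)
            assert est.tau2_hat + est.sigma_e2_hat == pytest.approx(
                float(y @ y) / m2, rel=1e-10
            )

    def test_unbiased_under_identity_covariance_small(self):
        # desk-size version of the Sigma = I unbiasedness property
        rng = np.random.default_rng(8)
        taus, sigs = [], []
        m2, nh = 200, 80
        for _ in range(150):
            W = rng.standard_normal((m2, nh))
            u = rng.normal(0, np.sqrt(1 / nh), nh)
            y = W @ u + rng.standard_normal(m2)
            est = mom_estimate(y, W)
            taus.append(est.tau2_hat)
            sigs.append(est.sigma_e2_hat)
        for vals in (taus, sigs):
            se = np.std(vals, ddof=1) / np.sqrt(len(vals))
            assert abs(np.mean(vals) - 1.0) < 3 * se


class TestH2Point:
    def test_interior_value_unclipped(self):
        raw, h2, clipped = h2_point(1.0, 1.0)
        assert (raw, h2, clipped) == (0.5, 0.5, False)

    def test_negative_tau_clips_low(self):
        raw, h2, clipped = h2_point(-0.1, 1.0)
        assert raw < 0 and h2 == 0.0001 and clipped

    def test_ratio_above_one_clips_high(self):
        raw, h2, clipped = h2_point(1.0, -0.2)
        assert raw > 1 and h2 == 0.9999 and clipped

    def test_zero_total_rejected(self):
        with pytest.raises(ZeroDivisionError):
            h2_point(0.0, 0.0)


class TestBootstrapSE:
    def test_identity_resample_returns_zero(self):
        rng = np.random.default_rng(9)
        W = rng.standard_normal((30, 5))
        y = W[:, 0] + rng.standard_normal(30)
        assert fixed_se(y, W, n_boot=1, seed=0) == 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        W = rng.standard_normal((40, 8))
        y = W[:, 0] + rng.standard_normal(40)
        assert fixed_se(y, W, n_boot=60, seed=3) == fixed_se(y, W, n_boot=60, seed=3)

    def test_calibrated_against_replicate_sd(self):
        # bootstrap SE within a factor 1.5 of the empirical SD of h2 across
        # independent replicates of the same generating process
        rng = np.random.default_rng(11)
        m2, nh = 120, 30
        h2s = []
        for _ in range(100):
            W = rng.standard_normal((m2, nh))
            u = rng.normal(0, np.sqrt(1 / nh), nh)
            y = W @ u + rng.standard_normal(m2)
            h2s.append(mom_estimate(y, W).h2)
        empirical_sd = np.std(h2s, ddof=1)
        W = rng.standard_normal((m2, nh))
        u = rng.normal(0, np.sqrt(1 / nh), nh)
        y = W @ u + rng.standard_normal(m2)
        se = fixed_se(y, W, n_boot=200, seed=5)
        assert empirical_sd / 1.5 < se < empirical_sd * 1.5


def test_estimator_class_wraps_functions():
    rng = np.random.default_rng(12)
    W = rng.standard_normal((50, 10))
    y = W[:, 0] + rng.standard_normal(50)
    est = MomentVarianceEstimator(n_boot=30, random_state=1).fit(W, y)
    ref = mom_estimate(y, W)
    assert est.tau2_ == ref.tau2_hat
    assert est.h2_ == ref.h2
    assert est.se_ is not None and est.se_ >= 0
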