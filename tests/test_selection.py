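"""Stage-1 checks: splitting, lambda grids, elastic-net KKT, one-SE rule."""

import numpy as np
import pytest

from sparseherit import (
    ElasticNetConfig,
    ElasticNetSelector,
    cross_validate,
    fit_elastic_net,
    lambda_grid,
    select_model,
    split_sample,
)
from sparseherit.selection import choose_lambda_one_se
from sparseherit._utils import SparseHeritError


def subgradient_violation(W, y, u, alpha, lam):
    """Independent stationarity check of the elastic-net objective.

    Derived directly from the objective
    (1/2m)||y-Wu||^2 + alpha*lam*||u||_1 + ((1-alpha)/2)*lam*||u||^2.
    """
    m = W.shape[0]
    grad_smooth = W.T @ (W @ u - y) / m + (1 - alpha) * lam * u
    worst = 0.0
    for j in range(len(u)):
        if u[j] > 0:
            worst = max(worst, abs(grad_smooth[j] + alpha * lam))
        elif u[j] < 0:
            worst = max(worst, abs(grad_smooth[j] - alpha * lam))
        else:
            worst = max(worst, max(0.0, abs(grad_smooth[j]) - alpha * lam))
    return worst


class TestSplit:
    def test_even_split(self):
        plan = split_sample(1000, seed=0)
        assert len(plan.half1) == len(plan.half2) == 500
        assert np.intersect1d(plan.half1, plan.half2).size == 0
        assert np.array_equal(
            np.sort(np.concatenate([plan.half1, plan.half2])), np.arange(1000)
        )

    def test_odd_split(self):
        plan = split_sample(7, seed=1)
        assert sorted([len(plan.half1), len(plan.half2)]) == [3, 4]

    def test_deterministic(self):
        a, b = split_sample(100, seed=9), split_sample(100, seed=9)
        assert np.array_equal(a.half1, b.half1)

    def test_too_small_rejected(self):
        with pytest.raises(SparseHeritError):
            split_sample(3, seed=0)


class TestLambdaGrid:
    def test_geometric_construction(self):
        # single predictor with (1/m) w'y = 2 => lam_max = 2 at alpha=1
        w = np.full(4, 1.0)
        y = np.full(4, 2.0)
        grid = lambda_grid(w[:, None], y, alpha=1.0, n_lambda=3, lambda_min_ratio=0.01)
        assert np.allclose(grid, [2.0, 0.2, 0.02])

    def test_alpha_scaling(self):
        rng = np.random.default_rng(0)
        W = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        g1 = lambda_grid(W, y, alpha=1.0)
        g05 = lambda_grid(W, y, alpha=0.5)
        assert g05[0] == pytest.approx(2 * g1[0])

    def test_strictly_decreasing(self):
        rng = np.random.default_rng(1)
        W = rng.standard_normal((15, 8))
        y = rng.standard_normal(15)
        grid = lambda_grid(W, y, alpha=0.7, n_lambda=50)
        assert np.all(np.diff(grid) < 0)

    def test_orthogonal_phenotype_rejected(self):
        W = np.array([[1.0], [-1.0]])
        y = np.array([1.0, 1.0])
        with pytest.raises(SparseHeritError, match="degenerate"):
            lambda_grid(W, y, alpha=1.0)


class TestFitElasticNet:
    def test_zero_above_lambda_max(self):
        rng = np.random.default_rng(2)
        W = rng.standard_normal((30, 10))
        y = rng.standard_normal(30)
        lam_max = lambda_grid(W, y, 1.0)[0]
        u = fit_elastic_net(W, y, alpha=1.0, lam=lam_max * 1.001)
        assert np.all(u == 0)

    def test_soft_threshold_closed_form(self):
        # single standardized predictor, (1/m)w'y = 2, (1/m)w'w = 1
        m = 8
        w = np.ones(m)
        y = 2 * np.ones(m)
        u = fit_elastic_net(w[:, None], y, alpha=1.0, lam=0.5)
        assert u[0] == pytest.approx(1.5, abs=1e-7)

    def test_elastic_net_closed_form(self):
        # S(2, alpha*lam)/(1 + (1-alpha)*lam) = S(2, 0.5)/1.5 = 1.0
        m = 8
        w = np.ones(m)
        y = 2 * np.ones(m)
        u = fit_elastic_net(w[:, None], y, alpha=0.5, lam=1.0)
        assert u[0] == pytest.approx(1.0, abs=1e-7)

    @pytest.mark.parametrize("alpha,lam_frac", [(1.0, 0.3), (0.5, 0.1), (0.2, 0.5)])
    def test_kkt_conditions_hold(self, alpha, lam_frac):
        rng = np.random.default_rng(7)
        W = rng.standard_normal((40, 25))
        y = W[:, 0] * 0.5 + rng.standard_normal(40)
        lam = lam_frac * lambda_grid(W, y, alpha)[0]
        u = fit_elastic_net(W, y, alpha=alpha, lam=lam)
        assert subgradient_violation(W, y, u, alpha, lam) <= 1e-6

    def test_objective_no_worse_than_zero(self):
        rng = np.random.default_rng(8)
        W = rng.standard_normal((25, 12))
        y = rng.standard_normal(25)

        def objective(u, alpha, lam):
            m = len(y)
            return (
                np.sum((y - W @ u) ** 2) / (2 * m)
                + alpha * lam * np.abs(u).sum()
                + (1 - alpha) / 2 * lam * np.sum(u**2)
            )

        for alpha, lam in [(1.0, 0.05), (0.5, 0.2)]:
            u = fit_elastic_net(W, y, alpha, lam)
            assert objective(u, alpha, lam) <= objective(np.zeros(12), alpha, lam) + 1e-12

    def test_warm_path_matches_cold_fits(self):
        from sklearn.linear_model import enet_path

        rng = np.random.default_rng(9)
        W = rng.standard_normal((30, 15))
        y = W[:, 1] - 0.5 * W[:, 2] + 0.3 * rng.standard_normal(30)
        lams = lambda_grid(W, y, 0.8, n_lambda=10, lambda_min_ratio=0.05)
        _, coefs, _ = enet_path(W, y, l1_ratio=0.8, alphas=lams, tol=1e-10)

        def objective(u, lam):
            m = len(y)
            return (
                np.sum((y - W @ u) ** 2) / (2 * m)
                + 0.8 * lam * np.abs(u).sum()
                + 0.1 * lam * np.sum(u**2)
            )

        for k, lam in enumerate(lams):
            cold = fit_elastic_net(W, y, 0.8, lam)
            assert objective(coefs[:, k], lam) == pytest.approx(
                objective(cold, lam), abs=1e-8
            )


class TestOneSERule:
    def test_spec_example(self):
        lams = np.array([1.0, 0.5, 0.1])
        mean = np.array([1.0, 0.8, 0.79])
        se = np.array([0.05, 0.05, 0.05])
        assert lams[choose_lambda_one_se(lams, mean, se, "sparse")] == 0.5

    def test_all_equal_chooses_sparsest(self):
        lams = np.array([1.0, 0.5, 0.1])
        mean = np.ones(3)
        se = np.full(3, 0.01)
        assert lams[choose_lambda_one_se(lams, mean, se, "sparse")] == 1.0

    def test_minimum_at_largest_lambda(self):
        lams = np.array([1.0, 0.5, 0.1])
        mean = np.array([0.5, 0.8, 0.9])
        se = np.full(3, 0.01)
        assert lams[choose_lambda_one_se(lams, mean, se, "sparse")] == 1.0

    def test_dense_direction_literal_reading(self):
        lams = np.array([1.0, 0.5, 0.1])
        mean = np.array([1.0, 0.8, 0.79])
        se = np.array([0.05, 0.05, 0.05])
        assert lams[choose_lambda_one_se(lams, mean, se, "dense")] == 0.1


@pytest.fixture(scope="module")
def cv_problem():
    rng = np.random.default_rng(12)
    W = rng.standard_normal((80, 40))
    u = np.zeros(40)
    u[:3] = [1.0, -0.8, 0.6]
    y = W @ u + 0.5 * rng.standard_normal(80)
    return W, y


class TestCrossValidate:
    def test_reproducible_given_seed(self, cv_problem):
        W, y = cv_problem
        cfg = ElasticNetConfig(alpha_grid=(0.5, 1.0), n_lambda=20, n_folds=5, cv_seed=4)
        a = cross_validate(W, y, cfg)
        b = cross_validate(W, y, cfg)
        assert np.array_equal(a.mean_mse, b.mean_mse)
        assert a.chosen_alpha == b.chosen_alpha and a.chosen_lambda == b.chosen_lambda

    def test_chosen_pair_in_grid(self, cv_problem):
        W, y = cv_problem
        cfg = ElasticNetConfig(alpha_grid=(0.5, 1.0), n_lambda=20, n_folds=5, cv_seed=4)
        path = cross_validate(W, y, cfg)
        assert path.chosen_alpha in (0.5, 1.0)
        i = list(path.alphas).index(path.chosen_alpha)
        assert path.chosen_lambda in path.lambdas[i]
        assert np.all(path.se_mse >= 0)

    def test_support_monotone_along_path(self, cv_problem):
        from sklearn.linear_model import enet_path

        W, y = cv_problem
        lams = lambda_grid(W, y, 1.0, n_lambda=12, lambda_min_ratio=0.05)
        _, coefs, _ = enet_path(W, y, l1_ratio=1.0, alphas=lams, tol=1e-9)
        nnz = (coefs != 0).sum(axis=0)
        # support grows (weakly) as lambda decreases on this well-behaved instance
        assert np.all(np.diff(nnz) >= 0)


class TestSelectModel:
    def test_recovers_planted_strong_support(self, sparse_cohort):
        # five strong, equal-magnitude causal SNPs at low noise: the lasso
        # path must contain them essentially always
        data, _, _ = sparse_cohort
        rng = np.random.default_rng(21)
        causal = np.array([10, 100, 250, 400, 550])
        u = np.zeros(data.n)
        u[causal] = 0.5 * np.array([1, -1, 1, 1, -1])
        y = data.W @ u + 0.1 * rng.standard_normal(data.m)
        hits = 0
        for seed in range(10):
            res = select_model(
                data.W,
                y - y.mean(),
                ElasticNetConfig(
                    alpha_grid=(0.5, 1.0), n_lambda=30, lambda_min_ratio=0.01,
                    cv_seed=seed,
                ),
            )
            if set(causal) <= set(res.M_hat):
                hits += 1
        assert hits >= 9

    def test_pure_noise_heavy_penalty_flags_empty(self):
        rng = np.random.default_rng(5)
        W = rng.standard_normal((60, 30))
        y = rng.standard_normal(60)
        cfg = ElasticNetConfig(alpha_grid=(1.0,), n_lambda=5, lambda_min_ratio=0.9,
                               n_folds=5)
        res = select_model(W, y, cfg)
        assert res.empty == (res.n_hat == 0)
        assert res.n_hat == np.count_nonzero(res.u_hat)

    def test_estimator_class_api(self, sparse_cohort):
        data, truth, y = sparse_cohort
        sel = ElasticNetSelector(
            alpha_grid=(1.0,), n_lambda=20, lambda_min_ratio=0.05, random_state=0
        ).fit(data.W, y - y.mean())
        assert sel.n_selected_ == len(sel.support_)
        assert np.array_equal(np.flatnonzero(sel.coef_), sel.support_)
        Wt = sel.transform(data.W)
        assert Wt.shape == (data.W.shape[0], sel.n_selected_)
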