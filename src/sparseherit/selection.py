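"""Stage 1: sample splitting and cross-validated elastic-net model selection.

The objective minimized on half 1 (m1 rows) is

    (1/(2 m1)) ||y1 - W1 u||_2^2 + alpha*lambda*||u||_1
        + ((1 - alpha)/2)*lambda*||u||_2^2,

with mixing weight alpha in (0, 1] (1 = lasso) and penalty lambda > 0 — the
parameterization of scikit-learn's ElasticNet(alpha=lambda, l1_ratio=alpha),
which does the coordinate descent.  For each alpha on a grid, 10-fold CV
traces the lambda path; the per-alpha lambda is picked by the one-standard-
error rule (sparse direction by default), and the final alpha is the one
whose path attains the smallest CV MSE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import ElasticNet, enet_path

from ._utils import ConvergenceError, SparseHeritError, as_rng

#: alpha grid the real-data analyses used (very polygenic traits)
REAL_DATA_ALPHA_GRID = (3e-5, 1e-4, 3e-4, 1e-3)


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint equal halves of the sample index range."""

    half1: np.ndarray
    half2: np.ndarray
    seed: int

    def __post_init__(self):
        if np.intersect1d(self.half1, self.half2).size:
            raise ValueError("halves must be disjoint")


@dataclass(frozen=True)
class ElasticNetConfig:
    """Grid and CV settings for stage 1.

    ``n_lambda=100`` geometric points down to ``lambda_min_ratio=1e-4`` of
    lambda_max mirror common path-fitting defaults.  ``precision`` controls
    the dtype of the fold-level path fits only; the final refit is always
    double precision.
    """

    alpha_grid: tuple[float, ...] = (0.001, 0.01, 0.1, 0.5, 1.0)
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    n_folds: int = 10
    cv_seed: int = 0
    one_se_direction: str = "sparse"
    precision: str = "single"
    tol: float = 1e-8
    max_iter: int = 100_000

    def __post_init__(self):
        if not all(0.0 < a <= 1.0 for a in self.alpha_grid):
            raise ValueError("every alpha must lie in (0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0.0 < self.lambda_min_ratio < 1.0:
            raise ValueError("lambda_min_ratio must lie in (0, 1)")
        if self.one_se_direction not in ("sparse", "dense"):
            raise ValueError("one_se_direction must be 'sparse' or 'dense'")
        if self.precision not in ("single", "double"):
            raise ValueError("precision must be 'single' or 'double'")


@dataclass
class CVPath:
    """CV surface over the (alpha, lambda) grid and the chosen pair."""

    alphas: np.ndarray  # (n_alpha,)
    lambdas: np.ndarray  # (n_alpha, n_lambda), descending per row
    mean_mse: np.ndarray  # (n_alpha, n_lambda)
    se_mse: np.ndarray  # (n_alpha, n_lambda)
    per_alpha_lambda: np.ndarray  # (n_alpha,) one-SE choice per alpha
    chosen_alpha: float
    chosen_lambda: float

    def table(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.alphas):
            for j in range(self.lambdas.shape[1]):
                rows.append((a, self.lambdas[i, j], self.mean_mse[i, j], self.se_mse[i, j]))
        return pd.DataFrame(rows, columns=["alpha", "lambda", "mean_mse", "se_mse"])


@dataclass
class SelectionResult:
    """Refit coefficients at the chosen (alpha, lambda) and their support."""

    u_hat: np.ndarray
    M_hat: np.ndarray
    n_hat: int
    cv_path: CVPath
    empty: bool = False


def split_sample(m: int, seed: int) -> SplitPlan:
    """Uniformly random partition into halves of size floor(m/2), ceil(m/2)."""
    if m < 4:
        raise SparseHeritError(f"need m >= 4 samples to run both stages, got {m}")
    perm = as_rng(seed).permutation(m)
    k = m // 2
    return SplitPlan(half1=np.sort(perm[:k]), half2=np.sort(perm[k:]), seed=seed)


def lambda_grid(
    W1: np.ndarray,
    y1: np.ndarray,
    alpha: float,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
) -> np.ndarray:
    """Descending geometric penalty grid from the smallest all-zero lambda.

    lambda_max = max_j |W1_j' y1| / (m1 * alpha) is the smallest penalty at
    which the all-zero vector satisfies the subgradient conditions.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    m1 = W1.shape[0]
    lam_max = float(np.max(np.abs(W1.T @ y1))) / (m1 * alpha)
    if lam_max <= 0.0:
        raise SparseHeritError("y1 is orthogonal to every column; lambda grid degenerate")
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def kkt_residual(
    W: np.ndarray, y: np.ndarray, u: np.ndarray, alpha: float, lam: float
) -> float:
    """Max violation of the stationarity (subgradient) conditions at u.

    g = -(1/m) W'(y - Wu) + (1-alpha)*lam*u must satisfy
    g_j = -alpha*lam*sign(u_j) on the support and |g_j| <= alpha*lam off it.
    """
    m = W.shape[0]
    g = -(W.T @ (y - W @ u)) / m + (1.0 - alpha) * lam * u
    on = u != 0
    res_on = np.abs(g[on] + alpha * lam * np.sign(u[on]))
    res_off = np.maximum(np.abs(g[~on]) - alpha * lam, 0.0)
    return float(max(res_on.max(initial=0.0), res_off.max(initial=0.0)))


def fit_elastic_net(
    W1: np.ndarray,
    y1: np.ndarray,
    alpha: float,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 100_000,
    kkt_tol: float = 1e-6,
) -> np.ndarray:
    """Single elastic-net fit at (alpha, lambda); KKT-checked to ``kkt_tol``."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    W1 = np.asarray(W1, dtype=np.float64)
    y1 = np.asarray(y1, dtype=np.float64)
    if lam == 0.0:
        return np.linalg.lstsq(W1, y1, rcond=None)[0]
    model = ElasticNet(
        alpha=lam, l1_ratio=alpha, fit_intercept=False, tol=tol, max_iter=max_iter
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(W1, y1)
    u = model.coef_.astype(np.float64)
    res = kkt_residual(W1, y1, u, alpha, lam)
    if res > kkt_tol:
        raise ConvergenceError(
            f"elastic net at (alpha={alpha}, lambda={lam:g}) did not reach "
            f"stationarity: KKT residual {res:.3e} > {kkt_tol:g}"
        )
    return u


def choose_lambda_one_se(
    lambdas: np.ndarray,
    mean_mse: np.ndarray,
    se_mse: np.ndarray,
    direction: str = "sparse",
) -> int:
    """Index of the one-SE-rule lambda on a descending grid.

    ``sparse``: the largest lambda whose mean CV MSE is within one standard
    error of the minimum (conventional rule).  ``dense``: the smallest such
    lambda (the literal 'smallest lambda within one SE' reading).
    """
    j_min = int(np.argmin(mean_mse))
    threshold = mean_mse[j_min] + se_mse[j_min]
    within = np.flatnonzero(mean_mse <= threshold)
    return int(within[0]) if direction == "sparse" else int(within[-1])


def cross_validate(
    W1: np.ndarray, y1: np.ndarray, config: ElasticNetConfig = ElasticNetConfig()
) -> CVPath:
    """k-fold CV over the (alpha, lambda) grid.

    Folds are contiguous blocks of a seeded shuffle, identical across the
    whole grid.  Per (alpha, lambda): mean held-out MSE and its standard
    error (SD across folds / sqrt(k)).  Per alpha the one-SE lambda is
    chosen; the final alpha minimizes the path-minimum MSE, ties broken
    toward the larger (sparser) alpha.
    """
    W1 = np.asarray(W1)
    y1 = np.asarray(y1, dtype=np.float64)
    m1 = W1.shape[0]
    if m1 < config.n_folds:
        raise SparseHeritError(f"need at least n_folds={config.n_folds} samples, got {m1}")
    dtype = np.float32 if config.precision == "single" else np.float64
    Wc = W1.astype(dtype, copy=False)
    yc = y1.astype(dtype, copy=False)

    perm = as_rng(config.cv_seed).permutation(m1)
    folds = np.array_split(perm, config.n_folds)

    n_alpha = len(config.alpha_grid)
    lambdas = np.empty((n_alpha, config.n_lambda))
    mean_mse = np.empty((n_alpha, config.n_lambda))
    se_mse = np.empty((n_alpha, config.n_lambda))
    per_alpha_lambda = np.empty(n_alpha)

    # fold fitting tolerance: path fits only need MSE curves, not support
    path_tol = max(config.tol, 1e-5 if dtype == np.float32 else 1e-7)

    for i, alpha in enumerate(config.alpha_grid):
        lams = lambda_grid(W1, y1, alpha, config.n_lambda, config.lambda_min_ratio)
        lambdas[i] = lams
        fold_mse = []
        for fold in folds:
            train = np.setdiff1d(perm, fold, assume_unique=True)
            if np.var(yc[train]) == 0.0:
                warnings.warn(
                    "CV fold with zero phenotype variance skipped", stacklevel=2
                )
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, coefs, _ = enet_path(
                    Wc[train],
                    yc[train],
                    l1_ratio=alpha,
                    alphas=lams,
                    tol=path_tol,
                    max_iter=config.max_iter,
                )
            resid = Wc[fold] @ coefs - yc[fold][:, None]
            fold_mse.append(np.mean(resid.astype(np.float64) ** 2, axis=0))
        if not fold_mse:
            raise SparseHeritError("every CV fold was degenerate")
        fold_mse = np.asarray(fold_mse)
        k_eff = fold_mse.shape[0]
        mean_mse[i] = fold_mse.mean(axis=0)
        se_mse[i] = (
            fold_mse.std(axis=0, ddof=1) / np.sqrt(k_eff) if k_eff > 1 else 0.0
        )
        per_alpha_lambda[i] = lams[
            choose_lambda_one_se(lams, mean_mse[i], se_mse[i], config.one_se_direction)
        ]

    path_min = mean_mse.min(axis=1)
    best = path_min.min()
    # ties (to 1e-12) broken toward the larger, sparser alpha
    candidates = np.flatnonzero(path_min <= best + 1e-12)
    i_star = int(candidates[np.argmax(np.asarray(config.alpha_grid)[candidates])])
    return CVPath(
        alphas=np.asarray(config.alpha_grid, dtype=float),
        lambdas=lambdas,
        mean_mse=mean_mse,
        se_mse=se_mse,
        per_alpha_lambda=per_alpha_lambda,
        chosen_alpha=float(config.alpha_grid[i_star]),
        chosen_lambda=float(per_alpha_lambda[i_star]),
    )


def select_model(
    W1: np.ndarray, y1: np.ndarray, config: ElasticNetConfig = ElasticNetConfig()
) -> SelectionResult:
    """Cross-validate, then refit on all of half 1 at the chosen pair."""
    cv = cross_validate(W1, y1, config)
    u = fit_elastic_net(
        W1, y1, cv.chosen_alpha, cv.chosen_lambda, tol=config.tol, max_iter=config.max_iter
    )
    M_hat = np.flatnonzero(u)
    return SelectionResult(
        u_hat=u,
        M_hat=M_hat,
        n_hat=int(M_hat.size),
        cv_path=cv,
        empty=M_hat.size == 0,
    )


class ElasticNetSelector(TransformerMixin, BaseEstimator):
    """Cross-validated elastic-net SNP selector (stage 1).

    Scikit-learn style: ``fit(W, y)`` runs the CV grid search and the final
    refit; ``transform(W)`` restricts a design matrix to the selected SNPs.

    Parameters mirror :class:`ElasticNetConfig`.  Fitted attributes:
    ``coef_`` (length-n effect vector), ``support_`` (selected indices),
    ``n_selected_``, ``alpha_``, ``lambda_``, ``cv_path_``, ``empty_``.
    """

    def __init__(
        self,
        alpha_grid=(0.001, 0.01, 0.1, 0.5, 1.0),
        n_lambda=100,
        lambda_min_ratio=1e-4,
        n_folds=10,
        one_se_direction="sparse",
        precision="single",
        tol=1e-8,
        max_iter=100_000,
        random_state=0,
    ):
        self.alpha_grid = alpha_grid
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.n_folds = n_folds
        self.one_se_direction = one_se_direction
        self.precision = precision
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _config(self) -> ElasticNetConfig:
        return ElasticNetConfig(
            alpha_grid=tuple(self.alpha_grid),
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            n_folds=self.n_folds,
            cv_seed=self.random_state,
            one_se_direction=self.one_se_direction,
            precision=self.precision,
            tol=self.tol,
            max_iter=self.max_iter,
        )

    def fit(self, W, y):
        W = np.asarray(W)
        y = np.asarray(y, dtype=np.float64)
        result = select_model(W, y, self._config())
        self.n_features_in_ = W.shape[1]
        self.coef_ = result.u_hat
        self.support_ = result.M_hat
        self.n_selected_ = result.n_hat
        self.alpha_ = result.cv_path.chosen_alpha
        self.lambda_ = result.cv_path.chosen_lambda
        self.cv_path_ = result.cv_path
        self.empty_ = result.empty
        return self

    def transform(self, W):
        W = np.asarray(W)
        if W.shape[1] != self.n_features_in_:
            raise ValueError("W has a different number of SNPs than at fit time")
        return W[:, self.support_]
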