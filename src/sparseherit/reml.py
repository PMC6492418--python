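"""Stage 2, random-effect branch: single-component GREML.

Fits y ~ N(X beta, sigma_g^2 K + sigma_e^2 I) by restricted maximum
likelihood, where K is the genetic relationship matrix over the selected
SNPs and X is the intercept (any other covariates are projected out
upstream).  Because there is a single GRM plus a residual, the fit is exact
without iterative schemes: K is eigendecomposed once, y is rotated to the
eigenbasis, and the restricted likelihood is profiled over the heritability
ratio h = sigma_g^2 / (sigma_g^2 + sigma_e^2) on a dense grid followed by
bounded local refinement.  The average-information matrix at the optimum
feeds a delta-method standard error for h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from ._utils import ConvergenceError, NonIdentifiableError, h2_ratio
from .grm import GRM, build_grm

_H_BOUNDS = (1e-6, 1.0 - 1e-6)


@dataclass
class RandomVarianceEstimate:
    """Random-effect branch output."""

    sigma_g2: float
    sigma_e2: float
    h2: float
    h2_raw: float
    se: float | None
    loglik: float
    converged: bool
    n_iter: int
    info_inv: np.ndarray | None = None
    m2: int = 0
    n_hat: int = 0


class _RotatedREML:
    """Restricted likelihood of one GRM + residual in the eigenbasis of K."""

    def __init__(self, y: np.ndarray, K: np.ndarray, n_projected: int = 0):
        y = np.asarray(y, dtype=np.float64)
        K = np.asarray(K, dtype=np.float64)
        m = y.shape[0]
        if K.shape != (m, m):
            raise ValueError("K must be m x m matching y")
        vals, vecs = np.linalg.eigh(K)
        spread = vals.max() - vals.min()
        if spread <= 1e-8 * max(1.0, abs(vals.max())):
            raise NonIdentifiableError(
                "GRM is numerically proportional to the identity; only "
                "sigma_g^2 + sigma_e^2 enters the likelihood"
            )
        self.m = m
        self.vals = np.clip(vals, 0.0, None)  # Gram matrices are PSD
        self.yt = vecs.T @ y
        self.Xt = vecs.T @ np.ones((m, 1))
        self.q = 1 + n_projected  # intercept + previously projected covariates
        self.df = m - self.q

    # -- profiled criterion over h ---------------------------------------
    def _w(self, h: float) -> np.ndarray:
        return h * self.vals + (1.0 - h)

    def profile_loglik(self, h: float) -> float:
        """Restricted log-likelihood maximized analytically over total variance."""
        w = self._w(h)
        yPy, logdet_M = self._quad(w)
        sigp2 = yPy / self.df
        return -0.5 * (
            self.df * np.log(sigp2)
            + np.sum(np.log(w))
            + logdet_M
            + self.df
            + self.df * np.log(2.0 * np.pi)
        )

    def _quad(self, w: np.ndarray) -> tuple[float, float]:
        """y'P y (unit total variance) and log|X' V_h^-1 X|."""
        a = self.yt / w
        B = self.Xt / w[:, None]
        M = self.Xt.T @ B
        beta = np.linalg.solve(M, B.T @ self.yt)
        yPy = float(self.yt @ a - (self.Xt.T @ a).T @ beta)
        sign, logdet = np.linalg.slogdet(M)
        if sign <= 0:
            raise NonIdentifiableError("X' V^-1 X is singular")
        return yPy, float(logdet)

    def components_at(self, h: float) -> tuple[float, float]:
        w = self._w(h)
        yPy, _ = self._quad(w)
        sigp2 = yPy / self.df
        return h * sigp2, (1.0 - h) * sigp2

    def loglik_at(self, sigma_g2: float, sigma_e2: float) -> float:
        """Unprofiled restricted log-likelihood at given components."""
        w = sigma_g2 * self.vals + sigma_e2
        a = self.yt / w
        B = self.Xt / w[:, None]
        M = self.Xt.T @ B
        beta = np.linalg.solve(M, B.T @ self.yt)
        yPy = float(self.yt @ a - (self.Xt.T @ a).T @ beta)
        sign, logdet_M = np.linalg.slogdet(M)
        return -0.5 * (
            np.sum(np.log(w)) + logdet_M + yPy + self.df * np.log(2.0 * np.pi)
        )

    # -- information matrices at the optimum ------------------------------
    def _P(self, w: np.ndarray):
        B = self.Xt / w[:, None]
        M = self.Xt.T @ B

        def apply(v: np.ndarray) -> np.ndarray:
            return v / w - B @ np.linalg.solve(M, self.Xt.T @ (v / w))

        return apply

    def average_information(self, sigma_g2: float, sigma_e2: float) -> np.ndarray:
        """AI matrix: AI_jk = (1/2) y'P V_j P V_k P y with V = (K, I)."""
        w = sigma_g2 * self.vals + sigma_e2
        P = self._P(w)
        py = P(self.yt)
        t = [self.vals * py, py]  # K Py, I Py
        AI = np.empty((2, 2))
        pt = [P(tj) for tj in t]
        for j in range(2):
            for k in range(2):
                AI[j, k] = 0.5 * float(t[j] @ pt[k])
        return AI

    def observed_information(
        self, sigma_g2: float, sigma_e2: float, rel_step: float = 1e-5
    ) -> np.ndarray:
        """Negative Hessian of the restricted log-likelihood (central differences)."""
        theta = np.array([sigma_g2, sigma_e2])
        hstep = rel_step * np.maximum(np.abs(theta), 1e-8)
        H = np.empty((2, 2))
        for j in range(2):
            for k in range(2):
                pts = []
                for sj in (1, -1):
                    for sk in (1, -1):
                        t = theta.copy()
                        t[j] += sj * hstep[j]
                        t[k] += sk * hstep[k]
                        pts.append(sj * sk * self.loglik_at(*np.maximum(t, 1e-12)))
                H[j, k] = (pts[0] - pts[1] - pts[2] + pts[3]) / (4 * hstep[j] * hstep[k])
        return -0.5 * (H + H.T)


def reml_fit(
    y2: np.ndarray,
    grm: GRM | np.ndarray,
    n_projected: int = 0,
    grid_size: int = 64,
    info: str = "average",
    compute_se: bool = True,
) -> RandomVarianceEstimate:
    """Exact single-component REML via eigen-rotation and 1-D profiling.

    ``y2`` should be centered/covariate-projected; the intercept is always
    part of the fixed effects.  The ratio h is searched on
    [1e-6, 1 - 1e-6] (grid of ``grid_size`` points, then Brent refinement on
    the bracketing interval); components are recovered from the profiled
    total variance and the clipped heritability uses the usual
    [0.0001, 0.9999] boundary sentinels.
    """
    K = grm.K if isinstance(grm, GRM) else np.asarray(grm)
    n_hat = grm.n_snps if isinstance(grm, GRM) else 0
    crit = _RotatedREML(y2, K, n_projected=n_projected)

    hs = np.linspace(_H_BOUNDS[0], _H_BOUNDS[1], grid_size)
    lls = np.array([crit.profile_loglik(h) for h in hs])
    i = int(np.argmax(lls))
    lo = hs[max(i - 1, 0)]
    hi = hs[min(i + 1, grid_size - 1)]
    res = minimize_scalar(
        lambda h: -crit.profile_loglik(h),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10, "maxiter": 500},
    )
    if not res.success:
        raise ConvergenceError(
            f"REML profile search failed on bracket [{lo:.6f}, {hi:.6f}]: {res.message}"
        )
    h_hat, ll_hat = float(res.x), float(-res.fun)
    if lls[i] > ll_hat:  # guard: refinement must not lose to the grid
        h_hat, ll_hat = float(hs[i]), float(lls[i])
    sigma_g2, sigma_e2 = crit.components_at(h_hat)

    h2_raw, h2, clipped = h2_ratio(sigma_g2, sigma_e2)
    se = None
    info_inv = None
    if compute_se:
        I = (
            crit.average_information(sigma_g2, sigma_e2)
            if info == "average"
            else crit.observed_information(sigma_g2, sigma_e2)
        )
        try:
            info_inv = np.linalg.inv(I)
            se = delta_se(sigma_g2, sigma_e2, info_inv)
        except np.linalg.LinAlgError:
            se = float("nan")

    return RandomVarianceEstimate(
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_e2),
        h2=h2,
        h2_raw=h2_raw,
        se=se,
        loglik=ll_hat,
        converged=True,
        n_iter=grid_size + int(res.nfev),
        info_inv=info_inv,
        m2=len(np.asarray(y2)),
        n_hat=n_hat,
    )


def reml_loglik(y2: np.ndarray, K: np.ndarray, sigma_g2: float, sigma_e2: float,
                n_projected: int = 0) -> float:
    """Restricted log-likelihood at given components (for cross-checks)."""
    return _RotatedREML(y2, K, n_projected=n_projected).loglik_at(sigma_g2, sigma_e2)


def delta_se(sigma_g2: float, sigma_e2: float, info_inv: np.ndarray) -> float:
    """Delta-method SE of h = sigma_g2/(sigma_g2+sigma_e2).

    g = (sigma_e2, -sigma_g2) / (sigma_g2 + sigma_e2)^2;
    SE = sqrt(g' info_inv g), with info_inv the component covariance.
    """
    info_inv = np.asarray(info_inv, dtype=np.float64)
    if info_inv.shape != (2, 2):
        raise ValueError("info_inv must be 2x2")
    if not np.allclose(info_inv, info_inv.T, atol=1e-10):
        raise ValueError("info_inv must be symmetric")
    eigs = np.linalg.eigvalsh(info_inv)
    if eigs.min() < -1e-10 * max(1.0, eigs.max()):
        raise ValueError("info_inv must be positive semi-definite")
    total = sigma_g2 + sigma_e2
    g = np.array([sigma_e2, -sigma_g2]) / total**2
    return float(np.sqrt(g @ info_inv @ g))


def h2_point_random(sigma_g2: float, sigma_e2: float) -> tuple[float, float, bool]:
    """(h2_raw, clipped h2, clipped flag); shared clipping rule."""
    return h2_ratio(sigma_g2, sigma_e2)


class GREMLVarianceEstimator(BaseEstimator):
    """Sklearn-style wrapper for the random-effect (GREML) branch.

    ``fit(W, y)`` builds K = W W'/n_hat from the selected standardized SNPs
    and runs the exact profiled REML.  ``fit_grm(grm, y)`` accepts a
    precomputed :class:`~sparseherit.grm.GRM`.  Fitted attributes:
    ``sigma_g2_``, ``sigma_e2_``, ``h2_``, ``h2_raw_``, ``se_``, ``loglik_``,
    ``converged_``, ``n_iter_``, ``estimate_``.
    """

    def __init__(self, grid_size=64, info="average", n_projected=0, compute_se=True):
        self.grid_size = grid_size
        self.info = info
        self.n_projected = n_projected
        self.compute_se = compute_se

    def fit(self, W, y):
        W = np.asarray(W)
        grm = build_grm(W)
        self.n_features_in_ = W.shape[1]
        return self.fit_grm(grm, y)

    def fit_grm(self, grm: GRM, y):
        est = reml_fit(
            y,
            grm,
            n_projected=self.n_projected,
            grid_size=self.grid_size,
            info=self.info,
            compute_se=self.compute_se,
        )
        self.estimate_ = est
        self.sigma_g2_ = est.sigma_g2
        self.sigma_e2_ = est.sigma_e2
        self.h2_ = est.h2
        self.h2_raw_ = est.h2_raw
        self.se_ = est.se
        self.loglik_ = est.loglik
        self.converged_ = est.converged
        self.n_iter_ = est.n_iter
        return self
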