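"""Stage 2, fixed-effect branch: method-of-moments variance estimation.

Estimates the genetic variance tau^2 = u*' Sigma u* and residual variance
sigma_e^2 from the quadratic summaries ||y||^2 and ||W' y||^2 together with
two trace summaries of the sample covariance S = (1/m2) W'W of the selected
SNPs:

    d1 = tr(S) / n_hat
    d2 = tr(S^2) / n_hat - tr(S)^2 / (n_hat * m2)

The estimator is valid in high dimension (n_hat > m2) and under column
correlation; it needs neither a model fit nor sparsity.  With c =
d1 / (m2 (m2+1) d2), the default ("reference") forms are

    tau^2_hat    = -n_hat * d1 * c * ||y||^2 + c * ||W'y||^2
    sigma_e2_hat = (1 + n_hat d1^2 / ((m2+1) d2)) ||y||^2 / m2 - c ||W'y||^2

which satisfy tau^2_hat + sigma_e2_hat = ||y||^2 / m2 exactly (total variance
decomposition).  A "literal" variant (leading d2^2 in the tau^2 term and a
1/n_hat total-variance factor) is kept behind ``formula="literal"`` for
comparison; it is biased and not recommended.

The point heritability is tau2/(tau2+sigma_e2) clipped into
[0.0001, 0.9999]; its standard error comes from a nonparametric bootstrap
over individuals, computed entirely on the m2 x m2 Gram matrix so the cost
does not grow with n_hat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from ._utils import DegenerateDesignError, as_rng, h2_ratio


@dataclass(frozen=True)
class MomentSummaries:
    """Sufficient summaries for the moment estimator."""

    d1: float
    d2: float
    y_norm2: float
    wy_norm2: float
    m2: int
    n_hat: int


@dataclass
class FixedVarianceEstimate:
    """Fixed-effect branch output."""

    tau2_hat: float
    sigma_e2_hat: float
    h2: float
    h2_raw: float
    se: float | None
    clipped: bool
    d1: float
    d2: float
    m2: int
    n_hat: int
    formula: str


def compute_d1_d2(W2: np.ndarray) -> tuple[float, float]:
    """Trace summaries d1, d2 of S = (1/m2) W2'W2.

    Works on the Gram form G = W2 W2' when n_hat > m2 so S is never
    materialized for wide panels: tr(S) = tr(G)/m2 and
    tr(S^2) = ||G||_F^2 / m2^2.
    """
    W2 = np.asarray(W2, dtype=np.float64)
    m2, n_hat = W2.shape
    if n_hat < 1 or m2 < 2:
        raise ValueError(f"need n_hat >= 1 and m2 >= 2, got shape {W2.shape}")
    if n_hat > m2:
        G = W2 @ W2.T
        tr_S = float(np.trace(G)) / m2
        tr_S2 = float(np.sum(G * G)) / (m2 * m2)
    else:
        A = W2.T @ W2
        tr_S = float(np.trace(A)) / m2
        tr_S2 = float(np.sum(A * A)) / (m2 * m2)
    return _d1_d2_from_traces(tr_S, tr_S2, m2, n_hat)


def _d1_d2_from_traces(tr_S: float, tr_S2: float, m2: int, n_hat: int) -> tuple[float, float]:
    d1 = tr_S / n_hat
    d2 = tr_S2 / n_hat - tr_S**2 / (n_hat * m2)
    scale = max(tr_S2 / n_hat, 1e-300)
    if d2 <= 1e-12 * scale:
        raise DegenerateDesignError(
            f"d2 = {d2:.3e} is not positive; the moment estimator is undefined "
            "(design covariance has no dispersion)"
        )
    return d1, d2


def _estimate_from_summaries(s: MomentSummaries, formula: str) -> tuple[float, float]:
    d1, d2, m2, n_hat = s.d1, s.d2, s.m2, s.n_hat
    c = d1 / (m2 * (m2 + 1) * d2)
    if formula == "reference":
        tau2 = -n_hat * d1 * c * s.y_norm2 + c * s.wy_norm2
        sig2 = (1.0 + n_hat * d1**2 / ((m2 + 1) * d2)) * s.y_norm2 / m2 - c * s.wy_norm2
    elif formula == "literal":
        tau2 = -(n_hat * d1**2 / (m2 * (m2 + 1) * d2**2)) * s.y_norm2 + c * s.wy_norm2
        sig2 = (1.0 + n_hat * d1**2 / ((m2 + 1) * d2)) * s.y_norm2 / n_hat - c * s.wy_norm2
    else:
        raise ValueError("formula must be 'reference' or 'literal'")
    return float(tau2), float(sig2)


def _summaries_from_gram(G: np.ndarray, y: np.ndarray, n_hat: int) -> MomentSummaries:
    """Moment summaries from the Gram matrix G = W2 W2' (bootstrap workhorse)."""
    m2 = G.shape[0]
    tr_S = float(np.trace(G)) / m2
    tr_S2 = float(np.sum(G * G)) / (m2 * m2)
    d1, d2 = _d1_d2_from_traces(tr_S, tr_S2, m2, n_hat)
    return MomentSummaries(
        d1=d1,
        d2=d2,
        y_norm2=float(y @ y),
        wy_norm2=float(y @ G @ y),
        m2=m2,
        n_hat=n_hat,
    )


def mom_estimate(
    y2: np.ndarray, W2: np.ndarray, formula: str = "reference"
) -> FixedVarianceEstimate:
    """Moment estimates of (tau^2, sigma_e^2) and the plug-in heritability.

    ``y2`` must already be centered (intercept/covariates projected out
    upstream).  Both estimates are linear in (||y2||^2, ||W2'y2||^2), hence
    homogeneous of degree 2 in y2.
    """
    y2 = np.asarray(y2, dtype=np.float64)
    W2 = np.asarray(W2, dtype=np.float64)
    m2, n_hat = W2.shape
    d1, d2 = compute_d1_d2(W2)
    wy = W2.T @ y2
    s = MomentSummaries(
        d1=d1, d2=d2, y_norm2=float(y2 @ y2), wy_norm2=float(wy @ wy), m2=m2, n_hat=n_hat
    )
    tau2, sig2 = _estimate_from_summaries(s, formula)
    if tau2 + sig2 == 0.0:
        # degenerate corner (e.g. y2 = 0): variances are zero, ratio undefined
        h2_raw, h2, clipped = float("nan"), float("nan"), False
    else:
        h2_raw, h2, clipped = h2_ratio(tau2, sig2)
    return FixedVarianceEstimate(
        tau2_hat=tau2,
        sigma_e2_hat=sig2,
        h2=h2,
        h2_raw=h2_raw,
        se=None,
        clipped=clipped,
        d1=d1,
        d2=d2,
        m2=m2,
        n_hat=n_hat,
        formula=formula,
    )


def h2_point(tau2_hat: float, sigma_e2_hat: float) -> tuple[float, float, bool]:
    """(h2_raw, h2 clipped into [0.0001, 0.9999], clipped flag)."""
    return h2_ratio(tau2_hat, sigma_e2_hat)


def fixed_se(
    y2: np.ndarray,
    W2: np.ndarray,
    n_boot: int = 200,
    seed=0,
    formula: str = "reference",
) -> float:
    """Bootstrap-over-individuals standard error of the clipped heritability.

    Each resample recomputes the moment estimator from the resampled Gram
    matrix; SE is the SD (ddof=1) of the bootstrap h2 values.  Deterministic
    given ``seed``.  Returns NaN with a warning if more than half the
    resamples are degenerate.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    y2 = np.asarray(y2, dtype=np.float64)
    W2 = np.asarray(W2, dtype=np.float64)
    m2, n_hat = W2.shape
    G = W2 @ W2.T
    rng = as_rng(seed)
    h2s = []
    n_bad = 0
    for _ in range(n_boot):
        idx = rng.integers(0, m2, size=m2) if n_boot > 1 else np.arange(m2)
        try:
            s = _summaries_from_gram(G[np.ix_(idx, idx)], y2[idx], n_hat)
            tau2, sig2 = _estimate_from_summaries(s, formula)
            _, h2, _ = h2_ratio(tau2, sig2)
            h2s.append(h2)
        except (DegenerateDesignError, ZeroDivisionError):
            n_bad += 1
    if n_bad > n_boot / 2:
        warnings.warn(
            f"{n_bad}/{n_boot} bootstrap resamples degenerate; SE unavailable",
            stacklevel=2,
        )
        return float("nan")
    if len(h2s) == 1:
        return 0.0
    return float(np.std(h2s, ddof=1))


class MomentVarianceEstimator(BaseEstimator):
    """Sklearn-style wrapper for the fixed-effect moment estimator.

    ``fit(W, y)`` expects the standardized genotypes of the estimation half
    restricted to the selected SNPs and a centered phenotype.  Fitted
    attributes: ``tau2_``, ``sigma_e2_``, ``h2_``, ``h2_raw_``, ``clipped_``,
    ``d1_``, ``d2_``, ``se_`` (None unless ``n_boot > 0``), ``estimate_``.
    """

    def __init__(self, formula="reference", n_boot=0, random_state=0):
        self.formula = formula
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, W, y):
        est = mom_estimate(y, W, formula=self.formula)
        if self.n_boot:
            est.se = fixed_se(
                y, W, n_boot=self.n_boot, seed=self.random_state, formula=self.formula
            )
        self.estimate_ = est
        self.tau2_ = est.tau2_hat
        self.sigma_e2_ = est.sigma_e2_hat
        self.h2_ = est.h2
        self.h2_raw_ = est.h2_raw
        self.clipped_ = est.clipped
        self.d1_ = est.d1
        self.d2_ = est.d2
        self.se_ = est.se
        self.n_features_in_ = np.asarray(W).shape[1]
        return self
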