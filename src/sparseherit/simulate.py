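"""Synthetic GWAS cohorts: genotypes under HWE with block LD, sparse effects.

The generator draws, per SNP, a true allele frequency from a uniform law on a
configurable MAF window, then produces two latent Gaussian haplotypes per
individual with AR(1) correlation inside blocks of consecutive SNPs; each
latent value is thresholded at the normal quantile of the allele frequency
and the two haplotypes are summed.  Marginals are therefore Binomial(2, p_j)
(Hardy-Weinberg) while adjacent SNPs within a block are correlated
(linkage-disequilibrium surrogate).  Effects are sparse: s uniformly chosen
indices carry i.i.d. N(0, 1/s) weights, so the expected total genetic
variance of the standardized design is 1 regardless of s.

No population structure, relatedness or selection pressure is emulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from ._utils import as_rng
from .io import GenotypeData


@dataclass(frozen=True)
class SimulationScenario:
    """Study conditions for one simulated cohort.

    Parameters
    ----------
    m, n, s
        Sample count, SNP count, and causal-SNP count (1 <= s <= n).
    sigma_e2
        Residual (noise) variance of the phenotype.
    maf_range
        Bounds of the uniform law for true allele frequencies, in (0, 0.5].
    ld_block_size, ld_rho
        SNPs per correlated block and the AR(1) latent correlation in [0, 1).
    seed
        Master seed; every draw is a pure function of it.
    """

    m: int
    n: int
    s: int
    sigma_e2: float = 1.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 100
    ld_rho: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.s <= self.n:
            raise ValueError(f"need 1 <= s <= n, got s={self.s}, n={self.n}")
        if self.m < 1:
            raise ValueError("m must be positive")
        if self.sigma_e2 <= 0:
            raise ValueError("sigma_e2 must be > 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must be ordered within (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")


@dataclass
class TrueModel:
    """Simulation ground truth: effect vector, support, and noise level."""

    u_star: np.ndarray
    M0: np.ndarray
    s: int
    sigma_u2: float
    sigma_e2: float | None = None
    h_tilde: float | None = None

    def __post_init__(self):
        support = np.flatnonzero(self.u_star)
        if not np.array_equal(np.sort(support), np.sort(self.M0)):
            raise ValueError("supp(u_star) must equal M0 exactly")
        if len(self.M0) != self.s:
            raise ValueError("|M0| must equal s")


def simulate_genotypes(scenario: SimulationScenario, rng=None) -> GenotypeData:
    """Draw an m x n {0,1,2} genotype matrix under HWE with block-AR(1) LD.

    Deterministic given ``scenario.seed`` (or an explicit ``rng``).
    """
    rng = as_rng(scenario.seed if rng is None else rng)
    m, n = scenario.m, scenario.n
    lo, hi = scenario.maf_range
    p = rng.uniform(lo, hi, size=n)
    thresh = norm.ppf(p)  # latent < thresh  <=>  allele present, prob p
    rho = scenario.ld_rho
    innov = np.sqrt(1.0 - rho * rho)

    Z = np.empty((m, n), dtype=np.int8)
    for start in range(0, n, scenario.ld_block_size):
        stop = min(start + scenario.ld_block_size, n)
        width = stop - start
        eps = rng.standard_normal((2, m, width))
        z = np.empty_like(eps)
        z[:, :, 0] = eps[:, :, 0]
        for j in range(1, width):
            z[:, :, j] = rho * z[:, :, j - 1] + innov * eps[:, :, j]
        alleles = (z < thresh[start:stop]).astype(np.int8)
        Z[:, start:stop] = alleles[0] + alleles[1]

    n_dig = max(4, len(str(n)))
    m_dig = max(4, len(str(m)))
    return GenotypeData(
        Z=Z,
        snp_ids=np.array([f"snp{j + 1:0{n_dig}d}" for j in range(n)]),
        chrom=np.array(["1"] * n),
        pos=np.arange(1, n + 1),
        a1=np.array(["A"] * n),
        a2=np.array(["B"] * n),
        sample_ids=np.array([f"ind{i + 1:0{m_dig}d}" for i in range(m)]),
        p=None,
        W=None,
    )


def simulate_effects(n: int, s: int, seed) -> TrueModel:
    """Sparse effect vector: s uniform indices with i.i.d. N(0, 1/s) weights."""
    if not 1 <= s <= n:
        raise ValueError(f"need 1 <= s <= n, got s={s}, n={n}")
    rng = as_rng(seed)
    M0 = np.sort(rng.choice(n, size=s, replace=False))
    u = np.zeros(n)
    sigma_u2 = 1.0 / s
    # resample any exact zero so supp(u*) = M0 holds with certainty
    vals = rng.normal(0.0, np.sqrt(sigma_u2), size=s)
    while (vals == 0.0).any():  # pragma: no cover - probability zero
        vals[vals == 0.0] = rng.normal(0.0, np.sqrt(sigma_u2), size=(vals == 0.0).sum())
    u[M0] = vals
    return TrueModel(u_star=u, M0=M0, s=s, sigma_u2=sigma_u2)


def simulate_phenotype(W: np.ndarray, true_model: TrueModel, seed) -> np.ndarray:
    """y = W u* + e with e ~ N(0, sigma_e2 I); deterministic given seed."""
    W = np.asarray(W)
    if W.shape[1] != len(true_model.u_star):
        raise ValueError(
            f"W has {W.shape[1]} columns but u_star has length {len(true_model.u_star)}"
        )
    if true_model.sigma_e2 is None:
        raise ValueError("true_model.sigma_e2 is unset")
    rng = as_rng(seed)
    e = rng.normal(0.0, np.sqrt(true_model.sigma_e2), size=W.shape[0])
    return W @ true_model.u_star + e


def approx_true_h2(W: np.ndarray, u_star: np.ndarray, sigma_e2: float) -> float:
    """Realized-variance approximation of heritability.

    h~* = (||W u*||^2 / m) / (||W u*||^2 / m + sigma_e2): the sample genetic
    variance of this cohort over the total.  Lies in [0, 1).
    """
    if sigma_e2 <= 0:
        raise ValueError("sigma_e2 must be > 0")
    g = np.asarray(W) @ np.asarray(u_star)
    vg = float(g @ g) / W.shape[0]
    return vg / (vg + sigma_e2)


def simulate_dataset(scenario: SimulationScenario):
    """Full cohort: standardized genotypes, ground truth and phenotype.

    Spawns three independent substreams (genotypes, effects, noise) from the
    scenario seed so components are individually reproducible.

    Returns
    -------
    (GenotypeData with W, TrueModel with sigma_e2 and h_tilde, y)
    """
    from .io import standardize

    ss_geno, ss_eff, ss_noise = np.random.SeedSequence(scenario.seed).spawn(3)
    data = simulate_genotypes(scenario, rng=np.random.default_rng(ss_geno))
    data = standardize(data)
    truth = simulate_effects(scenario.n, scenario.s, ss_eff)
    truth.sigma_e2 = scenario.sigma_e2
    y = simulate_phenotype(data.W, truth, ss_noise)
    truth.h_tilde = approx_true_h2(data.W, truth.u_star, scenario.sigma_e2)
    return data, truth, y
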