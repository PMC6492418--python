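"""Genotype I/O, quality control and standardization.

Reads and writes PLINK 1 binary triplets (.bed/.bim/.fam), applies the usual
per-SNP quality-control filters (call rate, minor allele frequency,
Hardy-Weinberg exact test), and builds the standardized design matrix

    W_ij = (Z_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)),

where Z counts copies of the .bim A1 allele and p_j is its sample frequency.
Missing genotypes become 0 on the standardized scale (mean imputation, the
GCTA convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import FormatError, SparseHeritError

#: sentinel for a missing genotype call in Z
MISSING = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_SNP_MAJOR = 0x01

# PLINK 1 two-bit codes (within-byte, little-endian pairs):
#   00 -> homozygous A1 (2 copies), 01 -> missing, 10 -> het, 11 -> homozygous A2
_CODE_TO_COUNT = np.array([2, MISSING, 1, 0], dtype=np.int8)
_COUNT_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


@dataclass
class GenotypeData:
    """An m x n genotype panel with per-SNP metadata.

    ``Z`` holds allele counts in {0, 1, 2} with :data:`MISSING` for no-calls;
    ``p`` and ``W`` are filled in by :func:`standardize`.
    """

    Z: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    sample_ids: np.ndarray
    p: np.ndarray | None = None
    W: np.ndarray | None = None

    def __post_init__(self):
        self.Z = np.asarray(self.Z)
        valid = np.isin(self.Z, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.asarray(self.Z)[~valid][0]
            raise ValueError(f"genotype entries must be 0/1/2 or missing, got {bad}")
        if self.Z.shape[1] != len(self.snp_ids):
            raise ValueError("Z column count does not match SNP metadata")
        if self.Z.shape[0] != len(self.sample_ids):
            raise ValueError("Z row count does not match sample metadata")

    @property
    def m(self) -> int:
        return self.Z.shape[0]

    @property
    def n(self) -> int:
        return self.Z.shape[1]

    def subset_snps(self, idx: np.ndarray) -> "GenotypeData":
        return GenotypeData(
            Z=self.Z[:, idx],
            snp_ids=self.snp_ids[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            a1=self.a1[idx],
            a2=self.a2[idx],
            sample_ids=self.sample_ids,
            p=None if self.p is None else self.p[idx],
            W=None if self.W is None else self.W[:, idx],
        )


@dataclass(frozen=True)
class QCThresholds:
    """Per-SNP inclusion thresholds: call rate, MAF and HWE exact-test p."""

    min_call_rate: float = 0.99
    min_maf: float = 0.01
    min_hwe_p: float = 1e-6

    def __post_init__(self):
        for name in ("min_call_rate", "min_maf", "min_hwe_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


# ---------------------------------------------------------------------------
# PLINK binary triplet
# ---------------------------------------------------------------------------

def write_plink(data: GenotypeData, prefix: str | Path) -> None:
    """Write a .bed/.bim/.fam triplet (SNP-major, v1.00 magic)."""
    prefix = Path(prefix)
    m, n = data.m, data.n
    Z = np.asarray(data.Z, dtype=np.int8)

    codes = np.empty_like(Z, dtype=np.uint8)
    for count, code in _COUNT_TO_CODE.items():
        codes[Z == count] = code
    n_bytes = (m + 3) // 4
    padded = np.zeros((n, 4 * n_bytes), dtype=np.uint8)
    # code 0b00 pads: spare high bits of the trailing byte are zero per spec
    padded[:, :m] = codes.T
    shifts = np.tile([0, 2, 4, 6], n_bytes)
    packed = np.bitwise_or.reduce(
        (padded << shifts).reshape(n, n_bytes, 4), axis=2
    ).astype(np.uint8)

    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_BED_SNP_MAJOR]))
        fh.write(packed.tobytes())

    bim = pd.DataFrame(
        {
            "chrom": data.chrom,
            "snp": data.snp_ids,
            "cm": np.zeros(n),
            "pos": data.pos,
            "a1": data.a1,
            "a2": data.a2,
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": data.sample_ids,
            "iid": data.sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix: str | Path) -> GenotypeData:
    """Read a .bed/.bim/.fam triplet into a :class:`GenotypeData`.

    Z counts the .bim A1 allele.  Rejects files without the v1.00 magic or
    in sample-major mode.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    m, n = len(fam), len(bim)

    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise FormatError(
            f"{prefix.with_suffix('.bed')}: bad magic bytes at offset 0: "
            f"{raw[:2].hex() if raw else '<empty>'}"
        )
    if raw[2] != _BED_SNP_MAJOR:
        raise FormatError(
            f"{prefix.with_suffix('.bed')}: sample-major mode (byte at offset 2 "
            f"is 0x{raw[2]:02x}); only SNP-major is supported"
        )
    n_bytes = (m + 3) // 4
    expected = 3 + n * n_bytes
    if len(raw) != expected:
        raise FormatError(
            f"{prefix.with_suffix('.bed')}: expected {expected} bytes for "
            f"{m} samples x {n} SNPs, found {len(raw)} (truncated at offset {len(raw)})"
        )

    packed = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(n, n_bytes)
    codes = np.empty((n, 4 * n_bytes), dtype=np.uint8)
    for k, shift in enumerate((0, 2, 4, 6)):
        codes[:, k::4] = (packed >> shift) & 0b11
    Z = _CODE_TO_COUNT[codes[:, :m]].T.copy()

    return GenotypeData(
        Z=Z,
        snp_ids=bim["snp"].to_numpy(),
        chrom=bim["chrom"].to_numpy(),
        pos=bim["pos"].to_numpy(),
        a1=bim["a1"].to_numpy(),
        a2=bim["a2"].to_numpy(),
        sample_ids=fam["iid"].to_numpy(),
    )


def read_phenotype(path: str | Path, sample_ids: np.ndarray | None = None) -> np.ndarray:
    """Read a whitespace-delimited FID IID VALUE phenotype file.

    Tolerates a header line; if ``sample_ids`` is given the values are
    reordered to match it (error on missing individuals).
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected at least 3 columns (FID IID VALUE)")
    # drop a header row if the value column is not numeric
    try:
        float(df.iloc[0, 2])
    except ValueError:
        df = df.iloc[1:]
    iid = df.iloc[:, 1].to_numpy()
    y = df.iloc[:, 2].astype(float).to_numpy()
    if sample_ids is None:
        return y
    lookup = dict(zip(iid, y))
    missing = [s for s in sample_ids if s not in lookup]
    if missing:
        raise SparseHeritError(f"phenotype file lacks {len(missing)} samples, e.g. {missing[0]}")
    return np.array([lookup[s] for s in sample_ids])


def write_phenotype(y: np.ndarray, sample_ids: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"fid": sample_ids, "iid": sample_ids, "value": y}).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_covariates(path: str | Path, sample_ids: np.ndarray | None = None) -> np.ndarray:
    """Read FID IID C1..Cq covariates; returns an m x q float matrix."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected at least 3 columns (FID IID C1..)")
    try:
        df.iloc[0, 2:].astype(float)
    except ValueError:
        df = df.iloc[1:]
    iid = df.iloc[:, 1].to_numpy()
    C = df.iloc[:, 2:].astype(float).to_numpy()
    if sample_ids is None:
        return C
    order = {s: k for k, s in enumerate(iid)}
    missing = [s for s in sample_ids if s not in order]
    if missing:
        raise SparseHeritError(f"covariate file lacks {len(missing)} samples, e.g. {missing[0]}")
    return C[[order[s] for s in sample_ids]]


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Hardy-Weinberg exact-test p-value (Wigginton et al. style, non-mid).

    Full enumeration of heterozygote counts conditional on the allele counts;
    p is the summed probability of configurations no more likely than the
    observed one.
    """
    n_het, n_hom1, n_hom2 = int(n_het), int(n_hom1), int(n_hom2)
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    rare = 2 * min(n_hom1, n_hom2) + n_het
    genotypes = n_het + n_hom1 + n_hom2
    if genotypes == 0:
        return 1.0

    # recurrence over possible heterozygote counts (same parity as rare)
    n_h = np.arange(rare % 2, rare + 1, 2)
    probs = np.zeros(len(n_h))
    # start from the mode-ish midpoint for numerical stability
    mid = rare * (2 * genotypes - rare) // (2 * genotypes)
    if mid % 2 != rare % 2:
        mid += 1
    k_mid = int(np.searchsorted(n_h, mid))
    probs[k_mid] = 1.0
    for k in range(k_mid, 0, -1):  # going down in het count
        het = n_h[k]
        hom_r = (rare - het) // 2
        hom_c = genotypes - het - hom_r
        probs[k - 1] = probs[k] * het * (het - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
    for k in range(k_mid, len(n_h) - 1):  # going up
        het = n_h[k]
        hom_r = (rare - het) // 2
        hom_c = genotypes - het - hom_r
        probs[k + 1] = probs[k] * 4.0 * hom_r * hom_c / ((het + 2.0) * (het + 1.0))
    probs /= probs.sum()
    p_obs = probs[int(np.searchsorted(n_h, n_het))]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def allele_freq(Z: np.ndarray) -> np.ndarray:
    """Per-SNP A1 allele frequency over non-missing calls."""
    Zm = np.ma.masked_equal(Z, MISSING)
    return np.asarray(Zm.mean(axis=0) / 2.0)


def qc_filter(
    data: GenotypeData, thresholds: QCThresholds = QCThresholds()
) -> tuple[GenotypeData, dict]:
    """Filter SNPs by call rate, MAF and HWE exact p.

    Returns the filtered panel plus a log of per-criterion exclusion counts.
    A SNP failing several criteria is counted under each.
    """
    Z = np.asarray(data.Z)
    m = Z.shape[0]
    n_missing = (Z == MISSING).sum(axis=0)
    call_rate = 1.0 - n_missing / m
    p = allele_freq(Z)
    maf = np.minimum(p, 1.0 - p)
    hwe_p = np.array(
        [
            hwe_exact_p(
                int((Z[:, j] == 1).sum()),
                int((Z[:, j] == 2).sum()),
                int((Z[:, j] == 0).sum()),
            )
            for j in range(Z.shape[1])
        ]
    )
    keep = (
        (call_rate >= thresholds.min_call_rate)
        & (maf >= thresholds.min_maf)
        & (hwe_p >= thresholds.min_hwe_p)
    )
    log = {
        "n_input": int(Z.shape[1]),
        "fail_call_rate": int((call_rate < thresholds.min_call_rate).sum()),
        "fail_maf": int((maf < thresholds.min_maf).sum()),
        "fail_hwe": int((hwe_p < thresholds.min_hwe_p).sum()),
        "n_retained": int(keep.sum()),
    }
    if not keep.any():
        raise SparseHeritError("QC removed every SNP; empty panel")
    return data.subset_snps(np.flatnonzero(keep)), log


# ---------------------------------------------------------------------------
# Standardization and covariate projection
# ---------------------------------------------------------------------------

def standardize(data: GenotypeData) -> GenotypeData:
    """Attach the standardized design matrix W (sample allele frequencies).

    W_ij = (Z_ij - 2 p_j) / sqrt(2 p_j (1-p_j)); missing cells are set to 0
    after standardization.  Monomorphic SNPs (p in {0, 1}) are an error.
    """
    Z = np.asarray(data.Z)
    p = allele_freq(Z)
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        j = int(np.flatnonzero(mono)[0])
        raise SparseHeritError(
            f"monomorphic SNP {data.snp_ids[j]!r} (p={p[j]:.3f}): "
            "standardization would divide by zero"
        )
    W = (Z.astype(np.float64) - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    W[Z == MISSING] = 0.0
    return replace(data, p=p, W=W)


def project_covariates(
    y: np.ndarray, W: np.ndarray | None, C: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray | None, int]:
    """Project nuisance covariates out of y (and optionally each column of W).

    Returns residualized ``(y_res, W_res, m_eff)`` with ``m_eff = m - q`` for
    downstream degrees-of-freedom accounting.  ``C`` may include an all-ones
    intercept column.  Rank-deficient C is an error; ``C=None``/``q=0`` is the
    identity.
    """
    y = np.asarray(y, dtype=np.float64)
    m = y.shape[0]
    if C is None or (hasattr(C, "shape") and np.size(C) == 0):
        return y, W, m
    C = np.atleast_2d(np.asarray(C, dtype=np.float64))
    if C.shape[0] != m:
        C = C.T
    q = C.shape[1]
    if q >= m:
        raise SparseHeritError(f"covariate count q={q} must be < m={m}")
    Q, R = np.linalg.qr(C)
    diag = np.abs(np.diag(R))
    if diag.min() <= 1e-10 * max(1.0, diag.max()):
        raise SparseHeritError("covariate matrix is rank deficient")
    y_res = y - Q @ (Q.T @ y)
    W_res = None if W is None else W - Q @ (Q.T @ W)
    return y_res, W_res, m - q
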