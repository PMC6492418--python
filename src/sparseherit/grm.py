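"""Genetic relationship matrix construction and GCTA binary-dialect I/O.

K = (1/n_hat) W W' over standardized genotypes; for interoperability the
matrix round-trips through the GCTA file triple (``<prefix>.grm.bin``
lower-triangle float32, ``<prefix>.grm.N.bin`` per-pair SNP counts,
``<prefix>.grm.id`` two-column text).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import FormatError, SparseHeritError


@dataclass
class GRM:
    """Relationship matrix with its provenance."""

    K: np.ndarray
    n_snps: int
    sample_ids: np.ndarray

    def __post_init__(self):
        K = np.asarray(self.K)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("K must be square")
        if len(self.sample_ids) != K.shape[0]:
            raise ValueError("sample_ids length must match K")


def build_grm(W2: np.ndarray, sample_ids: np.ndarray | None = None) -> GRM:
    """K = (1/n_hat) W2 W2' from an m2 x n_hat standardized matrix."""
    W2 = np.asarray(W2, dtype=np.float64)
    if W2.ndim == 1:
        W2 = W2[:, None]
    m2, n_hat = W2.shape
    if n_hat == 0:
        raise SparseHeritError("cannot build a GRM from zero SNPs")
    if sample_ids is None:
        sample_ids = np.array([f"s{i + 1}" for i in range(m2)])
    K = (W2 @ W2.T) / n_hat
    return GRM(K=K, n_snps=n_hat, sample_ids=np.asarray(sample_ids))


def _tril_indices(m: int):
    return np.tril_indices(m)


def write_grm(grm: GRM, prefix: str | Path) -> None:
    """Write the GCTA triple: grm.bin / grm.N.bin (float32) and grm.id."""
    prefix = Path(prefix)
    m = grm.K.shape[0]
    rows, cols = _tril_indices(m)
    vals = grm.K[rows, cols].astype("<f4")
    Path(f"{prefix}.grm.bin").write_bytes(vals.tobytes())
    counts = np.full(vals.shape, grm.n_snps, dtype="<f4")
    Path(f"{prefix}.grm.N.bin").write_bytes(counts.tobytes())
    pd.DataFrame({"fid": grm.sample_ids, "iid": grm.sample_ids}).to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False
    )


def read_grm(prefix: str | Path) -> GRM:
    """Read a GCTA GRM triple back into a symmetric dense matrix."""
    prefix = Path(prefix)
    ids = pd.read_csv(
        f"{prefix}.grm.id", sep=r"\s+", header=None, names=["fid", "iid"], dtype=str
    )
    m = len(ids)
    n_pairs = m * (m + 1) // 2
    vals = np.frombuffer(Path(f"{prefix}.grm.bin").read_bytes(), dtype="<f4")
    if vals.size != n_pairs:
        raise FormatError(
            f"{prefix}.grm.bin holds {vals.size} float32 values, expected {n_pairs} "
            f"for {m} samples"
        )
    counts = np.frombuffer(Path(f"{prefix}.grm.N.bin").read_bytes(), dtype="<f4")
    if counts.size != n_pairs:
        raise FormatError(f"{prefix}.grm.N.bin length mismatch")
    K = np.zeros((m, m))
    rows, cols = _tril_indices(m)
    K[rows, cols] = vals
    K[cols, rows] = vals
    n_snps = int(round(float(counts[0])))
    return GRM(K=K, n_snps=n_snps, sample_ids=ids["iid"].to_numpy())
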