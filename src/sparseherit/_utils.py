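"""Shared small helpers: heritability clipping, error types, seed handling."""

from __future__ import annotations

import numpy as np

#: Estimates whose raw variance ratio falls outside (0, 1) are pinned to these
#: boundary sentinels so downstream reports never contain impossible values.
CLIP_LO = 0.0001
CLIP_HI = 0.9999


class SparseHeritError(Exception):
    """Base class for all package errors."""


class FormatError(SparseHeritError):
    """Malformed on-disk genotype/GRM data."""


class DegenerateDesignError(SparseHeritError):
    """Design matrix too degenerate for the requested estimator."""


class NonIdentifiableError(SparseHeritError):
    """Variance components not separable (e.g. GRM proportional to identity)."""


class ConvergenceError(SparseHeritError):
    """An iterative solver failed to reach its tolerance."""


def clip_h2(h2_raw: float) -> tuple[float, float, bool]:
    """Clip a raw heritability ratio into [CLIP_LO, CLIP_HI].

    Returns ``(h2_raw, h2, clipped)``.  Values at or beyond the open
    interval (0, 1) are mapped to the boundary sentinels; anything strictly
    inside passes through unchanged.
    """
    if not np.isfinite(h2_raw):
        raise ValueError(f"non-finite heritability ratio: {h2_raw}")
    if h2_raw <= 0.0:
        return h2_raw, CLIP_LO, True
    if h2_raw >= 1.0:
        return h2_raw, CLIP_HI, True
    return h2_raw, float(h2_raw), False


def h2_ratio(var_g: float, var_e: float) -> tuple[float, float, bool]:
    """Heritability point estimate var_g / (var_g + var_e) with clipping."""
    total = var_g + var_e
    if total == 0.0:
        raise ZeroDivisionError("var_g + var_e is zero; heritability undefined")
    return clip_h2(var_g / total)


def spawn_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    """Derive ``n`` independent child seed sequences from one master seed."""
    return np.random.SeedSequence(seed).spawn(n)


def as_rng(seed) -> np.random.Generator:
    """Accept an int, SeedSequence or Generator and return a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
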