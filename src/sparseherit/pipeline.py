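"""End-to-end two-stage heritability estimation and the replicate harness.

Stage 1 (cross-validated elastic-net selection) runs on a random half of the
sample; stage 2 (method-of-moments and GREML variance estimation) runs on
the other, independent half restricted to the selected SNPs.  Estimating on
samples independent of selection is what keeps the estimator from inheriting
the optimism of the selection step.

The harness replays the canonical simulation scenario grids (noise levels,
sample sizes, SNP counts, sparsity levels) over seeded replicates and
summarizes each estimator variant with mean, SD and quartiles.  Variants:

* ``two_stage`` — selection on half 1, estimation on half 2;
* ``full``      — no selection, all SNPs estimated on half 2;
* ``oracle``    — the true support M0 supplied, estimation on half 2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import __version__
from ._utils import CLIP_LO, SparseHeritError
from .grm import build_grm
from .io import GenotypeData
from .moments import FixedVarianceEstimate, MomentVarianceEstimator
from .reml import GREMLVarianceEstimator, RandomVarianceEstimate
from .selection import ElasticNetSelector, SplitPlan, split_sample
from .simulate import SimulationScenario, TrueModel, simulate_dataset

SCHEMA_VERSION = 1

#: required keys of a serialized experiment summary (the shipped schema)
SUMMARY_SCHEMA = {
    "schema_version": int,
    "scenario": dict,
    "n_replicates": int,
    "variants": list,
    "summary": list,
}


@dataclass
class HeritabilityReport:
    """Complete record of one two-stage run."""

    m: int
    n: int
    half1: np.ndarray
    half2: np.ndarray
    alpha: float | None
    lambda_: float | None
    n_hat: int
    empty_selection: bool
    fixed: FixedVarianceEstimate | None
    random: RandomVarianceEstimate | None
    h2_fixed: float
    h2_random: float
    provenance: dict

    def to_dict(self) -> dict:
        d = {
            "m": self.m,
            "n": self.n,
            "half1": np.asarray(self.half1).tolist(),
            "half2": np.asarray(self.half2).tolist(),
            "alpha": self.alpha,
            "lambda": self.lambda_,
            "n_hat": self.n_hat,
            "empty_selection": self.empty_selection,
            "h2_fixed": self.h2_fixed,
            "h2_random": self.h2_random,
            "fixed": None,
            "random": None,
            "provenance": self.provenance,
        }
        if self.fixed is not None:
            d["fixed"] = {
                "tau2_hat": self.fixed.tau2_hat,
                "sigma_e2_hat": self.fixed.sigma_e2_hat,
                "h2": self.fixed.h2,
                "h2_raw": self.fixed.h2_raw,
                "se": self.fixed.se,
                "clipped": self.fixed.clipped,
                "d1": self.fixed.d1,
                "d2": self.fixed.d2,
            }
        if self.random is not None:
            d["random"] = {
                "sigma_g2": self.random.sigma_g2,
                "sigma_e2": self.random.sigma_e2,
                "h2": self.random.h2,
                "h2_raw": self.random.h2_raw,
                "se": self.random.se,
                "loglik": self.random.loglik,
                "converged": self.random.converged,
            }
        return d


class TwoStageHeritability(BaseEstimator):
    """Two-stage SNP-heritability estimator (sklearn-style).

    ``fit(W, y)`` takes the full standardized design matrix and phenotype,
    splits the sample, selects SNPs on half 1 and estimates both variance
    branches on half 2.  The phenotype is centered separately within each
    half; project covariates out beforehand with
    :func:`sparseherit.io.project_covariates`.

    Fitted attributes: ``report_``, ``h2_fixed_``, ``h2_random_``,
    ``support_``, ``n_selected_``.

    ``estimation_half="training"`` is a diagnostic hook that estimates on
    the same half used for selection — the anti-pattern whose overestimation
    motivates the independent split; never use it for reporting.
    """

    def __init__(
        self,
        alpha_grid=(0.001, 0.01, 0.1, 0.5, 1.0),
        n_lambda=100,
        lambda_min_ratio=1e-4,
        n_folds=10,
        one_se_direction="sparse",
        precision="single",
        formula="reference",
        n_boot=0,
        grid_size=64,
        random_state=0,
        estimation_half="independent",
    ):
        self.alpha_grid = alpha_grid
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.n_folds = n_folds
        self.one_se_direction = one_se_direction
        self.precision = precision
        self.formula = formula
        self.n_boot = n_boot
        self.grid_size = grid_size
        self.random_state = random_state
        self.estimation_half = estimation_half

    def fit(self, W, y):
        W = np.asarray(W)
        y = np.asarray(y, dtype=np.float64)
        m = y.shape[0]
        split_seed, cv_seed, boot_seed = _derive_seeds(self.random_state, 3)
        plan = split_sample(m, split_seed)
        assert np.intersect1d(plan.half1, plan.half2).size == 0

        idx1 = plan.half1
        y1 = y[idx1] - y[idx1].mean()
        selector = ElasticNetSelector(
            alpha_grid=self.alpha_grid,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            n_folds=self.n_folds,
            one_se_direction=self.one_se_direction,
            precision=self.precision,
            random_state=cv_seed,
        ).fit(W[idx1], y1)

        idx_est = plan.half1 if self.estimation_half == "training" else plan.half2
        fixed, rand_, h2f, h2r = _estimate_branches(
            W,
            y,
            idx_est,
            selector.support_,
            formula=self.formula,
            grid_size=self.grid_size,
            n_boot=self.n_boot,
            boot_seed=boot_seed,
        )

        self.report_ = HeritabilityReport(
            m=m,
            n=W.shape[1],
            half1=plan.half1,
            half2=plan.half2,
            alpha=selector.alpha_,
            lambda_=selector.lambda_,
            n_hat=selector.n_selected_,
            empty_selection=selector.empty_,
            fixed=fixed,
            random=rand_,
            h2_fixed=h2f,
            h2_random=h2r,
            provenance={
                "version": __version__,
                "seed": self.random_state,
                "params": self.get_params(),
                "estimation_half": self.estimation_half,
            },
        )
        self.h2_fixed_ = h2f
        self.h2_random_ = h2r
        self.support_ = selector.support_
        self.n_selected_ = selector.n_selected_
        self.selector_ = selector
        self.n_features_in_ = W.shape[1]
        return self


def _derive_seeds(seed: int, n: int) -> list[int]:
    """Stable child seeds (< 2^31) from one master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _estimate_branches(
    W, y, idx_est, support, *, formula, grid_size, n_boot, boot_seed
):
    """Run both stage-2 branches on the estimation half; handles empty support."""
    if len(support) == 0:
        return None, None, CLIP_LO, CLIP_LO
    y2 = y[idx_est] - y[idx_est].mean()
    W2 = W[np.asarray(idx_est)[:, None], np.asarray(support)[None, :]]
    mom = MomentVarianceEstimator(
        formula=formula, n_boot=n_boot, random_state=boot_seed
    ).fit(W2, y2)
    greml = GREMLVarianceEstimator(grid_size=grid_size).fit(W2, y2)
    return mom.estimate_, greml.estimate_, mom.h2_, greml.h2_


def run_two_stage(data, y, **params) -> HeritabilityReport:
    """Functional wrapper: two-stage estimation on a standardized panel.

    ``data`` may be a :class:`GenotypeData` carrying W or a bare matrix.
    """
    W = data.W if isinstance(data, GenotypeData) else np.asarray(data)
    if W is None:
        raise SparseHeritError("GenotypeData has no W; call standardize() first")
    return TwoStageHeritability(**params).fit(W, y).report_


def run_variant(
    data,
    y,
    variant: str,
    truth: TrueModel | None = None,
    seed: int = 0,
    selector_params: dict | None = None,
    formula: str = "reference",
    grid_size: int = 64,
    baseline_full_sample: bool = False,
) -> dict:
    """One estimator variant on one data set.

    ``full`` uses every SNP (no selection stage, same split and half-2
    estimation); ``oracle`` uses the true support M0; ``two_stage`` runs the
    whole strategy.  ``baseline_full_sample=True`` estimates the full/oracle
    baselines on the entire sample instead of half 2.
    """
    W = data.W if isinstance(data, GenotypeData) else np.asarray(data)
    y = np.asarray(y, dtype=np.float64)
    m = y.shape[0]

    if variant == "two_stage":
        est = TwoStageHeritability(
            **(selector_params or {}),
            formula=formula,
            grid_size=grid_size,
            random_state=seed,
        ).fit(W, y)
        rep = est.report_
        return {
            "variant": variant,
            "h_fixed": rep.h2_fixed,
            "h_rand": rep.h2_random,
            "n_hat": rep.n_hat,
            "clipped_fixed": rep.fixed.clipped if rep.fixed else True,
            "clipped_rand": rep.random.h2 != rep.random.h2_raw if rep.random else True,
            "alpha": rep.alpha,
            "lambda": rep.lambda_,
        }

    if variant == "oracle":
        if truth is None:
            raise SparseHeritError("oracle variant requires the true model")
        support = np.asarray(truth.M0)
    elif variant == "full":
        support = np.arange(W.shape[1])
    else:
        raise ValueError(f"unknown variant {variant!r}")

    split_seed, _, boot_seed = _derive_seeds(seed, 3)
    if baseline_full_sample:
        idx_est = np.arange(m)
    else:
        idx_est = split_sample(m, split_seed).half2
    fixed, rand_, h2f, h2r = _estimate_branches(
        W,
        y,
        idx_est,
        support,
        formula=formula,
        grid_size=grid_size,
        n_boot=0,
        boot_seed=boot_seed,
    )
    return {
        "variant": variant,
        "h_fixed": h2f,
        "h_rand": h2r,
        "n_hat": int(len(support)),
        "clipped_fixed": fixed.clipped if fixed else True,
        "clipped_rand": rand_.h2 != rand_.h2_raw if rand_ else True,
        "alpha": None,
        "lambda": None,
    }


@dataclass
class ExperimentResult:
    """Per-replicate estimates and their summary for one scenario."""

    scenario: SimulationScenario
    n_replicates: int
    variants: tuple[str, ...]
    table: pd.DataFrame
    summary: pd.DataFrame


def run_experiment(
    scenario: SimulationScenario,
    variants: tuple[str, ...] = ("two_stage", "full", "oracle"),
    n_replicates: int = 30,
    master_seed: int = 0,
    selector_params: dict | None = None,
    formula: str = "reference",
    grid_size: int = 64,
    baseline_full_sample: bool = False,
    max_failure_rate: float = 0.2,
) -> ExperimentResult:
    """Seeded replicate experiment over estimator variants.

    Each replicate gets an independent substream of ``master_seed`` for both
    data generation and estimation, so any single replicate can be
    reproduced in isolation.  Failed replicate-variant cells are recorded
    (``error`` column) rather than fatal, up to ``max_failure_rate``.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates for an SD")
    children = np.random.SeedSequence(master_seed).spawn(n_replicates)
    rows = []
    for r, child in enumerate(children):
        data_seed, est_seed = [int(s) for s in child.generate_state(2) % (2**31)]
        scen_r = replace(scenario, seed=data_seed)
        data, truth, y = simulate_dataset(scen_r)
        for variant in variants:
            row = {"replicate": r, "h_tilde": truth.h_tilde, "error": ""}
            try:
                row.update(
                    run_variant(
                        data,
                        y,
                        variant,
                        truth=truth,
                        seed=est_seed,
                        selector_params=selector_params,
                        formula=formula,
                        grid_size=grid_size,
                        baseline_full_sample=baseline_full_sample,
                    )
                )
            except SparseHeritError as exc:  # recorded, not fatal
                row.update(
                    {
                        "variant": variant,
                        "h_fixed": np.nan,
                        "h_rand": np.nan,
                        "n_hat": 0,
                        "clipped_fixed": False,
                        "clipped_rand": False,
                        "alpha": None,
                        "lambda": None,
                        "error": str(exc),
                    }
                )
            rows.append(row)
    table = pd.DataFrame(rows)
    n_failed = int((table["error"] != "").sum())
    if n_failed > max_failure_rate * len(table):
        raise SparseHeritError(
            f"{n_failed}/{len(table)} replicate cells failed (cap {max_failure_rate:.0%})"
        )
    summary = summarize_experiment(table)
    return ExperimentResult(
        scenario=scenario,
        n_replicates=n_replicates,
        variants=tuple(variants),
        table=table,
        summary=summary,
    )


def summarize_experiment(table: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD and quartiles per (variant, branch); whiskers = Q1/Q3."""
    ok = table[table["error"] == ""]
    recs = []
    for variant, grp in ok.groupby("variant", sort=False):
        for branch, col in (("fixed", "h_fixed"), ("rand", "h_rand")):
            v = grp[col].to_numpy(dtype=float)
            recs.append(
                {
                    "variant": variant,
                    "branch": branch,
                    "n": len(v),
                    "mean": float(np.mean(v)),
                    "sd": float(np.std(v, ddof=1)),
                    "q1": float(np.quantile(v, 0.25)),
                    "q3": float(np.quantile(v, 0.75)),
                }
            )
    v = ok.drop_duplicates("replicate")["h_tilde"].to_numpy(dtype=float)
    recs.append(
        {
            "variant": "approx",
            "branch": "truth",
            "n": len(v),
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            "q1": float(np.quantile(v, 0.25)),
            "q3": float(np.quantile(v, 0.75)),
        }
    )
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def write_report(result, prefix: str | Path) -> None:
    """Serialize a report or experiment: TSV table + JSON summary (+ log)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(result, HeritabilityReport):
        with open(f"{prefix}.json", "w") as fh:
            json.dump(result.to_dict(), fh, indent=2)
        return
    if not isinstance(result, ExperimentResult):
        raise TypeError(f"cannot serialize {type(result).__name__}")
    result.table.to_csv(f"{prefix}.tsv", sep="\t", index=False)
    payload = {
        "schema_version": SCHEMA_VERSION,
        "scenario": asdict(result.scenario),
        "n_replicates": result.n_replicates,
        "variants": list(result.variants),
        "summary": result.summary.to_dict(orient="records"),
    }
    validate_summary(payload)
    with open(f"{prefix}.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    with open(f"{prefix}.log", "w") as fh:
        n_failed = int((result.table["error"] != "").sum())
        fh.write(
            f"sparseherit {__version__}: {result.n_replicates} replicates, "
            f"variants={','.join(result.variants)}, failures={n_failed}\n"
        )


def validate_summary(payload: dict) -> None:
    """Check a serialized experiment summary against the shipped schema."""
    for key, typ in SUMMARY_SCHEMA.items():
        if key not in payload:
            raise SparseHeritError(f"summary JSON missing required key {key!r}")
        if not isinstance(payload[key], typ):
            raise SparseHeritError(
                f"summary key {key!r} has type {type(payload[key]).__name__}, "
                f"expected {typ.__name__}"
            )
    if payload["schema_version"] != SCHEMA_VERSION:
        raise SparseHeritError(f"unsupported schema version {payload['schema_version']}")


def read_experiment(prefix: str | Path) -> tuple[pd.DataFrame, dict]:
    """Round-trip reader for :func:`write_report` experiment output."""
    prefix = Path(prefix)
    table = pd.read_csv(f"{prefix}.tsv", sep="\t", keep_default_na=False)
    with open(f"{prefix}.json") as fh:
        payload = json.load(fh)
    validate_summary(payload)
    return table, payload


# ---------------------------------------------------------------------------
# Scenario presets (desk-scale versions of the published simulation grids)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentPreset:
    scenario: SimulationScenario
    variants: tuple[str, ...]
    selector_params: dict | None = None


#: selection settings for the desk-scale two-stage experiments: a two-point
#: alpha grid suited to sparse truths and a 40-point lambda path
_FAST_SELECTOR = {
    "alpha_grid": (0.5, 1.0),
    "n_lambda": 40,
    "lambda_min_ratio": 0.05,
    "n_folds": 10,
}


def _presets() -> dict[str, ExperimentPreset]:
    p: dict[str, ExperimentPreset] = {}
    # noise-level panel: dense truth, no selection stage
    for tag, s2 in (("", 1.0), ("_noise4", 4.0), ("_noise025", 0.25)):
        p[f"fig2a{tag}"] = ExperimentPreset(
            SimulationScenario(m=1000, n=10000, s=10000, sigma_e2=s2), ("full",)
        )
    for m in (300, 1000, 3000):
        p[f"fig2b_m{m}"] = ExperimentPreset(
            SimulationScenario(m=m, n=10000, s=10000), ("full",)
        )
    for n in (1000, 3000, 10000):
        p[f"fig2c_n{n}"] = ExperimentPreset(
            SimulationScenario(m=1000, n=n, s=n), ("full",)
        )
    for s in (100, 1000, 10000):
        p[f"fig2d_s{s}"] = ExperimentPreset(
            SimulationScenario(m=1000, n=10000, s=s), ("full", "oracle")
        )
    for tag, s in (("a", 10), ("b", 100), ("c", 1000), ("d", 10000)):
        p[f"fig3{tag}"] = ExperimentPreset(
            SimulationScenario(m=1000, n=100000, s=s),
            ("two_stage", "full", "oracle"),
            _FAST_SELECTOR,
        )
        p[f"fig3{tag}_scaled"] = ExperimentPreset(
            SimulationScenario(m=1000, n=10000, s=s),
            ("two_stage", "full", "oracle"),
            _FAST_SELECTOR,
        )
    return p


PRESETS = _presets()


def get_preset(name: str) -> ExperimentPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
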