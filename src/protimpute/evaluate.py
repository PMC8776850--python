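"""Performance measures (RMSE, NRMSE, SOR) and the benchmark harness.

RMSE and NRMSE are computed over the evaluation index set Omega — the
positions whose true values were hidden by injection or masking:

    RMSE  = sqrt( sum_Omega (Xhat - X)^2 / |Omega| )
    NRMSE = sqrt( sum_Omega (Xhat - X)^2 / (|Omega| * var(X_Omega)) )

with the *population* variance of the true values at Omega, so that filling
every entry with mean(X_Omega) gives NRMSE = 1 exactly. SOR sums, over the
proteins carrying missing values, each method's rank of protein-wise NRMSE
across the competing methods (rank 1 = best, ties averaged); it is only
comparable across methods within one report, not across missing rates.

The harness wires the full simulation workflow: generate or load data,
inject or mask missing values, run each imputer in its method-appropriate
space (see ``METHOD_SPACE``), map results back, and tabulate all three
measures per (method, rate, trial).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import baseline, cam, frmf, lowrank, simulate
from .core_data import (
    AbundanceMatrix,
    ExternalScores,
    GroundTruth,
    ImputationResult,
    IntensityMatrix,
)
from .preprocess import (
    destandardize_proteins,
    filter_by_missing_rate,
    log2_transform,
    standardize_proteins,
)

logger = logging.getLogger(__name__)

__all__ = [
    "rmse",
    "nrmse",
    "protein_nrmse",
    "sor",
    "BenchmarkConfig",
    "run_benchmark",
    "sweep_parameters",
    "METHOD_SPACE",
]


def _errors(truth: GroundTruth, result: ImputationResult) -> np.ndarray:
    if truth.space_tag != result.space_tag:
        raise ValueError(
            f"space mismatch: truth {truth.space_tag!r} vs result {result.space_tag!r}"
        )
    return result.at_omega(truth) - truth.true_values


def rmse(truth: GroundTruth, result: ImputationResult) -> float:
    """Root-mean-square error over Omega."""
    e = _errors(truth, result)
    return float(np.sqrt(np.mean(e**2)))


def nrmse(truth: GroundTruth, result: ImputationResult) -> float:
    """RMSE normalized by the population standard deviation of the true
    values at Omega."""
    if len(truth) < 2:
        raise ValueError("NRMSE needs |Omega| >= 2")
    var = float(np.var(truth.true_values))  # population variance
    if var == 0:
        raise ValueError("NRMSE undefined: zero variance at Omega")
    e = _errors(truth, result)
    return float(np.sqrt(np.mean(e**2) / var))


def protein_nrmse(truth: GroundTruth, result: ImputationResult) -> dict[int, float]:
    """Per-protein NRMSE over each protein's share of Omega.

    Proteins whose true values at Omega have zero population variance
    (including single-entry proteins) are excluded, with a log note; the
    exclusion depends only on the ground truth, so every method evaluated
    against the same truth sees the same protein subset.
    """
    e = _errors(truth, result)
    cols = truth.cols()
    out: dict[int, float] = {}
    skipped = 0
    for j in np.unique(cols):
        sel = cols == j
        vals = truth.true_values[sel]
        var = float(np.var(vals))
        if sel.sum() < 2 or var == 0:
            skipped += 1
            continue
        out[int(j)] = float(np.sqrt(np.mean(e[sel] ** 2) / var))
    if skipped:
        logger.debug("protein NRMSE: %d proteins excluded (variance guard)", skipped)
    return out


def sor(per_method: dict[str, dict[int, float]]) -> dict[str, float]:
    """Sum of ranks of protein-wise NRMSE across methods.

    For each protein, methods are ranked by NRMSE ascending (rank 1 best,
    ties averaged); SOR(method) is the sum of its ranks over the shared
    protein subset.
    """
    if len(per_method) < 2:
        raise ValueError("SOR needs at least two methods")
    keysets = [set(v.keys()) for v in per_method.values()]
    if any(ks != keysets[0] for ks in keysets[1:]):
        raise ValueError("protein subsets are misaligned across methods")
    proteins = sorted(keysets[0])
    methods = list(per_method)
    totals = {mth: 0.0 for mth in methods}
    for j in proteins:
        vals = np.array([per_method[mth][j] for mth in methods])
        ranks = rankdata(vals, method="average")
        for mth, r in zip(methods, ranks):
            totals[mth] += float(r)
    return totals


# ---------------------------------------------------------------------------
# benchmark harness

# which space each imputer runs in: "log" (log2 matrix as-is),
# "std" (protein-standardized log2, de-standardized afterwards),
# "intensity" (original scale; evaluated in intensity space)
METHOD_SPACE: dict[str, str] = {
    "Min/2": "log",
    "Mean": "log",
    "swKNN": "log",
    "pwKNN": "std",
    "PPCA": "std",
    "NIPALS": "std",
    "SVD": "std",
    "SVT": "std",
    "RMF": "std",
    "FRMF_self": "std",
    "FRMF_cross": "std",
    "CAM_complete": "intensity",
    "CAM_SVT": "intensity",
    "CAM_NIPALS": "intensity",
}


@dataclass
class BenchmarkConfig:
    """Configuration of one simulation benchmark run."""

    setting: int = 1
    mechanism: str = "MCAR"  # setting 1 only: MCAR | MNAR | MIX
    beta: float = 0.1  # MNAR proportion for MIX
    rates: tuple[float, ...] = (0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
    methods: tuple[tuple[str, dict], ...] = (("Mean", {}), ("Min/2", {}))
    trials: int = 1
    seed: int = 0
    # synthetic generator conditions
    m: int = 50
    n: int = 300
    k_archetypes: int = 3
    marker_fraction: float = 0.1
    noise_sigma: float = 0.3
    intensity_scale: float = 1e6
    # setting 2: how the authentic missingness is produced before masking
    authentic_alpha: float = 0.25
    authentic_beta: float = 0.5
    max_missing_rate: float = 0.8
    scores: ExternalScores | None = field(default=None, repr=False)

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkConfig":
        d = dict(d)
        if "methods" in d:
            d["methods"] = tuple(
                (mm["name"], dict(mm.get("params", {}))) if isinstance(mm, dict) else (mm, {})
                for mm in d["methods"]
            )
        if "rates" in d:
            d["rates"] = tuple(float(r) for r in d["rates"])
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _impute_one(
    name: str,
    params: dict,
    int_matrix: AbundanceMatrix,
    log_matrix: AbundanceMatrix,
    scores: ExternalScores | None,
    seed: int,
) -> tuple[np.ndarray, str]:
    """Run one method with its required preprocessing; return the completed
    grid in its evaluation space ("log2" or "intensity")."""
    space = METHOD_SPACE[name]
    if space == "log":
        if name == "Min/2":
            # halve on the intensity scale (fill = observed log2 min - 1)
            params.setdefault("halve_in", "intensity")
            return baseline.impute_min2(log_matrix, **params).completed, "log2"
        fn = {"Mean": baseline.impute_mean, "swKNN": baseline.impute_swknn}[name]
        return fn(log_matrix, **params).completed, "log2"
    if space == "std":
        std, scaling = standardize_proteins(log_matrix)
        if name == "pwKNN":
            res = baseline.impute_pwknn(std, **params)
            completed = res.completed
        elif name in {"PPCA", "NIPALS", "SVD", "SVT"}:
            fn = {
                "PPCA": lowrank.impute_ppca,
                "NIPALS": lowrank.impute_nipals,
                "SVD": lowrank.impute_svdimpute,
                "SVT": lowrank.impute_svt,
            }[name]
            if name == "PPCA":
                params = dict(params)
                params.setdefault("seed", seed)
            completed = fn(std, **params).completed
        elif name == "RMF":
            model = frmf.fit_rmf(std, seed=seed, **params)
            completed = frmf.impute_from_factors(std, model).completed
        elif name == "FRMF_self":
            params = dict(params)
            t = params.pop("t", 5)
            alpha = params.pop("alpha_fused", 1.0)
            ctx = frmf.build_similarity_self(std, t=t)
            model = frmf.fit_frmf(std, ctx, alpha, seed=seed, **params)
            completed = frmf.impute_from_factors(std, model).completed
        elif name == "FRMF_cross":
            if scores is None:
                raise ValueError("FRMF_cross needs external scores")
            params = dict(params)
            t = params.pop("t", 5)
            alpha = params.pop("alpha_fused", 1.0)
            ctx = frmf.build_similarity_external(scores, t=t)
            model = frmf.fit_frmf(std, ctx, alpha, seed=seed, **params)
            completed = frmf.impute_from_factors(std, model).completed
        else:
            raise ValueError(f"unknown method {name!r}")
        return destandardize_proteins(completed, scaling), "log2"
    if space == "intensity":
        if name == "CAM_complete":
            res = cam.cam_impute_complete(int_matrix, seed=seed, **params)
        else:
            init = "svt" if name == "CAM_SVT" else "nipals"
            res = cam.cam_impute_hybrid(int_matrix, initializer=init, seed=seed, **params)
        return res.completed, "intensity"
    raise ValueError(f"unknown method {name!r}")


def _cell_inputs(
    config: BenchmarkConfig, rate: float, trial_seed: int
) -> tuple[IntensityMatrix, GroundTruth]:
    truth = simulate.generate_synthetic(
        config.m,
        config.n,
        config.k_archetypes,
        config.marker_fraction,
        config.noise_sigma,
        config.intensity_scale,
        seed=trial_seed,
    )
    if config.setting == 1:
        if config.mechanism == "MCAR":
            return simulate.inject_mcar(truth.complete, rate, seed=trial_seed + 1)
        if config.mechanism == "MNAR":
            return simulate.inject_mnar(truth.complete, rate)
        return simulate.inject_mix(truth.complete, rate, config.beta, seed=trial_seed + 1)
    authentic, _ = simulate.inject_mix(
        truth.complete, config.authentic_alpha, config.authentic_beta, seed=trial_seed + 2
    )
    return simulate.mask_setting2(authentic, simulate.MaskSpec(rate, seed=trial_seed + 3))


def run_benchmark(config: BenchmarkConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full simulation benchmark.

    Returns (per-cell table, aggregate table). Each per-cell row holds one
    (method, rate, trial) with RMSE/NRMSE/SOR in that method's evaluation
    space; the aggregate table carries mean and sd over trials. Method
    failures are recorded (NaN metrics, error message) and the run
    continues.
    """
    rows: list[dict] = []
    for trial in range(config.trials):
        trial_seed = (config.seed + 7919 * trial) % (2**31 - 1)
        for rate in config.rates:
            injected, gt_int = _cell_inputs(config, rate, trial_seed)
            filtered, rep = filter_by_missing_rate(injected, config.max_missing_rate)
            gt_int = gt_int.restrict_to_proteins(rep.kept_indices)
            gt_log = GroundTruth(
                list(gt_int.omega), np.log2(gt_int.true_values), "log2"
            )
            log_matrix = log2_transform(filtered)
            per_space_pnrmse: dict[str, dict[str, dict[int, float]]] = {}
            cell_rows: list[dict] = []
            for name, params in config.methods:
                row = {
                    "setting": config.setting,
                    "mechanism": config.mechanism if config.setting == 1 else "authentic",
                    "rate": rate,
                    "trial": trial,
                    "seed": trial_seed,
                    "method": name,
                    "params": repr(params),
                    "n_omega": len(gt_int),
                }
                try:
                    completed, space = _impute_one(
                        name, dict(params), filtered, log_matrix, config.scores, trial_seed
                    )
                    gt = gt_log if space == "log2" else gt_int
                    result = ImputationResult(
                        completed, name, dict(params), filtered.missing, space
                    )
                    row["space"] = space
                    row["rmse"] = rmse(gt, result)
                    row["nrmse"] = nrmse(gt, result)
                    pn = protein_nrmse(gt, result)
                    per_space_pnrmse.setdefault(space, {})[name] = pn
                    row["sor"] = np.nan
                    row["error"] = ""
                except Exception as exc:  # noqa: BLE001 — harness must survive method failures
                    logger.warning("method %s failed at rate %.2f: %s", name, rate, exc)
                    row.update(space="", rmse=np.nan, nrmse=np.nan, sor=np.nan, error=str(exc))
                cell_rows.append(row)
            for space, group in per_space_pnrmse.items():
                if len(group) >= 2:
                    sor_vals = sor(group)
                    for row in cell_rows:
                        if row["method"] in sor_vals and row.get("space") == space:
                            row["sor"] = sor_vals[row["method"]]
            rows.extend(cell_rows)
    table = pd.DataFrame(rows)
    agg = (
        table.groupby(["setting", "mechanism", "rate", "method"], sort=False)
        .agg(
            nrmse_mean=("nrmse", "mean"),
            nrmse_sd=("nrmse", "std"),
            rmse_mean=("rmse", "mean"),
            rmse_sd=("rmse", "std"),
            sor_mean=("sor", "mean"),
            trials=("trial", "count"),
        )
        .reset_index()
    )
    return table, agg


def sweep_parameters(
    impute_fn: Callable[..., ImputationResult],
    grid: list[dict],
    matrix: AbundanceMatrix,
    truth: GroundTruth,
    criterion: Callable[[GroundTruth, ImputationResult], float] = nrmse,
) -> tuple[dict, pd.DataFrame]:
    """Evaluate every parameter combination on held-out ground truth.

    Returns the argmin of the criterion (first in grid order on ties,
    logged) and the full table."""
    if not grid:
        raise ValueError("empty parameter grid")
    scores = []
    for params in grid:
        result = impute_fn(matrix, **params)
        scores.append(criterion(truth, result))
    table = pd.DataFrame({"params": [dict(p) for p in grid], "score": scores})
    best_idx = int(np.argmin(scores))  # first minimum on ties
    if scores.count(scores[best_idx]) > 1:
        logger.info("parameter sweep tie: keeping first grid entry")
    return dict(grid[best_idx]), table
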