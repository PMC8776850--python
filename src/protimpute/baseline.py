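"""Simple reference imputers: Min/2, Mean, sample-wise and protein-wise KNN.

Min/2 targets left-censored (MNAR) missingness: a protein's missing values
are taken to lie below the detection limit and are filled with half the
protein's observed minimum. Mean is the classic MCAR baseline. The two KNN
variants exploit local similarity among samples (swKNN) or among proteins
(pwKNN), filling each missing entry with an inverse-distance-weighted
average of its nearest neighbours' observed values.
"""

from __future__ import annotations

import logging

import numpy as np

from .core_data import AbundanceMatrix, ImputationResult

logger = logging.getLogger(__name__)

__all__ = ["impute_min2", "impute_mean", "impute_swknn", "impute_pwknn"]

EPS_WEIGHT = 1e-9  # guard added to distances before inverting into weights


def _result(matrix: AbundanceMatrix, completed: np.ndarray, name: str, params: dict) -> ImputationResult:
    return ImputationResult(
        completed=completed,
        method_name=name,
        params=params,
        filled=matrix.missing.copy(),
        space_tag=matrix.space_tag,
    )


def _per_protein_fill(matrix: AbundanceMatrix, reducer, name: str) -> ImputationResult:
    vals = matrix.values
    miss = matrix.missing
    needs = np.where(miss.any(axis=0))[0]
    completed = vals.copy()
    for j in needs:
        obs = vals[~miss[:, j], j]
        if obs.size == 0:
            raise ValueError(
                f"cannot impute empty protein {matrix.protein_ids[j]!r}"
            )
        completed[miss[:, j], j] = reducer(obs)
    return _result(matrix, completed, name, {})


def impute_min2(matrix: AbundanceMatrix, halve_in: str = "stored") -> ImputationResult:
    """Fill each protein's missing entries with half its observed minimum.

    ``halve_in="stored"`` applies the rule to the values as stored (in log
    space a log-value of -1 fills as -0.5). ``halve_in="intensity"`` halves
    on the intensity scale: on a log2 matrix the fill is the observed
    minimum minus 1 (= log2 of half the minimum intensity), which is the
    behaviour intended for left-censored missingness; on an intensity
    matrix the two coincide.
    """
    if halve_in not in {"stored", "intensity"}:
        raise ValueError(f"unknown halve_in {halve_in!r}")
    if halve_in == "intensity" and matrix.space_tag == "log2":
        reducer = lambda obs: obs.min() - 1.0  # noqa: E731
    else:
        reducer = lambda obs: obs.min() / 2.0  # noqa: E731
    return _per_protein_fill(matrix, reducer, "Min/2")


def impute_mean(matrix: AbundanceMatrix) -> ImputationResult:
    """Fill each protein's missing entries with its observed mean."""
    return _per_protein_fill(matrix, lambda obs: obs.mean(), "Mean")


def _masked_distances(
    vals: np.ndarray, miss: np.ndarray, metric: str = "euclidean"
) -> np.ndarray:
    """Pairwise row distances over mutually observed columns; NaN where no
    columns are shared. Euclidean distances are scaled by 1/sqrt(shared
    count) so pairs with different overlaps are comparable; the
    "correlation" metric is 1 - Pearson r over the shared columns (needing
    >= 2 shared columns and nonzero variance)."""
    if metric not in {"euclidean", "correlation"}:
        raise ValueError(f"unknown metric {metric!r}")
    m = vals.shape[0]
    dist = np.full((m, m), np.nan)
    obs = ~miss
    for a in range(m):
        for b in range(a + 1, m):
            shared = obs[a] & obs[b]
            c = int(shared.sum())
            if c == 0:
                continue
            xa, xb = vals[a, shared], vals[b, shared]
            if metric == "euclidean":
                d = float(np.sqrt(np.sum((xa - xb) ** 2)) / np.sqrt(c))
            else:
                if c < 2:
                    continue
                sa, sb = xa.std(), xb.std()
                if sa == 0 or sb == 0:
                    continue
                r = float(np.mean((xa - xa.mean()) * (xb - xb.mean())) / (sa * sb))
                d = 1.0 - r
            dist[a, b] = dist[b, a] = d
    np.fill_diagonal(dist, np.nan)
    return dist


def _knn_fill_rows(
    vals: np.ndarray,
    miss: np.ndarray,
    k: int,
    fallback: str = "col",
    metric: str = "euclidean",
) -> np.ndarray:
    """KNN imputation treating rows as the units carrying similarity.

    For a missing (i, j): candidate rows observe column j and share at
    least one observed column with row i; the k nearest (ties to the
    smaller index) contribute a 1/(d+eps)-weighted average. Entries without
    candidates fall back to the observed mean of their column (``fallback=
    "col"``) or row (``"row"``).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    dist = _masked_distances(vals, miss, metric)
    completed = vals.copy()
    with np.errstate(all="ignore"):
        col_means = np.nanmean(vals, axis=0)
        row_means = np.nanmean(vals, axis=1)
    for i, j in zip(*np.where(miss)):
        cand = np.where(~miss[:, j] & ~np.isnan(dist[i]))[0]
        if cand.size == 0:
            fb = col_means[j] if fallback == "col" else row_means[i]
            if np.isnan(fb):
                raise ValueError(f"cannot impute entry ({i}, {j}): no observed values")
            completed[i, j] = fb
            logger.debug("KNN mean fallback at (%d, %d)", i, j)
            continue
        d = dist[i, cand]
        order = np.argsort(d, kind="stable")[:k]  # stable sort: ties -> smaller index
        chosen = cand[order]
        w = 1.0 / (d[order] + EPS_WEIGHT)
        completed[i, j] = float(np.sum(w * vals[chosen, j]) / np.sum(w))
    return completed


def impute_swknn(
    matrix: AbundanceMatrix, k: int = 10, metric: str = "euclidean"
) -> ImputationResult:
    """Sample-wise KNN: neighbours are samples with similar profiles."""
    completed = _knn_fill_rows(matrix.values, matrix.missing, k, metric=metric)
    return _result(matrix, completed, "swKNN", {"k": k, "metric": metric})


def impute_pwknn(
    matrix: AbundanceMatrix, k: int = 10, metric: str = "euclidean"
) -> ImputationResult:
    """Protein-wise KNN: neighbours are proteins with similar profiles.

    Intended to run on a protein-standardized matrix (so distances between
    protein profiles are comparable); the caller de-standardizes the result.
    The fallback for a protein with no candidates is the protein's observed
    mean, i.e. 0 in standardized space.
    """
    completed = _knn_fill_rows(
        matrix.values.T, matrix.missing.T, k, fallback="row", metric=metric
    ).T
    return _result(matrix, completed, "pwKNN", {"k": k, "metric": metric})
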