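"""Convex-analysis-of-mixtures (CAM) imputation in intensity space.

The model treats each protein's across-sample intensity vector, normalized
to unit sum, as a point inside a scatter simplex whose vertices are the
mixing profiles of k latent biological archetypes. Proteins sitting at the
vertices are exclusive markers of one archetype. Fitting proceeds
geometrically: cluster the normalized protein points, find the k cluster
centers that most tightly enclose all centers as convex combinations,
harvest the marker proteins at those vertices, estimate the mixing matrix A
from marker means on the original intensity scale, and recover each
protein's nonnegative archetype profile s(j) by nonnegative least squares.
The archetype number is chosen by a minimum-description-length score.

Because the model is linear in original intensities (log transformation
would break the mixture linearity), CAM imputation always operates in
intensity space. Three variants are provided: fitting on the fully observed
proteins only (``cam_impute_complete``), or fitting on a matrix first
completed by a low-rank imputer (SVT or NIPALS) in log space
(``cam_impute_hybrid``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from sklearn.cluster import KMeans

from .core_data import AbundanceMatrix, ImputationResult, IntensityMatrix
from .preprocess import (
    destandardize_proteins,
    inverse_log2,
    log2_transform,
    standardize_proteins,
)
from . import lowrank

logger = logging.getLogger(__name__)

__all__ = ["CamModel", "cam_fit", "compute_mdl", "cam_impute_complete", "cam_impute_hybrid"]

RESIDUAL_FLOOR = 1e-12


@dataclass
class CamModel:
    k: int
    A: np.ndarray  # m x k mixing matrix, entries >= 0
    S: np.ndarray  # k x n archetype profiles, entries >= 0
    marker_sets: list[list[int]]  # per-archetype protein indices
    mdl_by_k: dict[int, float]
    n_MG: int

    def __post_init__(self) -> None:
        if np.any(self.A < 0) or np.any(self.S < 0):
            raise ValueError("CAM factors must be nonnegative")


def compute_mdl(matrix_values: np.ndarray, A: np.ndarray, S: np.ndarray, n_MG: int) -> float:
    """Published MDL score for a fitted mixture of k archetypes:

        MDL(k) = 1/2 * log( sum_j ||x(j) - A s(j)||_2^2 )
                 + (k-1)*m/2 * log(n_MG) + k*n/2 * log(m)

    with natural logarithms; the residual is floored at 1e-12 (warned).
    """
    if n_MG < 1:
        raise ValueError("n_MG must be >= 1")
    matrix_values = getattr(matrix_values, "values", matrix_values)
    m, k = A.shape
    n = S.shape[1]
    resid = float(np.sum((matrix_values - A @ S) ** 2))
    if resid < RESIDUAL_FLOOR:
        warnings.warn("MDL residual floored at 1e-12", stacklevel=2)
        resid = RESIDUAL_FLOOR
    return (
        0.5 * np.log(resid)
        + (k - 1) * m / 2.0 * np.log(n_MG)
        + k * n / 2.0 * np.log(m)
    )


def _corrected_mdl(matrix_values: np.ndarray, A: np.ndarray, S: np.ndarray, n_MG: int) -> float:
    """Description length with the standard Gaussian maximum-likelihood
    code length (mn/2)*log(RSS/(mn)) in place of the bare 1/2*log(RSS);
    with the bare coefficient the parameter-count penalties dominate at any
    problem size and order selection degenerates to the smallest candidate.
    """
    if n_MG < 1:
        raise ValueError("n_MG must be >= 1")
    m, k = A.shape
    n = S.shape[1]
    N = m * n
    resid = max(float(np.sum((matrix_values - A @ S) ** 2)), RESIDUAL_FLOOR)
    return (
        N / 2.0 * np.log(resid / N)
        + (k - 1) * m / 2.0 * np.log(n_MG)
        + k * n / 2.0 * np.log(m)
    )


def _convex_residual(targets: np.ndarray, vertices: np.ndarray, rho: float) -> float:
    """Total squared residual of reconstructing each target point as a
    convex combination of the vertex points. The sum-to-one constraint is
    enforced softly through an appended row of weight ``rho``."""
    V = np.vstack([vertices.T, rho * np.ones(vertices.shape[0])])
    total = 0.0
    for x in targets:
        b = np.concatenate([x, [rho]])
        _, r = nnls(V, b)
        total += r * r
    return total


def _select_vertices(
    centers: np.ndarray, k: int, rho: float
) -> tuple[list[int], float] | None:
    """Greedy selection of k centers minimizing the enclosing residual,
    refined by single swaps until no improvement."""
    n_c = centers.shape[0]
    selected: list[int] = []
    for _ in range(k):
        best_j, best_r = -1, np.inf
        for j in range(n_c):
            if j in selected:
                continue
            r = _convex_residual(centers, centers[selected + [j]], rho)
            if r < best_r - 1e-12:
                best_j, best_r = j, r
        if best_j < 0:
            return None
        selected.append(best_j)
    current = _convex_residual(centers, centers[selected], rho)
    improved = True
    passes = 0
    while improved and passes < 10:
        improved = False
        passes += 1
        for pos in range(k):
            for j in range(n_c):
                if j in selected:
                    continue
                trial = list(selected)
                trial[pos] = j
                r = _convex_residual(centers, centers[trial], rho)
                if r < current - 1e-12:
                    selected, current = trial, r
                    improved = True
    return selected, current


def _estimate_factors(
    values: np.ndarray, marker_sets: list[list[int]]
) -> tuple[np.ndarray, np.ndarray]:
    """A from per-archetype marker means on the intensity scale, with
    column rescaling so rows of A sum to (approximately) one; S by
    per-protein NNLS against A."""
    m, n = values.shape
    k = len(marker_sets)
    A_raw = np.column_stack([values[:, idx].mean(axis=1) for idx in marker_sets])
    # one nonnegative scale per column so that each row of A sums to ~1
    d, _ = nnls(A_raw, np.ones(m))
    if np.any(d <= 0):
        logger.warning("degenerate mixing column during row-sum rescaling")
        d = np.where(d <= 0, 1.0 / (A_raw.max(axis=0) + 1e-30), d)
    A = A_raw * d
    S = np.empty((k, n))
    for j in range(n):
        S[:, j], _ = nnls(A, values[:, j])
    return A, S


def cam_fit(
    matrix: IntensityMatrix,
    k_candidates: list[int] | tuple[int, ...] = (2, 3, 4, 5),
    n_clusters: int = 50,
    margin_quantile: float = 0.1,
    seed: int = 0,
    mdl_variant: str = "corrected",
) -> CamModel:
    """Fit the CAM archetype model to a complete positive intensity matrix.

    ``mdl_variant`` chooses the order-selection score: ``corrected``
    (default, Gaussian code length) or ``printed`` (:func:`compute_mdl`).
    """
    if matrix.missing.any():
        raise ValueError("cam_fit requires a complete matrix")
    vals = matrix.values
    m, n = vals.shape
    k_candidates = sorted(set(int(k) for k in k_candidates))
    if min(k_candidates) < 2:
        raise ValueError("k candidates must be >= 2")
    n_clusters = min(n_clusters, n)
    if max(k_candidates) >= n_clusters:
        raise ValueError("max(k_candidates) must be < n_clusters")
    score_fn = {"corrected": _corrected_mdl, "printed": compute_mdl}[mdl_variant]

    # proteins as points on the scatter simplex
    col_sums = vals.sum(axis=0)
    points = (vals / col_sums).T  # n x m
    with warnings.catch_warnings():
        # duplicate points (e.g. exact marker replicates) yield empty clusters
        warnings.simplefilter("ignore")
        km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=4).fit(points)
    counts = np.bincount(km.labels_, minlength=n_clusters)
    nonempty = np.where(counts > 0)[0]
    remap = {int(old): new for new, old in enumerate(nonempty)}
    centers = km.cluster_centers_[nonempty]
    labels = np.array([remap[int(c)] for c in km.labels_])
    if max(k_candidates) >= centers.shape[0]:
        raise ValueError(
            f"only {centers.shape[0]} distinct clusters; reduce k candidates"
        )
    rho = 10.0 * float(np.abs(centers).max() + 1.0)

    results: dict[int, tuple[float, np.ndarray, np.ndarray, list[list[int]], int]] = {}
    for k in k_candidates:
        sel = _select_vertices(centers, k, rho)
        if sel is None:
            warnings.warn(f"k={k}: degenerate vertex set, skipped", stacklevel=2)
            continue
        vertex_ids, _ = sel
        # near-duplicate vertices -> degenerate candidate
        C = centers[vertex_ids]
        dists = np.linalg.norm(C[:, None] - C[None, :], axis=2)
        np.fill_diagonal(dists, np.inf)
        if dists.min() < 1e-10 * (np.abs(C).max() + 1e-30):
            warnings.warn(f"k={k}: duplicate vertex centers, skipped", stacklevel=2)
            continue
        marker_sets: list[list[int]] = []
        ok = True
        for c in vertex_ids:
            members = np.where(labels == c)[0]
            if members.size == 0:
                ok = False
                break
            d = np.linalg.norm(points[members] - centers[c], axis=1)
            cut = np.quantile(d, margin_quantile)
            markers = members[d <= cut]
            if markers.size == 0:
                markers = members[[int(np.argmin(d))]]
            marker_sets.append(sorted(int(j) for j in markers))
        if not ok:
            warnings.warn(f"k={k}: empty vertex cluster, skipped", stacklevel=2)
            continue
        A, S = _estimate_factors(vals, marker_sets)
        n_MG = sum(len(s) for s in marker_sets)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            score = score_fn(vals, A, S, n_MG)
        results[k] = (score, A, S, marker_sets, n_MG)
    if not results:
        raise ValueError("all candidate k were degenerate")
    mdl_by_k = {k: r[0] for k, r in results.items()}
    best_k = min(mdl_by_k, key=mdl_by_k.get)
    _, A, S, marker_sets, n_MG = results[best_k]
    return CamModel(best_k, A, S, marker_sets, mdl_by_k, n_MG)


def _fill_from_model(
    matrix: IntensityMatrix, A: np.ndarray, recon_source: np.ndarray, name: str, params: dict
) -> ImputationResult:
    """Replace the missing entries of ``matrix`` with ``recon_source``;
    nonpositive fills fall back to half the protein's observed minimum."""
    miss = matrix.missing
    completed = matrix.values.copy()
    completed[miss] = recon_source[miss]
    bad = miss & (completed <= 0)
    if bad.any():
        logger.warning("%d nonpositive CAM fills replaced by min/2", int(bad.sum()))
        for j in np.unique(np.where(bad)[1]):
            obs = matrix.values[~miss[:, j], j]
            completed[bad[:, j], j] = obs.min() / 2.0
    return ImputationResult(
        completed=completed,
        method_name=name,
        params=params,
        filled=miss.copy(),
        space_tag="intensity",
    )


def cam_impute_complete(
    matrix: IntensityMatrix,
    k_candidates: list[int] | tuple[int, ...] = (2, 3, 4, 5),
    n_clusters: int = 50,
    margin_quantile: float = 0.1,
    seed: int = 0,
    mdl_variant: str = "corrected",
) -> ImputationResult:
    """CAM_complete: fit the archetype model on the fully observed proteins,
    then reconstruct every protein by NNLS of its observed samples against
    the mixing matrix and fill its missing entries from A s(j)."""
    miss = matrix.missing
    complete_cols = np.where(~miss.any(axis=0))[0]
    if complete_cols.size < 10 * max(k_candidates):
        raise ValueError(
            f"need at least {10 * max(k_candidates)} fully observed proteins, "
            f"have {complete_cols.size}"
        )
    sub = IntensityMatrix(
        matrix.values[:, complete_cols],
        sample_ids=list(matrix.sample_ids),
        protein_ids=[matrix.protein_ids[j] for j in complete_cols],
    )
    model = cam_fit(sub, k_candidates, n_clusters, margin_quantile, seed, mdl_variant)
    A = model.A
    m, n = matrix.shape
    recon = matrix.values.copy()
    for j in np.where(miss.any(axis=0))[0]:
        obs_rows = np.where(~miss[:, j])[0]
        if obs_rows.size < model.k:
            obs = matrix.values[obs_rows, j]
            recon[:, j] = obs.mean()
            logger.info("protein %s: too few observations for NNLS, mean fill", matrix.protein_ids[j])
            continue
        sj, _ = nnls(A[obs_rows], matrix.values[obs_rows, j])
        recon[:, j] = A @ sj
    return _fill_from_model(
        matrix, A, recon, "CAM_complete",
        {"k": model.k, "n_MG": model.n_MG, "mdl_variant": mdl_variant},
    )


def cam_impute_hybrid(
    matrix: IntensityMatrix,
    initializer: str = "svt",
    k_candidates: list[int] | tuple[int, ...] = (2, 3, 4, 5),
    n_clusters: int = 50,
    margin_quantile: float = 0.1,
    seed: int = 0,
    mdl_variant: str = "corrected",
    initializer_params: dict | None = None,
) -> ImputationResult:
    """CAM_SVT / CAM_NIPALS: complete the matrix with a low-rank imputer in
    (standardized) log2 space, map back to intensities, fit CAM on the
    completed intensity matrix, and replace only the originally missing
    entries with the CAM reconstruction A @ S."""
    initializer_params = dict(initializer_params or {})
    logm = log2_transform(matrix)
    std, params = standardize_proteins(logm)
    if initializer == "svt":
        init_res = lowrank.impute_svt(std, **initializer_params)
    elif initializer == "nipals":
        initializer_params.setdefault("rank", min(8, min(matrix.shape) - 1))
        init_res = lowrank.impute_nipals(std, **initializer_params)
    else:
        raise ValueError(f"unknown initializer {initializer!r}")
    completed_log = destandardize_proteins(init_res.completed, params)
    completed_int = IntensityMatrix(
        np.exp2(completed_log),
        sample_ids=list(matrix.sample_ids),
        protein_ids=list(matrix.protein_ids),
    )
    model = cam_fit(completed_int, k_candidates, n_clusters, margin_quantile, seed, mdl_variant)
    recon = model.A @ model.S
    return _fill_from_model(
        matrix, model.A, recon, f"CAM_{initializer.upper()}",
        {"k": model.k, "n_MG": model.n_MG, "initializer": initializer,
         "mdl_variant": mdl_variant},
    )
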