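"""Synthetic data generation and missing-value simulation.

Two complementary evaluation designs are provided. In the first, artificial
missing values are injected into a complete matrix under MCAR (uniform
random), MNAR (global low-intensity quantile cut-off, emulating values below
the detection limit) or a mixture of the two. In the second, a matrix that
already carries authentic missing values has a small fraction of its
*observed* entries masked, with per-protein masking rates proportional to
each protein's authentic missing rate, so the mask mirrors the real
missingness pattern.

The complete-data generator emulates a low-rank archetype-mixture model:
each sample is a convex combination of k latent archetype profiles, a subset
of proteins are exclusive markers of one archetype, and measured intensities
carry multiplicative log-normal noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_data import AbundanceMatrix, GroundTruth, IntensityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticTruth",
    "MissingSpec",
    "MaskSpec",
    "generate_synthetic",
    "generate_clustered",
    "inject_mcar",
    "inject_mnar",
    "inject_mix",
    "mask_clustered",
    "mask_setting2",
]


@dataclass
class SyntheticTruth:
    """Ground-truth factors behind a generated complete matrix."""

    A_true: np.ndarray  # m x k mixing proportions, rows on the simplex
    S_true: np.ndarray  # k x n nonnegative archetype profiles
    marker_sets: list[list[int]]  # per-archetype exclusive protein indices
    noise_sigma: float
    complete: IntensityMatrix
    clusters: np.ndarray | None = field(default=None)  # per-sample cluster label


@dataclass
class MissingSpec:
    """Artificial-injection specification (setting with no authentic NAs).

    ``alpha`` is the total missing rate; ``beta`` the MNAR proportion
    (beta=0 is pure MCAR, beta=1 pure MNAR).
    """

    mechanism: str = "MIX"
    alpha: float = 0.3
    beta: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in {"MCAR", "MNAR", "MIX"}:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.mechanism == "MCAR":
            self.beta = 0.0
        elif self.mechanism == "MNAR":
            self.beta = 1.0
        if not 0 <= self.beta <= 1:
            raise ValueError("beta must be in [0, 1]")


@dataclass
class MaskSpec:
    """Proportional-masking specification (authentic-missingness setting)."""

    global_fraction: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.global_fraction <= 0.5:
            raise ValueError("global_fraction must be in (0, 0.5]")


# ---------------------------------------------------------------------------
# complete-data generation

# Log-normal dispersions for the archetype profiles: base abundance spread
# across proteins (dynamic range) and archetype-to-archetype variation within
# a protein, both on the natural-log scale.
_BASE_SIGMA = 1.2
_ARCHETYPE_SIGMA = 0.8
_MARKER_BOOST = 2.0


def _make_profiles(
    rng: np.random.Generator, k: int, n: int, marker_fraction: float
) -> tuple[np.ndarray, list[list[int]]]:
    base = np.exp(rng.normal(0.0, _BASE_SIGMA, size=n))
    S = base[None, :] * np.exp(rng.normal(0.0, _ARCHETYPE_SIGMA, size=(k, n)))
    n_markers = int(round(marker_fraction * n))
    order = rng.permutation(n)
    marker_sets: list[list[int]] = []
    pos = 0
    for a in range(k):
        idx = sorted(int(j) for j in order[pos : pos + n_markers])
        pos += n_markers
        for j in idx:
            S[:, j] = 0.0
            S[a, j] = base[j] * _MARKER_BOOST
        marker_sets.append(idx)
    return S, marker_sets


def _assemble(
    A: np.ndarray,
    S: np.ndarray,
    marker_sets: list[list[int]],
    noise_sigma: float,
    intensity_scale: float,
    rng: np.random.Generator,
    clusters: np.ndarray | None = None,
) -> SyntheticTruth:
    m, n = A.shape[0], S.shape[1]
    clean = A @ S * intensity_scale
    noise = np.exp(rng.normal(0.0, noise_sigma, size=(m, n))) if noise_sigma > 0 else 1.0
    complete = IntensityMatrix(
        clean * noise,
        sample_ids=[f"S{i:03d}" for i in range(m)],
        protein_ids=[f"P{j:04d}" for j in range(n)],
    )
    return SyntheticTruth(A, S, marker_sets, noise_sigma, complete, clusters)


def generate_synthetic(
    m: int = 50,
    n: int = 300,
    k: int = 3,
    marker_fraction: float = 0.1,
    noise_sigma: float = 0.3,
    intensity_scale: float = 1e6,
    seed: int = 0,
) -> SyntheticTruth:
    """Generate a complete archetype-mixture intensity matrix.

    Mixing rows are drawn from a flat Dirichlet on the k-simplex; a fraction
    ``marker_fraction`` of the proteins per archetype are exclusive markers
    (zero in every other archetype profile). Intensities are
    ``(A @ S) * intensity_scale`` perturbed entrywise by
    ``exp(N(0, noise_sigma**2))``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if m <= k:
        raise ValueError("need m > k samples")
    if n <= 10 * k:
        raise ValueError("need n > 10*k proteins")
    if k * marker_fraction > 0.9:
        raise ValueError("marker_fraction too large for k archetypes")
    rng = np.random.default_rng(seed)
    A = rng.dirichlet(np.ones(k), size=m)
    S, marker_sets = _make_profiles(rng, k, n, marker_fraction)
    return _assemble(A, S, marker_sets, noise_sigma, intensity_scale, rng)


def generate_clustered(
    m: int = 40,
    n: int = 150,
    k: int = 2,
    concentration: float = 8.0,
    marker_fraction: float = 0.1,
    noise_sigma: float = 0.3,
    intensity_scale: float = 1e6,
    seed: int = 0,
) -> SyntheticTruth:
    """Generate data whose samples fall into k clusters.

    Samples are assigned round-robin to clusters; a cluster-c sample's
    mixing row is drawn from Dirichlet(1 + (concentration-1)*e_c), so rows
    within a cluster are similar — the regime where similarity-fused
    factorization is expected to help.
    """
    if k < 2 or m <= k or n <= 10 * k:
        raise ValueError("parameter domain violation")
    rng = np.random.default_rng(seed)
    clusters = np.arange(m) % k
    A = np.empty((m, k))
    for i in range(m):
        alpha = np.ones(k)
        alpha[clusters[i]] = concentration
        A[i] = rng.dirichlet(alpha)
    S, marker_sets = _make_profiles(rng, k, n, marker_fraction)
    return _assemble(A, S, marker_sets, noise_sigma, intensity_scale, rng, clusters)


# ---------------------------------------------------------------------------
# setting 1: artificial injection into a complete matrix


def _as_missing(matrix: AbundanceMatrix, rows: np.ndarray, cols: np.ndarray) -> AbundanceMatrix:
    out = matrix.copy()
    out.values[rows, cols] = np.nan
    return out


def _truth_from(matrix: AbundanceMatrix, rows: np.ndarray, cols: np.ndarray) -> GroundTruth:
    pairs = list(zip(rows.tolist(), cols.tolist()))
    return GroundTruth(pairs, matrix.values[rows, cols].copy(), matrix.space_tag)


def _check_complete(matrix: AbundanceMatrix) -> None:
    if matrix.missing.any():
        raise ValueError("injection requires a complete matrix")


def _draw_mcar(
    free: np.ndarray, count: int, m: int, n: int, rng: np.random.Generator,
    already_missing: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Pick ``count`` flat positions uniformly from ``free``, redrawing (up
    to 100 times) if some protein that still has observations would lose
    them all."""
    for attempt in range(100):
        chosen = rng.choice(free, size=count, replace=False)
        rows, cols = np.unravel_index(chosen, (m, n))
        lost = np.bincount(cols, minlength=n) + already_missing
        # proteins already fully missing (e.g. from a prior MNAR cut-off)
        # cannot be protected; all others must keep >= 1 observed entry
        if np.all((lost < m) | (already_missing >= m)):
            return rows, cols
    raise ValueError("could not draw MCAR mask leaving every protein observed")


def inject_mcar(
    matrix: AbundanceMatrix, alpha: float, seed: int = 0
) -> tuple[AbundanceMatrix, GroundTruth]:
    """Remove exactly round(alpha*m*n) entries uniformly at random."""
    _check_complete(matrix)
    m, n = matrix.shape
    count = int(round(alpha * m * n))
    if count == 0:
        raise ValueError("empty evaluation set (alpha too small)")
    rng = np.random.default_rng(seed)
    rows, cols = _draw_mcar(
        np.arange(m * n), count, m, n, rng, np.zeros(n, dtype=int)
    )
    return _as_missing(matrix, rows, cols), _truth_from(matrix, rows, cols)


def _mnar_positions(values: np.ndarray, count: int) -> tuple[np.ndarray, np.ndarray]:
    """Flat positions of the ``count`` smallest values; ties broken by
    (row, column) lexicographic order via the stable sort on the row-major
    flattening."""
    flat = values.ravel()
    order = np.argsort(flat, kind="stable")[:count]
    return np.unravel_index(order, values.shape)


def inject_mnar(
    matrix: AbundanceMatrix, alpha: float
) -> tuple[AbundanceMatrix, GroundTruth]:
    """Remove the lowest floor(alpha*m*n) values — a global quantile
    cut-off emulating the lower limit of detection. Deterministic."""
    _check_complete(matrix)
    m, n = matrix.shape
    count = int(np.floor(alpha * m * n))
    if count == 0:
        raise ValueError("empty evaluation set (alpha too small)")
    rows, cols = _mnar_positions(matrix.values, count)
    return _as_missing(matrix, rows, cols), _truth_from(matrix, rows, cols)


def inject_mix(
    matrix: AbundanceMatrix, alpha: float, beta: float, seed: int = 0
) -> tuple[AbundanceMatrix, GroundTruth]:
    """Hybrid mechanism: a beta fraction of the missing entries follow the
    MNAR quantile rule (applied first, on the full dataset), the rest MCAR
    among the survivors."""
    _check_complete(matrix)
    if not 0 <= beta <= 1:
        raise ValueError("beta must be in [0, 1]")
    m, n = matrix.shape
    n_mnar = int(round(beta * alpha * m * n))
    n_mcar = int(round((1 - beta) * alpha * m * n))
    if n_mnar + n_mcar == 0:
        raise ValueError("empty evaluation set (alpha too small)")
    logger.debug("MIX injection: %d MNAR then %d MCAR entries", n_mnar, n_mcar)
    rows_parts, cols_parts = [], []
    already = np.zeros(n, dtype=int)
    if n_mnar:
        r, c = _mnar_positions(matrix.values, n_mnar)
        rows_parts.append(np.asarray(r))
        cols_parts.append(np.asarray(c))
        already = np.bincount(np.asarray(c), minlength=n)
    if n_mcar:
        taken = set()
        if n_mnar:
            taken = set((rows_parts[0] * n + cols_parts[0]).tolist())
        free = np.array([p for p in range(m * n) if p not in taken])
        rng = np.random.default_rng(seed)
        r, c = _draw_mcar(free, n_mcar, m, n, rng, already)
        rows_parts.append(r)
        cols_parts.append(c)
    rows = np.concatenate(rows_parts)
    cols = np.concatenate(cols_parts)
    return _as_missing(matrix, rows, cols), _truth_from(matrix, rows, cols)


def mask_clustered(
    truth: SyntheticTruth, fraction: float, seed: int = 0
) -> tuple[AbundanceMatrix, GroundTruth]:
    """Cluster-consistent masking for clustered synthetic data: each cluster
    gets its own random protein block, and entries of cluster samples within
    that block are masked at the rate that yields ``fraction`` overall."""
    if truth.clusters is None:
        raise ValueError("mask_clustered needs clustered synthetic data")
    matrix = truth.complete
    m, n = matrix.shape
    rng = np.random.default_rng(seed)
    k = int(truth.clusters.max()) + 1
    block_size = min(n, int(round(2 * fraction * n * k)) // k * 2)
    block_size = max(block_size, 1)
    rate = fraction * n / block_size
    rate = min(rate, 0.9)
    rows_l, cols_l = [], []
    for c in range(k):
        block = rng.choice(n, size=block_size, replace=False)
        for i in np.where(truth.clusters == c)[0]:
            hit = block[rng.random(block_size) < rate]
            rows_l.extend([i] * len(hit))
            cols_l.extend(int(j) for j in hit)
    rows = np.array(rows_l, dtype=int)
    cols = np.array(cols_l, dtype=int)
    # keep every protein observed in at least 2 samples
    miss_per_protein = np.bincount(cols, minlength=n)
    keep = np.ones(len(rows), dtype=bool)
    for j in np.where(miss_per_protein > m - 2)[0]:
        at_j = np.where(cols == j)[0]
        drop = rng.choice(at_j, size=int(miss_per_protein[j] - (m - 2)), replace=False)
        keep[drop] = False
    rows, cols = rows[keep], cols[keep]
    if len(rows) == 0:
        raise ValueError("empty evaluation set")
    return _as_missing(matrix, rows, cols), _truth_from(matrix, rows, cols)


# ---------------------------------------------------------------------------
# setting 2: proportional masking on top of authentic missingness


def mask_setting2(
    matrix: AbundanceMatrix, spec: MaskSpec
) -> tuple[AbundanceMatrix, GroundTruth]:
    """Mask observed entries with per-protein counts proportional to each
    protein's authentic missing rate.

    For protein p with authentic missing rate r_p and obs_p observed
    entries, the masked count is round(c * r_p * obs_p); the single constant
    c is calibrated by bisection so the total masked count equals
    round(global_fraction * total_observed) (within one entry, since counts
    are integers). Authentic NAs are untouched; only masked entries enter
    the ground truth.
    """
    missing = matrix.missing
    m, n = matrix.shape
    rates = missing.mean(axis=0)
    obs_counts = m - missing.sum(axis=0)
    if not np.any(rates > 0):
        raise ValueError("masking undefined without authentic missingness")
    if np.any(obs_counts < 2):
        logger.warning(
            "%d proteins have < 2 observed entries and will not be masked",
            int((obs_counts < 2).sum()),
        )
    total_obs = int(obs_counts.sum())
    target = int(round(spec.global_fraction * total_obs))
    if target == 0:
        raise ValueError("empty evaluation set (global_fraction too small)")

    caps = np.maximum(obs_counts - 1, 0)  # always leave >= 1 observed entry

    def counts_for(c: float) -> np.ndarray:
        raw = np.round(c * rates * obs_counts).astype(int)
        return np.minimum(raw, caps)

    lo, hi = 0.0, 1.0
    while counts_for(hi).sum() < target and hi < 1e6:
        hi *= 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if counts_for(mid).sum() < target:
            lo = mid
        else:
            hi = mid
    counts = counts_for(hi)
    logger.debug(
        "setting-2 calibration: c=%.6g, total masked %d (target %d)",
        hi, int(counts.sum()), target,
    )

    rng = np.random.default_rng(spec.seed)
    rows_l, cols_l = [], []
    for j in range(n):
        if counts[j] == 0:
            continue
        obs_rows = np.where(~missing[:, j])[0]
        pick = rng.choice(obs_rows, size=int(counts[j]), replace=False)
        rows_l.extend(int(i) for i in pick)
        cols_l.extend([j] * int(counts[j]))
    rows = np.array(rows_l, dtype=int)
    cols = np.array(cols_l, dtype=int)
    return _as_missing(matrix, rows, cols), _truth_from(matrix, rows, cols)
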