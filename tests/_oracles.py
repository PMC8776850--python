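"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written with plain Python loops and naive formulas,
deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np

EPS = 1e-9


def brute_knn_rows(vals: np.ndarray, miss: np.ndarray, k: int) -> np.ndarray:
    """Exhaustive-neighbour KNN over rows: for each missing (i, j) enumerate
    every candidate row, compute the shared-entry-normalized Euclidean
    distance, sort by (distance, index), take k, inverse-distance weight."""
    m, n = vals.shape
    out = vals.copy()
    for i in range(m):
        for j in range(n):
            if not miss[i, j]:
                continue
            cands = []
            for i2 in range(m):
                if i2 == i or miss[i2, j]:
                    continue
                shared = [jj for jj in range(n) if not miss[i, jj] and not miss[i2, jj]]
                if not shared:
                    continue
                d = math.sqrt(
                    sum((vals[i, jj] - vals[i2, jj]) ** 2 for jj in shared)
                ) / math.sqrt(len(shared))
                cands.append((d, i2))
            if not cands:
                obs = [vals[i2, j] for i2 in range(m) if not miss[i2, j]]
                out[i, j] = sum(obs) / len(obs)
                continue
            cands.sort(key=lambda t: (t[0], t[1]))
            top = cands[:k]
            wsum = sum(1.0 / (d + EPS) for d, _ in top)
            out[i, j] = sum(vals[i2, j] / (d + EPS) for d, i2 in top) / wsum
    return out


def direct_rmse(true_vals, imputed_vals) -> float:
    sq = [(a - b) ** 2 for a, b in zip(imputed_vals, true_vals)]
    return math.sqrt(sum(sq) / len(sq))


def direct_nrmse(true_vals, imputed_vals) -> float:
    mean = sum(true_vals) / len(true_vals)
    var = sum((v - mean) ** 2 for v in true_vals) / len(true_vals)
    sq = [(a - b) ** 2 for a, b in zip(imputed_vals, true_vals)]
    return math.sqrt(sum(sq) / (len(sq) * var))


def rank_sum_sor(per_method: dict[str, dict[int, float]]) -> dict[str, float]:
    """SOR by explicit per-protein rank enumeration with average ties."""
    methods = list(per_method)
    proteins = sorted(per_method[methods[0]])
    totals = {mth: 0.0 for mth in methods}
    for j in proteins:
        pairs = sorted((per_method[mth][j], mth) for mth in methods)
        # average rank for tied values
        i = 0
        while i < len(pairs):
            jj = i
            while jj + 1 < len(pairs) and pairs[jj + 1][0] == pairs[i][0]:
                jj += 1
            avg = (i + jj) / 2 + 1
            for t in range(i, jj + 1):
                totals[pairs[t][1]] += avg
            i = jj + 1
    return totals


def pairwise_cosine_obs(vals: np.ndarray, miss: np.ndarray) -> np.ndarray:
    """All-pairs cosine over mutually observed columns (NaN if none)."""
    m = vals.shape[0]
    sim = np.full((m, m), np.nan)
    for a in range(m):
        for b in range(m):
            if a == b:
                continue
            shared = [j for j in range(vals.shape[1]) if not miss[a, j] and not miss[b, j]]
            if not shared:
                continue
            xa = [vals[a, j] for j in shared]
            xb = [vals[b, j] for j in shared]
            na = math.sqrt(sum(x * x for x in xa))
            nb = math.sqrt(sum(x * x for x in xb))
            if na == 0 or nb == 0:
                continue
            sim[a, b] = sum(p * q for p, q in zip(xa, xb)) / (na * nb)
    return sim
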