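"""Low-rank matrix-factorization imputers: PPCA, NIPALS, SVDImpute, SVT.

All four assume the complete matrix is (approximately) rank-l and fill
missing entries from the fitted low-rank reconstruction. PPCA fits the
probabilistic PCA model by expectation-maximization over the observed
entries; NIPALS extracts principal components one at a time by alternating
regressions that simply skip missing cells; SVDImpute alternates truncated
SVD with refilling; SVT solves a nuclear-norm relaxation by iterative
soft-thresholding of singular values, so it needs no explicit rank.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.linalg import svd, solve, slogdet

from .core_data import AbundanceMatrix, ImputationResult

logger = logging.getLogger(__name__)

__all__ = [
    "LowRankFit",
    "svdimpute_fit",
    "nipals_fit",
    "ppca_fit",
    "svt_fit",
    "impute_svdimpute",
    "impute_nipals",
    "impute_ppca",
    "impute_svt",
]

SIGMA2_FLOOR = 1e-12


@dataclass
class LowRankFit:
    rank: int
    reconstruction: np.ndarray
    iterations: int
    trace: list[float] = field(default_factory=list)
    converged: bool = True


def _check_rank(rank: int, m: int, n: int) -> None:
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if rank >= min(m, n):
        raise ValueError(f"rank {rank} must be < min(m, n) = {min(m, n)}")


def _mean_fill(vals: np.ndarray, miss: np.ndarray) -> np.ndarray:
    filled = vals.copy()
    with np.errstate(all="ignore"):
        col_means = np.nanmean(vals, axis=0)
    if np.any(np.isnan(col_means[miss.any(axis=0)])):
        raise ValueError("cannot initialize: a protein has no observed values")
    jj = np.where(miss)[1]
    filled[miss] = col_means[jj]
    return filled


def _wrap(matrix: AbundanceMatrix, fit: LowRankFit, name: str, params: dict) -> ImputationResult:
    completed = matrix.values.copy()
    completed[matrix.missing] = fit.reconstruction[matrix.missing]
    params = dict(params, iterations=fit.iterations, converged=fit.converged)
    return ImputationResult(
        completed=completed,
        method_name=name,
        params=params,
        filled=matrix.missing.copy(),
        space_tag=matrix.space_tag,
    )


# ---------------------------------------------------------------------------
# SVDImpute


def svdimpute_fit(
    matrix: AbundanceMatrix, rank: int, tol: float = 1e-6, max_iter: int = 500
) -> LowRankFit:
    """Alternate truncated SVD of the filled matrix with refilling of the
    missing cells; missing entries start at the protein means. Convergence
    is measured as the relative Frobenius change of the imputed entries."""
    vals, miss = matrix.values, matrix.missing
    _check_rank(rank, *vals.shape)
    if not miss.any():
        return LowRankFit(rank, vals.copy(), 0, [], True)
    filled = _mean_fill(vals, miss)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        U, s, Vt = svd(filled, full_matrices=False)
        recon = (U[:, :rank] * s[:rank]) @ Vt[:rank]
        old = filled[miss]
        new = recon[miss]
        denom = np.linalg.norm(old) + 1e-30
        change = float(np.linalg.norm(new - old) / denom)
        trace.append(change)
        filled[miss] = new
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn("SVDImpute did not converge within max_iter", stacklevel=2)
    U, s, Vt = svd(filled, full_matrices=False)
    recon = (U[:, :rank] * s[:rank]) @ Vt[:rank]
    return LowRankFit(rank, recon, it, trace, converged)


def impute_svdimpute(
    matrix: AbundanceMatrix, rank: int, tol: float = 1e-6, max_iter: int = 500
) -> ImputationResult:
    fit = svdimpute_fit(matrix, rank, tol, max_iter)
    return _wrap(matrix, fit, "SVD", {"rank": rank})


# ---------------------------------------------------------------------------
# NIPALS


def _nipals_component(
    R: np.ndarray, obs: np.ndarray, t0: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """One score/loading pair by alternating regressions on the observed
    entries of the residual R."""
    m, n = R.shape
    t = t0
    p = np.zeros(n)
    converged = False
    iters = 0
    for iters in range(1, max_iter + 1):
        denom_p = obs.T @ (t**2)
        p_new = (R * obs).T @ t / np.where(denom_p > 0, denom_p, 1.0)
        norm = np.linalg.norm(p_new)
        if norm == 0:
            break
        p_new /= norm
        denom_t = obs @ (p_new**2)
        t_new = (R * obs) @ p_new / np.where(denom_t > 0, denom_t, 1.0)
        change = float(np.linalg.norm(t_new - t) / (np.linalg.norm(t) + 1e-30))
        t, p = t_new, p_new
        if change < tol:
            converged = True
            break
    return t, p, iters, converged


def nipals_fit(
    matrix: AbundanceMatrix,
    rank: int,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_sweeps: int = 5,
) -> LowRankFit:
    """Principal components by alternating regressions over the observed
    entries only, extracting one component at a time and deflating.

    With missing data a single sequential pass leaves deflation bias, so
    the extraction is cycled: in each subsequent sweep every component is
    removed from the running reconstruction and refitted against the
    residual of the others, until the reconstruction stabilizes (at most
    ``n_sweeps`` sweeps). The matrix is taken as supplied (no internal
    centering): run it on centered or standardized data.
    """
    vals, miss = matrix.values, matrix.missing
    _check_rank(rank, *vals.shape)
    m, n = vals.shape
    obs = ~miss
    X = np.where(obs, vals, 0.0)
    T = np.zeros((m, rank))
    P = np.zeros((n, rank))
    total_iters = 0
    converged_all = True
    prev_recon = np.zeros_like(vals)
    for sweep in range(n_sweeps):
        for comp in range(rank):
            recon_others = T @ P.T - np.outer(T[:, comp], P[:, comp])
            R = X - np.where(obs, recon_others, 0.0)
            if sweep == 0:
                j0 = int(np.argmax(np.sum(R**2 * obs, axis=0)))
                t0 = R[:, j0].copy()
                if np.linalg.norm(t0) == 0:
                    t0 = np.ones(m)
            else:
                t0 = T[:, comp]
            t, p, iters, converged = _nipals_component(R, obs, t0, tol, max_iter)
            total_iters += iters
            if sweep == 0 and not converged:
                converged_all = False
                warnings.warn(
                    f"NIPALS component {comp + 1} did not converge; keeping last iterate",
                    stacklevel=2,
                )
            T[:, comp], P[:, comp] = t, p
        recon = T @ P.T
        if np.linalg.norm(recon - prev_recon) <= tol * (np.linalg.norm(recon) + 1e-30):
            break
        prev_recon = recon
    return LowRankFit(rank, T @ P.T, total_iters, [], converged_all)


def impute_nipals(
    matrix: AbundanceMatrix, rank: int, tol: float = 1e-6, max_iter: int = 500
) -> ImputationResult:
    fit = nipals_fit(matrix, rank, tol, max_iter)
    return _wrap(matrix, fit, "NIPALS", {"rank": rank})


# ---------------------------------------------------------------------------
# PPCA


def ppca_fit(
    matrix: AbundanceMatrix,
    rank: int,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
) -> LowRankFit:
    """EM for the probabilistic PCA model x = W z + mu + eps with missing
    entries.

    The E-step computes per-sample latent posteriors over each sample's
    observed coordinates; the M-step jointly re-estimates the loadings W,
    the mean mu and the isotropic noise variance sigma^2 in closed form, so
    the observed-data log-likelihood (recorded in ``trace``) is
    non-decreasing. Initialization comes from an SVDImpute fill; ``seed``
    controls a vanishing random perturbation of the initial loadings that
    breaks exact degeneracies.
    """
    vals, miss = matrix.values, matrix.missing
    _check_rank(rank, *vals.shape)
    m, n = vals.shape
    obs = ~miss
    n_obs_total = int(obs.sum())
    l = rank

    # --- initialization from an SVDImpute fill
    if miss.any():
        init = svdimpute_fit(matrix, rank, tol=1e-4, max_iter=50)
        filled = vals.copy()
        filled[miss] = init.reconstruction[miss]
    else:
        filled = vals.copy()
    mu = filled.mean(axis=0)
    centered = filled - mu
    U, s, Vt = svd(centered, full_matrices=False)
    W = (Vt[:l].T * (s[:l] / np.sqrt(m)))
    rng = np.random.default_rng(seed)
    W = W + 1e-10 * rng.standard_normal(W.shape)
    resid = centered - (U[:, :l] * s[:l]) @ Vt[:l]
    sigma2 = max(float(np.mean(resid**2)), SIGMA2_FLOOR)

    obs_cols = [np.where(obs[i])[0] for i in range(m)]
    trace: list[float] = []
    converged = False
    Ez = np.zeros((m, l))
    it = 0
    for it in range(1, max_iter + 1):
        # --- E-step + observed-data log-likelihood at current parameters
        ll = 0.0
        Czz = np.zeros((m, l, l))
        for i in range(m):
            oc = obs_cols[i]
            Wo = W[oc]
            d = vals[i, oc] - mu[oc]
            Psi = sigma2 * np.eye(l) + Wo.T @ Wo
            b = Wo.T @ d
            Ez[i] = solve(Psi, b)
            Czz[i] = sigma2 * np.linalg.inv(Psi)
            _, logdet_psi = slogdet(Psi)
            logdet_C = (len(oc) - l) * np.log(sigma2) + logdet_psi
            quad = (d @ d - b @ Ez[i]) / sigma2
            ll += -0.5 * (len(oc) * np.log(2 * np.pi) + logdet_C + quad)
        trace.append(ll)
        if len(trace) > 1:
            prev = trace[-2]
            if abs(ll - prev) < tol * (abs(prev) + 1e-30):
                converged = True
                break
        # --- M-step: per-protein joint regression on [E z, 1]
        Ezz = Czz + Ez[:, :, None] * Ez[:, None, :]
        W_new = np.zeros_like(W)
        mu_new = np.zeros_like(mu)
        for j in range(n):
            ii = np.where(obs[:, j])[0]
            G = np.zeros((l + 1, l + 1))
            G[:l, :l] = Ezz[ii].sum(axis=0)
            G[:l, l] = G[l, :l] = Ez[ii].sum(axis=0)
            G[l, l] = len(ii)
            h = np.zeros(l + 1)
            h[:l] = Ez[ii].T @ vals[ii, j]
            h[l] = vals[ii, j].sum()
            theta = solve(G + 1e-12 * np.eye(l + 1), h)
            W_new[j] = theta[:l]
            mu_new[j] = theta[l]
        # --- noise variance from expected residuals
        s2 = 0.0
        for i in range(m):
            oc = obs_cols[i]
            Wo = W_new[oc]
            r = vals[i, oc] - Wo @ Ez[i] - mu_new[oc]
            s2 += float(r @ r) + float(np.trace(Wo @ Czz[i] @ Wo.T))
        W, mu = W_new, mu_new
        sigma2 = max(s2 / n_obs_total, SIGMA2_FLOOR)
    if not converged:
        warnings.warn("PPCA EM did not converge within max_iter", stacklevel=2)
    recon = mu[None, :] + Ez @ W.T
    return LowRankFit(rank, recon, it, trace, converged)


def impute_ppca(
    matrix: AbundanceMatrix,
    rank: int,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
) -> ImputationResult:
    fit = ppca_fit(matrix, rank, tol, max_iter, seed)
    return _wrap(matrix, fit, "PPCA", {"rank": rank, "seed": seed})


# ---------------------------------------------------------------------------
# SVT


def svt_default_tau(m: int, n: int) -> float:
    return 5.0 * np.sqrt(m * n)


def svt_fit(
    matrix: AbundanceMatrix,
    tau: float | None = None,
    delta: float | None = None,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> LowRankFit:
    """Singular value thresholding for nuclear-norm matrix completion.

    Iterates X_hat = shrink(Y, tau) (soft-threshold the singular values by
    tau) and Y <- Y + delta * P_obs(X - X_hat). Starting from Y = 0 the
    early iterations yield X_hat = 0 while Y merely accumulates
    delta*P_obs(X), so the standard warm start
    Y0 = k0*delta*P_obs(X), k0 = ceil(tau / (delta*||P_obs(X)||_2)),
    is applied — the same iterate sequence minus the idle warm-up.
    Defaults: tau = 5*sqrt(m*n), delta = 1.2 / observed_fraction. Stops when
    the relative residual on the observed entries drops below ``tol``;
    aborts if the residual grows to 10x its initial value.
    """
    vals, miss = matrix.values, matrix.missing
    m, n = vals.shape
    obs = ~miss
    if np.any(obs.sum(axis=0) == 0):
        raise ValueError("a protein has no observed entries")
    frac = obs.mean()
    if tau is None:
        tau = svt_default_tau(m, n)
    if delta is None:
        delta = 1.2 / frac
    X_obs = np.where(obs, vals, 0.0)
    norm_obs = np.linalg.norm(X_obs)
    spectral = np.linalg.norm(X_obs, ord=2)
    k0 = int(np.ceil(tau / (delta * spectral))) if spectral > 0 else 0
    Y = k0 * delta * X_obs
    trace: list[float] = []
    Xhat = np.zeros_like(vals)
    converged = False
    initial_resid = 1.0
    it = 0
    effective_rank = 0
    for it in range(1, max_iter + 1):
        U, s, Vt = svd(Y, full_matrices=False)
        s_shrunk = np.maximum(s - tau, 0.0)
        effective_rank = int(np.count_nonzero(s_shrunk))
        Xhat = (U * s_shrunk) @ Vt
        resid_mat = np.where(obs, vals - Xhat, 0.0)
        resid = float(np.linalg.norm(resid_mat) / (norm_obs + 1e-30))
        trace.append(resid)
        if it == 1:
            initial_resid = max(resid, 1e-30)
        if resid < tol:
            converged = True
            break
        if resid > 10.0 * initial_resid:
            raise RuntimeError(
                f"SVT diverged: residual {resid:.3g} exceeds 10x initial "
                f"{initial_resid:.3g} (tau={tau:.3g}, delta={delta:.3g})"
            )
        Y = Y + delta * resid_mat
    if not converged:
        warnings.warn("SVT did not converge within max_iter", stacklevel=2)
    return LowRankFit(effective_rank, Xhat, it, trace, converged)


def impute_svt(
    matrix: AbundanceMatrix,
    tau: float | None = None,
    delta: float | None = None,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> ImputationResult:
    fit = svt_fit(matrix, tau, delta, tol, max_iter)
    return _wrap(matrix, fit, "SVT", {"tau": tau, "delta": delta})
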