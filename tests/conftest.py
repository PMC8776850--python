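from __future__ import annotations

import numpy as np
import pytest

from protimpute.core_data import IntensityMatrix, LogMatrix


def make_log(values, missing=None) -> LogMatrix:
    values = np.array(values, dtype=float)
    if missing is not None:
        values = values.copy()
        for i, j in missing:
            values[i, j] = np.nan
    m, n = values.shape
    return LogMatrix(values, [f"s{i}" for i in range(m)], [f"p{j}" for j in range(n)])


def make_intensity(values, missing=None) -> IntensityMatrix:
    values = np.array(values, dtype=float)
    if missing is not None:
        values = values.copy()
        for i, j in missing:
            values[i, j] = np.nan
    m, n = values.shape
    return IntensityMatrix(values, [f"s{i}" for i in range(m)], [f"p{j}" for j in range(n)])


def random_masked_log(m, n, miss_frac, seed, low_rank=None):
    """Random (optionally low-rank) log-space matrix with MCAR holes; every
    column keeps at least one observed entry."""
    rng = np.random.default_rng(seed)
    if low_rank:
        vals = rng.standard_normal((m, low_rank)) @ rng.standard_normal((low_rank, n))
    else:
        vals = rng.standard_normal((m, n))
    miss = rng.random((m, n)) < miss_frac
    for j in range(n):
        if miss[:, j].all():
            miss[rng.integers(m), j] = False
    shown = vals.copy()
    shown[miss] = np.nan
    return make_log(shown), vals, miss


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        yield
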