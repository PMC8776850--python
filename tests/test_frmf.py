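import numpy as np
import pytest

from protimpute.core_data import ExternalScores
from protimpute.frmf import (
    SimilarityContext,
    _fused_operator,
    build_similarity_external,
    build_similarity_self,
    fit_frmf,
    fit_rmf,
    frmf_gradients,
    frmf_objective,
    impute_from_factors,
)

from _oracles import pairwise_cosine_obs
from conftest import make_log, random_masked_log


def random_instance(seed, m=5, n=6, l=2):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((m, n))
    obs = rng.random((m, n)) > 0.3
    A = rng.standard_normal((m, l))
    S = rng.standard_normal((l, n))
    nbrs = [sorted(rng.choice([k for k in range(m) if k != i],
                              size=rng.integers(0, 3), replace=False).tolist())
            for i in range(m)]
    ctx = SimilarityContext(nbrs, [[0.5] * len(nb) for nb in nbrs], "self", 5)
    return X, obs, A, S, ctx


def fd_gradient_check(seed, mode):
    X, obs, A, S, ctx = random_instance(seed)
    Q = _fused_operator(ctx, mode)
    lam_A, lam_S, alpha = 0.1, 0.2, 0.7
    gA, gS = frmf_gradients(X, obs, A, S, lam_A, lam_S, alpha, Q)
    eps = 1e-6
    for grid, grad in ((A, gA), (S, gS)):
        num = np.zeros_like(grid)
        for idx in np.ndindex(grid.shape):
            plus, minus = grid.copy(), grid.copy()
            plus[idx] += eps
            minus[idx] -= eps
            if grid is A:
                fp = frmf_objective(X, obs, plus, S, lam_A, lam_S, alpha, Q)
                fm = frmf_objective(X, obs, minus, S, lam_A, lam_S, alpha, Q)
            else:
                fp = frmf_objective(X, obs, A, plus, lam_A, lam_S, alpha, Q)
                fm = frmf_objective(X, obs, A, minus, lam_A, lam_S, alpha, Q)
            num[idx] = (fp - fm) / (2 * eps)
        rel = np.abs(grad - num).max() / (np.abs(num).max() + 1e-30)
        assert rel < 1e-5


class TestSimilarity:
    def test_duplicate_rows_mutual_top_neighbors(self):
        vals = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [5.0, -1.0, 0.5]])
        ctx = build_similarity_self(make_log(vals), t=1)
        assert ctx.neighborhoods[0] == [1]
        assert ctx.neighborhoods[1] == [0]
        assert ctx.similarities[0][0] == pytest.approx(1.0)

    def test_orthogonal_rows_zero_similarity(self):
        vals = np.array([[1.0, 0.0], [0.0, 1.0]])
        ctx = build_similarity_self(make_log(vals), t=1)
        assert ctx.similarities[0][0] == pytest.approx(0.0)

    def test_matches_brute_force_all_pairs(self):
        mat, _, miss = random_masked_log(6, 8, 0.25, seed=13)
        ctx = build_similarity_self(mat, t=3)
        sim = pairwise_cosine_obs(np.where(miss, np.nan, mat.values), miss)
        for i in range(6):
            valid = [k for k in range(6) if k != i and not np.isnan(sim[i, k])]
            expected = sorted(valid, key=lambda k: (-sim[i, k], k))[:3]
            assert ctx.neighborhoods[i] == expected

    def test_external_identical_scores(self):
        sc = ExternalScores(
            np.array([[1.0, 2.0], [1.0, 2.0], [4.0, 0.0]]),
            ["a", "b", "c"], ["g1", "g2"],
        )
        ctx = build_similarity_external(sc, t=1)
        assert ctx.neighborhoods[0] == [1]
        assert ctx.similarities[0][0] == pytest.approx(1.0)

    def test_context_invariants(self):
        with pytest.raises(ValueError, match="neighbour itself"):
            SimilarityContext([[0]], [[1.0]], "self", 5)


class TestGradients:
    @pytest.mark.parametrize("seed", range(5))
    def test_pairwise_finite_differences(self, seed):
        fd_gradient_check(seed, "pairwise")

    @pytest.mark.parametrize("seed", [0, 1])
    def test_average_mode_finite_differences(self, seed):
        fd_gradient_check(seed, "average")


class TestFit:
    def test_exact_factorization_no_penalty(self):
        rng = np.random.default_rng(0)
        U, s, Vt = np.linalg.svd(rng.standard_normal((10, 12)), full_matrices=False)
        X = (U[:, :2] * s[:2]) @ Vt[:2]
        mat = make_log(X)
        model = fit_rmf(mat, 2, 0.0, 0.0, max_iter=5000, seed=0)
        rel = np.linalg.norm(model.A @ model.S - X) / np.linalg.norm(X)
        assert rel < 1e-3
        assert model.objective_trace[-1] <= model.objective_trace[0]

    def test_alpha_zero_trace_identical_to_rmf(self):
        mat, _, _ = random_masked_log(8, 10, 0.2, seed=21)
        ctx = build_similarity_self(mat, t=3)
        m0 = fit_rmf(mat, 2, 0.1, 0.1, seed=5, max_iter=300)
        m1 = fit_frmf(mat, ctx, 0.0, 2, 0.1, 0.1, seed=5, max_iter=300)
        assert m0.objective_trace == m1.objective_trace
        np.testing.assert_array_equal(m0.A, m1.A)

    def test_large_alpha_fuses_duplicate_samples(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((6, 8))
        vals[1] = vals[0]
        mat = make_log(vals)
        ctx = build_similarity_self(mat, t=2)
        model = fit_frmf(mat, ctx, 1e3, 2, 0.1, 0.1, max_iter=20000, seed=0)
        assert np.linalg.norm(model.A[0] - model.A[1]) < 1e-2

    def test_deterministic(self):
        mat, _, _ = random_masked_log(6, 9, 0.2, seed=2)
        a = fit_rmf(mat, 2, seed=3, max_iter=100)
        b = fit_rmf(mat, 2, seed=3, max_iter=100)
        np.testing.assert_array_equal(a.A, b.A)
        np.testing.assert_array_equal(a.S, b.S)

    def test_objective_nonincreasing_after_burnin(self):
        mat, _, _ = random_masked_log(10, 12, 0.25, seed=8)
        model = fit_rmf(mat, 3, 0.1, 0.1, seed=0, max_iter=1000)
        trace = np.array(model.objective_trace[5:])
        assert np.all(np.diff(trace) <= 1e-8 * np.abs(trace[:-1]) + 1e-12)


class TestImputeFromFactors:
    def test_complete_matrix_nothing_filled(self):
        mat = make_log(np.random.default_rng(0).standard_normal((5, 6)))
        model = fit_rmf(mat, 2, seed=0, max_iter=50)
        res = impute_from_factors(mat, model)
        np.testing.assert_array_equal(res.completed, mat.values)
        assert not res.filled.any()

    def test_filled_set_equals_missing_set(self):
        mat, _, miss = random_masked_log(7, 9, 0.2, seed=4)
        model = fit_rmf(mat, 2, seed=0, max_iter=200)
        res = impute_from_factors(mat, model)
        np.testing.assert_array_equal(res.filled, miss)
        np.testing.assert_array_equal(res.completed[~miss], mat.values[~miss])

    def test_recovery_on_exact_fixture(self):
        rng = np.random.default_rng(5)
        U, s, Vt = np.linalg.svd(rng.standard_normal((12, 15)), full_matrices=False)
        X = (U[:, :2] * s[:2]) @ Vt[:2]
        mat = make_log(X)
        from protimpute.simulate import inject_mcar

        inj, gt = inject_mcar(mat, 0.1, seed=6)
        model = fit_rmf(inj, 2, 0.0, 0.0, max_iter=10000, seed=0, tol=1e-12)
        res = impute_from_factors(inj, model)
        assert np.abs(res.at_omega(gt) - gt.true_values).max() < 1e-2
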