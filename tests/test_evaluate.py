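import numpy as np
import pytest

from protimpute.core_data import GroundTruth, ImputationResult
from protimpute.evaluate import (
    BenchmarkConfig,
    nrmse,
    protein_nrmse,
    rmse,
    run_benchmark,
    sor,
    sweep_parameters,
)
from protimpute.lowrank import impute_svdimpute
from protimpute.simulate import generate_synthetic, inject_mcar

from _oracles import direct_nrmse, direct_rmse, rank_sum_sor
from conftest import make_log


def result_for(truth, imputed_vals, shape=(3, 3)):
    completed = np.ones(shape)
    filled = np.zeros(shape, bool)
    for (i, j), v in zip(truth.omega, imputed_vals):
        completed[i, j] = v
        filled[i, j] = True
    return ImputationResult(completed, "t", {}, filled, truth.space_tag)


class TestRmseNrmse:
    def test_hand_example(self):
        gt = GroundTruth([(0, 0), (1, 1)], np.array([1.0, 3.0]), "log2")
        res = result_for(gt, [2.0, 2.0])
        assert rmse(gt, res) == pytest.approx(1.0)
        assert nrmse(gt, res) == pytest.approx(1.0)  # population variance 1

    def test_perfect_imputation_zero(self):
        gt = GroundTruth([(0, 0), (1, 1)], np.array([1.0, 3.0]), "log2")
        res = result_for(gt, [1.0, 3.0])
        assert rmse(gt, res) == 0.0
        assert nrmse(gt, res) == 0.0

    def test_single_element_rmse(self):
        gt = GroundTruth([(2, 2)], np.array([5.0]), "log2")
        res = result_for(gt, [8.0])
        assert rmse(gt, res) == pytest.approx(3.0)

    def test_mean_of_omega_gives_exactly_one(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(10, 3, size=37)
        gt = GroundTruth([(0, j) for j in range(37)], vals, "log2")
        res = result_for(gt, [vals.mean()] * 37, shape=(1, 37))
        assert nrmse(gt, res) == pytest.approx(1.0, abs=1e-12)

    def test_space_mismatch_errors(self):
        gt = GroundTruth([(0, 0), (1, 1)], np.array([1.0, 3.0]), "intensity")
        res = ImputationResult(np.ones((3, 3)), "t", {}, np.zeros((3, 3), bool), "log2")
        with pytest.raises(ValueError, match="space mismatch"):
            rmse(gt, res)

    def test_zero_variance_errors(self):
        gt = GroundTruth([(0, 0), (1, 1)], np.array([2.0, 2.0]), "log2")
        res = result_for(gt, [2.0, 2.0])
        with pytest.raises(ValueError, match="undefined"):
            nrmse(gt, res)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(5, 40))
        true = rng.normal(0, 2, size=k)
        imp = true + rng.normal(0, 1, size=k)
        gt = GroundTruth([(0, j) for j in range(k)], true, "log2")
        res = result_for(gt, imp, shape=(1, k))
        assert rmse(gt, res) == pytest.approx(direct_rmse(true, imp), rel=1e-12)
        assert nrmse(gt, res) == pytest.approx(direct_nrmse(true, imp), rel=1e-12)


class TestProteinNrmseAndSor:
    def test_single_entry_protein_excluded(self):
        gt = GroundTruth([(0, 0), (1, 0), (0, 1)], np.array([1.0, 3.0, 5.0]), "log2")
        res = result_for(gt, [2.0, 2.0, 5.0])
        pn = protein_nrmse(gt, res)
        assert 1 not in pn  # protein 1 has a single omega entry
        assert pn[0] == pytest.approx(1.0)

    def test_two_protein_hand_computation(self):
        gt = GroundTruth(
            [(0, 0), (1, 0), (0, 1), (1, 1)], np.array([1.0, 3.0, 0.0, 4.0]), "log2"
        )
        res = result_for(gt, [2.0, 2.0, 1.0, 3.0])
        pn = protein_nrmse(gt, res)
        assert pn[0] == pytest.approx(1.0)
        assert pn[1] == pytest.approx(0.5)

    def test_sor_hand_example_and_conservation(self):
        per = {"A": {0: 0.1, 1: 0.2}, "B": {0: 0.3, 1: 0.5}}
        s = sor(per)
        assert s == {"A": 2.0, "B": 4.0}
        # tie handling: both get 1.5
        per2 = {"A": {0: 0.1, 1: 0.2}, "B": {0: 0.1, 1: 0.5}}
        s2 = sor(per2)
        assert s2["A"] == 1.5 + 1 and s2["B"] == 1.5 + 2

    @pytest.mark.parametrize("seed", range(3))
    def test_sor_matches_rank_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        methods = ["m1", "m2", "m3", "m4"]
        proteins = range(12)
        per = {
            mth: {j: float(rng.choice([0.1, 0.2, 0.3, 0.5, 0.8])) for j in proteins}
            for mth in methods
        }
        ours = sor(per)
        oracle = rank_sum_sor(per)
        for mth in methods:
            assert ours[mth] == pytest.approx(oracle[mth])
        # rank-sum conservation: P * M(M+1)/2
        assert sum(ours.values()) == pytest.approx(12 * 4 * 5 / 2)

    def test_misaligned_sets_error(self):
        with pytest.raises(ValueError, match="misaligned"):
            sor({"A": {0: 1.0}, "B": {1: 1.0}})


class TestBenchmark:
    def test_cardinality_and_determinism(self):
        cfg = BenchmarkConfig(
            setting=1, mechanism="MCAR", rates=(0.1, 0.3), trials=2, seed=3,
            m=15, n=60, methods=(("Mean", {}), ("Min/2", {})),
        )
        table, agg = run_benchmark(cfg)
        assert len(table) == 8  # 2 methods x 2 rates x 2 trials
        assert len(agg) == 4
        table2, _ = run_benchmark(cfg)
        np.testing.assert_array_equal(
            table[["nrmse", "rmse", "sor"]].to_numpy(),
            table2[["nrmse", "rmse", "sor"]].to_numpy(),
        )

    def test_sor_conservation_per_cell(self):
        cfg = BenchmarkConfig(
            setting=1, mechanism="MCAR", rates=(0.2,), trials=1, seed=1,
            m=15, n=60, methods=(("Mean", {}), ("Min/2", {}), ("swKNN", {"k": 3})),
        )
        table, _ = run_benchmark(cfg)
        sor_sum = table["sor"].sum()
        # sum over methods = P * M(M+1)/2 for some shared protein count P
        M = 3
        assert sor_sum % (M * (M + 1) / 2) == pytest.approx(0.0)

    def test_setting2_runs(self):
        cfg = BenchmarkConfig(
            setting=2, rates=(0.1,), trials=1, seed=2, m=20, n=80,
            methods=(("Mean", {}),),
        )
        table, _ = run_benchmark(cfg)
        assert table["mechanism"].iloc[0] == "authentic"
        assert np.isfinite(table["nrmse"].iloc[0])

    def test_method_failure_recorded_not_fatal(self):
        cfg = BenchmarkConfig(
            setting=1, mechanism="MCAR", rates=(0.2,), trials=1, seed=1,
            m=15, n=60,
            methods=(("Mean", {}), ("NIPALS", {"rank": 999})),
        )
        table, _ = run_benchmark(cfg)
        bad = table[table["method"] == "NIPALS"]
        assert bad["error"].iloc[0] != ""
        assert np.isnan(bad["nrmse"].iloc[0])
        assert np.isfinite(table[table["method"] == "Mean"]["nrmse"]).all()

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ValueError, match="unknown config"):
            BenchmarkConfig.from_dict({"bogus": 1})


class TestSweep:
    def test_singleton_grid(self):
        truth = generate_synthetic(m=15, n=60, k=2, seed=0)
        inj, gt = inject_mcar(truth.complete, 0.1, seed=1)
        from protimpute.preprocess import log2_transform

        logm = log2_transform(inj)
        gt_log = GroundTruth(list(gt.omega), np.log2(gt.true_values), "log2")
        best, table = sweep_parameters(
            impute_svdimpute, [{"rank": 2}], logm, gt_log
        )
        assert best == {"rank": 2}
        assert len(table) == 1

    def test_oracle_rank_selected(self):
        rng = np.random.default_rng(4)
        vals = rng.standard_normal((20, 30, )) * 0.01 + (
            rng.standard_normal((20, 3)) @ rng.standard_normal((3, 30))
        )
        inj, gt = inject_mcar(make_log(vals), 0.15, seed=5)
        grid = [{"rank": r} for r in (1, 2, 3)]
        best, table = sweep_parameters(impute_svdimpute, grid, inj, gt)
        assert best == {"rank": 3}
        assert len(table) == 3

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError, match="empty"):
            sweep_parameters(impute_svdimpute, [], None, None)
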