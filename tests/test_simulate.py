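import numpy as np
import pytest

from protimpute.simulate import (
    MaskSpec,
    generate_clustered,
    generate_synthetic,
    inject_mcar,
    inject_mix,
    inject_mnar,
    mask_clustered,
    mask_setting2,
)

from conftest import make_intensity


class TestGenerate:
    def test_zero_noise_is_exact_product(self):
        t = generate_synthetic(m=10, n=50, k=3, noise_sigma=0.0, intensity_scale=100.0, seed=4)
        np.testing.assert_allclose(t.complete.values, t.A_true @ t.S_true * 100.0)

    def test_marker_columns_single_archetype(self):
        t = generate_synthetic(m=10, n=60, k=3, marker_fraction=0.1, seed=2)
        for a, idx in enumerate(t.marker_sets):
            assert len(idx) == 6
            for j in idx:
                nz = np.nonzero(t.S_true[:, j])[0]
                assert list(nz) == [a]

    def test_deterministic(self):
        a = generate_synthetic(m=8, n=40, k=2, seed=7)
        b = generate_synthetic(m=8, n=40, k=2, seed=7)
        np.testing.assert_array_equal(a.complete.values, b.complete.values)

    def test_mixing_rows_on_simplex(self):
        t = generate_synthetic(m=12, n=40, k=3, seed=1)
        np.testing.assert_allclose(t.A_true.sum(axis=1), 1.0)
        assert (t.A_true >= 0).all()

    def test_rank_k_svd_captures_noiseless_variance(self):
        t = generate_synthetic(m=20, n=80, k=3, noise_sigma=0.0, seed=3)
        s = np.linalg.svd(t.complete.values, compute_uv=False)
        assert np.sum(s[:3] ** 2) / np.sum(s**2) >= 0.9999

    def test_parameter_domain(self):
        with pytest.raises(ValueError):
            generate_synthetic(k=1)
        with pytest.raises(ValueError):
            generate_synthetic(m=3, k=3)


class TestInjectMcar:
    def test_exact_count(self):
        t = generate_synthetic(m=10, n=31, k=3, seed=0)
        mat = make_intensity(t.complete.values[:, :10])
        out, gt = inject_mcar(mat, 0.5, seed=1)
        assert out.missing.sum() == 50
        assert len(gt) == 50

    def test_tiny_alpha_errors(self):
        mat = make_intensity(np.full((3, 3), 2.0))
        with pytest.raises(ValueError, match="empty evaluation"):
            inject_mcar(mat, 0.01, seed=0)

    def test_partition_and_truth_values(self):
        mat = make_intensity(np.arange(1.0, 26.0).reshape(5, 5))
        out, gt = inject_mcar(mat, 0.2, seed=3)
        assert out.missing.sum() + (~out.missing).sum() == 25
        for (i, j), v in zip(gt.omega, gt.true_values):
            assert mat.values[i, j] == v
            assert out.missing[i, j]

    def test_deterministic(self):
        mat = make_intensity(np.arange(1.0, 101.0).reshape(10, 10))
        a = inject_mcar(mat, 0.3, seed=5)[0]
        b = inject_mcar(mat, 0.3, seed=5)[0]
        np.testing.assert_array_equal(a.missing, b.missing)


class TestInjectMnar:
    def test_quantile_rule_2x2(self):
        mat = make_intensity([[1.0, 2.0], [3.0, 4.0]])
        out, gt = inject_mnar(mat, 0.25)
        assert out.missing.sum() == 1
        assert out.missing[0, 0]
        assert gt.true_values[0] == 1.0

    def test_separation_property(self):
        rng = np.random.default_rng(2)
        mat = make_intensity(np.exp(rng.normal(5, 2, size=(8, 12))))
        out, gt = inject_mnar(mat, 0.3)
        assert gt.true_values.max() <= np.nanmin(out.values)

    def test_zero_alpha_errors(self):
        mat = make_intensity([[1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(ValueError, match="empty evaluation"):
            inject_mnar(mat, 0.0)


class TestInjectMix:
    def test_count_arithmetic(self):
        mat = make_intensity(np.arange(1.0, 101.0).reshape(10, 10))
        out, _ = inject_mix(mat, 0.3, 0.4, seed=0)
        assert out.missing.sum() == round(0.4 * 30) + round(0.6 * 30)

    def test_beta_one_equals_mnar(self):
        mat = make_intensity(np.arange(1.0, 101.0).reshape(10, 10))
        a = inject_mix(mat, 0.2, 1.0, seed=9)[0]
        b = inject_mnar(mat, 0.2)[0]
        np.testing.assert_array_equal(a.missing, b.missing)

    def test_beta_zero_is_pure_mcar_count(self):
        mat = make_intensity(np.arange(1.0, 101.0).reshape(10, 10))
        out, _ = inject_mix(mat, 0.2, 0.0, seed=9)
        assert out.missing.sum() == 20


class TestMaskSetting2:
    @staticmethod
    def _authentic(seed=0, m=20, n=30):
        t = generate_synthetic(m=m, n=n, k=2, seed=seed)
        auth, _ = inject_mix(t.complete, 0.25, 0.5, seed=seed + 1)
        return auth

    def test_global_fraction_within_one_entry(self):
        auth = self._authentic()
        total_obs = int((~auth.missing).sum())
        out, gt = mask_setting2(auth, MaskSpec(0.2, seed=3))
        masked = len(gt)
        assert abs(masked - round(0.2 * total_obs)) <= 1
        # authentic NAs untouched, only observed entries masked
        assert (out.missing & auth.missing).sum() == auth.missing.sum()
        for (i, j) in gt.omega:
            assert not auth.missing[i, j]

    def test_zero_rate_protein_unmasked(self):
        auth = self._authentic(seed=5)
        rates = auth.missing.mean(axis=0)
        zero = np.where(rates == 0)[0]
        out, gt = mask_setting2(auth, MaskSpec(0.15, seed=1))
        masked_cols = {j for _, j in gt.omega}
        assert not (set(zero.tolist()) & masked_cols)

    def test_proportional_allocation_ratio(self):
        # two proteins, equal observed counts, authentic rates 0.1 vs 0.4
        m = 40
        vals = np.full((m, 3), 100.0)
        vals[:4, 0] = np.nan  # rate 0.1
        vals[:16, 1] = np.nan  # rate 0.4
        vals[:4, 2] = np.nan
        mat = make_intensity(vals)
        out, gt = mask_setting2(mat, MaskSpec(0.2, seed=2))
        counts = np.bincount([j for _, j in gt.omega], minlength=3)
        # proportional rule: counts scale with r_p * obs_p
        assert counts[1] > counts[0]
        expected_ratio = (0.4 * 24) / (0.1 * 36)
        assert counts[1] / max(counts[0], 1) == pytest.approx(expected_ratio, rel=0.5)

    def test_requires_authentic_missingness(self):
        mat = make_intensity(np.full((5, 5), 3.0))
        with pytest.raises(ValueError, match="authentic"):
            mask_setting2(mat, MaskSpec(0.2, seed=0))


class TestClustered:
    def test_cluster_labels_and_masking(self):
        t = generate_clustered(m=20, n=60, k=2, seed=0)
        assert set(t.clusters.tolist()) == {0, 1}
        inj, gt = mask_clustered(t, 0.2, seed=1)
        assert len(gt) > 0
        assert 0.05 < inj.missing.mean() < 0.4
        # every protein keeps at least 2 observed entries
        assert ((~inj.missing).sum(axis=0) >= 2).all()


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), alpha=st.floats(0.05, 0.5))
def test_mcar_count_partition_and_truth_properties(seed, alpha):
    rng = np.random.default_rng(seed)
    vals = np.exp(rng.normal(5, 1, size=(8, 12)))
    mat = make_intensity(vals)
    out, gt = inject_mcar(mat, alpha, seed=seed)
    assert out.missing.sum() == round(alpha * 96) == len(gt)
    for (i, j), v in zip(gt.omega, gt.true_values):
        assert v == vals[i, j]
    # every protein keeps at least one observed entry
    assert (~out.missing).any(axis=0).all()
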