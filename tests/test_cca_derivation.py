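import numpy as np
import pytest

from conftest import make_stride
from gaitlen import build_matrices, cca, generate_derivation_dataset, rank_parameters
from gaitlen.cca_derivation import X2_LABELS, stride_intervals
from gaitlen.marker_kinematics import KinematicSeries


def _noise_kin(n, seed=0, fs=100.0):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    return KinematicSeries(t=t, velocity=rng.standard_normal((n, 3)),
                          acceleration=rng.standard_normal((n, 3)))


class TestBuildMatrices:
    def test_constant_k_from_exact_tenth_root(self):
        # d_ref = 1.2 with a_r = 1024 gives K = 1.2 / 2 = 0.6
        strides = [make_stride(F=1.0, a_max=1026, a_min=2, d_ref=1.2) for _ in range(5)]
        intervals = [(i * 1.0, (i + 1) * 1.0) for i in range(5)]
        mats = build_matrices(strides, intervals, _noise_kin(500))
        np.testing.assert_allclose(mats.X1[:, 0], 0.6)

    def test_column_count_is_twenty(self):
        assert len(X2_LABELS) == 20
        strides, intervals, kin = generate_derivation_dataset(seed=1, n_strides=50)
        mats = build_matrices(strides, intervals, kin)
        assert mats.X2.shape == (50, 20)

    def test_constant_speed_duration_column_nearly_constant(self):
        strides, intervals, kin = generate_derivation_dataset(
            seed=2, n_strides=50, freq_jitter=0.0, length_noise_sd=0.0
        )
        mats = build_matrices(strides, intervals, kin)
        dur = mats.X2[:, list(X2_LABELS).index("stride_duration")]
        assert np.var(dur) < 1e-6 * np.mean(dur)

    def test_zero_range_strides_dropped(self):
        strides = [make_stride(a_max=8, a_min=8, d_ref=1.0)] + [
            make_stride(a_max=12, a_min=8, d_ref=1.0) for _ in range(4)
        ]
        intervals = [(i * 1.0, (i + 1) * 1.0) for i in range(5)]
        mats = build_matrices(strides, intervals, _noise_kin(500))
        assert mats.X1.shape[0] == 4 and mats.n_dropped == 1


class TestCca:
    def test_perfect_linear_dependence_gives_unit_correlation(self, rng):
        X2 = rng.standard_normal((200, 4))
        X1 = X2 @ np.array([0.5, -1.0, 0.2, 0.0])
        res = cca(X1.reshape(-1, 1), X2)
        assert res.correlations[0] == pytest.approx(1.0, abs=1e-8)

    def test_independent_noise_gives_near_zero_correlation(self):
        rng = np.random.default_rng(77)
        res = cca(rng.standard_normal((10000, 1)), rng.standard_normal((10000, 2)))
        assert res.correlations[0] < 0.05

    def test_first_correlation_matches_regression_oracle(self):
        import statsmodels.api as sm

        for seed in range(20):
            rng = np.random.default_rng(seed)
            X2 = rng.standard_normal((120, 5))
            y = X2 @ rng.standard_normal(5) + rng.standard_normal(120)
            res = cca(y.reshape(-1, 1), X2)
            r = np.sqrt(sm.OLS(y, sm.add_constant(X2)).fit().rsquared)
            assert res.correlations[0] == pytest.approx(r, abs=1e-8)

    def test_correlations_sorted_in_unit_interval(self, rng):
        X1 = rng.standard_normal((300, 3))
        X2 = rng.standard_normal((300, 6)) + 0.3 * np.tile(X1, (1, 2))
        res = cca(X1, X2)
        assert np.all(res.correlations >= 0) and np.all(res.correlations <= 1)
        assert np.all(np.diff(res.correlations) <= 1e-12)

    def test_invariant_to_affine_transform_of_x2(self, rng):
        X1 = rng.standard_normal((250, 2))
        X2 = rng.standard_normal((250, 4)) + 0.5 * np.hstack([X1, X1])
        base = cca(X1, X2).correlations
        for _ in range(5):
            A = rng.standard_normal((4, 4)) + 4 * np.eye(4)
            b = rng.standard_normal(4)
            np.testing.assert_allclose(cca(X1, X2 @ A + b).correlations, base, atol=1e-8)

    def test_zero_variance_column_dropped(self, rng):
        X2 = rng.standard_normal((100, 3))
        X2[:, 1] = 5.0
        res = cca(rng.standard_normal(100), X2, labels=("a", "b", "c"))
        assert res.dropped_labels == ("b",)
        assert res.labels == ("a", "c")

    def test_exactly_collinear_columns_rejected(self, rng):
        X2 = rng.standard_normal((100, 3))
        X2[:, 2] = 2 * X2[:, 0]
        with pytest.raises(ValueError, match="dependent"):
            cca(rng.standard_normal(100), X2)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="rows"):
            cca(rng.standard_normal(5), rng.standard_normal((5, 5)))


class TestRankParameters:
    def test_frequency_driven_constant_ranks_frequency_first(self):
        strides, intervals, kin = generate_derivation_dataset(seed=5)
        mats = build_matrices(strides, intervals, kin)
        res = cca(mats.X1, mats.X2, mats.labels)
        ranking = rank_parameters(res)
        assert ranking[0][0] == "stride_frequency"

    def test_standardization_makes_ranking_scale_free(self, rng):
        X2 = rng.standard_normal((300, 3))
        y = X2 @ np.array([1.0, 0.3, 0.1]) + 0.1 * rng.standard_normal(300)
        r1 = [l for l, _ in rank_parameters(cca(y, X2, labels=("a", "b", "c")))]
        X2s = X2 * np.array([100.0, 0.01, 1.0])
        r2 = [l for l, _ in rank_parameters(cca(y, X2s, labels=("a", "b", "c")))]
        assert r1 == r2

    def test_stride_intervals_helper(self):
        s = make_stride()
        s.start_idx, s.end_idx = 2, 8
        t = np.arange(10) * 0.1
        assert stride_intervals([s], t) == [(pytest.approx(0.2), pytest.approx(0.8))]
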