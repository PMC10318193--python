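"""Scale-and-shift convolution: decomposition, folding, counting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import correlate2d

from ssmri.exceptions import ConfigurationError, InvalidKernelError, ShapeError
from ssmri.ssconv import (
    ConvFilterBank,
    RowFactors,
    SSFactors,
    advanced_features,
    basic_features,
    conv2d,
    count_trainable,
    fold_row,
    fold_ss,
    load_bank,
    rft_forward,
    save_bank,
    ss_forward,
)


class TestBasicFeatures:
    def test_one_by_one_kernel_is_affine_map(self, rng):
        u = rng.normal(size=(6, 7))
        out = basic_features(u, np.array([[2.0]]), 0.5)
        np.testing.assert_allclose(out, 2.0 * u + 0.5)

    def test_delta_kernel_is_identity(self, rng):
        u = rng.normal(size=(8, 8))
        delta = np.zeros((3, 3))
        delta[1, 1] = 1.0
        np.testing.assert_allclose(basic_features(u, delta, 0.0), u)

    def test_box_kernel_matches_sliding_window_sum(self):
        # independent brute-force oracle over all positions, zero padding
        u = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = basic_features(u, np.ones((3, 3)), 0.0)
        np.testing.assert_allclose(out, [[10.0, 10.0], [10.0, 10.0]])

    def test_matches_scipy_correlate(self, rng):
        u = rng.normal(size=(9, 11))
        k = rng.normal(size=(3, 5))
        ref = correlate2d(u, k, mode="same") + 0.25
        np.testing.assert_allclose(basic_features(u, k, 0.25), ref, atol=1e-12)

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(InvalidKernelError):
            basic_features(rng.normal(size=(4, 4)), np.ones((2, 2)), 0.0)

    def test_nonfinite_input_rejected(self):
        u = np.full((4, 4), np.nan)
        with pytest.raises(ValueError):
            conv2d(u[None], np.ones((1, 1, 1, 1)))


class TestAdvancedFeatures:
    def test_single_kernel_filter_equals_basic(self, rng):
        bank = ConvFilterBank(rng.normal(size=(2, 1, 3, 3)), rng.normal(size=2))
        x = rng.normal(size=(1, 6, 6))
        adv = advanced_features(x, bank, 0)
        basic = basic_features(x[0], bank.weights[0, 0], bank.bias[0])
        np.testing.assert_array_equal(adv, basic)

    def test_opposite_kernels_cancel(self, rng):
        k = rng.normal(size=(3, 3))
        bank = ConvFilterBank(np.stack([np.stack([k, -k])]), np.zeros(1))
        u = rng.normal(size=(6, 6))
        x = np.stack([u, u])
        np.testing.assert_allclose(advanced_features(x, bank, 0), 0.0, atol=1e-12)

    def test_equals_per_kernel_loop_exactly(self, small_bank, small_input):
        """Decomposition: the filter map is the exact sum of basic features."""
        m = small_bank.n_channels
        for f in range(small_bank.n_filters):
            oracle = basic_features(
                small_input[0], small_bank.weights[f, 0], small_bank.bias[f] / m
            )
            for ch in range(1, m):
                oracle = oracle + basic_features(
                    small_input[ch],
                    small_bank.weights[f, ch],
                    small_bank.bias[f] / m,
                )
            np.testing.assert_array_equal(
                advanced_features(small_input, small_bank, f), oracle
            )

    def test_channel_mismatch_raises(self, small_bank, rng):
        with pytest.raises(ShapeError):
            advanced_features(rng.normal(size=(2, 5, 5)), small_bank, 0)


class TestSSForwardAndFold:
    def test_identity_factors_reproduce_plain_conv(self, small_bank, small_input):
        ident = SSFactors.identity(4, 3)
        plain = conv2d(small_input, small_bank.weights, small_bank.bias)
        np.testing.assert_allclose(
            ss_forward(small_input, small_bank, ident), plain, atol=1e-10
        )

    def test_uniform_scale_is_homogeneous(self, small_input, rng):
        bank = ConvFilterBank(rng.normal(size=(4, 3, 3, 3)), np.zeros(4))
        doubled = SSFactors(2 * np.ones((4, 3)), np.zeros((4, 3)))
        plain = conv2d(small_input, bank.weights, bank.bias)
        np.testing.assert_allclose(
            ss_forward(small_input, bank, doubled), 2.0 * plain, atol=1e-10
        )

    def test_fold_identity_returns_equal_bank(self, small_bank):
        folded = fold_ss(small_bank, SSFactors.identity(4, 3))
        np.testing.assert_array_equal(folded.weights, small_bank.weights)
        np.testing.assert_array_equal(folded.bias, small_bank.bias)

    def test_fold_scales_kernel_elementwise(self):
        bank = ConvFilterBank(np.ones((1, 1, 3, 3)), np.zeros(1))
        f = SSFactors(np.array([[3.0]]), np.array([[0.0]]))
        np.testing.assert_array_equal(fold_ss(bank, f).weights, 3.0 * np.ones((1, 1, 3, 3)))

    def test_fold_does_not_mutate_inputs(self, small_bank, random_factors):
        w0 = small_bank.weights.copy()
        s0 = random_factors.scale.copy()
        fold_ss(small_bank, random_factors)
        np.testing.assert_array_equal(small_bank.weights, w0)
        np.testing.assert_array_equal(random_factors.scale, s0)

    def test_fold_bias_aggregates_shifts(self, small_bank, random_factors):
        folded = fold_ss(small_bank, random_factors)
        np.testing.assert_allclose(
            folded.bias, small_bank.bias + random_factors.shift.sum(axis=1)
        )

    @settings(max_examples=30, deadline=None)
    @given(
        n=st.integers(1, 8),
        m=st.integers(1, 16),
        k=st.sampled_from([1, 3, 5]),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_fold_equivalence_random_instances(self, n, m, k, seed):
        """ss_forward equals plain conv with the folded bank (two routes)."""
        r = np.random.default_rng(seed)
        bank = ConvFilterBank(r.normal(size=(n, m, k, k)), r.normal(size=n))
        factors = SSFactors(r.normal(size=(n, m)), r.normal(size=(n, m)))
        x = r.normal(size=(m, 8, 8))
        folded = fold_ss(bank, factors)
        np.testing.assert_allclose(
            ss_forward(x, bank, factors),
            conv2d(x, folded.weights, folded.bias),
            atol=1e-10,
        )

    def test_shape_mismatch_is_configuration_error(self, small_bank):
        bad = SSFactors(np.ones((2, 2)), np.zeros((2, 2)))
        with pytest.raises(ConfigurationError):
            fold_ss(small_bank, bad)
        with pytest.raises(ConfigurationError):
            ss_forward(np.zeros((3, 5, 5)), small_bank, bad)


class TestRowForward:
    def test_identity_row_factors_reproduce_plain_conv(self, small_bank, small_input):
        ident = RowFactors.identity(4, 3, 3)
        plain = conv2d(small_input, small_bank.weights, small_bank.bias)
        np.testing.assert_allclose(
            rft_forward(small_input, small_bank, ident), plain, atol=1e-10
        )

    def test_shared_row_scale_degenerates_to_kernel_scale(
        self, small_bank, small_input, rng
    ):
        s = rng.normal(size=(4, 3))
        row = RowFactors(np.repeat(s[:, :, None], 3, axis=2), np.zeros((4, 3)))
        ss = SSFactors(s, np.zeros((4, 3)))
        np.testing.assert_allclose(
            rft_forward(small_input, small_bank, row),
            ss_forward(small_input, small_bank, ss),
            atol=1e-10,
        )

    def test_matches_explicit_row_fold_oracle(
        self, small_bank, small_input, random_row_factors
    ):
        w = small_bank.weights.copy()
        for n in range(4):
            for m in range(3):
                for r in range(3):
                    w[n, m, r, :] *= random_row_factors.row_scale[n, m, r]
        b = small_bank.bias + random_row_factors.shift.sum(axis=1)
        np.testing.assert_allclose(
            rft_forward(small_input, small_bank, random_row_factors),
            conv2d(small_input, w, b),
            atol=1e-10,
        )

    def test_fold_row_matches_rft_forward(
        self, small_bank, small_input, random_row_factors
    ):
        folded = fold_row(small_bank, random_row_factors)
        np.testing.assert_allclose(
            rft_forward(small_input, small_bank, random_row_factors),
            conv2d(small_input, folded.weights, folded.bias),
            atol=1e-10,
        )


class TestCountTrainable:
    @pytest.mark.parametrize(
        "strategy,expected",
        [("pt", 0), ("dt", 37), ("ft", 37), ("lft", 8), ("rft", 16)],
    )
    def test_single_layer_counts(self, strategy, expected):
        assert count_trainable(strategy, [(1, 4, 3, 3)]) == expected

    def test_multi_layer_sums(self):
        shapes = [(8, 2, 3, 3), (16, 8, 3, 3)]
        assert count_trainable("ft", shapes) == 8 * 19 + 16 * 73
        assert count_trainable("lft", shapes) == 2 * (8 * 2 + 16 * 8)

    @settings(max_examples=50, deadline=None)
    @given(
        n=st.integers(1, 64),
        m=st.integers(1, 64),
        k=st.sampled_from([3, 5, 7]),
    )
    def test_ordering_lft_below_rft_below_ft(self, n, m, k):
        shapes = [(n, m, k, k)]
        assert (
            count_trainable("lft", shapes)
            < count_trainable("rft", shapes)
            < count_trainable("ft", shapes)
        )

    def test_unknown_strategy_raises(self):
        with pytest.raises(ConfigurationError):
            count_trainable("adapter", [(1, 1, 3, 3)])


class TestValidationAndSerialization:
    def test_even_kernel_bank_rejected(self, rng):
        with pytest.raises(InvalidKernelError):
            ConvFilterBank(rng.normal(size=(2, 2, 4, 4)), np.zeros(2))

    def test_bias_length_checked(self, rng):
        with pytest.raises(ShapeError):
            ConvFilterBank(rng.normal(size=(2, 2, 3, 3)), np.zeros(3))

    def test_bank_round_trips_through_hdf5(self, tmp_path, small_bank, random_factors):
        import h5py

        path = tmp_path / "bank.h5"
        with h5py.File(path, "w") as fh:
            save_bank(fh, small_bank, random_factors)
        with h5py.File(path, "r") as fh:
            assert fh.attrs["layout"] == "NMHW"
            bank, factors = load_bank(fh)
        np.testing.assert_array_equal(bank.weights, small_bank.weights)
        np.testing.assert_array_equal(factors.scale, random_factors.scale)
        np.testing.assert_array_equal(factors.shift, random_factors.shift)

    def test_float32_dtype_preserved(self, rng):
        bank = ConvFilterBank(
            rng.normal(size=(2, 2, 3, 3)).astype(np.float32), np.zeros(2)
        )
        assert bank.weights.dtype == np.float32
        assert bank.bias.dtype == np.float32
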