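"""Layer-level mathematics: shapes, conv, BN, dropout, pooling, softmax."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from msnet import errors, nn_ops
from msnet.nn_ops import (
    BNState,
    ConvSpec,
    DropoutSpec,
    PoolSpec,
    batch_norm,
    conv2d,
    conv_out_shape,
    dropout,
    fc_forward,
    pool_deterministic,
    relu,
    softmax,
    stochastic_pool_expect,
    stochastic_pool_probs,
    stochastic_pool_sample,
)


class TestConvShapes:
    @pytest.mark.parametrize(
        "in_size,kernel,stride,padding,expected",
        [
            (5, 3, 1, 0, 3),
            (5, 3, 1, 1, 5),
            (256, 3, 2, "same", 128),
            (7, 3, 2, "same", 4),
        ],
    )
    def test_output_formula(self, in_size, kernel, stride, padding, expected):
        spec = ConvSpec(kernel, kernel, 1, 1, stride, padding)
        assert conv_out_shape(spec, in_size, in_size) == (expected, expected)

    def test_degenerate_output_rejected(self):
        with pytest.raises(errors.NonPositiveOutput):
            conv_out_shape(ConvSpec(7, 7, 1, 1, 1, 0), 3, 3)


class TestConv2d:
    def test_one_by_one_identity_filter(self, rng):
        x = rng.random((5, 5, 1))
        spec = ConvSpec(1, 1, 1, 1, 1, 0)
        out = conv2d(x, np.ones((1, 1, 1, 1)), spec)
        np.testing.assert_allclose(out, x)

    def test_linearity_zero_input(self):
        spec = ConvSpec(3, 3, 2, 4, 1, "same")
        out = conv2d(np.zeros((6, 6, 2)), np.ones((4, 3, 3, 2)), spec)
        assert out.shape == (6, 6, 4)
        np.testing.assert_array_equal(out, 0.0)

    def test_box_filter_interior_sum(self):
        spec = ConvSpec(3, 3, 1, 1, 1, "same")
        out = conv2d(np.full((5, 5), 2.0), np.ones((1, 3, 3, 1)), spec)
        assert out[2, 2, 0] == pytest.approx(18.0)  # 9 * 2 on the interior

    def test_channel_mismatch(self):
        with pytest.raises(errors.ChannelMismatch):
            conv2d(np.zeros((4, 4, 2)), np.ones((1, 3, 3, 3)), ConvSpec())


class TestReluSoftmaxFc:
    def test_relu_clamps_and_is_idempotent(self):
        x = np.array([-1.0, 0.0, 2.0])
        np.testing.assert_array_equal(relu(x), [0.0, 0.0, 2.0])
        np.testing.assert_array_equal(relu(relu(x)), relu(x))

    def test_softmax_symmetry_shift_invariance_stability(self):
        np.testing.assert_allclose(softmax(np.zeros(2)), [0.5, 0.5])
        z = np.array([0.3, -1.2, 4.0])
        np.testing.assert_allclose(softmax(z + 100.0), softmax(z), atol=1e-12)
        big = softmax(np.array([1000.0, 0.0]))
        assert np.isfinite(big).all() and big[0] == pytest.approx(1.0)

    def test_fc_forward_affine(self):
        np.testing.assert_array_equal(
            fc_forward(np.array([2.0, 3.0]), np.array([[1.0, 1.0]]), np.zeros(1)), [5.0]
        )
        np.testing.assert_array_equal(
            fc_forward(np.array([2.0, 3.0]), np.zeros((2, 2)), np.array([1.0, -1.0])),
            [1.0, -1.0],
        )
        with pytest.raises(errors.DimensionMismatch):
            fc_forward(np.zeros(3), np.zeros((2, 2)), np.zeros(2))


class TestBatchNorm:
    def test_hand_evaluated_standardization(self):
        state = BNState.init(1, epsilon=1e-12)
        out = batch_norm(np.array([1.0, 3.0]), state, "train")
        np.testing.assert_allclose(out, [-1.0, 1.0], atol=1e-5)

    def test_affine_scale_and_offset(self):
        state = BNState.init(1, epsilon=1e-12)
        state.scale[:] = 2.0
        state.offset[:] = 1.0
        out = batch_norm(np.array([1.0, 3.0]), state, "train")
        np.testing.assert_allclose(out, [-1.0, 3.0], atol=1e-5)

    def test_constant_batch_maps_to_offset(self):
        state = BNState.init(1)
        state.offset[:] = 0.7
        out = batch_norm(np.array([4.0, 4.0]), state, "train")
        np.testing.assert_allclose(out, [0.7, 0.7], atol=1e-2)

    def test_single_sample_train_rejected(self):
        with pytest.raises(errors.BatchTooSmall):
            batch_norm(np.array([1.0]), BNState.init(1), "train")

    def test_train_output_standardized_per_channel(self, rng):
        # pre-affine (gamma=1, beta=0) moments are ~0/1 across the batch
        state = BNState.init(3)
        batch = rng.normal(5.0, 2.0, size=(64, 4, 3))
        out = batch_norm(batch, state, "train")
        np.testing.assert_allclose(out.mean(axis=(0, 1)), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.var(axis=(0, 1)), 1.0, atol=1e-4)

    def test_inference_uses_running_moments(self, rng):
        state = BNState.init(1, momentum=1.0)  # running moments = last batch
        batch = rng.normal(2.0, 3.0, size=(128,))
        batch_norm(batch, state, "train")
        out = batch_norm(np.array([state.running_mean[0]]), state, "inference")
        np.testing.assert_allclose(out, [0.0], atol=1e-9)


class TestDropout:
    def test_identity_cases(self, rng, gradient_image):
        spec = DropoutSpec(0.0, "train")
        np.testing.assert_array_equal(dropout(gradient_image, spec, rng), gradient_image)
        spec = DropoutSpec(0.5, "inference")
        np.testing.assert_array_equal(dropout(gradient_image, spec, rng), gradient_image)

    def test_expectation_preserved(self):
        # inverted dropout: E[out] == input
        rng = np.random.default_rng(0)
        x = np.full(20000, 3.0)
        out = dropout(x, DropoutSpec(0.5, "train"), rng)
        assert out.mean() == pytest.approx(3.0, rel=0.02)
        assert set(np.unique(out)) == {0.0, 6.0}

    def test_seeded_reproducibility(self, gradient_image):
        a = dropout(gradient_image, DropoutSpec(0.3), np.random.default_rng(9))
        b = dropout(gradient_image, DropoutSpec(0.3), np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)


class TestDeterministicPooling:
    def test_region_examples(self):
        region = np.array([[1.0, 3.0], [2.0, 6.0]])
        out_max = pool_deterministic(region, PoolSpec(2, 2, "max"))
        out_avg = pool_deterministic(region, PoolSpec(2, 2, "average"))
        assert out_max[0, 0] == 6.0
        assert out_avg[0, 0] == 3.0

    def test_constant_map_invariant_under_both_modes(self):
        const = np.full((9, 9), 0.4)
        for mode in ("max", "average"):
            out = pool_deterministic(const, PoolSpec(3, 2, mode))
            assert out.shape == (5, 5)
            np.testing.assert_allclose(out, 0.4)

    def test_padding_excluded_from_average_denominator(self):
        # 'same' 3x3/s2 pooling of a 4x4 ones map: every window average is 1
        out = pool_deterministic(np.ones((4, 4)), PoolSpec(3, 2, "average"))
        np.testing.assert_allclose(out, 1.0)


class TestStochasticPooling:
    def test_probability_vector(self):
        np.testing.assert_allclose(stochastic_pool_probs([1.0, 3.0]), [0.25, 0.75])
        np.testing.assert_allclose(stochastic_pool_probs([5.0]), [1.0])
        np.testing.assert_allclose(stochastic_pool_probs([0.0] * 4), [0.25] * 4)
        with pytest.raises(errors.NegativeActivation):
            stochastic_pool_probs([-1.0, 2.0])

    def test_degenerate_one_hot_region(self):
        rng = np.random.default_rng(0)
        assert stochastic_pool_sample([0.0, 7.0, 0.0, 0.0], rng) == 7.0
        assert stochastic_pool_expect([0.0, 7.0, 0.0, 0.0]) == 7.0  # equals max

    def test_sampling_frequencies_match_probabilities(self):
        rng = np.random.default_rng(42)
        draws = np.array([stochastic_pool_sample([1.0, 3.0], rng) for _ in range(10_000)])
        freq3 = (draws == 3.0).mean()
        assert freq3 == pytest.approx(0.75, abs=0.02)  # ~4.6 sigma MC band

    def test_seeded_sample_sequence_reproducible(self):
        region = [0.5, 1.0, 2.0, 0.1]
        a = [stochastic_pool_sample(region, np.random.default_rng(3)) for _ in range(5)]
        b = [stochastic_pool_sample(region, np.random.default_rng(3)) for _ in range(5)]
        assert a == b

    def test_expectation_weighted_sum(self):
        assert stochastic_pool_expect([1.0, 3.0]) == pytest.approx(2.5)
        assert stochastic_pool_expect([0.7] * 9) == pytest.approx(0.7)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(hnp.arrays(np.float64, st.integers(1, 9),
                      elements=st.floats(0, 10, allow_nan=False)))
    def test_expectation_bounds(self, region):
        # min <= E <= max always; E >= mean for non-negative activations
        e = stochastic_pool_expect(region)
        assert region.min() - 1e-9 <= e <= region.max() + 1e-9
        if region.sum() > 0:
            assert e >= region.mean() - 1e-9

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(hnp.arrays(np.float64, 9, elements=st.floats(0, 5)), st.integers(0, 1000))
    def test_sample_is_element_of_region(self, region, seed):
        out = stochastic_pool_sample(region, np.random.default_rng(seed))
        assert out in region or (region.sum() == 0 and out == 0.0)


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs", [dict(stride=0), dict(filter_height=0),
                                        dict(num_filters=0), dict(padding=-1)])
    def test_conv_spec_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            ConvSpec(**kwargs)

    def test_dropout_spec_bounds(self):
        with pytest.raises(ValueError):
            DropoutSpec(1.0)
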