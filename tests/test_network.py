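"""Network primitives: shape calculus, initializers, BN, pooling, softmax,
dropout, and the assembled forward pass."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirnet.network import (
    ArchitectureSpec,
    ConvLayerSpec,
    PoolSpec,
    activation,
    batch_norm,
    build_network,
    default_architecture,
    dropout_mask,
    feature_length_after,
    forward,
    max_pool,
    msra_init,
    softmax,
    xavier_init,
)


class TestShapeCalculus:
    @pytest.mark.parametrize(
        "length,k,expected", [(1609, 1, 805), (1609, 6, 26), (1, 3, 1)]
    )
    def test_examples(self, length, k, expected):
        assert feature_length_after(length, k, PoolSpec()) == expected

    def test_matches_brute_force_pooling(self):
        """Repeated ceil division agrees with actually max-pooling an array."""
        pool = PoolSpec()
        for L in range(1, 201):
            x = np.arange(L, dtype=float)
            for k in range(9):
                assert len(x) == feature_length_after(L, k, pool)
                x = max_pool(x, pool)


class TestInitializers:
    def test_msra_variance_chi_square_bounds(self):
        # n=2 -> target variance 1.0; 99% chi-square band at 10^6 draws
        draws = msra_init((1_000_000,), fan_in=2, seed=0)
        assert 0.99 < draws.var() < 1.01
        assert abs(draws.mean()) < 0.005

    def test_msra_closed_form_scale(self):
        # kernel 9 x 32 input channels -> sd sqrt(2/288) ~= 0.0833
        draws = msra_init((100_000,), fan_in=288, seed=1)
        assert draws.std() == pytest.approx(np.sqrt(2 / 288), rel=0.02)

    def test_xavier_variance(self):
        draws = xavier_init((1_000_000,), fan_in=300, fan_out=100, seed=2)
        assert draws.var() == pytest.approx(2 / 400, rel=0.01)
        assert abs(draws.mean()) < 0.001

    def test_deterministic(self):
        np.testing.assert_array_equal(
            msra_init((4, 5), 10, seed=7), msra_init((4, 5), 10, seed=7)
        )

    def test_invalid_fan_in(self):
        with pytest.raises(ValueError):
            msra_init((3,), 0, seed=0)


class TestActivation:
    @pytest.mark.parametrize(
        "kind,x,expected",
        [
            ("relu", -3.0, 0.0),
            ("relu", 2.0, 2.0),
            ("leaky_relu", -1.0, -0.01),
            ("leaky_relu", 2.0, 2.0),
            ("sigmoid", 0.0, 0.5),
            ("tanh", 0.0, 0.0),
        ],
    )
    def test_pointwise_values(self, kind, x, expected):
        assert activation(np.array([x]), kind)[0] == pytest.approx(expected)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            activation(np.zeros(2), "swish")


class TestBatchNorm:
    def test_standardizes_batch(self):
        x = np.array([[0.0], [2.0]])
        out = batch_norm(x, np.ones(1), np.zeros(1), "train", epsilon=1e-12)
        np.testing.assert_allclose(out.ravel(), [-1.0, 1.0], atol=1e-5)

    def test_affine_restoration(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3.0, 2.0, size=(64, 4))
        gamma = x.std(axis=0)
        beta = x.mean(axis=0)
        out = batch_norm(x, gamma, beta, "train", epsilon=1e-12)
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_constant_batch_guarded_by_epsilon(self):
        x = np.full((8, 3), 5.0)
        out = batch_norm(x, np.ones(3), np.zeros(3), "train")
        np.testing.assert_allclose(out, 0.0, atol=1e-8)

    def test_batch_of_one_rejected_in_train_mode(self):
        with pytest.raises(ValueError):
            batch_norm(np.ones((1, 3)), np.ones(3), np.zeros(3), "train")

    def test_eval_mode_uses_running_statistics(self):
        x = np.array([[10.0], [10.0]])
        out = batch_norm(
            x, np.ones(1), np.zeros(1), "eval",
            running_mean=np.array([10.0]), running_var=np.array([4.0]),
            epsilon=0.0,
        )
        np.testing.assert_allclose(out, 0.0, atol=1e-12)


class TestMaxPool:
    @pytest.mark.parametrize(
        "signal,expected", [([1, 3, 2, 5], [3, 5]), ([1, 3, 2], [3, 2])]
    )
    def test_examples(self, signal, expected):
        np.testing.assert_array_equal(
            max_pool(np.array(signal, dtype=float)), expected
        )

    def test_long_signal_length(self):
        assert max_pool(np.zeros(1609)).shape == (805,)


class TestDropout:
    def test_p_zero_identity(self):
        np.testing.assert_array_equal(dropout_mask((10,), 0.0, "train", 0), 1.0)

    def test_zero_fraction_and_scaling(self):
        mask = dropout_mask((100_000,), 0.5, "train", seed=3)
        zero_frac = (mask == 0).mean()
        assert 0.49 < zero_frac < 0.51
        assert np.all(mask[mask > 0] == 2.0)  # survivors scaled by 1/(1-p)

    def test_eval_identity(self):
        np.testing.assert_array_equal(dropout_mask((50,), 0.9, "eval", 0), 1.0)

    def test_p_one_rejected(self):
        with pytest.raises(ValueError):
            dropout_mask((5,), 1.0, "train", 0)


class TestSoftmax:
    def test_uniform_at_zero_logits(self):
        np.testing.assert_allclose(softmax(np.zeros(8)), 0.125, atol=1e-12)

    def test_closed_form(self):
        np.testing.assert_allclose(
            softmax(np.array([0.0, np.log(3.0)])), [0.25, 0.75], atol=1e-12
        )

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=10),
        st.floats(-100, 100),
    )
    def test_probability_vector_and_shift_invariance(self, logits, shift):
        v = np.array(logits)
        s = softmax(v)
        assert np.all(s > 0)
        assert s.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(s, softmax(v + shift), atol=1e-12)


def _hand_parameter_count(arch: ArchitectureSpec, input_length: int) -> int:
    total = 2 if arch.batch_norm else 0  # input BN scale+shift
    in_ch = 1
    for spec in arch.conv_layers:
        total += spec.kernel_width * in_ch * spec.out_channels + spec.out_channels
        if arch.batch_norm:
            total += 2 * spec.out_channels
        in_ch = spec.out_channels
    L = feature_length_after(input_length, len(arch.conv_layers), arch.pool)
    in_dim = L * in_ch
    for width in arch.fc_widths:
        total += in_dim * width + width
        in_dim = width
    return total


class TestBuildNetwork:
    def test_default_first_fc_dimension(self):
        params = build_network(default_architecture(8), 1609, seed=0)
        assert params.fc[0]["W"].shape == (26 * 256, 512)  # 6656 inputs

    def test_parameter_count_closed_form(self):
        arch = default_architecture(8)
        params = build_network(arch, 1609, seed=0)
        assert params.n_parameters() == _hand_parameter_count(arch, 1609)

    def test_degenerate_input_length(self):
        arch = ArchitectureSpec(conv_layers=(ConvLayerSpec(3, 4),), fc_widths=(2,))
        params = build_network(arch, 2, seed=0)
        assert params.fc[0]["W"].shape == (4, 2)  # pooled length 1 x 4 channels

    def test_deterministic(self):
        a = build_network(default_architecture(8, n_conv_layers=2), 64, seed=5)
        b = build_network(default_architecture(8, n_conv_layers=2), 64, seed=5)
        for la, lb in zip(a.conv + a.fc, b.conv + b.fc):
            np.testing.assert_array_equal(la["W"], lb["W"])

    def test_inconsistent_class_count_rejected(self):
        with pytest.raises(ValueError):
            build_network(default_architecture(8), 64, seed=0, n_classes=5)

    def test_init_pairing_defaults(self):
        relu_net = build_network(default_architecture(4, 1, 1, "relu"), 16, 0)
        tanh_net = build_network(default_architecture(4, 1, 1, "tanh"), 16, 0)
        assert relu_net.init_method == "msra"
        assert tanh_net.init_method == "xavier"


class TestForward:
    def test_zero_network_gives_uniform_softmax(self):
        params = build_network(default_architecture(8, n_conv_layers=2), 32, seed=0)
        for layer in params.conv + params.fc:
            layer["W"][:] = 0.0
            layer["b"][:] = 0.0
        logits = forward(params, np.random.default_rng(0).normal(size=(4, 32)))
        np.testing.assert_allclose(logits, 0.0, atol=1e-7)
        np.testing.assert_allclose(softmax(logits), 0.125, atol=1e-7)

    def test_eval_mode_deterministic(self):
        params = build_network(default_architecture(8, n_conv_layers=2), 32, seed=0)
        x = np.random.default_rng(1).normal(size=(3, 32))
        np.testing.assert_array_equal(forward(params, x), forward(params, x))

    def test_identity_kernel_linear_path(self):
        """Center-tap kernel + identity FC reproduces the pooled signal."""
        arch = ArchitectureSpec(
            conv_layers=(ConvLayerSpec(3, 1),),
            fc_widths=(4,),
            activation="relu",
            dropout_p=0.0,
            batch_norm=False,
        )
        params = build_network(arch, 8, seed=0, dtype=np.float64)
        params.conv[0]["W"][:] = [[[0.0, 1.0, 0.0]]]
        params.conv[0]["b"][:] = 0.0
        params.fc[0]["W"][:] = np.eye(4)
        params.fc[0]["b"][:] = 0.0
        x = np.array([[1.0, 3.0, 2.0, 5.0, 4.0, 0.0, 2.0, 7.0]])
        np.testing.assert_allclose(forward(params, x), [[3.0, 5.0, 4.0, 7.0]])

    def test_shape_mismatch_rejected(self):
        params = build_network(default_architecture(8, n_conv_layers=1), 32, seed=0)
        with pytest.raises(ValueError):
            forward(params, np.zeros((2, 31)))


def test_save_load_round_trip(tmp_path):
    from nirnet.network import load_params, save_params

    params = build_network(default_architecture(4, n_conv_layers=2), 48, seed=3)
    x = np.random.default_rng(0).normal(size=(2, 48))
    before = forward(params, x)
    save_params(params, tmp_path / "model.npz")
    after = forward(load_params(tmp_path / "model.npz"), x)
    np.testing.assert_array_equal(before, after)
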