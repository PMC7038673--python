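"""Loss functions, LR schedule, SGD, gradient correctness, and training."""

import numpy as np
import pytest

from nirnet.dataset import SplitSpec, split_dataset
from nirnet.network import (
    ArchitectureSpec,
    ConvLayerSpec,
    build_network,
    forward_backward,
)
from nirnet.training import (
    TrainingConfig,
    cross_entropy,
    l2_penalty,
    lr_at_round,
    sgd_step,
    train,
    _grad_items,
)


class TestCrossEntropy:
    def test_certainty_is_zero(self):
        assert cross_entropy(np.array([1.0, 0.0]), np.array([1.0, 0.0])) == 0.0

    def test_uniform_eight_classes(self):
        S = np.full(8, 0.125)
        y = np.eye(8)[0]
        assert cross_entropy(S, y) == pytest.approx(np.log(8), abs=1e-12)

    def test_half_probability(self):
        S = np.array([0.5, 0.5])
        assert cross_entropy(S, np.array([1.0, 0.0])) == pytest.approx(0.6931, abs=1e-4)

    def test_batch_mean(self):
        S = np.array([[1.0, 0.0], [0.5, 0.5]])
        y = np.array([[1.0, 0.0], [1.0, 0.0]])
        assert cross_entropy(S, y) == pytest.approx(np.log(2) / 2)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy(np.array([0.9, 0.3]), np.array([1.0, 0.0]))


class TestL2Penalty:
    def _single_weight_params(self, value):
        arch = ArchitectureSpec(conv_layers=(), fc_widths=(1,), batch_norm=False,
                                dropout_p=0.0)
        params = build_network(arch, 1, seed=0, dtype=np.float64)
        params.fc[0]["W"][:] = value
        return params

    def test_zero_lambda(self):
        assert l2_penalty(self._single_weight_params(3.0), 0.0) == 0.0

    def test_single_weight(self):
        assert l2_penalty(self._single_weight_params(3.0), 0.1) == pytest.approx(0.9)

    def test_quadratic_homogeneity(self):
        p1 = l2_penalty(self._single_weight_params(2.0), 0.3)
        p2 = l2_penalty(self._single_weight_params(4.0), 0.3)
        assert p2 == pytest.approx(4 * p1)


class TestLearningRateSchedule:
    def test_initial_rate(self):
        assert lr_at_round(0, TrainingConfig()) == 0.01

    def test_reference_endpoint(self):
        # 0.01 * 0.99**(990000/1652) ~= 2.42e-5
        lr = lr_at_round(990_000, TrainingConfig())
        assert lr == pytest.approx(2.42e-5, rel=5e-3)

    def test_one_decay_period(self):
        assert lr_at_round(1652, TrainingConfig()) == pytest.approx(0.0099)

    def test_monotone_and_bounded(self):
        config = TrainingConfig()
        rates = [lr_at_round(r, config) for r in range(0, 100_000, 997)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))
        assert all(0 < r <= config.init_lr for r in rates)

    def test_staircase_flooring(self):
        config = TrainingConfig(staircase=True)
        assert lr_at_round(1651, config) == 0.01
        assert lr_at_round(1652, config) == pytest.approx(0.0099)

    def test_negative_round_rejected(self):
        with pytest.raises(ValueError):
            lr_at_round(-1, TrainingConfig())


def _tiny_params(dtype=np.float64, activation="tanh", batch_norm=True):
    arch = ArchitectureSpec(
        conv_layers=(ConvLayerSpec(3, 2),),
        fc_widths=(5, 3),
        activation=activation,
        dropout_p=0.0,
        batch_norm=batch_norm,
    )
    return build_network(arch, 8, seed=1, dtype=dtype)


class TestSgdStep:
    def _params_and_grads(self):
        params = _tiny_params()
        rng = np.random.default_rng(2)
        X = rng.normal(size=(4, 8))
        Y = np.eye(3)[[0, 1, 2, 0]]
        _, _, grads, _ = forward_backward(params, X, Y, rng, l2_lambda=0.0)
        return params, grads

    def test_zero_lr_leaves_params_unchanged(self):
        params, grads = self._params_and_grads()
        before = params.fc[0]["W"].copy()
        sgd_step(params, grads, 0.0)
        np.testing.assert_array_equal(params.fc[0]["W"], before)

    def test_update_rule(self):
        params, grads = self._params_and_grads()
        w = params.fc[1]["W"].copy()
        g = grads["fc"][1]["W"]
        sgd_step(params, grads, 0.1)
        np.testing.assert_allclose(params.fc[1]["W"], w - 0.1 * g, atol=1e-12)

    def test_two_steps_linear_in_fixed_gradient(self):
        params, grads = self._params_and_grads()
        twice = params.copy()
        sgd_step(params, grads, 0.2)
        sgd_step(twice, grads, 0.1)
        sgd_step(twice, grads, 0.1)
        np.testing.assert_allclose(params.fc[0]["W"], twice.fc[0]["W"], atol=1e-10)

    def test_shape_mismatch_rejected(self):
        params, grads = self._params_and_grads()
        grads["fc"][0]["W"] = grads["fc"][0]["W"][:, :2]
        with pytest.raises(ValueError):
            sgd_step(params, grads, 0.1)


class TestGradients:
    def test_finite_difference_check(self):
        """Analytic gradients match central differences through the whole
        stack (conv + BN + activation + pool + FC + softmax CE + L2)."""
        params = _tiny_params(dtype=np.float64)
        rng = np.random.default_rng(2)
        X = rng.normal(size=(4, 8))
        Y = np.eye(3)[[0, 1, 2, 0]]
        lam = 1e-3

        def total_loss():
            ce, l2, _, _ = forward_backward(
                params, X, Y, np.random.default_rng(0), l2_lambda=lam
            )
            return ce + l2

        _, _, grads, _ = forward_backward(
            params, X, Y, np.random.default_rng(0), l2_lambda=lam
        )
        worst = 0.0
        pick = np.random.default_rng(3)
        for layer, g, key in _grad_items(params, grads):
            w = layer[key]
            for flat in pick.choice(w.size, size=min(8, w.size), replace=False):
                idx = np.unravel_index(flat, w.shape)
                eps, orig = 1e-6, w[idx]
                w[idx] = orig + eps
                up = total_loss()
                w[idx] = orig - eps
                down = total_loss()
                w[idx] = orig
                fd = (up - down) / (2 * eps)
                rel = abs(fd - g[key][idx]) / max(abs(fd), abs(g[key][idx]), 1e-8)
                worst = max(worst, rel)
        assert worst <= 1e-4

    def test_l2_only_updates_shrink_weights(self):
        """With zero data gradient the L2 term shrinks weight norms."""
        params = _tiny_params()
        lam, lr = 0.01, 0.1
        norms = []
        for _ in range(5):
            grads = {
                "conv": [{"W": 2 * lam * l["W"], "b": np.zeros_like(l["b"]),
                          "gamma": np.zeros_like(l["gamma"]),
                          "beta": np.zeros_like(l["beta"])}
                         for l in params.conv],
                "fc": [{"W": 2 * lam * l["W"], "b": np.zeros_like(l["b"])}
                       for l in params.fc],
            }
            sgd_step(params, grads, lr)
            norms.append(sum(float(np.vdot(w, w)) for w in params.weight_tensors()))
        assert all(a > b for a, b in zip(norms, norms[1:]))


class TestTrain:
    def _arch(self, n_classes=2):
        return ArchitectureSpec(
            conv_layers=(ConvLayerSpec(9, 8), ConvLayerSpec(3, 16)),
            fc_widths=(32, n_classes),
        )

    def test_zero_rounds_returns_initial_params(self, twoclass_dataset):
        config = TrainingConfig(total_rounds=0, seed=0)
        params, log = train(twoclass_dataset, None, self._arch(), config)
        assert log.rows == []
        reference = build_network(self._arch(), 64, seed=0, dtype=np.float32)
        np.testing.assert_array_equal(params.fc[0]["W"], reference.fc[0]["W"])

    def test_deterministic_logs(self, twoclass_dataset):
        config = TrainingConfig(total_rounds=30, eval_every=10, seed=4)
        _, log1 = train(twoclass_dataset, None, self._arch(), config)
        _, log2 = train(twoclass_dataset, None, self._arch(), config)
        assert log1.rows == log2.rows

    def test_learns_separable_two_class_problem(self, twoclass_dataset):
        tr, te = split_dataset(twoclass_dataset, SplitSpec(0.8, 0))
        config = TrainingConfig(
            total_rounds=2000, eval_every=100, seed=0, target_test_accuracy=0.95
        )
        params, log = train(tr, te, self._arch(), config)
        assert log.rows[-1]["test_accuracy"] >= 0.95

    def test_batch_larger_than_dataset_rejected(self, twoclass_dataset):
        small = twoclass_dataset.subset(np.arange(8))
        with pytest.raises(ValueError):
            train(small, None, self._arch(), TrainingConfig(batch_size=16))

    def test_non_finite_loss_aborts_with_round(self, twoclass_dataset):
        params = build_network(self._arch(), 64, seed=0)
        params.conv[0]["W"][0, 0, 0] = np.nan
        config = TrainingConfig(total_rounds=5, eval_every=1, seed=0)
        with pytest.raises(FloatingPointError, match="round 1"):
            train(twoclass_dataset, None, self._arch(), config, params=params)

    def test_log_rounds_strictly_increasing(self, twoclass_dataset):
        config = TrainingConfig(total_rounds=25, eval_every=10, seed=0)
        _, log = train(twoclass_dataset, None, self._arch(), config)
        rounds = [r["round"] for r in log.rows]
        assert rounds == sorted(set(rounds)) == [10, 20, 25]
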