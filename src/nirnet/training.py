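"""Mini-batch SGD training with exponential learning-rate decay.

The loss is softmax cross-entropy plus an L2 weight penalty; the learning
rate follows init_lr * decay_rate**(round / decay_steps) (exponent floored
in staircase mode).  A "round" is one mini-batch update.  Training shuffles
the sample order each epoch with a seeded generator, so a run is fully
reproducible from (architecture, data, config).
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import SpectralDataset, one_hot_encode
from .network import (
    ArchitectureSpec,
    NetworkParameters,
    build_network,
    forward_backward,
    predict_labels,
)

__all__ = [
    "TrainingConfig",
    "LossValue",
    "TrainingLog",
    "cross_entropy",
    "l2_penalty",
    "lr_at_round",
    "sgd_step",
    "train",
]


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 16
    init_lr: float = 0.01
    decay_rate: float = 0.99
    decay_steps: int = 1652
    staircase: bool = False
    l2_lambda: float = 1e-4
    total_rounds: int = 10000
    eval_every: int = 500
    seed: int = 0
    momentum: float = 0.0
    # optional early stop: end training once test accuracy reaches this level
    target_test_accuracy: float | None = None
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (batch norm needs it)")
        if not 0.0 < self.decay_rate <= 1.0:
            raise ValueError("decay_rate must be in (0, 1]")
        if self.init_lr <= 0:
            raise ValueError("init_lr must be positive")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")
        if self.decay_steps < 1:
            raise ValueError("decay_steps must be >= 1")
        if self.total_rounds < 0 or self.eval_every < 1:
            raise ValueError("total_rounds must be >= 0 and eval_every >= 1")


@dataclass(frozen=True)
class LossValue:
    cross_entropy: float
    l2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.cross_entropy) and np.isfinite(self.l2)):
            raise ValueError("loss components must be finite")
        if self.cross_entropy < 0 or self.l2 < 0:
            raise ValueError("loss components must be nonnegative")

    @property
    def total(self) -> float:
        return self.cross_entropy + self.l2


@dataclass
class TrainingLog:
    """Per-evaluation rows of (round, lr, train batch accuracy/loss, test acc)."""

    rows: list[dict] = field(default_factory=list)

    def append(self, round: int, learning_rate: float, train_accuracy: float,
               train_loss: float, test_accuracy: float | None = None) -> None:
        if self.rows and round <= self.rows[-1]["round"]:
            raise ValueError("rounds must be strictly increasing")
        if not 0.0 <= train_accuracy <= 1.0:
            raise ValueError("accuracy must be in [0,1]")
        self.rows.append(
            {
                "round": round,
                "learning_rate": learning_rate,
                "train_accuracy": train_accuracy,
                "train_loss": train_loss,
                "test_accuracy": test_accuracy,
            }
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = ["round", "learning_rate", "train_accuracy", "train_loss",
                "test_accuracy"]
        return pd.DataFrame(self.rows, columns=cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def cross_entropy(S: np.ndarray, y: np.ndarray) -> float:
    """Mean -log predicted probability of the true class.

    ``S`` is one probability vector or a batch of them; ``y`` the matching
    one-hot labels.  The true-class probability is clipped at 1e-12.
    """
    S = np.atleast_2d(np.asarray(S, dtype=np.float64))
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    if S.shape != y.shape:
        raise ValueError(f"shape mismatch {S.shape} vs {y.shape}")
    if np.any(np.abs(S.sum(axis=1) - 1.0) > 1e-6) or np.any(S < -1e-12):
        raise ValueError("S rows must be probability vectors")
    true = np.clip((S * y).sum(axis=1), 1e-12, None)
    return float(-np.log(true).mean())


def l2_penalty(params: NetworkParameters, l2_lambda: float) -> float:
    """l2_lambda * sum of squared entries over weight tensors only."""
    if l2_lambda < 0:
        raise ValueError("l2_lambda must be >= 0")
    if l2_lambda == 0:
        return 0.0
    return l2_lambda * sum(
        float((w.astype(np.float64) ** 2).sum()) for w in params.weight_tensors()
    )


def lr_at_round(round: int, config: TrainingConfig) -> float:
    """Exponentially decayed learning rate at a given round."""
    if round < 0:
        raise ValueError("round must be >= 0")
    exponent = round / config.decay_steps
    if config.staircase:
        exponent = float(int(exponent))
    return config.init_lr * config.decay_rate ** exponent


def _grad_items(params: NetworkParameters, grads: dict):
    if params.input_bn is not None and "input_bn" in grads:
        for k in ("gamma", "beta"):
            yield params.input_bn, grads["input_bn"], k
    for layer, g in zip(params.conv, grads["conv"]):
        for k in g:
            yield layer, g, k
    for layer, g in zip(params.fc, grads["fc"]):
        for k in g:
            yield layer, g, k


def sgd_step(params: NetworkParameters, grads: dict, lr: float,
             momentum: float = 0.0, velocity: dict | None = None
             ) -> NetworkParameters:
    """In-place gradient-descent update w <- w - lr * grad (optional classical
    momentum when a velocity store is supplied); returns params."""
    for layer, g, k in _grad_items(params, grads):
        if layer[k].shape != g[k].shape:
            raise ValueError(
                f"gradient shape {g[k].shape} does not match parameter "
                f"shape {layer[k].shape} for {k!r}"
            )
        update = g[k].astype(layer[k].dtype, copy=False)
        if momentum > 0.0 and velocity is not None:
            key = (id(layer), k)
            v = velocity.get(key)
            v = momentum * v + update if v is not None else update
            velocity[key] = v
            update = v
        layer[k] -= lr * update
    return params


def train(
    dataset_train: SpectralDataset,
    dataset_test: SpectralDataset | None,
    arch: ArchitectureSpec,
    config: TrainingConfig,
    init_method: str | None = None,
    params: NetworkParameters | None = None,
    progress: bool = False,
) -> tuple[NetworkParameters, TrainingLog]:
    """Run ``config.total_rounds`` mini-batch updates and log the curves.

    Evaluation happens every ``eval_every`` rounds (and at the final round):
    accuracy/loss on the current training batch, plus test-set accuracy when
    a test set is given.  Raises on non-finite loss, naming the round.
    """
    n = dataset_train.n_samples
    if config.batch_size > n:
        raise ValueError(f"batch_size {config.batch_size} exceeds n={n}")
    C = arch.n_classes
    if dataset_train.n_classes != C:
        raise ValueError(
            f"dataset has {dataset_train.n_classes} classes, architecture {C}"
        )
    dtype = np.dtype(config.dtype)
    if params is None:
        params = build_network(arch, dataset_train.n_points, seed=config.seed,
                               init_method=init_method, dtype=dtype)
    log = TrainingLog()
    if config.total_rounds == 0:
        return params, log

    rng = np.random.default_rng(config.seed + 1)
    X = np.ascontiguousarray(dataset_train.spectra, dtype=dtype)
    Y = one_hot_encode(dataset_train.labels, C)
    velocity: dict = {} if config.momentum > 0 else None

    order = rng.permutation(n)
    cursor = 0
    for round_ in range(1, config.total_rounds + 1):
        if cursor + config.batch_size > n:
            order = rng.permutation(n)
            cursor = 0
        idx = order[cursor : cursor + config.batch_size]
        cursor += config.batch_size

        lr = lr_at_round(round_ - 1, config)
        try:
            ce, l2, grads, probs = forward_backward(
                params, X[idx], Y[idx], rng, l2_lambda=config.l2_lambda
            )
        except ValueError as exc:
            raise FloatingPointError(
                f"non-finite values in forward/backward at round {round_}: {exc}"
            ) from exc
        if not np.isfinite(ce + l2):
            raise FloatingPointError(
                f"non-finite loss (ce={ce}, l2={l2}) at round {round_}"
            )
        sgd_step(params, grads, lr, config.momentum, velocity)

        if round_ % config.eval_every == 0 or round_ == config.total_rounds:
            batch_acc = float(
                (np.argmax(probs, axis=1) == np.argmax(Y[idx], axis=1)).mean()
            )
            test_acc = None
            if dataset_test is not None:
                pred = predict_labels(params, dataset_test.spectra.astype(dtype))
                test_acc = float((pred == dataset_test.labels).mean())
            log.append(round_, lr, batch_acc, ce + l2, test_acc)
            if progress and round_ % 1000 == 0:
                print(
                    f"round {round_}: lr={lr:.5g} batch_acc={batch_acc:.3f} "
                    f"loss={ce + l2:.4f}"
                    + (f" test_acc={test_acc:.3f}" if test_acc is not None else ""),
                    file=sys.stderr,
                )
            if (
                config.target_test_accuracy is not None
                and test_acc is not None
                and test_acc >= config.target_test_accuracy
            ):
                break
    return params, log
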