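"""1-D convolutional network for spectral classification.

The network follows the design that works well on long 1-D absorbance
vectors: a stack of same-padded 1-D convolutions (wide 1x9 kernels first to
pick up broad band structure, narrow 1x3 kernels deeper in the stack),
batch normalization before every activation, ceil-mode 1x2 max pooling so
only pooling shrinks the signal, then fully connected layers with inverted
dropout, and a softmax read-out.

Everything here — convolution, batch norm, pooling, dropout, the
MSRA (He) and Xavier (Glorot) weight initializers, and the full backward
pass — is implemented directly on NumPy arrays.  Gradients are exact
(they are validated against central finite differences in the test suite)
and the whole computation is deterministic given a seed.

Shape bookkeeping: stride-1 same-padded convolution preserves length, so
after k pooling layers an input of length L has length ceil(L / 2) applied
k times; e.g. 1609 -> 805 -> 403 -> 202 -> 101 -> 51 -> 26.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConvLayerSpec",
    "PoolSpec",
    "ArchitectureSpec",
    "NetworkParameters",
    "default_architecture",
    "feature_length_after",
    "build_network",
    "msra_init",
    "xavier_init",
    "activation",
    "batch_norm",
    "max_pool",
    "dropout_mask",
    "softmax",
    "forward",
    "forward_backward",
    "save_params",
    "load_params",
]

_ACTIVATIONS = ("relu", "leaky_relu", "sigmoid", "tanh")
BN_EPSILON = 1e-5
BN_MOMENTUM = 0.9


@dataclass(frozen=True)
class ConvLayerSpec:
    """Same-padded stride-1 1-D convolution layer."""

    kernel_width: int
    out_channels: int
    stride: int = 1

    def __post_init__(self) -> None:
        if self.kernel_width < 1 or self.kernel_width % 2 == 0:
            raise ValueError(f"kernel_width must be odd, got {self.kernel_width}")
        if self.out_channels < 1:
            raise ValueError("out_channels must be >= 1")
        if self.stride != 1:
            raise ValueError("only stride-1 convolutions are supported")


@dataclass(frozen=True)
class PoolSpec:
    """Ceil-mode max pooling: a trailing partial window is kept."""

    width: int = 2
    stride: int = 2

    def __post_init__(self) -> None:
        if self.width < 1 or self.stride < 1:
            raise ValueError("pool width and stride must be >= 1")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative conv/pool/FC stack description.

    ``fc_widths`` includes the output layer, so its last entry is the
    number of classes C.  Dropout applies after hidden FC activations
    only, never to the output layer.
    """

    conv_layers: tuple[ConvLayerSpec, ...]
    pool: PoolSpec = PoolSpec()
    fc_widths: tuple[int, ...] = (512, 512, 8)
    activation: str = "relu"
    leaky_slope: float = 0.01
    dropout_p: float = 0.5
    batch_norm: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "conv_layers", tuple(self.conv_layers))
        object.__setattr__(self, "fc_widths", tuple(self.fc_widths))
        if not self.fc_widths:
            raise ValueError("fc_widths must be nonempty")
        if any(w < 1 for w in self.fc_widths):
            raise ValueError("fc widths must be positive")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError(f"dropout_p must be in [0,1), got {self.dropout_p}")

    @property
    def n_classes(self) -> int:
        return self.fc_widths[-1]


#: default channel schedule, strictly increasing from 32 to 256
DEFAULT_CONV_CHANNELS = (32, 64, 96, 128, 192, 256)
#: wide kernels first to capture broad bands, then narrow for fine structure
DEFAULT_KERNEL_WIDTHS = (9, 9, 9, 3, 3, 3)


def default_architecture(
    n_classes: int = 8,
    n_conv_layers: int = 6,
    n_fc_layers: int = 3,
    activation: str = "relu",
) -> ArchitectureSpec:
    """The 6C-3F reference architecture (prefixes of the channel schedule
    for shallower variants; extra hidden FC layers are 512 wide)."""
    if not 1 <= n_conv_layers <= len(DEFAULT_CONV_CHANNELS):
        raise ValueError(f"n_conv_layers must be in 1..{len(DEFAULT_CONV_CHANNELS)}")
    if n_fc_layers < 1:
        raise ValueError("n_fc_layers must be >= 1")
    conv = tuple(
        ConvLayerSpec(DEFAULT_KERNEL_WIDTHS[i], DEFAULT_CONV_CHANNELS[i])
        for i in range(n_conv_layers)
    )
    fc = (512,) * (n_fc_layers - 1) + (n_classes,)
    return ArchitectureSpec(conv_layers=conv, fc_widths=fc, activation=activation)


def feature_length_after(input_length: int, n_pool_layers: int, pool: PoolSpec) -> int:
    """Signal length after n pooling layers (same-padded convs preserve it)."""
    if input_length < 1:
        raise ValueError("input_length must be >= 1")
    length = input_length
    for _ in range(n_pool_layers):
        length = -(-length // pool.stride)  # ceil division
    return length


# ---------------------------------------------------------------------------
# initializers

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def msra_init(shape, fan_in: int, seed, dtype=np.float64) -> np.ndarray:
    """He/Kaiming weights: i.i.d. N(0, 2/fan_in), variance chosen to keep
    the activation variance constant through ReLU layers."""
    if fan_in < 1:
        raise ValueError(f"fan_in must be >= 1, got {fan_in}")
    rng = _as_rng(seed)
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape).astype(dtype)


def xavier_init(shape, fan_in: int, fan_out: int, seed, dtype=np.float64) -> np.ndarray:
    """Glorot weights: i.i.d. N(0, 2/(fan_in+fan_out)), suited to the
    saturating activations (sigmoid, tanh)."""
    if fan_in < 1 or fan_out < 1:
        raise ValueError("fan_in and fan_out must be >= 1")
    rng = _as_rng(seed)
    return rng.normal(0.0, math.sqrt(2.0 / (fan_in + fan_out)), size=shape).astype(dtype)


# ---------------------------------------------------------------------------
# parameters

@dataclass
class NetworkParameters:
    """All trainable tensors plus BN running statistics.

    ``conv[i]`` holds W (out_ch, in_ch, k), b (out_ch,) and, with batch
    norm, gamma/beta and running mean/var per channel.  ``fc[i]`` holds
    W (in, out) and b (out,).  ``input_bn`` standardizes the raw spectrum.
    """

    arch: ArchitectureSpec
    input_length: int
    init_method: str
    input_bn: dict | None
    conv: list[dict]
    fc: list[dict]

    @property
    def dtype(self):
        return self.fc[-1]["W"].dtype

    def weight_tensors(self) -> list[np.ndarray]:
        """Weight matrices/kernels subject to L2 (biases and BN excluded)."""
        return [layer["W"] for layer in self.conv] + [layer["W"] for layer in self.fc]

    def n_parameters(self) -> int:
        total = 0
        for layer, key in self._trainable_items():
            total += layer[key].size
        return total

    def _trainable_items(self):
        if self.input_bn is not None:
            yield self.input_bn, "gamma"
            yield self.input_bn, "beta"
        for layer in self.conv:
            yield layer, "W"
            yield layer, "b"
            if "gamma" in layer:
                yield layer, "gamma"
                yield layer, "beta"
        for layer in self.fc:
            yield layer, "W"
            yield layer, "b"

    def copy(self) -> "NetworkParameters":
        def cp(d):
            return {k: (v.copy() if isinstance(v, np.ndarray) else v) for k, v in d.items()}

        return NetworkParameters(
            arch=self.arch,
            input_length=self.input_length,
            init_method=self.init_method,
            input_bn=None if self.input_bn is None else cp(self.input_bn),
            conv=[cp(d) for d in self.conv],
            fc=[cp(d) for d in self.fc],
        )


def _bn_state(n_channels: int, dtype) -> dict:
    return {
        "gamma": np.ones(n_channels, dtype=dtype),
        "beta": np.zeros(n_channels, dtype=dtype),
        "run_mean": np.zeros(n_channels, dtype=dtype),
        "run_var": np.ones(n_channels, dtype=dtype),
    }


def build_network(
    arch: ArchitectureSpec,
    input_length: int,
    seed: int,
    init_method: str | None = None,
    n_classes: int | None = None,
    dtype=np.float32,
) -> NetworkParameters:
    """Allocate and initialize all parameters.

    ``init_method`` defaults to the standard pairing: MSRA for ReLU-family
    activations, Xavier for sigmoid/tanh.  ``"normal"`` gives naive
    sd-0.01 Gaussian weights (the un-scaled baseline for ablations).
    Deterministic given the seed.
    """
    if n_classes is not None and arch.fc_widths[-1] != n_classes:
        raise ValueError(
            f"fc_widths ends in {arch.fc_widths[-1]} but n_classes={n_classes}"
        )
    if input_length < 1:
        raise ValueError("input_length must be >= 1")
    if init_method is None:
        init_method = "msra" if arch.activation in ("relu", "leaky_relu") else "xavier"
    if init_method not in ("msra", "xavier", "normal"):
        raise ValueError(f"unknown init_method {init_method!r}")
    rng = np.random.default_rng(seed)

    def draw(shape, fan_in, fan_out):
        if init_method == "msra":
            return msra_init(shape, fan_in, rng, dtype=dtype)
        if init_method == "xavier":
            return xavier_init(shape, fan_in, fan_out, rng, dtype=dtype)
        return rng.normal(0.0, 0.01, size=shape).astype(dtype)

    conv_params: list[dict] = []
    in_ch = 1
    for spec in arch.conv_layers:
        fan_in = spec.kernel_width * in_ch
        fan_out = spec.kernel_width * spec.out_channels
        layer = {
            "W": draw((spec.out_channels, in_ch, spec.kernel_width), fan_in, fan_out),
            "b": np.zeros(spec.out_channels, dtype=dtype),
            "fan_in": fan_in,
        }
        if arch.batch_norm:
            layer.update(_bn_state(spec.out_channels, dtype))
        conv_params.append(layer)
        in_ch = spec.out_channels

    pooled = feature_length_after(input_length, len(arch.conv_layers), arch.pool)
    flat = pooled * in_ch if arch.conv_layers else input_length
    fc_params: list[dict] = []
    in_dim = flat
    for width in arch.fc_widths:
        fc_params.append(
            {
                "W": draw((in_dim, width), in_dim, width),
                "b": np.zeros(width, dtype=dtype),
                "fan_in": in_dim,
            }
        )
        in_dim = width

    input_bn = _bn_state(1, dtype) if arch.batch_norm else None
    return NetworkParameters(
        arch=arch,
        input_length=input_length,
        init_method=init_method,
        input_bn=input_bn,
        conv=conv_params,
        fc=fc_params,
    )


# ---------------------------------------------------------------------------
# elementwise operations

def activation(x: np.ndarray, kind: str, leaky_slope: float = 0.01) -> np.ndarray:
    x = np.asarray(x)
    if kind == "relu":
        return np.maximum(x, 0)
    if kind == "leaky_relu":
        return np.where(x >= 0, x, leaky_slope * x)
    if kind == "sigmoid":
        # split by sign for stability at large |x|
        out = np.empty_like(x, dtype=np.result_type(x, np.float32))
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        return out
    if kind == "tanh":
        return np.tanh(x)
    raise ValueError(f"unknown activation kind {kind!r}")


def _activation_forward(x, kind, leaky_slope):
    y = activation(x, kind, leaky_slope)
    cache = y if kind in ("sigmoid", "tanh") else x >= 0
    return y, cache


def _activation_backward(dy, cache, kind, leaky_slope):
    if kind == "relu":
        return dy * cache
    if kind == "leaky_relu":
        return dy * np.where(cache, 1.0, leaky_slope).astype(dy.dtype)
    if kind == "sigmoid":
        return dy * cache * (1.0 - cache)
    return dy * (1.0 - cache * cache)  # tanh


def softmax(V: np.ndarray) -> np.ndarray:
    """Stable softmax along the last axis; shift-invariant by construction."""
    V = np.asarray(V, dtype=np.float64)
    if not np.all(np.isfinite(V)):
        raise ValueError("softmax requires finite logits")
    z = V - V.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# batch normalization

def batch_norm(
    x: np.ndarray,
    scale: np.ndarray,
    shift: np.ndarray,
    mode: str = "train",
    running_mean: np.ndarray | None = None,
    running_var: np.ndarray | None = None,
    epsilon: float = BN_EPSILON,
    momentum: float = BN_MOMENTUM,
) -> np.ndarray:
    """Per-channel batch normalization with affine restoration.

    Accepts (N, C) or (N, C, L) input.  In train mode the batch statistics
    are used and, when running arrays are passed, updated in place; in eval
    mode the running statistics are used.
    """
    y, _ = _bn_forward(x, scale, shift, mode, running_mean, running_var,
                       epsilon, momentum)
    return y


def _bn_axes(x):
    if x.ndim == 2:
        return (0,), (1, -1)
    if x.ndim == 3:
        return (0, 2), (1, -1, 1)
    raise ValueError("batch norm expects (N, C) or (N, C, L) input")


def _bn_forward(x, gamma, beta, mode, run_mean, run_var, eps, momentum):
    x = np.asarray(x)
    axes, bshape = _bn_axes(x)
    g = np.asarray(gamma).reshape(bshape)
    b = np.asarray(beta).reshape(bshape)
    if mode == "train":
        if x.shape[0] < 2:
            raise ValueError("batch norm in train mode requires batch size >= 2")
        mu = x.mean(axis=axes)
        var = x.var(axis=axes)
        if run_mean is not None:
            run_mean *= momentum
            run_mean += (1.0 - momentum) * mu
        if run_var is not None:
            run_var *= momentum
            run_var += (1.0 - momentum) * var
    elif mode == "eval":
        if run_mean is None or run_var is None:
            raise ValueError("eval mode requires running statistics")
        mu, var = run_mean, run_var
    else:
        raise ValueError(f"unknown mode {mode!r}")
    inv_std = 1.0 / np.sqrt(var.reshape(bshape) + eps)
    xhat = (x - mu.reshape(bshape)) * inv_std
    y = g * xhat + b
    cache = (xhat, g, inv_std, axes, bshape)
    return y.astype(x.dtype, copy=False), cache


def _bn_backward(dy, cache):
    xhat, g, inv_std, axes, bshape = cache
    m = np.prod([dy.shape[a] for a in axes])
    dgamma = (dy * xhat).sum(axis=axes)
    dbeta = dy.sum(axis=axes)
    dxhat = dy * g
    dx = inv_std * (
        dxhat
        - (dxhat.sum(axis=axes) / m).reshape(bshape)
        - xhat * ((dxhat * xhat).sum(axis=axes) / m).reshape(bshape)
    )
    return dx.astype(dy.dtype, copy=False), dgamma, dbeta


# ---------------------------------------------------------------------------
# convolution and pooling

def _conv1d_forward(x, W, b):
    """Same-padded stride-1 1-D convolution.

    Computed as a sum of k shifted batched matmuls
    y = sum_j W[:, :, j] @ x_padded[:, :, j : j + L], which keeps every
    product a BLAS call without materializing an im2col matrix.
    """
    N, Cin, L = x.shape
    Cout, _, k = W.shape
    p = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
    y = np.matmul(W[:, :, 0], xp[:, :, 0:L])
    for j in range(1, k):
        y += np.matmul(W[:, :, j], xp[:, :, j : j + L])
    y += b[None, :, None]
    return y, (xp, x.shape)


def _conv1d_backward(dy, W, cache):
    xp, xshape = cache
    N, Cin, L = xshape
    Cout, _, k = W.shape
    p = (k - 1) // 2
    dW = np.empty_like(W)
    dxp = np.zeros_like(xp)
    WT = np.ascontiguousarray(W.transpose(2, 1, 0))  # (k, Cin, Cout)
    xpT = xp.transpose(0, 2, 1)  # (N, L + 2p, Cin) view
    for j in range(k):
        dW[:, :, j] = np.matmul(dy, xpT[:, j : j + L, :]).sum(axis=0)
        dxp[:, :, j : j + L] += np.matmul(WT[j], dy)
    db = dy.sum(axis=(0, 2))
    return dxp[:, :, p : p + L], dW, db


def max_pool(x: np.ndarray, pool: PoolSpec = PoolSpec()) -> np.ndarray:
    """Ceil-mode max pooling along the last axis; works on any leading shape."""
    x = np.asarray(x)
    L = x.shape[-1]
    n_out = -(-max(L - pool.width, 0) // pool.stride) + 1 if L >= 1 else 0
    segments = [
        x[..., i * pool.stride : i * pool.stride + pool.width].max(axis=-1)
        for i in range(n_out)
    ]
    return np.stack(segments, axis=-1)


def _maxpool_forward(x, pool):
    """Fast path for the training pipeline (width == stride)."""
    if pool.width != pool.stride:
        raise ValueError("training pipeline requires pool width == stride")
    N, C, L = x.shape
    s = pool.stride
    pad = (-L) % s
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (0, pad)), constant_values=-np.inf)
    Lc = x.shape[2] // s
    xr = x.reshape(N, C, Lc, s)
    if s == 2:
        right = xr[..., 1] > xr[..., 0]  # left element wins ties
        y = np.where(right, xr[..., 1], xr[..., 0])
        return y, (right, L, s)
    idx = xr.argmax(axis=3)
    y = np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]
    return y, (idx, L, s)


def _maxpool_backward(dy, cache):
    idx, L, s = cache
    N, C, Lc = dy.shape
    if s == 2:
        dxr = np.empty((N, C, Lc, 2), dtype=dy.dtype)
        np.multiply(dy, ~idx, out=dxr[..., 0])
        np.multiply(dy, idx, out=dxr[..., 1])
        return dxr.reshape(N, C, Lc * 2)[..., :L]
    dxr = np.zeros((N, C, Lc, s), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=3)
    return dxr.reshape(N, C, Lc * s)[..., :L]


def dropout_mask(shape, p: float, mode: str = "train", seed=0) -> np.ndarray:
    """Inverted-dropout mask: zeros w.p. p, survivors scaled by 1/(1-p);
    the identity in eval mode so inference needs no correction."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"dropout p must be in [0,1), got {p}")
    if mode == "eval" or p == 0.0:
        return np.ones(shape)
    rng = _as_rng(seed)
    return (rng.random(shape) >= p) / (1.0 - p)


# ---------------------------------------------------------------------------
# full pipeline

def _pipeline_forward(params, batch, mode, rng):
    """Run the full stack, collecting caches for the backward pass."""
    arch = params.arch
    dtype = params.dtype
    x = np.ascontiguousarray(np.asarray(batch, dtype=dtype))
    if x.ndim != 2 or x.shape[1] != params.input_length:
        raise ValueError(
            f"batch must be (n, {params.input_length}), got {x.shape}"
        )
    caches: dict = {"conv": [], "fc": []}

    if arch.conv_layers:
        x = x[:, None, :]  # (N, 1, L)
        if params.input_bn is not None:
            x, caches["input_bn"] = _bn_forward(
                x, params.input_bn["gamma"], params.input_bn["beta"], mode,
                params.input_bn["run_mean"], params.input_bn["run_var"],
                BN_EPSILON, BN_MOMENTUM,
            )
        for layer in params.conv:
            x, c_conv = _conv1d_forward(x, layer["W"], layer["b"])
            c_bn = None
            if "gamma" in layer:
                x, c_bn = _bn_forward(
                    x, layer["gamma"], layer["beta"], mode,
                    layer["run_mean"], layer["run_var"], BN_EPSILON, BN_MOMENTUM,
                )
            x, c_act = _activation_forward(x, arch.activation, arch.leaky_slope)
            x, c_pool = _maxpool_forward(x, arch.pool)
            caches["conv"].append((c_conv, c_bn, c_act, c_pool))
        caches["conv_out_shape"] = x.shape
        x = x.reshape(x.shape[0], -1)
    else:
        if params.input_bn is not None:
            x, caches["input_bn"] = _bn_forward(
                x, params.input_bn["gamma"], params.input_bn["beta"], mode,
                params.input_bn["run_mean"], params.input_bn["run_var"],
                BN_EPSILON, BN_MOMENTUM,
            )

    n_fc = len(params.fc)
    for i, layer in enumerate(params.fc):
        z = x @ layer["W"] + layer["b"]
        if i < n_fc - 1:
            a, c_act = _activation_forward(z, arch.activation, arch.leaky_slope)
            mask = None
            if mode == "train" and arch.dropout_p > 0.0:
                mask = dropout_mask(a.shape, arch.dropout_p, "train", rng).astype(dtype)
                out = a * mask
            else:
                out = a
            caches["fc"].append((x, c_act, mask))
            x = out
        else:
            caches["fc"].append((x, None, None))
            x = z
    return x, caches


def forward(params: NetworkParameters, batch: np.ndarray, mode: str = "eval",
            rng=None) -> np.ndarray:
    """Logits (n, C) for a batch of spectra.

    Eval mode is deterministic (running BN statistics, no dropout); train
    mode uses batch statistics and draws dropout masks from ``rng``.
    """
    if mode not in ("train", "eval"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "train" and rng is None:
        rng = np.random.default_rng(0)
    logits, _ = _pipeline_forward(params, batch, mode, rng)
    return logits


def predict_labels(params: NetworkParameters, spectra: np.ndarray,
                   batch_size: int = 256) -> np.ndarray:
    """Eval-mode 1-based class predictions, batched to bound memory."""
    out = []
    for start in range(0, len(spectra), batch_size):
        logits = forward(params, spectra[start : start + batch_size], mode="eval")
        out.append(np.argmax(logits, axis=1) + 1)
    return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


def forward_backward(
    params: NetworkParameters,
    batch: np.ndarray,
    onehot: np.ndarray,
    rng,
    l2_lambda: float = 0.0,
):
    """One train-mode pass: softmax cross-entropy + L2 loss and all gradients.

    Returns ``(cross_entropy, l2, grads, probs)`` where ``grads`` mirrors
    the parameter layout.  The cross-entropy is the batch mean; the L2 term
    is l2_lambda * sum of squared weights and its gradient 2*l2_lambda*W is
    folded into the weight gradients.
    """
    logits, caches = _pipeline_forward(params, batch, "train", rng)
    n = logits.shape[0]
    probs = softmax(logits)
    true = np.clip((probs * onehot).sum(axis=1), 1e-12, None)
    ce = float(-np.log(true).mean())

    dtype = params.dtype
    dlogits = ((probs - onehot) / n).astype(dtype)
    grads = {"conv": [], "fc": []}

    dx = dlogits
    for i in range(len(params.fc) - 1, -1, -1):
        x_in, c_act, mask = caches["fc"][i]
        layer = params.fc[i]
        if i < len(params.fc) - 1:
            if mask is not None:
                dx = dx * mask
            dx = _activation_backward(dx, c_act, params.arch.activation,
                                      params.arch.leaky_slope)
        gW = x_in.T @ dx
        if l2_lambda:
            gW += (2.0 * l2_lambda) * layer["W"]
        grads["fc"].insert(0, {"W": gW, "b": dx.sum(axis=0)})
        dx = dx @ layer["W"].T

    if params.arch.conv_layers:
        dx = dx.reshape(caches["conv_out_shape"])
        for i in range(len(params.conv) - 1, -1, -1):
            c_conv, c_bn, c_act, c_pool = caches["conv"][i]
            layer = params.conv[i]
            dx = _maxpool_backward(dx, c_pool)
            dx = _activation_backward(dx, c_act, params.arch.activation,
                                      params.arch.leaky_slope)
            g = {}
            if c_bn is not None:
                dx, g["gamma"], g["beta"] = _bn_backward(dx, c_bn)
            dx, gW, g["b"] = _conv1d_backward(dx, layer["W"], c_conv)
            if l2_lambda:
                gW += (2.0 * l2_lambda) * layer["W"]
            g["W"] = gW
            grads["conv"].insert(0, g)

    if params.input_bn is not None:
        dx_in, dgamma, dbeta = _bn_backward(dx, caches["input_bn"])
        grads["input_bn"] = {"gamma": dgamma, "beta": dbeta}

    l2 = l2_lambda * sum(float(np.vdot(w, w))
                         for w in params.weight_tensors()) if l2_lambda else 0.0
    return ce, l2, grads, probs


# ---------------------------------------------------------------------------
# persistence

def save_params(params: NetworkParameters, path) -> None:
    """Serialize parameters (and the architecture) to an .npz archive."""
    import json

    arch = params.arch
    meta = {
        "conv_layers": [(s.kernel_width, s.out_channels, s.stride)
                        for s in arch.conv_layers],
        "pool": (arch.pool.width, arch.pool.stride),
        "fc_widths": list(arch.fc_widths),
        "activation": arch.activation,
        "leaky_slope": arch.leaky_slope,
        "dropout_p": arch.dropout_p,
        "batch_norm": arch.batch_norm,
        "input_length": params.input_length,
        "init_method": params.init_method,
    }
    arrays = {"_meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    if params.input_bn is not None:
        for k, v in params.input_bn.items():
            arrays[f"input_bn.{k}"] = v
    for i, layer in enumerate(params.conv):
        for k, v in layer.items():
            if isinstance(v, np.ndarray):
                arrays[f"conv{i}.{k}"] = v
    for i, layer in enumerate(params.fc):
        for k, v in layer.items():
            if isinstance(v, np.ndarray):
                arrays[f"fc{i}.{k}"] = v
    np.savez(path, **arrays)


def load_params(path) -> NetworkParameters:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        arch = ArchitectureSpec(
            conv_layers=tuple(ConvLayerSpec(*t) for t in meta["conv_layers"]),
            pool=PoolSpec(*meta["pool"]),
            fc_widths=tuple(meta["fc_widths"]),
            activation=meta["activation"],
            leaky_slope=meta["leaky_slope"],
            dropout_p=meta["dropout_p"],
            batch_norm=meta["batch_norm"],
        )
        params = build_network(arch, meta["input_length"], seed=0,
                               init_method=meta["init_method"])
        if params.input_bn is not None:
            for k in list(params.input_bn):
                params.input_bn[k] = data[f"input_bn.{k}"]
        for i, layer in enumerate(params.conv):
            for k in list(layer):
                if isinstance(layer[k], np.ndarray):
                    layer[k] = data[f"conv{i}.{k}"]
        for i, layer in enumerate(params.fc):
            for k in list(layer):
                if isinstance(layer[k], np.ndarray):
                    layer[k] = data[f"fc{i}.{k}"]
    return params
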