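"""The compact 3D CNN that scores Syed suitability from contour anatomy.

Six convolutional blocks (zero-pad -> 3D conv -> max-pool -> batch-norm ->
ReLU) followed by global average pooling, a dense layer of 8 units, dropout,
a single output unit and a sigmoid.  The default block specification is:

    block   pad        filters  kernel     pool
    1       (1,1,1)    4        (3,2,2)    (3,3,3)
    2       (1,1,1)    4        (2,2,2)    (2,2,2)
    3       (1,1,1)    8        (3,3,3)    (2,2,2)
    4       (2,1,1)    8        (3,2,2)    (2,2,2)
    5       (1,1,1)    4        (3,3,3)    (2,2,2)
    6       (1,1,1)    4        (3,3,3)    (2,2,2)

which totals 3409 parameters for 3 input channels (3281 conv/dense weights
and biases plus 4 batch-norm values per normalized channel) and 3313 for the
single-channel mask-only variant.

The network is implemented directly on NumPy arrays with an explicit
backward pass; at ~3.4k parameters there is nothing a heavyweight autodiff
framework would add, and every gradient is verified against central finite
differences in the test suite.

Conventions (the literature leaves them open; fixed here and documented in
the methods note): convolutions are stride 1 and applied after zero
padding; pooling is non-overlapping with ceil-mode windows (a window must
fit at least once, trailing partial windows are allowed); initialization is
uniform fan-in scaling with a fixed seed; dropout sits between the two
dense layers and is inactive at inference; inference uses batch-norm
running statistics, making predictions independent of batch composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ShapeError
from .structures import SYED, TANDO

__all__ = [
    "BlockSpec",
    "NetworkSpec",
    "Network",
    "build_network",
    "count_parameters",
    "classify",
    "SYED",
    "TANDO",
]


@dataclass(frozen=True)
class BlockSpec:
    zero_pad: tuple
    n_filters: int
    filter_size: tuple
    pool_size: tuple


DEFAULT_BLOCKS = (
    BlockSpec((1, 1, 1), 4, (3, 2, 2), (3, 3, 3)),
    BlockSpec((1, 1, 1), 4, (2, 2, 2), (2, 2, 2)),
    BlockSpec((1, 1, 1), 8, (3, 3, 3), (2, 2, 2)),
    BlockSpec((2, 1, 1), 8, (3, 2, 2), (2, 2, 2)),
    BlockSpec((1, 1, 1), 4, (3, 3, 3), (2, 2, 2)),
    BlockSpec((1, 1, 1), 4, (3, 3, 3), (2, 2, 2)),
)


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters; defaults are the production network."""

    blocks: tuple = DEFAULT_BLOCKS
    dense_units: tuple = (8, 1)
    dropout_rate: float = 0.10
    in_channels: int = 3

    @classmethod
    def default(cls, in_channels: int = 3, dropout_rate: float = 0.10) -> "NetworkSpec":
        return cls(in_channels=in_channels, dropout_rate=dropout_rate)

    @classmethod
    def mask_only(cls, dropout_rate: float = 0.10) -> "NetworkSpec":
        return cls(in_channels=1, dropout_rate=dropout_rate)

    def output_spatial_shape(self, spatial_shape) -> tuple:
        """Walk the conv/pool chain; raises ShapeError when it cannot fit."""
        shape = tuple(int(s) for s in spatial_shape)
        if len(shape) != 3:
            raise ShapeError("input must be 3-dimensional")
        for bi, blk in enumerate(self.blocks, start=1):
            conv = tuple(
                s + 2 * p - k + 1
                for s, p, k in zip(shape, blk.zero_pad, blk.filter_size)
            )
            if any(c < 1 for c in conv):
                raise ShapeError(
                    f"block {bi}: kernel {blk.filter_size} does not fit input {shape} "
                    f"with padding {blk.zero_pad}"
                )
            if any(c < p for c, p in zip(conv, blk.pool_size)):
                raise ShapeError(
                    f"block {bi}: pooling window {blk.pool_size} larger than "
                    f"feature map {conv}"
                )
            shape = tuple(math.ceil(c / p) for c, p in zip(conv, blk.pool_size))
        return shape


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class _Layer:
    """Minimal layer protocol: params/grads dicts plus forward/backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def trainable_keys(self):
        return list(self.params)

    def forward(self, x, training=False, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv3D(_Layer):
    """Stride-1 3D convolution with zero padding, NCDHW layout."""

    def __init__(self, in_channels, n_filters, kernel, pad, rng, dtype=np.float64):
        super().__init__()
        self.kernel = tuple(kernel)
        self.pad = tuple(pad)
        fan_in = in_channels * int(np.prod(kernel))
        limit = 1.0 / math.sqrt(fan_in)
        self.params["W"] = rng.uniform(
            -limit, limit, size=(n_filters, in_channels, *kernel)
        ).astype(dtype)
        self.params["b"] = np.zeros(n_filters, dtype=dtype)

    def forward(self, x, training=False, rng=None):
        pd, ph, pw = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
        kd, kh, kw = self.kernel
        B, C, D, H, W = xp.shape
        Do, Ho, Wo = D - kd + 1, H - kh + 1, W - kw + 1
        if min(Do, Ho, Wo) < 1:
            raise ShapeError(f"kernel {self.kernel} does not fit input {x.shape[2:]}")
        Wk = self.params["W"]
        out = np.zeros((B, Wk.shape[0], Do, Ho, Wo), dtype=x.dtype)
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    xs = xp[:, :, i : i + Do, j : j + Ho, k : k + Wo]
                    out += np.einsum("bcdhw,fc->bfdhw", xs, Wk[:, :, i, j, k], optimize=True)
        out += self.params["b"][None, :, None, None, None]
        self._cache = xp
        return out

    def backward(self, dy, need_input_grad=True):
        xp = self._cache
        kd, kh, kw = self.kernel
        Do, Ho, Wo = dy.shape[2:]
        Wk = self.params["W"]
        dW = np.zeros_like(Wk)
        dxp = np.zeros_like(xp) if need_input_grad else None
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    xs = xp[:, :, i : i + Do, j : j + Ho, k : k + Wo]
                    dW[:, :, i, j, k] = np.einsum("bfdhw,bcdhw->fc", dy, xs, optimize=True)
                    if need_input_grad:
                        dxp[:, :, i : i + Do, j : j + Ho, k : k + Wo] += np.einsum(
                            "bfdhw,fc->bcdhw", dy, Wk[:, :, i, j, k], optimize=True
                        )
        self.grads["W"] = dW
        self.grads["b"] = dy.sum(axis=(0, 2, 3, 4))
        if not need_input_grad:
            return None
        pd, ph, pw = self.pad
        D, H, W = xp.shape[2:]
        return dxp[:, :, pd : D - pd, ph : H - ph, pw : W - pw]


class MaxPool3D(_Layer):
    """Non-overlapping max pooling, ceil mode (trailing partial windows)."""

    def __init__(self, pool):
        super().__init__()
        self.pool = tuple(pool)

    def forward(self, x, training=False, rng=None):
        pd, ph, pw = self.pool
        B, C, D, H, W = x.shape
        if D < pd or H < ph or W < pw:
            raise ShapeError(f"pooling window {self.pool} larger than input {(D, H, W)}")
        Do, Ho, Wo = math.ceil(D / pd), math.ceil(H / ph), math.ceil(W / pw)
        pad = (Do * pd - D, Ho * ph - H, Wo * pw - W)
        xp = np.pad(
            x,
            ((0, 0), (0, 0), (0, pad[0]), (0, pad[1]), (0, pad[2])),
            constant_values=-np.inf,
        )
        win = (
            xp.reshape(B, C, Do, pd, Ho, ph, Wo, pw)
            .transpose(0, 1, 2, 4, 6, 3, 5, 7)
            .reshape(B, C, Do, Ho, Wo, pd * ph * pw)
        )
        arg = win.argmax(axis=-1)
        out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, xp.shape, arg)
        return out

    def backward(self, dy):
        x_shape, xp_shape, arg = self._cache
        pd, ph, pw = self.pool
        B, C, D, H, W = x_shape
        Do, Ho, Wo = dy.shape[2:]
        dwin = np.zeros((B, C, Do, Ho, Wo, pd * ph * pw), dtype=dy.dtype)
        np.put_along_axis(dwin, arg[..., None], dy[..., None], axis=-1)
        dxp = (
            dwin.reshape(B, C, Do, Ho, Wo, pd, ph, pw)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(xp_shape)
        )
        return dxp[:, :, :D, :H, :W]


class BatchNorm3D(_Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels, momentum=0.1, eps=1e-5, dtype=np.float64):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        # running statistics: part of the state (and of the parameter count
        # convention) but never touched by the optimizer
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x, training=False, rng=None):
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(x.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv_std[None, :, None, None, None]
        out = (
            self.params["gamma"][None, :, None, None, None] * xhat
            + self.params["beta"][None, :, None, None, None]
        )
        self._cache = (xhat, inv_std, training, x.shape)
        return out

    def backward(self, dy):
        xhat, inv_std, training, shape = self._cache
        axes = (0, 2, 3, 4)
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"][None, :, None, None, None]
        if not training:
            return dy * g * inv_std[None, :, None, None, None]
        n = shape[0] * shape[2] * shape[3] * shape[4]
        dxhat = dy * g
        return (
            inv_std[None, :, None, None, None]
            / n
            * (
                n * dxhat
                - dxhat.sum(axis=axes, keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True)
            )
        )


class ReLU(_Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class GlobalAvgPool(_Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dy):
        B, C, D, H, W = self._shape
        return np.broadcast_to(
            dy[:, :, None, None, None] / (D * H * W), self._shape
        ).copy()


class Dense(_Layer):
    def __init__(self, n_in, n_out, rng, dtype=np.float64):
        super().__init__()
        limit = 1.0 / math.sqrt(n_in)
        self.params["W"] = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(dtype)
        self.params["b"] = np.zeros(n_out, dtype=dtype)

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Dropout(_Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate):
        super().__init__()
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


def _sigmoid(z):
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


class Network:
    """Built network state: layers, weights, and batch-norm statistics."""

    def __init__(self, spec: NetworkSpec, seed: int, input_shape=None, dtype=np.float32):
        self.spec = spec
        self.seed = int(seed)
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(self.seed)
        self.layers: list[_Layer] = []
        in_ch = spec.in_channels
        for blk in spec.blocks:
            self.layers.append(
                Conv3D(in_ch, blk.n_filters, blk.filter_size, blk.zero_pad, rng, dtype=self.dtype)
            )
            self.layers.append(MaxPool3D(blk.pool_size))
            self.layers.append(BatchNorm3D(blk.n_filters, dtype=self.dtype))
            self.layers.append(ReLU())
            in_ch = blk.n_filters
        self.layers.append(GlobalAvgPool())
        n_hidden, n_out = spec.dense_units
        self.layers.append(Dense(in_ch, n_hidden, rng, dtype=self.dtype))
        self.layers.append(Dropout(spec.dropout_rate))
        self.layers.append(Dense(n_hidden, n_out, rng, dtype=self.dtype))
        if input_shape is not None:
            spec.output_spatial_shape(input_shape)

    # -- inference ---------------------------------------------------------

    def forward_logits(self, x, training=False, rng=None):
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 4:
            x = x[None]
        if x.shape[1] != self.spec.in_channels:
            raise ShapeError(
                f"expected {self.spec.in_channels} channels, got {x.shape[1]}"
            )
        self.spec.output_spatial_shape(x.shape[2:])
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x[:, 0].astype(np.float64)

    def forward(self, x, training=False, rng=None):
        """Suitability scores p in (0, 1), one per input sample."""
        return _sigmoid(self.forward_logits(x, training=training, rng=rng))

    def predict(self, inputs, batch_size=8):
        """Score a sequence of ModelInput (or channel arrays) in eval mode."""
        arrays = [getattr(m, "channels", m) for m in inputs]
        out = []
        for i in range(0, len(arrays), batch_size):
            out.append(self.forward(np.stack(arrays[i : i + batch_size])))
        return np.concatenate(out) if out else np.zeros(0)

    # -- training plumbing -------------------------------------------------

    def backward_from_logits(self, dlogits):
        """Backpropagate d(loss)/d(logit); fills every layer's grads."""
        dy = np.asarray(dlogits, dtype=self.dtype)[:, None]
        first = self.layers[0]
        for layer in reversed(self.layers):
            if layer is first and isinstance(layer, Conv3D):
                # nothing upstream needs the input gradient
                return layer.backward(dy, need_input_grad=False)
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        """Yield (layer, key, array) for every optimizer-updated parameter."""
        for layer in self.layers:
            for key in layer.trainable_keys():
                yield layer, key, layer.params[key]

    def parameter_vector(self) -> np.ndarray:
        return np.concatenate([p.ravel() for _, _, p in self.parameters()] or [np.zeros(0)])

    def l1_norm(self) -> float:
        return float(sum(np.abs(p).sum() for _, _, p in self.parameters()))

    def set_all_weights(self, value: float) -> None:
        for layer in self.layers:
            for key in layer.params:
                layer.params[key][...] = value

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: architecture spec + all state arrays."""
        import json

        arrays = {}
        for i, layer in enumerate(self.layers):
            for key, val in layer.params.items():
                arrays[f"layer{i}.{key}"] = val
            if isinstance(layer, BatchNorm3D):
                arrays[f"layer{i}.running_mean"] = layer.running_mean
                arrays[f"layer{i}.running_var"] = layer.running_var
        spec_doc = {
            "blocks": [
                [list(b.zero_pad), b.n_filters, list(b.filter_size), list(b.pool_size)]
                for b in self.spec.blocks
            ],
            "dense_units": list(self.spec.dense_units),
            "dropout_rate": self.spec.dropout_rate,
            "in_channels": self.spec.in_channels,
            "seed": self.seed,
        }
        arrays["spec_json"] = np.frombuffer(
            json.dumps(spec_doc).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "Network":
        import json

        with np.load(path) as data:
            spec_doc = json.loads(bytes(data["spec_json"]).decode())
            spec = NetworkSpec(
                blocks=tuple(
                    BlockSpec(tuple(p), f, tuple(k), tuple(q))
                    for p, f, k, q in spec_doc["blocks"]
                ),
                dense_units=tuple(spec_doc["dense_units"]),
                dropout_rate=spec_doc["dropout_rate"],
                in_channels=spec_doc["in_channels"],
            )
            net = cls(spec, seed=spec_doc["seed"])
            for i, layer in enumerate(net.layers):
                for key in layer.params:
                    layer.params[key] = data[f"layer{i}.{key}"]
                if isinstance(layer, BatchNorm3D):
                    layer.running_mean = data[f"layer{i}.running_mean"]
                    layer.running_var = data[f"layer{i}.running_var"]
        return net


def build_network(spec: NetworkSpec, seed: int, input_shape=None) -> Network:
    """Deterministically initialize a network from its specification."""
    return Network(spec, seed=seed, input_shape=input_shape)


def count_parameters(network: Network) -> int:
    """Parameter count under the 4-per-batch-norm-channel convention.

    Every convolution and dense weight and bias counts once; each
    batch-normalized channel contributes four values (scale, shift, running
    mean, running variance).  This is the convention under which the default
    3-channel configuration counts 3409.
    """
    total = 0
    for layer in network.layers:
        if isinstance(layer, (Conv3D, Dense)):
            total += layer.params["W"].size + layer.params["b"].size
        elif isinstance(layer, BatchNorm3D):
            total += 4 * layer.params["gamma"].size
    return total


def classify(scores, threshold: float = 0.5):
    """Map suitability scores to applicator labels: SYED iff p >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.where(scores >= threshold, SYED, TANDO)
    return labels if labels.ndim else int(labels)
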