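"""Minimal channel-last neural-network engine on numpy.

Implements exactly the layer set the segmentation architecture needs —
2D convolution ('same' padding), 2x2/stride-2 transposed convolution,
batch normalization, 2x2 max pooling, 3x3/stride-1 max pooling, dropout,
channel concatenation and per-pixel softmax — each with a hand-derived
backward pass, plus the Adam optimizer.  Tensors are float32 arrays of
shape (N, H, W, C).

The engine is deliberately small: layers cache whatever their backward
pass needs during ``forward`` and release it on the next call, and the
graph container executes nodes in insertion order (which is required to
be topological).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


@dataclass
class Param:
    """A tensor of weights with its gradient accumulator."""

    value: np.ndarray
    trainable: bool = True
    grad: np.ndarray | None = None

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    """Base layer: forward/backward over positional input tensors."""

    def forward(self, *xs: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def out_channels(self, in_channels: tuple[int, ...]) -> int:
        return in_channels[0]

    def spatial_factor(self) -> float:
        """Output spatial size as a multiple of input size."""
        return 1.0


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class Conv2D(Layer):
    """k x k convolution, stride 1, 'same' zero padding, optional ReLU.

    Weights have shape (k, k, c_in, c_out); bias always present.
    """

    def __init__(self, kernel_size: int, c_in: int, c_out: int,
                 activation: str = "linear", rng: np.random.Generator | None = None):
        if kernel_size % 2 != 1 or kernel_size < 1:
            raise ValueError("kernel_size must be odd and positive")
        if activation not in ("linear", "relu"):
            raise ValueError(f"unknown activation {activation!r}")
        self.k, self.c_in, self.c_out = kernel_size, c_in, c_out
        self.activation = activation
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (kernel_size * kernel_size * c_in))
        self.w = Param(rng.normal(0.0, std, (kernel_size, kernel_size, c_in, c_out)).astype(DTYPE))
        self.b = Param(np.zeros(c_out, dtype=DTYPE))
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def out_channels(self, in_channels: tuple[int, ...]) -> int:
        return self.c_out

    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray) -> np.ndarray:
        k = w.shape[0]
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # windows: (N, H, W, C, k, k)
        win = sliding_window_view(xp, (k, k), axis=(1, 2))
        return np.tensordot(win, w, axes=([3, 4, 5], [2, 0, 1])).astype(DTYPE)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        z = self._conv(x, self.w.value) + self.b.value
        y = _relu(z) if self.activation == "relu" else z
        self._cache = (x, z if self.activation == "relu" else None)
        return y

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        x, z = self._cache
        if self.activation == "relu":
            gy = gy * (z > 0)
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N,H,W,Cin,k,k)
        # dW: contract over batch and space -> (Cin,k,k,Cout) -> (k,k,Cin,Cout)
        gw = np.tensordot(win, gy, axes=([0, 1, 2], [0, 1, 2])).transpose(1, 2, 0, 3)
        self.w.grad = gw.astype(DTYPE)
        self.b.grad = gy.sum(axis=(0, 1, 2)).astype(DTYPE)
        # dX: correlate gy with spatially flipped, channel-swapped kernel
        w_flip = self.w.value[::-1, ::-1].transpose(0, 1, 3, 2)  # (k,k,Cout,Cin)
        gx = self._conv(gy, w_flip)
        self._cache = None
        return (gx,)


class TransposedConv2x2(Layer):
    """2x2 transposed convolution with stride 2 (exact 2x upsampling).

    Each input pixel maps to a disjoint 2x2 output block, so the layer is a
    per-pixel linear map from c_in to 4*c_out followed by a reshape.
    """

    def __init__(self, c_in: int, c_out: int, activation: str = "relu",
                 rng: np.random.Generator | None = None):
        self.c_in, self.c_out = c_in, c_out
        self.activation = activation
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (4 * c_in))
        self.w = Param(rng.normal(0.0, std, (2, 2, c_in, c_out)).astype(DTYPE))
        self.b = Param(np.zeros(c_out, dtype=DTYPE))
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def out_channels(self, in_channels: tuple[int, ...]) -> int:
        return self.c_out

    def spatial_factor(self) -> float:
        return 2.0

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, _ = x.shape
        t = np.tensordot(x, self.w.value, axes=([3], [2]))  # (N,H,W,2,2,Cout)
        y = t.transpose(0, 1, 3, 2, 4, 5).reshape(n, 2 * h, 2 * w, self.c_out)
        z = (y + self.b.value).astype(DTYPE)
        out = _relu(z) if self.activation == "relu" else z
        self._cache = (x, z if self.activation == "relu" else None)
        return out

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        x, z = self._cache
        if self.activation == "relu":
            gy = gy * (z > 0)
        n, h2, w2, _ = gy.shape
        h, w = h2 // 2, w2 // 2
        gt = gy.reshape(n, h, 2, w, 2, self.c_out).transpose(0, 1, 3, 2, 4, 5)
        gw = np.tensordot(x, gt, axes=([0, 1, 2], [0, 1, 2]))  # (Cin,2,2,Cout)
        self.w.grad = gw.transpose(1, 2, 0, 3).astype(DTYPE)
        self.b.grad = gy.sum(axis=(0, 1, 2)).astype(DTYPE)
        gx = np.tensordot(gt, self.w.value, axes=([3, 4, 5], [0, 1, 3])).astype(DTYPE)
        self._cache = None
        return (gx,)


class BatchNorm(Layer):
    """Per-channel batch normalization with optional fused ReLU.

    gamma/beta are trainable; running mean/variance are the non-trainable
    statistics (2 per channel each way).
    """

    def __init__(self, channels: int, activation: str = "linear",
                 momentum: float = 0.99, eps: float = 1e-3):
        self.channels = channels
        self.activation = activation
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=DTYPE))
        self.beta = Param(np.zeros(channels, dtype=DTYPE))
        self.running_mean = Param(np.zeros(channels, dtype=DTYPE), trainable=False)
        self.running_var = Param(np.ones(channels, dtype=DTYPE), trainable=False)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta, self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean.value = (m * self.running_mean.value + (1 - m) * mean).astype(DTYPE)
            self.running_var.value = (m * self.running_var.value + (1 - m) * var).astype(DTYPE)
        else:
            mean = self.running_mean.value
            var = self.running_var.value
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        z = (self.gamma.value * xhat + self.beta.value).astype(DTYPE)
        y = _relu(z) if self.activation == "relu" else z
        self._cache = (xhat.astype(DTYPE), inv.astype(DTYPE), training,
                       z if self.activation == "relu" else None)
        return y

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        xhat, inv, training, z = self._cache
        if self.activation == "relu":
            gy = gy * (z > 0)
        self.gamma.grad = (gy * xhat).sum(axis=(0, 1, 2)).astype(DTYPE)
        self.beta.grad = gy.sum(axis=(0, 1, 2)).astype(DTYPE)
        g = self.gamma.value
        if not training:
            gx = gy * (g * inv)
        else:
            m = gy.shape[0] * gy.shape[1] * gy.shape[2]
            gxhat = gy * g
            gx = (inv / m) * (m * gxhat
                              - gxhat.sum(axis=(0, 1, 2))
                              - xhat * (gxhat * xhat).sum(axis=(0, 1, 2)))
        self._cache = None
        return (gx.astype(DTYPE),)


class MaxPool2x2(Layer):
    """2x2 max pooling with stride 2."""

    def spatial_factor(self) -> float:
        return 0.5

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        xr = xr.reshape(n, h // 2, w // 2, 4, c)
        self._idx = xr.argmax(axis=3)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        n, h, w, c = self._shape
        gxr = np.zeros((n, h // 2, w // 2, 4, c), dtype=DTYPE)
        np.put_along_axis(gxr, self._idx[:, :, :, None, :], gy[:, :, :, None, :], axis=3)
        gx = gxr.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, h, w, c)
        return (gx,)


class MaxPool3x3Same(Layer):
    """3x3 max pooling with stride 1 and 'same' padding (Inception branch)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)), constant_values=-np.inf)
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N,H,W,C,3,3)
        flat = win.reshape(win.shape[:4] + (9,))
        self._argmax = flat.argmax(axis=4)
        self._shape = x.shape
        return flat.max(axis=4).astype(DTYPE)

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        n, h, w, c = self._shape
        gxp = np.zeros((n, h + 2, w + 2, c), dtype=DTYPE)
        # window (i, j) covers padded rows i..i+2; argmax a -> (i + a//3, j + a%3)
        ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        rows = ii[None, :, :, None] + self._argmax // 3
        cols = jj[None, :, :, None] + self._argmax % 3
        nn_idx = np.broadcast_to(np.arange(n)[:, None, None, None], self._argmax.shape)
        cc = np.broadcast_to(np.arange(c)[None, None, None, :], self._argmax.shape)
        np.add.at(gxp, (nn_idx, rows, cols, cc), gy)
        return (gxp[:, 1:-1, 1:-1, :],)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        self.rate = rate
        self.rng = np.random.default_rng(0)
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        if self._mask is None:
            return (gy,)
        return (gy * self._mask,)


class Concat(Layer):
    """Channel-axis concatenation of two tensors."""

    def out_channels(self, in_channels: tuple[int, ...]) -> int:
        return sum(in_channels)

    def forward(self, *xs: np.ndarray, training: bool = False) -> np.ndarray:
        self._splits = np.cumsum([x.shape[-1] for x in xs])[:-1]
        return np.concatenate(xs, axis=-1)

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        return tuple(np.split(gy, self._splits, axis=-1))


class Softmax(Layer):
    """Per-pixel softmax over the channel axis."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        y = (e / e.sum(axis=-1, keepdims=True)).astype(DTYPE)
        self._y = y
        return y

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        y = self._y
        gx = y * (gy - (gy * y).sum(axis=-1, keepdims=True))
        return (gx.astype(DTYPE),)


@dataclass
class _Node:
    name: str
    layer: Layer | None
    inputs: list[str]
    shape: tuple[int, int, int]  # (H, W, C) for batch size 1


class Graph:
    """Ordered DAG of layers with named nodes and named outputs.

    Nodes must be added in topological order; ``outputs`` maps role names
    ('final', 'bottleneck') to node names.
    """

    def __init__(self, input_shape: tuple[int, int, int]):
        self.nodes: dict[str, _Node] = {
            "input": _Node("input", None, [], input_shape)}
        self.outputs: dict[str, str] = {}

    def add(self, name: str, layer: Layer, inputs: str | list[str]) -> str:
        if isinstance(inputs, str):
            inputs = [inputs]
        if name in self.nodes:
            raise ValueError(f"duplicate node name {name!r}")
        for src in inputs:
            if src not in self.nodes:
                raise ValueError(f"unknown input node {src!r} for {name!r}")
        shapes = [self.nodes[s].shape for s in inputs]
        f = layer.spatial_factor()
        h = int(round(shapes[0][0] * f))
        w = int(round(shapes[0][1] * f))
        c = layer.out_channels(tuple(s[2] for s in shapes))
        self.nodes[name] = _Node(name, layer, inputs, (h, w, c))
        return name

    # -- execution -----------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> dict[str, np.ndarray]:
        """Run the graph; returns {role: tensor} for the declared outputs."""
        acts: dict[str, np.ndarray] = {"input": x.astype(DTYPE)}
        for node in self.nodes.values():
            if node.layer is None:
                continue
            xs = [acts[s] for s in node.inputs]
            acts[node.name] = node.layer.forward(*xs, training=training)
        self._acts = acts
        return {role: acts[name] for role, name in self.outputs.items()}

    def activations(self) -> dict[str, np.ndarray]:
        return self._acts

    def backward(self, output_grads: dict[str, np.ndarray],
                 capture: set[str] | None = None) -> dict[str, np.ndarray]:
        """Backpropagate from seed gradients on output roles.

        ``capture`` names nodes whose accumulated output gradient should be
        returned (used by Grad-CAM); parameter gradients are stored on the
        layers either way.
        """
        acc: dict[str, np.ndarray] = {}
        for role, g in output_grads.items():
            name = self.outputs[role]
            acc[name] = acc.get(name, 0) + g
        captured: dict[str, np.ndarray] = {}
        for node in reversed(list(self.nodes.values())):
            if node.name not in acc:
                continue
            g = acc.pop(node.name)
            if capture and node.name in capture:
                captured[node.name] = g
            if node.layer is None:
                captured.setdefault("input", g)
                continue
            gxs = node.layer.backward(g)
            for src, gx in zip(node.inputs, gxs):
                acc[src] = acc.get(src, 0) + gx
        return captured

    # -- parameters ----------------------------------------------------

    def params(self) -> list[Param]:
        out: list[Param] = []
        for node in self.nodes.values():
            if node.layer is not None:
                out.extend(node.layer.params())
        return out

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for node in self.nodes.values():
            if isinstance(node.layer, Dropout):
                node.layer.rng = rng

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for node in self.nodes.values():
            if node.layer is None:
                continue
            for i, p in enumerate(node.layer.params()):
                out[f"{node.name}/{i}"] = p.value
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for node in self.nodes.values():
            if node.layer is None:
                continue
            for i, p in enumerate(node.layer.params()):
                key = f"{node.name}/{i}"
                if p.value.shape != weights[key].shape:
                    raise ValueError(f"shape mismatch for {key}")
                p.value = weights[key].astype(DTYPE)


class Adam:
    """Adam optimizer over a graph's trainable parameters."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = [p for p in params if p.trainable]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if g is None:
                continue
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p.value -= (self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(DTYPE)
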