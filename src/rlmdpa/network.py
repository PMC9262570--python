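"""Convolutional Q-network in plain NumPy.

The policy/Q-function maps a single-channel square image to one action
value per class (two for binary screening).  The default architecture is
five stride-2, padding-1, kernel-3 convolution layers with 128/64/32/16/8
filters, each followed by ReLU and a 2x2 ceil-mode max-pool, then fully
connected layers of 128/64/32 units with dropout, and a linear two-unit
output head.

Both the forward pass and the gradient of the squared temporal-difference
loss are implemented here by hand (im2col convolution, argmax-scatter
pooling).  All learnable parameters are exposed through a bijective flat
row-major vector encoding so that a population-based optimizer can treat
the whole network as a point in R^D.

Pooling uses ceil mode and is skipped whenever its input spatial dimension
is already 1; with the default five-layer stack on a 100x100 input the
realized spatial sizes are logged in the layer plan and the final feature
map is 1x1x8.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import ConfigurationError, DimensionMismatchError, InputError

__all__ = [
    "NetworkArchitecture",
    "QNetwork",
    "WeightVector",
    "LayoutEntry",
    "build_network",
    "encode_weights",
    "decode_weights",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# architecture


@dataclass(frozen=True)
class NetworkArchitecture:
    """Static description of the Q-network.

    Parameters
    ----------
    input_size
        Height = width of the (single-channel) input image.
    conv_filters
        Output channels of each convolution layer, in order.
    kernel, stride, padding
        Shared geometry of every convolution layer (defaults 3/2/1).
    pool
        Edge length of the max-pool window after each convolution;
        pooling is ceil-mode and skipped once the spatial size is 1.
    fc_sizes
        Hidden-unit counts of the fully connected layers.
    n_actions
        Output dimension; 2 for binary classification.
    dropout_p
        Dropout probability applied after each hidden FC layer
        (training mode only).
    activation
        "relu" (default) or "tanh".
    """

    input_size: int = 100
    conv_filters: tuple[int, ...] = (128, 64, 32, 16, 8)
    kernel: int = 3
    stride: int = 2
    padding: int = 1
    pool: int = 2
    fc_sizes: tuple[int, ...] = (128, 64, 32)
    n_actions: int = 2
    dropout_p: float = 0.4
    activation: str = "relu"

    def __post_init__(self) -> None:
        object.__setattr__(self, "conv_filters", tuple(int(f) for f in self.conv_filters))
        object.__setattr__(self, "fc_sizes", tuple(int(f) for f in self.fc_sizes))

    # -- validation and geometry ------------------------------------------

    def validate(self) -> None:
        if not self.conv_filters or not self.fc_sizes:
            raise ConfigurationError("conv_filters and fc_sizes must be non-empty")
        if any(f <= 0 for f in self.conv_filters):
            raise ConfigurationError(f"non-positive conv filter count in {self.conv_filters}")
        if any(f <= 0 for f in self.fc_sizes):
            raise ConfigurationError(f"non-positive FC size in {self.fc_sizes}")
        if self.n_actions != 2:
            raise ConfigurationError("n_actions must be 2 (binary classification)")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ConfigurationError("dropout_p must be in [0, 1)")
        if self.activation not in ("relu", "tanh"):
            raise ConfigurationError(f"unknown activation {self.activation!r}")
        if self.input_size < self.kernel:
            raise ConfigurationError(
                f"input_size {self.input_size} smaller than kernel {self.kernel}"
            )
        self.layer_plan()  # raises on spatial collapse

    def layer_plan(self) -> list[dict]:
        """Realized per-layer geometry: channels, spatial sizes, pooling.

        Raises :class:`ConfigurationError` naming the first layer whose
        spatial output would collapse to zero.
        """
        plan = []
        size = self.input_size
        channels = 1
        for i, out_c in enumerate(self.conv_filters):
            conv_size = (size + 2 * self.padding - self.kernel) // self.stride + 1
            if conv_size < 1:
                raise ConfigurationError(
                    f"conv layer {i} collapses spatial size {size} -> {conv_size}"
                )
            pooled = conv_size > 1  # skip pooling on 1x1 maps
            pool_size = -(-conv_size // self.pool) if pooled else conv_size
            plan.append(
                {
                    "layer": i,
                    "in_channels": channels,
                    "out_channels": out_c,
                    "in_size": size,
                    "conv_size": conv_size,
                    "pooled": pooled,
                    "out_size": pool_size,
                }
            )
            size, channels = pool_size, out_c
        return plan

    @property
    def feature_size(self) -> int:
        """Flattened length of the last conv feature map."""
        plan = self.layer_plan()
        last = plan[-1]
        return last["out_channels"] * last["out_size"] ** 2

    def parameter_shapes(self) -> list[tuple[str, tuple[int, ...]]]:
        """Ordered (name, shape) pairs: conv layers first, then FC, then head."""
        shapes: list[tuple[str, tuple[int, ...]]] = []
        in_c = 1
        for i, out_c in enumerate(self.conv_filters):
            shapes.append((f"conv{i}.weight", (out_c, in_c, self.kernel, self.kernel)))
            shapes.append((f"conv{i}.bias", (out_c,)))
            in_c = out_c
        in_dim = self.feature_size
        for i, units in enumerate(self.fc_sizes):
            shapes.append((f"fc{i}.weight", (units, in_dim)))
            shapes.append((f"fc{i}.bias", (units,)))
            in_dim = units
        shapes.append(("out.weight", (self.n_actions, in_dim)))
        shapes.append(("out.bias", (self.n_actions,)))
        return shapes

    @property
    def n_parameters(self) -> int:
        return sum(int(np.prod(s)) for _, s in self.parameter_shapes())

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "input_size": self.input_size,
            "conv_filters": list(self.conv_filters),
            "kernel": self.kernel,
            "stride": self.stride,
            "padding": self.padding,
            "pool": self.pool,
            "fc_sizes": list(self.fc_sizes),
            "n_actions": self.n_actions,
            "dropout_p": self.dropout_p,
            "activation": self.activation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkArchitecture":
        d = dict(d)
        for key in ("conv_filters", "fc_sizes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def digest(self) -> str:
        """Stable hash of the architecture, used to guard checkpoints."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# weight vector


@dataclass(frozen=True)
class LayoutEntry:
    name: str
    shape: tuple[int, ...]
    offset: int

    @property
    def size(self) -> int:
        return int(np.prod(self.shape))


@dataclass
class WeightVector:
    """Flat row-major encoding of all learnable parameters.

    Conv layers come first (network order), each tensor immediately
    followed by its bias; then the FC layers and the output head.  Every
    tensor is flattened in C (row-major) order, so a 2x2 kernel
    [[a, b], [c, d]] occupies four consecutive slots (a, b, c, d).
    """

    values: np.ndarray
    layout: tuple[LayoutEntry, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        total = sum(e.size for e in self.layout)
        if total != self.values.size:
            raise DimensionMismatchError(
                f"layout covers {total} parameters but vector has {self.values.size}"
            )

    def __len__(self) -> int:
        return self.values.size

    def segment(self, name: str) -> np.ndarray:
        for e in self.layout:
            if e.name == name:
                return self.values[e.offset : e.offset + e.size]
        raise KeyError(name)


def _make_layout(arch: NetworkArchitecture) -> tuple[LayoutEntry, ...]:
    entries = []
    offset = 0
    for name, shape in arch.parameter_shapes():
        entries.append(LayoutEntry(name, tuple(shape), offset))
        offset += int(np.prod(shape))
    return tuple(entries)


# ---------------------------------------------------------------------------
# layer primitives (forward + backward)


def _conv_forward(x, w, b, stride, pad):
    bsz, in_c, h, _ = x.shape
    out_c, _, k, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    oh, ow = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(bsz, oh * ow, in_c * k * k)
    y = cols @ w.reshape(out_c, -1).T + b
    out = y.transpose(0, 2, 1).reshape(bsz, out_c, oh, ow)
    cache = (cols, x.shape, w, stride, pad, (oh, ow))
    return out, cache


def _conv_backward(dout, cache):
    cols, xshape, w, stride, pad, (oh, ow) = cache
    bsz, in_c, h, wd = xshape
    out_c, _, k, _ = w.shape
    dflat = dout.reshape(bsz, out_c, oh * ow).transpose(0, 2, 1)  # (b, P, out_c)
    dw = np.einsum("bpo,bpi->oi", dflat, cols).reshape(w.shape)
    db = dflat.sum(axis=(0, 1))
    dcols = dflat @ w.reshape(out_c, -1)  # (b, P, in_c*k*k)
    dwin = dcols.reshape(bsz, oh, ow, in_c, k, k)
    dxp = np.zeros((bsz, in_c, h + 2 * pad, wd + 2 * pad))
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki : ki + stride * oh : stride, kj : kj + stride * ow : stride] += (
                dwin[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
            )
    dx = dxp[:, :, pad : pad + h, pad : pad + wd] if pad else dxp
    return dx, dw, db


def _pool_forward(x, p):
    bsz, c, h, w = x.shape
    oh, ow = -(-h // p), -(-w // p)
    # ceil mode: pad right/bottom with -inf so partial windows are valid
    xp = np.pad(
        x, ((0, 0), (0, 0), (0, oh * p - h), (0, ow * p - w)), constant_values=-np.inf
    )
    win = xp.reshape(bsz, c, oh, p, ow, p).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(bsz, c, oh, ow, p * p)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape, p, (oh, ow))


def _pool_backward(dout, cache):
    idx, xshape, p, (oh, ow) = cache
    bsz, c, h, w = xshape
    dwin = np.zeros((bsz, c, oh, ow, p * p))
    np.put_along_axis(dwin, idx[..., None], dout[..., None], axis=-1)
    dxp = dwin.reshape(bsz, c, oh, ow, p, p).transpose(0, 1, 2, 4, 3, 5)
    dxp = dxp.reshape(bsz, c, oh * p, ow * p)
    return dxp[:, :, :h, :w]


def _act_forward(x, kind):
    if kind == "relu":
        out = np.maximum(x, 0.0)
        return out, (kind, x > 0)
    out = np.tanh(x)
    return out, (kind, out)


def _act_backward(dout, cache):
    kind, saved = cache
    if kind == "relu":
        return dout * saved
    return dout * (1.0 - saved**2)


# ---------------------------------------------------------------------------
# the network


class QNetwork:
    """Action-value network with explicit parameters and manual gradients."""

    def __init__(self, arch: NetworkArchitecture, params: dict[str, np.ndarray]):
        arch.validate()
        self.arch = arch
        expected = dict(arch.parameter_shapes())
        for name, shape in expected.items():
            got = params[name]
            if tuple(got.shape) != tuple(shape):
                raise DimensionMismatchError(
                    f"parameter {name}: expected shape {shape}, got {got.shape}"
                )
        self.params = {k: np.asarray(v, dtype=np.float64) for k, v in params.items()}

    # -- constructors ------------------------------------------------------

    @classmethod
    def zeros(cls, arch: NetworkArchitecture) -> "QNetwork":
        return cls(arch, {n: np.zeros(s) for n, s in arch.parameter_shapes()})

    @classmethod
    def build(cls, arch: NetworkArchitecture, seed: int,
              bounds: tuple[float, float] = (-1.0, 1.0)) -> "QNetwork":
        """Uniformly seeded weights in ``bounds`` (the bee-colony search box)."""
        arch.validate()
        rng = np.random.default_rng(seed)
        lo, hi = bounds
        params = {n: rng.uniform(lo, hi, size=s) for n, s in arch.parameter_shapes()}
        return cls(arch, params)

    @classmethod
    def from_vector(cls, values: np.ndarray | WeightVector,
                    arch: NetworkArchitecture) -> "QNetwork":
        if isinstance(values, WeightVector):
            values = values.values
        values = np.asarray(values, dtype=np.float64).ravel()
        if values.size != arch.n_parameters:
            raise DimensionMismatchError(
                f"expected weight vector of length {arch.n_parameters}, got {values.size}"
            )
        params = {}
        offset = 0
        for name, shape in arch.parameter_shapes():
            size = int(np.prod(shape))
            params[name] = values[offset : offset + size].reshape(shape).copy()
            offset += size
        return cls(arch, params)

    def copy(self) -> "QNetwork":
        return QNetwork(self.arch, {k: v.copy() for k, v in self.params.items()})

    # -- encoding ----------------------------------------------------------

    def encode(self) -> WeightVector:
        layout = _make_layout(self.arch)
        values = np.concatenate([self.params[e.name].ravel() for e in layout])
        return WeightVector(values, layout)

    # -- forward -----------------------------------------------------------

    def _check_input(self, images) -> np.ndarray:
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3:
            raise InputError(f"expected (h, w) or (batch, h, w) images, got ndim={x.ndim}")
        n = self.arch.input_size
        if x.shape[1] != n or x.shape[2] != n:
            raise InputError(
                f"expected {n}x{n} images, got {x.shape[1]}x{x.shape[2]}"
            )
        if np.isnan(x).any():
            raise InputError("NaN in input images")
        return x[:, None]  # add channel axis

    def _forward(self, x, training, rng):
        caches = []
        a = self.arch
        h = x
        for i in range(len(a.conv_filters)):
            h, c = _conv_forward(h, self.params[f"conv{i}.weight"],
                                 self.params[f"conv{i}.bias"], a.stride, a.padding)
            caches.append(("conv", i, c))
            h, c = _act_forward(h, a.activation)
            caches.append(("act", i, c))
            if h.shape[2] > 1:
                h, c = _pool_forward(h, a.pool)
                caches.append(("pool", i, c))
        bsz = h.shape[0]
        flat_shape = h.shape
        h = h.reshape(bsz, -1)
        caches.append(("flatten", None, flat_shape))
        for i in range(len(a.fc_sizes)):
            w, b = self.params[f"fc{i}.weight"], self.params[f"fc{i}.bias"]
            caches.append(("fc", i, h))
            h = h @ w.T + b
            h, c = _act_forward(h, a.activation)
            caches.append(("act_fc", i, c))
            if training and a.dropout_p > 0.0:
                if rng is None:
                    raise InputError("training-mode forward needs an rng for dropout")
                mask = (rng.random(h.shape) >= a.dropout_p) / (1.0 - a.dropout_p)
                h = h * mask
                caches.append(("dropout", i, mask))
        caches.append(("fc_out", None, h))
        q = h @ self.params["out.weight"].T + self.params["out.bias"]
        return q, caches

    def forward(self, images, training: bool = False, rng=None) -> np.ndarray:
        """Action values, shape (batch, n_actions).

        Evaluation mode (``training=False``) is deterministic: dropout is
        disabled and identical inputs give identical outputs.
        """
        x = self._check_input(images)
        q, _ = self._forward(x, training, rng)
        return q

    # -- gradients ---------------------------------------------------------

    def loss_and_grads(self, images, actions, targets, training: bool = True,
                       rng=None):
        """Squared TD loss sum_i (y_i - Q(s_i, a_i))^2 and its gradients.

        Returns ``(loss, grads)`` with one gradient array per parameter.
        The targets are constants (no gradient flows through them).
        """
        x = self._check_input(images)
        actions = np.asarray(actions, dtype=np.intp)
        targets = np.asarray(targets, dtype=np.float64)
        if x.shape[0] == 0:
            raise InputError("empty batch")
        q, caches = self._forward(x, training, rng)
        rows = np.arange(q.shape[0])
        resid = targets - q[rows, actions]
        loss = float(np.sum(resid**2))

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dq = np.zeros_like(q)
        dq[rows, actions] = -2.0 * resid

        # output head
        h_out = caches[-1][2]
        grads["out.weight"] = dq.T @ h_out
        grads["out.bias"] = dq.sum(axis=0)
        dh = dq @ self.params["out.weight"]

        for kind, i, c in reversed(caches[:-1]):
            if kind == "dropout":
                dh = dh * c
            elif kind == "act_fc":
                dh = _act_backward(dh, c)
            elif kind == "fc":
                w = self.params[f"fc{i}.weight"]
                grads[f"fc{i}.weight"] = dh.T @ c
                grads[f"fc{i}.bias"] = dh.sum(axis=0)
                dh = dh @ w
            elif kind == "flatten":
                dh = dh.reshape(c)
            elif kind == "pool":
                dh = _pool_backward(dh, c)
            elif kind == "act":
                dh = _act_backward(dh, c)
            elif kind == "conv":
                dh, dw, db = _conv_backward(dh, c)
                grads[f"conv{i}.weight"] = dw
                grads[f"conv{i}.bias"] = db
        return loss, grads


# ---------------------------------------------------------------------------
# module-level conveniences (the functional surface)


def build_network(arch: NetworkArchitecture, seed: int) -> QNetwork:
    return QNetwork.build(arch, seed)


def encode_weights(net: QNetwork) -> WeightVector:
    return net.encode()


def decode_weights(v: WeightVector | np.ndarray, arch: NetworkArchitecture) -> QNetwork:
    return QNetwork.from_vector(v, arch)


def save_checkpoint(path, net: QNetwork) -> None:
    """Write weights + architecture to an .npz checkpoint."""
    vec = net.encode()
    np.savez(
        path,
        weights=vec.values,
        arch_json=np.array(json.dumps(net.arch.to_dict())),
        arch_digest=np.array(net.arch.digest()),
    )


def load_checkpoint(path) -> QNetwork:
    with np.load(path, allow_pickle=False) as z:
        arch = NetworkArchitecture.from_dict(json.loads(str(z["arch_json"])))
        if str(z["arch_digest"]) != arch.digest():
            raise ConfigurationError("checkpoint architecture digest mismatch")
        return QNetwork.from_vector(z["weights"], arch)
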