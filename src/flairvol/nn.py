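"""A compact numpy neural-network engine for the FLAIR classifiers.

Implements exactly the layers the declared architectures need — N-dimensional
"same" convolution (stride 1), 2x/2x2x2 max pooling, batch normalization,
ReLU, dense layers and softmax — with analytic backward passes and an SGD
optimizer with momentum.  The convolution inner loops are numba-compiled
(direct convolution outperforms im2col+GEMM at these small channel counts);
the input gradient of a stride-1 same-padded convolution is itself a
convolution with the spatially flipped, channel-transposed kernel, so the
backward pass reuses the same kernels.

Everything is deterministic given the ``numpy.random.Generator`` used for
initialization and batching, which is what makes seeded training runs
bit-reproducible on CPU.
"""

from __future__ import annotations

import numba
import numpy as np

from .architecture import ArchitectureSpec


class Layer:
    """Base layer: forward caches what backward needs; params exposes weights."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[dict]:
        return []


@numba.njit(fastmath=True)
def _conv3d_valid(xp, w):  # pragma: no cover - exercised via Conv
    B, C, mp, np_, lp = xp.shape
    O, _, kd, kh, kw = w.shape
    m, n, l = mp - kd + 1, np_ - kh + 1, lp - kw + 1
    out = np.zeros((B, O, m, n, l), dtype=xp.dtype)
    for b in range(B):
        for o in range(O):
            for c in range(C):
                for di in range(kd):
                    for dj in range(kh):
                        for dz in range(kw):
                            wv = w[o, c, di, dj, dz]
                            for i in range(m):
                                for j in range(n):
                                    for z in range(l):
                                        out[b, o, i, j, z] += wv * xp[b, c, i + di, j + dj, z + dz]
    return out


@numba.njit(fastmath=True)
def _conv3d_dw(xp, dout):  # pragma: no cover - exercised via Conv
    B, C, mp, np_, lp = xp.shape
    O = dout.shape[1]
    m, n, l = dout.shape[2], dout.shape[3], dout.shape[4]
    kd, kh, kw = mp - m + 1, np_ - n + 1, lp - l + 1
    dw = np.zeros((O, C, kd, kh, kw), dtype=xp.dtype)
    for b in range(B):
        for o in range(O):
            for c in range(C):
                for di in range(kd):
                    for dj in range(kh):
                        for dz in range(kw):
                            acc = xp.dtype.type(0.0)
                            for i in range(m):
                                for j in range(n):
                                    for z in range(l):
                                        acc += dout[b, o, i, j, z] * xp[b, c, i + di, j + dj, z + dz]
                            dw[o, c, di, dj, dz] += acc
    return dw


@numba.njit(fastmath=True)
def _conv2d_valid(xp, w):  # pragma: no cover - exercised via Conv
    B, C, mp, np_ = xp.shape
    O, _, kd, kh = w.shape
    m, n = mp - kd + 1, np_ - kh + 1
    out = np.zeros((B, O, m, n), dtype=xp.dtype)
    for b in range(B):
        for o in range(O):
            for c in range(C):
                for di in range(kd):
                    for dj in range(kh):
                        wv = w[o, c, di, dj]
                        for i in range(m):
                            for j in range(n):
                                out[b, o, i, j] += wv * xp[b, c, i + di, j + dj]
    return out


@numba.njit(fastmath=True)
def _conv2d_dw(xp, dout):  # pragma: no cover - exercised via Conv
    B, C, mp, np_ = xp.shape
    O = dout.shape[1]
    m, n = dout.shape[2], dout.shape[3]
    kd, kh = mp - m + 1, np_ - n + 1
    dw = np.zeros((O, C, kd, kh), dtype=xp.dtype)
    for b in range(B):
        for o in range(O):
            for c in range(C):
                for di in range(kd):
                    for dj in range(kh):
                        acc = xp.dtype.type(0.0)
                        for i in range(m):
                            for j in range(n):
                                acc += dout[b, o, i, j] * xp[b, c, i + di, j + dj]
                        dw[o, c, di, dj] += acc
    return dw


def _pad_spatial(x: np.ndarray, k: tuple[int, ...]) -> np.ndarray:
    return np.pad(x, [(0, 0), (0, 0)] + [(ki // 2, ki // 2) for ki in k])


def _conv_nd(x: np.ndarray, w: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """Stride-1 "same" N-D convolution (cross-correlation).

    x: (B, C, *spatial); w: (O, C, *k) with odd k; returns (B, O, *spatial).
    The inner loops are numba-compiled; the first call per dtype pays a
    one-time JIT cost.
    """
    nd = w.ndim - 2
    xp = _pad_spatial(x, w.shape[2:])
    out = _conv3d_valid(xp, w) if nd == 3 else _conv2d_valid(xp, w)
    if b is not None:
        out += b.reshape((1, -1) + (1,) * nd)
    return out


class Conv(Layer):
    """N-D convolution, odd kernel, stride 1, "same" zero padding, He init."""

    def __init__(self, in_channels: int, out_channels: int, filter_size: tuple[int, ...], rng: np.random.Generator, dtype=np.float32):
        fan_in = in_channels * int(np.prod(filter_size))
        scale = np.sqrt(2.0 / fan_in)
        self.w = (rng.standard_normal((out_channels, in_channels) + tuple(filter_size)) * scale).astype(dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    def forward(self, x, train):
        xp = _pad_spatial(x, self.w.shape[2:])
        if train:
            self._xp = xp
        nd = self.w.ndim - 2
        out = _conv3d_valid(xp, self.w) if nd == 3 else _conv2d_valid(xp, self.w)
        out += self.b.reshape((1, -1) + (1,) * nd)
        return out

    def backward(self, dout):
        nd = self.w.ndim - 2
        dout = np.ascontiguousarray(dout)
        self.dw = (_conv3d_dw if nd == 3 else _conv2d_dw)(self._xp, dout)
        self.db = dout.sum(axis=(0,) + tuple(range(2, 2 + nd))).astype(self.b.dtype)
        self._xp = None
        # input gradient: same-padded conv with the flipped, transposed kernel
        w_t = np.flip(self.w, axis=tuple(range(2, 2 + nd))).swapaxes(0, 1)
        return _conv_nd(dout, np.ascontiguousarray(w_t), None)

    def params(self):
        return [
            {"value": self.w, "grad": lambda: self.dw, "set": lambda v: setattr(self, "w", v)},
            {"value": self.b, "grad": lambda: self.db, "set": lambda v: setattr(self, "b", v)},
        ]


class MaxPool(Layer):
    """2-per-axis max pooling with stride 2; trailing odd voxels are dropped."""

    def __init__(self, filter_size: tuple[int, ...]):
        if any(f != 2 for f in filter_size):
            raise ValueError("only 2-per-axis pooling is supported")
        self.nd = len(filter_size)

    def forward(self, x, train):
        nd = self.nd
        sp = x.shape[2:]
        out_sp = tuple(s // 2 for s in sp)
        if any(s < 1 for s in out_sp):
            raise ValueError(f"maxpool underflow on input spatial shape {sp}")
        crop = (slice(None), slice(None)) + tuple(slice(0, 2 * s) for s in out_sp)
        xc = x[crop]
        shape = xc.shape[:2] + tuple(v for s in out_sp for v in (s, 2))
        xr = xc.reshape(shape)
        # bring the window axes last: (B, C, *out_sp, 2**nd)
        order = [0, 1] + [2 + 2 * i for i in range(nd)] + [3 + 2 * i for i in range(nd)]
        xt = xr.transpose(order).reshape(xc.shape[:2] + out_sp + (2**nd,))
        if train:
            self._amax = xt.argmax(axis=-1)
            self._in_shape = x.shape
        return xt.max(axis=-1)

    def backward(self, dout):
        nd = self.nd
        out_sp = dout.shape[2:]
        onehot = np.zeros(dout.shape + (2**nd,), dtype=dout.dtype)
        np.put_along_axis(onehot, self._amax[..., None], 1.0, axis=-1)
        g = onehot * dout[..., None]
        g = g.reshape(dout.shape + (2,) * nd)
        inv = [0, 1]
        for i in range(nd):
            inv += [2 + i, 2 + nd + i]
        g = g.transpose(inv).reshape(dout.shape[:2] + tuple(2 * s for s in out_sp))
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        crop = (slice(None), slice(None)) + tuple(slice(0, 2 * s) for s in out_sp)
        dx[crop] = g
        return dx


class BatchNorm(Layer):
    """Per-feature batch normalization over batch (and spatial) axes.

    For convolutional inputs the feature axis is the channel axis; for flat
    inputs each unit is a feature.  Running statistics (momentum 0.9) are used
    at evaluation time.
    """

    def __init__(self, n_features: int, dtype=np.float32, eps: float = 1e-5, momentum: float = 0.9):
        self.gamma = np.ones(n_features, dtype=dtype)
        self.beta = np.zeros(n_features, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_features, dtype=np.float64)
        self.running_var = np.ones(n_features, dtype=np.float64)
        self.eps = eps
        self.momentum = momentum

    def _axes_and_shape(self, x):
        if x.ndim == 2:
            return (0,), (1, -1)
        return (0,) + tuple(range(2, x.ndim)), (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, train):
        axes, bshape = self._axes_and_shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean.astype(np.float64)
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var.astype(np.float64)
            std = np.sqrt(var + self.eps)
            xhat = (x - mean.reshape(bshape)) / std.reshape(bshape)
            self._xhat, self._std, self._axes, self._bshape = xhat, std, axes, bshape
            n = x.size // x.shape[1] if x.ndim > 2 else x.shape[0]
            self._nred = n
        else:
            mean = self.running_mean.astype(x.dtype)
            std = np.sqrt(self.running_var + self.eps).astype(x.dtype)
            xhat = (x - mean.reshape(bshape)) / std.reshape(bshape)
        return self.gamma.reshape(bshape) * xhat + self.beta.reshape(bshape)

    def backward(self, dout):
        axes, bshape = self._axes, self._bshape
        xhat, std, n = self._xhat, self._std, self._nred
        self.dgamma = (dout * xhat).sum(axis=axes).astype(self.gamma.dtype)
        self.dbeta = dout.sum(axis=axes).astype(self.beta.dtype)
        g = self.gamma.reshape(bshape) / std.reshape(bshape)
        return g * (
            dout
            - self.dbeta.reshape(bshape) / n
            - xhat * self.dgamma.reshape(bshape) / n
        )

    def params(self):
        return [
            {"value": self.gamma, "grad": lambda: self.dgamma, "set": lambda v: setattr(self, "gamma", v)},
            {"value": self.beta, "grad": lambda: self.dbeta, "set": lambda v: setattr(self, "beta", v)},
        ]


class ReLU(Layer):
    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_units: int, units: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / in_units)
        self.w = (rng.standard_normal((in_units, units)) * scale).astype(dtype)
        self.b = np.zeros(units, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw = (self._x.T @ dout).astype(self.w.dtype)
        self.db = dout.sum(axis=0).astype(self.b.dtype)
        return dout @ self.w.T

    def params(self):
        return [
            {"value": self.w, "grad": lambda: self.dw, "set": lambda v: setattr(self, "w", v)},
            {"value": self.b, "grad": lambda: self.db, "set": lambda v: setattr(self, "b", v)},
        ]


class Softmax(Layer):
    """Softmax over the last axis; backward maps dL/dp to dL/dlogits."""

    def forward(self, x, train):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        self._p = p
        return p

    def backward(self, dout):
        p = self._p
        return p * (dout - (dout * p).sum(axis=-1, keepdims=True))


class Network:
    """An instantiated layer stack with forward/backward and batched predict."""

    def __init__(self, layers: list[Layer], spec: ArchitectureSpec):
        self.layers = layers
        self.spec = spec

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self) -> list[dict]:
        return [p for layer in self.layers for p in layer.params()]

    def predict_proba(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(self.forward(x[i : i + batch_size], train=False))
        return np.concatenate(out, axis=0)

    def state_dict(self) -> dict:
        state = {}
        for i, layer in enumerate(self.layers):
            for name in ("w", "b", "gamma", "beta", "running_mean", "running_var"):
                if hasattr(layer, name):
                    state[f"{i}.{name}"] = getattr(layer, name)
        return state

    def save(self, path) -> None:
        np.savez_compressed(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            for key, value in data.items():
                idx, name = key.split(".", 1)
                setattr(self.layers[int(idx)], name, value)


def build_network(spec: ArchitectureSpec, seed: int | np.random.Generator = 0, dtype=np.float32) -> Network:
    """Instantiate ``spec`` with He-initialized weights.

    The same seed always yields identical initial weights because layer
    construction consumes the generator in a fixed order.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    from math import prod

    spatial = tuple(spec.input_extents)
    channels = spec.in_channels
    flat: int | None = None
    layers: list[Layer] = []
    for ls in spec.layers:
        if ls.kind in ("conv3d", "conv2d"):
            layers.append(Conv(channels, ls.out_channels, ls.filter_size, rng, dtype))
            channels = ls.out_channels
        elif ls.kind == "maxpool":
            layers.append(MaxPool(ls.filter_size))
            spatial = tuple(s // 2 for s in spatial)
        elif ls.kind == "batchnorm":
            layers.append(BatchNorm(flat if flat is not None else channels, dtype))
        elif ls.kind == "relu":
            layers.append(ReLU())
        elif ls.kind == "flatten":
            flat = channels * prod(spatial)
            layers.append(Flatten())
        elif ls.kind == "dense":
            layers.append(Dense(flat, ls.units, rng, dtype))
            flat = ls.units
        elif ls.kind == "softmax":
            layers.append(Softmax())
    return Network(layers, spec)


class SGD:
    """Stochastic gradient descent with momentum; learning rate set per step."""

    def __init__(self, network: Network, momentum: float = 0.9):
        self.momentum = momentum
        self.slots = network.params()
        self.velocity = [np.zeros_like(s["value"]) for s in self.slots]

    def step(self, lr: float) -> None:
        for slot, v in zip(self.slots, self.velocity):
            g = slot["grad"]()
            v *= self.momentum
            v -= lr * g
            slot["value"] += v
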