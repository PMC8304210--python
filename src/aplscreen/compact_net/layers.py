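"""Minimal CPU neural-network layers (numpy, float32, BLAS-backed).

Each layer exposes ``forward(x, train)`` and ``backward(dy)`` and owns its
``Param`` objects. Convolutions use an explicit im2col lowering so the
inner loop is one large matrix multiply; the im2col / col2im transforms
and max-pooling iterate over the k*k kernel offsets with strided slices,
which keeps everything vectorized without per-pixel scatter.

Array layout is NHWC (channels last) throughout: every slice then has a
contiguous channel run, so the big elementwise passes stay cache-friendly.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.ascontiguousarray(data, dtype=F32)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _buf(self, name: str, shape: tuple, dtype=F32) -> np.ndarray:
        """Persistent scratch array; reallocated only when the shape changes.

        Training repeats identical batch shapes thousands of times, so
        reusing the large im2col / gradient buffers avoids most allocator
        (mmap) churn in the hot loop.
        """
        store = getattr(self, "_buffers", None)
        if store is None:
            store = self._buffers = {}
        buf = store.get(name)
        if buf is None or buf.shape != shape or buf.dtype != dtype:
            buf = store[name] = np.empty(shape, dtype=dtype)
        return buf


# ---------------------------------------------------------------------------
# im2col / col2im by kernel-offset slicing
# ---------------------------------------------------------------------------

def conv_out_size(size: int, kernel: int, stride: int, padding: int) -> int:
    return (size + 2 * padding - kernel) // stride + 1


class Conv2d(Layer):
    """3x3 (by default) convolution; weight stored as (k*k*Cin, Cout)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 stride: int = 1, padding: int = 1, rng: np.random.Generator | None = None,
                 name: str = "conv"):
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel * kernel
        w = rng.standard_normal((fan_in, out_channels), dtype=F32) * F32(np.sqrt(2.0 / fan_in))
        self.weight = Param(f"{name}.weight", w)
        self.bias = Param(f"{name}.bias", np.zeros(out_channels))
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel, self.stride, self.padding = kernel, stride, padding
        #: the input layer of a network can skip its input gradient
        self.needs_input_grad = True
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _pad(self, x: np.ndarray, name: str) -> np.ndarray:
        p = self.padding
        if not p:
            return x
        n, h, w, c = x.shape
        xp = self._buf(name, (n, h + 2 * p, w + 2 * p, c), x.dtype)
        xp[:, :p, :, :] = 0
        xp[:, -p:, :, :] = 0
        xp[:, :, :p, :] = 0
        xp[:, :, -p:, :] = 0
        xp[:, p:-p, p:-p, :] = x
        return xp

    def _im2col(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        n, c = xp.shape[0], xp.shape[3]
        k, s = self.kernel, self.stride
        cols = self._buf("cols", (n, ho, wo, k, k, c), xp.dtype)
        for ki in range(k):
            for kj in range(k):
                cols[:, :, :, ki, kj, :] = xp[:, ki:ki + s * ho:s, kj:kj + s * wo:s, :]
        return cols.reshape(n * ho * wo, k * k * c)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, _ = x.shape
        k, s, p = self.kernel, self.stride, self.padding
        ho, wo = conv_out_size(h, k, s, p), conv_out_size(w, k, s, p)
        cols = self._im2col(self._pad(x, "xp"), ho, wo)
        out = self._buf("out", (cols.shape[0], self.out_channels), cols.dtype)
        np.matmul(cols, self.weight.data, out=out)
        out += self.bias.data
        self._cache = (cols if train else None, x.shape, ho, wo)
        return out.reshape(n, ho, wo, self.out_channels)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape, ho, wo = self._cache
        self._cache = None
        n, h, w, c = xshape
        k, s, p = self.kernel, self.stride, self.padding
        dyr = dy.reshape(-1, self.out_channels)
        self.weight.grad += cols.T @ dyr
        self.bias.grad += dyr.sum(axis=0)
        if not self.needs_input_grad:
            return None
        dcols = self._buf("dcols", cols.shape, cols.dtype)
        np.matmul(dyr, self.weight.data.T, out=dcols)
        # col2im: scatter patch gradients back with strided slice adds
        dxp = self._buf("dxp", (n, h + 2 * p, w + 2 * p, c), dcols.dtype)
        dxp[...] = 0
        d6 = dcols.reshape(n, ho, wo, k, k, c)
        for ki in range(k):
            for kj in range(k):
                dxp[:, ki:ki + s * ho:s, kj:kj + s * wo:s, :] += d6[:, :, :, ki, kj, :]
        if p:
            return dxp[:, p:-p, p:-p, :]
        return dxp


class BatchNorm2d(Layer):
    """Batch normalization with affine scale/shift and running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn"):
        self.gamma = Param(f"{name}.weight", np.ones(channels))
        self.beta = Param(f"{name}.bias", np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self.eps, self.momentum = eps, momentum
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            cnt = x.shape[0] * x.shape[1] * x.shape[2]
            m = x.mean(axis=(0, 1, 2))
            xhat = self._buf("xhat", x.shape, x.dtype)
            np.subtract(x, m, out=xhat)  # mean first keeps the variance stable
            v = np.einsum("nhwc,nhwc->c", xhat, xhat) / F32(cnt)
            self.running_mean += F32(self.momentum) * (m - self.running_mean)
            self.running_var += F32(self.momentum) * (
                v * cnt / max(cnt - 1, 1) - self.running_var)
            invstd = 1.0 / np.sqrt(v + F32(self.eps))
            xhat *= invstd
            self._cache = (xhat, invstd)
        else:
            m, v = self.running_mean, self.running_var
            invstd = 1.0 / np.sqrt(v + F32(self.eps))
            xhat = (x - m) * invstd
        out = self._buf("out", x.shape, x.dtype)
        np.multiply(xhat, self.gamma.data, out=out)
        out += self.beta.data
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        self._cache = None
        cnt = dy.shape[0] * dy.shape[1] * dy.shape[2]
        dgamma = np.einsum("nhwc,nhwc->c", dy, xhat)
        dbeta = dy.sum(axis=(0, 1, 2))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        # reuse the xhat cache as the output buffer:
        # dx = g * (dy - dbeta/cnt - xhat * dgamma/cnt)
        xhat *= dgamma / F32(cnt)
        xhat += dbeta / F32(cnt)
        np.subtract(dy, xhat, out=xhat)
        xhat *= self.gamma.data * invstd
        return xhat


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        self._out = out if train else None
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy *= self._out > 0  # in place: upstream gradients are scratch
        self._out = None
        return dy


class MaxPool2d(Layer):
    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        k, s, p = self.kernel, self.stride, self.padding
        ho, wo = conv_out_size(h, k, s, p), conv_out_size(w, k, s, p)
        if p:
            xp = self._buf("xp", (n, h + 2 * p, w + 2 * p, c), x.dtype)
            xp[...] = -np.inf
            xp[:, p:-p, p:-p, :] = x
        else:
            xp = x
        out = self._buf("out", (n, ho, wo, c), x.dtype)
        out[...] = xp[:, 0:s * ho:s, 0:s * wo:s, :]
        arg = np.zeros(out.shape, dtype=np.int8) if train else None
        for t in range(1, k * k):
            ki, kj = divmod(t, k)
            win = xp[:, ki:ki + s * ho:s, kj:kj + s * wo:s, :]
            if train:
                arg[win > out] = t
            np.maximum(out, win, out=out)
        if train:
            self._cache = (arg, x.shape)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        arg, xshape = self._cache
        self._cache = None
        n, h, w, c = xshape
        k, s, p = self.kernel, self.stride, self.padding
        ho, wo = arg.shape[1], arg.shape[2]
        dxp = self._buf("dxp", (n, h + 2 * p, w + 2 * p, c), dy.dtype)
        dxp[...] = 0
        for t in range(k * k):
            ki, kj = divmod(t, k)
            target = dxp[:, ki:ki + s * ho:s, kj:kj + s * wo:s, :]
            np.add(target, dy, out=target, where=arg == t)
        if p:
            return dxp[:, p:-p, p:-p, :]
        return dxp


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class SEModule(Layer):
    """Squeeze-and-excitation channel attention.

    Squeeze: global average pool per channel. Excite: two-layer bottleneck
    (C -> C/ratio -> C) with ReLU in between and a channel gate on top —
    softmax across channels (weights form a probability vector) or the
    conventional per-channel sigmoid. The feature map is rescaled
    channel-wise by the gate output.
    """

    def __init__(self, channels: int, ratio: int = 16, gate: str = "softmax",
                 rng: np.random.Generator | None = None, name: str = "se"):
        if channels % ratio != 0:
            raise ValueError(f"SE ratio {ratio} must divide the channel count {channels}")
        if gate not in ("softmax", "sigmoid"):
            raise ValueError(f"unknown SE gate {gate!r}")
        rng = rng or np.random.default_rng()
        hidden = channels // ratio
        self.w1 = Param(f"{name}.fc1.weight",
                        rng.standard_normal((channels, hidden), dtype=F32)
                        * F32(np.sqrt(2.0 / channels)))
        self.b1 = Param(f"{name}.fc1.bias", np.zeros(hidden))
        self.w2 = Param(f"{name}.fc2.weight",
                        rng.standard_normal((hidden, channels), dtype=F32)
                        * F32(np.sqrt(2.0 / hidden)))
        self.b2 = Param(f"{name}.fc2.bias", np.zeros(channels))
        self.channels, self.ratio, self.gate = channels, ratio, gate
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w1, self.b1, self.w2, self.b2]

    def gate_weights(self, x: np.ndarray) -> np.ndarray:
        """Channel weights for a batch of NHWC feature maps (no caching)."""
        s = x.mean(axis=(1, 2))
        h = np.maximum(s @ self.w1.data + self.b1.data, 0.0)
        z = h @ self.w2.data + self.b2.data
        if self.gate == "softmax":
            return _softmax(z, axis=1)
        return 1.0 / (1.0 + np.exp(-z))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        s = x.mean(axis=(1, 2))
        pre = s @ self.w1.data + self.b1.data
        h = np.maximum(pre, 0.0)
        z = h @ self.w2.data + self.b2.data
        if self.gate == "softmax":
            g = _softmax(z, axis=1)
        else:
            g = 1.0 / (1.0 + np.exp(-z))
        if train:
            self._cache = (x, s, pre, h, g)
        return x * g[:, None, None, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, s, pre, h, g = self._cache
        self._cache = None
        dg = (dy * x).sum(axis=(1, 2))
        if self.gate == "softmax":
            dz = g * (dg - (dg * g).sum(axis=1, keepdims=True))
        else:
            dz = dg * g * (1.0 - g)
        self.w2.grad += h.T @ dz
        self.b2.grad += dz.sum(axis=0)
        dh = dz @ self.w2.data.T
        dh *= pre > 0
        self.w1.grad += s.T @ dh
        self.b1.grad += dh.sum(axis=0)
        ds = dh @ self.w1.data.T
        hw = x.shape[1] * x.shape[2]
        return dy * g[:, None, None, :] + ds[:, None, None, :] / F32(hw)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, name: str = "fc"):
        rng = rng or np.random.default_rng()
        w = (rng.standard_normal((in_features, out_features), dtype=F32)
             * F32(np.sqrt(2.0 / in_features)))
        self.weight = Param(f"{name}.weight", w)
        self.bias = Param(f"{name}.bias", np.zeros(out_features))
        self.in_features, self.out_features = in_features, out_features
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x if train else None
        return x @ self.weight.data + self.bias.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ dy
        self.bias.grad += dy.sum(axis=0)
        self._x = None
        return dy @ self.weight.data.T


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, rate: float = 0.5, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / F32(keep)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dy = dy * self._mask
        self._mask = None
        return dy


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    probs = _softmax(logits.astype(np.float64), axis=1)
    n = logits.shape[0]
    loss = -np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean()
    grad = probs
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(logits.dtype)


class SGDMomentum:
    """SGD with classical momentum: v <- mu*v + g; w <- w - lr*v."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            v *= F32(self.momentum)
            v += p.grad
            p.data -= F32(self.lr) * v
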