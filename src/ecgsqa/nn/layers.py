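"""Layer implementations with hand-written forward/backward passes.

Activations are float32 arrays in channels-last layout (N, H, W, C); dense
layers operate on (N, F).  Each layer owns its parameters and accumulates
gradients of the minibatch loss in ``grads`` during ``backward``.  Weight
initialization follows the He scheme (zero-mean Gaussian with variance
2 / fan-in), the standard choice for rectifier networks.

Large intermediate arrays are drawn from per-layer scratch buffers that are
reused across minibatches, and elementwise work happens in place wherever
the dataflow allows.  Consequence for callers: the array a layer returns is
owned by that layer and is overwritten on its next forward/backward call —
copy it if it must outlive the step.  Convolutions are lowered to BLAS
matrix products, either per kernel offset or through a single patch-matrix
product when the fan-in is small.
"""

from __future__ import annotations

import numpy as np

_DTYPE = np.float32


class Layer:
    """Base layer: parameter-free identity with a scratch-buffer pool."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._buffers: dict[str, np.ndarray] = {}

    def _buf(self, key: str, shape: tuple[int, ...], dtype=_DTYPE) -> np.ndarray:
        """Reusable zero-initialized scratch array; shrinking the leading
        (batch) axis returns a view of the cached buffer."""
        b = self._buffers.get(key)
        if (
            b is None
            or b.dtype != dtype
            or b.shape[1:] != tuple(shape[1:])
            or b.shape[0] < shape[0]
        ):
            b = np.zeros(shape, dtype=dtype)
            self._buffers[key] = b
        return b[: shape[0]] if b.shape[0] != shape[0] else b

    def free_buffers(self) -> None:
        self._buffers.clear()

    def cast(self, dtype) -> None:
        """Cast parameters (e.g. to float64 for numerical gradient checks)."""
        for k in self.params:
            self.params[k] = self.params[k].astype(dtype)
        self._buffers.clear()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv2d(Layer):
    """2-D convolution, stride 1, size-preserving (same) zero padding.

    Kernel shape (kh, kw, C_in, C_out); odd kernel extents only.  A 1 x 3
    kernel on (N, 1, L, C) input is the 1-D convolution used on raw-signal
    branches.  Both passes are lowered to one BLAS matrix product over a
    persistent im2col patch matrix; a trunk's first convolution is built
    with ``input_grad=False`` since no layer consumes its input gradient.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, int], rng: np.random.Generator,
                 input_grad: bool = True) -> None:
        super().__init__()
        kh, kw = kernel
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("kernel extents must be odd for same padding")
        self.kh, self.kw = kh, kw
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.input_grad = input_grad
        self._is_1x1 = (kh, kw) == (1, 1)
        fan_in = in_channels * kh * kw
        w = rng.standard_normal((kh, kw, in_channels, out_channels)) * np.sqrt(2.0 / fan_in)
        self.params = {"w": w.astype(_DTYPE), "b": np.zeros(out_channels, dtype=_DTYPE)}
        self._cache: tuple | None = None

    def _col(self, x: np.ndarray) -> np.ndarray:
        """Persistent (N, H, W, kh*kw*C) patch matrix of the padded input."""
        n, h, w, c = x.shape
        if self._is_1x1:
            return x
        ph, pw = self.kh // 2, self.kw // 2
        xp = self._buf("xp", (n, h + 2 * ph, w + 2 * pw, c))
        # borders stay zero: the buffer is zero-born and only the core is
        # ever written
        xp[:, ph:ph + h, pw:pw + w, :] = x
        col = self._buf("col", (n, h, w, self.kh * self.kw * c))
        t = 0
        for i in range(self.kh):
            for j in range(self.kw):
                col[..., t * c:(t + 1) * c] = xp[:, i:i + h, j:j + w, :]
                t += 1
        return col

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, _ = x.shape
        c_out = self.out_channels
        dt = self.params["w"].dtype
        col = self._col(np.ascontiguousarray(x, dtype=dt))
        col2 = col.reshape(n * h * w, -1)
        out2 = self._buf("out", (n * h * w, c_out), dtype=dt)
        np.matmul(col2, self.params["w"].reshape(-1, c_out), out=out2)
        out2 += self.params["b"]
        if training:
            self._cache = (col2, (n, h, w))
        return out2.reshape(n, h, w, c_out)

    def backward(self, grad: np.ndarray) -> np.ndarray | None:
        col2, (n, h, w) = self._cache
        self._cache = None
        c_in, c_out = self.in_channels, self.out_channels
        dt = self.params["w"].dtype
        wk = self.params["w"]
        if grad.flags.c_contiguous:
            g2 = grad.reshape(n * h * w, c_out)
        else:
            gbuf = self._buf("gbuf", (n, h, w, c_out), dtype=dt)
            np.copyto(gbuf, grad)
            g2 = gbuf.reshape(n * h * w, c_out)
        self.grads = {
            "w": (col2.T @ g2).reshape(wk.shape),
            "b": np.einsum("nc->c", g2),
        }
        if not self.input_grad:
            return None
        if self._is_1x1:
            dx = self._buf("dx", (n * h * w, c_in), dtype=dt)
            np.matmul(g2, wk.reshape(-1, c_out).T, out=dx)
            return dx.reshape(n, h, w, c_in)
        # dW is already computed, so the col buffer can hold dcol in place
        np.matmul(g2, wk.reshape(-1, c_out).T, out=col2)
        dcol4 = col2.reshape(n, h, w, -1)
        ph, pw = self.kh // 2, self.kw // 2
        dxp = self._buf("dxp", (n, h + 2 * ph, w + 2 * pw, c_in), dtype=dt)
        dxp.fill(0)
        t = 0
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, i:i + h, j:j + w, :] += dcol4[..., t * c_in:(t + 1) * c_in]
                t += 1
        return dxp[:, ph:ph + h, pw:pw + w, :]


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W).

    Training uses minibatch statistics and updates exponential running
    averages (momentum 0.1); evaluation uses the running averages, making
    inference deterministic.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {
            "gamma": np.ones(channels, dtype=_DTYPE),
            "beta": np.zeros(channels, dtype=_DTYPE),
        }
        self.running_mean = np.zeros(channels, dtype=_DTYPE)
        self.running_var = np.ones(channels, dtype=_DTYPE)
        self._cache: tuple | None = None

    def cast(self, dtype) -> None:
        super().cast(dtype)
        self.running_mean = self.running_mean.astype(dtype)
        self.running_var = self.running_var.astype(dtype)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        c = x.shape[-1]
        if training:
            # moment sums via einsum: no large temporaries
            sub = "nhwc->c" if x.ndim == 4 else "nc->c"
            sub2 = "nhwc,nhwc->c" if x.ndim == 4 else "nc,nc->c"
            m = x.size // c
            mean = np.einsum(sub, x) / m
            var = np.maximum(np.einsum(sub2, x, x) / m - mean * mean, 0.0)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(_DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(_DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
            # running stats updated with momentum 0.1 during training
        dt = x.dtype
        ivar = (1.0 / np.sqrt(var + self.eps)).astype(dt)
        # one fused affine pass: out = x * a + c0
        a = (self.params["gamma"] * ivar).astype(dt)
        c0 = (self.params["beta"] - mean * a).astype(dt)
        out = self._buf("out", x.shape, dtype=dt)
        np.multiply(x, a, out=out)
        out += c0
        if training:
            self._cache = (x, mean.astype(dt), ivar)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, mean, ivar = self._cache
        self._cache = None
        m = x.size // x.shape[-1]
        dt = x.dtype
        xhat = self._buf("xhat", x.shape, dtype=dt)
        np.subtract(x, mean, out=xhat)
        xhat *= ivar
        sub = "nhwc->c" if x.ndim == 4 else "nc->c"
        sub2 = "nhwc,nhwc->c" if x.ndim == 4 else "nc,nc->c"
        dgamma = np.einsum(sub2, grad, xhat, dtype=dt)
        dbeta = np.einsum(sub, grad, dtype=dt)
        self.grads = {"gamma": dgamma, "beta": dbeta}
        # reuse the incoming gradient buffer for dx (its producer is done
        # with it): dx = gamma*ivar/m * (m*g - dbeta - xhat*dgamma)
        xhat *= dgamma
        grad *= dt.type(m)
        grad -= dbeta
        grad -= xhat
        grad *= (self.params["gamma"] * ivar / m).astype(dt)
        return grad


class ReLU(Layer):
    """Rectifier applied in place: the input array (its producer's scratch
    buffer) is clipped directly, sparing one activation-sized buffer."""

    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mask = self._buf("mask", x.shape, dtype=np.bool_)
            np.greater(x, 0, out=mask)
            self._mask = mask
        np.maximum(x, 0, out=x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad *= self._mask
        self._mask = None
        return grad


class MaxPool2d(Layer):
    """Non-overlapping max pooling; odd trailing rows/columns are dropped
    (floor division of the spatial extents)."""

    def __init__(self, pool: tuple[int, int]) -> None:
        super().__init__()
        self.ph, self.pw = pool
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        ph, pw = self.ph, self.pw
        ho, wo = h // ph, w // pw
        # (N, Ho, Wo, C, ph*pw) window matrix for one max/argmax per window
        xw = self._buf("xw", (n, ho, wo, c, ph * pw), dtype=x.dtype)
        src = x[:, :ho * ph, :wo * pw, :].reshape(n, ho, ph, wo, pw, c)
        np.copyto(xw.reshape(n, ho, wo, c, ph, pw), src.transpose(0, 1, 3, 5, 2, 4))
        out = self._buf("out", (n, ho, wo, c), dtype=x.dtype)
        np.max(xw, axis=-1, out=out)
        if training:
            idx = self._buf("idx", (n, ho, wo, c), dtype=np.intp)
            np.argmax(xw, axis=-1, out=idx)
            self._cache = (idx, x.shape)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        idx, in_shape = self._cache
        self._cache = None
        n, h, w, c = in_shape
        ph, pw = self.ph, self.pw
        ho, wo = h // ph, w // pw
        dxw = self._buf("dxw", (n, ho, wo, c, ph * pw), dtype=grad.dtype)
        dxw.fill(0)
        np.put_along_axis(dxw, idx[..., None], grad[..., None], axis=-1)
        dx = self._buf("dx", in_shape, dtype=grad.dtype)
        dx.fill(0)
        dxw6 = dxw.reshape(n, ho, wo, c, ph, pw)
        for a in range(ph):
            for b in range(pw):
                dx[:, a:ho * ph:ph, b:wo * pw:pw, :] = dxw6[:, :, :, :, a, b]
        return dx


class Flatten(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._shape = x.shape
        return np.ascontiguousarray(x).reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad.reshape(self._shape)
        self._shape = None
        return out


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        super().__init__()
        w = rng.standard_normal((in_features, out_features)) * np.sqrt(2.0 / in_features)
        self.params = {"w": w.astype(_DTYPE), "b": np.zeros(out_features, dtype=_DTYPE)}
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._x = x.copy()
        return x @ self.params["w"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads = {"w": self._x.T @ grad, "b": grad.sum(axis=0)}
        out = grad @ self.params["w"].T
        self._x = None
        return out


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.p == 0.0:
            return x
        self._mask = ((self.rng.random(x.shape) >= self.p) / (1.0 - self.p)).astype(x.dtype)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        out = grad * self._mask
        self._mask = None
        return out


class Softmax(Layer):
    """Softmax over the last axis; backward expects dL/d(probabilities)."""

    def __init__(self) -> None:
        super().__init__()
        self._p: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        if training:
            self._p = p
        return p

    def backward(self, grad: np.ndarray) -> np.ndarray:
        p = self._p
        self._p = None
        return (p * (grad - (grad * p).sum(axis=-1, keepdims=True))).astype(p.dtype)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def n_parameters(self) -> int:
        return sum(layer.n_parameters() for layer in self.layers)

    def free_buffers(self) -> None:
        for layer in self.layers:
            layer.free_buffers()

    def cast(self, dtype) -> None:
        for layer in self.layers:
            layer.cast(dtype)

    def iter_layers(self):
        for layer in self.layers:
            if isinstance(layer, Sequential):
                yield from layer.iter_layers()
            else:
                yield layer
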