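"""Minimal CPU neural-network layers with explicit backpropagation.

Everything the residual detector needs, implemented on numpy/numba in
float32. Data layout is NHWC (channels last), which keeps the channel
reductions contiguous. 3x3 convolutions run through a direct numba
kernel while the spatial grid is large (where im2col's 9x data
duplication is the bottleneck) and fall back to an im2col + BLAS
matmul once feature maps are small and channel counts large; 1x1
convolutions are plain matmuls. Each layer caches what its backward
pass needs, so a forward/backward pair is not reentrant — fine for
plain minibatch training.

The stack is deliberately small: Conv2d, BatchNorm2d, ReLU, MaxPool2d,
Linear, a ResidualBlock composite, softmax cross-entropy, and Adam.
"""

from __future__ import annotations

import numba
import numpy as np

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "Linear",
    "ResidualBlock",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]

# direct conv pays off while H*W is large; below this, BLAS im2col wins
_DIRECT_CONV_MIN_PIXELS = 16


def _f32(x: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(x, dtype=np.float32)


@numba.njit(cache=True, fastmath=True)
def _conv3_fwd(xp, w):  # pragma: no cover - exercised via Conv2d
    b, hp, wp, cin = xp.shape
    h, wd = hp - 2, wp - 2
    cout = w.shape[3]
    out = np.zeros((b, h, wd, cout), dtype=np.float32)
    for bi in range(b):
        for y in range(h):
            orow = out[bi, y]
            for ki in range(3):
                xrow = xp[bi, y + ki]
                for kj in range(3):
                    wk = w[ki, kj]
                    for x in range(wd):
                        px = xrow[x + kj]
                        oo = orow[x]
                        for ci in range(cin):
                            v = px[ci]
                            wr = wk[ci]
                            for co in range(cout):
                                oo[co] += v * wr[co]
    return out


@numba.njit(cache=True, fastmath=True)
def _conv3_bwd(xp, w, dout):  # pragma: no cover - exercised via Conv2d
    b, hp, wp, cin = xp.shape
    h, wd = hp - 2, wp - 2
    cout = w.shape[3]
    dxp = np.zeros_like(xp)
    dw = np.zeros((3, 3, cin, cout), dtype=np.float32)
    for bi in range(b):
        for y in range(h):
            drow = dout[bi, y]
            for ki in range(3):
                xrow = xp[bi, y + ki]
                dxrow = dxp[bi, y + ki]
                for kj in range(3):
                    wk = w[ki, kj]
                    dwk = dw[ki, kj]
                    for x in range(wd):
                        d = drow[x]
                        px = xrow[x + kj]
                        dpx = dxrow[x + kj]
                        for ci in range(cin):
                            v = px[ci]
                            wr = wk[ci]
                            dwr = dwk[ci]
                            acc = np.float32(0.0)
                            for co in range(cout):
                                dc = d[co]
                                acc += wr[co] * dc
                                dwr[co] += v * dc
                            dpx[ci] += acc
    return dxp, dw


@numba.njit(cache=True, fastmath=True)
def _adam_kernel(p, g, m, v, lr, b1, b2, eps, c1, c2):  # pragma: no cover
    for i in range(p.size):
        gi = g[i]
        mi = m[i] + (1.0 - b1) * (gi - m[i])
        vi = v[i] + (1.0 - b2) * (gi * gi - v[i])
        m[i] = mi
        v[i] = vi
        p[i] -= lr * (mi / c1) / (np.sqrt(vi / c2) + eps)


class Layer:
    """Base: parameter dict + matching gradient dict."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Same-padding stride-1 convolution, kernel size 3 or 1 (NHWC).

    Weights are stored as (k, k, c_in, c_out); He initialization.
    """

    def __init__(
        self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator
    ) -> None:
        super().__init__()
        if ksize not in (1, 3):
            raise ValueError("ksize must be 1 or 3")
        self.c_in, self.c_out, self.k = c_in, c_out, ksize
        fan_in = c_in * ksize * ksize
        w = rng.standard_normal((ksize, ksize, c_in, c_out)) * np.sqrt(2.0 / fan_in)
        self.params = {"w": _f32(w), "b": np.zeros(c_out, dtype=np.float32)}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if self.k == 1:
            self._x = x
            out = x @ self.params["w"][0, 0] + self.params["b"]
            return out
        b, h, wd, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        if h * wd >= _DIRECT_CONV_MIN_PIXELS:
            self._cache = ("direct", xp)
            return _conv3_fwd(xp, self.params["w"]) + self.params["b"]
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
        cols = _f32(win).reshape(b * h * wd, c * 9)  # inner order (c, ki, kj)
        wflat = self.params["w"].transpose(2, 0, 1, 3).reshape(c * 9, self.c_out)
        out = cols @ wflat + self.params["b"]
        self._cache = ("im2col", cols, x.shape)
        return out.reshape(b, h, wd, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.k == 1:
            x2 = self._x.reshape(-1, self.c_in)
            d2 = _f32(dout).reshape(-1, self.c_out)
            self.grads["w"] = (x2.T @ d2).reshape(1, 1, self.c_in, self.c_out)
            self.grads["b"] = d2.sum(axis=0)
            del self._x
            return dout @ self.params["w"][0, 0].T
        if self._cache[0] == "direct":
            _, xp = self._cache
            dout = _f32(dout)
            dxp, dw = _conv3_bwd(xp, self.params["w"], dout)
            self.grads["w"] = dw
            self.grads["b"] = dout.sum(axis=(0, 1, 2))
            del self._cache
            return dxp[:, 1:-1, 1:-1, :]
        _, cols, x_shape = self._cache
        b, h, wd, c = x_shape
        dflat = _f32(dout).reshape(b * h * wd, self.c_out)
        wflat = self.params["w"].transpose(2, 0, 1, 3).reshape(c * 9, self.c_out)
        dwflat = cols.T @ dflat
        self.grads["w"] = (
            dwflat.reshape(c, 3, 3, self.c_out).transpose(1, 2, 0, 3).copy()
        )
        self.grads["b"] = dflat.sum(axis=0)
        dcols = (dflat @ wflat.T).reshape(b, h, wd, c, 3, 3)
        dxp = np.zeros((b, h + 2, wd + 2, c), dtype=np.float32)
        for ki in range(3):
            for kj in range(3):
                dxp[:, ki : ki + h, kj : kj + wd, :] += dcols[:, :, :, :, ki, kj]
        del self._cache
        return dxp[:, 1:-1, 1:-1, :]


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {
            "gamma": np.ones(channels, dtype=np.float32),
            "beta": np.zeros(channels, dtype=np.float32),
        }
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, train)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, train = self._cache
        del self._cache
        if not train:
            # running statistics are constants: the map is affine in x
            return _f32(dout * (self.params["gamma"] * inv))
        n = dout.shape[0] * dout.shape[1] * dout.shape[2]
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 1, 2))
        self.grads["beta"] = dout.sum(axis=(0, 1, 2))
        dxhat = dout * self.params["gamma"]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 1, 2))
            - xhat * (dxhat * xhat).sum(axis=(0, 1, 2)) / n
        ) * inv
        return _f32(dx)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2d(Layer):
    """2x2/stride-2 max pooling (NHWC); odd trailing rows/cols dropped."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        quads = (
            x[:, : 2 * h2, : 2 * w2, :]
            .reshape(b, h2, 2, w2, 2, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(b, h2, w2, c, 4)
        )
        idx = quads.argmax(axis=4)
        out = np.take_along_axis(quads, idx[..., None], axis=4)[..., 0]
        self._cache = (idx, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, x_shape = self._cache
        b, h, w, c = x_shape
        h2, w2 = h // 2, w // 2
        dquads = np.zeros((b, h2, w2, c, 4), dtype=np.float32)
        np.put_along_axis(dquads, idx[..., None], _f32(dout)[..., None], axis=4)
        dx = np.zeros(x_shape, dtype=np.float32)
        dx[:, : 2 * h2, : 2 * w2, :] = (
            dquads.reshape(b, h2, w2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(b, 2 * h2, 2 * w2, c)
        )
        del self._cache
        return dx


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.params = {"w": _f32(w), "b": np.zeros(n_out, dtype=np.float32)}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = _f32(dout)
        self.grads["w"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        del self._x
        return dout @ self.params["w"].T


class ResidualBlock(Layer):
    """conv-bn-relu-conv-bn plus identity (or 1x1-projection) shortcut,
    joined by addition and a final ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.bn1 = BatchNorm2d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.bn2 = BatchNorm2d(c_out)
        self.relu_out = ReLU()
        if c_in != c_out:
            self.proj: Conv2d | None = Conv2d(c_in, c_out, 1, rng)
            self.bn_proj: BatchNorm2d | None = BatchNorm2d(c_out)
        else:
            self.proj = None
            self.bn_proj = None

    def sublayers(self) -> list[Layer]:
        layers: list[Layer] = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.proj is not None:
            layers += [self.proj, self.bn_proj]
        return layers

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.relu1.forward(
            self.bn1.forward(self.conv1.forward(x, train), train), train
        )
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        if self.proj is not None:
            s = self.bn_proj.forward(self.proj.forward(x, train), train)
        else:
            s = x
        return self.relu_out.forward(h + s, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dout)
        dh = self.conv1.backward(
            self.bn1.backward(
                self.relu1.backward(self.conv2.backward(self.bn2.backward(d)))
            )
        )
        if self.proj is not None:
            ds = self.proj.backward(self.bn_proj.backward(d))
        else:
            ds = d
        return dh + ds


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = float(-np.mean(np.log(p[np.arange(n), labels] + 1e-12)))
    dlogits = p
    dlogits[np.arange(n), labels] -= 1.0
    return loss, _f32(dlogits / n)


class Adam:
    def __init__(
        self,
        layers: list[Layer],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.layers = layers
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in layer.params.items()} for layer in layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in layer.params.items()} for layer in layers
        ]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for i, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                _adam_kernel(
                    p.reshape(-1),
                    _f32(layer.grads[k]).reshape(-1),
                    self.m[i][k].reshape(-1),
                    self.v[i][k].reshape(-1),
                    self.lr,
                    b1,
                    b2,
                    self.eps,
                    c1,
                    c2,
                )
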