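"""Minimal CPU neural-network engine (numpy, float32).

Implements exactly the layers the tissue classifier needs — 3x3 same-padding
convolution, batch normalization, ReLU, 2x2 floor-mode max pooling, dense
layers — with analytic backward passes for both parameter gradients
(training) and input gradients (attribution).  Convolutions are lowered to
matrix multiplies via im2col so the heavy lifting stays in BLAS.

No autograd framework is available in the deployment environment, which is
why this exists; the API is intentionally tiny and specific.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "Flatten",
    "Linear",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy_grad",
]

_DTYPE = np.float32


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -float(np.mean(np.log(p[np.arange(n), targets] + eps)))
    grad = p.copy()
    grad[np.arange(n), targets] -= 1.0
    return loss, (grad / n).astype(_DTYPE)


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        return []

    def state(self) -> dict[str, np.ndarray]:
        return {name: p for name, p, _ in self.params()}


class Conv2d(Layer):
    """3x3 convolution, stride 1, symmetric zero padding (spatial size preserved)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, kernel: int = 3):
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd to preserve spatial size")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        self.W = (rng.standard_normal((out_ch, in_ch, kernel, kernel)) *
                  np.sqrt(2.0 / fan_in)).astype(_DTYPE)
        self.b = np.zeros(out_ch, dtype=_DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.k // 2
        xpad = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xpad, (self.k, self.k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (n*h*w, c*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        cols = np.ascontiguousarray(cols, dtype=_DTYPE)
        out = cols @ self.W.reshape(self.out_ch, -1).T + self.b
        self._cols = cols
        self._xshape = x.shape
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, h, w = dout.shape
        k, p = self.k, self.k // 2
        d2 = np.ascontiguousarray(dout.transpose(0, 2, 3, 1).reshape(n * h * w, f), dtype=_DTYPE)
        self.dW += (d2.T @ self._cols).reshape(self.W.shape)
        self.db += d2.sum(axis=0)
        dcols = (d2 @ self.W.reshape(f, -1)).reshape(n, h, w, self.in_ch, k, k)
        dxpad = np.zeros((n, self.in_ch, h + 2 * p, w + 2 * p), dtype=_DTYPE)
        for ki in range(k):
            for kj in range(k):
                dxpad[:, :, ki : ki + h, kj : kj + w] += dcols[:, :, :, :, ki, kj].transpose(
                    0, 3, 1, 2
                )
        return dxpad[:, :, p : p + h, p : p + w]

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for eval mode."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n_ch, dtype=_DTYPE)
        self.beta = np.zeros(n_ch, dtype=_DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_ch, dtype=_DTYPE)
        self.running_var = np.ones(n_ch, dtype=_DTYPE)
        self.momentum, self.eps = momentum, eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean +
                                 self.momentum * mean).astype(_DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var +
                                self.momentum * var).astype(_DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat.astype(_DTYPE), inv.astype(_DTYPE), train, x.shape)
        return (self.gamma[None, :, None, None] * xhat +
                self.beta[None, :, None, None]).astype(_DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, train, shape = self._cache
        self.dgamma += (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta += dout.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None] * inv[None, :, None, None]
        if not train:
            # Eval mode treats mean/var as constants.
            return (dout * g).astype(_DTYPE)
        m = shape[0] * shape[2] * shape[3]
        dxhat = dout * self.gamma[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (inv[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)
        return dx.astype(_DTYPE)

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def state(self):
        return {
            "gamma": self.gamma,
            "beta": self.beta,
            "running_mean": self.running_mean,
            "running_var": self.running_var,
        }


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(_DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return (dout * self._mask).astype(_DTYPE)


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2, floor mode (trailing row/col dropped)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
        blocks = xc.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._argmax = blocks.argmax(axis=-1)
        self._inshape = x.shape
        return blocks.max(axis=-1).astype(_DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._inshape
        h2, w2 = h // 2, w // 2
        dblocks = np.zeros((n, c, h2, w2, 4), dtype=_DTYPE)
        np.put_along_axis(dblocks, self._argmax[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, c, h, w), dtype=_DTYPE)
        dx[:, :, : 2 * h2, : 2 * w2] = (
            dblocks.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, 2 * h2, 2 * w2)
        )
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((n_out, n_in)) * np.sqrt(2.0 / n_in)).astype(_DTYPE)
        self.b = np.zeros(n_out, dtype=_DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW += dout.T @ self._x
        self.db += dout.sum(axis=0)
        return (dout @ self.W).astype(_DTYPE)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=_DTYPE)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for layer in self.layers:
            for _, _, g in layer.params():
                g[...] = 0

    def params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        out = []
        for i, layer in enumerate(self.layers):
            for name, p, g in layer.params():
                out.append((f"{i}.{name}", p, g))
        return out

    def input_gradient(self, x: np.ndarray, dlogits: np.ndarray) -> np.ndarray:
        """Gradient of ``dlogits . logits`` w.r.t. the input, eval mode."""
        self.forward(x, train=False)
        self.zero_grad()
        return self.backward(np.asarray(dlogits, dtype=_DTYPE))

    def save(self, weights_path: str | Path) -> None:
        arrays: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.state().items():
                arrays[f"{i}.{name}"] = arr
        np.savez(weights_path, **arrays)

    def load(self, weights_path: str | Path) -> None:
        data = np.load(weights_path)
        for i, layer in enumerate(self.layers):
            for name, arr in layer.state().items():
                arr[...] = data[f"{i}.{name}"]


class Adam:
    def __init__(self, model: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(p) for name, p, _ in model.params()}
        self.v = {name: np.zeros_like(p) for name, p, _ in model.params()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, p, g in self.model.params():
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / (1 - b1 ** self.t)
            vhat = self.v[name] / (1 - b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
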