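"""Minimal NHWC neural-network layers with analytic backprop.

Implements exactly the operations the study's residual classifier needs:
2-D convolution, max pooling, the Swish activation, dense layers, global
max pooling, softmax cross-entropy and Adam.  Forward passes cache what
the backward pass needs; ``backward`` consumes the cache of the most
recent forward call.

Two backward variants exist at activation sites: the ordinary chain rule,
and the "guided" rule used by guided backpropagation, which additionally
zeroes the signal wherever the incoming gradient is negative or the
forward pre-activation is negative.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "MaxPool2D",
    "GlobalMaxPool",
    "Swish",
    "Dense",
    "ResidualBlock",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # overflow-safe and branch-free: sigma(x) = (1 + tanh(x/2)) / 2
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Layer:
    """Base class: parameters in ``params``, matching gradients in ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray, guided: bool = False) -> np.ndarray:
        raise NotImplementedError  # pragma: no cover


class Conv2D(Layer):
    """k×k convolution, NHWC, zero 'same'-style padding.

    Forward and backward are expressed through im2col so each pass is one
    large GEMM.  ``skip_input_grad`` lets the first layer of a network
    omit the (unused) gradient w.r.t. its input during training.
    """

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        super().__init__()
        self.k, self.stride = k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        self.skip_input_grad = False
        rng = rng or np.random.default_rng()
        fan_in = k * k * cin
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, cin, cout))
        self.params = {"W": w.astype(dtype), "b": np.zeros(cout, dtype=dtype)}

    def _im2col(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        k, s = self.k, self.stride
        n, _, _, cin = xp.shape
        sw = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        sw = sw[:, ::s, ::s][:, :ho, :wo]          # (N,ho,wo,Cin,k,k)
        return sw.transpose(0, 1, 2, 4, 5, 3).reshape(n * ho * wo, k * k * cin)

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        n, h, w, cin = x.shape
        cout = self.params["W"].shape[-1]
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        col = self._im2col(xp, ho, wo)
        out = col @ self.params["W"].reshape(k * k * cin, cout)
        out += self.params["b"]
        self._cache = (col, x.shape, (ho, wo))
        return out.reshape(n, ho, wo, cout)

    def backward(self, gout: np.ndarray, guided: bool = False) -> np.ndarray:
        col, xshape, (ho, wo) = self._cache
        k, s, p = self.k, self.stride, self.pad
        n, h, w, cin = xshape
        cout = gout.shape[-1]
        g2 = gout.reshape(-1, cout)
        w2 = self.params["W"].reshape(k * k * cin, cout)
        self.grads = {"W": (col.T @ g2).reshape(k, k, cin, cout),
                      "b": g2.sum(axis=0)}
        if self.skip_input_grad:
            return np.zeros(xshape, dtype=gout.dtype)
        gcol = (g2 @ w2.T).reshape(n, ho, wo, k, k, cin)
        gxp = np.zeros((n, h + 2 * p, w + 2 * p, cin), dtype=gout.dtype)
        for i in range(k):
            for j in range(k):
                gxp[:, i:i + s * ho:s, j:j + s * wo:s, :] += gcol[:, :, :, i, j, :]
        return gxp[:, p:p + h, p:p + w, :] if p else gxp


class MaxPool2D(Layer):
    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1) -> None:
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)),
                    constant_values=-np.inf) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        best = np.full((n, ho, wo, c), -np.inf, dtype=x.dtype)
        arg = np.zeros((n, ho, wo, c), dtype=np.int8)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            xs = xp[:, i:i + s * ho:s, j:j + s * wo:s, :]
            m = xs > best
            np.copyto(arg, idx, where=m)
            best = np.where(m, xs, best)
        self._cache = (arg, xp.shape, x.shape, (ho, wo))
        return best

    def backward(self, gout: np.ndarray, guided: bool = False) -> np.ndarray:
        arg, xpshape, xshape, (ho, wo) = self._cache
        k, s, p = self.k, self.stride, self.pad
        gxp = np.zeros(xpshape, dtype=gout.dtype)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            gxp[:, i:i + s * ho:s, j:j + s * wo:s, :] += gout * (arg == idx)
        h, w = xshape[1], xshape[2]
        return gxp[:, p:p + h, p:p + w, :] if p else gxp


class GlobalMaxPool(Layer):
    """(N,H,W,C) -> (N,C), max over the spatial grid."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        flat = x.reshape(n, h * w, c)
        self._arg = flat.argmax(axis=1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._arg[:, None, :], axis=1)[:, 0, :]

    def backward(self, gout: np.ndarray, guided: bool = False) -> np.ndarray:
        n, h, w, c = self._shape
        gflat = np.zeros((n, h * w, c), dtype=gout.dtype)
        np.put_along_axis(gflat, self._arg[:, None, :], gout[:, None, :], axis=1)
        return gflat.reshape(n, h, w, c)


class Swish(Layer):
    """x * sigmoid(x); the study's activation everywhere in the network."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._sig = _sigmoid(x)
        return x * self._sig

    def backward(self, gout: np.ndarray, guided: bool = False) -> np.ndarray:
        dy = self._sig * (1.0 + self._x * (1.0 - self._sig))
        if guided:
            # zero the signal where it is negative or the unit was inactive
            gout = gout * (gout > 0) * (self._x > 0)
        return gout * dy


class Dense(Layer):
    def __init__(self, cin: int, cout: int,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / cin), size=(cin, cout))
        self.params = {"W": w.astype(dtype), "b": np.zeros(cout, dtype=dtype)}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gout: np.ndarray, guided: bool = False) -> np.ndarray:
        self.grads = {"W": self._x.T @ gout, "b": gout.sum(axis=0)}
        return gout @ self.params["W"].T


class ResidualBlock(Layer):
    """Two 3×3 convolutions with a skip connection, Swish after the add.

    When the block changes resolution or width, the skip uses a 1×1
    projection convolution with the same stride.
    """

    def __init__(self, cin: int, cout: int, stride: int = 1,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        self.conv1 = Conv2D(cin, cout, 3, stride=stride, rng=rng, dtype=dtype)
        self.act1 = Swish()
        self.conv2 = Conv2D(cout, cout, 3, rng=rng, dtype=dtype)
        self.proj = None
        if stride != 1 or cin != cout:
            self.proj = Conv2D(cin, cout, 1, stride=stride, pad=0, rng=rng,
                               dtype=dtype)
        self.act_out = Swish()

    @property
    def sublayers(self) -> list[Layer]:
        subs = [self.conv1, self.conv2]
        if self.proj is not None:
            subs.append(self.proj)
        return subs

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.conv2.forward(self.act1.forward(self.conv1.forward(x)))
        s = self.proj.forward(x) if self.proj is not None else x
        return self.act_out.forward(h + s)

    def backward(self, gout: np.ndarray, guided: bool = False) -> np.ndarray:
        g = self.act_out.backward(gout, guided)
        gmain = self.conv1.backward(
            self.act1.backward(self.conv2.backward(g, guided), guided), guided)
        gskip = self.proj.backward(g, guided) if self.proj is not None else g
        return gmain + gskip


class Adam:
    """Adam with optional decoupled-into-gradient L2 penalty on weight matrices."""

    def __init__(self, layers: list[Layer], lr: float = 2e-4, l2: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.entries = []
        for layer in layers:
            for name, p in layer.params.items():
                self.entries.append((layer, name,
                                     np.zeros_like(p), np.zeros_like(p)))
        self.lr, self.l2 = lr, l2
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer, name, m, v in self.entries:
            g = layer.grads.get(name)
            if g is None:
                continue
            if self.l2 and name == "W":
                g = g + self.l2 * layer.params[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mh = m / (1 - b1 ** self.t)
            vh = v / (1 - b2 ** self.t)
            layer.params[name] -= self.lr * mh / (np.sqrt(vh) + self.eps)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                          sample_weight: np.ndarray | None = None
                          ) -> tuple[float, np.ndarray]:
    """Mean weighted cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    ll = -np.log(p[np.arange(n), labels] + eps)
    if sample_weight is None:
        sample_weight = np.ones(n, dtype=logits.dtype)
    wsum = sample_weight.sum()
    loss = float((ll * sample_weight).sum() / wsum)
    grad = p
    grad[np.arange(n), labels] -= 1.0
    grad *= (sample_weight / wsum)[:, None]
    return loss, grad
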