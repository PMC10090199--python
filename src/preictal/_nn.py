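"""Minimal NumPy neural-network kernels used by the classifiers.

Implements exactly what the two architectures need — dense, 1-D
convolution, batch norm, (spatial) dropout, swish, a bidirectional LSTM
read out at its final states, softmax cross-entropy, and Adam — with
hand-written backward passes.  Layers expose ``params``/``grads`` lists of
arrays; ``forward(x, train=...)`` caches whatever ``backward(grad)`` needs.
Dropout layers draw from the ``rng`` handed to ``forward`` so a seeded
generator makes training fully reproducible.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def swish(x: np.ndarray) -> np.ndarray:
    """Self-gated activation x * sigmoid(x)."""
    return x * sigmoid(x)


def softmax(x: np.ndarray) -> np.ndarray:
    """Row-wise softmax, shift-invariant and overflow-safe."""
    x = np.asarray(x, dtype=np.float64)
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x, train=False, rng=None):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class Dropout(Layer):
    """Inverted elementwise dropout (identity at eval time)."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class SpatialDropout1d(Layer):
    """Drops whole feature maps of a (B, C, T) tensor."""

    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape[:2]) < keep)[..., None] / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Swish(Layer):
    def forward(self, x, train=False, rng=None):
        self._x = x
        self._s = sigmoid(x)
        return x * self._s

    def backward(self, grad):
        s = self._s
        return grad * (s + self._x * s * (1.0 - s))


class Conv1d(Layer):
    """'same'-padded temporal convolution on (B, C_in, T) tensors."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (c_in * kernel + c_out * kernel))
        self.W = rng.uniform(-limit, limit, size=(c_out, c_in, kernel))
        self.b = np.zeros(c_out)
        self.kernel, self.stride = kernel, stride
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        k, s = self.kernel, self.stride
        pad_l = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad_l, k - 1 - pad_l)))
        t_out = (x.shape[2] - 1) // s + 1
        self._xp, self._t_out = xp, t_out
        out = np.zeros((x.shape[0], self.b.size, t_out))
        for j in range(k):
            xs = xp[:, :, j:j + s * t_out:s][:, :, :t_out]
            out += np.einsum("oc,bct->bot", self.W[:, :, j], xs)
        return out + self.b[:, None]

    def backward(self, grad):
        k, s = self.kernel, self.stride
        xp = self._xp
        dxp = np.zeros_like(xp)
        for j in range(k):
            xs = xp[:, :, j:j + s * self._t_out:s][:, :, :self._t_out]
            self.grads[0][:, :, j] = np.einsum("bot,bct->oc", grad, xs)
            dslice = np.einsum("oc,bot->bct", self.W[:, :, j], grad)
            target = dxp[:, :, j:j + s * self._t_out:s]
            target[:, :, :self._t_out] += dslice
        self.grads[1][...] = grad.sum(axis=(0, 2))
        pad_l = (k - 1) // 2
        t = xp.shape[2] - (k - 1)
        return dxp[:, :, pad_l:pad_l + t]


class BatchNorm1d(Layer):
    """Per-channel normalisation of (B, C, T) over batch and time."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def forward(self, x, train=False, rng=None):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[:, None]) / std[:, None]
        self._std = std
        return self.gamma[:, None] * self._xhat + self.beta[:, None]

    def backward(self, grad):
        xhat, std = self._xhat, self._std
        n = grad.shape[0] * grad.shape[2]
        self.grads[0][...] = (grad * xhat).sum(axis=(0, 2))
        self.grads[1][...] = grad.sum(axis=(0, 2))
        g = grad * self.gamma[:, None]
        dx = (g - g.mean(axis=(0, 2), keepdims=True)
              - xhat * (g * xhat).sum(axis=(0, 2), keepdims=True) / n)
        return dx / std[:, None]


class BiLSTM(Layer):
    """Bidirectional LSTM over (B, T, D), read out at the final states.

    Returns the concatenation of the forward direction's last hidden state
    and the backward direction's state after consuming the reversed
    sequence: shape (B, 2H).
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.dirs = []
        for _ in range(2):
            lim_w = np.sqrt(6.0 / (d_in + 4 * hidden))
            lim_u = np.sqrt(6.0 / (hidden + 4 * hidden))
            W = rng.uniform(-lim_w, lim_w, size=(d_in, 4 * hidden))
            U = rng.uniform(-lim_u, lim_u, size=(hidden, 4 * hidden))
            b = np.zeros(4 * hidden)
            b[hidden:2 * hidden] = 1.0  # forget-gate bias
            self.dirs.append([W, U, b])
            self.params += [W, U, b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def _run(self, x, W, U, b):
        B, T, _ = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        for t in range(T):
            z = x[:, t] @ W + h @ U + b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((x[:, t], h, c, i, f, g, o, c_new, tc))
            h, c = h_new, c_new
        return h, cache

    def _run_back(self, dh_last, cache, W, U, dW, dU, db):
        H = self.hidden
        dh = dh_last
        dc = np.zeros_like(dh)
        dx = np.zeros((dh.shape[0], len(cache), W.shape[0]))
        for t in range(len(cache) - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, c_new, tc = cache[t]
            do = dh * tc
            dc = dc + dh * o * (1 - tc ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            dW += xt.T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ W.T
            dh = dz @ U.T
            dc = dc * f
        return dx

    def forward(self, x, train=False, rng=None):
        self._x = x
        h_f, self._cache_f = self._run(x, *self.dirs[0])
        h_b, self._cache_b = self._run(x[:, ::-1], *self.dirs[1])
        return np.concatenate([h_f, h_b], axis=1)

    def backward(self, grad):
        H = self.hidden
        for gr in self.grads:
            gr[...] = 0.0
        dx_f = self._run_back(grad[:, :H], self._cache_f,
                              self.dirs[0][0], self.dirs[0][1],
                              self.grads[0], self.grads[1], self.grads[2])
        dx_b = self._run_back(grad[:, H:], self._cache_b,
                              self.dirs[1][0], self.dirs[1][1],
                              self.grads[3], self.grads[4], self.grads[5])
        return dx_f + dx_b[:, ::-1]


class Transpose(Layer):
    """(B, C, T) <-> (B, T, C) adapter between conv blocks and the LSTM."""

    def forward(self, x, train=False, rng=None):
        return x.transpose(0, 2, 1)

    def backward(self, grad):
        return grad.transpose(0, 2, 1)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for lay in self.layers for p in lay.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for lay in self.layers for g in lay.grads]

    def forward(self, x, train=False, rng=None):
        for lay in self.layers:
            x = lay.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad):
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        return grad

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w


def cross_entropy(logits: np.ndarray, y: np.ndarray
                  ) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(y)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


class Adam:
    """Adaptive moment estimation with the usual bias correction."""

    def __init__(self, params: list[np.ndarray], lr: float = 3e-4,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g ** 2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
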