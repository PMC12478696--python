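"""Layers with hand-written reverse-mode gradients.

Conventions: batch axis first; sequence (position) axis second; feature
axis last.  Each layer caches what its backward pass needs during forward
and returns the gradient w.r.t. its input from backward; parameter
gradients accumulate into ``Parameter.grad``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax_last(x: np.ndarray) -> np.ndarray:
    # in-place-friendly: callers pass freshly computed score arrays
    x = np.subtract(x, x.max(axis=-1, keepdims=True), out=x)
    np.exp(x, out=x)
    x /= x.sum(axis=-1, keepdims=True)
    return x


def _softmax_backward(p: np.ndarray, dp: np.ndarray) -> np.ndarray:
    # d(logits) for p = softmax(logits) along the last axis
    out = dp * p
    out -= p * out.sum(axis=-1, keepdims=True)
    return out


class Parameter:
    """A trainable array with an accumulated gradient."""

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def astype(self, dtype) -> None:
        self.value = self.value.astype(dtype)
        self.grad = self.grad.astype(dtype)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []


class Dense(Layer):
    """y = act(x @ W + b) applied along the last axis."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str | None = None, name: str = "dense"):
        self.W = Parameter(glorot(rng, (n_in, n_out), n_in, n_out), f"{name}.W")
        self.b = Parameter(np.zeros(n_out), f"{name}.b")
        if activation not in (None, "relu", "tanh"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.activation = activation

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        z = x @ self.W.value + self.b.value
        if self.activation == "relu":
            self._mask = z > 0
            return z * self._mask
        if self.activation == "tanh":
            self._out = np.tanh(z)
            return self._out
        return z

    def backward(self, d: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            d = d * self._mask
        elif self.activation == "tanh":
            d = d * (1.0 - self._out ** 2)
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = d.reshape(-1, d.shape[-1])
        self.W.grad += x2.T @ d2
        self.b.grad += d2.sum(axis=0)
        return d @ self.W.value.T

    def parameters(self):
        return [self.W, self.b]


class Conv1D(Layer):
    """Valid-padding, stride-1 cross-correlation with optional ReLU.

    Input (B, L, C_in) -> output (B, L - K + 1, F).  Implemented as im2col
    followed by one matmul; backward scatters window gradients back with a
    loop over the K kernel offsets (K is small).
    """

    def __init__(self, c_in: int, filters: int, kernel: int, rng: np.random.Generator,
                 activation: str | None = "relu", name: str = "conv"):
        fan_in = kernel * c_in
        self.W = Parameter(glorot(rng, (kernel, c_in, filters), fan_in, filters), f"{name}.W")
        self.b = Parameter(np.zeros(filters), f"{name}.b")
        self.kernel = kernel
        self.c_in = c_in
        self.filters = filters
        self.activation = activation

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        K = self.kernel
        # (B, Lc, C, K) -> (B, Lc, K, C) -> (B, Lc, K*C)
        win = sliding_window_view(x, K, axis=1)          # (B, Lc, C, K)
        cols = np.ascontiguousarray(np.swapaxes(win, 2, 3)).reshape(B, L - K + 1, K * C)
        self._cols = cols
        self._x_shape = x.shape
        z = cols @ self.W.value.reshape(K * C, self.filters) + self.b.value
        if self.activation == "relu":
            self._mask = z > 0
            return z * self._mask
        self._mask = None
        return z

    def backward(self, d: np.ndarray) -> np.ndarray:
        if self._mask is not None:
            d = d * self._mask
        B, Lc, F = d.shape
        K, C = self.kernel, self.c_in
        cols2 = self._cols.reshape(-1, K * C)
        d2 = d.reshape(-1, F)
        self.W.grad += (cols2.T @ d2).reshape(K, C, F)
        self.b.grad += d2.sum(axis=0)
        dcols = (d2 @ self.W.value.reshape(K * C, F).T).reshape(B, Lc, K, C)
        dx = np.zeros(self._x_shape, dtype=d.dtype)
        for k in range(K):
            dx[:, k:k + Lc, :] += dcols[:, :, k, :]
        return dx

    def parameters(self):
        return [self.W, self.b]


class MaxPool1D(Layer):
    """Max pooling along the position axis with window ``pool`` and stride
    ``stride`` (non-overlapping when equal, the default geometry)."""

    def __init__(self, pool: int, stride: int | None = None):
        self.pool = pool
        self.stride = stride if stride is not None else pool

    def output_length(self, L: int) -> int:
        return (L - self.pool) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, F = x.shape
        Lo = self.output_length(L)
        starts = np.arange(Lo) * self.stride
        idx = starts[:, None] + np.arange(self.pool)[None, :]     # (Lo, pool)
        windows = x[:, idx, :]                                     # (B, Lo, pool, F)
        self._argmax = windows.argmax(axis=2)                      # (B, Lo, F)
        self._idx = idx
        self._in_shape = x.shape
        return windows.max(axis=2)

    def backward(self, d: np.ndarray) -> np.ndarray:
        B, Lo, F = d.shape
        dx = np.zeros(self._in_shape, dtype=d.dtype)
        # position in x of each max: window start + offset of the argmax
        pos = self._argmax + (np.arange(Lo) * self.stride)[None, :, None]
        b_idx = np.arange(B)[:, None, None]
        f_idx = np.arange(F)[None, None, :]
        np.add.at(dx, (b_idx, pos, f_idx), d)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity when not training."""

    def __init__(self, p: float):
        self.p = p

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None) -> np.ndarray:
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = ((rng.random(x.shape) >= self.p) / (1.0 - self.p)).astype(x.dtype)
        return x * self._mask

    def backward(self, d: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return d
        return d * self._mask


class LayerNorm(Layer):
    """Per-position normalization over the feature axis with learned gain/bias."""

    def __init__(self, dim: int, name: str = "ln", eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim), f"{name}.gamma")
        self.beta = Parameter(np.zeros(dim), f"{name}.beta")
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self._xhat * self.gamma.value + self.beta.value

    def backward(self, d: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        F = d.shape[-1]
        dd = d.reshape(-1, F)
        self.gamma.grad += (dd * xhat.reshape(-1, F)).sum(axis=0)
        self.beta.grad += dd.sum(axis=0)
        dxhat = d * self.gamma.value
        return inv * (dxhat - dxhat.mean(axis=-1, keepdims=True)
                      - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True))

    def parameters(self):
        return [self.gamma, self.beta]


class MultiHeadSelfAttention(Layer):
    """Scaled dot-product multi-head self-attention over positions.

    Input (B, L, F); per head d_h = F / n_heads; attention matrices are
    (B, heads, L, L) with query on rows and key on columns, each row a
    softmax distribution.  The most recent forward's attention maps are kept
    on ``self.attention`` so interpretability code can capture them.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator, name: str = "mha"):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.dim, self.n_heads, self.dh = dim, n_heads, dim // n_heads
        self.Wq = Parameter(glorot(rng, (dim, dim), dim, dim), f"{name}.Wq")
        self.Wk = Parameter(glorot(rng, (dim, dim), dim, dim), f"{name}.Wk")
        self.Wv = Parameter(glorot(rng, (dim, dim), dim, dim), f"{name}.Wv")
        self.Wo = Parameter(glorot(rng, (dim, dim), dim, dim), f"{name}.Wo")
        self.bq = Parameter(np.zeros(dim), f"{name}.bq")
        self.bk = Parameter(np.zeros(dim), f"{name}.bk")
        self.bv = Parameter(np.zeros(dim), f"{name}.bv")
        self.bo = Parameter(np.zeros(dim), f"{name}.bo")
        self.attention: np.ndarray | None = None

    def _split(self, x: np.ndarray) -> np.ndarray:
        B, L, _ = x.shape
        return x.reshape(B, L, self.n_heads, self.dh).transpose(0, 2, 1, 3)

    def _join(self, x: np.ndarray) -> np.ndarray:
        B, h, L, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, L, h * dh)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        Q = self._split(x @ self.Wq.value + self.bq.value)
        K = self._split(x @ self.Wk.value + self.bk.value)
        V = self._split(x @ self.Wv.value + self.bv.value)
        scores = Q @ K.transpose(0, 1, 3, 2) / float(np.sqrt(self.dh))
        A = _softmax_last(scores)
        self.attention = A
        self._Q, self._K, self._V = Q, K, V
        ctx = A @ V                                   # (B, h, L, dh)
        self._ctx = ctx
        return self._join(ctx) @ self.Wo.value + self.bo.value

    def backward(self, d: np.ndarray) -> np.ndarray:
        B, L, F = d.shape
        joined = self._join(self._ctx)
        self.Wo.grad += joined.reshape(-1, F).T @ d.reshape(-1, F)
        self.bo.grad += d.reshape(-1, F).sum(axis=0)
        dctx = self._split(d @ self.Wo.value.T)       # (B, h, L, dh)
        A, Q, K, V = self.attention, self._Q, self._K, self._V
        dA = dctx @ V.transpose(0, 1, 3, 2)
        dV = A.transpose(0, 1, 3, 2) @ dctx
        dS = _softmax_backward(A, dA) / float(np.sqrt(self.dh))
        dQ = dS @ K
        dK = dS.transpose(0, 1, 3, 2) @ Q
        dx = np.zeros_like(self._x)
        x2 = self._x.reshape(-1, F)
        for dproj, W, b in ((dQ, self.Wq, self.bq), (dK, self.Wk, self.bk), (dV, self.Wv, self.bv)):
            dj = self._join(dproj)
            W.grad += x2.T @ dj.reshape(-1, F)
            b.grad += dj.reshape(-1, F).sum(axis=0)
            dx += dj @ W.value.T
        return dx

    def parameters(self):
        return [self.Wq, self.bq, self.Wk, self.bk, self.Wv, self.bv, self.Wo, self.bo]


class HierarchicalAttention(Layer):
    """Soft position weighting: S = sum_i softmax_i(tanh(W h_i + b) . u) h_i.

    A learned context vector u scores a tanh hidden representation of each
    position; the softmax over positions yields non-negative weights summing
    to one, and the output is the weighted sum of position vectors.  The most
    recent weights are kept on ``self.weights``.
    """

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator, name: str = "hattn"):
        self.Wh = Parameter(glorot(rng, (dim, hidden), dim, hidden), f"{name}.Wh")
        self.bh = Parameter(np.zeros(hidden), f"{name}.bh")
        self.uc = Parameter(glorot(rng, (hidden,), hidden, 1), f"{name}.uc")
        self.weights: np.ndarray | None = None

    def forward(self, h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        self._h = h
        self._u = np.tanh(h @ self.Wh.value + self.bh.value)       # (B, L, A)
        scores = self._u @ self.uc.value                            # (B, L)
        alpha = _softmax_last(scores)
        self.weights = alpha
        s = np.einsum("bl,blf->bf", alpha, h)
        return s, alpha

    def backward(self, ds: np.ndarray) -> np.ndarray:
        h, u, alpha = self._h, self._u, self.weights
        dalpha = np.einsum("bf,blf->bl", ds, h)
        dh = alpha[:, :, None] * ds[:, None, :]
        dscores = _softmax_backward(alpha, dalpha)
        self.uc.grad += np.einsum("bla,bl->a", u, dscores)
        du = dscores[:, :, None] * self.uc.value[None, None, :]
        dpre = du * (1.0 - u ** 2)
        A = dpre.shape[-1]
        F = h.shape[-1]
        self.Wh.grad += h.reshape(-1, F).T @ dpre.reshape(-1, A)
        self.bh.grad += dpre.reshape(-1, A).sum(axis=0)
        dh += dpre @ self.Wh.value.T
        return dh

    def parameters(self):
        return [self.Wh, self.bh, self.uc]
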