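"""Primitive differentiable layers, NHWC layout, float32 working precision.

Every layer caches what its backward pass needs during forward and exposes
``params`` / ``grads`` dictionaries keyed by parameter name.  Convolution
weight matrices are registered under the name ``"W"``; only these enter the
L2 regularizer (biases and batch-norm scale/shift are excluded).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "PointwiseConv",
    "DepthwiseConv3x3",
    "Conv3x3",
    "BatchNorm",
    "ReLU",
    "MaxPool2x2",
    "GlobalAvgPool",
    "NonlocalBlock",
    "softmax",
]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Layer:
    """Base: parameter/grad registry plus a sub-layer tree."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.children: list["Layer"] = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def walk(self):
        """Yield self and all descendants, depth-first."""
        yield self
        for c in self.children:
            yield from c.walk()

    def parameter_items(self):
        """Yield (layer, name, array) for every parameter in the tree."""
        for layer in self.walk():
            for name, arr in layer.params.items():
                yield layer, name, arr

    def n_params(self) -> int:
        return sum(arr.size for _, _, arr in self.parameter_items())

    def zero_grads(self) -> None:
        for layer in self.walk():
            for name, arr in layer.params.items():
                layer.grads[name] = np.zeros_like(arr)


DTYPE = np.float32  # working precision; ops follow input/param dtype


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class PointwiseConv(Layer):
    """1x1 convolution (channel mixing), optional spatial stride."""

    def __init__(self, c_in: int, c_out: int, stride: int = 1, bias: bool = False,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.params["W"] = _he_init(rng, (c_in, c_out), c_in)
        if bias:
            self.params["b"] = np.zeros(c_out, dtype=DTYPE)

    def forward(self, x, training=False):
        if self.stride > 1:
            s = self.stride
            self._full_h, self._full_w = x.shape[1], x.shape[2]
            x = x[:, ::s, ::s, :]
        self._x = x
        y = x @ self.params["W"]
        if "b" in self.params:
            y = y + self.params["b"]
        return y

    def backward(self, dy):
        x = self._x
        self.grads["W"] = np.einsum("nhwc,nhwo->co", x, dy)
        if "b" in self.params:
            self.grads["b"] = dy.sum(axis=(0, 1, 2))
        dx_sub = dy @ self.params["W"].T
        if self.stride > 1:
            s = self.stride
            # stride-s subsampling scatters gradient back onto the full grid
            dx = np.zeros((dx_sub.shape[0], self._full_h, self._full_w, dx_sub.shape[3]),
                          dtype=dx_sub.dtype)
            dx[:, ::s, ::s, :] = dx_sub
            return dx
        return dx_sub


def _pad1(x: np.ndarray) -> np.ndarray:
    return np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))


def _shifted(xp: np.ndarray, i: int, j: int, h: int, w: int) -> np.ndarray:
    """The (i, j)-offset window of a 1-padded array, shape (N, h, w, C)."""
    return xp[:, i : i + h, j : j + w, :]


class DepthwiseConv3x3(Layer):
    """Per-channel 3x3 spatial convolution, unit stride, same padding.

    Computed as nine shift-and-accumulate passes over the padded input,
    which is far cheaper than materializing patch tensors.
    """

    def __init__(self, c: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = _he_init(rng, (3, 3, c), 9)

    def forward(self, x, training=False):
        self._xp = _pad1(x)
        n, h, w, c = x.shape
        self._hw = (h, w)
        W = self.params["W"]
        y = np.zeros_like(x)
        # correlation convention (no kernel flip), as in deep-learning convs
        for i in range(3):
            for j in range(3):
                y += W[i, j] * _shifted(self._xp, i, j, h, w)
        return y

    def backward(self, dy):
        h, w = self._hw
        W = self.params["W"]
        dW = np.empty_like(W)
        dyp = _pad1(dy)
        dx = np.zeros_like(dy)
        for i in range(3):
            for j in range(3):
                dW[i, j] = np.einsum(
                    "nhwc,nhwc->c", _shifted(self._xp, i, j, h, w), dy
                )
                # transposed (full) convolution with the flipped kernel
                dx += W[2 - i, 2 - j] * _shifted(dyp, i, j, h, w)
        self.grads["W"] = dW
        return dx


class Conv3x3(Layer):
    """Full 3x3 convolution, unit stride, same padding."""

    def __init__(self, c_in: int, c_out: int, bias: bool = True,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = _he_init(rng, (3, 3, c_in, c_out), 9 * c_in)
        if bias:
            self.params["b"] = np.zeros(c_out, dtype=DTYPE)

    def forward(self, x, training=False):
        self._xp = _pad1(x)
        n, h, w, c = x.shape
        self._hw = (h, w)
        W = self.params["W"]
        y = np.zeros((n, h, w, W.shape[3]), dtype=x.dtype)
        for i in range(3):
            for j in range(3):
                y += _shifted(self._xp, i, j, h, w) @ W[i, j]
        if "b" in self.params:
            y = y + self.params["b"]
        return y

    def backward(self, dy):
        h, w = self._hw
        W = self.params["W"]
        dW = np.empty_like(W)
        dyp = _pad1(dy)
        dx = np.zeros(self._xp.shape[:1] + (h, w, W.shape[2]), dtype=dy.dtype)
        for i in range(3):
            for j in range(3):
                dW[i, j] = np.einsum(
                    "nhwc,nhwo->co", _shifted(self._xp, i, j, h, w), dy
                )
                dx += _shifted(dyp, i, j, h, w) @ W[2 - i, 2 - j].T
        self.grads["W"] = dW
        if "b" in self.params:
            self.grads["b"] = dy.sum(axis=(0, 1, 2))
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W).

    Batch statistics during training with exponentially updated running
    averages; running averages at inference.
    """

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(c, dtype=DTYPE)
        self.params["beta"] = np.zeros(c, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        # debiased exponential averages (zero-initialized, corrected by 1-m^t)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.zeros(c, dtype=DTYPE)
        self.n_updates = 0

    def _corrected_stats(self):
        if self.n_updates == 0:
            return np.zeros_like(self.running_mean), np.ones_like(self.running_var)
        corr = 1.0 - self.momentum**self.n_updates
        return self.running_mean / corr, self.running_var / corr

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(mean.dtype)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(var.dtype)
            self.n_updates += 1
        else:
            mean, var = self._corrected_stats()
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._m = x.shape[0] * x.shape[1] * x.shape[2]
        self._training = training
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        xhat, std, m = self._xhat, self._std, self._m
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 1, 2))
        self.grads["beta"] = dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.params["gamma"]
        if not self._training:
            return dxhat / std
        s1 = dxhat.sum(axis=(0, 1, 2))
        s2 = (dxhat * xhat).sum(axis=(0, 1, 2))
        return (dxhat - s1 / m - xhat * s2 / m) / std


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2x2(Layer):
    def forward(self, x, training=False):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max-pool 2x2 needs even spatial dims, got {h}x{w}")
        win = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        win = win.reshape(n, h // 2, w // 2, c, 4)
        self._argmax = win.argmax(axis=-1)
        self._shape = x.shape
        return win.max(axis=-1)

    def backward(self, dy):
        n, h, w, c = self._shape
        dwin = np.zeros((n, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(dwin, self._argmax[..., None], dy[..., None], axis=-1)
        dwin = dwin.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dwin.reshape(n, h, w, c)


class GlobalAvgPool(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :], self._shape) / (h * w)


class NonlocalBlock(Layer):
    """Embedded-Gaussian nonlocal operation.

    For a c-channel h x w map x with per-position vectors x_i, the output is

        r_i = (1 / C_i(x)) * sum_j exp(phi(x_i)^T psi(x_j)) g(x_j)

    with C_i normalizing over all positions j, so the weights form a softmax
    over positions.  phi, psi and g are learned 1x1 convolutions.
    """

    def __init__(self, c: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        # small phi/psi init keeps early attention near-uniform; the value
        # kernel starts at zero so the block begins as an identity (inside a
        # residual) and the attention pathway is learned gradually
        scale = 1.0 / np.sqrt(c)
        self.params["W_phi"] = rng.normal(0.0, scale, size=(c, c)).astype(DTYPE)
        self.params["W_psi"] = rng.normal(0.0, scale, size=(c, c)).astype(DTYPE)
        self.params["W_g"] = np.zeros((c, c), dtype=DTYPE)

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        X = x.reshape(n, h * w, c)
        phi = X @ self.params["W_phi"]
        psi = X @ self.params["W_psi"]
        g = X @ self.params["W_g"]
        logits = phi @ psi.transpose(0, 2, 1)
        A = softmax(logits, axis=2)
        r = A @ g
        self._cache = (X, phi, psi, g, A, (n, h, w, c))
        return r.reshape(n, h, w, c)

    @property
    def last_attention(self) -> np.ndarray:
        """Row-stochastic attention matrix from the last forward call."""
        return self._cache[4]

    def backward(self, dy):
        X, phi, psi, g, A, (n, h, w, c) = self._cache
        dr = dy.reshape(n, h * w, c)
        dA = dr @ g.transpose(0, 2, 1)
        dg = A.transpose(0, 2, 1) @ dr
        # softmax backward, rows of A
        dS = A * (dA - (dA * A).sum(axis=2, keepdims=True))
        dphi = dS @ psi
        dpsi = dS.transpose(0, 2, 1) @ phi
        self.grads["W_phi"] = np.einsum("npc,npd->cd", X, dphi)
        self.grads["W_psi"] = np.einsum("npc,npd->cd", X, dpsi)
        self.grads["W_g"] = np.einsum("npc,npd->cd", X, dg)
        dX = (
            dphi @ self.params["W_phi"].T
            + dpsi @ self.params["W_psi"].T
            + dg @ self.params["W_g"].T
        )
        return dX.reshape(n, h, w, c)


def nonlocal_reference(x: np.ndarray, w_phi: np.ndarray, w_psi: np.ndarray,
                       w_g: np.ndarray) -> np.ndarray:
    """Naive double-loop nonlocal operation, for cross-checking.

    Computes r_i = sum_j f(x_i, x_j) g(x_j) / sum_j f(x_i, x_j) with
    f = exp(phi(x_i)^T psi(x_j)) literally, position pair by position pair.
    """
    h, w, c = x.shape
    X = x.reshape(h * w, c)
    out = np.zeros_like(X)
    for i in range(X.shape[0]):
        phi_i = X[i] @ w_phi
        weights = np.array([np.exp(phi_i @ (X[j] @ w_psi)) for j in range(X.shape[0])])
        norm = weights.sum()
        for j in range(X.shape[0]):
            out[i] += (weights[j] / norm) * (X[j] @ w_g)
    return out.reshape(h, w, c)
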