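"""Minimal convolutional network engine with explicit backward passes.

Provides exactly the layer vocabulary needed by the compact image GAN used
for inversion-based out-of-distribution screening: strided convolution,
transposed convolution, batch normalization, (leaky) rectifiers, Tanh and
sigmoid, a sequential container, binary cross-entropy on logits, and Adam.

Everything runs in float32 on NCHW arrays.  Convolutions are evaluated as
matrix products over im2col patch matrices, so a single BLAS call carries
each layer; transposed convolution is implemented as the exact adjoint
(col2im scatter-add) of the matching convolution, which is what makes the
end-to-end analytic gradients pass finite-difference checks.

All randomness is injected through ``numpy.random.Generator`` instances;
the module itself never touches global random state.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


# ---------------------------------------------------------------------------
# im2col / col2im
# ---------------------------------------------------------------------------

def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Extract k x k patches of ``x`` (N,C,H,W) into a (C*k*k, N*L) matrix.

    The channel-major layout lets each convolution run as one full-size
    BLAS gemm over all batch elements at once.
    """
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (N,C,Ho,Wo,k,k)
    n, c, ho, wo = windows.shape[:4]
    cols = windows.transpose(1, 4, 5, 0, 2, 3).reshape(c * k * k, n * ho * wo)
    return cols, (ho, wo)


def col2im(cols: np.ndarray, out_shape: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patch columns back to images.

    ``cols`` has shape (C*k*k, N*Ho*Wo); ``out_shape`` is the unpadded
    (N, C, H, W) target.
    """
    n, c, h, w = out_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    patches = cols.reshape(c, k, k, n, ho, wo)
    out = np.zeros((c, n, hp, wp), dtype=cols.dtype)
    for ki in range(k):
        i_end = ki + stride * ho
        for kj in range(k):
            j_end = kj + stride * wo
            out[:, :, ki:i_end:stride, kj:j_end:stride] += patches[:, ki, kj]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return np.ascontiguousarray(out.transpose(1, 0, 2, 3))


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Layer:
    """Base class: layers hold named parameters and matching gradients."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Strided 2-D convolution without bias (batchnorm supplies the shift)."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int):
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        self.params["w"] = np.zeros((c_out, c_in, k, k), dtype=DTYPE)
        self.grads["w"] = np.zeros_like(self.params["w"])

    def forward(self, x, train):
        self._x_shape = x.shape
        self._cols, (ho, wo) = im2col(x, self.k, self.stride, self.pad)
        n = x.shape[0]
        w2 = self.params["w"].reshape(self.c_out, -1)
        out = w2 @ self._cols  # (Cout, N*L)
        return np.ascontiguousarray(out.reshape(self.c_out, n, ho, wo).transpose(1, 0, 2, 3))

    def backward(self, dout):
        n = dout.shape[0]
        d2 = np.ascontiguousarray(dout.transpose(1, 0, 2, 3)).reshape(self.c_out, -1)
        self.grads["w"][...] = (d2 @ self._cols.T).reshape(self.params["w"].shape)
        w2 = self.params["w"].reshape(self.c_out, -1)
        dcols = w2.T @ d2
        return col2im(dcols, self._x_shape, self.k, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Transposed (fractionally strided) convolution without bias.

    Weight layout (C_in, C_out, k, k); the forward pass is the adjoint of a
    stride-s convolution, so output side = (H-1)*s - 2p + k.
    """

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int):
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        self.params["w"] = np.zeros((c_in, c_out, k, k), dtype=DTYPE)
        self.grads["w"] = np.zeros_like(self.params["w"])

    def forward(self, x, train):
        n, _, h, w = x.shape
        self._in_hw = (h, w)
        self._xr = np.ascontiguousarray(x.transpose(1, 0, 2, 3)).reshape(self.c_in, -1)
        w2 = self.params["w"].reshape(self.c_in, -1)  # (Cin, Cout*k*k)
        cols = w2.T @ self._xr  # (Cout*k*k, N*L)
        ho = (h - 1) * self.stride - 2 * self.pad + self.k
        wo = (w - 1) * self.stride - 2 * self.pad + self.k
        self._out_shape = (n, self.c_out, ho, wo)
        return col2im(cols, self._out_shape, self.k, self.stride, self.pad)

    def backward(self, dout):
        n = dout.shape[0]
        dcols, _ = im2col(dout, self.k, self.stride, self.pad)  # (Cout*k*k, N*L)
        self.grads["w"][...] = (self._xr @ dcols.T).reshape(self.params["w"].shape)
        w2 = self.params["w"].reshape(self.c_in, -1)
        dx = w2 @ dcols  # (Cin, N*L)
        h, w = self._in_hw
        return np.ascontiguousarray(dx.reshape(self.c_in, n, h, w).transpose(1, 0, 2, 3))


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics.

    Training mode normalizes with batch moments and updates the running
    estimates (momentum 0.1); evaluation mode uses the frozen running
    moments, which makes the network a fixed deterministic map — required
    so latent inversion optimizes against a stationary generator.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(c, dtype=DTYPE)
        self.params["beta"] = np.zeros(c, dtype=DTYPE)
        self.grads["gamma"] = np.zeros(c, dtype=DTYPE)
        self.grads["beta"] = np.zeros(c, dtype=DTYPE)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)

    def forward(self, x, train):
        self._train = train
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            self._inv_std = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mu[None, :, None, None]) * self._inv_std[None, :, None, None]
            return g * self._xhat + b
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        self._eval_scale = self.params["gamma"] * inv
        xhat = (x - self.running_mean[None, :, None, None]) * inv[None, :, None, None]
        self._xhat = xhat
        return g * xhat + b

    def backward(self, dout):
        self.grads["gamma"][...] = (dout * self._xhat).sum(axis=(0, 2, 3))
        self.grads["beta"][...] = dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        if not self._train:
            return dout * self._eval_scale[None, :, None, None]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dxhat = dout * g
        mean_d = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        mean_dx = (dxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True)
        inv = self._inv_std[None, :, None, None]
        return inv * (dxhat - mean_d - self._xhat * mean_dx)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class Tanh(Layer):
    def forward(self, x, train):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y * self._y)


class Sequential:
    """Ordered layer stack with symmetric forward/backward traversal."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        """Yield (layer, name, array) triples in a stable order."""
        for layer in self.layers:
            for name in sorted(layer.params):
                yield layer, name, layer.params[name]

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and batchnorm buffers."""
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                out[f"{i}.{name}"] = arr
            if isinstance(layer, BatchNorm2d):
                out[f"{i}.running_mean"] = layer.running_mean
                out[f"{i}.running_var"] = layer.running_var
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for key, arr in self.state_arrays().items():
            arr[...] = state[key]

    def cast(self, dtype) -> "Sequential":
        """Convert all parameters/buffers in place (e.g. to float64 for
        high-precision finite-difference gradient verification)."""
        for layer in self.layers:
            for name in layer.params:
                layer.params[name] = layer.params[name].astype(dtype)
                layer.grads[name] = layer.grads[name].astype(dtype)
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = layer.running_mean.astype(dtype)
                layer.running_var = layer.running_var.astype(dtype)
        return self


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy of sigmoid(logits) against a constant target.

    Returns (loss, d_loss/d_logits).  Computed on logits for stability; the
    gradient is (sigmoid(logit) - target) / n.
    """
    z = logits.ravel().astype(np.float64)
    # log(1+exp(-|z|)) formulation avoids overflow either side
    loss = np.mean(np.maximum(z, 0) - z * target + np.log1p(np.exp(-np.abs(z))))
    grad = (sigmoid(logits) - target) / logits.size
    return float(loss), grad.astype(DTYPE)


class Adam:
    """Adam optimizer over a list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1: float, beta2: float,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
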