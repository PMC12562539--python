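"""Minimal neural-network layers with explicit backpropagation.

The package trains small 3D convolutional encoders and linear heads on CPU;
this module provides exactly the layers those models need, as numpy arrays
with hand-written forward/backward passes.  Every backward pass is covered by
finite-difference tests.

Conventions
-----------
* Volumetric activations are ``(N, C, D, H, W)`` float arrays; fully connected
  activations are ``(N, F)``.
* Each layer stores its parameters in ``self.params`` and the gradients of the
  last backward call in ``self.grads`` (same keys, same shapes).
* Non-trainable state (batch-norm running statistics) lives in
  ``self.buffers`` and is excluded from parameter flattening.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv3d",
    "Linear",
    "ReLU",
    "MaxPool3d",
    "AvgPool3d",
    "Flatten",
    "GlobalAvgPool3d",
    "BatchNorm3d",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "SGD",
    "AdamW",
]


class Layer:
    """Base class: a differentiable map with named parameters."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    def named_parameters(self):
        for k in self.params:
            yield self, k

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


class Conv3d(Layer):
    """3D convolution (cross-correlation) with zero padding.

    Forward and weight gradients run as one GEMM over an im2col buffer; the
    input gradient scatters columns back over the k**3 kernel offsets.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.k, self.s, self.p = kernel, stride, pad
        fan_in = c_in * kernel ** 3
        # He initialization, appropriate for ReLU nets
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel, kernel)
        ).astype(np.float64)
        self.params["b"] = np.zeros(c_out)
        self.zero_grad()
        self._cache: tuple | None = None

    def _im2col(self, xp, Do, Ho, Lo):
        k, s = self.k, self.s
        sw = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k),
                                                      axis=(2, 3, 4))
        sw = sw[:, :, ::s, ::s, ::s]  # (N, C, Do, Ho, Lo, k, k, k)
        N, C = xp.shape[:2]
        # (N, P, C*k^3) with P = Do*Ho*Lo
        return (sw.transpose(0, 2, 3, 4, 1, 5, 6, 7)
                  .reshape(N, Do * Ho * Lo, C * k ** 3))

    def forward(self, x, train=False):
        k, s, p = self.k, self.s, self.p
        W = self.params["W"]
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        N, C, D, H, L = xp.shape
        Do, Ho, Lo = (D - k) // s + 1, (H - k) // s + 1, (L - k) // s + 1
        cols = self._im2col(xp, Do, Ho, Lo)
        Wm = W.reshape(W.shape[0], -1)
        out = cols @ Wm.T + self.params["b"]
        self._cache = (cols, xp.shape, x.shape, (Do, Ho, Lo))
        return out.transpose(0, 2, 1).reshape(N, W.shape[0], Do, Ho, Lo)

    def backward(self, dout):
        k, s, p = self.k, self.s, self.p
        W = self.params["W"]
        cols, xp_shape, x_shape, (Do, Ho, Lo) = self._cache
        N, co = dout.shape[:2]
        dflat = dout.reshape(N, co, -1).transpose(0, 2, 1)  # (N, P, co)
        self.grads["W"] += np.einsum("npo,npc->oc", dflat, cols,
                                     optimize=True).reshape(W.shape)
        self.grads["b"] += dout.sum(axis=(0, 2, 3, 4))
        dcols = dflat @ W.reshape(co, -1)  # (N, P, C*k^3)
        C = xp_shape[1]
        dcols = (dcols.reshape(N, Do, Ho, Lo, C, k, k, k)
                      .transpose(0, 4, 1, 2, 3, 5, 6, 7))
        dxp = np.zeros(xp_shape, dtype=dout.dtype)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    dxp[:, :, dz:dz + s * Do:s, dy:dy + s * Ho:s,
                        dx:dx + s * Lo:s] += dcols[..., dz, dy, dx]
        _, _, D, H, L = x_shape
        return dxp[:, :, p:p + D, p:p + H, p:p + L]


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / d_in),
                                      size=(d_out, d_in)).astype(np.float64)
        self.params["b"] = np.zeros(d_out)
        self.zero_grad()
        self._x: np.ndarray | None = None

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout):
        self.grads["W"] += dout.T @ self._x
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool3d(Layer):
    """Non-overlapping max pooling with window 2 (spatial dims must be even)."""

    def forward(self, x, train=False):
        N, C, D, H, L = x.shape
        if D % 2 or H % 2 or L % 2:
            raise ValueError(f"MaxPool3d(2) needs even spatial dims, got {x.shape}")
        xr = (x.reshape(N, C, D // 2, 2, H // 2, 2, L // 2, 2)
               .transpose(0, 1, 2, 4, 6, 3, 5, 7)
               .reshape(N, C, D // 2, H // 2, L // 2, 8))
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        N, C, D, H, L = self._shape
        dxr = np.zeros((N, C, D // 2, H // 2, L // 2, 8), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        return (dxr.reshape(N, C, D // 2, H // 2, L // 2, 2, 2, 2)
                   .transpose(0, 1, 2, 5, 3, 6, 4, 7)
                   .reshape(N, C, D, H, L))


class AvgPool3d(Layer):
    """Non-overlapping average pooling with window 2."""

    def forward(self, x, train=False):
        N, C, D, H, L = x.shape
        if D % 2 or H % 2 or L % 2:
            raise ValueError(f"AvgPool3d(2) needs even spatial dims, got {x.shape}")
        self._shape = x.shape
        return x.reshape(N, C, D // 2, 2, H // 2, 2, L // 2, 2).mean(
            axis=(3, 5, 7))

    def backward(self, dout):
        N, C, D, H, L = self._shape
        d = np.broadcast_to(
            dout[:, :, :, None, :, None, :, None] / 8.0,
            (N, C, D // 2, 2, H // 2, 2, L // 2, 2))
        return d.reshape(N, C, D, H, L)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class GlobalAvgPool3d(Layer):
    """Average over all spatial positions, returning ``(N, C)``."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout):
        N, C, D, H, L = self._shape
        return np.broadcast_to(dout[:, :, None, None, None] / (D * H * L),
                               self._shape).copy()


class BatchNorm3d(Layer):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(c)
        self.params["beta"] = np.zeros(c)
        self.buffers["running_mean"] = np.zeros(c)
        self.buffers["running_var"] = np.ones(c)
        self.zero_grad()

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3, 4))
            var = x.var(axis=(0, 2, 3, 4))
            self.buffers["running_mean"] = ((1 - self.momentum)
                                            * self.buffers["running_mean"]
                                            + self.momentum * mean)
            self.buffers["running_var"] = ((1 - self.momentum)
                                           * self.buffers["running_var"]
                                           + self.momentum * var)
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        bc = (None, slice(None), None, None, None)
        self._xhat = (x - mean[bc]) / np.sqrt(var[bc] + self.eps)
        self._std = np.sqrt(var + self.eps)
        self._train = train
        return self.params["gamma"][bc] * self._xhat + self.params["beta"][bc]

    def backward(self, dout):
        bc = (None, slice(None), None, None, None)
        xhat, std = self._xhat, self._std
        self.grads["gamma"] += (dout * xhat).sum(axis=(0, 2, 3, 4))
        self.grads["beta"] += dout.sum(axis=(0, 2, 3, 4))
        dxhat = dout * self.params["gamma"][bc]
        if not self._train:
            return dxhat / std[bc]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3] * dout.shape[4]
        # standard batch-norm backward through the batch statistics
        return (dxhat - dxhat.mean(axis=(0, 2, 3, 4))[bc]
                - xhat * (dxhat * xhat).mean(axis=(0, 2, 3, 4))[bc]) / std[bc]


class Residual(Layer):
    """Residual wrapper: out = relu(body(x) + shortcut(x))."""

    def __init__(self, body: "Sequential", shortcut: "Sequential | None" = None):
        super().__init__()
        self.body = body
        self.shortcut = shortcut

    def forward(self, x, train=False):
        y = self.body(x, train=train)
        sc = x if self.shortcut is None else self.shortcut(x, train=train)
        self._mask = (y + sc) > 0
        return (y + sc) * self._mask

    def backward(self, dout):
        d = dout * self._mask
        dx = self.body.backward(d)
        if self.shortcut is None:
            dx = dx + d
        else:
            dx = dx + self.shortcut.backward(d)
        return dx

    def zero_grad(self):
        self.body.zero_grad()
        if self.shortcut is not None:
            self.shortcut.zero_grad()

    def named_parameters(self):
        yield from self.body.named_parameters()
        if self.shortcut is not None:
            yield from self.shortcut.named_parameters()


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def named_parameters(self):
        for layer in self.layers:
            yield from layer.named_parameters()


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -logp[np.arange(n), y].mean()
    p = np.exp(logp)
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


class SGD:
    def __init__(self, named_params, lr: float, clip_norm: float | None = 5.0):
        self.named_params = list(named_params)
        self.lr = lr
        self.clip_norm = clip_norm

    def _clip(self) -> None:
        """Global-norm gradient clipping across all managed parameters."""
        if self.clip_norm is None:
            return
        total = np.sqrt(sum(float((layer.grads[k] ** 2).sum())
                            for layer, k in self.named_params))
        if total > self.clip_norm:
            scale = self.clip_norm / total
            for layer, k in self.named_params:
                layer.grads[k] = layer.grads[k] * scale

    def step(self) -> None:
        self._clip()
        for layer, k in self.named_params:
            layer.params[k] -= self.lr * layer.grads[k]

    def zero_grad(self) -> None:
        for layer, k in self.named_params:
            layer.grads[k] = np.zeros_like(layer.params[k])


class AdamW(SGD):
    """AdamW with decoupled weight decay (used by the full-scale profile)."""

    def __init__(self, named_params, lr: float, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.95,
                 clip_norm: float | None = 5.0):
        super().__init__(named_params, lr, clip_norm)
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(layer.params[k]) for layer, k in self.named_params]
        self.v = [np.zeros_like(layer.params[k]) for layer, k in self.named_params]

    def step(self) -> None:
        self._clip()
        self.t += 1
        for i, (layer, k) in enumerate(self.named_params):
            g = layer.grads[k]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            layer.params[k] -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                          + self.wd * layer.params[k])
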