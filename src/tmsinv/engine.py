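"""Minimal neural-network engine on numpy.

Implements exactly the layer zoo the inverse-mapping architectures need —
3D convolution (stride 1, odd kernels), 2x2x2 max-pooling, nearest-neighbour
2x upsampling, fully connected layers, batch normalisation, ReLU and bounded
ReLU activations, a Gaussian variational sampler, and the Adadelta optimizer —
with hand-written backward passes. Convolutions are evaluated as a single GEMM
over im2col patches; backward passes are exact gradients (finite-difference
checked in the test suite).

Arrays are ``float32`` by default; gradient-check tests run the same code in
``float64``. Volumetric activations use the layout ``(N, C, D, H, W)``.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Layer",
    "Conv3d",
    "MaxPool3d",
    "Upsample3d",
    "Linear",
    "BatchNorm",
    "ReLU",
    "BoundedReLU",
    "Flatten",
    "Reshape",
    "MaskLayer",
    "VariationalSampler",
    "Sequential",
    "Adadelta",
    "parameter_checksum",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    def __init__(self, value: np.ndarray) -> None:
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base layer: ``forward`` caches what ``backward`` needs."""

    training: bool = True
    #: frozen layers still propagate input gradients but skip the (useless)
    #: parameter-gradient computation
    skip_param_grad: bool = False

    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def set_training(self, flag: bool) -> None:
        self.training = flag

    def set_skip_param_grad(self, flag: bool) -> None:
        self.skip_param_grad = flag


def _glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                    fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Conv3d(Layer):
    """3D convolution, stride 1, symmetric zero padding.

    Only odd kernel sizes with ``pad = (k - 1) // 2`` (shape preserving) are
    used by the architectures here, but any ``pad`` works.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, pad: int | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32,
                 bias_init: float = 0.0) -> None:
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        self.pad = (kernel - 1) // 2 if pad is None else pad
        fan_in = in_ch * kernel ** 3
        self.weight = Parameter(_glorot_uniform(
            rng, (out_ch, in_ch, kernel, kernel, kernel), fan_in, out_ch, dtype))
        self.bias = Parameter(np.full(out_ch, bias_init, dtype=dtype))
        self._x: np.ndarray | None = None
        self._cols: np.ndarray | None = None

    def params(self) -> list[Parameter]:
        return [self.weight, self.bias]

    @staticmethod
    def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
        """Return patches as a matrix of shape (N*D'*H'*W', C*k^3)."""
        if pad:
            x = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
        # view: (N, C, D', H', W', k, k, k)
        v = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
        n, c, d, h, w = v.shape[:5]
        cols = v.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * d * h * w, c * k ** 3)
        return np.ascontiguousarray(cols)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n = x.shape[0]
        cols = self._im2col(x, self.k, self.pad)
        if self.training:
            self._x = x
            self._cols = cols if not self.skip_param_grad else None
        w2 = self.weight.value.reshape(self.out_ch, -1)
        out_side = x.shape[2] + 2 * self.pad - self.k + 1
        y = cols @ w2.T + self.bias.value
        y = y.reshape(n, out_side, out_side, out_side, self.out_ch)
        return np.ascontiguousarray(y.transpose(0, 4, 1, 2, 3))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        n, _, d, h, w = gy.shape
        gy2 = gy.transpose(0, 2, 3, 4, 1).reshape(-1, self.out_ch)
        if not self.skip_param_grad:
            cols = self._cols if self._cols is not None \
                else self._im2col(x, self.k, self.pad)
            self.weight.grad += (gy2.T @ cols).reshape(self.weight.value.shape)
            self.bias.grad += gy2.sum(axis=0)
        # grad wrt input: full correlation with spatially flipped kernels
        w_flip = self.weight.value[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        gcols = self._im2col(gy, self.k, self.k - 1 - self.pad)
        gx = gcols @ w_flip.reshape(self.in_ch, -1).T
        gx = gx.reshape(n, x.shape[2], x.shape[3], x.shape[4], self.in_ch)
        return np.ascontiguousarray(gx.transpose(0, 4, 1, 2, 3))


class MaxPool3d(Layer):
    """2x2x2 max pooling with stride 2 (halves every spatial side)."""

    def __init__(self) -> None:
        self._mask: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, d, h, w = x.shape
        xr = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5, 7))
        if self.training:
            ye = y[:, :, :, None, :, None, :, None]
            mask = (xr == ye)
            # distribute evenly over ties so the gradient stays exact
            counts = mask.sum(axis=(3, 5, 7), keepdims=True)
            self._mask = mask / counts
            self._shape = x.shape
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = gy[:, :, :, None, :, None, :, None] * self._mask
        return g.reshape(self._shape)


class Upsample3d(Layer):
    """Nearest-neighbour 2x upsampling along each spatial axis."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, d, h, w = gy.shape
        return gy.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(3, 5, 7))


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None, dtype=np.float32,
                 bias_init: float = 0.0) -> None:
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_glorot_uniform(rng, (out_dim, in_dim),
                                                in_dim, out_dim, dtype))
        self.bias = Parameter(np.full(out_dim, bias_init, dtype=dtype))
        self._x: np.ndarray | None = None

    def params(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if not self.skip_param_grad:
            self.weight.grad += gy.T @ self._x
            self.bias.grad += gy.sum(axis=0)
        return gy @ self.weight.value


class BatchNorm(Layer):
    """Batch normalisation over the batch (and spatial axes for volumes).

    Works on both ``(N, F)`` and ``(N, C, D, H, W)`` inputs; statistics are
    per feature / per channel. Running statistics are used in eval mode.
    """

    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5, dtype=np.float32) -> None:
        self.gamma = Parameter(np.ones(num_features, dtype=dtype))
        self.beta = Parameter(np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    @staticmethod
    def _axes(x: np.ndarray) -> tuple[int, ...]:
        return (0,) if x.ndim == 2 else (0, 2, 3, 4)

    def _shape(self, x: np.ndarray) -> tuple[int, ...]:
        return (1, -1) if x.ndim == 2 else (1, -1, 1, 1, 1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes, shp = self._axes(x), self._shape(x)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shp)) * inv.reshape(shp)
        if self.training:
            m = x.size // x.shape[1] if x.ndim == 5 else x.shape[0]
            self._cache = (xhat, inv, m)
        return self.gamma.value.reshape(shp) * xhat + self.beta.value.reshape(shp)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv, m = self._cache
        axes, shp = self._axes(gy), self._shape(gy)
        self.gamma.grad += (gy * xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        g = gy * self.gamma.value.reshape(shp)
        gx = (g - g.mean(axis=axes).reshape(shp)
              - xhat * (g * xhat).mean(axis=axes).reshape(shp)) * inv.reshape(shp)
        return gx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            self._mask = x > 0
        else:
            self._mask = None
        return np.maximum(x, 0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class BoundedReLU(Layer):
    """min(1, max(0, x)): keeps reconstructions in the normalised field range.

    The true gradient is zero outside (0, 1), which permanently kills units
    once the whole (sparse) output saturates at 0. The backward pass therefore
    uses the interior gradient plus a straight-through escape at the
    boundaries: a saturated unit receives the gradient only when it would pull
    it back into the active range. Identical to the exact gradient everywhere
    in (0, 1) and at any boundary the optimiser is not trying to leave.
    """

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            self._x = x
        return np.clip(x, 0.0, 1.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        interior = (x > 0) & (x < 1)
        rescue_low = (x <= 0) & (gy < 0)   # loss wants the output larger
        rescue_high = (x >= 1) & (gy > 0)  # loss wants the output smaller
        return gy * (interior | rescue_low | rescue_high)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: Sequence[int]) -> None:
        self.shape = tuple(shape)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy.reshape(self._in_shape)


class MaskLayer(Layer):
    """Multiply by a fixed binary cortical mask.

    Also the attachment point for the l1 activity penalty: the penalty acts on
    the layer's *input* (the pre-mask reconstruction), so ``l1_value`` after a
    forward pass and the extra ``backward`` term implement
    ``l1_weight * sum|pre-mask output|``.
    """

    def __init__(self, mask: np.ndarray, l1_weight: float = 0.0) -> None:
        self.mask = mask.astype(np.float32)
        self.l1_weight = float(l1_weight)
        self.l1_value = 0.0
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            self._x = x
        self.l1_value = float(self.l1_weight * np.abs(x).sum()) if self.l1_weight else 0.0
        return x * self.mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = gy * self.mask
        if self.l1_weight:
            g = g + self.l1_weight * np.sign(self._x)
        return g


class VariationalSampler(Layer):
    """Gaussian latent bottleneck: h -> (mu, logvar) -> z -> projection.

    Forward: ``mu = W_mu h``, ``logvar = W_lv h``, ``z = mu + exp(logvar/2) * eps``
    with ``eps ~ N(0, I)`` in sampling mode and ``z = mu`` in mean mode, then a
    linear projection of ``z`` back to ``out_dim`` (so the decoder sees the same
    shape whichever path produced the code).

    The KL divergence to the standard-normal prior,
    ``mean_batch( 0.5 * sum_n [exp(lv) + mu^2 - 1 - lv] )``,
    is computed each forward pass (``kl_value``) and its gradient is injected
    during ``backward`` so a plain MSE backward pass trains the full objective.
    """

    def __init__(self, in_dim: int, latent_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        rng = rng or np.random.default_rng()
        self.latent_dim = latent_dim
        self.mu_layer = Linear(in_dim, latent_dim, rng=rng, dtype=dtype)
        # negative logvar bias: start with small sampling noise so the decoder
        # does not learn to ignore the latent before mu carries signal
        self.lv_layer = Linear(in_dim, latent_dim, rng=rng, dtype=dtype,
                               bias_init=-5.0)
        self.proj = Linear(latent_dim, out_dim, rng=rng, dtype=dtype)
        self.sample = True          # draw eps (training) vs use the mean (inference)
        self.kl_enabled = True      # whether backward injects the KL gradient
        self.kl_weight = 1.0        # multiplier on the KL term and its gradient
        self.rng = rng
        self.kl_value = 0.0
        self.last_mu: np.ndarray | None = None
        self.last_logvar: np.ndarray | None = None
        self._eps: np.ndarray | None = None

    def params(self) -> list[Parameter]:
        return self.mu_layer.params() + self.lv_layer.params() + self.proj.params()

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for sub in (self.mu_layer, self.lv_layer, self.proj):
            sub.set_training(flag)

    def set_skip_param_grad(self, flag: bool) -> None:
        self.skip_param_grad = flag
        for sub in (self.mu_layer, self.lv_layer, self.proj):
            sub.set_skip_param_grad(flag)

    #: clamp on logvar; exp() overflows float32 far earlier than this helps
    LOGVAR_CLAMP = 10.0

    def forward(self, h: np.ndarray) -> np.ndarray:
        mu = self.mu_layer.forward(h)
        lv_raw = self.lv_layer.forward(h)
        self._lv_mask = np.abs(lv_raw) < self.LOGVAR_CLAMP
        lv = np.clip(lv_raw, -self.LOGVAR_CLAMP, self.LOGVAR_CLAMP)
        self.last_mu, self.last_logvar = mu, lv
        n = h.shape[0]
        self.kl_value = self.kl_weight * float(
            0.5 * np.sum(np.exp(lv) + mu ** 2 - 1.0 - lv) / n)
        if self.sample:
            eps = self.rng.standard_normal(mu.shape).astype(mu.dtype)
        else:
            eps = np.zeros_like(mu)
        self._eps = eps
        z = mu + np.exp(0.5 * lv) * eps
        return self.proj.forward(z)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gz = self.proj.backward(gy)
        mu, lv, eps = self.last_mu, self.last_logvar, self._eps
        n = mu.shape[0]
        gmu = gz.copy()
        glv = gz * 0.5 * np.exp(0.5 * lv) * eps
        if self.kl_enabled:
            gmu += self.kl_weight * mu / n
            glv += self.kl_weight * (np.exp(lv) - 1.0) / (2.0 * n)
        glv *= self._lv_mask
        return self.mu_layer.backward(gmu) + self.lv_layer.backward(glv)


class Sequential(Layer):
    def __init__(self, layers: Iterable[Layer]) -> None:
        self.layers = list(layers)

    def params(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.params()]

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for layer in self.layers:
            layer.set_training(flag)

    def set_skip_param_grad(self, flag: bool) -> None:
        self.skip_param_grad = flag
        for layer in self.layers:
            layer.set_skip_param_grad(flag)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def kl_total(self) -> float:
        """Sum of KL terms over any variational sampler layers (post-forward)."""
        return sum(l.kl_value for l in self.layers if isinstance(l, VariationalSampler))

    def l1_total(self) -> float:
        return sum(l.l1_value for l in self.layers if isinstance(l, MaskLayer))


class Adadelta:
    """Adadelta with the learning-rate multiplier used by common frameworks.

    update: ``x += lr * delta`` where ``delta`` follows Zeiler's accumulators
    (decay ``rho``, stabiliser ``eps``).
    """

    def __init__(self, params: Sequence[Parameter], lr: float = 1.0,
                 rho: float = 0.95, eps: float = 1e-6) -> None:
        self.params = list(params)
        self.lr, self.rho, self.eps = lr, rho, eps
        self._eg2 = [np.zeros_like(p.value) for p in self.params]
        self._ed2 = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        rho, eps = self.rho, self.eps
        for p, eg2, ed2 in zip(self.params, self._eg2, self._ed2):
            g = p.grad
            eg2 *= rho
            eg2 += (1 - rho) * g * g
            delta = -np.sqrt((ed2 + eps) / (eg2 + eps)) * g
            ed2 *= rho
            ed2 += (1 - rho) * delta * delta
            p.value += self.lr * delta


def parameter_checksum(params: Sequence[Parameter]) -> str:
    """SHA-256 over the raw bytes of all parameter values (freeze audits)."""
    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p.value).tobytes())
    return h.hexdigest()
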