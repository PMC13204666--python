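"""Layers with explicit forward/backward passes.

Conventions
-----------
* Convolutional tensors are ``(batch, channels, length)``; recurrent tensors
  are ``(batch, time, features)``.
* ``forward(x, training)`` caches whatever ``backward`` needs only when
  ``training`` is true; ``backward(dout)`` returns the gradient w.r.t. the
  layer input and accumulates parameter gradients in ``Param.grad``.
* Default dtype is float32 for speed; pass ``dtype=np.float64`` for
  gradient checking.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.special import expit as _sigmoid

from ..exceptions import ConfigurationError


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class Conv1d(Layer):
    """Length-preserving 1-D convolution (odd kernel, symmetric zero padding)."""

    def __init__(self, in_channels, out_channels, kernel_size=3,
                 rng: Optional[np.random.Generator] = None, dtype=np.float32):
        if kernel_size % 2 != 1:
            raise ConfigurationError("kernel_size must be odd to preserve length")
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size
        std = np.sqrt(2.0 / fan_in)  # He init (ReLU follows)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.pad = (kernel_size - 1) // 2
        self.W = Param("conv.W", (rng.standard_normal((out_channels, fan_in)) * std).astype(dtype))
        self.b = Param("conv.b", np.zeros(out_channels, dtype=dtype))
        self._cache = None

    def forward(self, x, training=False):
        B, C, L = x.shape
        if C != self.in_channels:
            raise ConfigurationError(
                f"expected {self.in_channels} input channels, got {C}")
        xpad = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        win = np.lib.stride_tricks.sliding_window_view(xpad, self.kernel_size, axis=2)
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B * L, -1)
        out = cols @ self.W.value.T + self.b.value
        if training:
            self._cache = (cols, (B, C, L))
        return out.reshape(B, L, self.out_channels).transpose(0, 2, 1)

    def backward(self, dout):
        cols, (B, C, L) = self._cache
        g = np.ascontiguousarray(dout.transpose(0, 2, 1)).reshape(B * L, -1)
        self.W.grad += g.T @ cols
        self.b.grad += g.sum(axis=0)
        dcols = (g @ self.W.value).reshape(B, L, C, self.kernel_size)
        dcols = dcols.transpose(0, 2, 1, 3)  # (B, C, L, k)
        dxpad = np.zeros((B, C, L + 2 * self.pad), dtype=dout.dtype)
        for j in range(self.kernel_size):
            dxpad[:, :, j:j + L] += dcols[:, :, :, j]
        self._cache = None
        return dxpad[:, :, self.pad:self.pad + L]

    def params(self):
        return [self.W, self.b]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over batch and time axes."""

    def __init__(self, channels, momentum=0.1, eps=1e-5, dtype=np.float32):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param("bn.gamma", np.ones(channels, dtype=dtype))
        self.beta = Param("bn.beta", np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(x.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) / std[None, :, None]
        if training:
            self._cache = (xhat, std)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, dout):
        xhat, std = self._cache
        m = dout.shape[0] * dout.shape[2]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2))
        self.beta.grad += dout.sum(axis=(0, 2))
        dxhat = dout * self.gamma.value[None, :, None]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        dx = (dxhat - s1 / m - xhat * s2 / m) / std[None, :, None]
        self._cache = None
        return dx

    def params(self):
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x, training=False):
        out = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dout):
        return dout * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling; temporal length halves (floor) at stride 2."""

    def __init__(self, kernel_size=2, stride=None):
        if stride is not None and stride != kernel_size:
            raise ConfigurationError("only stride == kernel_size is supported")
        self.k = kernel_size

    def forward(self, x, training=False):
        B, C, L = x.shape
        Lo = L // self.k
        xr = x[:, :, :Lo * self.k].reshape(B, C, Lo, self.k)
        if training:
            self._idx = xr.argmax(axis=-1)
            self._in_shape = (B, C, L)
        return xr.max(axis=-1)

    def backward(self, dout):
        B, C, L = self._in_shape
        Lo = dout.shape[-1]
        dxr = np.zeros((B, C, Lo, self.k), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros((B, C, L), dtype=dout.dtype)
        dx[:, :, :Lo * self.k] = dxr.reshape(B, C, Lo * self.k)
        return dx


class Linear(Layer):
    def __init__(self, in_features, out_features, init="he",
                 rng: Optional[np.random.Generator] = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        std = np.sqrt((2.0 if init == "he" else 1.0) / in_features)
        self.in_features = in_features
        self.W = Param("linear.W",
                       (rng.standard_normal((out_features, in_features)) * std).astype(dtype))
        self.b = Param("linear.b", np.zeros(out_features, dtype=dtype))

    def forward(self, x, training=False):
        if x.shape[1] != self.in_features:
            raise ConfigurationError(
                f"expected input width {self.in_features}, got {x.shape[1]}")
        if training:
            self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dout):
        self.W.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        dx = dout @ self.W.value
        self._x = None
        return dx

    def params(self):
        return [self.W, self.b]


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: Optional[np.random.Generator] = None):
        if not 0 <= p < 1:
            raise ConfigurationError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x, training=False):
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(x.dtype)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask.astype(dout.dtype)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Transpose(Layer):
    """(batch, channels, time) <-> (batch, time, channels)."""

    def forward(self, x, training=False):
        return np.ascontiguousarray(x.transpose(0, 2, 1))

    def backward(self, dout):
        return np.ascontiguousarray(dout.transpose(0, 2, 1))


class Softmax(Layer):
    """Row-wise softmax over the last axis."""

    def forward(self, x, training=False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        self._p = p
        return p

    def backward(self, dout):
        p = self._p
        return p * (dout - (dout * p).sum(axis=-1, keepdims=True))


class BiLSTM(Layer):
    """Stacked bidirectional LSTM over (batch, time, features) sequences.

    Each layer runs a forward-time and a backward-time LSTM with zero
    initial hidden and cell states and concatenates the per-step hidden
    states, so the output width is ``2 * hidden_size`` and the sequence
    length is preserved. Gates are ordered (input, forget, output, cell)
    internally so sigmoid/tanh each apply to one contiguous block; forget
    gate biases start at 1.
    """

    def __init__(self, input_size, hidden_size, num_layers=1,
                 rng: Optional[np.random.Generator] = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        self._params: list[dict[str, tuple[Param, Param, Param]]] = []
        H = hidden_size
        s = 1.0 / np.sqrt(H)
        for layer in range(num_layers):
            D = input_size if layer == 0 else 2 * H
            entry = {}
            for direction in ("f", "b"):
                Wx = (rng.uniform(-s, s, (D, 4 * H))).astype(dtype)
                Wh = (rng.uniform(-s, s, (H, 4 * H))).astype(dtype)
                bias = np.zeros(4 * H, dtype=dtype)
                bias[H:2 * H] = 1.0  # forget gate
                entry[direction] = (
                    Param(f"lstm{layer}.{direction}.Wx", Wx),
                    Param(f"lstm{layer}.{direction}.Wh", Wh),
                    Param(f"lstm{layer}.{direction}.b", bias),
                )
            self._params.append(entry)
        self._caches = None

    def params(self):
        out = []
        for entry in self._params:
            for direction in ("f", "b"):
                out.extend(entry[direction])
        return out

    def _run_direction(self, x, Wx, Wh, b, reverse, training):
        B, T, D = x.shape
        H = self.hidden_size
        xr = x[:, ::-1] if reverse else x
        Xp = xr.reshape(B * T, D) @ Wx.value + b.value
        Xp = Xp.reshape(B, T, 4 * H)
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        outs = np.empty((B, T, H), dtype=x.dtype)
        cache = {
            "gates": np.empty((B, T, 4 * H), dtype=x.dtype),
            "c_prev": np.empty((B, T, H), dtype=x.dtype),
            "h_prev": np.empty((B, T, H), dtype=x.dtype),
            "tc": np.empty((B, T, H), dtype=x.dtype),
        } if training else None
        Whv = Wh.value
        for t in range(T):
            a = Xp[:, t] + h @ Whv
            sig = _sigmoid(a[:, :3 * H])
            i, f, o = sig[:, :H], sig[:, H:2 * H], sig[:, 2 * H:]
            g = np.tanh(a[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            if training:
                cache["gates"][:, t, :H] = i
                cache["gates"][:, t, H:2 * H] = f
                cache["gates"][:, t, 2 * H:3 * H] = o
                cache["gates"][:, t, 3 * H:] = g
                cache["c_prev"][:, t] = c
                cache["h_prev"][:, t] = h
                cache["tc"][:, t] = tc
            c = c_new
            h = o * tc
            outs[:, t] = h
        if training:
            cache["xr"] = xr
        out = outs[:, ::-1] if reverse else outs
        return out, cache

    def _backward_direction(self, dh_out, params, cache, reverse):
        Wx, Wh, b = params
        xr = cache["xr"]
        B, T, D = xr.shape
        H = self.hidden_size
        dh_r = dh_out[:, ::-1] if reverse else dh_out
        gates, c_prev_all = cache["gates"], cache["c_prev"]
        tc_all, h_prev_all = cache["tc"], cache["h_prev"]
        dA = np.empty((B, T, 4 * H), dtype=dh_out.dtype)
        dh_next = np.zeros((B, H), dtype=dh_out.dtype)
        dc_next = np.zeros((B, H), dtype=dh_out.dtype)
        WhT = Wh.value.T
        for t in range(T - 1, -1, -1):
            g4 = gates[:, t]
            i, f, o, g = g4[:, :H], g4[:, H:2 * H], g4[:, 2 * H:3 * H], g4[:, 3 * H:]
            tc = tc_all[:, t]
            dh = dh_r[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc * tc) + dc_next
            dc_next = dc * f
            da = dA[:, t]
            da[:, :H] = dc * g * i * (1 - i)
            da[:, H:2 * H] = dc * c_prev_all[:, t] * f * (1 - f)
            da[:, 2 * H:3 * H] = do * o * (1 - o)
            da[:, 3 * H:] = dc * i * (1 - g * g)
            dh_next = da @ WhT
        dA2 = dA.reshape(B * T, 4 * H)
        Wx.grad += xr.reshape(B * T, D).T @ dA2
        Wh.grad += h_prev_all.reshape(B * T, H).T @ dA2
        b.grad += dA2.sum(axis=0)
        dxr = (dA2 @ Wx.value.T).reshape(B, T, D)
        return dxr[:, ::-1] if reverse else dxr

    def forward(self, x, training=False):
        if x.shape[2] != self.input_size:
            raise ConfigurationError(
                f"expected input width {self.input_size}, got {x.shape[2]}")
        caches = []
        for layer, entry in enumerate(self._params):
            out_f, cache_f = self._run_direction(x, *entry["f"], reverse=False,
                                                 training=training)
            out_b, cache_b = self._run_direction(x, *entry["b"], reverse=True,
                                                 training=training)
            x = np.concatenate([out_f, out_b], axis=-1)
            caches.append((cache_f, cache_b))
        if training:
            self._caches = caches
        return x

    def backward(self, dout):
        H = self.hidden_size
        for layer in range(self.num_layers - 1, -1, -1):
            entry = self._params[layer]
            cache_f, cache_b = self._caches[layer]
            dx_f = self._backward_direction(dout[:, :, :H], entry["f"], cache_f, False)
            dx_b = self._backward_direction(dout[:, :, H:], entry["b"], cache_b, True)
            dout = dx_f + dx_b
        self._caches = None
        return dout
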