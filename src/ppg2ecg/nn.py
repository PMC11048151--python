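"""Minimal 1-D neural-network layers with explicit backpropagation.

NumPy-only building blocks for the W-shaped reconstruction networks:
strided 1-D convolution and transposed convolution (the down/up paths),
batch normalisation, ReLU/Tanh, dropout, a bidirectional LSTM, and the
Adam optimiser.  Every layer implements ``forward`` and ``backward``
explicitly; convolutions are lowered to a single large GEMM per layer so
training is practical on one CPU core.

Tensors are ``(batch, channels, length)`` float32 throughout; gradient
correctness of every layer is checked against central finite differences
in the test suite.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

DTYPE = np.float32

__all__ = [
    "Parameter",
    "Module",
    "Conv1d",
    "ConvTranspose1d",
    "BatchNorm1d",
    "ReLU",
    "Tanh",
    "Dropout",
    "ConstantPad1d",
    "Crop1d",
    "Upsample1d",
    "Sequential",
    "BiLSTM",
    "Adam",
]


class Parameter:
    """A trainable array and its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "param"):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: explicit forward/backward, flat parameter listing."""

    training: bool = True

    def parameters(self) -> List[Parameter]:
        out: List[Parameter] = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for v in vars(self).values():
            if isinstance(v, Module):
                v.set_training(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.set_training(mode)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def state_dict(self) -> List[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state does not match model parameters")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError(f"shape mismatch for {p.name}: {p.data.shape} vs {s.shape}")
            p.data[...] = s

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _im2col(xp: np.ndarray, k: int, stride: int, l_out: int) -> np.ndarray:
    """(B, C, Lp) -> (B, C, k, l_out) patch view assembled by strided slices."""
    b, c, _ = xp.shape
    cols = np.empty((b, c, k, l_out), dtype=xp.dtype)
    for j in range(k):
        cols[:, :, j, :] = xp[:, :, j : j + stride * l_out : stride]
    return cols


class Conv1d(Module):
    """Strided 1-D convolution (cross-correlation), kernel 4 / stride 2 default."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 4,
        stride: int = 2,
        padding: int = 1,
        rng: Optional[np.random.Generator] = None,
        name: str = "conv",
    ):
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, size=(out_channels, in_channels, kernel_size)),
            f"{name}.weight",
        )
        self.bias = Parameter(np.zeros(out_channels), f"{name}.bias")
        self._cache: tuple = ()

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, l = x.shape
        p, k, s = self.padding, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        l_out = (l + 2 * p - k) // s + 1
        cols = _im2col(xp, k, s, l_out).reshape(b, c * k, l_out)
        w2 = self.weight.data.reshape(self.out_channels, c * k)
        y = np.matmul(w2, cols) + self.bias.data[None, :, None]
        self._cache = (cols, xp.shape, l)
        return y

    def backward(self, gout: np.ndarray) -> np.ndarray:
        cols, xp_shape, l = self._cache
        b, ck, l_out = cols.shape
        p, k, s = self.padding, self.k, self.stride
        co = self.out_channels
        g2 = np.ascontiguousarray(gout.transpose(1, 0, 2)).reshape(co, b * l_out)
        c2 = np.ascontiguousarray(cols.transpose(1, 0, 2)).reshape(ck, b * l_out)
        self.weight.grad += (g2 @ c2.T).reshape(self.weight.data.shape)
        self.bias.grad += gout.sum(axis=(0, 2))
        w2 = self.weight.data.reshape(co, ck)
        dcols = np.matmul(w2.T, gout).reshape(b, self.in_channels, k, l_out)
        dxp = np.zeros(xp_shape, dtype=DTYPE)
        for j in range(k):
            dxp[:, :, j : j + s * l_out : s] += dcols[:, :, j, :]
        return dxp[:, :, p : p + l] if p else dxp


class ConvTranspose1d(Module):
    """Strided 1-D transposed convolution (the learned upsampling path)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 4,
        stride: int = 2,
        padding: int = 1,
        rng: Optional[np.random.Generator] = None,
        name: str = "tconv",
    ):
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size // stride
        std = np.sqrt(2.0 / max(fan_in, 1))
        self.weight = Parameter(
            rng.normal(0.0, std, size=(in_channels, out_channels, kernel_size)),
            f"{name}.weight",
        )
        self.bias = Parameter(np.zeros(out_channels), f"{name}.bias")
        self._cache: tuple = ()

    def out_length(self, l: int) -> int:
        return (l - 1) * self.stride - 2 * self.padding + self.k

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, l = x.shape
        k, s, p = self.k, self.stride, self.padding
        co = self.out_channels
        w2 = self.weight.data.reshape(c, co * k)
        patches = np.matmul(w2.T, x).reshape(b, co, k, l)
        l_full = (l - 1) * s + k
        y_full = np.zeros((b, co, l_full), dtype=DTYPE)
        for j in range(k):
            y_full[:, :, j : j + s * l : s] += patches[:, :, j, :]
        y = y_full[:, :, p : p + self.out_length(l)] if p else y_full
        self._cache = (x, l)
        return y + self.bias.data[None, :, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x, l = self._cache
        b, c, _ = x.shape
        k, s, p = self.k, self.stride, self.padding
        co = self.out_channels
        l_full = (l - 1) * s + k
        g_full = np.zeros((b, co, l_full), dtype=DTYPE)
        g_full[:, :, p : p + gout.shape[2]] = gout
        dpatches = np.empty((b, co, k, l), dtype=DTYPE)
        for j in range(k):
            dpatches[:, :, j, :] = g_full[:, :, j : j + s * l : s]
        dp2 = np.ascontiguousarray(dpatches.reshape(b, co * k, l).transpose(1, 0, 2)).reshape(
            co * k, b * l
        )
        x2 = np.ascontiguousarray(x.transpose(1, 0, 2)).reshape(c, b * l)
        self.weight.grad += (x2 @ dp2.T).reshape(self.weight.data.shape)
        self.bias.grad += gout.sum(axis=(0, 2))
        w2 = self.weight.data.reshape(c, co * k)
        dx = np.matmul(w2, dpatches.reshape(b, co * k, l))
        return dx


class BatchNorm1d(Module):
    """Per-channel batch normalisation over (batch, length)."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn"):
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(num_features), f"{name}.gamma")
        self.beta = Parameter(np.zeros(num_features), f"{name}.beta")
        self.running_mean = np.zeros(num_features, dtype=DTYPE)
        self.running_var = np.ones(num_features, dtype=DTYPE)
        self._cache: tuple = ()

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(DTYPE)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * invstd[None, :, None]
        self._cache = (xhat, invstd)
        return self.gamma.data[None, :, None] * xhat + self.beta.data[None, :, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        b, c, l = gout.shape
        n = b * l
        self.gamma.grad += (gout * xhat).sum(axis=(0, 2))
        self.beta.grad += gout.sum(axis=(0, 2))
        if not self.training:
            return gout * (self.gamma.data * invstd)[None, :, None]
        gx_sum = (gout * xhat).sum(axis=(0, 2))[None, :, None]
        gsum = gout.sum(axis=(0, 2))[None, :, None]
        coef = (self.gamma.data * invstd)[None, :, None] / n
        return coef * (n * gout - gsum - xhat * gx_sum)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE, copy=False)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class Tanh(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * (1.0 - self._y**2)


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float = 0.5, rng: Optional[np.random.Generator] = None):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gout
        return gout * self._mask


class ConstantPad1d(Module):
    """Pad the length axis with a constant (houses the 375 -> 384 entry pad)."""

    def __init__(self, left: int, right: int, value: float = 0.0):
        self.left, self.right, self.value = left, right, value

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.pad(
            x, ((0, 0), (0, 0), (self.left, self.right)), constant_values=self.value
        ).astype(DTYPE, copy=False)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        end = gout.shape[2] - self.right
        return gout[:, :, self.left : end]


class Crop1d(Module):
    """Inverse of the entry pad: crop the length axis back (384 -> 375)."""

    def __init__(self, left: int, right: int):
        self.left, self.right = left, right

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._len = x.shape[2]
        end = self._len - self.right
        return x[:, :, self.left : end]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        out = np.zeros(gout.shape[:2] + (self._len,), dtype=DTYPE)
        out[:, :, self.left : self._len - self.right] = gout
        return out


class Upsample1d(Module):
    """Nearest-neighbour upsampling by an integer factor along the length axis."""

    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(x, self.factor, axis=2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        b, c, l = gout.shape
        return gout.reshape(b, c, l // self.factor, self.factor).sum(axis=3)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout


class _LSTMDirection(Module):
    """One LSTM direction with full BPTT (gates ordered i, f, g, o)."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator, name: str):
        self.input_size = input_size
        self.hidden_size = hidden_size
        bound = 1.0 / np.sqrt(hidden_size)
        self.w_x = Parameter(
            rng.uniform(-bound, bound, size=(input_size, 4 * hidden_size)), f"{name}.w_x"
        )
        self.w_h = Parameter(
            rng.uniform(-bound, bound, size=(hidden_size, 4 * hidden_size)), f"{name}.w_h"
        )
        b = np.zeros(4 * hidden_size)
        b[hidden_size : 2 * hidden_size] = 1.0  # forget-gate bias
        self.bias = Parameter(b, f"{name}.bias")
        self._cache: tuple = ()

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (B, T, I) -> h: (B, T, H)
        b, t, _ = x.shape
        hsz = self.hidden_size
        h = np.zeros((b, hsz), dtype=DTYPE)
        c = np.zeros((b, hsz), dtype=DTYPE)
        hs = np.empty((b, t, hsz), dtype=DTYPE)
        caches = []
        xw = np.matmul(x, self.w_x.data)  # (B, T, 4H)
        for step in range(t):
            z = xw[:, step] + h @ self.w_h.data + self.bias.data
            i = 1.0 / (1.0 + np.exp(-z[:, :hsz]))
            f = 1.0 / (1.0 + np.exp(-z[:, hsz : 2 * hsz]))
            g = np.tanh(z[:, 2 * hsz : 3 * hsz])
            o = 1.0 / (1.0 + np.exp(-z[:, 3 * hsz :]))
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            hs[:, step] = h
            caches.append((i, f, g, o, c_prev, tc, h_prev))
        self._cache = (x, caches)
        return hs

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x, caches = self._cache
        b, t, _ = x.shape
        hsz = self.hidden_size
        dx = np.zeros_like(x)
        dh_next = np.zeros((b, hsz), dtype=DTYPE)
        dc_next = np.zeros((b, hsz), dtype=DTYPE)
        dwx = np.zeros_like(self.w_x.data)
        dwh = np.zeros_like(self.w_h.data)
        db = np.zeros_like(self.bias.data)
        for step in range(t - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = caches[step]
            dh = gout[:, step] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            ).astype(DTYPE, copy=False)
            dwx += x[:, step].T @ dz
            dwh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, step] = dz @ self.w_x.data.T
            dh_next = dz @ self.w_h.data.T
        self.w_x.grad += dwx
        self.w_h.grad += dwh
        self.bias.grad += db
        return dx


class BiLSTM(Module):
    """Bidirectional LSTM over the length axis of a (B, C, T) tensor.

    Hidden size per direction defaults to C/2 so the concatenated output has
    the same channel count as the input and drops into the bottleneck of an
    encoder-decoder without any adapter layer.
    """

    def __init__(
        self,
        channels: int,
        hidden_size: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
        name: str = "bilstm",
    ):
        rng = rng or np.random.default_rng(0)
        if hidden_size is None:
            if channels % 2:
                raise ValueError("channels must be even to infer hidden size")
            hidden_size = channels // 2
        self.hidden_size = hidden_size
        self.fwd = _LSTMDirection(channels, hidden_size, rng, f"{name}.fwd")
        self.bwd = _LSTMDirection(channels, hidden_size, rng, f"{name}.bwd")

    def forward(self, x: np.ndarray) -> np.ndarray:
        seq = np.ascontiguousarray(x.transpose(0, 2, 1))  # (B, T, C)
        hf = self.fwd.forward(seq)
        hb = self.bwd.forward(seq[:, ::-1])[:, ::-1]
        out = np.concatenate([hf, hb], axis=2)
        return np.ascontiguousarray(out.transpose(0, 2, 1))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = np.ascontiguousarray(gout.transpose(0, 2, 1))  # (B, T, 2H)
        hsz = self.hidden_size
        dseq = self.fwd.backward(np.ascontiguousarray(g[:, :, :hsz]))
        dseq = dseq + self.bwd.backward(np.ascontiguousarray(g[:, ::-1, hsz:]))[:, ::-1]
        return np.ascontiguousarray(dseq.transpose(0, 2, 1))


class Adam:
    """Adam with a mutable learning rate (for step-decay schedules)."""

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 1e-3,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
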