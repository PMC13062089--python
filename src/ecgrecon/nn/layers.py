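"""Neural-network building blocks (dense, conv, LSTM, layer norm) and Adam.

Parameters are plain :class:`~ecgrecon.nn.tensor.Tensor` objects with
``requires_grad=True``; modules expose them through :meth:`Module.parameters`
for the optimizer and for flat serialization to ``.npz`` checkpoints.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concatenate, conv1d, conv_transpose1d

__all__ = [
    "Module", "Dense", "Conv1d", "ConvTranspose1d", "GatedConv1d",
    "LayerNorm", "GLU", "LSTM", "Adam", "sinusoidal_encoding",
]


class Module:
    """Base class: collects parameters from attributes, recursively."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for obj in self.__dict__.values():
            for p in _collect(obj):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def named_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for i, p in enumerate(params):
            a = arrays[f"p{i}"]
            if a.shape != p.data.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = np.asarray(a, dtype=np.float64)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _collect(obj):
    if isinstance(obj, Tensor):
        if obj.requires_grad:
            yield obj
    elif isinstance(obj, Module):
        yield from obj.parameters()
    elif isinstance(obj, (list, tuple)):
        for item in obj:
            yield from _collect(item)
    elif isinstance(obj, dict):
        for item in obj.values():
            yield from _collect(item)


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        self.w = _glorot(rng, (d_in, d_out), d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w
        if self.b is not None:
            y = y + self.b
        return y


class Conv1d(Module):
    """(N, C_in, T) -> (N, C_out, T_out) with 'same'-style padding by default."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None):
        self.stride = stride
        self.pad = (k - 1) // 2 if pad is None else pad
        self.w = _glorot(rng, (c_out, c_in, k), c_in * k, c_out * k)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        y = conv1d(x, self.w, stride=self.stride, pad=self.pad)
        return y + self.b.reshape(1, -1, 1)


class ConvTranspose1d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None, output_padding: int = 0):
        self.stride = stride
        self.pad = (k - 1) // 2 if pad is None else pad
        self.output_padding = output_padding
        self.w = _glorot(rng, (c_in, c_out, k), c_in * k, c_out * k)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        y = conv_transpose1d(x, self.w, stride=self.stride, pad=self.pad,
                             output_padding=self.output_padding)
        return y + self.b.reshape(1, -1, 1)


class GatedConv1d(Module):
    """GLU-style gated convolution: conv_a(x) * sigmoid(conv_b(x))."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1):
        self.conv_a = Conv1d(c_in, c_out, k, rng, stride=stride)
        self.conv_b = Conv1d(c_in, c_out, k, rng, stride=stride)
        self.force_gate_open = False  # testing hook: gate == 1 -> plain conv

    def __call__(self, x: Tensor) -> Tensor:
        a = self.conv_a(x)
        if self.force_gate_open:
            return a
        return a * self.conv_b(x).sigmoid()


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        norm = (x - mu) * ((var + self.eps) ** -0.5)
        return norm * self.gamma + self.beta


class GLU(Module):
    """Gated linear unit: sigmoid(W4 x + b4) * (W5 x + b5)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.gate = Dense(d_in, d_out, rng)
        self.lin = Dense(d_in, d_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.gate(x).sigmoid() * self.lin(x)


def _lstm_scan(x: Tensor, wx: Tensor, wh: Tensor, b: Tensor,
               d: int) -> Tensor:
    """LSTM over (N, T, d_in) as one primitive with a hand-derived BPTT
    backward pass; avoids building a per-timestep autodiff graph."""
    xd, wxd, whd, bd = x.data, wx.data, wh.data, b.data
    n, t, _ = xd.shape
    pre_x = xd @ wxd + bd                      # (N, T, 4d)
    hs = np.zeros((n, t, d))
    cs = np.zeros((n, t, d))
    gates = np.zeros((n, t, 4 * d))
    h = np.zeros((n, d))
    c = np.zeros((n, d))
    for ti in range(t):
        pre = pre_x[:, ti] + h @ whd
        i = 1.0 / (1.0 + np.exp(-pre[:, :d]))
        f = 1.0 / (1.0 + np.exp(-pre[:, d:2 * d]))
        g = np.tanh(pre[:, 2 * d:3 * d])
        o = 1.0 / (1.0 + np.exp(-pre[:, 3 * d:]))
        c = f * c + i * g
        h = o * np.tanh(c)
        gates[:, ti, :d] = i
        gates[:, ti, d:2 * d] = f
        gates[:, ti, 2 * d:3 * d] = g
        gates[:, ti, 3 * d:] = o
        cs[:, ti] = c
        hs[:, ti] = h

    def bwd(grad):
        dx = np.zeros_like(xd)
        dwx = np.zeros_like(wxd)
        dwh = np.zeros_like(whd)
        db = np.zeros_like(bd)
        dh_next = np.zeros((n, d))
        dc_next = np.zeros((n, d))
        for ti in range(t - 1, -1, -1):
            i = gates[:, ti, :d]
            f = gates[:, ti, d:2 * d]
            g = gates[:, ti, 2 * d:3 * d]
            o = gates[:, ti, 3 * d:]
            c_t = cs[:, ti]
            c_prev = cs[:, ti - 1] if ti > 0 else np.zeros((n, d))
            h_prev = hs[:, ti - 1] if ti > 0 else np.zeros((n, d))
            tanh_c = np.tanh(c_t)
            dh = grad[:, ti] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c ** 2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dpre = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g ** 2), do * o * (1 - o),
            ], axis=1)
            dx[:, ti] = dpre @ wxd.T
            dwx += xd[:, ti].T @ dpre
            dwh += h_prev.T @ dpre
            db += dpre.sum(axis=0)
            dh_next = dpre @ whd.T
        return dx, dwx, dwh, db

    return Tensor._make(hs, (x, wx, wh, b), bwd)


class LSTM(Module):
    """Single-layer LSTM over (N, T, d_in) -> (N, T, d_hidden)."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.d_hidden = d_hidden
        self.wx = _glorot(rng, (d_in, 4 * d_hidden), d_in, 4 * d_hidden)
        self.wh = _glorot(rng, (d_hidden, 4 * d_hidden), d_hidden, 4 * d_hidden)
        b = np.zeros(4 * d_hidden)
        b[d_hidden:2 * d_hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor, reverse: bool = False) -> Tensor:
        if reverse:
            flipped = x[:, ::-1, :]
            out = _lstm_scan(flipped, self.wx, self.wh, self.b, self.d_hidden)
            return out[:, ::-1, :]
        return _lstm_scan(x, self.wx, self.wh, self.b, self.d_hidden)


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def sinusoidal_encoding(t_len: int, d_model: int) -> np.ndarray:
    """Standard additive sinusoidal positional encoding, shape (t_len, d_model)."""
    pos = np.arange(t_len)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc
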