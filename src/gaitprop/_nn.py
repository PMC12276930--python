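"""Minimal neural-network engine (numpy, float32) with reverse-mode gradients.

Implements exactly the layer inventory the propulsion estimators need —
dense layers, 2-D convolution, average pooling, ReLU, stacked bidirectional
LSTMs — plus the Adam optimizer and the mean-squared-error loss.  Gradients
are hand-derived and verified against central finite differences in the test
suite.  Everything runs in float32 on a single CPU core and is deterministic
given the seed used at initialization and the order of optimizer steps.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    # plain logistic; float32 exp overflow saturates harmlessly to 0
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.ascontiguousarray(data, dtype=F32)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


def _uniform(rng: np.random.Generator, shape, bound: float) -> np.ndarray:
    return rng.uniform(-bound, bound, size=shape).astype(F32)


class Layer:
    needs_input_grad = True  # first layers of a branch may switch this off

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Linear(Layer):
    """y = x W + b, fan-in uniform init (U(-1/sqrt(n_in), 1/sqrt(n_in)))."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = "linear"):
        bound = 1.0 / np.sqrt(n_in)
        self.W = Param(_uniform(rng, (n_in, n_out), bound), f"{name}.W")
        self.b = Param(_uniform(rng, (n_out,), bound), f"{name}.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, g):
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.data.T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Conv2d(Layer):
    """Valid (no padding) 2-D convolution via im2col, stride 1."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, name: str = "conv"):
        fan_in = c_in * k * k
        bound = 1.0 / np.sqrt(fan_in)
        self.W = Param(_uniform(rng, (c_out, fan_in), bound), f"{name}.W")
        self.b = Param(_uniform(rng, (c_out,), bound), f"{name}.b")
        self.c_in, self.c_out, self.k = c_in, c_out, k

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        B, C, H, W = x.shape
        k = self.k
        oh, ow = H - k + 1, W - k + 1
        # (B, C, oh, ow, k, k) view -> (B*oh*ow, C*k*k) matrix
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * oh * ow, C * k * k)
        self._cols = np.ascontiguousarray(cols)
        self._xshape = (B, C, H, W)
        out = self._cols @ self.W.data.T + self.b.data
        return out.reshape(B, oh, ow, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, g):
        B, C, H, W = self._xshape
        k = self.k
        oh, ow = H - k + 1, W - k + 1
        g_rs = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * oh * ow, self.c_out)
        self.W.grad += g_rs.T @ self._cols
        self.b.grad += g_rs.sum(axis=0)
        if not self.needs_input_grad:
            return None
        dcols = (g_rs @ self.W.data).reshape(B, oh, ow, C, k, k)
        dcols = np.ascontiguousarray(dcols.transpose(0, 3, 4, 5, 1, 2))  # (B,C,k,k,oh,ow)
        dx = np.zeros(self._xshape, dtype=F32)
        for di in range(k):
            for dj in range(k):
                dx[:, :, di:di + oh, dj:dj + ow] += dcols[:, :, di, dj]
        return dx


class AvgPool2(Layer):
    """2x2 average pooling, stride 2 (spatial dims must be even)."""

    def forward(self, x):
        B, C, H, W = x.shape
        self._shape = x.shape
        return x.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(self, g):
        B, C, H, W = self._shape
        up = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * F32(0.25)
        return up.astype(F32, copy=False)


class LSTM(Layer):
    """Single unidirectional LSTM layer; returns the full output sequence.

    Gate order [i, f, o, g] (sigmoid gates contiguous), initial state zero,
    torch-style uniform init with bound 1/sqrt(hidden).
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator, name: str = "lstm"):
        bound = 1.0 / np.sqrt(hidden)
        self.Wx = Param(_uniform(rng, (n_in, 4 * hidden), bound), f"{name}.Wx")
        self.Wh = Param(_uniform(rng, (hidden, 4 * hidden), bound), f"{name}.Wh")
        self.b = Param(_uniform(rng, (4 * hidden,), bound), f"{name}.b")
        self.n_in, self.hidden = n_in, hidden

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x):
        B, T, _ = x.shape
        H = self.hidden
        self._x = x
        gx = x.reshape(B * T, self.n_in) @ self.Wx.data + self.b.data
        gx = gx.reshape(B, T, 4 * H)
        h = np.zeros((B, H), dtype=F32)
        c = np.zeros((B, H), dtype=F32)
        cache = []
        out = np.empty((B, T, H), dtype=F32)
        for t in range(T):
            a = gx[:, t, :] + h @ self.Wh.data
            s = sigmoid(a[:, :3 * H])
            i, f, o = s[:, :H], s[:, H:2 * H], s[:, 2 * H:]
            gc = np.tanh(a[:, 3 * H:])
            c_prev, h_prev = c, h
            c = f * c_prev + i * gc
            tc = np.tanh(c)
            h = o * tc
            out[:, t, :] = h
            cache.append((i, f, gc, o, c_prev, h_prev, tc))
        self._cache = cache
        return out

    def backward(self, dout):
        B, T, _ = self._x.shape
        H = self.hidden
        dG = np.empty((B, T, 4 * H), dtype=F32)
        dh_next = np.zeros((B, H), dtype=F32)
        dc_next = np.zeros((B, H), dtype=F32)
        WhT = self.Wh.data.T
        for t in range(T - 1, -1, -1):
            i, f, gc, o, c_prev, h_prev, tc = self._cache[t]
            dh = dout[:, t, :] + dh_next
            dc = dh * o * (1.0 - tc * tc) + dc_next
            da = dG[:, t, :]
            da[:, :H] = dc * gc * i * (1.0 - i)
            da[:, H:2 * H] = dc * c_prev * f * (1.0 - f)
            da[:, 2 * H:3 * H] = dh * tc * o * (1.0 - o)
            da[:, 3 * H:] = dc * i * (1.0 - gc * gc)
            dh_next = da @ WhT
            dc_next = dc * f
            self.Wh.grad += h_prev.T @ da
        dG2 = dG.reshape(B * T, 4 * H)
        X2 = self._x.reshape(B * T, self.n_in)
        self.Wx.grad += X2.T @ dG2
        self.b.grad += dG2.sum(axis=0)
        if not self.needs_input_grad:
            return None
        return (dG2 @ self.Wx.data.T).reshape(B, T, self.n_in)


class BiLSTM(Layer):
    """Bidirectional LSTM layer; output concatenates the two directions."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator, name: str = "bilstm"):
        self.fw = LSTM(n_in, hidden, rng, f"{name}.fw")
        self.bw = LSTM(n_in, hidden, rng, f"{name}.bw")
        self.hidden = hidden

    def params(self):
        return self.fw.params() + self.bw.params()

    def forward(self, x):
        out_f = self.fw.forward(x)
        out_b = self.bw.forward(x[:, ::-1, :])[:, ::-1, :]
        return np.concatenate([out_f, out_b], axis=2)

    def backward(self, g):
        H = self.hidden
        self.fw.needs_input_grad = self.bw.needs_input_grad = self.needs_input_grad
        dx_f = self.fw.backward(np.ascontiguousarray(g[:, :, :H]))
        dx_b = self.bw.backward(np.ascontiguousarray(g[:, ::-1, H:]))
        if not self.needs_input_grad:
            return None
        return dx_f + dx_b[:, ::-1, :]


class TakeLast(Layer):
    """Select the output at the final timestep of a sequence."""

    def forward(self, x):
        self._shape = x.shape
        return x[:, -1, :]

    def backward(self, g):
        dx = np.zeros(self._shape, dtype=F32)
        dx[:, -1, :] = g
        return dx


class TakeEnds(Layer):
    """Final state of a bidirectional sequence output.

    Concatenation of the forward direction at the last timestep and the
    backward direction at the first timestep — each direction's hidden state
    after consuming the whole sequence.
    """

    def __init__(self, hidden: int):
        self.hidden = hidden

    def forward(self, x):
        self._shape = x.shape
        H = self.hidden
        return np.concatenate([x[:, -1, :H], x[:, 0, H:]], axis=1)

    def backward(self, g):
        H = self.hidden
        dx = np.zeros(self._shape, dtype=F32)
        dx[:, -1, :H] = g[:, :H]
        dx[:, 0, H:] = g[:, H:]
        return dx


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: list[Param], lr: float = 5e-4, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + F32(self.weight_decay) * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * (g * g)
            p.data -= F32(self.lr) * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. the prediction."""
    diff = (pred - target).astype(F32)
    loss = float(np.mean(diff * diff))
    return loss, (2.0 / diff.size) * diff
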