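"""Minimal feed-forward / recurrent network engine in numpy.

Implements exactly the layers the force-estimation architectures need
(dense, 2-D/1-D convolution, max-pooling, batch normalization, dropout,
LSTM) with hand-derived backward passes and an Adam optimizer.  All layers
are float64 and single-threaded-deterministic given their construction RNG.

Conventions
-----------
* Batch axis first everywhere.
* Dense:   (B, F)
* Conv2D:  (B, C, H, W), stride 1, padding "same" or "valid"
* Conv1D:  (B, C, L), arbitrary stride, "valid" padding
* LSTM:    (B, T, F) -> (B, T, H), full output sequence
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(_glorot(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    """Reshape everything after the batch axis (row-major)."""

    def __init__(self, shape: tuple[int, ...]):
        self.shape = tuple(shape)

    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class BatchNorm(Layer):
    """Batch normalization over the batch (and any spatial) axes.

    Input (B, F) normalizes per feature; (B, C, ...) per channel C.
    """

    def __init__(self, num_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(num_features))
        self.beta = Param(np.zeros(num_features))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def params(self):
        return [self.gamma, self.beta]

    def _axes(self, x):
        # feature axis is 1 for ndim >= 2; reduce over everything else
        return tuple(i for i in range(x.ndim) if i != 1)

    def _bshape(self, x):
        return tuple(-1 if i == 1 else 1 for i in range(x.ndim))

    def forward(self, x, training=False):
        axes = self._axes(x)
        bs = self._bshape(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(bs)) * inv.reshape(bs)
        self._cache = (xhat, inv, axes, bs, training)
        return self.gamma.value.reshape(bs) * xhat + self.beta.value.reshape(bs)

    def backward(self, grad):
        xhat, inv, axes, bs, training = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value.reshape(bs)
        if not training:
            return g * inv.reshape(bs)
        n = np.prod([xhat.shape[i] for i in axes])
        gm = g.sum(axis=axes).reshape(bs)
        gx = (g * xhat).sum(axis=axes).reshape(bs)
        return inv.reshape(bs) * (g - gm / n - xhat * gx / n)


class Conv2D(Layer):
    """2-D convolution (cross-correlation), stride 1."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, padding: str = "same"):
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        fan_in = in_ch * kernel * kernel
        fan_out = out_ch * kernel * kernel
        self.W = Param(_glorot(rng, (out_ch, in_ch, kernel, kernel), fan_in, fan_out))
        self.b = Param(np.zeros(out_ch))
        self.kernel = kernel
        self.padding = padding

    def params(self):
        return [self.W, self.b]

    def _pad(self):
        k = self.kernel
        if self.padding == "same":
            return (k - 1) // 2, k - 1 - (k - 1) // 2
        return 0, 0

    def forward(self, x, training=False):
        k = self.kernel
        p0, p1 = self._pad()
        xp = np.pad(x, ((0, 0), (0, 0), (p0, p1), (p0, p1)))
        self._xp = xp
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # B,C,H',W',k,k
        out = np.einsum("bchwij,ocij->bohw", win, self.W.value, optimize=True)
        return out + self.b.value[None, :, None, None]

    def backward(self, grad):
        k = self.kernel
        win = sliding_window_view(self._xp, (k, k), axis=(2, 3))
        self.W.grad += np.einsum("bchwij,bohw->ocij", win, grad, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2, 3))
        # dx: full correlation of grad with kernel flipped in space
        p0, p1 = self._pad()
        gp = np.pad(grad, ((0, 0), (0, 0), (k - 1 - p0, k - 1 - p1),
                           (k - 1 - p0, k - 1 - p1)))
        Wf = self.W.value[:, :, ::-1, ::-1]
        gwin = sliding_window_view(gp, (k, k), axis=(2, 3))
        return np.einsum("bohwij,ocij->bchw", gwin, Wf, optimize=True)


class MaxPool2D(Layer):
    """Non-overlapping max pooling; trailing rows/cols are cropped."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x, training=False):
        p = self.pool
        B, C, H, W = x.shape
        Ho, Wo = H // p, W // p
        self._in_shape = x.shape
        xc = x[:, :, :Ho * p, :Wo * p].reshape(B, C, Ho, p, Wo, p)
        xc = xc.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho, Wo, p * p)
        self._arg = xc.argmax(axis=-1)
        return xc.max(axis=-1)

    def backward(self, grad):
        p = self.pool
        B, C, H, W = self._in_shape
        Ho, Wo = H // p, W // p
        dx = np.zeros((B, C, Ho, Wo, p * p))
        np.put_along_axis(dx, self._arg[..., None], grad[..., None], axis=-1)
        dx = dx.reshape(B, C, Ho, Wo, p, p).transpose(0, 1, 2, 4, 3, 5)
        out = np.zeros(self._in_shape)
        out[:, :, :Ho * p, :Wo * p] = dx.reshape(B, C, Ho * p, Wo * p)
        return out


class Conv1D(Layer):
    """1-D strided convolution, valid padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        if stride < 1:
            raise ValueError("stride must be >= 1")
        fan_in = in_ch * kernel
        self.W = Param(_glorot(rng, (out_ch, in_ch, kernel), fan_in, out_ch * kernel))
        self.b = Param(np.zeros(out_ch))
        self.kernel = kernel
        self.stride = stride

    @staticmethod
    def out_len(L: int, kernel: int, stride: int) -> int:
        if kernel > L:
            raise ValueError(f"kernel {kernel} exceeds input length {L}")
        return (L - kernel) // stride + 1

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        k, v = self.kernel, self.stride
        self._x = x
        win = sliding_window_view(x, k, axis=2)[:, :, ::v]  # B,C,T,k
        self._win = win
        out = np.einsum("bctk,ock->bot", win, self.W.value, optimize=True)
        return out + self.b.value[None, :, None]

    def backward(self, grad):
        k, v = self.kernel, self.stride
        self.W.grad += np.einsum("bctk,bot->ock", self._win, grad, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2))
        dx = np.zeros_like(self._x)
        T = grad.shape[2]
        contrib = np.einsum("bot,ock->bctk", grad, self.W.value, optimize=True)
        for t in range(T):
            dx[:, :, t * v:t * v + k] += contrib[:, :, t, :]
        return dx


class LSTM(Layer):
    """Single-layer LSTM returning the full hidden-state sequence.

    Gate order in the stacked weight matrices: input (update), forget,
    candidate, output.  Forget-gate bias initialized to 1.
    """

    def __init__(self, input_size: int, hidden: int, rng: np.random.Generator):
        H = hidden
        self.Wx = Param(_glorot(rng, (input_size, 4 * H), input_size + H, H))
        self.Wh = Param(_glorot(rng, (H, 4 * H), input_size + H, H))
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0  # forget bias
        self.b = Param(b)
        self.hidden = H

    def params(self):
        return [self.Wx, self.Wh, self.b]

    @staticmethod
    def _sigmoid(z):
        return 0.5 * (1.0 + np.tanh(0.5 * z))

    def forward(self, x, training=False):
        B, T, F = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._x = x
        self._cache = []
        out = np.empty((B, T, H))
        for t in range(T):
            z = x[:, t] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = self._sigmoid(z[:, :H])
            f = self._sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = self._sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            out[:, t] = h
        self._out = out
        return out

    def backward(self, grad):
        x = self._x
        B, T, F = x.shape
        H = self.hidden
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dh = grad[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g * g),
                do * o * (1 - o),
            ], axis=1)
            self.Wx.grad += x[:, t].T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T
            dc_next = dc * f
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self):
        for p in self.params():
            p.zero_grad()

    def get_state(self) -> list[np.ndarray]:
        """Snapshot of all trainable values and batch-norm running stats."""
        state = [p.value.copy() for p in self.params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        for p, v in zip(ps, state[:len(ps)]):
            p.value[...] = v
        extra = iter(state[len(ps):])
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = next(extra)
                layer.running_var[...] = next(extra)

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))


class Adam:
    """Adaptive-moment estimation with bias correction."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
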