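"""Minimal NumPy neural-network core: layers with explicit backprop + Adam.

The estimation network (residual CNN -> BiLSTM -> linear heads) is small
enough to train on one CPU, so the layers are implemented directly on NumPy
arrays with hand-derived gradients.  Conventions:

- images are channels-last ``(B, H, W, C)``; sequences are ``(B, M, D)``;
- every layer caches what its ``backward`` needs during ``forward``;
- ``layer.params`` and ``layer.grads`` are parallel lists of arrays, gathered
  by the containers for the optimizer;
- all weight initialization is driven by an explicit ``numpy`` Generator, so
  a seed fixes the model bit-for-bit.

Convolutions are stride-1, 'same'-padded, and evaluated as a sum over the
k x k taps of a broadcast matmul — no im2col buffer, which keeps memory flat
and is fast at these sizes.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: list
    grads: list

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """k x k stride-1 convolution with 'same' zero padding, channels-last."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, k: int = 3):
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.k = k
        scale = np.sqrt(2.0 / (cin * k * k))  # He init for ReLU trunks
        self.W = rng.normal(0.0, scale, size=(k, k, cin, cout))
        self.b = np.zeros(cout)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        b_, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp = xp
        self._in_shape = x.shape
        out = np.broadcast_to(self.b, (b_, h, w, self.W.shape[-1])).copy()
        for i in range(k):
            for j in range(k):
                out += xp[:, i : i + h, j : j + w, :] @ self.W[i, j]
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        _, h, w, _ = self._in_shape
        xp = self._xp
        gxp = np.zeros_like(xp)
        gW, gb = self.grads
        gW[...] = 0.0
        gb[...] = g.sum(axis=(0, 1, 2))
        for i in range(k):
            for j in range(k):
                patch = xp[:, i : i + h, j : j + w, :]
                gW[i, j] = np.einsum("bhwc,bhwo->co", patch, g, optimize=True)
                gxp[:, i : i + h, j : j + w, :] += g @ self.W[i, j].T
        return gxp[:, p : p + h, p : p + w, :] if p else gxp


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (B, H, W), channels-last.

    Batch statistics during training, exponential running averages at
    evaluation (momentum 0.1), learned scale/shift.  The mode is set by the
    caller via ``forward(x, train=...)`` threading in the containers.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.run_mean += self.momentum * (mean - self.run_mean)
            self.run_var += self.momentum * (var - self.run_var)
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._xhat, self._inv, self._train = xhat, inv, train
        return self.gamma * xhat + self.beta

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.grads[0][...] = (g * xhat).sum(axis=(0, 1, 2))
        self.grads[1][...] = g.sum(axis=(0, 1, 2))
        if not self._train:
            # running statistics are constants w.r.t. the input
            return self.gamma * inv * g
        gmean = g.mean(axis=(0, 1, 2))
        gxmean = (g * xhat).mean(axis=(0, 1, 2))
        return self.gamma * inv * (g - gmean - xhat * gxmean)

    # running statistics live outside params/grads; snapshots must carry them
    def state(self) -> list:
        return [self.run_mean.copy(), self.run_var.copy()]

    def load_state(self, state: list) -> None:
        self.run_mean[...] = state[0]
        self.run_var[...] = state[1]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, 0.0)


class AvgPool2D(Layer):
    """Non-overlapping (ph, pw) average pooling; trailing remainder trimmed."""

    def __init__(self, ph: int, pw: int):
        super().__init__()
        self.ph, self.pw = ph, pw

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        ph, pw = self.ph, self.pw
        ho, wo = h // ph, w // pw
        self._in_shape = x.shape
        xt = x[:, : ho * ph, : wo * pw, :].reshape(b, ho, ph, wo, pw, c)
        return xt.mean(axis=(2, 4))

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, h, w, c = self._in_shape
        ph, pw = self.ph, self.pw
        ho, wo = h // ph, w // pw
        gx = np.zeros(self._in_shape)
        spread = np.repeat(np.repeat(g, ph, axis=1), pw, axis=2) / (ph * pw)
        gx[:, : ho * ph, : wo * pw, :] = spread
        return gx


class ResBlock(Layer):
    """conv-BN-ReLU-conv-BN with identity (or 1x1-projected) skip, then ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2D(cin, cout, rng)
        self.bn1 = BatchNorm2D(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv2D(cout, cout, rng)
        self.bn2 = BatchNorm2D(cout)
        self.proj = Conv2D(cin, cout, rng, k=1) if cin != cout else None
        self.relu2 = ReLU()
        layers = [self.conv1, self.bn1, self.conv2, self.bn2] + ([self.proj] if self.proj else [])
        for lay in layers:
            self.params += lay.params
            self.grads += lay.grads
        self.batchnorms = [self.bn1, self.bn2]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = self.bn1.forward(self.conv1.forward(x), train)
        y = self.bn2.forward(self.conv2.forward(self.relu1.forward(y)), train)
        skip = self.proj.forward(x) if self.proj else x
        return self.relu2.forward(y + skip)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.relu2.backward(g)
        gskip = self.proj.backward(g) if self.proj else g
        gmain = self.conv1.backward(self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(g)))))
        return gmain + gskip


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, h, w, c = self._in_shape
        return np.broadcast_to(g[:, None, None, :] / (h * w), self._in_shape).copy()


class Linear(Layer):
    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(1.0 / din)
        self.W = rng.normal(0.0, scale, size=(din, dout))
        self.b = np.zeros(dout)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.W.T


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class LSTM(Layer):
    """Single-direction LSTM over (B, M, D); returns the last hidden state.

    Gate order i, f, g, o; forget-gate bias initialized to 1 (standard trick
    so early training does not forget).  Full BPTT — sequence lengths here are
    the handful of slices per clip, so the cost is negligible.
    """

    def __init__(self, din: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        s = np.sqrt(1.0 / hidden)
        self.Wx = rng.uniform(-s, s, size=(din, 4 * hidden))
        self.Wh = rng.uniform(-s, s, size=(hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(self.Wx), np.zeros_like(self.Wh), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, m, _ = x.shape
        hdim = self.hidden
        h = np.zeros((b, hdim))
        c = np.zeros((b, hdim))
        self._x = x
        self._cache = []
        for t in range(m):
            z = x[:, t, :] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :hdim])
            f = _sigmoid(z[:, hdim : 2 * hdim])
            g = np.tanh(z[:, 2 * hdim : 3 * hdim])
            o = _sigmoid(z[:, 3 * hdim :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            self._cache.append((h, c, i, f, g, o, tc))
            h, c = o * tc, c_new
        return h

    def backward(self, gh_last: np.ndarray) -> np.ndarray:
        x = self._x
        b, m, _ = x.shape
        hdim = self.hidden
        gWx, gWh, gb = self.grads
        gWx[...] = 0.0
        gWh[...] = 0.0
        gb[...] = 0.0
        gx = np.zeros_like(x)
        gh = gh_last
        gc = np.zeros((b, hdim))
        for t in range(m - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            go = gh * tc
            gc = gc + gh * o * (1.0 - tc * tc)
            gi = gc * g
            gg = gc * i
            gf = gc * c_prev
            gz = np.concatenate(
                [gi * i * (1 - i), gf * f * (1 - f), gg * (1 - g * g), go * o * (1 - o)], axis=1
            )
            gWx += x[:, t, :].T @ gz
            gWh += h_prev.T @ gz
            gb += gz.sum(axis=0)
            gx[:, t, :] = gz @ self.Wx.T
            gh = gz @ self.Wh.T
            gc = gc * f
        return gx


class BiLSTM(Layer):
    """Bidirectional LSTM; output is [h_fwd_last, h_bwd_last] (2 * hidden)."""

    def __init__(self, din: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = LSTM(din, hidden, rng)
        self.bwd = LSTM(din, hidden, rng)
        self.params = self.fwd.params + self.bwd.params
        self.grads = self.fwd.grads + self.bwd.grads

    def forward(self, x: np.ndarray) -> np.ndarray:
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1, :])
        return np.concatenate([hf, hb], axis=1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        hdim = self.fwd.hidden
        gf = self.fwd.backward(g[:, :hdim])
        gb = self.bwd.backward(g[:, hdim:])
        return gf + gb[:, ::-1, :]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    p = softmax(logits)
    b = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(b), targets], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(b), targets] -= 1.0
    return loss, grad / b


def l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute deviation and its (sub)gradient w.r.t. pred."""
    d = pred - target
    return float(np.abs(d).mean()), np.sign(d) / d.size


def l2_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared deviation and its gradient w.r.t. pred."""
    d = pred - target
    return float((d * d).mean()), 2.0 * d / d.size


class Adam:
    """Adam over a flat list of parameter arrays (in-place updates)."""

    def __init__(self, params: list, grads: list, lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.grads = grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
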