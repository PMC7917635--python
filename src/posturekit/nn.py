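"""Minimal reverse-mode automatic differentiation and the layers used by the
convolutional-recurrent posture classifier.

The engine is a plain numpy tape: every operation appends a node holding its
output array and a closure that routes the output gradient to the operands.
It supports exactly the operations the classifier needs — matrix products,
broadcast bias addition, elementwise arithmetic, sigmoid/tanh/relu, column
and row gathers, and a fused softmax cross-entropy — and is verified against
central finite differences in the test suite.

Everything is float64 and seeded; identical seeds give bit-identical
parameters, updates and predictions.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


class Tensor:
    """A node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        _prev: tuple["Tensor", ...] = (),
        _backward: Callable[[], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._prev = _prev
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        # iterative post-order topological sort
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))

        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()


def _needs(*ts: Tensor) -> bool:
    return any(t.requires_grad for t in ts)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data @ b.data, requires_grad=_needs(a, b), _prev=(a, b))

    def bw():
        if a.requires_grad:
            a._accum(out.grad @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ out.grad)

    out._backward = bw
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data + b.data, requires_grad=_needs(a, b), _prev=(a, b))

    def bw():
        if a.requires_grad:
            a._accum(_unbroadcast(out.grad, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(out.grad, b.data.shape))

    out._backward = bw
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data * b.data, requires_grad=_needs(a, b), _prev=(a, b))

    def bw():
        if a.requires_grad:
            a._accum(_unbroadcast(out.grad * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(out.grad * a.data, b.data.shape))

    out._backward = bw
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, requires_grad=a.requires_grad, _prev=(a,))

    def bw():
        if a.requires_grad:
            a._accum(out.grad * s * (1.0 - s))

    out._backward = bw
    return out


def tanh(a: Tensor) -> Tensor:
    th = np.tanh(a.data)
    out = Tensor(th, requires_grad=a.requires_grad, _prev=(a,))

    def bw():
        if a.requires_grad:
            a._accum(out.grad * (1.0 - th * th))

    out._backward = bw
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, requires_grad=a.requires_grad, _prev=(a,))

    def bw():
        if a.requires_grad:
            a._accum(out.grad * mask)

    out._backward = bw
    return out


def cols(a: Tensor, lo: int, hi: int) -> Tensor:
    """Column slice ``a[:, lo:hi]`` with scatter-add backward."""
    out = Tensor(a.data[:, lo:hi], requires_grad=a.requires_grad, _prev=(a,))

    def bw():
        if a.requires_grad:
            g = np.zeros_like(a.data)
            g[:, lo:hi] = out.grad
            a._accum(g)

    out._backward = bw
    return out


def take_rows(a: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather ``a[idx]`` with scatter-add backward."""
    out = Tensor(a.data[idx], requires_grad=a.requires_grad, _prev=(a,))

    def bw():
        if a.requires_grad:
            g = np.zeros_like(a.data)
            np.add.at(g, idx, out.grad)
            a._accum(g)

    out._backward = bw
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of softmax(logits) against integer labels."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-300))
    out = Tensor(np.asarray(loss), requires_grad=logits.requires_grad, _prev=(logits,))

    def bw():
        if logits.requires_grad:
            g = p.copy()
            g[np.arange(n), labels] -= 1.0
            logits._accum(out.grad * g / n)

    out._backward = bw
    return out


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


class Parameter(Tensor):
    def __init__(self, data: np.ndarray):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def im2col(x: np.ndarray, kernel: int) -> np.ndarray:
    """Unfold (B, L, C) into (B, L-k+1, k*C) windows along the time axis."""
    B, L, C = x.shape
    Lp = L - kernel + 1
    out = np.empty((B, Lp, kernel * C))
    for t in range(kernel):
        out[:, :, t * C : (t + 1) * C] = x[:, t : t + Lp, :]
    return out


class LstmLayer:
    """One LSTM layer; gate order i, f, g, o along the 4H weight columns."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(in_dim + hidden)
        self.hidden = hidden
        self.Wx = Parameter(rng.uniform(-s, s, size=(in_dim, 4 * hidden)))
        self.Wh = Parameter(rng.uniform(-s, s, size=(hidden, 4 * hidden)))
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias keeps memory early on
        self.b = Parameter(b)

    def params(self) -> list[Parameter]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, xs: list[Tensor], batch: int) -> list[Tensor]:
        H = self.hidden
        h = Tensor(np.zeros((batch, H)))
        c = Tensor(np.zeros((batch, H)))
        out: list[Tensor] = []
        for x in xs:
            z = add(add(matmul(x, self.Wx), matmul(h, self.Wh)), self.b)
            i = sigmoid(cols(z, 0, H))
            f = sigmoid(cols(z, H, 2 * H))
            g = tanh(cols(z, 2 * H, 3 * H))
            o = sigmoid(cols(z, 3 * H, 4 * H))
            c = add(mul(f, c), mul(i, g))
            h = mul(o, tanh(c))
            out.append(h)
        return out


class ConvRecurrentNet:
    """1-D convolution over the 30-channel window, then stacked LSTM layers,
    then a softmax readout from the final timestep.

    Input windows are (batch, L, 30); the convolution slides along the L time
    samples with ``kernel`` taps and ``filters`` output maps, followed by a
    rectifier; ``depth`` LSTM layers of width ``hidden`` consume the filtered
    sequence; the last hidden state feeds a linear layer over the classes.
    """

    def __init__(
        self,
        n_channels: int = 30,
        n_classes: int = 7,
        filters: int = 64,
        kernel: int = 5,
        hidden: int = 64,
        depth: int = 2,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.kernel = kernel
        self.filters = filters
        self.n_classes = n_classes
        s = 1.0 / np.sqrt(kernel * n_channels)
        self.Wc = Parameter(rng.uniform(-s, s, size=(kernel * n_channels, filters)))
        self.bc = Parameter(np.zeros(filters))
        self.lstms = [
            LstmLayer(filters if d == 0 else hidden, hidden, rng) for d in range(depth)
        ]
        so = 1.0 / np.sqrt(hidden)
        self.Wo = Parameter(rng.uniform(-so, so, size=(hidden, n_classes)))
        self.bo = Parameter(np.zeros(n_classes))

    def params(self) -> list[Parameter]:
        ps = [self.Wc, self.bc, self.Wo, self.bo]
        for l in self.lstms:
            ps.extend(l.params())
        return ps

    def forward(self, x: np.ndarray) -> Tensor:
        """Logits tensor for a batch of windows (B, L, C)."""
        B, L, C = x.shape
        col = im2col(x, self.kernel)  # (B, Lp, k*C)
        Lp = col.shape[1]
        flat = Tensor(col.reshape(B * Lp, -1))
        conv = relu(add(matmul(flat, self.Wc), self.bc))  # (B*Lp, F)
        xs = [take_rows(conv, np.arange(B) * Lp + t) for t in range(Lp)]
        for lstm in self.lstms:
            xs = lstm.forward(xs, B)
        return add(matmul(xs[-1], self.Wo), self.bo)

    def predict_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        out = []
        for lo in range(0, len(x), batch):
            out.append(softmax_probs(self.forward(x[lo : lo + batch]).data))
        return np.vstack(out)

    def get_weights(self) -> dict[str, np.ndarray]:
        w = {"Wc": self.Wc.data, "bc": self.bc.data, "Wo": self.Wo.data, "bo": self.bo.data}
        for d, l in enumerate(self.lstms):
            w[f"lstm{d}_Wx"] = l.Wx.data
            w[f"lstm{d}_Wh"] = l.Wh.data
            w[f"lstm{d}_b"] = l.b.data
        return w

    def set_weights(self, w: dict[str, np.ndarray]) -> None:
        self.Wc.data = np.asarray(w["Wc"], dtype=float)
        self.bc.data = np.asarray(w["bc"], dtype=float)
        self.Wo.data = np.asarray(w["Wo"], dtype=float)
        self.bo.data = np.asarray(w["bo"], dtype=float)
        for d, l in enumerate(self.lstms):
            l.Wx.data = np.asarray(w[f"lstm{d}_Wx"], dtype=float)
            l.Wh.data = np.asarray(w[f"lstm{d}_Wh"], dtype=float)
            l.b.data = np.asarray(w[f"lstm{d}_b"], dtype=float)
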