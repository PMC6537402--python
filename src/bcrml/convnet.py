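"""A compact 1-D convolutional network over CDR position x Kidera channels.

The architecture is a stack of Conv -> LeakyReLU(0.2) -> MaxPool units
applied along the 33-position axis (10 input channels), followed by fully
connected hidden layers with LeakyReLU activations and inverted dropout,
and a final 2-way softmax.  Optimization is Adam on the cross-entropy
loss with minibatches of 100.  Everything is plain numpy with explicit
backward passes; a finite-difference check in the test suite guards the
gradients.

``dropout_keep`` is the probability of *keeping* a unit (1.0 disables
dropout).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LEAK = 0.2


@dataclass(slots=True)
class ConvNetConfig:
    learning_rate: float = 1e-4
    dropout_keep: float = 0.8
    n_conv_layers: int = 1
    n_kernels: int = 100
    kernel_width: int = 3
    pool_width: int = 2
    n_fc_layers: int = 1
    fc_units: int = 128
    epochs: int = 20
    batch_size: int = 100
    seed: int = 0


def _leaky(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, LEAK * x)


def _leaky_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, LEAK)


class _Conv1D:
    def __init__(self, rng, in_ch: int, out_ch: int, width: int):
        scale = np.sqrt(2.0 / (in_ch * width))
        self.W = rng.normal(0.0, scale, size=(width * in_ch, out_ch))
        self.b = np.zeros(out_ch)
        self.width = width
        self.in_ch = in_ch

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, length, _ = x.shape
        lp = length - self.width + 1
        patches = np.stack([x[:, i : i + self.width, :] for i in range(lp)], axis=1)
        self._patches = patches.reshape(n, lp, -1)
        self._x_shape = x.shape
        return self._patches @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, lp, _ = grad.shape
        self.dW = np.einsum("nlk,nlo->ko", self._patches, grad) / n
        self.db = grad.mean(axis=(0, 1)) * lp
        dpatches = (grad @ self.W.T).reshape(n, lp, self.width, self.in_ch)
        dx = np.zeros(self._x_shape)
        for i in range(lp):
            dx[:, i : i + self.width, :] += dpatches[:, i]
        return dx

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class _Dense:
    def __init__(self, rng, n_in: int, n_out: int):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n = grad.shape[0]
        self.dW = self._x.T @ grad / n
        self.db = grad.mean(axis=0)
        return grad @ self.W.T

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class ConvNetClassifier:
    """Binary classifier over (n, 33, 10) feature arrays."""

    def __init__(self, config: ConvNetConfig):
        self.config = config
        self._built = False

    # -- architecture ------------------------------------------------------
    def _build(self, length: int, channels: int) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.convs: list[_Conv1D] = []
        in_ch = channels
        for _ in range(cfg.n_conv_layers):
            if length < cfg.kernel_width:
                break
            self.convs.append(_Conv1D(rng, in_ch, cfg.n_kernels, cfg.kernel_width))
            length = length - cfg.kernel_width + 1
            if length >= cfg.pool_width:
                length //= cfg.pool_width
                self._pools = getattr(self, "_pools", []) + [True]
            else:
                self._pools = getattr(self, "_pools", []) + [False]
            in_ch = cfg.n_kernels
        if not hasattr(self, "_pools"):
            self._pools = []
        n_flat = length * in_ch
        self.fcs: list[_Dense] = []
        for _ in range(cfg.n_fc_layers):
            self.fcs.append(_Dense(rng, n_flat, cfg.fc_units))
            n_flat = cfg.fc_units
        self.out = _Dense(rng, n_flat, 2)
        self._rng = rng
        self._built = True

    def _layers(self):
        return [*self.convs, *self.fcs, self.out]

    # -- forward / backward ------------------------------------------------
    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cfg = self.config
        self._cache = []
        h = x
        for conv, pooled in zip(self.convs, self._pools):
            z = conv.forward(h)
            a = _leaky(z)
            if pooled:
                n, lp, c = a.shape
                lq = lp // cfg.pool_width
                view = a[:, : lq * cfg.pool_width, :].reshape(n, lq, cfg.pool_width, c)
                arg = view.argmax(axis=2)
                pooled_a = np.take_along_axis(view, arg[:, :, None, :], axis=2)[:, :, 0, :]
                self._cache.append(("convpool", z, a.shape, arg))
                h = pooled_a
            else:
                self._cache.append(("conv", z, None, None))
                h = a
        self._flat_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        for fc in self.fcs:
            z = fc.forward(h)
            a = _leaky(z)
            if train and cfg.dropout_keep < 1.0:
                mask = (
                    self._rng.random(a.shape) < cfg.dropout_keep
                ).astype(float) / cfg.dropout_keep
            else:
                mask = None
            self._cache.append(("fc", z, mask, None))
            h = a * mask if mask is not None else a
        logits = self.out.forward(h)
        return logits

    def _backward(self, dlogits: np.ndarray) -> None:
        cfg = self.config
        grad = self.out.backward(dlogits)
        for fc in reversed(self.fcs):
            kind, z, mask, _ = self._cache.pop()
            if mask is not None:
                grad = grad * mask
            grad = fc.backward(grad * _leaky_grad(z))
        grad = grad.reshape(self._flat_shape)
        for conv, pooled in zip(reversed(self.convs), reversed(self._pools)):
            kind, z, a_shape, arg = self._cache.pop()
            if pooled:
                n, lp, c = a_shape
                lq = lp // cfg.pool_width
                up = np.zeros((n, lq, cfg.pool_width, c))
                np.put_along_axis(up, arg[:, :, None, :], grad[:, :, None, :], axis=2)
                full = np.zeros((n, lp, c))
                full[:, : lq * cfg.pool_width, :] = up.reshape(n, lq * cfg.pool_width, c)
                grad = full
            grad = conv.backward(grad * _leaky_grad(z))

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    # -- training ----------------------------------------------------------
    def fit(self, x: np.ndarray, y: np.ndarray) -> "ConvNetClassifier":
        """Train on features ``x`` (n, 33, 10) and binary labels ``y``."""
        cfg = self.config
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if not self._built:
            self._build(x.shape[1], x.shape[2])
        # Adam state
        state = {}
        t = 0
        for epoch in range(cfg.epochs):
            order = self._rng.permutation(len(x))
            for start in range(0, len(x), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = x[idx], y[idx]
                logits = self._forward(xb, train=True)
                probs = self._softmax(logits)
                dlogits = probs.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                self._backward(dlogits)
                t += 1
                self._adam_step(state, t)
        return self

    def _adam_step(self, state, t, beta1=0.9, beta2=0.999, eps=1e-8):
        lr = self.config.learning_rate
        for li, layer in enumerate(self._layers()):
            for name, param, gname in layer.params():
                g = getattr(layer, gname)
                key = (li, name)
                m, v = state.get(key, (np.zeros_like(param), np.zeros_like(param)))
                m = beta1 * m + (1 - beta1) * g
                v = beta2 * v + (1 - beta2) * g * g
                state[key] = (m, v)
                mhat = m / (1 - beta1**t)
                vhat = v / (1 - beta2**t)
                param -= lr * mhat / (np.sqrt(vhat) + eps)

    def loss(self, x: np.ndarray, y: np.ndarray) -> float:
        """Mean cross-entropy (used by the gradient-check test)."""
        logits = self._forward(np.asarray(x, float), train=False)
        probs = self._softmax(logits)
        return float(-np.log(probs[np.arange(len(y)), y] + 1e-300).mean())

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """P(tumor) per row; tumor is class 1."""
        if not self._built:
            raise RuntimeError("classifier is not fitted")
        x = np.asarray(x, dtype=float)
        out = []
        for start in range(0, len(x), 4096):
            logits = self._forward(x[start : start + 4096], train=False)
            out.append(self._softmax(logits)[:, 1])
        return np.concatenate(out)
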