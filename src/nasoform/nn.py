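"""Minimal feed-forward neural-network core with explicit forward/backward passes.

Implements exactly the primitives the nasal-photogrammetry networks need —
2D convolution, ReLU, max-pooling, dropout, dense layers, global average
pooling, sigmoid/softmax heads, mean-squared-error and cross-entropy losses,
and Adam / plain gradient-descent updates.  Everything is NumPy; gradients are
hand-derived and verified against central finite differences (see
``finite_difference_gradcheck``).

Array layout is NHWC (batch, height, width, channels).  Convolutions are
stride-1 with 'same' or 'valid' padding; spatial reduction is done by the
pooling layers.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: stateless unless it owns parameters."""

    #: list of parameter arrays (same objects across calls; updated in place)
    params: list[np.ndarray]
    #: gradient arrays aligned with :attr:`params`, filled by ``backward``
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 2D convolution (cross-correlation) with bias.

    The forward map is the textbook contribution sum: each output cell is the
    filter-weighted sum of the corresponding input window plus a bias,
    ``out[a,b,co] = sum_ij sum_ci w[i,j,ci,co] * x[a+i, b+j, ci] + bias[co]``
    (valid mode; 'same' pads the input symmetrically with zeros first).
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, padding: str = "same",
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValueError(f"padding must be 'same' or 'valid', got {padding!r}")
        rng = rng or np.random.default_rng()
        self.k, self.padding = k, padding
        # He initialisation: suits ReLU-activated stacks
        scale = np.sqrt(2.0 / (k * k * c_in))
        self.w = (rng.standard_normal((k, k, c_in, c_out)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k = self.k
        if self.padding == "same":
            p0, p1 = (k - 1) // 2, k // 2
            xp = np.pad(x, ((0, 0), (p0, p1), (p0, p1), (0, 0)))
        else:
            if x.shape[1] < k or x.shape[2] < k:
                raise ValueError(
                    f"filter {k}x{k} larger than input {x.shape[1]}x{x.shape[2]}")
            xp = x
        self._xp = xp
        ho, wo = xp.shape[1] - k + 1, xp.shape[2] - k + 1
        out = np.tile(self.b, (x.shape[0], ho, wo, 1)).astype(self.w.dtype)
        for i in range(k):
            for j in range(k):
                out += xp[:, i:i + ho, j:j + wo, :] @ self.w[i, j]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp = self._xp
        k = self.k
        ho, wo = dout.shape[1], dout.shape[2]
        dxp = np.zeros_like(xp)
        dw, db = self.grads
        dw[...] = 0.0
        db[...] = dout.sum(axis=(0, 1, 2))
        for i in range(k):
            for j in range(k):
                xs = xp[:, i:i + ho, j:j + wo, :]
                dw[i, j] = np.einsum("bhwc,bhwd->cd", xs, dout, optimize=True)
                dxp[:, i:i + ho, j:j + wo, :] += dout @ self.w[i, j].T
        if self.padding == "same":
            p0, p1 = (k - 1) // 2, k // 2
            h, w = dxp.shape[1] - p0 - p1, dxp.shape[2] - p0 - p1
            return dxp[:, p0:p0 + h, p0:p0 + w, :]
        return dxp


class ReLU(Layer):
    """Rectified linear unit: f(x) = x if x > 0 else 0, elementwise."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(x.dtype)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0).astype(dout.dtype)


def relu(x):
    """Functional ReLU: ``max(0, x)`` elementwise (scalars and arrays)."""
    return np.maximum(0, x)


class MaxPool2D(Layer):
    """Max pooling with window ``k`` and stride ``s`` ('same'-style padding).

    Output side = ceil(input side / stride); padding uses -inf so padded cells
    never win the max.
    """

    def __init__(self, k: int, stride: int) -> None:
        super().__init__()
        self.k, self.s = k, stride

    def _pad(self, x: np.ndarray) -> tuple[np.ndarray, int, int]:
        k, s = self.k, self.s
        h, w = x.shape[1], x.shape[2]
        ho, wo = -(-h // s), -(-w // s)
        ph = max((ho - 1) * s + k - h, 0)
        pw = max((wo - 1) * s + k - w, 0)
        xp = np.pad(x, ((0, 0), (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2), (0, 0)),
                    constant_values=-np.inf)
        return xp, ho, wo

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s = self.k, self.s
        xp, ho, wo = self._pad(x)
        self._xshape, self._xpshape = x.shape, xp.shape
        stack = np.stack([
            xp[:, i:i + (ho - 1) * s + 1:s, j:j + (wo - 1) * s + 1:s, :]
            for i in range(k) for j in range(k)
        ])
        self._arg = np.argmax(stack, axis=0)
        return np.max(stack, axis=0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k, s = self.k, self.s
        dxp = np.zeros(self._xpshape, dtype=dout.dtype)
        ho, wo = dout.shape[1], dout.shape[2]
        for idx in range(k * k):
            i, j = divmod(idx, k)
            mask = self._arg == idx
            view = dxp[:, i:i + (ho - 1) * s + 1:s, j:j + (wo - 1) * s + 1:s, :]
            np.add.at(view, mask.nonzero(), dout[mask])
        b, h, w, c = self._xshape
        ph = self._xpshape[1] - h
        pw = self._xpshape[2] - w
        return dxp[:, ph // 2:ph // 2 + h, pw // 2:pw // 2 + w, :]


class Dropout(Layer):
    """Inverted dropout; active only when ``train=True``."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p, self.rng = p, rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return (x * self._mask).astype(x.dtype)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return (dout * self._mask).astype(dout.dtype)


class GlobalAvgPool(Layer):
    """Average each channel over the spatial grid: NHWC -> (N, C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :] / (h * w), self._shape).astype(dout.dtype)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer ``y = x @ W + b``."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / d_in)
        self.w = (rng.standard_normal((d_in, d_out)) * scale).astype(dtype)
        self.b = np.zeros(d_out, dtype=dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.w.T


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return (dout * self._y * (1.0 - self._y)).astype(dout.dtype)


class Sequential:
    """A plain layer stack with a combined forward/backward."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_params(self) -> int:
        return sum(p.size for p in self.params)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all elements; returns (loss, dloss/dpred)."""
    diff = pred - target
    loss = float(np.mean(diff ** 2))
    return loss, (2.0 / diff.size) * diff.astype(pred.dtype)

def cross_entropy_loss(logits: np.ndarray, labels: np.ndarray
                       ) -> tuple[float, np.ndarray]:
    """Softmax cross-entropy; ``labels`` are integer class indices.

    Returns (mean loss, dloss/dlogits).
    """
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(np.clip(p[np.arange(n), labels], 1e-12, None))))
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(logits.dtype)


class Adam:
    """Adam optimizer updating parameter arrays in place."""

    def __init__(self, params: list[np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        if lr <= 0:
            raise ValueError(f"learning rate must be positive, got {lr}")
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * np.square(g)
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)


class SGD:
    """Plain gradient descent ``W <- W - f * dE/dW`` with learning rate ``f``."""

    def __init__(self, params: list[np.ndarray], lr: float = 0.001) -> None:
        if lr <= 0:
            raise ValueError(f"learning rate must be positive, got {lr}")
        self.params, self.lr = params, lr

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g in zip(self.params, grads):
            p -= (self.lr * g).astype(p.dtype)


def make_optimizer(name: str, params: list[np.ndarray], lr: float):
    name = name.lower()
    if name == "adam":
        return Adam(params, lr=lr)
    if name == "sgd":
        return SGD(params, lr=lr)
    raise ValueError(f"unknown optimizer {name!r}")


def finite_difference_gradcheck(
    model: Sequential,
    x: np.ndarray,
    target: np.ndarray,
    loss_fn=mse_loss,
    eps: float = 1e-5,
    max_checks_per_param: int = 50,
    rng: np.random.Generator | None = None,
) -> float:
    """Compare analytic gradients with central finite differences.

    Runs forward/backward once to get analytic gradients, then perturbs up to
    ``max_checks_per_param`` randomly chosen entries of each parameter array
    by +/-eps and compares.  Returns the maximum relative error
    ``|analytic - numeric| / max(1e-12, |analytic| + |numeric|)``.

    Intended for small nets (<= ~1e4 parameters) in float64.
    """
    if not (0 < eps <= 1e-2):
        raise ValueError(f"eps must be in (0, 1e-2], got {eps}")
    rng = rng or np.random.default_rng(0)

    def loss_of() -> float:
        out = model.forward(x, train=False)
        return loss_fn(out, target)[0]

    out = model.forward(x, train=False)
    loss, dout = loss_fn(out, target)
    model.backward(dout)

    max_rel = 0.0
    for p, g in zip(model.params, model.grads):
        flat_p = p.reshape(-1)
        flat_g = g.reshape(-1)
        n = flat_p.size
        idx = (np.arange(n) if n <= max_checks_per_param
               else rng.choice(n, size=max_checks_per_param, replace=False))
        for i in idx:
            orig = flat_p[i]
            flat_p[i] = orig + eps
            lp = loss_of()
            flat_p[i] = orig - eps
            lm = loss_of()
            flat_p[i] = orig
            numeric = (lp - lm) / (2 * eps)
            analytic = flat_g[i]
            denom = max(1e-12, abs(analytic) + abs(numeric))
            max_rel = max(max_rel, abs(analytic - numeric) / denom)
    return max_rel
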