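"""Minimal NumPy feed-forward network machinery.

Implements exactly the pieces the sequence models need: affine layers, a
"linear block" LB(x) = ReLU(BN(Wx + b)) with batch normalization that
uses batch statistics during training and accumulated running statistics
at inference, reverse-mode gradients for all of it, and the Adam
optimizer. Arrays are float64 row-major with samples along axis 0.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as sigmoid  # numerically stable logistic


def softplus(x: np.ndarray) -> np.ndarray:
    """log(1 + e^x), overflow-safe."""
    return np.logaddexp(0.0, x)


def bce_sum(pred: np.ndarray, target: np.ndarray, eps: float = 1e-7) -> float:
    """Elementwise binary cross-entropy summed over all entries.

    Predictions are clamped to [eps, 1-eps] for stability at the
    saturated ends of the sigmoid.
    """
    p = np.clip(pred, eps, 1.0 - eps)
    return float(-(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)).sum())


class Dense:
    """Affine layer y = xW + b with fan-in scaled normal initialization."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, 1.0 / np.sqrt(in_dim), size=(in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    @property
    def grads(self):
        return {"W": self.dW, "b": self.db}


class BatchNorm:
    """1-D batch normalization with learnable scale/shift.

    Training mode normalizes with batch statistics and updates running
    statistics by exponential moving average; inference mode uses the
    running statistics, so single-sample generation is well defined.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv_std
            self._cache = (xhat, inv_std)
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * inv_std
        return self.gamma * xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n = dout.shape[0]
        self.dgamma = (dout * xhat).sum(axis=0)
        self.dbeta = dout.sum(axis=0)
        dxhat = dout * self.gamma
        # standard batch-norm backward over the batch dimension
        return (
            inv_std
            / n
            * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        )

    @property
    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    @property
    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    @property
    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class LinearBlock:
    """LB(x) = ReLU(BN(Wx + b)) — the model's basic building unit."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.dense = Dense(in_dim, out_dim, rng)
        self.bn = BatchNorm(out_dim)
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = self.bn.forward(self.dense.forward(x, training), training)
        if training:
            self._mask = h > 0
        return np.maximum(h, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.dense.backward(self.bn.backward(dout * self._mask))


class MLP:
    """A stack of linear blocks applied in sequence."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        self.blocks = [
            LinearBlock(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)
        ]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for blk in self.blocks:
            x = blk.forward(x, training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for blk in reversed(self.blocks):
            dout = blk.backward(dout)
        return dout


def collect(module, prefix: str = "") -> dict[str, np.ndarray]:
    """Flatten a module tree's parameters into a ``{name: array}`` dict."""
    out: dict[str, np.ndarray] = {}
    if isinstance(module, MLP):
        for i, blk in enumerate(module.blocks):
            out.update(collect(blk, f"{prefix}block{i}."))
    elif isinstance(module, LinearBlock):
        out.update(collect(module.dense, prefix + "dense."))
        out.update(collect(module.bn, prefix + "bn."))
    else:
        for name, arr in module.params.items():
            out[prefix + name] = arr
    return out


def collect_grads(module, prefix: str = "") -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    if isinstance(module, MLP):
        for i, blk in enumerate(module.blocks):
            out.update(collect_grads(blk, f"{prefix}block{i}."))
    elif isinstance(module, LinearBlock):
        out.update(collect_grads(module.dense, prefix + "dense."))
        out.update(collect_grads(module.bn, prefix + "bn."))
    else:
        for name, arr in module.grads.items():
            out[prefix + name] = arr
    return out


def collect_state(module, prefix: str = "") -> dict[str, np.ndarray]:
    """Non-trainable state (batch-norm running statistics)."""
    out: dict[str, np.ndarray] = {}
    if isinstance(module, MLP):
        for i, blk in enumerate(module.blocks):
            out.update(collect_state(blk, f"{prefix}block{i}."))
    elif isinstance(module, LinearBlock):
        out.update(collect_state(module.bn, prefix + "bn."))
    elif isinstance(module, BatchNorm):
        for name, arr in module.state.items():
            out[prefix + name] = arr
    return out


def load_arrays(module, arrays: dict[str, np.ndarray], prefix: str = "") -> None:
    """Write saved parameter/state arrays back into a module tree in place."""
    if isinstance(module, MLP):
        for i, blk in enumerate(module.blocks):
            load_arrays(blk, arrays, f"{prefix}block{i}.")
    elif isinstance(module, LinearBlock):
        load_arrays(module.dense, arrays, prefix + "dense.")
        load_arrays(module.bn, arrays, prefix + "bn.")
    elif isinstance(module, Dense):
        module.W[...] = arrays[prefix + "W"]
        module.b[...] = arrays[prefix + "b"]
    elif isinstance(module, BatchNorm):
        module.gamma[...] = arrays[prefix + "gamma"]
        module.beta[...] = arrays[prefix + "beta"]
        module.running_mean[...] = arrays[prefix + "running_mean"]
        module.running_var[...] = arrays[prefix + "running_var"]


class Adam:
    """Adam optimizer over a named parameter dict.

    Both moment-decay constants default to 0.9 — the configuration used
    for every model in this package.
    """

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 5e-4,
        beta1: float = 0.9,
        beta2: float = 0.9,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
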