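"""Minimal numpy recurrent networks with hand-written backpropagation.

Two small architectures are needed: a univariate gated-recurrent (GRU)
next-value regressor for imputation/filter initialization, and a two-layer
LSTM binary classifier.  Both are small enough (<=70 and <=128 hidden
units) that vectorized numpy BPTT trains them in seconds, so the package
carries its own implementation rather than depending on a deep-learning
framework.

Conventions: batch-major inputs, float64 throughout, Glorot-uniform
initialization from a caller-supplied ``numpy.random.Generator`` (all
determinism flows from that generator), Adam updates, optional global-norm
gradient clipping.  Gradient correctness is pinned by finite-difference
tests.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Adam",
    "GRURegressor",
    "LSTMLayer",
    "Dense",
    "dropout_forward",
    "clip_global_norm",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...] | None = None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


def clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> None:
    """In-place global-norm gradient clipping (no-op under the threshold)."""
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


class Adam:
    """Adam optimizer over a named parameter dict (updates in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            p -= self.lr * (self.m[k] / bias1) / (
                np.sqrt(self.v[k] / bias2) + self.eps)


class Dense:
    """Fully connected layer with optional activation ('relu' or None)."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int,
                 activation: str | None = None, prefix: str = "dense"):
        self.activation = activation
        self.prefix = prefix
        self.params = {
            f"{prefix}_W": _glorot(rng, n_in, n_out),
            f"{prefix}_b": np.zeros(n_out),
        }

    def forward(self, x: np.ndarray):
        z = x @ self.params[f"{self.prefix}_W"] + self.params[f"{self.prefix}_b"]
        if self.activation == "relu":
            a = np.maximum(z, 0.0)
        else:
            a = z
        return a, (x, z)

    def backward(self, cache, da: np.ndarray):
        x, z = cache
        dz = da * (z > 0) if self.activation == "relu" else da
        grads = {
            f"{self.prefix}_W": x.T @ dz,
            f"{self.prefix}_b": dz.sum(axis=0),
        }
        dx = dz @ self.params[f"{self.prefix}_W"].T
        return dx, grads


def dropout_forward(x: np.ndarray, rate: float, rng: np.random.Generator,
                    training: bool):
    """Inverted dropout; returns (output, mask)."""
    if not training or rate <= 0.0:
        return x, None
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * mask, mask


class GRURegressor:
    """Univariate next-value predictor: one GRU layer, rectified output
    state, one linear unit.

    Input is a (batch, window) array of scalar series values; output a
    (batch,) prediction of the next value.  The gating follows the
    standard update/reset formulation; the rectifier is applied to the
    final hidden state before the linear read-out.
    """

    def __init__(self, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        h = hidden
        self.params = {
            "Wz": _glorot(rng, 1, h), "Uz": _glorot(rng, h, h), "bz": np.zeros(h),
            "Wr": _glorot(rng, 1, h), "Ur": _glorot(rng, h, h), "br": np.zeros(h),
            "Wn": _glorot(rng, 1, h), "Un": _glorot(rng, h, h), "bn": np.zeros(h),
            "Wd": _glorot(rng, h, 1), "bd": np.zeros(1),
        }

    def forward(self, X: np.ndarray):
        """X: (batch, window).  Returns (y_hat (batch,), cache)."""
        p = self.params
        B, T = X.shape
        h = np.zeros((B, self.hidden))
        steps = []
        for t in range(T):
            x = X[:, t:t + 1]
            z = sigmoid(x @ p["Wz"] + h @ p["Uz"] + p["bz"])
            r = sigmoid(x @ p["Wr"] + h @ p["Ur"] + p["br"])
            n = np.tanh(x @ p["Wn"] + (r * h) @ p["Un"] + p["bn"])
            h_new = (1.0 - z) * n + z * h
            steps.append((x, h, z, r, n))
            h = h_new
        a = np.maximum(h, 0.0)  # rectified cell output
        y = (a @ p["Wd"] + p["bd"])[:, 0]
        cache = (steps, h, a)
        return y, cache

    def backward(self, cache, dy: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        steps, h_last, a = cache
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dy = dy[:, None]
        grads["Wd"] = a.T @ dy
        grads["bd"] = dy.sum(axis=0)
        dh = (dy @ p["Wd"].T) * (h_last > 0)
        for x, h_prev, z, r, n in reversed(steps):
            dz = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            dh_prev = dh * z
            a_n = dn * (1.0 - n * n)
            grads["Wn"] += x.T @ a_n
            grads["Un"] += (r * h_prev).T @ a_n
            grads["bn"] += a_n.sum(axis=0)
            drh = a_n @ p["Un"].T
            dr = drh * h_prev
            dh_prev = dh_prev + drh * r
            a_r = dr * r * (1.0 - r)
            grads["Wr"] += x.T @ a_r
            grads["Ur"] += h_prev.T @ a_r
            grads["br"] += a_r.sum(axis=0)
            dh_prev = dh_prev + a_r @ p["Ur"].T
            a_z = dz * z * (1.0 - z)
            grads["Wz"] += x.T @ a_z
            grads["Uz"] += h_prev.T @ a_z
            grads["bz"] += a_z.sum(axis=0)
            dh = dh_prev + a_z @ p["Uz"].T
        return grads

    def predict(self, X: np.ndarray) -> np.ndarray:
        y, _ = self.forward(np.atleast_2d(X))
        return y


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    return np.maximum(x, 0.0) if kind == "relu" else np.tanh(x)


def _dact(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (x > 0).astype(float)
    t = np.tanh(x)
    return 1.0 - t * t


class LSTMLayer:
    """Batch-major LSTM layer with configurable cell activation.

    ``activation`` replaces the conventional tanh on both the candidate
    and the cell output (the table-specified rectifier variant); the
    three gates stay sigmoid.  Supports returning the full hidden
    sequence or only the last state.
    """

    def __init__(self, rng: np.random.Generator, input_dim: int, units: int,
                 activation: str = "relu", prefix: str = "lstm",
                 return_sequences: bool = False):
        self.units = units
        self.activation = activation
        self.prefix = prefix
        self.return_sequences = return_sequences
        u = units
        # gate order: [i, f, g, o] stacked along columns
        self.params = {
            f"{prefix}_W": _glorot(rng, input_dim, 4 * u,
                                   shape=(input_dim, 4 * u)),
            f"{prefix}_U": _glorot(rng, u, 4 * u, shape=(u, 4 * u)),
            f"{prefix}_b": np.zeros(4 * u),
        }
        # forget-gate bias 1.0: standard stabilizer for cell-state flow
        self.params[f"{prefix}_b"][u:2 * u] = 1.0

    def forward(self, X: np.ndarray):
        """X: (batch, T, input_dim) -> (batch, T, units) or (batch, units)."""
        p, u, act = self.params, self.units, self.activation
        W, U, b = p[f"{self.prefix}_W"], p[f"{self.prefix}_U"], p[f"{self.prefix}_b"]
        B, T, _ = X.shape
        h = np.zeros((B, u))
        c = np.zeros((B, u))
        steps = []
        hs = np.empty((B, T, u))
        for t in range(T):
            x = X[:, t, :]
            pre = x @ W + h @ U + b
            i = sigmoid(pre[:, :u])
            f = sigmoid(pre[:, u:2 * u])
            g_pre = pre[:, 2 * u:3 * u]
            g = _act(g_pre, act)
            o = sigmoid(pre[:, 3 * u:])
            c_new = f * c + i * g
            h_new = o * _act(c_new, act)
            steps.append((x, h, c, i, f, g_pre, g, o, c_new))
            h, c = h_new, c_new
            hs[:, t, :] = h
        cache = (X.shape, steps)
        return (hs if self.return_sequences else h), cache

    def backward(self, cache, dout: np.ndarray):
        """dout matches forward's output shape; returns (dX, grads)."""
        p, u, act = self.params, self.units, self.activation
        W, U = p[f"{self.prefix}_W"], p[f"{self.prefix}_U"]
        (B, T, D), steps = cache
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dX = np.zeros((B, T, D))
        dh = np.zeros((B, u))
        dc = np.zeros((B, u))
        for t in range(T - 1, -1, -1):
            x, h_prev, c_prev, i, f, g_pre, g, o, c_new = steps[t]
            if self.return_sequences:
                dh = dh + dout[:, t, :]
            elif t == T - 1:
                dh = dh + dout
            do = dh * _act(c_new, act)
            dc = dc + dh * o * _dact(c_new, act)
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            a_i = di * i * (1.0 - i)
            a_f = df * f * (1.0 - f)
            a_g = dg * _dact(g_pre, act)
            a_o = do * o * (1.0 - o)
            a = np.concatenate([a_i, a_f, a_g, a_o], axis=1)
            grads[f"{self.prefix}_W"] += x.T @ a
            grads[f"{self.prefix}_U"] += h_prev.T @ a
            grads[f"{self.prefix}_b"] += a.sum(axis=0)
            dX[:, t, :] = a @ W.T
            dh = a @ U.T
            dc = dc * f
        return dX, grads
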