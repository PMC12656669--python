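"""Gated-recurrent initialization: a lightweight next-frame predictor that
imputes missing coordinates and seeds the unscented tracker.

The predictor is a single gated recurrent layer (30/50/70 units, rectified
output state) followed by one linear unit.  It is univariate: every
coordinate channel (keypoint x or y series) is z-scored with train-time
per-channel statistics and pooled into 5-frame sliding windows, and one
shared model learns the next-value mapping across all channels.  Missing
values are reconstructed iteratively in time order, each prediction
feeding the next window, so an arbitrarily long missing suffix can be
filled from the last five observed frames.

The model also supplies the tracker's starting point: the initial state
stacks the one-step position prediction with a finite-difference velocity,
and the initial covariance carries the model's held-out one-step MSE on
the position diagonal (doubled for velocity, the variance of a difference
of two one-step estimates).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._nn import Adam, GRURegressor, clip_global_norm
from .sequences import GaitSequence
from .skeleton import KEYPOINT_NAMES, N_KEYPOINTS

logger = logging.getLogger(__name__)

__all__ = [
    "GatedInitConfig",
    "GatedInitModel",
    "make_windows",
    "train",
    "iterative_reconstruct",
    "initial_state",
]


@dataclass(frozen=True)
class GatedInitConfig:
    """Training configuration for the gated initialization network."""

    window: int = 5
    hidden_units: int = 50
    step_size: float = 0.001
    epochs: int = 50
    batch: int = 32
    seed: int = 0
    val_fraction: float = 0.1
    max_windows: int | None = 20_000  # seeded cap on pooled training windows
    clip_norm: float = 5.0

    def __post_init__(self) -> None:
        if self.window < 1 or self.hidden_units < 1:
            raise ValueError("window and hidden_units must be >= 1")


def make_windows(series: np.ndarray, window: int = 5,
                 valid: np.ndarray | None = None,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Sliding input/target pairs from one coordinate series.

    Pair ``t`` has input ``series[t : t+window]`` and target
    ``series[t + window]``.  Pairs whose input or target touches an
    invalid entry (explicit ``valid`` mask, else the exact-zero sentinel)
    are excluded.  Returns ``(X, y)`` with ``X`` of shape
    ``(n_pairs, window)``.
    """
    series = np.asarray(series, dtype=float)
    if valid is None:
        valid = series != 0.0
    else:
        valid = np.asarray(valid, dtype=bool)
    n = series.size
    if n < window + 1:
        warnings.warn(
            f"series of length {n} is shorter than window+1={window + 1}; "
            "no training pairs", stacklevel=2,
        )
        return np.empty((0, window)), np.empty(0)
    spans = sliding_window_view(series, window + 1)  # (n-window, window+1)
    ok = np.all(sliding_window_view(valid, window + 1), axis=1)
    return spans[ok, :window].copy(), spans[ok, window].copy()


class GatedInitModel:
    """Trained gated predictor plus its normalization statistics."""

    def __init__(self, net: GRURegressor, config: GatedInitConfig,
                 norm_mean: np.ndarray, norm_scale: np.ndarray,
                 holdout_mse: float, history: list[dict] | None = None,
                 chain_profile: np.ndarray | None = None):
        self.net = net
        self.config = config
        self.norm_mean = norm_mean  # (17, 2) per-channel mean
        self.norm_scale = norm_scale  # (17, 2) per-channel scale
        self.holdout_mse = holdout_mse  # one-step MSE in normalized units
        self.history = history or []
        # chain_profile[d-1]: measured growth of chained d-step prediction
        # error relative to one-step error (monotone, >= 1)
        self.chain_profile = chain_profile

    @property
    def window(self) -> int:
        return self.config.window

    def predict_next(self, windows: np.ndarray, kp: np.ndarray,
                     axis: np.ndarray) -> np.ndarray:
        """One-step prediction in pixel units.

        ``windows``: (batch, window) raw pixel values; ``kp``/``axis``
        index each row's coordinate channel for de/normalization.
        """
        windows = np.atleast_2d(np.asarray(windows, dtype=float))
        kp = np.atleast_1d(kp)
        axis = np.atleast_1d(axis)
        mu = self.norm_mean[kp, axis][:, None]
        sd = self.norm_scale[kp, axis][:, None]
        y = self.net.predict((windows - mu) / sd)
        return y * sd[:, 0] + mu[:, 0]

    def holdout_mse_px(self, kp: int, axis: int) -> float:
        """Held-out one-step MSE in pixel^2 for one coordinate channel."""
        return float(self.holdout_mse * self.norm_scale[kp, axis] ** 2)

    def save(self, path) -> None:
        extra = {}
        if self.chain_profile is not None:
            extra["chain_profile"] = self.chain_profile
        np.savez(
            path,
            config=json.dumps(asdict(self.config)),
            norm_mean=self.norm_mean,
            norm_scale=self.norm_scale,
            holdout_mse=self.holdout_mse,
            **extra,
            **{f"param_{k}": v for k, v in self.net.params.items()},
        )

    @classmethod
    def load(cls, path) -> "GatedInitModel":
        data = np.load(path, allow_pickle=False)
        config = GatedInitConfig(**json.loads(str(data["config"])))
        net = GRURegressor(config.hidden_units,
                           np.random.default_rng(config.seed))
        for k in net.params:
            net.params[k] = data[f"param_{k}"]
        profile = data["chain_profile"] if "chain_profile" in data else None
        return cls(net, config, data["norm_mean"], data["norm_scale"],
                   float(data["holdout_mse"]), chain_profile=profile)


def _pool_windows(seqs: list[GaitSequence], cfg: GatedInitConfig,
                  norm_mean: np.ndarray, norm_scale: np.ndarray,
                  ) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for seq in seqs:
        for k in range(N_KEYPOINTS):
            valid = seq.visibility[:, k]
            for ax in (0, 1):
                series = (seq.coords[:, k, ax] - norm_mean[k, ax]
                          ) / norm_scale[k, ax]
                X, y = make_windows(series, cfg.window, valid=valid)
                if len(X):
                    xs.append(X)
                    ys.append(y)
    if not xs:
        raise ValueError("no training windows could be formed")
    return np.concatenate(xs), np.concatenate(ys)


def train(train_seqs: list[GaitSequence],
          cfg: GatedInitConfig = GatedInitConfig()) -> GatedInitModel:
    """Train the shared univariate predictor on pooled, normalized windows.

    Training sequences are expected to be complete; windows touching any
    invisible entry are excluded defensively.  The parameters achieving
    the best held-out (validation) MSE are kept, and that MSE becomes the
    model's initial-covariance scale.
    """
    if not train_seqs:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)

    # per-channel z-scoring statistics from visible training values
    sums = np.zeros((N_KEYPOINTS, 2))
    sqs = np.zeros((N_KEYPOINTS, 2))
    counts = np.zeros((N_KEYPOINTS, 2))
    for seq in train_seqs:
        vis = seq.visibility[..., None]
        sums += np.sum(seq.coords * vis, axis=0)
        sqs += np.sum(seq.coords**2 * vis, axis=0)
        counts += np.sum(vis, axis=0)
    counts = np.maximum(counts, 1.0)
    norm_mean = sums / counts
    norm_scale = np.sqrt(np.maximum(sqs / counts - norm_mean**2, 0.0))
    norm_scale = np.maximum(norm_scale, 1e-6)

    X, y = _pool_windows(train_seqs, cfg, norm_mean, norm_scale)
    order = rng.permutation(len(X))
    X, y = X[order], y[order]
    if cfg.max_windows is not None and len(X) > cfg.max_windows:
        X, y = X[:cfg.max_windows], y[:cfg.max_windows]

    n_val = max(1, int(round(cfg.val_fraction * len(X))))
    X_val, y_val = X[:n_val], y[:n_val]
    X_tr, y_tr = X[n_val:], y[n_val:]
    if len(X_tr) == 0:
        X_tr, y_tr = X_val, y_val

    net = GRURegressor(cfg.hidden_units, rng)
    opt = Adam(net.params, lr=cfg.step_size)
    best_val = np.inf
    best_params = {k: v.copy() for k, v in net.params.items()}
    history: list[dict] = []
    n = len(X_tr)
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        total = 0.0
        for start in range(0, n, cfg.batch):
            idx = perm[start:start + cfg.batch]
            xb, yb = X_tr[idx], y_tr[idx]
            pred, cache = net.forward(xb)
            err = pred - yb
            total += float(np.sum(err**2))
            grads = net.backward(cache, 2.0 * err / len(idx))
            clip_global_norm(grads, cfg.clip_norm)
            opt.step(grads)
        val_pred, _ = net.forward(X_val)
        val_mse = float(np.mean((val_pred - y_val) ** 2))
        history.append({"epoch": epoch + 1, "train_mse": total / n,
                        "val_mse": val_mse})
        if val_mse < best_val:
            best_val = val_mse
            best_params = {k: v.copy() for k, v in net.params.items()}
    net.params.update(best_params)
    logger.info("gated init trained: %d windows, best val MSE %.3g",
                len(X), best_val)
    model = GatedInitModel(net, cfg, norm_mean, norm_scale, best_val, history)
    model.chain_profile = _measure_chain_profile(model, train_seqs)
    return model


def _measure_chain_profile(model: GatedInitModel,
                           seqs: list[GaitSequence],
                           max_probes: int = 8) -> np.ndarray:
    """Growth curve of chained prediction error with gap depth.

    The model reconstructs an artificial suffix gap on probe sequences
    (all keypoints removed) and the squared error at each depth d is
    averaged over channels and normalized by the depth-1 error.  The
    curve quantifies how fast iterated self-feeding predictions degrade —
    the uncertainty schedule the tracker uses when fusing them.
    """
    probes = [s for s in seqs if s.visibility.all()][:max_probes]
    if not probes:
        return np.ones(1)
    w = model.window
    depth = max(min(s.n_frames - w - 1 for s in probes), 1)
    errs = np.zeros(depth)
    count = 0
    for seq in probes:
        gap = seq.copy()
        t0 = seq.n_frames - depth
        gap.coords[t0:] = 0.0
        gap = GaitSequence(gap.subject_id, gap.label, gap.coords)
        recon = iterative_reconstruct(model, gap)
        e = np.sum((recon.coords[t0:] - seq.coords[t0:]) ** 2, axis=2)
        errs += e.sum(axis=1)
        count += e.shape[1]
    g = errs / max(count, 1)
    g = g / max(g[0], 1e-12)
    return np.maximum.accumulate(np.maximum(g, 1.0))


def iterative_reconstruct(model: GatedInitModel,
                          seq: GaitSequence) -> GaitSequence:
    """Fill missing coordinates frame by frame with chained predictions.

    Frames are scanned in time order; each missing coordinate is predicted
    from the previous ``window`` values (observed or already
    reconstructed) and written back, so later predictions consume earlier
    ones.  Observed values are never altered; reconstructed entries are
    flagged in the ``imputed`` mask.  Every affected keypoint needs at
    least ``window`` visible frames before its first missing frame.
    """
    w = model.window
    out = seq.copy()
    missing = ~out.visibility
    if not missing.any():
        return out
    # available[t, k] — value usable at time t (observed or reconstructed)
    available = out.visibility.copy()
    for k in np.flatnonzero(missing.any(axis=0)):
        t0 = int(np.argmax(missing[:, k]))
        if t0 < w or not available[t0 - w:t0, k].all():
            raise ValueError(
                f"keypoint {k} ({KEYPOINT_NAMES[k]}): fewer than {w} visible "
                f"frames precede the first missing frame {t0 + 1}"
            )
    for t in range(w, out.n_frames):
        todo = np.flatnonzero(missing[t] & available[t - w:t].all(axis=0))
        if todo.size == 0:
            continue
        # both axes of each missing keypoint, one batched forward pass
        kp = np.repeat(todo, 2)
        axis = np.tile([0, 1], todo.size)
        windows = out.coords[t - w:t, kp, axis].T  # (2*|todo|, w)
        preds = model.predict_next(windows, kp, axis)
        out.coords[t, kp, axis] = preds
        out.imputed[t, todo] = True
        available[t, todo] = True
    if (~out.visibility & ~out.imputed).any():
        bad = np.flatnonzero((~out.visibility & ~out.imputed).any(axis=0))
        raise ValueError(
            f"keypoints {bad.tolist()} could not be reconstructed "
            "(insufficient preceding context)"
        )
    return out


def initial_state(model: GatedInitModel, seq: GaitSequence, t0: int,
                  keypoint: int,
                  reconstructed: GaitSequence | None = None,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Tracker starting point for one keypoint at its first missing frame.

    Returns ``(x0, P0)`` with state ``[x, y, vx, vy]``: position is the
    model's one-step prediction at ``t0`` (taken from the iterative
    reconstruction), velocity the finite difference of the two last
    available positions, and ``P0`` diagonal with the model's held-out
    one-step MSE as position variance and twice that as velocity variance.
    """
    w = model.window
    if t0 < w:
        raise ValueError(
            f"t0={t0} leaves fewer than window={w} preceding frames")
    if reconstructed is None:
        reconstructed = iterative_reconstruct(model, seq)
    pos = reconstructed.coords[t0, keypoint]
    prev = reconstructed.coords[t0 - 1, keypoint]
    vel = pos - prev
    x0 = np.array([pos[0], pos[1], vel[0], vel[1]])
    var_x = max(model.holdout_mse_px(keypoint, 0), 1e-6)
    var_y = max(model.holdout_mse_px(keypoint, 1), 1e-6)
    P0 = np.diag([var_x, var_y, 2.0 * var_x, 2.0 * var_y])
    return x0, P0
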