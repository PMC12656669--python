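"""PD/Healthy sequence classifier and the leakage-safe dataset split.

The network is a small two-layer LSTM stack: 128 units, dropout 0.2,
64 units, a 32-unit dense layer, dropout 0.2, and a single sigmoid output,
with rectified cell activations throughout.  By default the flattened
1700-value record enters as a single time step of 1700 features
(``input_shape="flat"``); ``input_shape="frames"`` instead feeds 50 steps
of 34 features.  Features are z-scored with training statistics.

Training uses Adam with binary cross-entropy, batch 32, at most 50
epochs, and early stopping on a validation split (15% carved from the
training set) with patience 5; the parameters from the best validation
epoch are kept.  A prediction is PD iff its probability strictly exceeds
0.5.

The train/test split is stratified by class and grouped by base subject:
the four augmented variants of one subject never straddle the split, so
augmentation cannot leak test information into training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._nn import (Adam, Dense, LSTMLayer, clip_global_norm, dropout_forward,
                  sigmoid)
from .metrics import ClassificationReport, confusion_counts
from .sequences import GaitSequence, Label, flatten_record
from .skeleton import N_KEYPOINTS

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierConfig",
    "GaitClassifier",
    "split_dataset",
    "train_classifier",
    "evaluate",
]


@dataclass(frozen=True)
class ClassifierConfig:
    units1: int = 128
    units2: int = 64
    dense_units: int = 32
    dropout: float = 0.2
    step_size: float = 0.0005  # midpoint of the 5e-5..1e-3 regime
    epochs: int = 50
    batch: int = 32
    patience: int = 5
    val_fraction: float = 0.15
    threshold: float = 0.5
    input_shape: str = "flat"  # or "frames"
    seed: int = 0
    clip_norm: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout rate must lie in [0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.input_shape not in ("flat", "frames"):
            raise ValueError("input_shape must be 'flat' or 'frames'")


def split_dataset(seqs: list[GaitSequence],
                  fractions: tuple[float, float] = (0.7, 0.3),
                  seed: int = 0) -> tuple[list[GaitSequence], list[GaitSequence]]:
    """Stratified, subject-grouped train/test split.

    Splitting operates on base subjects within each class, so augmented
    variants of one subject land on one side only.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    if fractions[1] <= 0.0 or fractions[0] <= 0.0:
        raise ValueError("both split fractions must be positive")
    by_class: dict[Label, dict[str, list[GaitSequence]]] = {}
    for seq in seqs:
        by_class.setdefault(seq.label, {}).setdefault(seq.base_id, []).append(seq)
    if len(by_class) < 2:
        raise ValueError("both classes must be present to split")
    rng = np.random.default_rng(seed)
    train: list[GaitSequence] = []
    test: list[GaitSequence] = []
    for label in sorted(by_class, key=lambda l: l.value):
        groups = by_class[label]
        base_ids = sorted(groups)
        if len(base_ids) < 2:
            raise ValueError(
                f"class {label.value} has {len(base_ids)} base subject(s); "
                "need at least 2 to split"
            )
        order = rng.permutation(len(base_ids))
        n_test = max(1, int(round(fractions[1] * len(base_ids))))
        test_ids = {base_ids[i] for i in order[:n_test]}
        for bid in base_ids:
            (test if bid in test_ids else train).extend(groups[bid])
    return train, test


class GaitClassifier:
    """Trained two-layer LSTM classifier."""

    def __init__(self, config: ClassifierConfig, n_frames: int):
        self.config = config
        self.n_frames = n_frames
        rng = np.random.default_rng(config.seed)
        if config.input_shape == "flat":
            self.t_steps, self.n_feat = 1, n_frames * 2 * N_KEYPOINTS
        else:
            self.t_steps, self.n_feat = n_frames, 2 * N_KEYPOINTS
        self.lstm1 = LSTMLayer(rng, self.n_feat, config.units1,
                               activation="relu", prefix="lstm1",
                               return_sequences=True)
        self.lstm2 = LSTMLayer(rng, config.units1, config.units2,
                               activation="relu", prefix="lstm2")
        self.dense = Dense(rng, config.units2, config.dense_units,
                           activation="relu", prefix="dense")
        self.out = Dense(rng, config.dense_units, 1, prefix="out")
        self.params: dict[str, np.ndarray] = {}
        for layer in (self.lstm1, self.lstm2, self.dense, self.out):
            self.params.update(layer.params)
        self.feat_mean: np.ndarray | None = None
        self.feat_scale: np.ndarray | None = None
        self.history: list[dict] = []

    # -- data plumbing -------------------------------------------------
    def _design(self, seqs: list[GaitSequence]) -> np.ndarray:
        for seq in seqs:
            if seq.n_frames != self.n_frames:
                raise ValueError(
                    f"{seq.subject_id}: {seq.n_frames} frames, classifier "
                    f"expects {self.n_frames}"
                )
        X = np.stack([flatten_record(s) for s in seqs])
        if self.feat_mean is not None:
            X = (X - self.feat_mean) / self.feat_scale
        return X.reshape(len(seqs), self.t_steps, self.n_feat)

    # -- forward / backward -------------------------------------------
    def _forward(self, X3: np.ndarray, training: bool = False,
                 rng: np.random.Generator | None = None):
        h1, c1 = self.lstm1.forward(X3)
        d1, m1 = dropout_forward(h1, self.config.dropout, rng, training)
        h2, c2 = self.lstm2.forward(d1)
        a3, c3 = self.dense.forward(h2)
        d3, m3 = dropout_forward(a3, self.config.dropout, rng, training)
        logit, c4 = self.out.forward(d3)
        prob = sigmoid(logit[:, 0])
        cache = (c1, m1, c2, c3, m3, c4)
        return prob, cache

    def _backward(self, cache, dlogit: np.ndarray) -> dict[str, np.ndarray]:
        c1, m1, c2, c3, m3, c4 = cache
        grads: dict[str, np.ndarray] = {}
        dd3, g4 = self.out.backward(c4, dlogit[:, None])
        grads.update(g4)
        if m3 is not None:
            dd3 = dd3 * m3
        dh2, g3 = self.dense.backward(c3, dd3)
        grads.update(g3)
        dd1, g2 = self.lstm2.backward(c2, dh2)
        grads.update(g2)
        if m1 is not None:
            dd1 = dd1 * m1
        _, g1 = self.lstm1.backward(c1, dd1)
        grads.update(g1)
        return grads

    # -- public API ----------------------------------------------------
    def predict_proba(self, seqs: list[GaitSequence]) -> np.ndarray:
        prob, _ = self._forward(self._design(seqs), training=False)
        return prob

    def predict(self, seqs: list[GaitSequence]
                ) -> tuple[np.ndarray, np.ndarray]:
        """Returns (labels, probabilities); PD iff p > threshold (strict)."""
        prob = self.predict_proba(seqs)
        labels = np.where(prob > self.config.threshold, Label.PD.value,
                          Label.HEALTHY.value)
        return labels, prob


def _bce(prob: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(prob, 1e-12, 1.0 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def train_classifier(train_seqs: list[GaitSequence],
                     cfg: ClassifierConfig = ClassifierConfig()
                     ) -> GaitClassifier:
    """Fit the classifier with early stopping; returns the best-epoch model."""
    if not train_seqs:
        raise ValueError("empty training set")
    labels = np.array([1.0 if s.label == Label.PD else 0.0 for s in train_seqs])
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    model = GaitClassifier(cfg, train_seqs[0].n_frames)
    rng = np.random.default_rng(cfg.seed + 1)

    X = np.stack([flatten_record(s) for s in train_seqs])
    model.feat_mean = X.mean(axis=0)
    model.feat_scale = np.maximum(X.std(axis=0), 1e-6)
    Xn = ((X - model.feat_mean) / model.feat_scale).reshape(
        len(train_seqs), model.t_steps, model.n_feat)

    # stratified validation carve-out
    idx_pos = np.flatnonzero(labels == 1.0)
    idx_neg = np.flatnonzero(labels == 0.0)
    rng.shuffle(idx_pos)
    rng.shuffle(idx_neg)
    n_vp = max(1, int(round(cfg.val_fraction * len(idx_pos))))
    n_vn = max(1, int(round(cfg.val_fraction * len(idx_neg))))
    val_idx = np.concatenate([idx_pos[:n_vp], idx_neg[:n_vn]])
    tr_idx = np.concatenate([idx_pos[n_vp:], idx_neg[n_vn:]])
    if len(tr_idx) == 0:
        tr_idx = val_idx
    X_tr, y_tr = Xn[tr_idx], labels[tr_idx]
    X_val, y_val = Xn[val_idx], labels[val_idx]

    opt = Adam(model.params, lr=cfg.step_size)
    best_val = np.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    stale = 0
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(X_tr))
        total = 0.0
        for start in range(0, len(X_tr), cfg.batch):
            idx = perm[start:start + cfg.batch]
            xb, yb = X_tr[idx], y_tr[idx]
            prob, cache = model._forward(xb, training=True, rng=rng)
            if not np.all(np.isfinite(prob)):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch + 1}")
            total += _bce(prob, yb) * len(idx)
            dlogit = (prob - yb) / len(idx)
            grads = model._backward(cache, dlogit)
            clip_global_norm(grads, cfg.clip_norm)
            opt.step(grads)
        val_prob, _ = model._forward(X_val, training=False)
        val_loss = _bce(val_prob, y_val)
        model.history.append({"epoch": epoch + 1,
                              "train_loss": total / len(X_tr),
                              "val_loss": val_loss})
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                logger.info("early stopping at epoch %d (best val loss %.4f)",
                            epoch + 1, best_val)
                break
    for k, v in best_params.items():
        model.params[k][...] = v
    return model


def evaluate(model: GaitClassifier, seqs: list[GaitSequence]
             ) -> ClassificationReport:
    """Confusion-derived metrics with PD as the positive class."""
    pred_labels, _ = model.predict(seqs)
    true_labels = np.array([s.label.value for s in seqs])
    tp, tn, fp, fn = confusion_counts(true_labels, pred_labels,
                                      positive=Label.PD.value)
    return ClassificationReport(tp=tp, tn=tn, fp=fp, fn=fn)
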