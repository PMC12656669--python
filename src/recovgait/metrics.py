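"""Recovery and classification metrics, plus long-format sweep tables.

Recovery error between a ground-truth and a reconstructed sequence is
reported as MAE, MSE and MAPE over the flattened coordinate record:

    MAE  = (1/n) sum |y - y_hat|
    MSE  = (1/n) sum (y - y_hat)^2
    MAPE = (100/n) sum |y - y_hat| / |y|        (reported in percent)

By default the sums run over ALL n = frames x 34 values of the record,
not only the missing ones — the convention pinned down by the analytic
zero-fill identity: zero-filling m of n strictly-positive values gives
MAPE exactly 100 * m / n (e.g. a 40-frame head suffix on a 50-frame
record: 100 * 400 / 1700 = 23.5294%).  Truth values exactly 0 are
excluded from the MAPE sum with a logged count; synthetic ground truth
never contains them.

Classification metrics derive from the confusion counts in the usual way
(accuracy, precision, recall, F1), with precision/recall defined as 0 on
an empty denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequences import GaitSequence, flatten_record

logger = logging.getLogger(__name__)

__all__ = [
    "RecoveryReport",
    "ClassificationReport",
    "error_metrics",
    "classification_metrics",
    "confusion_counts",
    "sweep_report",
]


@dataclass
class RecoveryReport:
    """MAE (px), MSE (px^2) and MAPE (percent) for one condition."""

    mae: float
    mse: float
    mape: float
    n_values: int
    group: str = "all"
    missing_frames: int | None = None

    def as_dict(self) -> dict:
        return {
            "group": self.group,
            "missing_frames": self.missing_frames,
            "mae": self.mae,
            "mse": self.mse,
            "mape": self.mape,
            "n_values": self.n_values,
        }


@dataclass
class ClassificationReport:
    """Confusion counts and the four derived ratios."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float = field(init=False)
    precision: float = field(init=False)
    recall: float = field(init=False)
    f1: float = field(init=False)

    def __post_init__(self) -> None:
        tp, tn, fp, fn = self.tp, self.tn, self.fp, self.fn
        total = tp + tn + fp + fn
        if total == 0:
            raise ValueError("all confusion counts are zero")
        if min(tp, tn, fp, fn) < 0:
            raise ValueError("confusion counts must be >= 0")
        self.accuracy = (tp + tn) / total
        if tp + fp == 0:
            logger.info("precision denominator zero; defining precision = 0")
            self.precision = 0.0
        else:
            self.precision = tp / (tp + fp)
        if tp + fn == 0:
            logger.info("recall denominator zero; defining recall = 0")
            self.recall = 0.0
        else:
            self.recall = tp / (tp + fn)
        if self.precision + self.recall == 0:
            self.f1 = 0.0
        else:
            self.f1 = (2 * self.precision * self.recall
                       / (self.precision + self.recall))

    @property
    def n_samples(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
        }


def error_metrics(truth: GaitSequence | list[GaitSequence],
                  pred: GaitSequence | list[GaitSequence],
                  scope: str = "all",
                  group: str = "all",
                  missing_frames: int | None = None) -> RecoveryReport:
    """Pooled recovery errors between ground truth and reconstruction.

    ``scope`` is ``"all"`` (every value of the flattened record, the
    default reporting convention) or ``"missing"`` (only values the
    occluded copy lost, identified by the prediction's non-visible mask).
    Accepts single sequences or parallel lists, pooling all values.
    """
    if isinstance(truth, GaitSequence):
        truth = [truth]
        pred = [pred]  # type: ignore[list-item]
    if len(truth) != len(pred):
        raise ValueError("truth and prediction lists differ in length")
    ys, yhats = [], []
    for t_seq, p_seq in zip(truth, pred):
        if t_seq.coords.shape != p_seq.coords.shape:
            raise ValueError(
                f"shape mismatch for {t_seq.subject_id}: "
                f"{t_seq.coords.shape} vs {p_seq.coords.shape}"
            )
        y = flatten_record(t_seq)
        yhat = flatten_record(p_seq)
        if scope == "missing":
            mask = np.repeat((~p_seq.visibility).reshape(-1), 2)
            y, yhat = y[mask], yhat[mask]
        elif scope != "all":
            raise ValueError(f"unknown scope {scope!r}")
        ys.append(y)
        yhats.append(yhat)
    y = np.concatenate(ys)
    yhat = np.concatenate(yhats)
    n = y.size
    if n == 0:
        return RecoveryReport(0.0, 0.0, 0.0, 0, group, missing_frames)
    abs_err = np.abs(y - yhat)
    mae = float(np.mean(abs_err))
    mse = float(np.mean((y - yhat) ** 2))
    nonzero = y != 0.0
    if not nonzero.all():
        logger.info("MAPE: excluding %d zero-valued truth entries from the "
                    "denominator sum", int(np.sum(~nonzero)))
    mape = float(100.0 / n * np.sum(abs_err[nonzero] / np.abs(y[nonzero])))
    return RecoveryReport(mae, mse, mape, n, group, missing_frames)


def confusion_counts(true_labels: np.ndarray, pred_labels: np.ndarray,
                     positive) -> tuple[int, int, int, int]:
    """(tp, tn, fp, fn) with ``positive`` as the positive class."""
    true_pos = np.asarray(true_labels) == positive
    pred_pos = np.asarray(pred_labels) == positive
    tp = int(np.sum(true_pos & pred_pos))
    tn = int(np.sum(~true_pos & ~pred_pos))
    fp = int(np.sum(~true_pos & pred_pos))
    fn = int(np.sum(true_pos & ~pred_pos))
    return tp, tn, fp, fn


def classification_metrics(tp: int, tn: int, fp: int, fn: int,
                           ) -> ClassificationReport:
    """Build the report from confusion counts."""
    return ClassificationReport(tp=tp, tn=tn, fp=fp, fn=fn)


_KEY_COLS = ["technique", "group", "missing_frames", "hidden_units", "seed"]


def sweep_report(results: list[dict]) -> pd.DataFrame:
    """Long-format sweep table keyed by
    (technique, group, missing_frames, hidden_units, seed).

    Each input dict carries the key columns it uses plus metric columns;
    missing key columns are filled with a placeholder.  Duplicate keys are
    an error; row order is stable under input permutation (sorted keys).
    """
    if not results:
        return pd.DataFrame(columns=_KEY_COLS)
    df = pd.DataFrame(results)
    for col in _KEY_COLS:
        if col not in df.columns:
            df[col] = "-"
    df = df.fillna({c: "-" for c in _KEY_COLS})
    dup = df.duplicated(subset=_KEY_COLS)
    if dup.any():
        raise ValueError(
            f"duplicate sweep keys: {df.loc[dup, _KEY_COLS].to_dict('records')}"
        )
    df = df.sort_values(_KEY_COLS, kind="stable").reset_index(drop=True)
    ordered = _KEY_COLS + [c for c in df.columns if c not in _KEY_COLS]
    return df[ordered]
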