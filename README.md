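# recovgait

Recovery of occluded 2D human-gait keypoints by combining a lightweight
gated-recurrent imputer with per-keypoint unscented Kalman tracking, plus
a Parkinson's-disease gait classifier and the evaluation harness that
quantifies how occlusion and recovery affect both reconstruction error
and classification accuracy.

## The problem

Video-based Parkinson's-disease (PD) screening extracts COCO-17 skeleton
keypoints from walking videos and classifies the coordinate sequences.
Occlusion — furniture, walking aids, self-occlusion of one leg by the
other — makes pose estimators drop or corrupt exactly the keypoints that
matter most (hips and legs), which degrades classification badly.  This
package recovers the missing coordinates so the classifier sees a
plausible, complete skeleton.

## The method

Each record is one subject: 50 frames x 17 keypoints x (x, y) = 1700
coordinate values; a missing keypoint is the exact sentinel (0, 0).
Occlusion is detected from redundant-detection confidence scores by a
score–weight merge,

    merge_score_i = Σ_j cluster_scores[j,i] · masked_scores[j,i] / Σ_k masked_scores[k,i],

with keypoint *i* visible iff `merge_score_i > τ` (τ = 0.5).  Recovery
combines two components:

1. **Gated initialization** — a univariate GRU (30/50/70 units, rectified
   output state, one linear unit) trained on 5-frame sliding windows of
   z-scored coordinate series, pooled over all keypoints.  Missing values
   are reconstructed iteratively, each prediction feeding the next
   window; the model also supplies the tracker's initial state x̂₀
   (one-step position prediction + finite-difference velocity) and
   covariance P₀ (held-out one-step MSE on the diagonal).
2. **Unscented tracking** — an independent 4-state constant-velocity
   unscented Kalman filter per keypoint (scaled unscented transform,
   2n+1 sigma points, λ = α²(n+κ) − n).  Observed frames update with the
   real measurement; occluded frames fuse the imputer's value as a
   pseudo-measurement whose noise is calibrated from the subject's own
   observed prefix and grows with gap depth along the model's measured
   chain-error profile.  A short validation gap carved from the prefix
   decides, per keypoint, whether the fusion actually helps.

The classifier is a two-layer LSTM (128 → 64 units, dropout 0.2, dense
32, sigmoid output) over the flattened 1700-value record, trained with
Adam, binary cross-entropy and early stopping, always on complete data;
occlusion is simulated only on the test branch.  Recovery quality is
reported as MAE, MSE and MAPE = (100/n) Σ|y−ŷ|/|y| over all 1700 values
of the record; classification as accuracy, precision, recall and F1 from
the confusion counts.  Zero-filling m of the n values of a record with
strictly positive coordinates gives MAPE exactly 100·m/n, which anchors
the evaluation analytically (e.g. a 40-frame head suffix: 100·400/1700 =
23.5294%).

The recurrent networks are compact numpy implementations (hand-written
backpropagation, verified against finite differences) — the models are
small enough that no deep-learning framework is needed.

## Worked example

```python
import numpy as np
from recovgait import (BodyPart, GatedInitConfig, OcclusionSpec,
                       error_metrics, make_dataset, recover_sequence,
                       simulate_missing)
from recovgait import gated_init

# 12 synthetic subjects; train the imputer on 8, evaluate on 4
cohort = make_dataset(n_pd=6, n_healthy=6, seed=7, augmented=False)
train, test = cohort[:4] + cohort[6:10], cohort[4:6] + cohort[10:]

model = gated_init.train(train, GatedInitConfig(hidden_units=50, seed=7))
print(f"imputer held-out one-step MSE: {model.holdout_mse:.4f} (normalized)")

spec = OcclusionSpec(groups=(BodyPart.LEGS,), missing_frames=40)
for truth in test:
    occluded = simulate_missing(truth, spec)
    recovered = recover_sequence(occluded, model)
    zf = error_metrics(truth, occluded).mape
    rec = error_metrics(truth, recovered).mape
    print(f"{truth.subject_id}: zero-fill MAPE {zf:.4f}% -> recovered {rec:.4f}%")
```

Output:

```
imputer held-out one-step MSE: 0.0704 (normalized)
pd004: zero-fill MAPE 18.8235% -> recovered 0.6626%
pd005: zero-fill MAPE 18.8235% -> recovered 0.4879%
hc004: zero-fill MAPE 18.8235% -> recovered 1.4074%
hc005: zero-fill MAPE 18.8235% -> recovered 1.6378%
```

The zero-fill MAPE is the analytic 100·(4 keypoints·2·40 frames)/1700;
recovery reduces it by more than an order of magnitude.  The same
workflow is available from the shell via the `recovgait` command
(`simulate`, `occlude`, `train-init`, `recover`, `ablate`).

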