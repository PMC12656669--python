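# Methods

This note documents the models, the synthetic data, the numerical
choices, and the design decisions behind them.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model

A gait record is one subject's fixed-length trajectory: 50 frames of 17
COCO keypoints, each an (x, y) pixel pair, flattened frame-major to 1700
values.  Coordinates use the image convention (origin top-left, y
downward); frames are 0-indexed internally and 1-indexed in messages.
A missing keypoint is the exact sentinel (0, 0); the canvas offset of the
synthetic generator guarantees no true coordinate is ever 0, so the
sentinel is unambiguous and the zero-fill error identities are exact.
The four body-part groups partition the skeleton: head {0–4}, body
{5–8}, hips {9–12} (the wrists ride at hip height during walking and are
grouped here), legs {13–16}.

The CSV record layout is `subject_id, label`, then frame-major 34-value
blocks with (x, y) interleaved per keypoint.  The interleaving is a
convention of this package — coordinate order inside a frame is not
dictated by the record arithmetic — and the CSV carries coordinates only;
pose-estimator JSON is the score-bearing format.  When JSON contains
several detected people, the one with the highest mean keypoint score is
kept (recordings are single-patient).

## Synthetic gait generator

The generator exists so that every stage is testable without recordings.
Each subject is a kinematic skeleton: the pelvis translates at constant
walking speed; knees and ankles oscillate sinusoidally about their
neutral offsets at the gait cadence (left/right in antiphase); elbows
and wrists counter-swing; head keypoints ride the trunk with a small
double-frequency vertical bob; white Gaussian jitter models detector
noise on every coordinate.

Class profiles: the healthy default walks at 4 px/frame with 20 px
stride amplitude, 12 px arm swing and 0.08 cycles/frame; the
Parkinsonian profile at 2 px/frame, 8 px stride, 4 px arm swing and
0.065 cycles/frame — the reduced, shuffling step and diminished arm
swing of the PD gait phenotype, scaled so that a simple threshold on
ankle oscillation separates the default classes (a tested property that
underwrites the classifier experiments).  Jitter defaults to 0.5 px.
Between-subject variation multiplies amplitudes, speed and cadence by
seeded lognormal factors (sd 10%).  Cadence 0.08 puts four full gait
cycles in a 50-frame window, giving the recurrent imputer enough
repetition to learn from; at 25 fps this corresponds to a brisk but
plausible 2 cycles/s scaled for test economy.

What the generator does not emulate: anatomical constraint between
joints, camera projection, sit/stand phases, outlier detections, and the
heavy-tailed, temporally correlated error structure of real pose
estimators.  Passing tests therefore demonstrate the machinery and its
internal consistency, not clinical performance.

Augmentation is exactly x4: original, horizontal flip about the mean
mid-hip x, scaling by 0.9 about the mid-hip center, translation by
(15, 10) px.  Magnitudes are package conventions (recorded in config);
sentinels remain (0, 0) under every transform.  Train/test splitting is
grouped by base subject so augmented variants never straddle the split.

## Occlusion

Detection merges redundant-detection confidence scores per keypoint with
the score–weight rule and flags a keypoint occluded unless the merged
score strictly exceeds τ = 0.5.  A keypoint all of whose mask weights
are zero merges to 0 and is treated as occluded — the conservative
reading of a keypoint no detection supports.  Mask construction
("too far from the reference pose") is upstream pose-NMS behaviour and
is accepted as input.

Simulation removes whole body-part groups over the last k frames
(k ∈ {10, 20, 30, 40}), replacing coordinates with the sentinel.  Suffix
removal is the canonical scheme — trackers only have past frames to
extrapolate from — and is what makes the zero-fill MAPE identities come
out exactly (100·m/1700); an explicit frame-range mode is retained as an
option.

## Gated initialization network

A univariate next-value predictor: one gated recurrent (GRU) layer with
30/50/70 units, a rectifier on the final hidden state, one linear output
unit.  Every coordinate channel is z-scored with per-channel training
statistics, cut into 5-frame windows, and pooled; one shared model
serves all channels.  Table-driven choices: window 5, Adam at 0.001,
MSE loss.  Package choices: 50 epochs, batch 32, a seeded cap of 20 000
pooled windows (training cost then scales with model size rather than
cohort size), 10% of windows held out for validation, parameters kept
from the best validation epoch.  The held-out one-step MSE becomes the
position variance of the tracker's initial covariance (velocity variance
doubled, as the variance of a difference of two one-step estimates).

After fitting, the model measures its own *chain-error profile*: on up to
eight complete training sequences an artificial suffix gap is
reconstructed and the squared error at gap depth d, normalized by the
depth-1 error, gives a monotone growth curve g(d).  This curve is the
uncertainty schedule used when the tracker fuses chained predictions.

Iterative reconstruction scans frames in order; each missing coordinate
is predicted from the previous five values (observed or previously
reconstructed) and written back.  Observed values are never altered;
reconstructed entries are flagged `imputed`.  Every affected keypoint
needs at least five visible frames before its first missing frame.

## Unscented tracker

The engine is a generic scaled unscented transform: sigma points
X₀ = x, Xᵢ = x ± column_i(√((n+λ)P)), weights Wm₀ = λ/(n+λ),
Wc₀ = Wm₀ + 1 − α² + β, Wmᵢ = Wcᵢ = 1/(2(n+λ)), with defaults α = 10⁻³,
β = 2, κ = 0.  It accepts arbitrary non-linear f and h (exercised by a
non-linear oscillator in the tests); keypoint tracking instantiates it
with a linear constant-velocity state [x, y, vx, vy], Δt = 1 frame, and
position-only measurements, one independent filter per keypoint.

Noise model: Q is the discrete white-noise-acceleration form.  The
package default σ_q = 3 px/frame² comes from the curvature scale of the
synthetic gait (a 20 px oscillation at 0.08 cycles/frame peaks at about
A·ω² ≈ 5 px/frame² of acceleration); R = σ_r²·I with σ_r = 2 px.
Covariance hygiene: P is re-symmetrized every step, the Cholesky of
(n+λ)P climbs a jitter ladder (0 → 10⁻¹² → … → 10⁻⁶) before failing
with the offending eigenvalue, and posterior eigenvalues are floored at
zero.  A singular innovation covariance falls back to a pseudo-inverse
with a warning.

### Missing-measurement policy (the combination)

Frames with a real observation update the filter normally.  For occluded
frames the imputer's reconstructed coordinate is fused as a
pseudo-measurement.  The default, calibrated policy measures everything
it needs from the subject's own observed prefix:

* **Prefix smoothing.**  The observed prefix is forward-filtered
  (measurement noise estimated from third differences, for which a
  smooth signal contributes little) and the denoised positions seed the
  imputation chain.  Noisy seed windows are what chained imputation
  amplifies most; on clean data the filter is a near-identity there.
* **Process noise** per keypoint from second differences of the prefix —
  the trajectory's empirical acceleration scale.
* **Pseudo-measurement noise** from the imputer's one-step errors on the
  prefix, shrunk halfway toward the within-subject cross-keypoint mean
  (the prefix offers only ~5 error samples per channel), decomposed into
  an observation-noise floor plus a model-excess part that grows with
  gap depth along the trained chain-error profile g(d).  Only the excess
  accumulates along a chain, so a near-noise-floor imputer keeps the
  filter glued to its values while a drifting one is progressively
  smoothed toward the dynamics.
* **Per-keypoint validation.**  A 4-frame artificial gap is carved from
  the tail of the observed prefix; the fused and imputer-only
  reconstructions are scored against the actually observed frames there,
  and the losing arm is discarded for that keypoint.  The filter is
  applied exactly where the subject's own data says it helps.

A fixed-inflation fallback (`calibrate=False`: pseudo-measurement noise
`r_pseudo_scale · R`) is retained.  The calibrated design emerged from
development on held-out synthetic cohorts: no fixed (σ_q, inflation)
pair behaves well across both the regime where the imputer is nearly
perfect (any smoothing adds constant-velocity lag bias) and the regime
where it drifts (smoothing wins large).  On near-noiseless synthetic
gait the imputer can sit at the observation-noise floor, and there the
combination's margin over imputation alone is thin and not guaranteed on
every cohort — a property of the synthetic conditions, not of real
pose-estimator data, whose noise is larger and structured.

The tracking-only arm (no imputer) initializes from the last two
observed frames with a large diagonal covariance and coasts predict-only
through gaps.

## Classifier

Two LSTM layers (128 then 64 units, rectified cell activations as
specified by the architecture table, sigmoid gates), dropout 0.2 after
each block, a 32-unit rectified dense layer, and a single sigmoid
output.  The flattened 1700-value record enters as one time step of
1700 features (the table's `(None, 1, 128)` first output shape); a
50-steps-of-34-features variant is available behind
`input_shape="frames"`.  Features are z-scored with training statistics;
with rectified activations on raw pixel values training would not be
stable.  Training: Adam at 0.0005 (midpoint of the 5·10⁻⁵–10⁻³ regime),
binary cross-entropy, batch 32, up to 50 epochs, early stopping with
patience 5 on a stratified 15% validation carve-out, best-epoch
checkpoint.  A prediction is PD iff its probability strictly exceeds
0.5 (a tie goes to healthy).  The classifier always trains on complete
sequences; occlusion and recovery touch only the test branch.

Both networks are compact numpy implementations with hand-written
backpropagation (Glorot initialization, forget-gate bias 1, global-norm
gradient clipping at 5, seeded determinism throughout); gradients are
pinned by central-difference tests.  At these sizes (≤70 and ≤128
units) vectorized numpy trains them in seconds.

## Evaluation conventions

Recovery errors pool all n = frames×34 values of the flattened record —
not only the missing ones — because that convention makes zero-filling m
values give MAPE exactly 100·m/n, which anchors the harness with
analytic targets (head 40-frame suffix: 23.5294%; four-keypoint groups:
18.8235%; all parts: 80%).  Truth values exactly 0 are excluded from the
MAPE denominator with a logged count; synthetic truth never contains
them.  MAPE is reported in percent; tables print four decimals.
Precision and recall are defined as 0 on an empty denominator.

## Experiment harness

`run_ablation` trains the imputer and classifier once per seed on the
complete training split, occludes test copies per (group, k) cell,
applies each technique (zero-fill passthrough / tracking-only /
imputer-only / combined), and emits one recovery row and one
classification row per cell plus a complete-data baseline; failures
isolate to cells.  `run_part_sensitivity` measures classification
degradation with no recovery; `run_multipart` measures recovery error
under nested multi-part occlusion (legs ⊂ legs+hips ⊂ body+legs+hips ⊂
all).  Reports are long-format tables keyed by (technique, group,
missing_frames, hidden_units, seed), byte-identical across reruns with
the same configuration.

## Problem sizes

The test suite and the acceptance script use cohorts sized for a few
CPU-minutes: the recovery ablation trains a 50-unit imputer on 16
complete subjects and evaluates 20 held-out subjects (legs, k = 40); the
classification-restoration experiment uses the full 26 + 50 subject
cohort (304 sequences after augmentation, 70/30 split) over five seeds.
The study-protocol alternative of training the imputer on the augmented
split was examined and set aside: mirror-flipped and rescaled variants
of the same subjects dilute the shared univariate model without adding
kinematic information.

## Known limitations

* The kinematic generator is deliberately simple; none of the reported
  synthetic numbers transfer to real video.
* The imputer is univariate and shared across channels; per-coordinate
  models or multivariate (skeleton-aware) imputation are out of scope.
* Filters are independent per keypoint; no skeletal constraints, no
  smoothers (RTS), no square-root filtering.
* The prefix-calibrated noise estimates rest on ~5–10 observed frames
  and are correspondingly coarse; the validation gate exists to absorb
  their failures.
* Only suffix and contiguous-range missing patterns are first-class;
  scattered missingness works through the same code paths but is
  untested territory for the calibration heuristics.
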