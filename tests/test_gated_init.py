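"""Gated-recurrent imputer: windowing, training, iterative reconstruction
and tracker initialization."""

from dataclasses import replace

import numpy as np
import pytest

from recovgait import (BodyPart, GatedInitConfig, GaitSequence, Label,
                       OcclusionSpec, generate_subject, make_windows,
                       simulate_missing)
from recovgait import gated_init
from recovgait.synthetic import HEALTHY_PROFILE


class TestMakeWindows:
    def test_clean_series_counts(self):
        X, y = make_windows(np.arange(1.0, 51.0), window=5)
        assert X.shape == (45, 5)
        assert np.array_equal(X[0], [1, 2, 3, 4, 5]) and y[0] == 6

    def test_minimal_series_single_pair(self):
        X, y = make_windows(np.array([1.0, 2, 3, 4, 5, 6]), window=5)
        assert X.shape == (1, 5)
        assert np.array_equal(X[0], [1, 2, 3, 4, 5]) and y[0] == 6

    def test_sentinel_excludes_touching_windows(self):
        series = np.arange(1.0, 51.0)
        series[19] = 0.0  # sentinel at frame 20 (1-indexed)
        X, y = make_windows(series, window=5)
        # brute-force oracle: enumerate pairs touching index 19
        expected = sum(
            1 for t in range(45)
            if 19 not in range(t, t + 6)
        )
        assert expected == 39
        assert len(X) == expected
        assert not np.any(X == 0.0) and not np.any(y == 0.0)

    def test_too_short_series_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            X, y = make_windows(np.arange(4.0), window=5)
        assert len(X) == 0


def _complete_seqs(n=6, jitter=0.5):
    profile = replace(HEALTHY_PROFILE, jitter_sd=jitter)
    return [generate_subject(profile, seed=s) for s in range(n)]


class TestTrain:
    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gated_init.train([], GatedInitConfig())

    def test_constant_series_predicted_within_one_percent(self):
        coords = np.full((50, 17, 2), 1.0)
        coords *= np.arange(1, 35).reshape(17, 2)[None] * 10.0  # distinct constants
        seq = GaitSequence("const", Label.UNKNOWN, coords)
        cfg = GatedInitConfig(hidden_units=8, epochs=30, seed=0)
        model = gated_init.train([seq], cfg)
        window = np.full((1, 5), 130.0)  # keypoint 6, x-channel constant
        pred = model.predict_next(window, np.array([6]), np.array([0]))
        assert abs(pred[0] - 130.0) / 130.0 < 0.01

    def test_sinusoid_one_step_error_under_five_percent(self):
        """Noiseless sinusoids: held-out one-step prediction within 5% of
        the closed-form next value."""
        model = _sinus_model()
        rng = np.random.default_rng(3)
        t = np.arange(50)
        phase = rng.uniform(0, 2 * np.pi)
        series = 200.0 + 10.0 * np.sin(2 * np.pi * 0.08 * t + phase)
        mu, sd = model.norm_mean[0, 0], model.norm_scale[0, 0]
        win = (series[20:25] - mu) / sd
        pred = model.net.predict(win[None, :])[0] * sd + mu
        truth = series[25]
        assert abs(pred - truth) < 0.05 * 10.0  # 5% of the amplitude

    def test_seeded_reproducibility(self):
        seqs = _complete_seqs(2)
        cfg = GatedInitConfig(hidden_units=8, epochs=3, max_windows=1000, seed=7)
        a = gated_init.train(seqs, cfg)
        b = gated_init.train(seqs, cfg)
        assert a.history[-1]["train_mse"] == b.history[-1]["train_mse"]
        for k in a.net.params:
            assert np.array_equal(a.net.params[k], b.net.params[k])

    def test_capacity_ordering(self):
        """More hidden units cannot fit pooled windows worse than one unit."""
        seqs = _complete_seqs(2)
        small = gated_init.train(
            seqs, GatedInitConfig(hidden_units=1, epochs=10,
                                  max_windows=2000, seed=1))
        large = gated_init.train(
            seqs, GatedInitConfig(hidden_units=50, epochs=10,
                                  max_windows=2000, seed=1))
        assert (min(h["train_mse"] for h in large.history)
                <= min(h["train_mse"] for h in small.history))


def _sinus_model():
    """Model trained on pure sinusoid channels (module-level cache)."""
    if not hasattr(_sinus_model, "cache"):
        rng = np.random.default_rng(0)
        t = np.arange(50)
        seqs = []
        for s in range(6):
            coords = np.empty((50, 17, 2))
            for k in range(17):
                for ax in range(2):
                    phase = rng.uniform(0, 2 * np.pi)
                    coords[:, k, ax] = 200.0 + 10.0 * np.sin(
                        2 * np.pi * 0.08 * t + phase)
            seqs.append(GaitSequence(f"s{s}", Label.UNKNOWN, coords))
        cfg = GatedInitConfig(hidden_units=30, epochs=40, seed=2)
        _sinus_model.cache = gated_init.train(seqs, cfg)
    return _sinus_model.cache


class TestIterativeReconstruct:
    def test_no_missing_values_identity(self, tiny_init_model, small_cohort):
        out = gated_init.iterative_reconstruct(tiny_init_model, small_cohort[0])
        assert np.array_equal(out.coords, small_cohort[0].coords)

    def test_single_trailing_gap_equals_one_prediction(self, tiny_init_model,
                                                       small_cohort):
        seq = small_cohort[0].copy()
        spec = OcclusionSpec(groups=(BodyPart.LEGS,), missing_frames=1)
        occluded = simulate_missing(seq, spec)
        out = gated_init.iterative_reconstruct(tiny_init_model, occluded)
        k = 13
        win = occluded.coords[44:49, k, 0][None, :]
        expected = tiny_init_model.predict_next(win, np.array([k]),
                                                np.array([0]))[0]
        assert np.isclose(out.coords[49, k, 0], expected)

    def test_long_suffix_leaves_no_sentinels(self, tiny_init_model,
                                             small_cohort):
        spec = OcclusionSpec(groups=(BodyPart.LEGS,), missing_frames=40)
        occluded = simulate_missing(small_cohort[1], spec)
        n_sentinels_before = int(np.sum(occluded.sentinel_mask()))
        assert n_sentinels_before == 4 * 40
        out = gated_init.iterative_reconstruct(tiny_init_model, occluded)
        assert int(np.sum(out.sentinel_mask())) == 0
        assert out.imputed[10:, 13:].all()

    def test_observed_values_never_modified(self, tiny_init_model,
                                            small_cohort):
        spec = OcclusionSpec(groups=(BodyPart.HIPS,), missing_frames=30)
        occluded = simulate_missing(small_cohort[2], spec)
        out = gated_init.iterative_reconstruct(tiny_init_model, occluded)
        vis = occluded.visibility
        assert np.array_equal(out.coords[vis], occluded.coords[vis])

    def test_insufficient_leading_context_rejected(self, tiny_init_model,
                                                   small_cohort):
        occluded = simulate_missing(
            small_cohort[3],
            OcclusionSpec(groups=(BodyPart.HEAD,), missing_frames=47))
        with pytest.raises(ValueError, match="nose"):
            gated_init.iterative_reconstruct(tiny_init_model, occluded)

    def test_oracle_model_recovers_noiseless_suffix(self, recurrence_oracle,
                                                    clean_subject):
        """With an exact next-value predictor, iterative reconstruction
        recovers a noiseless synthetic suffix to float precision."""
        spec = OcclusionSpec(groups=(BodyPart.LEGS,), missing_frames=40)
        occluded = simulate_missing(clean_subject, spec)
        out = gated_init.iterative_reconstruct(recurrence_oracle, occluded)
        missing = ~occluded.visibility
        err = np.abs(out.coords - clean_subject.coords)[missing]
        truth = np.abs(clean_subject.coords)[missing]
        mape = 100.0 * np.mean(err / truth)
        assert mape < 1.0
        assert err.max() < 1e-5


class TestInitialState:
    def test_constant_series_zero_velocity(self):
        coords = np.full((50, 17, 2), 100.0)
        seq = GaitSequence("c", Label.UNKNOWN, coords)
        cfg = GatedInitConfig(hidden_units=8, epochs=25, seed=4)
        model = gated_init.train([seq], cfg)
        occluded = seq.copy()
        occluded.coords[40:, 13, :] = 0.0
        occluded = GaitSequence("c", Label.UNKNOWN, occluded.coords)
        x0, P0 = gated_init.initial_state(model, occluded, 40, 13)
        assert np.abs(x0[2:]).max() < 1.0  # near-zero velocity
        assert np.abs(x0[:2] - 100.0).max() < 2.0

    def test_linear_ramp_velocity_matches_slope(self, recurrence_oracle,
                                                clean_subject):
        spec = OcclusionSpec(groups=(BodyPart.LEGS,), missing_frames=10)
        occluded = simulate_missing(clean_subject, spec)
        x0, P0 = gated_init.initial_state(recurrence_oracle, occluded, 40, 15)
        truth_v = (clean_subject.coords[40, 15] - clean_subject.coords[39, 15])
        assert np.allclose(x0[2:], truth_v, atol=1e-6)

    def test_initial_covariance_positive_definite(self, tiny_init_model,
                                                  small_cohort):
        spec = OcclusionSpec(groups=(BodyPart.LEGS,), missing_frames=10)
        occluded = simulate_missing(small_cohort[4], spec)
        x0, P0 = gated_init.initial_state(tiny_init_model, occluded, 40, 15)
        assert np.all(np.linalg.eigvalsh(P0) > 0)
        assert np.allclose(P0, P0.T)
        # velocity variance doubles the position variance
        assert np.isclose(P0[2, 2], 2 * P0[0, 0])
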