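"""Unscented transform, filter recursions and sequence recovery.

The key oracle is a directly coded textbook linear Kalman filter: on a
linear-Gaussian system the unscented filter must reproduce it to float
precision.
"""

import numpy as np
import pytest

from recovgait import (BodyPart, OcclusionSpec, UKFParams, UKFState,
                       constant_velocity_fns, cv_process_noise,
                       default_keypoint_params, generate_subject,
                       recover_sequence, sigma_points, simulate_missing,
                       ukf_only_recover, ut_weights)
from recovgait import ukf as ukf_mod
from recovgait.synthetic import HEALTHY_PROFILE


class LinearKF:
    """Independent textbook Kalman filter (predict/update in closed form)."""

    def __init__(self, F, H, Q, R, x0, P0):
        self.F, self.H, self.Q, self.R = F, H, Q, R
        self.x, self.P = x0.copy(), P0.copy()

    def predict(self):
        self.x = self.F @ self.x
        self.P = self.F @ self.P @ self.F.T + self.Q

    def update(self, z):
        S = self.H @ self.P @ self.H.T + self.R
        K = self.P @ self.H.T @ np.linalg.inv(S)
        self.x = self.x + K @ (z - self.H @ self.x)
        self.P = self.P - K @ S @ K.T


class TestUtWeights:
    def test_closed_form_example(self):
        Wm, Wc, lam = ut_weights(2, alpha=1.0, beta=0.0, kappa=1.0)
        assert np.isclose(lam, 1.0)
        assert np.isclose(Wm[0], 1.0 / 3.0)
        assert np.allclose(Wm[1:], 1.0 / 6.0)

    def test_mean_weights_sum_to_one(self):
        for n, alpha, kappa in [(1, 0.5, 0.0), (4, 1e-3, 0.0), (8, 1.0, 3.0)]:
            Wm, _, _ = ut_weights(n, alpha, 2.0, kappa)
            assert np.isclose(Wm.sum(), 1.0)

    def test_wc0_equals_wm0_when_alpha_one_beta_zero(self):
        Wm, Wc, _ = ut_weights(3, alpha=1.0, beta=0.0, kappa=1.0)
        assert np.isclose(Wc[0], Wm[0])
        assert np.allclose(Wc[1:], Wm[1:])

    def test_invalid_spread_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ut_weights(2, alpha=1.0, beta=0.0, kappa=-2.0)
        with pytest.raises(ValueError, match="alpha"):
            ut_weights(2, alpha=0.0, beta=0.0, kappa=0.0)


class TestSigmaPoints:
    def test_scalar_closed_form(self):
        # n=1, lambda=2: points are {0, +sqrt(3), -sqrt(3)}
        params = UKFParams(n=1, alpha=1.0, beta=0.0, kappa=2.0,
                           Q=np.zeros((1, 1)), R=np.eye(1))
        pts = sigma_points(np.zeros(1), np.ones((1, 1)), params)
        assert np.allclose(sorted(pts[:, 0]), [-np.sqrt(3), 0, np.sqrt(3)])

    @pytest.mark.parametrize("n", [1, 2, 4, 8])
    def test_moment_reconstruction(self, n):
        """Weighted sigma-point mean is x; covariance rebuilds P to 1e-10."""
        rng = np.random.default_rng(n)
        A = rng.normal(size=(n, n)) / np.sqrt(n)
        P = A @ A.T + 0.5 * np.eye(n)
        x = rng.normal(size=n)
        params = UKFParams(n=n, alpha=1e-3, beta=2.0, kappa=0.0,
                           Q=np.zeros((n, n)), R=np.eye(1))
        pts = sigma_points(x, P, params)
        mean = params.Wm @ pts
        dev = pts - mean
        cov = dev.T @ (params.Wc[:, None] * dev)
        assert np.abs(mean - x).max() < 1e-9
        assert np.abs(cov - P).max() < 1e-10

    def test_indefinite_covariance_reported(self):
        params = UKFParams(n=2, alpha=1.0, beta=0.0, kappa=1.0)
        P = np.array([[1.0, 0.0], [0.0, -1.0]])
        with pytest.raises(np.linalg.LinAlgError, match="eigenvalue"):
            sigma_points(np.zeros(2), P, params)


class TestPredictUpdate:
    def _params(self, Q=None, R=None):
        return UKFParams(n=4, alpha=1e-3, beta=2.0, kappa=0.0,
                         Q=np.zeros((4, 4)) if Q is None else Q,
                         R=np.eye(2) if R is None else R)

    def test_identity_transition_is_fixed_point(self):
        fns = ukf_mod.ModelFns(f=lambda s: s, h=lambda s: s[:2])
        state = UKFState(np.array([1.0, 2, 3, 4]), np.diag([1.0, 2, 3, 4]))
        prior = ukf_mod.predict(state, fns, self._params())
        assert np.allclose(prior.x, state.x, atol=1e-9)
        assert np.allclose(prior.P, state.P, atol=1e-9)

    def test_constant_velocity_propagation(self):
        state = UKFState(np.array([0.0, 0.0, 1.0, 2.0]), np.eye(4))
        prior = ukf_mod.predict(state, constant_velocity_fns(), self._params())
        assert np.allclose(prior.x[:2], [1.0, 2.0], atol=1e-9)

    def test_linear_prior_covariance_matches_closed_form(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(4, 4))
        P = A @ A.T + np.eye(4)
        Q = cv_process_noise(0.7)
        state = UKFState(rng.normal(size=4), P)
        F = np.eye(4)
        F[0, 2] = F[1, 3] = 1.0
        prior = ukf_mod.predict(state, constant_velocity_fns(),
                                self._params(Q=Q))
        assert np.allclose(prior.P, F @ P @ F.T + Q, atol=1e-9)

    def test_zero_innovation_keeps_prior_mean(self):
        params = self._params(Q=cv_process_noise(0.5))
        fns = constant_velocity_fns()
        prior = UKFState(np.array([5.0, 6.0, 1.0, 1.0]), np.eye(4))
        post = ukf_mod.update(prior, prior.x[:2], fns, params)
        assert np.allclose(post.x, prior.x, atol=1e-12)

    def test_vanishing_measurement_noise_trusts_measurement(self):
        params = UKFParams(n=1, alpha=1.0, beta=0.0, kappa=2.0,
                           Q=np.zeros((1, 1)), R=np.array([[1e-14]]))
        fns = ukf_mod.ModelFns(f=lambda s: s, h=lambda s: s)
        prior = UKFState(np.array([1.0]), np.array([[4.0]]))
        post = ukf_mod.update(prior, np.array([3.0]), fns, params)
        assert np.isclose(post.x[0], 3.0, atol=1e-6)

    def test_update_never_increases_covariance_trace(self):
        rng = np.random.default_rng(5)
        params = self._params(R=4.0 * np.eye(2))
        fns = constant_velocity_fns()
        for _ in range(20):
            A = rng.normal(size=(4, 4))
            prior = UKFState(rng.normal(size=4), A @ A.T + 0.1 * np.eye(4))
            post = ukf_mod.update(prior, rng.normal(size=2), fns, params)
            assert np.trace(post.P) <= np.trace(prior.P) + 1e-9

    def test_matches_linear_kalman_filter_over_50_steps(self):
        """Oracle equivalence on a linear-Gaussian CV system to 1e-8."""
        rng = np.random.default_rng(42)
        F = np.eye(4)
        F[0, 2] = F[1, 3] = 1.0
        H = np.zeros((2, 4))
        H[0, 0] = H[1, 1] = 1.0
        Q = cv_process_noise(0.5)
        R = 4.0 * np.eye(2)
        x0 = np.array([0.0, 0.0, 1.0, -0.5])
        P0 = 10.0 * np.eye(4)

        kf = LinearKF(F, H, Q, R, x0, P0)
        # alpha=1: unit sigma-point spread, O(1) weights (the equivalence is
        # exact for any valid spread; small alpha only adds float noise)
        params = UKFParams(n=4, alpha=1.0, beta=2.0, kappa=0.0, Q=Q, R=R)
        fns = constant_velocity_fns()
        state = UKFState(x0, P0)

        truth = x0.copy()
        for _ in range(50):
            truth = F @ truth + rng.multivariate_normal(np.zeros(4), Q)
            z = H @ truth + rng.multivariate_normal(np.zeros(2), R)
            kf.predict()
            kf.update(z)
            state = ukf_mod.predict(state, fns, params)
            state = ukf_mod.update(state, z, fns, params)
            assert np.abs(state.x - kf.x).max() < 1e-8
            assert np.abs(state.P - kf.P).max() < 1e-8

    def test_nonlinear_model_filters_below_measurement_noise(self):
        """Generic engine on a non-linear oscillator: filtered position RMSE
        beats the raw measurements."""
        rng = np.random.default_rng(7)
        dt, omega = 1.0, 0.35

        def f(s):  # position, velocity with sinusoidal restoring force
            x, v = s
            return np.array([x + dt * v, v - dt * 8.0 * np.sin(omega * x)])

        def h(s):
            return s[:1]

        Q = np.diag([1e-4, 1e-3])
        R = np.array([[4.0]])
        params = UKFParams(n=2, alpha=1e-3, beta=2.0, kappa=1.0, Q=Q, R=R)
        fns = ukf_mod.ModelFns(f=f, h=h)
        truth = np.array([1.0, 0.0])
        state = UKFState(np.array([0.5, 0.0]), np.eye(2))
        err_filt, err_meas = [], []
        for _ in range(80):
            truth = f(truth)
            z = truth[:1] + rng.normal(0, 2.0, size=1)
            state = ukf_mod.predict(state, fns, params)
            state = ukf_mod.update(state, z, fns, params)
            err_filt.append((state.x[0] - truth[0]) ** 2)
            err_meas.append((z[0] - truth[0]) ** 2)
        assert np.sqrt(np.mean(err_filt)) < np.sqrt(np.mean(err_meas))

    def test_filtering_beats_raw_measurement_noise(self):
        """Constant-velocity tracks with noise sd 2: filtered position RMSE
        below the measurement noise, aggregated over 200 seeded runs."""
        sigma = 2.0
        F = np.eye(4)
        F[0, 2] = F[1, 3] = 1.0
        params = UKFParams(n=4, alpha=1e-3, beta=2.0, kappa=0.0,
                           Q=cv_process_noise(0.05), R=sigma**2 * np.eye(2))
        fns = constant_velocity_fns()
        sq_filt = []
        rng = np.random.default_rng(11)
        for _ in range(200):
            truth = np.array([0.0, 0.0, *rng.uniform(-2, 2, 2)])
            state = UKFState(truth + rng.normal(0, 1, 4), 5.0 * np.eye(4))
            for _ in range(30):
                truth = F @ truth
                z = truth[:2] + rng.normal(0, sigma, 2)
                state = ukf_mod.predict(state, fns, params)
                state = ukf_mod.update(state, z, fns, params)
            sq_filt.append(np.sum((state.x[:2] - truth[:2]) ** 2))
        rmse = np.sqrt(np.mean(sq_filt) / 2)
        assert rmse < sigma


class TestRecoverSequence:
    def test_no_missing_values_is_identity(self, tiny_init_model,
                                           small_cohort):
        out = recover_sequence(small_cohort[0], tiny_init_model)
        assert np.array_equal(out.coords, small_cohort[0].coords)

    def test_exact_constant_velocity_recovery(self, recurrence_oracle):
        """Noiseless CV track + perfect pseudo-measurements: recovered
        positions match ground truth to < 1e-6 px."""
        from recovgait import GaitSequence, Label
        t = np.arange(50)[:, None, None]
        base = np.linspace(100, 400, 34).reshape(17, 2)[None]
        vel = np.linspace(0.5, 2.0, 34).reshape(17, 2)[None]
        coords = base + vel * t
        truth = GaitSequence("cv", Label.UNKNOWN, coords)

        class CVOracle:
            window = 5
            holdout_mse = 1e-10

            def predict_next(self, windows, kp, axis):
                windows = np.atleast_2d(windows)
                return 2.0 * windows[:, -1] - windows[:, -2]

            def holdout_mse_px(self, kp, axis):
                return 1e-10

        occluded = simulate_missing(
            truth, OcclusionSpec(groups=(BodyPart.LEGS,), missing_frames=10))
        out = recover_sequence(occluded, CVOracle(),
                               default_keypoint_params())
        missing = ~occluded.visibility
        err = np.abs(out.coords - truth.coords)[missing]
        assert err.max() < 1e-6

    def test_observed_coordinates_pass_through(self, tiny_init_model,
                                               small_cohort):
        occluded = simulate_missing(
            small_cohort[5],
            OcclusionSpec(groups=(BodyPart.LEGS,), missing_frames=40))
        out = recover_sequence(occluded, tiny_init_model)
        vis = occluded.visibility
        assert np.array_equal(out.coords[vis], occluded.coords[vis])
        assert int(np.sum(out.sentinel_mask())) == 0

    def test_ukf_only_needs_two_observed_frames(self):
        seq = generate_subject(HEALTHY_PROFILE, seed=1)
        occluded = simulate_missing(
            seq, OcclusionSpec(groups=(BodyPart.HEAD,), missing_frames=49))
        with pytest.raises(ValueError, match="two observed frames"):
            ukf_only_recover(occluded)

    def test_ukf_only_tracks_linear_drift(self):
        """Predict-only coasting recovers a constant-velocity suffix."""
        from recovgait import GaitSequence, Label
        t = np.arange(50)[:, None, None]
        coords = (np.full((17, 2), 100.0)[None]
                  + np.full((17, 2), 1.5)[None] * t)
        truth = GaitSequence("lin", Label.UNKNOWN, coords)
        occluded = simulate_missing(
            truth, OcclusionSpec(groups=(BodyPart.LEGS,), missing_frames=20))
        out = ukf_only_recover(occluded)
        missing = ~occluded.visibility
        assert np.abs(out.coords - truth.coords)[missing].max() < 1e-6
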