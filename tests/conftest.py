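import numpy as np
import pytest

from recovgait import (GatedInitConfig, HEALTHY_PROFILE, PD_PROFILE,
                       generate_subject, make_dataset)
from recovgait import gated_init


@pytest.fixture(scope="session")
def small_cohort():
    """Unaugmented 6 PD + 6 healthy subjects, 50 frames."""
    return make_dataset(6, 6, seed=11, augmented=False)


@pytest.fixture(scope="session")
def clean_subject():
    """One noiseless healthy walking sequence (analytic kinematics)."""
    from dataclasses import replace
    profile = replace(HEALTHY_PROFILE, jitter_sd=0.0)
    return generate_subject(profile, frames=50, seed=3)


@pytest.fixture(scope="session")
def tiny_init_model(small_cohort):
    """A quickly trained small gated init model shared across tests."""
    cfg = GatedInitConfig(hidden_units=16, epochs=12, max_windows=4000, seed=5)
    return gated_init.train(small_cohort[:8], cfg)


class RecurrenceOracle:
    """Exact next-value predictor for the noiseless synthetic kinematics.

    Every noiseless coordinate series is a sum of a linear ramp, a
    sinusoid at the gait frequency and one at its double, so it satisfies
    a linear recurrence whose characteristic roots are
    {1, 1, e^{+-i w}, e^{+-2i w}} — order six, inside a 7-frame window.
    Serves as an independent stand-in for a perfectly trained model.
    """

    def __init__(self, cadence, holdout_mse=1e-12):
        w = 2 * np.pi * cadence
        roots = [1.0, 1.0, np.exp(1j * w), np.exp(-1j * w),
                 np.exp(2j * w), np.exp(-2j * w)]
        self.coeffs = np.real(np.poly(roots))  # monic, degree 6
        self.window = 7
        self.holdout_mse = holdout_mse
        self.config = GatedInitConfig(window=7)

    def predict_next(self, windows, kp, axis):
        windows = np.atleast_2d(windows)
        # x_t = -(c1 x_{t-1} + ... + c6 x_{t-6}); window rows are oldest-first
        past = windows[:, ::-1][:, :6]
        return -past @ self.coeffs[1:]

    def holdout_mse_px(self, kp, axis):
        return self.holdout_mse


@pytest.fixture(scope="session")
def recurrence_oracle():
    return RecurrenceOracle(cadence=HEALTHY_PROFILE.cadence)
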