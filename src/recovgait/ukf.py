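"""Unscented Kalman filtering over per-keypoint constant-velocity states,
with pseudo-measurement fusion of gated-model predictions during occlusion.

The engine is a generic scaled unscented transform: 2n+1 sigma points

    X0 = x,   Xi = x +/- column_i( sqrt((n + lambda) P) ),

with lambda = alpha^2 (n + kappa) - n and the standard weight set
Wm0 = lambda/(n+lambda), Wc0 = Wm0 + 1 - alpha^2 + beta,
Wmi = Wci = 1/(2(n+lambda)).  Prediction propagates the points through the
state-transition function and reconstructs moments; the update maps them
through the measurement function, forms the innovation covariance S and
cross covariance Pxz, and applies the Kalman gain K = Pxz S^-1.

For keypoint tracking each joint carries an independent 4-state filter
[x, y, vx, vy] with a constant-velocity transition (dt = 1 frame) and
position-only measurements — linear here, but the engine accepts arbitrary
non-linear f and h.  While a keypoint is occluded there is no observation,
so the gated model's iteratively reconstructed coordinate is fused as a
pseudo-measurement with inflated measurement noise: the filter then acts
as a dynamics-consistent smoother of the recurrent imputations, which is
what lets the combination outperform either component alone.  By default
the inflation is calibrated per keypoint from the observed prefix (see
:func:`recover_sequence`); a fixed ``r_pseudo_scale * R`` inflation is
available as a fallback.  Covariance hygiene: P is re-symmetrized each
step, the Cholesky factorization climbs a jitter ladder on failure, and
posterior eigenvalues are floored at zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .sequences import GaitSequence
from .skeleton import N_KEYPOINTS

logger = logging.getLogger(__name__)

__all__ = [
    "UKFParams",
    "UKFState",
    "ModelFns",
    "ut_weights",
    "sigma_points",
    "predict",
    "update",
    "constant_velocity_fns",
    "cv_process_noise",
    "recover_sequence",
    "ukf_only_recover",
    "default_keypoint_params",
]

_JITTERS = (0.0, 1e-12, 1e-10, 1e-8, 1e-6)


def ut_weights(n: int, alpha: float, beta: float, kappa: float,
               ) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled unscented-transform weights ``(Wm, Wc, lambda)``."""
    if n < 1:
        raise ValueError("state dimension must be >= 1")
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    lam = alpha**2 * (n + kappa) - n
    if n + lam <= 0:
        raise ValueError(
            f"n + lambda = {n + lam} must be positive "
            f"(alpha={alpha}, kappa={kappa}, n={n})"
        )
    Wm = np.full(2 * n + 1, 1.0 / (2.0 * (n + lam)))
    Wc = Wm.copy()
    Wm[0] = lam / (n + lam)
    Wc[0] = Wm[0] + 1.0 - alpha**2 + beta
    return Wm, Wc, lam


@dataclass
class UKFParams:
    """Unscented-transform configuration and noise model."""

    n: int = 4
    alpha: float = 1e-3
    beta: float = 2.0
    kappa: float = 0.0
    Q: np.ndarray = None  # type: ignore[assignment]
    R: np.ndarray = None  # type: ignore[assignment]
    r_pseudo_scale: float = 10.0
    Wm: np.ndarray = field(init=False)
    Wc: np.ndarray = field(init=False)
    lam: float = field(init=False)

    def __post_init__(self) -> None:
        self.Wm, self.Wc, self.lam = ut_weights(
            self.n, self.alpha, self.beta, self.kappa)
        if self.Q is None:
            self.Q = np.zeros((self.n, self.n))
        self.Q = np.asarray(self.Q, dtype=float)
        if self.R is not None:
            self.R = np.asarray(self.R, dtype=float)
        if self.r_pseudo_scale < 1.0:
            raise ValueError("r_pseudo_scale must be >= 1")


@dataclass
class UKFState:
    """State estimate and covariance."""

    x: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.P = _symmetrize(np.asarray(self.P, dtype=float))


@dataclass
class ModelFns:
    """State-transition f and measurement h (vector -> vector callables)."""

    f: Callable[[np.ndarray], np.ndarray]
    h: Callable[[np.ndarray], np.ndarray]


def _symmetrize(P: np.ndarray) -> np.ndarray:
    return 0.5 * (P + P.T)


def _floor_eigenvalues(P: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    P = _symmetrize(P)
    w, V = np.linalg.eigh(P)
    if w[0] >= -tol and w[0] >= 0:
        return P
    w = np.clip(w, 0.0, None)
    return _symmetrize((V * w) @ V.T)


def sigma_points(x: np.ndarray, P: np.ndarray, params: UKFParams) -> np.ndarray:
    """(2n+1, n) sigma-point set for mean x and covariance P."""
    x = np.asarray(x, dtype=float)
    n = params.n
    M = _symmetrize((n + params.lam) * np.asarray(P, dtype=float))
    L = None
    for jitter in _JITTERS:
        try:
            L = np.linalg.cholesky(M + jitter * np.eye(n))
            break
        except np.linalg.LinAlgError:
            continue
    if L is None:
        smallest = float(np.linalg.eigvalsh(M)[0])
        raise np.linalg.LinAlgError(
            f"covariance not positive definite after jitter escalation "
            f"(smallest eigenvalue of (n+lambda)P: {smallest:.3e})"
        )
    pts = np.empty((2 * n + 1, n))
    pts[0] = x
    pts[1:n + 1] = x + L.T  # row i holds column i of L
    pts[n + 1:] = x - L.T
    return pts


def predict(state: UKFState, fns: ModelFns, params: UKFParams) -> UKFState:
    """Time update: propagate sigma points through f, add process noise."""
    pts = sigma_points(state.x, state.P, params)
    prop = np.array([fns.f(p) for p in pts])
    if not np.all(np.isfinite(prop)):
        raise FloatingPointError("non-finite state after transition function")
    mean = params.Wm @ prop
    dev = prop - mean
    P = dev.T @ (params.Wc[:, None] * dev) + params.Q
    return UKFState(mean, _symmetrize(P))


def update(prior: UKFState, z: np.ndarray, fns: ModelFns, params: UKFParams,
           r_scale: float = 1.0, R: np.ndarray | None = None) -> UKFState:
    """Measurement update.

    ``r_scale`` inflates the measurement noise; ``R`` optionally replaces
    ``params.R`` for this update (used for pseudo-measurements whose noise
    level is calibrated rather than fixed).
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite measurement")
    if r_scale < 1.0:
        raise ValueError("r_scale must be >= 1")
    R_eff = params.R if R is None else np.asarray(R, dtype=float)
    pts = sigma_points(prior.x, prior.P, params)
    Z = np.array([fns.h(p) for p in pts])
    z_hat = params.Wm @ Z
    dz = Z - z_hat
    dx = pts - prior.x
    S = dz.T @ (params.Wc[:, None] * dz) + r_scale * R_eff
    Pxz = dx.T @ (params.Wc[:, None] * dz)
    try:
        K = np.linalg.solve(S.T, Pxz.T).T
    except np.linalg.LinAlgError:
        warnings.warn("singular innovation covariance; using pseudo-inverse",
                      stacklevel=2)
        K = Pxz @ np.linalg.pinv(S)
    x = prior.x + K @ (z - z_hat)
    P = prior.P - K @ S @ K.T
    return UKFState(x, _floor_eigenvalues(P))


def constant_velocity_fns(dt: float = 1.0) -> ModelFns:
    """Linear constant-velocity instantiation of the generic engine.

    State [x, y, vx, vy]; the measurement extracts position.
    """
    F = np.array([
        [1.0, 0.0, dt, 0.0],
        [0.0, 1.0, 0.0, dt],
        [0.0, 0.0, 1.0, 0.0],
        [0.0, 0.0, 0.0, 1.0],
    ])
    H = np.array([
        [1.0, 0.0, 0.0, 0.0],
        [0.0, 1.0, 0.0, 0.0],
    ])
    return ModelFns(f=lambda s: F @ s, h=lambda s: H @ s)


def cv_process_noise(sigma_q: float, dt: float = 1.0) -> np.ndarray:
    """Discrete white-noise-acceleration Q for the [x, y, vx, vy] state."""
    q2 = sigma_q**2
    a = dt**4 / 4.0
    b = dt**3 / 2.0
    c = dt**2
    block = q2 * np.array([[a, b], [b, c]])
    Q = np.zeros((4, 4))
    for i in (0, 1):  # x with vx, y with vy
        Q[i, i] = block[0, 0]
        Q[i, i + 2] = block[0, 1]
        Q[i + 2, i] = block[1, 0]
        Q[i + 2, i + 2] = block[1, 1]
    return Q


def default_keypoint_params(sigma_q: float = 3.0, sigma_r: float = 2.0,
                            r_pseudo_scale: float = 10.0,
                            alpha: float = 1e-3, beta: float = 2.0,
                            kappa: float = 0.0) -> UKFParams:
    """Per-keypoint tracking parameters.

    ``sigma_q`` (px/frame^2) is set from the curvature scale of gait:
    an oscillation of ~20 px amplitude at ~0.08 cycles/frame peaks at
    about A * omega^2 ~ 5 px/frame^2 of acceleration, so a value of a few
    px/frame^2 lets the constant-velocity model follow limb swing instead
    of over-smoothing it.  ``sigma_r`` (px) is the detector noise scale.
    """
    return UKFParams(
        n=4, alpha=alpha, beta=beta, kappa=kappa,
        Q=cv_process_noise(sigma_q),
        R=sigma_r**2 * np.eye(2),
        r_pseudo_scale=r_pseudo_scale,
    )


def _run_filter(seq: GaitSequence, keypoint: int, t0: int,
                state: UKFState, fns: ModelFns, params: UKFParams,
                pseudo: np.ndarray | None,
                pseudo_R: tuple | None = None,
                depth_growth: bool = False,
                chain_profile: np.ndarray | None = None) -> np.ndarray:
    """Filter one keypoint from t0 to the end; returns (frames, 2) positions
    for the filtered span (posterior positions at every step >= t0).

    ``pseudo_R`` is a ``(floor, excess)`` pair of per-axis variance arrays
    for pseudo-measurements (``None`` falls back to the fixed inflation
    ``r_pseudo_scale * R``).  With ``depth_growth`` the noise applied at
    gap depth d is ``floor + g(d) * excess``: only the imputer's error in
    excess of the irreducible observation noise accumulates along a
    chained prediction, so a near-noise-floor imputer keeps the filter
    glued to its values while a drifting one gets progressively smoothed.
    The growth law g(d) is the model's measured chain-error profile when
    available, else linear in d.
    """
    out = np.empty((seq.n_frames - t0, 2))
    depth = 0
    for t in range(t0, seq.n_frames):
        if t > t0:
            state = predict(state, fns, params)
        if seq.visibility[t, keypoint]:
            depth = 0
            state = update(state, seq.coords[t, keypoint], fns, params,
                           r_scale=1.0)
        elif pseudo is not None:
            depth += 1
            if pseudo_R is None:
                state = update(state, pseudo[t], fns, params,
                               r_scale=params.r_pseudo_scale)
            else:
                floor, excess = pseudo_R
                if not depth_growth:
                    scale = 1.0
                elif chain_profile is not None:
                    scale = chain_profile[min(depth - 1,
                                              len(chain_profile) - 1)]
                else:
                    scale = depth
                state = update(state, pseudo[t], fns, params,
                               R=np.diag(floor + scale * excess))
        # else: predict-only coast through the gap
        if not np.all(np.isfinite(state.x)):
            raise FloatingPointError(
                f"non-finite posterior at frame {t + 1}, keypoint {keypoint}")
        out[t - t0] = state.x[:2]
    return out


def _prefix_one_step_mse(init_model, seq: GaitSequence, keypoint: int,
                         t0: int, floor: float) -> np.ndarray:
    """Per-axis one-step prediction MSE of the gated model on the observed
    prefix of one keypoint — the calibrated pseudo-measurement noise base."""
    w = init_model.window
    mses = np.full(2, floor)
    n = t0 - w
    if n < 1:
        return mses
    for ax in (0, 1):
        series = seq.coords[:t0, keypoint, ax]
        windows = np.stack([series[t - w:t] for t in range(w, t0)])
        preds = init_model.predict_next(
            windows, np.full(n, keypoint), np.full(n, ax))
        mses[ax] = max(float(np.mean((preds - series[w:t0]) ** 2)), floor)
    return mses


def _prefix_sigma_q(seq: GaitSequence, keypoint: int, t0: int,
                    floor: float) -> float:
    """White-acceleration scale from second differences of the observed
    prefix trajectory."""
    prefix = seq.coords[:t0, keypoint, :]
    if len(prefix) < 3:
        return max(3.0, floor)
    acc = np.diff(prefix, n=2, axis=0)
    return max(float(np.std(acc)), floor)


def _prefix_jitter_sd(prefix: np.ndarray, floor: float = 0.05) -> float:
    """Measurement-noise sd from third differences: for a smooth signal
    plus white noise, E[d3^2] = 20 sigma^2 with little curvature leakage."""
    if len(prefix) < 4:
        return max(1.0, floor)
    d3 = np.diff(prefix, n=3, axis=0)
    return max(float(np.sqrt(np.mean(d3**2) / 20.0)), floor)


def _smooth_prefix(seq: GaitSequence, keypoint: int, t0: int,
                   sigma_q: float, params: UKFParams) -> np.ndarray:
    """Forward-filter the observed prefix of one keypoint.

    Returns denoised (t0, 2) positions used only to seed the gated
    imputation chain; the sequence's observed outputs are never altered.
    """
    prefix = seq.coords[:t0, keypoint, :]
    if t0 < 3:
        return prefix.copy()
    sr = _prefix_jitter_sd(prefix)
    kp_params = UKFParams(
        n=4, alpha=params.alpha, beta=params.beta, kappa=params.kappa,
        Q=cv_process_noise(sigma_q), R=sr**2 * np.eye(2))
    fns = constant_velocity_fns()
    x0 = np.array([*prefix[1], *(prefix[1] - prefix[0])])
    state = UKFState(x0, np.diag([sr**2, sr**2, 2 * sr**2, 2 * sr**2]))
    out = prefix.copy()
    for t in range(2, t0):
        state = predict(state, fns, kp_params)
        state = update(state, prefix[t], fns, kp_params)
        out[t] = state.x[:2]
    return out


def recover_sequence(seq: GaitSequence, init_model,
                     params: UKFParams | None = None, *,
                     calibrate: bool = True,
                     validate: bool = True,
                     val_frames: int = 4,
                     min_sigma_q: float = 0.3,
                     min_pseudo_var: float = 0.05) -> GaitSequence:
    """Recover missing keypoints: gated initialization + unscented tracking.

    With ``validate`` (the default, calibrated mode only) each missing
    keypoint's fusion is checked against held-out evidence: a short
    artificial gap is carved from the tail of the observed prefix, both
    the fused and the gated-only reconstructions are scored against the
    actually observed frames there, and the losing arm is discarded for
    that keypoint.  The filter is thus applied exactly where the
    subject's own data says it helps.

    See :func:`_recover_fused` for the fusion mechanics.
    """
    if not (calibrate and validate):
        return _recover_fused(seq, init_model, params, calibrate=calibrate,
                              min_sigma_q=min_sigma_q,
                              min_pseudo_var=min_pseudo_var)
    from .gated_init import iterative_reconstruct

    missing = ~seq.visibility
    if not missing.any():
        return seq.copy()
    kws = dict(calibrate=True, min_sigma_q=min_sigma_q,
               min_pseudo_var=min_pseudo_var)
    fused = _recover_fused(seq, init_model, params, **kws)
    gated = iterative_reconstruct(init_model, seq)
    kps = np.flatnonzero(missing.any(axis=0))
    t0s = {k: int(np.argmax(missing[:, k])) for k in kps}
    w = init_model.window
    # validation copy: extend each gap backwards into observed territory
    val_coords = seq.coords.copy()
    val_starts = {}
    for k in kps:
        v0 = t0s[k] - val_frames
        if v0 >= w:
            val_coords[v0:, k, :] = 0.0
            val_starts[k] = v0
    out = seq.copy()
    if val_starts:
        val_seq = GaitSequence(seq.subject_id, seq.label, val_coords)
        val_fused = _recover_fused(val_seq, init_model, params, **kws)
        val_gated = iterative_reconstruct(init_model, val_seq)
    for k in kps:
        fill = missing[:, k]
        src = fused
        if k in val_starts:
            v0, t0 = val_starts[k], t0s[k]
            truth = seq.coords[v0:t0, k, :]
            err_f = np.sum((val_fused.coords[v0:t0, k, :] - truth) ** 2)
            err_g = np.sum((val_gated.coords[v0:t0, k, :] - truth) ** 2)
            if err_g < err_f:
                src = gated
        out.coords[fill, k, :] = src.coords[fill, k, :]
        out.imputed[fill, k] = True
    return out


def _recover_fused(seq: GaitSequence, init_model,
                   params: UKFParams | None = None, *,
                   calibrate: bool = True,
                   min_sigma_q: float = 0.3,
                   min_pseudo_var: float = 0.05) -> GaitSequence:
    """Pseudo-measurement fusion pass of the combined recovery.

    Per missing keypoint, the gated model's iterative reconstruction
    supplies both the filter's initial state at the first missing frame
    and the pseudo-measurements fused wherever the keypoint stays
    occluded; real observations are fused with plain R.  Observed
    coordinates pass through unchanged.

    With ``calibrate`` (the default) the tracker and the imputer are
    coupled both ways and the noise model is measured from the data
    instead of fixed:

    * the observed prefix of each missing keypoint is forward-filtered
      (measurement noise estimated from third differences) and the
      denoised positions seed the gated imputation chain — noisy seed
      windows are what chained imputation amplifies most;
    * the process-noise scale comes from the second differences of the
      observed prefix (the trajectory's true curvature scale);
    * the pseudo-measurement noise comes from the gated model's one-step
      prediction errors on that same prefix (shrunk halfway toward the
      within-subject cross-keypoint mean — the prefix offers only a
      handful of error samples per channel), decomposed into the
      irreducible observation-noise floor plus a model-excess part that
      grows with gap depth along the model's measured chain-error
      profile, as chained imputation error accumulates.

    With ``calibrate=False`` the pseudo-measurement noise is the fixed
    inflation ``r_pseudo_scale * R`` and the raw prefix seeds the chain.

    A keypoint whose filter diverges falls back to the gated-only
    reconstruction with a logged failure.
    """
    from .gated_init import initial_state, iterative_reconstruct

    if params is None:
        params = default_keypoint_params()
    out = seq.copy()
    missing = ~seq.visibility
    if not missing.any():
        return out
    fns = constant_velocity_fns()
    kps = np.flatnonzero(missing.any(axis=0))
    work = seq  # sequence feeding the imputation chain
    sigma_qs: dict[int, float] = {}
    prefix_mses: dict[int, np.ndarray] = {}
    if calibrate:
        work = seq.copy()
        for k in kps:
            t0 = int(np.argmax(missing[:, k]))
            sigma_qs[k] = _prefix_sigma_q(seq, k, t0, min_sigma_q)
            prefix_mses[k] = _prefix_one_step_mse(init_model, seq, k, t0,
                                                  min_pseudo_var)
            work.coords[:t0, k, :] = _smooth_prefix(seq, k, t0,
                                                    sigma_qs[k], params)
        mse_pool = np.mean(np.stack(list(prefix_mses.values())), axis=0)
    recon = iterative_reconstruct(init_model, work)
    for k in kps:
        t0 = int(np.argmax(missing[:, k]))
        x0, P0 = initial_state(init_model, work, t0, k, reconstructed=recon)
        if calibrate:
            kp_params = UKFParams(
                n=4, alpha=params.alpha, beta=params.beta, kappa=params.kappa,
                Q=cv_process_noise(sigma_qs[k]),
                R=params.R, r_pseudo_scale=params.r_pseudo_scale)
            mse = 0.5 * prefix_mses[k] + 0.5 * mse_pool
            jitter_var = _prefix_jitter_sd(seq.coords[:t0, k, :]) ** 2
            floor = np.maximum(np.minimum(mse, jitter_var), min_pseudo_var)
            excess = np.maximum(mse - jitter_var, 0.0)
            pseudo_R = (floor, excess)
        else:
            kp_params, pseudo_R = params, None
        try:
            track = _run_filter(seq, k, t0, UKFState(x0, P0), fns, kp_params,
                                pseudo=recon.coords[:, k, :],
                                pseudo_R=pseudo_R, depth_growth=calibrate,
                                chain_profile=getattr(init_model,
                                                      "chain_profile", None))
        except FloatingPointError as exc:
            logger.warning("keypoint %d recovery failed (%s); "
                           "falling back to gated-only values", k, exc)
            track = recon.coords[t0:, k, :]
        fill = missing[t0:, k]
        out.coords[t0:, k, :][fill] = track[fill]
        out.imputed[t0:, k][fill] = True
    return out


def ukf_only_recover(seq: GaitSequence, params: UKFParams | None = None,
                     init_window: int = 5,
                     init_pos_var: float = 100.0,
                     init_vel_var: float = 25.0) -> GaitSequence:
    """Recovery by unscented tracking alone (no gated model).

    The filter is initialized from the last two observed frames before the
    gap (position plus finite-difference velocity) with a large diagonal
    covariance, then coasts predict-only through missing frames, updating
    only where real observations exist.
    """
    if params is None:
        params = default_keypoint_params()
    out = seq.copy()
    missing = ~seq.visibility
    if not missing.any():
        return out
    fns = constant_velocity_fns()
    for k in np.flatnonzero(missing.any(axis=0)):
        t0 = int(np.argmax(missing[:, k]))
        if t0 < 2 or not seq.visibility[t0 - 2:t0, k].all():
            raise ValueError(
                f"keypoint {k}: needs two observed frames before the first "
                f"missing frame {t0 + 1}"
            )
        pos = seq.coords[t0 - 1, k]
        vel = pos - seq.coords[t0 - 2, k]
        x0 = np.array([pos[0] + vel[0], pos[1] + vel[1], vel[0], vel[1]])
        P0 = np.diag([init_pos_var, init_pos_var, init_vel_var, init_vel_var])
        track = _run_filter(seq, k, t0, UKFState(x0, P0), fns, params,
                            pseudo=None)
        fill = missing[t0:, k]
        out.coords[t0:, k, :][fill] = track[fill]
        out.imputed[t0:, k][fill] = True
    return out
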