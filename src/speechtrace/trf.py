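"""Ridge-regression temporal response functions (TRFs).

A TRF is the linear kernel w(channel, lag) mapping the speech amplitude
envelope to the EEG response.  With S the lagged envelope design matrix
(lags -300..+600 ms on a 10 ms grid, 91 columns) and r the EEG trial, the
ridge solution is

    w = (S'S + lambda*I)^-1 S'r,        lambda = 100 by default.

Envelopes are scaled to unit variance without demeaning (shape
preserved); EEG is z-scored per channel over the fitted window.  TRFs are
fit per trial and averaged within condition x session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .envelope import EnvelopeSeries
from .montage import ROI_CHANNELS

LAG_MIN_MS = -300
LAG_MAX_MS = 600
LAG_STEP_MS = 10
RIDGE_LAMBDA = 100.0


@dataclass
class LaggedDesign:
    matrix: np.ndarray          # (n_times, n_lags)
    lags_ms: np.ndarray         # lag grid in ms


@dataclass
class TRFKernel:
    weights: np.ndarray         # (n_channels, n_lags)
    lags_ms: np.ndarray
    channels: list[str]
    lam: float = RIDGE_LAMBDA
    meta: dict = field(default_factory=dict)


def lag_grid_ms(lag_min: float = LAG_MIN_MS, lag_max: float = LAG_MAX_MS,
                step: float = LAG_STEP_MS) -> np.ndarray:
    if lag_min >= lag_max:
        raise ValueError("lag_min must be < lag_max")
    return np.arange(lag_min, lag_max + step / 2, step)


def lagged_design(env, rate: float = 100.0, lag_min: float = LAG_MIN_MS,
                  lag_max: float = LAG_MAX_MS,
                  step: float = LAG_STEP_MS) -> LaggedDesign:
    """Time x lag design matrix; out-of-range samples are zero-filled.

    Column k at row t holds the envelope at time t - lag_k, so positive
    lags describe the response following the stimulus.
    """
    if isinstance(env, EnvelopeSeries):
        rate = env.rate
        env = env.values
    x = np.asarray(env, float)
    lags = lag_grid_ms(lag_min, lag_max, step)
    shifts = np.round(lags / 1000.0 * rate).astype(int)
    n = len(x)
    M = np.zeros((n, len(lags)))
    for k, s in enumerate(shifts):
        if s >= 0:
            M[s:, k] = x[:n - s] if s < n else 0.0
        else:
            M[:s, k] = x[-s:]
    return LaggedDesign(matrix=M, lags_ms=lags)


def normalize_envelope(env: np.ndarray) -> np.ndarray:
    """Scale to unit variance without demeaning (shape preserved)."""
    sd = np.std(env)
    if sd == 0:
        raise ValueError("constant envelope cannot be variance-normalized")
    return np.asarray(env, float) / sd


def zscore(x: np.ndarray, axis=-1) -> np.ndarray:
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance signal cannot be z-scored")
    return (x - mu) / sd


def ridge_trf(design: LaggedDesign, response: np.ndarray,
              lam: float = RIDGE_LAMBDA, channels=None) -> TRFKernel:
    """Closed-form ridge solution per channel.

    ``response`` is (n_channels, n_times) or (n_times,).  ``lam`` is on
    the scale of the normalized design (envelope variance 1, EEG
    z-scored); ``lam=0`` falls back to ordinary least squares and raises
    on singular S'S.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    r = np.atleast_2d(np.asarray(response, float))
    S = design.matrix
    if S.shape[0] != r.shape[1]:
        raise ValueError("design rows must equal response time samples")
    StS = S.T @ S
    Str = S.T @ r.T                      # (n_lags, n_channels)
    A = StS + lam * np.eye(S.shape[1])
    if lam == 0 and np.linalg.matrix_rank(StS) < StS.shape[0]:
        raise np.linalg.LinAlgError("singular system with lambda=0")
    w = np.linalg.solve(A, Str).T        # (n_channels, n_lags)
    if channels is None:
        channels = [f"ch{i}" for i in range(w.shape[0])]
    return TRFKernel(weights=w, lags_ms=design.lags_ms.copy(),
                     channels=list(channels), lam=lam)


def estimate_condition_trf(epochs, envelopes, lam: float = RIDGE_LAMBDA,
                           fit_window=(LAG_MIN_MS / 1000.0,
                                       LAG_MAX_MS / 1000.0),
                           standardize_trials: bool = False) -> dict:
    """Per-trial ridge TRFs averaged within condition x session.

    ``envelopes`` is a sequence (one per trial, order matching
    ``epochs.trials``) of EnvelopeSeries or arrays at the epoch rate.
    Each trial is fit on the stimulus-locked window ``fit_window``
    (seconds, default -0.3..0.6 s); the envelope enters zero-padded to
    that window.  With ``standardize_trials`` each per-trial weight
    matrix is z-normalized before averaging; the default is the plain
    mean of per-trial kernels.

    Returns ``{(condition, session): TRFKernel}``.
    """
    n_trials = epochs.data.shape[0]
    if len(envelopes) != n_trials:
        raise ValueError("need one envelope per trial")
    t0, t1 = fit_window
    tmask = (epochs.time >= t0) & (epochs.time < t1)
    n_fit = int(tmask.sum())
    onset_idx = int(np.round((0.0 - t0) * epochs.rate))
    sums: dict[tuple, np.ndarray] = {}
    counts: dict[tuple, int] = {}
    lags = None
    for i in range(n_trials):
        env = envelopes[i]
        if isinstance(env, EnvelopeSeries):
            env = env.values
        env = normalize_envelope(env)
        # place the envelope at stimulus onset inside the fit window
        x = np.zeros(n_fit)
        n_copy = min(len(env), n_fit - onset_idx)
        x[onset_idx:onset_idx + n_copy] = env[:n_copy]
        design = lagged_design(x, rate=epochs.rate)
        lags = design.lags_ms
        r = zscore(epochs.data[i][:, tmask], axis=-1)
        k = ridge_trf(design, r, lam=lam, channels=epochs.channels)
        w = k.weights
        if standardize_trials:
            w = (w - w.mean()) / w.std()
        key = (epochs.trials["condition"].iloc[i],
               epochs.trials["session"].iloc[i])
        if key not in sums:
            sums[key] = np.zeros_like(w)
            counts[key] = 0
        sums[key] += w
        counts[key] += 1
    if not sums:
        raise ValueError("no trials to fit")
    return {key: TRFKernel(weights=sums[key] / counts[key], lags_ms=lags,
                           channels=list(epochs.channels), lam=lam,
                           meta=dict(condition=key[0], session=key[1],
                                     n_trials=counts[key]))
            for key in sums}


def roi_timecourse(trf: TRFKernel, channels=ROI_CHANNELS) -> np.ndarray:
    """Mean TRF weight over a channel region of interest, per lag."""
    missing = [c for c in channels if c not in trf.channels]
    if missing:
        raise KeyError(f"ROI channels missing from kernel: {missing}")
    idx = [trf.channels.index(c) for c in channels]
    return trf.weights[idx].mean(axis=0)
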