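"""Time-resolved decoding of speech type from EEG topographies.

Epochs are realigned to sentence offset (1 s before to 0.5 s after,
150 samples at 100 Hz), z-scored per channel over all selected time
points, and classified at each time point with an L2-regularized
squared-hinge linear SVM.  The regularization constant C is selected by
nested cross-validation: an outer stratified 10-fold loop estimates
accuracy while an inner 10-fold loop on each training split picks C from
the grid 2^-5, 2^-3, ..., 2^15 (11 values); ties go to the smallest C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, KFold
from sklearn.svm import LinearSVC

from .eeg import EpochSet

OFFSET_WINDOW = (-1.0, 0.5)     # seconds relative to sentence offset
C_EXPONENTS = np.arange(-5, 16, 2)          # 2^-5 .. 2^15, 11 values
C_GRID = 2.0 ** C_EXPONENTS


@dataclass
class DecodingConfig:
    window: tuple = OFFSET_WINDOW
    c_grid: np.ndarray = field(default_factory=lambda: C_GRID.copy())
    outer_folds: int = 10
    inner_folds: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(self.c_grid) == 0:
            raise ValueError("empty C grid")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("need >= 2 folds")


def offset_align(epochs: EpochSet,
                 window: tuple = OFFSET_WINDOW) -> EpochSet:
    """Re-epoch to a fixed window around each trial's sentence offset.

    The window is [offset + window[0], offset + window[1]) seconds,
    half-open in samples.  Trials whose window falls outside the epoch
    are dropped with a warning.
    """
    if "duration" not in epochs.trials.columns:
        raise ValueError("per-trial stimulus durations required")
    w0, w1 = window
    n_keep = int(round((w1 - w0) * epochs.rate))
    kept, segs = [], []
    for i in range(epochs.data.shape[0]):
        offset = float(epochs.trials["duration"].iloc[i])
        i0 = int(np.round((offset + w0 - epochs.time[0]) * epochs.rate))
        i1 = i0 + n_keep
        if i0 < 0 or i1 > epochs.data.shape[-1]:
            warnings.warn(f"trial {i}: offset window outside epoch, dropped")
            continue
        kept.append(i)
        segs.append(epochs.data[i, :, i0:i1])
    if not segs:
        raise ValueError("no trial fits the offset window")
    data = np.stack(segs)
    time = w0 + np.arange(n_keep) / epochs.rate
    out = epochs.copy_with(data=data, time=time,
                           trials=epochs.trials.iloc[kept])
    out.field_meta["aligned_to"] = "sentence_offset"
    return out


def zscore_channels(epochs: EpochSet) -> EpochSet:
    """Standardize each channel over all trials x time points jointly."""
    d = epochs.data
    if d.shape[0] * d.shape[2] < 2:
        raise ValueError("need at least 2 samples per channel")
    mu = d.mean(axis=(0, 2), keepdims=True)
    sd = d.std(axis=(0, 2), keepdims=True)
    flat_sd = sd.ravel()
    if np.any(flat_sd == 0):
        bad = [epochs.channels[i] for i in np.flatnonzero(flat_sd == 0)]
        raise ValueError(f"zero-variance channel(s): {bad}")
    return epochs.copy_with(data=(d - mu) / sd)


def _fit_svm(X, y, C):
    # capped iterations: at very large C on noisy data the dual solver
    # oscillates; accuracy-based C selection is insensitive to the tail
    clf = LinearSVC(C=C, penalty="l2", loss="squared_hinge", dual=True,
                    max_iter=100, tol=1e-2, random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    return clf


def _folds(y, n_folds, stratified, rng_seed):
    if stratified:
        return StratifiedKFold(n_splits=n_folds, shuffle=True,
                               random_state=rng_seed).split(np.zeros(len(y)), y)
    return KFold(n_splits=n_folds, shuffle=True,
                 random_state=rng_seed).split(np.zeros(len(y)))


def nested_cv_decode(X: np.ndarray, y: np.ndarray,
                     config: DecodingConfig | None = None) -> float:
    """Nested-CV accuracy of a linear SVM at one time point.

    Outer folds estimate accuracy; inner folds on each training split
    select C (smallest C among accuracy ties).  Returns the mean
    accuracy over outer test folds.
    """
    if config is None:
        config = DecodingConfig()
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need two classes to decode")
    counts = np.array([(y == c).sum() for c in classes])
    if counts.min() < config.outer_folds:
        raise ValueError("each class needs >= outer_folds members")
    accs = []
    for fold_i, (tr, te) in enumerate(
            _folds(y, config.outer_folds, config.stratified, config.seed)):
        Xtr, ytr = X[tr], y[tr]
        inner_acc = np.zeros(len(config.c_grid))
        # inner folds cannot exceed the smallest class in the training split
        n_inner = min(config.inner_folds,
                      int(min((ytr == c).sum() for c in classes)))
        for itr, ite in _folds(ytr, n_inner, config.stratified,
                               config.seed + 1000 + fold_i):
            for ci, C in enumerate(config.c_grid):
                clf = _fit_svm(Xtr[itr], ytr[itr], C)
                inner_acc[ci] += np.mean(clf.predict(Xtr[ite]) == ytr[ite])
        best_c = config.c_grid[int(np.argmax(inner_acc))]  # first = smallest
        clf = _fit_svm(Xtr, ytr, best_c)
        accs.append(np.mean(clf.predict(X[te]) == y[te]))
    return float(np.mean(accs))


def decode_timecourse(epochs: EpochSet, pair: tuple[str, str],
                      config: DecodingConfig | None = None,
                      time_indices=None) -> dict:
    """Per-time-point nested-CV decoding accuracy for one condition pair.

    ``epochs`` must be offset-aligned and channel z-scored.  Returns a
    dict with ``time`` (seconds) and ``accuracy`` arrays.  ``time_indices``
    restricts the computation to a subset of time points.
    """
    if config is None:
        config = DecodingConfig()
    labels = epochs.trials["condition"].to_numpy()
    mask = np.isin(labels, pair)
    if mask.sum() == 0:
        raise ValueError(f"no trials for pair {pair}")
    data = epochs.data[mask]
    y = labels[mask]
    if time_indices is None:
        time_indices = np.arange(data.shape[-1])
    time_indices = np.asarray(time_indices, int)
    acc = np.empty(len(time_indices))
    for j, t in enumerate(time_indices):
        acc[j] = nested_cv_decode(data[:, :, t], y, config)
    return dict(time=epochs.time[time_indices], accuracy=acc, pair=pair)
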