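"""Epoch container, filtering/baseline utilities, and EEG amplitude spectra.

Epochs are trials x channels x time at a uniform rate (100 Hz throughout
the analyses) with channel names, 3-D electrode positions, and per-trial
labels (subject, session, condition, stimulus duration).  Sentence-level
spectra trim each trial to its own stimulus duration, drop the first
100 ms (onset response), apply a Hann taper, and zero-pad the FFT to 400
samples, giving a 0.25 Hz grid; single-trial amplitude spectra are then
averaged within condition x session.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

#: Canonical frequency bands (Hz) for band-limited tracking analyses.
BANDS = {"delta": (1.0, 3.0), "theta": (4.0, 7.0), "alpha": (8.0, 13.0)}

SPECTRUM_PAD = 400  # samples; 100 Hz / 400 = 0.25 Hz resolution


@dataclass
class EpochSet:
    """Trials x channels x time EEG array with metadata."""

    data: np.ndarray                  # (n_trials, n_channels, n_times)
    time: np.ndarray                  # seconds, uniform
    rate: float
    channels: list[str]
    positions: np.ndarray             # (n_channels, 3)
    trials: pd.DataFrame              # per-trial labels
    field_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        self.time = np.asarray(self.time, float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, time)")
        n_tr, n_ch, n_t = self.data.shape
        if len(self.channels) != n_ch:
            raise ValueError("channel list length mismatch")
        if len(self.time) != n_t:
            raise ValueError("time axis length mismatch")
        if len(self.trials) != n_tr:
            raise ValueError("trial table length mismatch")

    def copy_with(self, data=None, time=None, trials=None) -> "EpochSet":
        return EpochSet(
            data=self.data.copy() if data is None else data,
            time=self.time.copy() if time is None else time,
            rate=self.rate,
            channels=list(self.channels),
            positions=self.positions.copy(),
            trials=(self.trials if trials is None else trials).reset_index(drop=True),
            field_meta=dict(self.field_meta),
        )

    def select_trials(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return self.copy_with(data=self.data[mask],
                              trials=self.trials[mask])

    # -- on-disk container: JSON metadata + flat float32 binary ---------
    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = dict(
            shape=list(self.data.shape),
            rate=self.rate,
            time=self.time.tolist(),
            channels=list(self.channels),
            positions=self.positions.tolist(),
            trials=self.trials.to_dict(orient="list"),
            field_meta=self.field_meta,
            dtype="<f4",
            order="trial-major",
        )
        (path / "epochs.json").write_text(json.dumps(meta))
        self.data.astype("<f4").tofile(path / "epochs.f32")

    @classmethod
    def from_dir(cls, path) -> "EpochSet":
        path = Path(path)
        meta = json.loads((path / "epochs.json").read_text())
        data = np.fromfile(path / "epochs.f32", dtype="<f4").astype(float)
        data = data.reshape(meta["shape"])
        return cls(
            data=data,
            time=np.asarray(meta["time"], float),
            rate=meta["rate"],
            channels=meta["channels"],
            positions=np.asarray(meta["positions"], float),
            trials=pd.DataFrame(meta["trials"]),
            field_meta=meta.get("field_meta", {}),
        )


def rereference_average(epochs: EpochSet) -> EpochSet:
    """Subtract the instantaneous mean across channels (average reference)."""
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return epochs.copy_with(data=data)


def bandpass(epochs: EpochSet, f_lo: float, f_hi: float,
             order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass (two passes of an ``order``-pole IIR)."""
    nyq = epochs.rate / 2.0
    if not (0 < f_lo < f_hi < nyq):
        raise ValueError(f"band ({f_lo}, {f_hi}) Hz outside (0, {nyq}) Hz")
    sos = signal.butter(order, [f_lo, f_hi], btype="bandpass",
                        fs=epochs.rate, output="sos")
    data = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return epochs.copy_with(data=data)


def bandpass_named(epochs: EpochSet, band: str) -> EpochSet:
    f_lo, f_hi = BANDS[band]
    return bandpass(epochs, f_lo, f_hi)


def baseline_correct(epochs: EpochSet,
                     window: tuple[float, float] = (-1.0, 0.0)) -> EpochSet:
    """Subtract each trial/channel's mean over ``window`` (seconds)."""
    t0, t1 = window
    mask = (epochs.time >= t0) & (epochs.time < t1)
    if not mask.any():
        raise ValueError(f"baseline window {window} not inside epoch")
    base = epochs.data[:, :, mask].mean(axis=-1, keepdims=True)
    return epochs.copy_with(data=epochs.data - base)


def amplitude_spectrum(epochs: EpochSet, f_lo: float = 1.0,
                       f_hi: float = 15.0, onset_skip: float = 0.1,
                       pad_to: int = SPECTRUM_PAD,
                       min_samples: int = 10):
    """Per-condition x session mean single-trial amplitude spectra.

    Each trial is trimmed to [``onset_skip``, stimulus duration] seconds
    relative to stimulus onset (t=0), Hann-tapered, and zero-padded to
    ``pad_to`` samples before the FFT; amplitude is ``2|X|/N`` with N the
    trimmed length.  Trials whose trimmed segment is shorter than
    ``min_samples`` are skipped with a warning.

    Returns ``(freqs, table)`` where ``table`` maps
    ``(condition, session) -> (channels, n_freqs)`` mean amplitude.
    """
    if "duration" not in epochs.trials.columns:
        raise ValueError("per-trial stimulus durations required")
    freqs_full = np.fft.rfftfreq(pad_to, d=1.0 / epochs.rate)
    keep = (freqs_full >= f_lo) & (freqs_full <= f_hi)
    freqs = freqs_full[keep]
    sums: dict[tuple, np.ndarray] = {}
    counts: dict[tuple, int] = {}
    for i in range(epochs.data.shape[0]):
        dur = float(epochs.trials["duration"].iloc[i])
        i0 = int(np.round((onset_skip - epochs.time[0]) * epochs.rate))
        i1 = int(np.round((dur - epochs.time[0]) * epochs.rate))
        i1 = min(i1, epochs.data.shape[-1])
        if i1 - i0 < min_samples:
            warnings.warn(f"trial {i}: trimmed segment too short, skipped")
            continue
        seg = epochs.data[i, :, i0:i1]
        n = seg.shape[-1]
        win = signal.windows.hann(n, sym=False)
        spec = np.fft.rfft(seg * win, n=max(pad_to, n), axis=-1)
        if max(pad_to, n) != pad_to:  # segment longer than pad: full-res FFT
            f_local = np.fft.rfftfreq(max(pad_to, n), d=1.0 / epochs.rate)
            amp = 2.0 * np.abs(spec) / n
            amp = np.stack([np.interp(freqs, f_local, amp[c])
                            for c in range(amp.shape[0])])
        else:
            amp = 2.0 * np.abs(spec[:, keep]) / n
        key = (epochs.trials["condition"].iloc[i],
               epochs.trials["session"].iloc[i])
        if key not in sums:
            sums[key] = np.zeros_like(amp)
            counts[key] = 0
        sums[key] += amp
        counts[key] += 1
    table = {k: sums[k] / counts[k] for k in sums}
    return freqs, table
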