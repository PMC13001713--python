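"""Acoustic front-end: cochlear-band envelopes and modulation spectra.

Speech waveforms are passed through a bank of 4th-order gammatone filters
with logarithmically spaced center frequencies (default 32 bands spanning
50–8000 Hz).  Each band's Hilbert envelope is anti-alias filtered and
resampled to 100 Hz, then the bands are averaged into a single broadband
amplitude envelope.  The modulation spectrum is the FFT amplitude of the
mean-removed envelope on a common zero-padded grid, and band averages of
it (e.g., over 5.4–11.7 Hz) quantify how strongly the acoustic energy
fluctuates at syllabic-to-phonemic rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

ENVELOPE_RATE = 100.0  # Hz; shared with the EEG analyses


@dataclass
class AudioStim:
    """A labeled waveform.

    ``modulator`` optionally stores the ground-truth amplitude modulator a
    synthetic stimulus was built from (same sample rate as ``samples``);
    it is ``None`` for recorded audio.
    """

    samples: np.ndarray
    rate: float
    condition: str = ""
    speaker: str = ""
    sentence: int = 0
    session: str = ""
    modulator: np.ndarray | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, float)
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class EnvelopeSeries:
    """Band-averaged amplitude envelope at 100 Hz."""

    values: np.ndarray
    rate: float = ENVELOPE_RATE
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, float)


@dataclass
class ModSpectrum:
    """One-sided FFT amplitude of a mean-removed envelope."""

    freqs: np.ndarray
    amplitude: np.ndarray
    n_samples_original: int
    labels: dict = field(default_factory=dict)


def gammatone_center_freqs(n_bands: int = 32, fmin: float = 50.0,
                           fmax: float = 8000.0) -> np.ndarray:
    """Logarithmically spaced gammatone center frequencies.

    ``f_i = fmin * (fmax/fmin)**(i/(n_bands-1))`` for ``i = 0..n_bands-1``.
    """
    if n_bands < 2:
        raise ValueError("need at least 2 bands")
    if not (0 < fmin < fmax):
        raise ValueError("require 0 < fmin < fmax")
    i = np.arange(n_bands)
    return fmin * (fmax / fmin) ** (i / (n_bands - 1))


def _resample_to(x: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    """Polyphase resampling with anti-alias filtering."""
    if rate_in == rate_out:
        return x
    from fractions import Fraction

    frac = Fraction(rate_out / rate_in).limit_denominator(10**6)
    return signal.resample_poly(x, frac.numerator, frac.denominator)


def extract_envelope(stim: AudioStim, n_bands: int = 32, fmin: float = 50.0,
                     fmax: float = 8000.0) -> EnvelopeSeries:
    """Broadband amplitude envelope of a stimulus.

    Per band: 4th-order IIR gammatone filter, magnitude of the analytic
    signal, polyphase resampling to 100 Hz; bands are averaged after
    resampling.  The result is nonnegative up to resampling ripple, which
    is clipped at zero.
    """
    x = np.asarray(stim.samples, float)
    if stim.rate < 2 * fmax:
        raise ValueError(
            f"sample rate {stim.rate} Hz too low for fmax={fmax} Hz")
    n_out = int(round(len(x) / stim.rate * ENVELOPE_RATE))
    if n_out < 3:
        raise ValueError("stimulus too short for envelope extraction")
    acc = None
    nyq = stim.rate / 2.0
    for fc in gammatone_center_freqs(n_bands, fmin, fmax):
        # a band centered exactly at Nyquist is nudged just below it
        fc = min(fc, nyq * (1.0 - 1e-9))
        b, a = signal.gammatone(fc, "iir", fs=stim.rate)
        band = signal.lfilter(b, a, x)
        env = np.abs(signal.hilbert(band))
        env100 = _resample_to(env, stim.rate, ENVELOPE_RATE)
        acc = env100 if acc is None else acc + env100
    env = acc / n_bands
    np.clip(env, 0.0, None, out=env)
    labels = dict(condition=stim.condition, speaker=stim.speaker,
                  sentence=stim.sentence, session=stim.session)
    return EnvelopeSeries(values=env, rate=ENVELOPE_RATE, labels=labels)


def modulation_spectrum(env: EnvelopeSeries, pad_to: int | None = None,
                        fmax: float = 30.0) -> ModSpectrum:
    """FFT amplitude spectrum of a mean-removed envelope.

    The envelope is zero-padded to ``pad_to`` samples (a common grid for a
    set of variable-length sentences), transformed, and scaled as
    ``2|X|/N`` with ``N = len(env)`` so that a unit-amplitude sinusoidal
    envelope component recovers amplitude ~1 at its bin.  Frequencies up
    to ``fmax`` are retained.
    """
    x = np.asarray(env.values, float)
    n = len(x)
    if pad_to is None:
        pad_to = n
    if pad_to < n:
        raise ValueError(f"pad_to={pad_to} < envelope length {n}")
    x = x - x.mean()
    spec = np.fft.rfft(x, n=pad_to)
    freqs = np.fft.rfftfreq(pad_to, d=1.0 / env.rate)
    amp = 2.0 * np.abs(spec) / n
    keep = freqs <= fmax
    return ModSpectrum(freqs=freqs[keep], amplitude=amp[keep],
                       n_samples_original=n, labels=dict(env.labels))


def band_average(spec: ModSpectrum, f_lo: float, f_hi: float) -> float:
    """Mean spectral amplitude over bins with ``f_lo <= f <= f_hi``."""
    if f_lo >= f_hi:
        raise ValueError("require f_lo < f_hi")
    mask = (spec.freqs >= f_lo) & (spec.freqs <= f_hi)
    if not mask.any():
        raise ValueError(f"no frequency bins in [{f_lo}, {f_hi}] Hz")
    return float(spec.amplitude[mask].mean())


def modulation_spectra_table(envelopes, pad_to=None, fmax: float = 30.0):
    """Modulation spectra of a set of envelopes on one common grid.

    Returns ``(freqs, amplitudes, labels)`` with ``amplitudes`` of shape
    (n_stimuli, n_freqs).  ``pad_to`` defaults to the longest envelope in
    the set.
    """
    envelopes = list(envelopes)
    if not envelopes:
        raise ValueError("empty envelope set")
    if pad_to is None:
        pad_to = max(len(e.values) for e in envelopes)
    specs = [modulation_spectrum(e, pad_to=pad_to, fmax=fmax)
             for e in envelopes]
    freqs = specs[0].freqs
    amps = np.stack([s.amplitude for s in specs])
    labels = [s.labels for s in specs]
    return freqs, amps, labels
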