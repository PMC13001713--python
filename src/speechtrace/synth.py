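"""Forward simulation of stimuli, EEG, and behavior.

The generator emulates the statistical structure the analyses assume:

* **Stimuli** — pink-noise carriers amplitude-modulated by a positive
  envelope whose modulation spectrum peaks near 4 Hz (syllable rate)
  plus a band-limited 5.4-11.7 Hz component scaled by a per-condition
  gain.  Only the envelope matters downstream, so no attempt is made to
  sound like speech.  Three conditions (HS = human speech, AI-NF =
  AI without fine-tuning, AI-FT = fine-tuned AI) x speakers x sessions
  x sentences, durations < 3 s.

* **EEG** — per trial, the stimulus envelope convolved with a
  ground-truth channel x lag kernel, plus 1/f noise and spatially
  smooth correlated noise, scaled to a target SNR.  The base kernel has
  auditory-evoked components near 50, 200, and 300 ms with a central
  scalp maximum.  In "post"(-training) mode, condition-specific bumps
  with compact support are added at 55, 210, and 455 ms, emulating
  training-induced neural differentiation; in "pre" mode all conditions
  share one kernel.

* **Behavior** — an equal-variance Gaussian signal-detection observer:
  evidence x ~ N(mu[session, condition], 1), response "AI" iff
  x > lambda[session].  Default means are chosen so the recovered d'
  per condition/session and the pre-to-post criterion shift match the
  magnitudes typical of naive listeners judging modern voice clones
  (d' well below 1, criterion moving from ~0 to conservative), while
  the observer is identical across kernel modes — the behavioral null
  that accompanies the neural "post" effect.

Everything is deterministic given ``SynthConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

from .eeg import EpochSet
from .envelope import AudioStim
from .montage import channel_positions
from .trf import lagged_design, lag_grid_ms, normalize_envelope

CONDITIONS = ("HS", "AI-NF", "AI-FT")
SESSIONS = ("S1", "S2")

# modulator composition (relative to a mean level of 1); the band depth is
# large enough that the carrier's intrinsic envelope noise floor does not
# mask the configured condition gains after filterbank extraction
_SYLLABIC_DEPTH = 0.45      # 3-4.6 Hz narrowband component
_SYLLABIC_BAND = (3.0, 4.6)
_BAND_DEPTH = 0.32          # 5.4-11.7 Hz component, scaled by condition gain
_BAND = (5.4, 11.7)


@dataclass
class ObserverParams:
    """Equal-variance SDT observer: evidence means and decision threshold.

    ``mu[session][condition]`` is the mean AI-ness evidence (z units);
    ``lam[session]`` the decision threshold (respond "AI" iff x > lam).
    ``subject_sd_mu`` / ``subject_sd_lam`` add Gaussian between-subject
    jitter to means and thresholds.
    """

    mu: dict = field(default_factory=lambda: {
        "S1": {"HS": 0.0, "AI-NF": 0.512, "AI-FT": 0.266},
        "S2": {"HS": 0.0, "AI-NF": 0.764, "AI-FT": 0.341},
    })
    lam: dict = field(default_factory=lambda: {"S1": 0.0, "S2": 0.73})
    subject_sd_mu: float = 0.25
    subject_sd_lam: float = 0.30


@dataclass
class SynthConfig:
    n_subjects: int = 30
    n_sentences_per_cell: int = 33
    conditions: tuple = CONDITIONS
    speakers: int = 3
    sessions: tuple = SESSIONS
    sample_rate_audio: float = 16000.0
    sample_rate_eeg: float = 100.0
    sentence_duration_range: tuple = (1.2, 2.8)
    mod_band_gains: dict = field(default_factory=lambda: {
        "HS": 1.3, "AI-FT": 1.15, "AI-NF": 1.0})
    snr_db: float = -6.0
    epoch_pre: float = 1.5          # seconds of prestimulus silence
    epoch_post: float = 5.0         # seconds after stimulus onset
    subject_kernel_gain_sd: float = 0.2    # between-subject gain jitter
    subject_latency_sd_ms: float = 10.0    # between-subject latency jitter
    observer_params: ObserverParams = field(default_factory=ObserverParams)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.sentence_duration_range
        if not (0 < lo < hi):
            raise ValueError("duration range must satisfy 0 < min < max")
        if hi >= 3.0:
            raise ValueError("longest sentences must be < 3 s")
        for c in self.conditions:
            if self.mod_band_gains.get(c, 0) <= 0:
                raise ValueError(f"nonpositive modulation gain for {c!r}")

    def with_(self, **kw) -> "SynthConfig":
        return replace(self, **kw)


@dataclass
class GroundTruthKernel:
    channels: list
    lags_ms: np.ndarray
    weights: np.ndarray            # (n_channels, n_lags)
    mode: str
    condition: str = ""


def _stream_rng(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *keys]))


def _pink_noise(rng, n: int, n_series: int | None = None) -> np.ndarray:
    """1/f-amplitude Gaussian noise, unit variance per series.

    Returns shape (n,) when ``n_series`` is None, else (n_series, n).
    """
    shape = (n,) if n_series is None else (n_series, n)
    spec = np.fft.rfft(rng.standard_normal(shape), axis=-1)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if len(f) > 1 else 1.0
    spec /= np.sqrt(f)
    spec[..., 0] = 0
    x = np.fft.irfft(spec, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _bandpassed_noise(rng, n: int, rate: float, f_lo: float,
                      f_hi: float) -> np.ndarray:
    """Band-limited Gaussian noise with unit RMS."""
    x = rng.standard_normal(n)
    sos = signal.butter(4, [f_lo, f_hi], btype="bandpass", fs=rate,
                        output="sos")
    y = signal.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def make_modulator(rng, n_env: int, rate: float, band_gain: float) -> np.ndarray:
    """Positive amplitude modulator at the envelope rate.

    1 + syllabic (3-5 Hz) component + band-limited 5.4-11.7 Hz component
    scaled by the condition gain, floored just above zero.
    """
    syll = _bandpassed_noise(rng, n_env, rate, *_SYLLABIC_BAND)
    band = _bandpassed_noise(rng, n_env, rate, *_BAND)
    m = 1.0 + _SYLLABIC_DEPTH * syll + _BAND_DEPTH * band_gain * band
    return np.clip(m, 0.02, None)


def gen_stimuli(config: SynthConfig) -> list[AudioStim]:
    """Factorial set of noise-carrier stimuli with condition-scaled 5.4-11.7 Hz modulation.

    Each sentence (speaker x session x index) has one duration, one
    syllabic modulator, and one 5.4-11.7 Hz band component shared across
    the three conditions — the same utterance rendered three ways — with
    the band component scaled by each condition's gain and only the noise
    carrier drawn per rendition.  This mirrors a design where every
    sentence exists as a human recording and two synthetic clones of it:
    condition envelopes are matched except for the configured band-gain
    contrast, so with equal gains the conditions are exchangeable by
    construction.
    """
    stims = []
    fs = config.sample_rate_audio
    env_rate = config.sample_rate_eeg
    lo, hi = config.sentence_duration_range
    for sp in range(config.speakers):
        for si, sess in enumerate(config.sessions):
            for sent in range(config.n_sentences_per_cell):
                sent_rng = _stream_rng(config.seed, 1, sp, si, sent)
                dur = sent_rng.uniform(lo, hi)
                n_env = max(int(round(dur * env_rate)), 3)
                n_audio = int(round(n_env / env_rate * fs))
                syll = _bandpassed_noise(sent_rng, n_env, env_rate,
                                         *_SYLLABIC_BAND)
                band = _bandpassed_noise(sent_rng, n_env, env_rate, *_BAND)
                t_env = np.arange(n_env) / env_rate
                t_audio = np.arange(n_audio) / fs
                for ci, cond in enumerate(config.conditions):
                    gain = config.mod_band_gains[cond]
                    rng = _stream_rng(config.seed, 1, sp, si, sent, 10 + ci)
                    mod_env = np.clip(
                        1.0 + _SYLLABIC_DEPTH * syll
                        + _BAND_DEPTH * gain * band, 0.02, None)
                    mod = np.interp(t_audio, t_env, mod_env)
                    carrier = _pink_noise(rng, n_audio)
                    samples = 0.1 * carrier * mod
                    stims.append(AudioStim(
                        samples=samples, rate=fs, condition=cond,
                        speaker=f"spk{sp + 1}",
                        sentence=sent + si * config.n_sentences_per_cell,
                        session=sess, modulator=mod))
    return stims


def write_wav(stim: AudioStim, path) -> None:
    """Write a stimulus as 16-bit PCM WAV (deterministic quantization)."""
    x = np.asarray(stim.samples, float)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak * 0.9
    wavfile.write(path, int(stim.rate), (x * 32767).astype(np.int16))


def true_envelope(stim: AudioStim, rate: float = 100.0) -> np.ndarray:
    """Ground-truth modulator resampled to the envelope rate."""
    if stim.modulator is None:
        raise ValueError("stimulus carries no ground-truth modulator")
    n_out = int(round(len(stim.modulator) / stim.rate * rate))
    t_out = np.arange(n_out) / rate
    t_in = np.arange(len(stim.modulator)) / stim.rate
    return np.interp(t_out, t_in, stim.modulator)


# ---------------------------------------------------------------------
# ground-truth TRF kernels

_BASE_COMPONENTS = (        # (latency ms, width ms, amplitude)
    (50.0, 20.0, 1.0),
    (200.0, 45.0, -0.8),
    (300.0, 60.0, 0.45),
)
EFFECT_LATENCIES_MS = (55.0, 210.0, 455.0)
_EFFECT_HALFWIDTH_MS = 40.0          # compact support: +-40 ms < +-50 ms
_EFFECT_AMPLITUDES = (0.6, 0.55, 0.65)
#: per-condition multipliers of the effect bumps (sum need not be zero)
_EFFECT_CONDITION_SCALE = {"HS": 0.0, "AI-NF": 1.0, "AI-FT": -1.0}


def _central_profile(channels) -> np.ndarray:
    names, pos = channel_positions(channels)
    cz = pos[names.index("Cz")] if "Cz" in names else pos.mean(axis=0)
    d = np.linalg.norm(pos - cz, axis=1)
    return np.exp(-(d ** 2) / (2 * 0.055 ** 2))


def _hann_bump(lags: np.ndarray, center: float, halfwidth: float) -> np.ndarray:
    x = (lags - center) / halfwidth
    out = np.zeros_like(lags, float)
    inside = np.abs(x) < 1
    out[inside] = 0.5 * (1 + np.cos(np.pi * x[inside]))
    return out


def gen_true_kernels(mode: str, channels=None, effect_scale: float = 1.0,
                     conditions=CONDITIONS) -> dict:
    """Per-condition ground-truth kernels on the -300..+600 ms lag grid.

    ``mode="pre"``: identical kernels for all conditions.  ``mode="post"``:
    condition-specific bumps (compact support, +-40 ms) added at 55, 210,
    and 455 ms, scaled by ``effect_scale``.
    """
    if mode not in ("pre", "post"):
        raise ValueError(f"unknown kernel mode {mode!r}")
    if channels is None:
        channels, _ = channel_positions()
    lags = lag_grid_ms()
    base_t = np.zeros_like(lags)
    for lat, width, amp in _BASE_COMPONENTS:
        base_t += amp * np.exp(-((lags - lat) ** 2) / (2 * width ** 2))
    profile = _central_profile(channels)
    base = np.outer(profile, base_t)
    out = {}
    for cond in conditions:
        w = base.copy()
        if mode == "post" and effect_scale != 0:
            scale = _EFFECT_CONDITION_SCALE.get(cond, 0.0)
            bump_t = np.zeros_like(lags)
            for lat, amp in zip(EFFECT_LATENCIES_MS, _EFFECT_AMPLITUDES):
                bump_t += amp * _hann_bump(lags, lat, _EFFECT_HALFWIDTH_MS)
            w = w + effect_scale * scale * np.outer(profile, bump_t)
        out[cond] = GroundTruthKernel(channels=list(channels),
                                      lags_ms=lags.copy(), weights=w,
                                      mode=mode, condition=cond)
    return out


# ---------------------------------------------------------------------
# EEG forward model

def _smooth_topographies(rng, positions: np.ndarray, n_maps: int) -> np.ndarray:
    """Random spatially smooth topographies (n_maps, n_channels)."""
    centers = positions[rng.integers(0, len(positions), n_maps)]
    jitter = rng.normal(0, 0.02, centers.shape)
    maps = np.empty((n_maps, len(positions)))
    for i in range(n_maps):
        d = np.linalg.norm(positions - (centers[i] + jitter[i]), axis=1)
        maps[i] = rng.choice([-1.0, 1.0]) * np.exp(-(d ** 2) / (2 * 0.05 ** 2))
    return maps


def gen_eeg(stimuli, kernels: dict, config: SynthConfig,
            subjects=None) -> EpochSet:
    """Simulate epoched EEG for every subject x stimulus.

    Per trial and channel: (envelope (*) kernel) + pink noise + spatially
    correlated smooth noise, scaled so the stimulus-window signal-to-noise
    ratio equals ``config.snr_db`` (``-inf`` means noise only).  Epochs run
    from ``-epoch_pre`` (silence baseline) to ``+epoch_post`` seconds.

    Between-subject heterogeneity mimics individual differences in
    auditory evoked responses: each subject's kernel is scaled by a
    gain ~ N(1, ``subject_kernel_gain_sd``) and shifted along the lag
    axis by a latency jitter ~ N(0, ``subject_latency_sd_ms``) rounded
    to the grid.  Without such heterogeneity the subject x condition
    interaction term of group statistics would be unrealistically
    small; set both SDs to 0 for exact parameter-recovery studies.
    """
    first = next(iter(kernels.values()))
    channels = list(first.channels)
    for k in kernels.values():
        if list(k.channels) != channels:
            raise ValueError("kernels disagree on channel sets")
    names, positions = channel_positions(channels)
    rate = config.sample_rate_eeg
    n_pre = int(round(config.epoch_pre * rate))
    n_post = int(round(config.epoch_post * rate))
    n_time = n_pre + n_post
    time = (np.arange(n_time) - n_pre) / rate
    if subjects is None:
        subjects = range(1, config.n_subjects + 1)
    subjects = list(subjects)

    data = []
    rows = []
    signal_power = None
    for subj in subjects:
        srng = _stream_rng(config.seed, 2, int(subj))
        gain_jitter = srng.normal(1.0, config.subject_kernel_gain_sd)
        lag_shift = int(np.round(
            srng.normal(0.0, config.subject_latency_sd_ms / 10.0)))
        subj_kernels = {}
        for cond, k in kernels.items():
            w = np.roll(k.weights, lag_shift, axis=1)
            if lag_shift > 0:
                w[:, :lag_shift] = 0.0
            elif lag_shift < 0:
                w[:, lag_shift:] = 0.0
            subj_kernels[cond] = gain_jitter * w
        topo = _smooth_topographies(srng, positions, 4)
        for ti, stim in enumerate(stimuli):
            if stim.condition not in kernels:
                raise KeyError(f"no kernel for condition {stim.condition!r}")
            env = true_envelope(stim, rate) if stim.modulator is not None \
                else None
            if env is None:
                raise ValueError("gen_eeg requires synthetic stimuli with "
                                 "ground-truth modulators")
            env = normalize_envelope(env)
            timeline = np.zeros(n_time)
            n_copy = min(len(env), n_post)
            timeline[n_pre:n_pre + n_copy] = env[:n_copy]
            design = lagged_design(timeline, rate=rate)
            W = subj_kernels[stim.condition]
            sig = (design.matrix @ W.T).T                 # (ch, time)
            # stimulus-window signal power, averaged over channels
            on = slice(n_pre, n_pre + n_copy)
            p_sig = float(np.mean(sig[:, on] ** 2))
            trng = _stream_rng(config.seed, 3, int(subj), ti)
            noise = _pink_noise(trng, n_time, len(channels))
            shared = topo.T @ _pink_noise(trng, n_time, topo.shape[0])
            noise = noise + shared
            noise /= noise.std()
            if np.isfinite(config.snr_db) and p_sig > 0:
                noise_scale = np.sqrt(p_sig) * 10 ** (-config.snr_db / 20.0)
                trial = sig + noise_scale * noise
            else:
                trial = noise
            data.append(trial)
            rows.append(dict(subject=int(subj), session=stim.session,
                             condition=stim.condition, speaker=stim.speaker,
                             sentence=stim.sentence,
                             duration=len(stim.samples) / stim.rate))
    return EpochSet(data=np.stack(data), time=time, rate=rate,
                    channels=names, positions=positions,
                    trials=pd.DataFrame(rows),
                    field_meta=dict(snr_db=config.snr_db,
                                    kernel_mode=first.mode))


# ---------------------------------------------------------------------
# SDT observer

def gen_behavior(config: SynthConfig) -> pd.DataFrame:
    """Simulate per-trial human/AI judgments from the SDT observer.

    Evidence x ~ N(mu[session, condition] + subject jitter, 1); the
    response is "AI" iff x exceeds the subject's session threshold.
    Returns a long table (subject, session, speaker, sentence, condition,
    response, rt).
    """
    obs = config.observer_params
    n = config.n_sentences_per_cell * config.speakers
    speakers = np.array([f"spk{i % config.speakers + 1}" for i in range(n)])
    sentences = np.arange(n) // config.speakers
    frames = []
    for subj in range(1, config.n_subjects + 1):
        srng = _stream_rng(config.seed, 4, subj)
        mu_jit = {(sess, c): srng.normal(0, obs.subject_sd_mu)
                  for sess in config.sessions for c in config.conditions}
        lam_jit = {sess: srng.normal(0, obs.subject_sd_lam)
                   for sess in config.sessions}
        for sess in config.sessions:
            lam_s = obs.lam[sess] + lam_jit[sess]
            for cond in config.conditions:
                mu_s = obs.mu[sess][cond] + mu_jit[(sess, cond)]
                x = srng.normal(mu_s, 1.0, n)
                frames.append(pd.DataFrame(dict(
                    subject=subj, session=sess, speaker=speakers,
                    sentence=sentences, condition=cond,
                    response=np.where(x > lam_s, "AI", "human"),
                    rt=srng.lognormal(0.0, 0.3, n))))
    return pd.concat(frames, ignore_index=True)
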