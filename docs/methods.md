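# Methods

`speechtrace` implements the analysis chain of a perceptual-training study
on human versus AI-generated (cloned) speech: acoustic characterization of
the stimuli, signal-detection analysis of listeners' human/AI judgments,
envelope-tracking (TRF) analysis of EEG, EEG amplitude spectra,
cluster-based permutation inference, and time-resolved decoding — together
with a seeded forward simulator that generates stimuli, EEG, and behavior
with the statistical structure these analyses assume. This note documents
the models, the defaults, and the choices made where the design was open.

## Acoustic front-end

Waveforms are filtered through a bank of 4th-order IIR gammatone filters
with 32 logarithmically spaced center frequencies from 50 to 8000 Hz
(`f_i = 50·160^(i/31)`; a center falling exactly at Nyquist is nudged
infinitesimally below it, since the IIR design is undefined there). Band
envelopes are magnitudes of the analytic (Hilbert) signal, anti-alias
resampled to 100 Hz by polyphase filtering, then averaged across bands —
downsample-then-average, in that order. Modulation spectra are FFT
amplitudes (`2|X|/N`, `N` the envelope length) of mean-removed envelopes,
zero-padded to a common length (the longest envelope of the analysis set)
so that variable-duration sentences share one frequency grid without
interpolation; the stimulus contrast uses 0–30 Hz. Mean removal, padding
scheme, and amplitude normalization are our choices — any consistent
convention leaves the F-contrast unchanged, and a sinusoidal envelope
component's amplitude is recovered exactly at its bin.

## Signal-detection behavior

Responses are binary human/AI judgments. Per subject × session ×
target condition a 2×2 confusion matrix is built: with human speech (HS)
as target, both AI conditions pool into the noise class; with one AI
condition as target, HS is the noise class and the other AI condition is
discarded. Sensitivity and bias follow the equal-variance Gaussian model,
`d' = z(H) − z(F)` and `c = −(z(H)+z(F))/2`. Extreme rates are clipped to
`[1/(2N), 1−1/(2N)]` with the cell's own trial count `N` — a standard
correction; other conventions (e.g., log-linear) would shift extreme cells
slightly. The group analysis is a two-way fully within-subject ANOVA
(Speech type × Session) with uncorrected degrees of freedom (no
Greenhouse–Geisser), partial η² = SS_effect/(SS_effect+SS_error), followed
by paired t tests per condition with Benjamini–Hochberg FDR across the
three comparisons; Cohen's d for paired tests is mean(diff)/SD(diff).

## Temporal response functions

The TRF is the linear kernel mapping the 100 Hz amplitude envelope to each
EEG channel over lags −300…+600 ms on a 10 ms grid (91 lags). With `S` the
lagged design matrix (out-of-range samples zero-filled) and `r` one
trial's EEG, the ridge solution is `w = (SᵀS + λI)⁻¹ Sᵀr` with λ = 100.
Before fitting, the envelope is scaled to unit variance *without*
demeaning (its shape, including the DC pedestal, is part of the stimulus)
and the EEG is z-scored per channel over the fitted window; λ is
meaningful only on this normalized scale. Fits are per trial on the
stimulus-locked −300…+600 ms window, then averaged within condition ×
session as a plain mean of per-trial weight matrices (an optional
`standardize_trials` flag z-normalizes each trial's weights first; the
plain mean is the default because it is the estimator whose parameter
recovery we verify). The central ROI for time courses is FCz, FC1, FC2,
Cz, C1, C2, CPz, CP1, CP2. Note the per-trial window has fewer samples
(90) than lag parameters (91); ridge makes the problem well-posed but
single-trial estimates are strongly regularized and only trial averages
are interpretable.

## Cluster-based permutation inference

Point-wise statistics: one-way independent-samples ANOVA F (acoustic
contrasts, items as units) or within-subject repeated-measures ANOVA F
(EEG contrasts, subjects as units, df = (k−1, (k−1)(n−1))). The
multivariate (Hotelling-type) dependent-samples F used by some toolboxes
is *not* implemented; the univariate rmANOVA F is the documented stand-in.
Clusters are formed above the parametric F critical value at α = 0.05;
suprathreshold (channel, sample) points with fewer than `min_nb_chan = 3`
suprathreshold spatial neighbors at that sample are pruned (single pass),
then connected components over the Delaunay-triangulated electrode
adjacency (azimuthal-equidistant projection of the 3-D positions) plus
temporal/spectral contiguity are scored by summed F. Only positive
clusters exist (F is one-tailed). Significance is Monte Carlo with the
maxsum statistic: dependent designs permute condition labels within each
subject, independent designs permute item labels across groups;
`p = (1 + #{null ≥ observed})/(1 + n_perm)`. For tiny dependent designs an
exact mode enumerates all `(k!)^n` relabelings. On exchangeable null data
(12 subjects × 3 conditions × 16 channels × 50 samples) the measured
family-wise error at α = 0.05 is ≈ 0.05 over 200 simulated datasets.

For 1-D maps (modulation spectra) there is a single "channel", adjacency
is bin contiguity, and no neighbor pruning applies.

## Decoding

Epochs are re-cut to [offset−1.0 s, offset+0.5 s) around each sentence's
end (150 samples at 100 Hz; trials whose window leaves the epoch are
dropped with a warning), and each channel is z-scored over all selected
trials × time points jointly. At each time point a linear SVM
(L2-regularized squared-hinge loss, dual) classifies condition pairs —
binary problems, i.e., chance = 50%. C is selected by nested
cross-validation: stratified outer 10-fold for accuracy, inner 10-fold on
each training split over the grid 2⁻⁵…2¹⁵ in steps of 2² (11 values),
ties resolved toward the smallest C (maximal regularization at equal
fit). Stratification is our addition to keep folds valid at small n; a
flag disables it. The solver runs with a capped iteration budget
(`max_iter=100, tol=1e-2`): at very large C on noisy data the dual
coordinate method oscillates without changing which C wins, and the
calibration tests (null within the chance CI, separable construction
≥ 95%) hold under the cap. Inner folds shrink automatically when a
training split's smaller class has fewer members than 10.

## The forward simulator

The generator's defaults are the study conditions; they are fixed, not
tuning knobs.

**Stimuli.** Each sentence is a pink-noise carrier multiplied by a
positive modulator `1 + 0.45·syll + 0.32·g_c·band`, where `syll` is
unit-RMS band-limited noise at 3–4.6 Hz (the syllabic ~4 Hz peak), `band`
is unit-RMS noise in 5.4–11.7 Hz, and `g_c` is the per-condition gain
(HS 1.3, AI-FT 1.15, AI-NF 1.0) — the acoustic fingerprint that separates
human speech from clones in this band, ordered HS > AI-FT > AI-NF.
Durations are uniform on (1.2, 2.8) s. The same sentence (duration +
syllabic modulator) is rendered once per condition with its own band
component and carrier, mirroring a design where each sentence exists as
one human recording and two synthetic renditions; this is what makes the
paired band post hocs meaningful. The depths were chosen so that (a) the
modulation spectrum peaks near 4 Hz, and (b) the configured gain ratios
survive the full gammatone extraction within 5% despite the carrier's
intrinsic envelope noise floor. No attempt is made at intelligible
speech: only the envelope reaches the downstream analyses.

**EEG.** Ground-truth kernels live on the −300…+600 ms lag grid: smooth
components at ~50, 200, 300 ms (amplitudes +1, −0.8, +0.45; widths 20,
45, 60 ms) with a central (Cz-maximal Gaussian) topography. In `pre` mode
all conditions share this kernel. In `post` mode, condition-specific Hann
bumps of ±40 ms support are added at 55, 210, 455 ms (amplitudes 0.6,
0.55, 0.65 × `effect_scale`; condition multipliers HS 0, AI-NF +1,
AI-FT −1), so condition differences vanish outside ±50 ms of those
latencies — the "training-induced neural differentiation". Per trial, the
unit-variance envelope convolved with the kernel is summed with pink
(1/f) channel noise plus four spatially smooth random topographies with
pink time courses (making adjacency-based clustering nontrivial), scaled
to the configured SNR (default −6 dB over the stimulus window;
`snr_db = −inf` yields noise only). Between-subject heterogeneity: kernel
gain ~ N(1, 0.2) and latency jitter ~ N(0, 10 ms) per subject. Epochs run
from −1.5 s (silence baseline) to +epoch_post seconds.

**Behavior.** An equal-variance SDT observer: evidence
`x ~ N(μ[session, condition], 1)`, response "AI" iff `x > λ[session]`,
with per-subject Gaussian jitter on μ (SD 0.25) and λ (SD 0.30). For an
AI target with HS noise this observer's d′ equals μ exactly, so the
default means are the study-typical per-condition sensitivities
(S1: AI-NF 0.512, AI-FT 0.266; S2: 0.764, 0.341; HS μ = 0), and the
thresholds (S1: 0.0; S2: 0.73) produce the shift from neutral to
conservative responding after training. The observer never sees the
kernel mode: behavior is identical across `pre`/`post`, which is exactly
the neural–behavioral dissociation the end-to-end test checks.

## What the synthetic data does and does not show

The generator reproduces the *structure* the analyses assume — envelope-
locked EEG, a band-limited acoustic contrast, an unbiased-by-construction
observer — not the physiology of real recordings: no eye/cardiac
artifacts (artifact removal is out of scope), no 1/f slope variation
across subjects, no real speech acoustics. Passing tests therefore
validate the estimators and their calibration, not claims about real
brains.

One real-data subtlety the simulator *does* expose: with a fixed stimulus
set shared by all subjects, per-trial ridge estimates carry
stimulus-realization-specific bias that is common across subjects, so
with unequal modulation gains the three conditions are not exchangeable
even when their kernels are identical — the within-subject permutation
test then (correctly) rejects. End-to-end null calibration of the TRF
cluster test is therefore run with equal modulation gains, where
conditions are exchangeable by construction; with the study's trial
counts per condition this false-positive rate is at the nominal level.
The acoustic confound itself is reported by the acoustic stage, which is
designed to detect it.

## Problem sizes

Desk-scale defaults used by the tests and the acceptance script:
behavioral simulation at full scale (30 subjects × 99 trials per
condition × session); acoustic contrast at full stimulus scale (198
items per condition); TRF cluster runs at 8–10 subjects with 36 trials
per condition, 300–500 permutations; null calibration at 12 subjects ×
16 channels × 50 samples × 400 permutations × 100–200 datasets; decoding
on 150-trial constructions. These sizes were chosen so each stage's
sampling error is small relative to the effects it measures while whole
suites run in minutes.
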