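"""End-to-end orchestration of the synthetic study.

``run_pipeline`` drives the stages in order — simulate, acoustic
modulation-spectrum contrast, behavioral SDT + rmANOVA, TRF estimation
and cluster test, EEG amplitude-spectrum cluster test, and time-resolved
decoding — from a single config with one global seed, and returns (and
optionally writes) a per-stage results dictionary.  Each stage block
records the parameters it ran with, so the output is self-describing.

The numbered scripts under ``analysis/`` are thin narrative drivers over
the same stage functions; this module is what the tests and the
acceptance script import.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cluster, decode, sdt, synth
from .envelope import modulation_spectra_table, EnvelopeSeries
from .eeg import amplitude_spectrum
from .trf import estimate_condition_trf
from .synth import SynthConfig, true_envelope

logger = logging.getLogger("speechtrace")

ACOUSTIC_BAND = (5.4, 11.7)


@dataclass
class PipelineConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    kernel_mode: str = "post"
    effect_scale: float = 1.0
    n_perm: int = 1000
    alpha: float = 0.05
    min_nb_chan: int = 3
    decode_time_step: int = 10        # decode every k-th time point
    stages: tuple = ("synth", "acoustics", "behavior", "trf",
                     "spectra", "decoding")
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth_kw = raw.pop("synth", {})
        obs_kw = synth_kw.pop("observer_params", None)
        cfg = SynthConfig(**synth_kw)
        if obs_kw:
            cfg = cfg.with_(observer_params=synth.ObserverParams(**obs_kw))
        return cls(synth=cfg, **raw)


def stage_acoustics(stimuli, config: PipelineConfig, use_true_envelope=False):
    """Modulation spectra, independent-samples cluster test, band post hocs."""
    if use_true_envelope:
        envs = [EnvelopeSeries(values=true_envelope(s),
                               labels=dict(condition=s.condition))
                for s in stimuli]
    else:
        from .envelope import extract_envelope

        envs = [extract_envelope(s) for s in stimuli]
    freqs, amps, labels = modulation_spectra_table(envs)
    conds = np.array([l["condition"] for l in labels])
    groups = [amps[conds == c] for c in synth.CONDITIONS]
    res = cluster.permutation_test(
        [g[:, None, :] for g in groups], design="independent",
        n_perm=config.n_perm, seed=config.synth.seed + 11,
        alpha=config.alpha, min_nb_chan=0)
    band_means = {}
    band_by_item = {}
    for c, g in zip(synth.CONDITIONS, groups):
        mask = (freqs >= ACOUSTIC_BAND[0]) & (freqs <= ACOUSTIC_BAND[1])
        vals = g[:, mask].mean(axis=1)
        band_by_item[c] = vals
        band_means[c] = float(vals.mean())
    # pairwise band contrasts with FDR (items are matched across conditions
    # by construction, so paired t applies)
    pairs = [("HS", "AI-NF"), ("AI-FT", "AI-NF"), ("HS", "AI-FT")]
    stats = {f"{a} vs {b}": sdt.paired_t(band_by_item[a], band_by_item[b])
             for a, b in pairs}
    padj = sdt.fdr_adjust([stats[k]["p"] for k in stats])
    for k, p in zip(stats, padj):
        stats[k]["p_fdr"] = float(p)
    sig = res.significant
    return dict(
        freqs=freqs.tolist(),
        mean_spectra={c: groups[i].mean(axis=0).tolist()
                      for i, c in enumerate(synth.CONDITIONS)},
        band=ACOUSTIC_BAND, band_means=band_means,
        n_significant_clusters=len(sig),
        clusters=[dict(stat=c.stat, p=c.p_value,
                       f_lo=float(freqs[c.sample_range()[0]]),
                       f_hi=float(freqs[c.sample_range()[1]]))
                  for c in res.clusters],
        posthoc=stats,
    )


def stage_behavior(trials, config: PipelineConfig):
    """SDT measures, Speech type x Session rmANOVA, FDR post hocs."""
    table = sdt.sdt_table(trials)
    out = {"cell_means": {}}
    subjects = sorted(table["subject"].unique())
    sessions = sorted(table["session"].unique())
    for measure in ("d_prime", "criterion"):
        piv = table.pivot_table(index="subject", columns=["condition", "session"],
                                values=measure)
        arr = np.stack([
            [[piv.loc[s, (c, se)] for se in sessions]
             for c in sdt.CONDITIONS] for s in subjects])
        anova = sdt.rm_anova_2way(arr)
        posthoc = {}
        for ci, c in enumerate(sdt.CONDITIONS):
            posthoc[c] = sdt.paired_t(arr[:, ci, 0], arr[:, ci, 1])
        padj = sdt.fdr_adjust([posthoc[c]["p"] for c in sdt.CONDITIONS])
        for c, p in zip(sdt.CONDITIONS, padj):
            posthoc[c]["p_fdr"] = float(p)
        out[measure] = dict(
            anova={k: dict(F=v["F"], df=list(v["df"]), p=v["p"],
                           partial_eta_sq=v["partial_eta_sq"])
                   for k, v in anova.items()},
            posthoc_session=posthoc)
        out["cell_means"][measure] = {
            f"{c}/{se}": float(arr[:, ci, si].mean())
            for ci, c in enumerate(sdt.CONDITIONS)
            for si, se in enumerate(sessions)}
    return out


def stage_trf(epochs, stimuli, config: PipelineConfig,
              lag_window_ms=(0, 500)):
    """Per-subject condition TRFs and the dependent-samples cluster test."""
    env_by_stim = {}
    for ti, s in enumerate(stimuli):
        env_by_stim[(s.condition, s.speaker, s.session, s.sentence)] = \
            true_envelope(s)
    subjects = sorted(epochs.trials["subject"].unique())
    per_subject = {}
    for subj in subjects:
        sub = epochs.select_trials(
            (epochs.trials["subject"] == subj).to_numpy())
        envs = [env_by_stim[(r.condition, r.speaker, r.session, r.sentence)]
                for r in sub.trials.itertuples()]
        per_subject[subj] = estimate_condition_trf(sub, envs)
    # stack (subjects, conditions, channels, lags) per session
    first = next(iter(per_subject.values()))
    lags = next(iter(first.values())).lags_ms
    lmask = (lags >= lag_window_ms[0]) & (lags <= lag_window_ms[1])
    adjacency = cluster.adjacency_from_positions(epochs.positions)
    sessions = sorted(epochs.trials["session"].unique())
    results = {}
    for sess in sessions:
        data = np.stack([
            np.stack([per_subject[s][(c, sess)].weights[:, lmask]
                      for c in synth.CONDITIONS]) for s in subjects])
        res = cluster.permutation_test(
            data, design="dependent", adjacency=adjacency,
            n_perm=config.n_perm, seed=config.synth.seed + 13,
            alpha=config.alpha, min_nb_chan=config.min_nb_chan)
        results[sess] = dict(
            n_significant_clusters=len(res.significant),
            clusters=[dict(stat=c.stat, p=c.p_value,
                           lag_lo_ms=float(lags[lmask][c.sample_range()[0]]),
                           lag_hi_ms=float(lags[lmask][c.sample_range()[1]]))
                      for c in res.clusters])
    return dict(sessions=results, lags_ms=lags[lmask].tolist(),
                per_subject=per_subject)


def stage_spectra(epochs, config: PipelineConfig):
    """Condition x session EEG amplitude spectra and cluster tests."""
    subjects = sorted(epochs.trials["subject"].unique())
    sessions = sorted(epochs.trials["session"].unique())
    adjacency = cluster.adjacency_from_positions(epochs.positions)
    per = {}
    freqs = None
    for subj in subjects:
        sub = epochs.select_trials(
            (epochs.trials["subject"] == subj).to_numpy())
        freqs, table = amplitude_spectrum(sub)
        per[subj] = table
    results = {}
    for sess in sessions:
        data = np.stack([
            np.stack([per[s][(c, sess)] for c in synth.CONDITIONS])
            for s in subjects])
        res = cluster.permutation_test(
            data, design="dependent", adjacency=adjacency,
            n_perm=config.n_perm, seed=config.synth.seed + 17,
            alpha=config.alpha, min_nb_chan=config.min_nb_chan)
        results[sess] = dict(
            n_significant_clusters=len(res.significant),
            clusters=[dict(stat=c.stat, p=c.p_value) for c in res.clusters])
    return dict(freqs=freqs.tolist(), sessions=results)


def stage_decoding(epochs, config: PipelineConfig,
                   pairs=(("HS", "AI-NF"), ("HS", "AI-FT"),
                          ("AI-NF", "AI-FT"))):
    """Offset-aligned per-subject pairwise decoding curves."""
    aligned = decode.offset_align(epochs)
    subjects = sorted(aligned.trials["subject"].unique())
    step = max(config.decode_time_step, 1)
    tidx = np.arange(0, aligned.data.shape[-1], step)
    out = {}
    for pair in pairs:
        curves = []
        for subj in subjects:
            sub = aligned.select_trials(
                (aligned.trials["subject"] == subj).to_numpy())
            sub = decode.zscore_channels(sub)
            cfg = decode.DecodingConfig(seed=config.synth.seed + subj)
            res = decode.decode_timecourse(sub, pair, cfg, time_indices=tidx)
            curves.append(res["accuracy"])
        curves = np.stack(curves)
        mean_curve = curves.mean(axis=0)
        if len(subjects) >= 2 and curves.std(axis=0).min() > 0:
            ps = [sdt.paired_t(curves[:, j], np.full(len(subjects), 0.5))["p"]
                  for j in range(curves.shape[1])]
            n_sig = int((sdt.fdr_adjust(ps) < config.alpha).sum())
        else:
            n_sig = 0
        out[" vs ".join(pair)] = dict(
            time=res["time"].tolist(), mean_accuracy=mean_curve.tolist(),
            grand_mean=float(mean_curve.mean()),
            n_sig_timepoints_fdr=n_sig)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the results bundle."""
    report: dict = {"config": dict(seed=config.synth.seed,
                                   kernel_mode=config.kernel_mode,
                                   effect_scale=config.effect_scale,
                                   n_perm=config.n_perm,
                                   stages=list(config.stages))}
    stimuli = behavior = epochs = None
    if "synth" in config.stages:
        logger.info("stage synth: generating stimuli, behavior, EEG")
        stimuli = synth.gen_stimuli(config.synth)
        behavior = synth.gen_behavior(config.synth)
        kernels = synth.gen_true_kernels(config.kernel_mode,
                                         effect_scale=config.effect_scale)
        epochs = synth.gen_eeg(stimuli, kernels, config.synth)
        report["synth"] = dict(n_stimuli=len(stimuli),
                               n_trials_behavior=len(behavior),
                               n_epochs=int(epochs.data.shape[0]))
    try:
        if "acoustics" in config.stages:
            logger.info("stage acoustics")
            report["acoustics"] = stage_acoustics(stimuli, config)
        if "behavior" in config.stages:
            logger.info("stage behavior")
            report["behavior"] = stage_behavior(behavior, config)
        if "trf" in config.stages:
            logger.info("stage trf")
            trf_res = stage_trf(epochs, stimuli, config)
            trf_res.pop("per_subject")
            report["trf"] = trf_res
        if "spectra" in config.stages:
            logger.info("stage spectra")
            report["spectra"] = stage_spectra(epochs, config)
        if "decoding" in config.stages:
            logger.info("stage decoding")
            report["decoding"] = stage_decoding(epochs, config)
    except Exception as e:  # annotate which stage failed
        raise RuntimeError(f"pipeline stage failed: {e}") from e
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "results.json").write_text(json.dumps(report, indent=2))
    return report
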