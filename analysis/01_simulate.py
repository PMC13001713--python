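#!/usr/bin/env python
"""Generate the synthetic study: stimuli, behavioral judgments, and EEG.

Produces a desk-scale version of the experiment (fewer subjects and
sentences than the full design so later stages run in minutes):
stimuli as WAV plus a behavior CSV and two EEG epoch containers
(pre-training kernels for session S1, post-training kernels for S2)
under scratch/, and a summary under results/.

Run: python analysis/01_simulate.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

from speechtrace import synth

ROOT = Path(__file__).resolve().parents[1]


def study_config(seed: int) -> synth.SynthConfig:
    # 12 subjects x (12 sentences x 2 speakers) per condition/session
    return synth.SynthConfig(n_subjects=12, n_sentences_per_cell=12,
                             speakers=2, seed=seed, epoch_post=3.5,
                             snr_db=-6.0)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    cfg = study_config(args.seed)
    scratch = ROOT / "scratch" / "study"
    (scratch / "stimuli").mkdir(parents=True, exist_ok=True)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    stimuli = synth.gen_stimuli(cfg)
    for i, s in enumerate(stimuli):
        synth.write_wav(s, scratch / "stimuli" /
                        f"{s.condition}_{s.speaker}_{s.session}_{s.sentence:03d}.wav")
    print(f"wrote {len(stimuli)} stimuli "
          f"({len(stimuli) // 3} sentences x 3 conditions)")

    behavior = synth.gen_behavior(cfg)
    behavior.to_csv(scratch / "behavior.csv", index=False)
    print(f"wrote {len(behavior)} behavioral trials")

    for sess, mode in (("S1", "pre"), ("S2", "post")):
        kernels = synth.gen_true_kernels(mode, effect_scale=1.0)
        sess_stims = [s for s in stimuli if s.session == sess]
        epochs = synth.gen_eeg(sess_stims, kernels, cfg)
        epochs.to_dir(scratch / f"epochs_{sess}")
        print(f"session {sess} ({mode} kernels): "
              f"{epochs.data.shape[0]} epochs x {epochs.data.shape[1]} ch")

    summary = dict(seed=args.seed, n_subjects=cfg.n_subjects,
                   n_stimuli=len(stimuli),
                   n_behavior_trials=len(behavior),
                   gains=cfg.mod_band_gains, snr_db=cfg.snr_db)
    (results / "simulation_summary.json").write_text(
        json.dumps(summary, indent=2))
    print("summary -> results/simulation_summary.json")


if __name__ == "__main__":
    main()
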