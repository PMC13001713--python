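#!/usr/bin/env python
"""Ridge TRF estimation and the spatiotemporal cluster contrast.

Fits per-trial ridge TRFs (lags -300..+600 ms, lambda=100) to the
simulated epochs, averages them within condition per subject, and runs
the dependent-samples cluster permutation test over channels x lags
(0-500 ms) separately for session S1 (pre-training kernels: no
condition differences expected beyond the acoustic confound) and S2
(post-training kernels: injected differences at 55/210/455 ms).

Run: python analysis/04_trf.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

import numpy as np

from speechtrace import synth
from speechtrace.cluster import adjacency_from_positions, permutation_test
from speechtrace.eeg import EpochSet
from speechtrace.trf import estimate_condition_trf, roi_timecourse

ROOT = Path(__file__).resolve().parents[1]

import importlib.util as _iu
_spec = _iu.spec_from_file_location("sim", Path(__file__).parent / "01_simulate.py")
_sim = _iu.module_from_spec(_spec)
_spec.loader.exec_module(_sim)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--nperm", type=int, default=500)
    args = ap.parse_args()
    cfg = _sim.study_config(args.seed)
    stimuli = synth.gen_stimuli(cfg)
    env_map = {(s.condition, s.speaker, s.session, s.sentence):
               synth.true_envelope(s) for s in stimuli}
    out = {}
    roi_curves = {}
    for sess in ("S1", "S2"):
        epochs = EpochSet.from_dir(ROOT / "scratch" / "study" /
                                   f"epochs_{sess}")
        subjects = sorted(epochs.trials["subject"].unique())
        per = {}
        for subj in subjects:
            sub = epochs.select_trials(
                (epochs.trials["subject"] == subj).to_numpy())
            envs = [env_map[(r.condition, r.speaker, r.session, r.sentence)]
                    for r in sub.trials.itertuples()]
            per[subj] = estimate_condition_trf(sub, envs)
        lags = per[subjects[0]][("HS", sess)].lags_ms
        lmask = (lags >= 0) & (lags <= 500)
        data = np.stack([
            np.stack([per[s][(c, sess)].weights[:, lmask]
                      for c in synth.CONDITIONS]) for s in subjects])
        adj = adjacency_from_positions(epochs.positions)
        res = permutation_test(data, "dependent", adjacency=adj,
                               n_perm=args.nperm, seed=args.seed + 13)
        print(f"session {sess}: {len(res.significant)} significant "
              f"cluster(s)")
        for c in res.significant:
            lo, hi = c.sample_range()
            print(f"  F-sum={c.stat:.1f} p={c.p_value:.4f} "
                  f"lags {lags[lmask][lo]:.0f}-{lags[lmask][hi]:.0f} ms")
        out[sess] = [dict(stat=c.stat, p=c.p_value,
                          lag_lo_ms=float(lags[lmask][c.sample_range()[0]]),
                          lag_hi_ms=float(lags[lmask][c.sample_range()[1]]))
                     for c in res.clusters]
        for c_name in synth.CONDITIONS:
            mean_w = np.mean([per[s][(c_name, sess)].weights
                              for s in subjects], axis=0)
            k = per[subjects[0]][(c_name, sess)]
            k2 = type(k)(weights=mean_w, lags_ms=k.lags_ms,
                         channels=k.channels)
            roi_curves[f"{sess}/{c_name}"] = roi_timecourse(k2).tolist()

    results = ROOT / "results"
    (results / "trf.json").write_text(json.dumps(dict(
        clusters=out, lags_ms=lags.tolist(), roi=roi_curves), indent=2))
    print("-> results/trf.json")


if __name__ == "__main__":
    main()
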