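#!/usr/bin/env python
"""EEG amplitude spectra (1-15 Hz) and their condition contrast.

Per trial: trim to the stimulus duration, drop the first 100 ms, Hann
taper, FFT zero-padded to 400 samples (0.25 Hz grid); average within
condition x session per subject; dependent-samples cluster permutation
test across conditions per session.

Run: python analysis/05_spectra.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

import numpy as np

from speechtrace import synth
from speechtrace.cluster import adjacency_from_positions, permutation_test
from speechtrace.eeg import EpochSet, amplitude_spectrum

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--nperm", type=int, default=500)
    args = ap.parse_args()
    out = {}
    for sess in ("S1", "S2"):
        epochs = EpochSet.from_dir(ROOT / "scratch" / "study" /
                                   f"epochs_{sess}")
        subjects = sorted(epochs.trials["subject"].unique())
        per = {}
        for subj in subjects:
            sub = epochs.select_trials(
                (epochs.trials["subject"] == subj).to_numpy())
            freqs, table = amplitude_spectrum(sub)
            per[subj] = table
        data = np.stack([
            np.stack([per[s][(c, sess)] for c in synth.CONDITIONS])
            for s in subjects])
        adj = adjacency_from_positions(epochs.positions)
        res = permutation_test(data, "dependent", adjacency=adj,
                               n_perm=args.nperm, seed=args.seed + 17)
        print(f"session {sess}: {len(res.clusters)} cluster(s), "
              f"{len(res.significant)} significant")
        out[sess] = [dict(stat=c.stat, p=c.p_value) for c in res.clusters]
    (ROOT / "results" / "spectra.json").write_text(
        json.dumps(dict(freqs=freqs.tolist(), clusters=out), indent=2))
    print("-> results/spectra.json")


if __name__ == "__main__":
    main()
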