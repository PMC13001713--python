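#!/usr/bin/env python
"""Acoustic contrast of the three speech types in the modulation spectrum.

Reads the WAV stimuli written by 01_simulate.py, extracts gammatone-band
envelopes, computes modulation spectra on a common grid, runs the
independent-samples cluster permutation test over 0-30 Hz, and averages
the 5.4-11.7 Hz band per sentence for paired post hoc t tests (BH-FDR).

Expected outcome with the default generator gains: the ordering
HS > AI-FT > AI-NF in band means with strongly significant paired post
hocs.  The independent-samples cluster test needs the full stimulus set
(198 items per type, as run by scripts/acceptance.py) for reliable
significance; at this demo scale (48 per type) it is underpowered.

Run: python analysis/02_acoustics.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from speechtrace import envelope as ev, sdt, synth
from speechtrace.cluster import permutation_test

ROOT = Path(__file__).resolve().parents[1]
BAND = (5.4, 11.7)


def load_stimuli(stim_dir: Path):
    stims = []
    for path in sorted(stim_dir.glob("*.wav")):
        cond, speaker, session, sent = path.stem.rsplit("_", 3)
        rate, x = wavfile.read(path)
        stims.append(ev.AudioStim(samples=x / 32767.0, rate=float(rate),
                                  condition=cond, speaker=speaker,
                                  session=session, sentence=int(sent)))
    return stims


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    stims = load_stimuli(ROOT / "scratch" / "study" / "stimuli")
    print(f"loaded {len(stims)} stimuli")
    envs = [ev.extract_envelope(s) for s in stims]
    freqs, amps, labels = ev.modulation_spectra_table(envs)
    conds = np.array([l["condition"] for l in labels])
    groups = [amps[conds == c][:, None, :] for c in synth.CONDITIONS]
    res = permutation_test(groups, "independent", n_perm=1000,
                           seed=args.seed + 11, min_nb_chan=0)
    print(f"clusters: {len(res.clusters)}, significant: "
          f"{len(res.significant)}")
    for c in res.significant:
        lo, hi = c.sample_range()
        print(f"  F-sum={c.stat:.1f}  p={c.p_value:.4f}  "
              f"{freqs[lo]:.2f}-{freqs[hi]:.2f} Hz")

    mask = (freqs >= BAND[0]) & (freqs <= BAND[1])
    band = {c: amps[conds == c][:, mask].mean(axis=1)
            for c in synth.CONDITIONS}
    pairs = [("HS", "AI-NF"), ("AI-FT", "AI-NF"), ("HS", "AI-FT")]
    stats = {f"{a} vs {b}": sdt.paired_t(band[a], band[b]) for a, b in pairs}
    padj = sdt.fdr_adjust([v["p"] for v in stats.values()])
    for (k, v), p in zip(stats.items(), padj):
        v["p_fdr"] = float(p)
        print(f"  band {k}: t={v['t']:.2f} p_fdr={v['p_fdr']:.2g} "
              f"d={v['cohens_d']:.2f}")

    out = ROOT / "results"
    pd.DataFrame({c: s.mean(axis=0) for c, s in
                  zip(synth.CONDITIONS, (amps[conds == c] for c in
                                         synth.CONDITIONS))},
                 index=pd.Index(freqs, name="freq_hz")) \
        .to_csv(out / "modulation_spectra.csv")
    (out / "acoustics.json").write_text(json.dumps(dict(
        n_stimuli=len(stims),
        clusters=[dict(stat=c.stat, p=c.p_value,
                       f_lo=float(freqs[c.sample_range()[0]]),
                       f_hi=float(freqs[c.sample_range()[1]]))
                  for c in res.clusters],
        band_means={c: float(v.mean()) for c, v in band.items()},
        posthoc=stats), indent=2))
    print("-> results/acoustics.json, results/modulation_spectra.csv")


if __name__ == "__main__":
    main()
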