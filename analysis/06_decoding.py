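#!/usr/bin/env python
"""Time-resolved decoding of speech type from EEG topographies.

Offset-aligned 1.5 s epochs, per-channel z-scoring, and a nested-CV
linear SVM per time point (subsampled grid) for each pair of speech
conditions, per subject; subject-mean curves and the count of
FDR-significant time points are reported.

Run: python analysis/06_decoding.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

from speechtrace.eeg import EpochSet
from speechtrace.pipeline import PipelineConfig, stage_decoding

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--session", default="S2")
    args = ap.parse_args()
    epochs = EpochSet.from_dir(ROOT / "scratch" / "study" /
                               f"epochs_{args.session}")
    cfg = PipelineConfig(decode_time_step=50)   # 3 time points per curve
    cfg.synth = cfg.synth.with_(seed=args.seed)
    res = stage_decoding(epochs, cfg)
    for pair, r in res.items():
        print(f"{pair}: grand mean accuracy {100 * r['grand_mean']:.1f}%  "
              f"significant time points (FDR): {r['n_sig_timepoints_fdr']}")
    (ROOT / "results" / f"decoding_{args.session}.json").write_text(
        json.dumps(res, indent=2))
    print(f"-> results/decoding_{args.session}.json")


if __name__ == "__main__":
    main()
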