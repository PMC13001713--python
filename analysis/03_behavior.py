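#!/usr/bin/env python
"""Signal-detection analysis of the simulated human/AI judgments.

Builds per-subject confusion matrices with the study's pooling rules
(HS target: both AI conditions pooled as noise; AI target: the other AI
condition discarded), computes d' and criterion, runs the Speech type x
Session repeated-measures ANOVA, and session post hocs with BH-FDR.

Expected outcome with the default observer: low d' everywhere (< 1), a
strong speech-type main effect, and a criterion shift toward
conservative responding in session 2 — training changes bias, not
sensitivity.

Run: python analysis/03_behavior.py
"""

import json
from pathlib import Path

import pandas as pd

from speechtrace.pipeline import PipelineConfig, stage_behavior
from speechtrace import sdt

ROOT = Path(__file__).resolve().parents[1]


def main():
    trials = pd.read_csv(ROOT / "scratch" / "study" / "behavior.csv")
    table = sdt.sdt_table(trials)
    res = stage_behavior(trials, PipelineConfig())
    print("d' cell means:")
    for k, v in res["cell_means"]["d_prime"].items():
        print(f"  {k}: {v:.3f}")
    a = res["d_prime"]["anova"]
    print(f"d' rmANOVA: speech type F{tuple(a['A']['df'])}={a['A']['F']:.2f} "
          f"p={a['A']['p']:.2g}; session F{tuple(a['B']['df'])}="
          f"{a['B']['F']:.2f} p={a['B']['p']:.2g}")
    c = res["criterion"]["anova"]
    print(f"criterion rmANOVA: session F{tuple(c['B']['df'])}="
          f"{c['B']['F']:.2f} p={c['B']['p']:.2g}")

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    table.to_csv(out / "sdt_table.csv", index=False)
    (out / "behavior.json").write_text(json.dumps(res, indent=2))
    print("-> results/behavior.json, results/sdt_table.csv")


if __name__ == "__main__":
    main()
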