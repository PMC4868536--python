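#!/usr/bin/env python
"""Generate a demonstration cohort and summarize its behavior.

Simulates 8 subjects (full 1080-trial design, behavior only — the EEG stages
regenerate their own data at the sizes they need), writes the behavior
summary under results/cohort/ (full per-subject trial tables go to scratch/,
they are regenerated exactly from the seed), and prints the
THREAT+/THREAT- accuracy split that motivates the modelling.
"""

from pathlib import Path

import pandas as pd

import threatsense as ts
from threatsense import recovery as R

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "cohort"
OUT.mkdir(parents=True, exist_ok=True)
RAW = ROOT / "scratch" / "cohort"
RAW.mkdir(parents=True, exist_ok=True)

trials = R.simulate_behavior_cohort(8, seed=101)
for sid, tr in trials.items():
    tr.to_csv(RAW / f"{sid}_trials.csv", index=False)

big = pd.concat(trials.values())
summary = ts.summarize_behavior(big)
summary.to_csv(OUT / "behavior_summary.csv", index=False)

th = summary[summary["emotion"] == "all"].set_index("threat_label")
print(f"simulated {len(trials)} subjects x {len(next(iter(trials.values())))} trials")
print(f"accuracy THREAT+ : {th.loc['THREAT+', 'accuracy']:.3f}")
print(f"accuracy THREAT- : {th.loc['THREAT-', 'accuracy']:.3f}")
print("threat-signaling gaze-emotion pairings are categorized more accurately,")
print("as expected when their perceptual sensitivity (w) is multiplicatively higher")
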