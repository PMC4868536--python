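#!/usr/bin/env python
"""Anxiety coupling and group-level statistical calibration.

Recovers the programmed anxiety x threat-gain correlation from a 24-subject
cohort (temporal encoding path), screens for outliers with leave-one-out
prediction intervals, and reports the calibration of the cluster-based
permutation test and the jackknife onset test on matched null/effect
simulations.  Writes results/groupstats/.
"""

import json
from pathlib import Path

import threatsense as ts
from threatsense import recovery as R

OUT = Path(__file__).resolve().parents[1] / "results" / "groupstats"
OUT.mkdir(parents=True, exist_ok=True)

anx = R.anxiety_recovery(n_subjects=24, seed=501)
anx["gains"].to_csv(OUT / "temporal_gains.csv", index=False)
anx["anxiety"].to_csv(OUT / "anxiety_scores.csv", index=False)
print(f"anxiety x threat-gain correlation: r = {anx['r']:.3f} "
      f"(generative rho = {anx['true_rho']}), p = {anx['p']:.4f}")
print(f"median-split interaction: F(1,22) = {anx['interaction_F']:.1f}, "
      f"p = {anx['interaction_p']:.4f}")
print(f"leave-one-out screen flagged {anx['n_outliers']} subject(s)")

fw = R.cluster_fwer(n_replicates=200, seed=502)
print(f"\ncluster permutation family-wise error (200 null replicates): "
      f"{fw['fwer']:.3f}")

det = R.onset_difference_detection(n_replicates=20, seed=503)
nul = R.onset_null_rejection(n_replicates=40, seed=504)
print(f"jackknife onset test: detection rate {det['detection_rate']:.2f} "
      f"(150 vs 540 ms), null rejection rate {nul['rejection_rate']:.3f}")

p_diff = ts.compare_correlations(0.66, -0.42, 12, 12)
print(f"Fisher z difference between r = 0.66 and r = -0.42 (n = 12 each): "
      f"p = {p_diff:.4f}")

summary = {
    "anxiety_r": anx["r"], "anxiety_p": anx["p"],
    "interaction_F": anx["interaction_F"], "interaction_p": anx["interaction_p"],
    "cluster_fwer": fw["fwer"],
    "onset_detection_rate": det["detection_rate"],
    "onset_null_rejection_rate": nul["rejection_rate"],
    "correlation_difference_p": p_diff,
}
(OUT / "summary.json").write_text(json.dumps(summary, indent=2))
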