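#!/usr/bin/env python
"""Recover the programmed THREAT+ gain in single-trial EEG encoding.

Simulates 24 subjects whose temporal-channel amplitude encodes emotion
strength with a 1.5x multiplier on THREAT+ trials, fits per-subject
condition-split encoding GLMs, and reports the recovered group gain ratio
and encoding peak latency.  Writes results/encoding/.
"""

import json
from pathlib import Path

from threatsense import recovery as R

OUT = Path(__file__).resolve().parents[1] / "results" / "encoding"
OUT.mkdir(parents=True, exist_ok=True)

ratio = R.encoding_gain_ratio(n_subjects=24, seed=201)
peak = R.encoding_peak_latency(n_subjects=12, seed=202)

(OUT / "gain_ratio.json").write_text(json.dumps({**ratio, **peak}, indent=2))
print(f"group beta THREAT+ = {ratio['beta_plus']:.4f} a.u./strength unit")
print(f"group beta THREAT- = {ratio['beta_minus']:.4f} a.u./strength unit")
print(f"recovered gain ratio = {ratio['ratio']:.3f} (programmed {ratio['true_ratio']})")
print(f"encoding peak at {1000 * peak['peak_s']:.0f} ms "
      f"(programmed {1000 * peak['true_peak_s']:.0f} ms)")
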