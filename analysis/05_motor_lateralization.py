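#!/usr/bin/env python
"""Motor-preparatory encoding of emotion strength: fast vs slow responses.

Simulates 12 subjects whose 8-32 Hz motor lateralization encodes signed
emotion strength from 150 ms on fast trials but only from 540 ms on slow
trials, runs the full spectral path (multitaper power, hand-referenced
lateralization, within-strength-level RT split), and jackknifes the group
onset difference.  Writes results/motor/.

The group-level acceptance checks rerun this at 24 subjects; 12 keeps this
driver quick.
"""

import json
from pathlib import Path

from threatsense import recovery as R

OUT = Path(__file__).resolve().parents[1] / "results" / "motor"
OUT.mkdir(parents=True, exist_ok=True)

res = R.motor_rt_split_onsets(n_subjects=12, seed=401)
(OUT / "rt_split_onsets.json").write_text(json.dumps(res, indent=2, default=float))

print(f"fast-trial encoding onset : {1000 * res['onset_fast_s']:.0f} ms")
print(f"slow-trial encoding onset : {1000 * res['onset_slow_s']:.0f} ms")
print(f"jackknife t = {res['t']:.2f}, p = {res['p']:.4f}")
print("(multitaper smoothing shifts both onsets earlier by a similar amount;")
print(" the fast-slow difference is the recovered quantity)")
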