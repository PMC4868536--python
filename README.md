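# threatsense

Analysis pipeline for a question in social perceptual decision-making: when a
facial emotion is paired with the gaze direction that makes it
threat-signaling — anger looking *at* you, fear looking *away* — does the
brain shift its decision criterion toward that emotion (an additive **bias**,
`b`), or multiplicatively raise its perceptual **sensitivity** to it (a gain
on the evidence, `w`)?  The package implements the full computational chain
used to answer this with behavior and EEG, and — since no recordings are
public for this design — a synthetic-data generator that reproduces the
experiment's statistical structure so every stage is validated by parameter
recovery.

The observer model is a lapse-contaminated probit psychometric function over
signed emotion strength `x ∈ {−7..+7}` (morph distance from neutral,
negative = fear):

    P(anger) = Φ(w·x + b)·(1 − ε) + ε/2

compared across three nested variants (no context effect; gaze-dependent
`b`; THREAT±-dependent `w`) by 10-fold cross-validated evidence with
fixed-effects Bayes factors and random-effects exceedance probabilities.
The same logic runs on the neural side: single-trial EEG amplitude is
regressed on emotion strength per channel and time point (neural encoding);
encoding residuals `e` re-enter the choice model additively (`b_mod·e`) or
multiplicatively (`w_mod·e·x`) to ask *how* neural fluctuations drive
decisions; 8–32 Hz multitaper power over motor cortex yields a
hand-referenced lateralization index whose signed-strength encoding onset is
compared across conditions and response speeds; and group-level inference
uses sign-flip cluster permutation, jackknife onset tests, BIC Bayes factors
for evidence of absence, and anxiety median-split/correlation analyses.

Intended users: cognitive/computational neuroscientists who want a tested
reference implementation of this analysis chain, or a calibrated synthetic
testbed for psychometric model selection and EEG-informed choice modelling.

## Layout

- `src/threatsense/` — the library: `design`, `observer`, `eegsim`, `cohort`
  (synthetic data); `psychometric`, `modelselect` (behavioral models);
  `encoding`, `mediation`, `motor` (EEG analyses); `groupstats`;
  `recovery` (study-scale recovery experiments); `pipeline`, `cli`.
- `analysis/01…06_*.py` — numbered drivers, one per analysis stage; each
  prints what it found and writes tables under `results/`.
- `scripts/acceptance.py` — recomputes the headline numbers from scratch.

## Worked example

```
$ python analysis/02_fit_behavior.py
subject_id  w_plus  w_minus      b  lapse     nll
       s01   0.499    0.310 -0.002  0.055 395.079
       s02   0.382    0.325  0.044  0.012 379.437
       ...
mean w+ = 0.430 (true 0.45), mean w- = 0.296 (true 0.30)
fixed-effects log10 BF (sensitivity vs bias) = 2.92
exceedance probabilities: {'null': 0.0123, 'bias': 0.0408, 'sensitivity': 0.9469}
```

Eight simulated subjects were generated from the sensitivity variant
(w⁺ = 0.45 on THREAT+, w⁻ = 0.30 on THREAT−).  The per-subject maximum-
likelihood estimates recover both gains; the cross-validated evidence favors
the sensitivity variant over the bias variant by ~2.9 log10 units jointly
across the 8 subjects, and the random-effects analysis puts ~0.95
probability on sensitivity being the most frequent generating model — the
model-selection signature of a multiplicative threat effect (decisive at the
full 24-subject scale, see the acceptance results).

A 15-second end-to-end demo (4 subjects, reduced design, all stages):

```
threatsense demo --out runs/demo --seed 3
```

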