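# Methods

`threatsense` reimplements, over fully synthetic data, the analysis chain of
an emotion-categorization EEG experiment in which gaze direction acts as an
implicit threat context: anger with direct gaze and fear with averted gaze
(THREAT+ pairings) signal more threat to the observer than the complementary
pairings (THREAT-).  The scientific question the chain addresses is whether
this context shifts the decision criterion (an additive bias) or
multiplicatively raises perceptual sensitivity to the threat-signaling
emotion — behaviorally, in broadband EEG, and in motor-preparatory
oscillations.  Because no public recordings exist for this design, a
synthetic-data generator is a first-class component: every downstream stage
is validated by recovering parameters the generator injected.

## Observer model

Choices follow a probit psychometric family with a lapse mixture,

    P(anger) = Φ(w·x + b)·(1 − ε) + ε/2,

with signed emotion strength x ∈ {−7..+7} (negative = fear), sensitivity w,
additive bias b, and lapse rate ε ∈ [0, 1] (no 0.5 cap).  Three nested
variants: *null* (single w, b), *bias* (b depends on gaze direction — the
criterion shifts toward the threat-consistent response under each gaze), and
*sensitivity* (w depends on the THREAT± pairing).  ε, and b outside the bias
variant, are shared across conditions.  Neutral trials enter fits at x = 0;
they inform b and ε.  Cohort default: sensitivity variant with w⁺ = 0.45,
w⁻ = 0.30, b = 0, ε = 0.05 — effect sizes that produce the ~5–8 point
THREAT+ accuracy advantage typical of this paradigm.

Fitting is maximum likelihood on response counts aggregated into
(strength × condition) binomial cells, with analytic gradients, L-BFGS-B,
a logit transform for ε, and one fixed plus 10 seeded random starts
(cross-validation refits warm-start from the full-data fit and use fewer
restarts; the aggregated objective is smooth enough that restarts agree to
<0.01 log-units).  w and b are box-bounded at ±10 purely to keep degenerate
data finite; a solution at a bound is flagged as non-converged.

Model evidence is 10-fold cross-validated log-likelihood with folds
stratified by emotion × gaze × strength and **shared across variants**, so
evidence differences cannot come from partition noise.  Fixed-effects
comparison sums evidence differences over subjects (reported as log10 Bayes
factors; linear BF only within |log10| < 12).  Random-effects comparison
uses a variational Dirichlet model of per-subject model frequencies;
exceedance probabilities use the closed-form Beta tail for two models and
seeded Dirichlet Monte-Carlo otherwise.

## Synthetic design and EEG

The stimulus design is enumerated exactly: 36 identities (half female) × (7
morph levels × 2 emotions × 2 gazes + 2 neutral) = 1080 stimuli, each shown
once, dealt into 9 blocks of 120 balanced on emotion, gaze, gender and
morph level (stratified round-robin assignment, then within-block shuffle —
the balancing algorithm itself is our choice).  RTs are lognormal with the
median falling linearly in |x| (0.95 s at neutral, −0.05 s per strength
unit, σ = 0.25, clipped at the 2 s deadline): a descriptive stand-in, since
no RT model is fitted anywhere downstream.

Broadband channels are organized in three groups (temporal, centro-parietal,
frontal; four electrodes each).  Each group's signal is

    y(trial, t) = m·g·gain(t) + e·profile(t) + N(0, noise_sd²)

with unsigned strength m, condition gain g (1 on THREAT−, 1.5 on THREAT+ by
default), a Gaussian gain time course (temporal/frontal peak 280 ms,
centro-parietal 500 ms), a shared per-trial standard-normal residual e with
its own time profile, and white sensor noise (sd 1).  The gain amplitude
(0.12 a.u. per strength unit) gives single-subject peak encoding t-values
near 7 and group effects comparable to human cohorts.  Epochs default to
−0.2..1.0 s at 500 Hz (the analysis window); motor simulations use
−0.5..1.5 s so the lowest-frequency taper windows keep support over the
analysis range.

Residual–choice coupling is generated in two passes: residuals e are drawn
first, then choices are re-simulated from the mediation equation
Φ((w + w_mod·e)·x + b + b_mod·e) (observer lapse retained), so recovered
modulators have exact ground truth.  Defaults couple the centro-parietal
group multiplicatively (w_mod = 0.1, b_mod = 0); the additive comparison
condition uses b_mod = 0.3, chosen to match the multiplicative coupling's
drive magnitude (sd(w_mod·e·x) ≈ sd(b_mod·e)).  The mediation fits omit the
lapse term, matching the fitted equations; the resulting slight attenuation
is realistic and does not affect model identification.

Motor channels (C3/CP3/P3 vs C4/CP4/P4) carry band-limited 8–32 Hz carriers
whose envelopes implement a signed lateralization: power contralateral to
the anger hand is suppressed by lat/2 and contralateral to the fear hand
raised by lat/2, where lat(t) combines a choice-locked preparation ramp
(gain 0.5, rising over the 300 ms before the response) and a
signed-strength encoding ramp (0.06 per strength unit) whose onset is 200 ms
on THREAT+ trials and 440 ms on THREAT− trials (or 150/540 ms for
fast/slow trials in the RT-split mode).  Flipping the hand mapping swaps
the physical hemispheres while leaving broadband channels untouched.

Cohorts draw STAI state scores from N(30.5, 6.8²) and trait from
N(38.2, 7.8²), clipped to the inventory's 20–80 range.  State anxiety is
coupled to two generative parameters as exact Pearson constructions
(ρ·z + √(1−ρ²)·noise): the temporal THREAT+ − THREAT− gain difference
(ρ = −0.5; between-subject sd 0.35, wide enough that individual subjects can
show no difference or an inverted one, matching the dispersion such cohorts
show) and the motor THREAT+ encoding gain (ρ = +0.5, relative sd 0.5).

What the generator does **not** emulate: scalp topography and volume
conduction, 1/f background spectra, artifacts, trial-order or learning
effects, and between-subject variability in psychometric parameters.
Passing recovery tests therefore demonstrates correctness and calibration of
the estimators under the assumed statistical structure, not robustness to
real-EEG nuisance structure.

## Encoding, mediation, spectral analyses

Encoding is ordinary least squares of single-trial amplitude on unsigned
strength (plus optional identity-level threat/trust ratings), independently
per channel and time point, intercept always included.  Regressors are
z-scored per subject by default so betas are unit-free and comparable across
subjects (a raw-scale option exists; condition-split and recovery analyses
use raw slopes since the generator's units are known).  Condition splits
exclude neutral trials.  Residual scores for the mediation analysis average
residuals over the electrodes of interest at one time point and are z-scored
within subject.

Mediation models are probit regressions of choice on {x, e, e·x} —
additive (b_mod), multiplicative (w_mod), or combined — with w and b
re-estimated jointly at each time point, no temporal regularization, and CV
evidence on the same shared-fold machinery as the behavioral fits.

Spectral power uses a multitaper transform (Slepian tapers, 8–32 Hz in 2 Hz
steps, 5 cycles per window, 3 tapers, i.e. time-bandwidth 4), yielding
frequency smoothing of ±0.4·f.  Samples within half a taper window of an
epoch edge are set to NaN rather than reported from zero-padded data.  The
lateralization index band-averages power (uniform weights), averages each
hemisphere's triplet, and signs the difference by the subject's hand mapping
as contralateral-to-fear-hand minus contralateral-to-anger-hand activity, so
positive values mark anger-hand preparation and signed-strength slopes come
out positive.  The RT split is computed within each strength level
(removing the strength–RT confound) and is balanced to within one trial per
level; levels with <4 trials are dropped with a warning.

Because the 8 Hz tapers span 625 ms, multitaper smoothing advances detected
onsets by roughly 150–180 ms in both conditions; onset *differences* are
preserved, and all onset claims through the spectral path are made on
differences, not absolute latencies.

## Group statistics

Cluster-based permutation: per time point one-sample t across subjects;
contiguous same-sign runs past the two-sided α = 0.05 critical value form
clusters scored by summed t (mass).  The null is 1000 seeded sign-flip
permutations scored by the maximal |mass| (sign-flipping is the exact
permutation scheme for paired condition differences); corrected p-values use
the add-one estimator (count+1)/(n_perm+1).  Clustering is over time only,
at preselected electrode groups.

Onset latency: first time at which uncorrected significance is sustained
for 20 ms (at least 3 samples on any grid), with the critical-value crossing
linearly interpolated so the latency varies continuously with the data.  A
fixed 3-sample rule at 500 Hz spans only 6 ms and admits isolated false
runs that destabilize the jackknife test, and a non-interpolated (discrete)
onset underestimates jackknife variance; both choices were validated by the
calibration experiments in `threatsense.recovery` (null rejection ≈ 0.05,
detection of a 390 ms onset difference ≈ 1.0 at n = 24).  The jackknife test
recomputes onsets on each leave-one-subject-out subsample and applies the
(n−1)/n variance correction with n−1 degrees of freedom; an onset undefined
in any subsample flags the result rather than raising.

Evidence-of-absence Bayes factors model per-subject effects as normal with
free σ, comparing μ = 0 against free μ by BIC (bf10 = exp(−ΔBIC/2); below
1/3 is substantial evidence for the null).  The anxiety analysis
median-splits subjects (odd n: the median subject joins the low group),
computes the 2 × 2 mixed-design interaction (for two groups × two conditions
the interaction F is exactly the squared two-sample t on the within-subject
difference; verified against a general mixed-ANOVA implementation), the
Pearson correlation of anxiety with the THREAT+ − THREAT− gain difference,
and a leave-one-out 95% prediction-interval outlier screen with the
correlation recomputed after exclusion.  Correlation pairs are compared with
the independent-groups Fisher z test (Steiger's Z for dependent overlapping
correlations).

## Problem sizes and determinism

All recovery experiments run at the design's own scale — 24 subjects × 1080
trials — with two deliberate reductions: EEG cohorts simulate only the
channel group under analysis (the groups are statistically independent by
construction), and the spectral pipeline decimates the power time course to
100 Hz (power varies on the taper-window scale, so nothing is lost).  The
demo pipeline (4 subjects, 12 identities) exercises every stage end to end
in under a minute.  Every stochastic routine takes an explicit seed and
spawns all internal streams from it; reruns are bit-identical.

## Known limitations

Single-subject gain-*ratio* estimates are noisy (the denominator is a noisy
slope); group ratios are computed as ratios of group-mean betas.  The bias
variant can imitate much of the sensitivity variant's accuracy pattern at
small trial counts, so variant identification needs full-scale cohorts (the
4-subject demo may select either).  Exceedance probabilities at small n
follow the variational approximation, not exact posterior sampling.  The
lapse-free mediation fits mildly attenuate modulator estimates when the
generating observer lapses; an option fixes ε from the behavioral fit.
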