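"""Study-scale parameter-recovery and calibration experiments.

Each function regenerates synthetic data at the study's scale (24 subjects x
1080 trials unless stated), runs the corresponding analysis end to end, and
returns the recovered quantities together with the generative truth.  These
are the experiments behind the numbered analysis drivers and the acceptance
checks; all randomness derives from the ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .cohort import CohortConfig, iter_cohort
from .design import generate_trial_table
from .eegsim import MotorConfig, SynthEEGConfig, default_groups, simulate_eeg
from .encoding import condition_encoding, encode_glm, extract_residual_score
from .groupstats import (
    anxiety_analysis,
    bic_bayes_null,
    cluster_permutation,
    jackknife_onset_diff,
)
from .mediation import fit_mediation, mediation_cv_evidence, select_mediation_model
from .modelselect import exceedance_prob
from .motor import lateralization_index, multitaper_power, rt_split_encoding
from .observer import simulate_observer
from .psychometric import ObserverParams, evidence_table, fit_psychometric

TRUE_OBSERVER = ObserverParams(variant="sensitivity", w=(0.45, 0.30), b=0.0, lapse=0.05)


# ---------------------------------------------------------------------------
# behavior

def simulate_behavior_cohort(n_subjects: int, seed: int, observer=TRUE_OBSERVER):
    """Trial tables for a behavior-only cohort (no EEG)."""
    rng = np.random.default_rng(seed)
    out = {}
    for s in range(n_subjects):
        sid = f"s{s + 1:02d}"
        tt = generate_trial_table(seed=int(rng.integers(2**31)), subject_id=sid)
        out[sid] = simulate_observer(tt, observer, seed=int(rng.integers(2**31)))
    return out


def _subject_bootstrap_ci(tr, fit, n_boot, seed, level=0.95):
    """Trial-level bootstrap CI of one subject's sensitivity-variant fit.

    Resampling 1080 trials with replacement is equivalent to drawing the
    per-cell trial counts from a multinomial and the per-cell "anger" counts
    from binomials at the empirical rates, so each bootstrap replicate refits
    on resampled cells (warm-started from the original fit).
    """
    from scipy.optimize import minimize

    from .psychometric import _cells, _nll_grad, _params_to_theta, _unpack

    cx, cw, cb, ck, cn = _cells(tr, "sensitivity")
    n_total = int(cn.sum())
    p_cell = cn / n_total
    p_anger = ck / cn
    warm = _params_to_theta(fit.params)
    bounds = [(-10, 10)] * 3 + [(-15, 15)]
    rng = np.random.default_rng(seed)
    est = np.empty((n_boot, 4))
    for b in range(n_boot):
        n_star = rng.multinomial(n_total, p_cell).astype(float)
        keep = n_star > 0
        k_star = rng.binomial(n_star[keep].astype(int), p_anger[keep]).astype(float)
        res = minimize(
            _nll_grad, warm,
            args=("sensitivity", cx[keep], cw[keep], cb[keep], k_star, n_star[keep]),
            jac=True, method="L-BFGS-B", bounds=bounds,
        )
        w_all, b_all, eps, _, _ = _unpack(res.x, "sensitivity")
        est[b] = [w_all[0], w_all[1], b_all[0], eps]
    a = 100 * (1 - level) / 2
    return np.percentile(est, a, axis=0), np.percentile(est, 100 - a, axis=0)


def psychometric_recovery(
    n_cohorts: int = 20,
    n_subjects: int = 24,
    n_boot: int = 99,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate cohorts: fit all variants, select models, bootstrap recovery.

    For each replicate cohort the sensitivity variant is fitted per subject
    with a trial-level bootstrap 95% CI per parameter (checked against the
    generative value), and random-effects selection over {null, bias,
    sensitivity} CV evidence yields the exceedance probability of the
    generating (sensitivity) variant.  ``covered_*`` columns report the
    fraction of subjects whose CI covers the truth.
    """
    truth = {"w_plus": 0.45, "w_minus": 0.30, "b": 0.0, "lapse": 0.05}
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_cohorts):
        cseed = int(rng.integers(2**30))
        trials = simulate_behavior_cohort(n_subjects, cseed)
        est = []
        covered = np.zeros((n_subjects, 4))
        for i, (sid, tr) in enumerate(trials.items()):
            fit = fit_psychometric(tr, "sensitivity", seed=cseed)
            est.append([fit.params.w[0], fit.params.w[1], fit.params.b,
                        fit.params.lapse])
            lo, hi = _subject_bootstrap_ci(tr, fit, n_boot, cseed + 7 * i + 1)
            tvals = np.array(list(truth.values()))
            covered[i] = (lo <= tvals) & (tvals <= hi)
        est = np.asarray(est)
        ev = evidence_table(trials, k=10, seed=cseed + 2)
        pexc = exceedance_prob(ev, seed=cseed + 3).exceedance_probs["sensitivity"]
        row = {"cohort": c, "p_exc_sensitivity": pexc}
        for j, name in enumerate(truth):
            row[f"mean_{name}"] = est[:, j].mean()
            row[f"covered_{name}"] = covered[:, j].mean()
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# broadband encoding

def _temporal_only_config(**group_overrides) -> SynthEEGConfig:
    g = replace(default_groups()["temporal"], **group_overrides)
    return SynthEEGConfig(groups={"temporal": g}, motor=None)


def encoding_gain_ratio(n_subjects: int = 24, seed: int = 0) -> dict:
    """Recover the programmed THREAT+/THREAT- gain ratio at the temporal peak.

    Group-level ratio of condition-split slopes averaged over the temporal
    electrodes in a +-20 ms window around the programmed peak.
    """
    cfg = _temporal_only_config()
    g = cfg.groups["temporal"]
    rng = np.random.default_rng(seed)
    bp, bm = [], []
    for s in range(n_subjects):
        tt = generate_trial_table(seed=int(rng.integers(2**31)), subject_id=f"s{s:02d}")
        tr = simulate_observer(tt, cfg.observer, seed=int(rng.integers(2**31)))
        eeg, truth = simulate_eeg(tr, cfg, seed=int(rng.integers(2**31)))
        cond = condition_encoding(eeg, truth.trials, zscore=False)
        win = np.abs(eeg.times - g.peak_time) <= 0.02
        bp.append(cond["THREAT+"].beta("morph_level")[:, win].mean())
        bm.append(cond["THREAT-"].beta("morph_level")[:, win].mean())
    ratio = float(np.mean(bp) / np.mean(bm))
    return {"ratio": ratio, "true_ratio": g.threat_plus_mult,
            "beta_plus": float(np.mean(bp)), "beta_minus": float(np.mean(bm)),
            "n_subjects": n_subjects}


def encoding_peak_latency(n_subjects: int = 12, seed: int = 0) -> dict:
    """Latency of the group-mean encoding peak vs the programmed 280 ms."""
    cfg = _temporal_only_config()
    rng = np.random.default_rng(seed)
    betas = []
    for s in range(n_subjects):
        tt = generate_trial_table(seed=int(rng.integers(2**31)))
        tr = simulate_observer(tt, cfg.observer, seed=int(rng.integers(2**31)))
        eeg, truth = simulate_eeg(tr, cfg, seed=int(rng.integers(2**31)))
        res = encode_glm(eeg, truth.trials[["morph_level"]], zscore=False)
        betas.append(res.beta("morph_level").mean(axis=0))
        times = eeg.times
    group = np.mean(betas, axis=0)
    peak = float(times[np.argmax(np.abs(group))])
    return {"peak_s": peak, "true_peak_s": cfg.groups["temporal"].peak_time,
            "n_subjects": n_subjects}


# ---------------------------------------------------------------------------
# neural-choice mediation

def _cp_config(w_mod: float, b_mod: float) -> SynthEEGConfig:
    cp = replace(default_groups()["centro_parietal"], w_mod_true=w_mod,
                 b_mod_true=b_mod)
    return SynthEEGConfig(groups={"centro_parietal": cp}, motor=None)


def mediation_selection(
    coupling: str, n_subjects: int = 24, seed: int = 0
) -> dict:
    """Model selection on a cohort with known residual-choice coupling.

    ``coupling`` is "multiplicative" (w_mod 0.1), "additive" (b_mod 0.3,
    matched in drive magnitude), or "none".  Residual scores are extracted
    from the EEG at the centro-parietal peak; additive and multiplicative
    mediation variants compete on shared 10-fold CV evidence.
    """
    params = {"multiplicative": (0.1, 0.0), "additive": (0.0, 0.3),
              "none": (0.0, 0.0)}[coupling]
    cfg = _cp_config(*params)
    chans = list(cfg.groups["centro_parietal"].channels)
    peak = cfg.groups["centro_parietal"].peak_time
    rng = np.random.default_rng(seed)
    ev = {}
    for s in range(n_subjects):
        sid = f"s{s:02d}"
        tt = generate_trial_table(seed=int(rng.integers(2**31)), subject_id=sid)
        tr = simulate_observer(tt, cfg.observer, seed=int(rng.integers(2**31)))
        eeg, truth = simulate_eeg(tr, cfg, seed=int(rng.integers(2**31)))
        res = encode_glm(eeg, truth.trials[["morph_level"]], residual_channels=chans)
        e = extract_residual_score(res, chans, peak)
        ev[sid] = mediation_cv_evidence(truth.trials, e, k=10,
                                        seed=int(rng.integers(2**31)))
    sel = select_mediation_model(pd.DataFrame(ev).T, seed=seed)
    return sel


def mediation_null_bf(
    n_replicates: int = 200, n_subjects: int = 24, seed: int = 0
) -> dict:
    """Null calibration: uncoupled residuals should favor the null BF.

    Per replicate, every subject's residual score is redrawn independently of
    behavior (the uncoupled generator's defining property), the multiplicative
    modulator is estimated per subject, and the group-level BIC Bayes factor
    of the w_mod effect is computed.  Reports the median bf10.
    """
    trials = simulate_behavior_cohort(n_subjects, seed)
    rng = np.random.default_rng(seed + 1)
    bfs = []
    for r in range(n_replicates):
        wmods = []
        for tr in trials.values():
            e = rng.standard_normal(len(tr))
            e = (e - e.mean()) / e.std()
            fit = fit_mediation(tr, e, "multiplicative")
            wmods.append(fit.w_mod)
        bfs.append(bic_bayes_null(np.asarray(wmods)).bf10)
    bfs = np.asarray(bfs)
    return {"median_bf10": float(np.median(bfs)),
            "frac_below_third": float(np.mean(bfs < 1 / 3)),
            "n_replicates": n_replicates}


# ---------------------------------------------------------------------------
# group statistics calibrations

def cluster_fwer(
    n_replicates: int = 500,
    n_subjects: int = 24,
    n_times: int = 600,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Family-wise error of the cluster permutation test under a Gaussian null."""
    rng = np.random.default_rng(seed)
    fw = 0
    for r in range(n_replicates):
        X = rng.standard_normal((n_subjects, n_times))
        res = cluster_permutation(X, n_perm=n_perm, seed=int(rng.integers(2**31)))
        fw += any(c.p_corrected <= 0.05 for c in res.clusters)
    return {"fwer": fw / n_replicates, "n_replicates": n_replicates}


def _ramp_cohort(rng, onset, times, n_subjects=24, slope=2.0, noise_sd=1.0,
                 rise=0.3):
    """Subject-wise encoding curves: linear rise from ``onset`` plus noise."""
    ramp = np.clip((times - onset) / rise, 0, None) * slope
    return ramp + noise_sd * rng.standard_normal((n_subjects, len(times)))


def onset_difference_detection(
    n_replicates: int = 20,
    onset_a: float = 0.150,
    onset_b: float = 0.540,
    n_subjects: int = 24,
    seed: int = 0,
    p_crit: float = 0.01,
) -> dict:
    """Jackknife detection rate for programmed fast/slow onsets (150 vs 540 ms)."""
    times = np.arange(-0.2, 1.0, 0.002)
    rng = np.random.default_rng(seed)
    hits = 0
    diffs = []
    for r in range(n_replicates):
        A = _ramp_cohort(rng, onset_a, times, n_subjects)
        B = _ramp_cohort(rng, onset_b, times, n_subjects)
        res = jackknife_onset_diff(A, B, times)
        hits += (not res.undefined) and res.p < p_crit
        if not res.undefined:
            diffs.append(res.diff)
    return {"detection_rate": hits / n_replicates,
            "mean_onset_diff_s": float(np.mean(diffs)) if diffs else np.nan,
            "n_replicates": n_replicates}


def onset_null_rejection(
    n_replicates: int = 60,
    onset: float = 0.300,
    n_subjects: int = 24,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Jackknife false-rejection rate when both conditions share an onset."""
    times = np.arange(-0.2, 1.0, 0.002)
    rng = np.random.default_rng(seed)
    rej = und = 0
    for r in range(n_replicates):
        A = _ramp_cohort(rng, onset, times, n_subjects)
        B = _ramp_cohort(rng, onset, times, n_subjects)
        res = jackknife_onset_diff(A, B, times)
        if res.undefined:
            und += 1
        elif res.p < alpha:
            rej += 1
    return {"rejection_rate": rej / n_replicates,
            "undefined_rate": und / n_replicates,
            "n_replicates": n_replicates}


# ---------------------------------------------------------------------------
# anxiety

def anxiety_gain_table(n_subjects: int = 24, seed: int = 0):
    """Per-subject THREAT+/- temporal encoding gains plus anxiety scores."""
    cfg = CohortConfig(
        n_subjects=n_subjects,
        eeg=_temporal_only_config(),
    )
    g = cfg.eeg.groups["temporal"]
    rows, anx_rows = [], []
    for sub in iter_cohort(cfg, seed=seed):
        cond = condition_encoding(sub.eeg, sub.trials, zscore=False)
        win = np.abs(sub.eeg.times - g.peak_time) <= 0.02
        rows.append(
            {
                "subject_id": sub.subject_id,
                "threat_plus": cond["THREAT+"].beta("morph_level")[:, win].mean(),
                "threat_minus": cond["THREAT-"].beta("morph_level")[:, win].mean(),
                "true_mult": sub.temporal_mult,
            }
        )
        anx_rows.append(
            {
                "subject_id": sub.subject_id,
                "state_score": sub.state_score,
                "trait_score": sub.trait_score,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(anx_rows), cfg


def anxiety_recovery(n_subjects: int = 24, seed: int = 0) -> dict:
    """Recover the generative anxiety-coupling correlation from the EEG path."""
    gains, anx, cfg = anxiety_gain_table(n_subjects, seed)
    res = anxiety_analysis(gains, anx)
    return {
        "r": res.correlation.r,
        "p": res.correlation.p,
        "true_rho": cfg.coupling_temporal,
        "interaction_F": res.interaction_F,
        "interaction_p": res.interaction_p,
        "n_outliers": len(res.correlation.outliers),
        "n_subjects": n_subjects,
        "gains": gains,
        "anxiety": anx,
    }


# ---------------------------------------------------------------------------
# motor RT-split, full spectral path

def motor_rt_split_onsets(n_subjects: int = 12, seed: int = 0) -> dict:
    """Fast vs slow motor-encoding onsets through the full spectral path.

    Simulates motor channels whose signed-strength encoding ramps earlier on
    fast trials (150 ms) than slow trials (540 ms), runs multitaper power,
    the hand-referenced lateralization index and the within-level RT split,
    and jackknifes the group onset difference.
    """
    motor = MotorConfig(rt_split_onsets=(0.150, 0.540))
    cfg = SynthEEGConfig(groups={}, epoch=(-0.5, 1.5), motor=motor)
    rng = np.random.default_rng(seed)
    fast, slow = [], []
    for s in range(n_subjects):
        mapping = "anger_left" if s % 2 == 0 else "anger_right"
        tt = generate_trial_table(seed=int(rng.integers(2**31)),
                                  subject_id=f"s{s:02d}", hand_mapping=mapping)
        tr = simulate_observer(tt, TRUE_OBSERVER, seed=int(rng.integers(2**31)))
        eeg, truth = simulate_eeg(tr, cfg, seed=int(rng.integers(2**31)))
        tfr = multitaper_power(eeg, decim=5)
        lat = lateralization_index(tfr, tr)
        enc = rt_split_encoding(lat, tr)
        fast.append(enc["fast"][0])
        slow.append(enc["slow"][0])
        times = enc["times"]
    valid = np.isfinite(np.vstack(fast)).all(axis=0) & np.isfinite(np.vstack(slow)).all(axis=0)
    F = np.vstack(fast)[:, valid]
    S = np.vstack(slow)[:, valid]
    res = jackknife_onset_diff(F, S, times[valid])
    return {
        "onset_fast_s": res.onset_a,
        "onset_slow_s": res.onset_b,
        "t": res.t,
        "p": res.p,
        "undefined": res.undefined,
        "n_subjects": n_subjects,
    }
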