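"""Synthetic EEG generator: ground truth, invariances, degenerate limits."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import threatsense as ts
from threatsense.eegsim import (
    GroupConfig,
    MotorConfig,
    SynthEEGConfig,
    default_groups,
    deterministic_broadband,
    simulate_eeg,
)
from threatsense.encoding import encode_glm
from threatsense.motor import lateralization_index, multitaper_power


@pytest.fixture(scope="module")
def small_trials(sens_params):
    d = ts.DesignParams(n_identities=6, n_blocks=1)
    tt = ts.generate_trial_table(d, seed=31, subject_id="s01")
    return ts.simulate_observer(tt, sens_params, seed=32)


def _uncoupled(groups):
    return {k: replace(g, w_mod_true=0.0, b_mod_true=0.0) for k, g in groups.items()}


def test_requires_choices():
    tt = ts.generate_trial_table(ts.DesignParams(n_identities=1, n_blocks=1), seed=0)
    with pytest.raises(ValueError, match="choices"):
        simulate_eeg(tt, SynthEEGConfig(motor=None))


def test_noise_sd_must_be_positive():
    with pytest.raises(ValueError, match="noise_sd"):
        SynthEEGConfig(noise_sd=0.0).validate()


def test_zero_gain_generator_yields_null_encoding(small_trials):
    """All gains zero: encoding t-values exceed the critical value at ~alpha."""
    from scipy import stats

    groups = {
        "temporal": replace(default_groups()["temporal"], amplitude=0.0,
                            resid_amplitude=0.0, w_mod_true=0.0)
    }
    cfg = SynthEEGConfig(groups=groups, motor=None)
    eeg, truth = simulate_eeg(small_trials, cfg, seed=40)
    res = encode_glm(eeg, truth.trials[["morph_level"]])
    t = res.tvals("morph_level")
    crit = stats.t.ppf(0.975, len(small_trials) - 2)
    rate = np.mean(np.abs(t) > crit)
    assert rate < 0.12


def test_ground_truth_predicts_noiseless_means(small_trials):
    """In the noise_sd -> 0 limit channels equal the deterministic record."""
    groups = _uncoupled(default_groups())
    cfg = SynthEEGConfig(groups=groups, motor=None, noise_sd=1e-9)
    eeg, truth = simulate_eeg(small_trials, cfg, seed=41)
    det = deterministic_broadband(truth.trials, cfg, truth.e_true)
    assert np.allclose(eeg.data, det, atol=1e-5)


def test_hand_mapping_flip_changes_motor_not_broadband(small_trials):
    """Flipping the mapping negates motor lateralization, broadband unchanged."""
    cfg = SynthEEGConfig(groups=_uncoupled(default_groups()), motor=MotorConfig())
    tr_l = small_trials.copy()
    tr_l["response_hand_mapping"] = "anger_left"
    tr_r = small_trials.copy()
    tr_r["response_hand_mapping"] = "anger_right"
    eeg_l, _ = simulate_eeg(tr_l, cfg, seed=42)
    eeg_r, _ = simulate_eeg(tr_r, cfg, seed=42)
    n_bb = sum(len(g.channels) for g in cfg.groups.values())
    assert np.array_equal(eeg_l.data[:, :n_bb], eeg_r.data[:, :n_bb])

    # choice-conditioned physical left-minus-right band power flips sign
    import warnings as _w

    def choice_contrast(eeg, tr):
        tfr = multitaper_power(eeg, picks=["C3", "C4"], decim=5)
        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            band = np.nanmean(tfr.power, axis=2)  # trials x 2 x time
        late = (tfr.times > 0.4) & (tfr.times < 0.9)
        lr = np.nanmean(band[:, 0, :][:, late] - band[:, 1, :][:, late], axis=1)
        anger = (tr["choice"] == "anger").to_numpy()
        return lr[anger].mean() - lr[~anger].mean()

    c_l = choice_contrast(eeg_l, tr_l)
    c_r = choice_contrast(eeg_r, tr_r)
    # anger prepared with the left hand suppresses the right hemisphere
    assert c_l > 0 > c_r


def test_coupling_resimulates_choices(small_trials):
    cfg = SynthEEGConfig(groups=default_groups(), motor=None)  # cp coupling on
    _, truth = simulate_eeg(small_trials, cfg, seed=43)
    assert truth.choices_resimulated
    cfg0 = SynthEEGConfig(groups=_uncoupled(default_groups()), motor=None)
    _, truth0 = simulate_eeg(small_trials, cfg0, seed=43)
    assert not truth0.choices_resimulated
    assert truth0.trials["choice"].equals(small_trials["choice"])


def test_cohort_anxiety_scores_in_stai_range():
    from threatsense.cohort import CohortConfig, simulate_cohort

    cfg = CohortConfig(
        n_subjects=24,
        design=ts.DesignParams(n_identities=1, n_blocks=1),
    )
    subs, anx = simulate_cohort(cfg, seed=44, with_eeg=False)
    assert len(subs) == 24
    assert anx["state_score"].between(20, 80).all()
    assert anx["trait_score"].between(20, 80).all()


def test_cohort_coupling_zero_gives_null_correlation():
    from threatsense.cohort import CohortConfig, iter_cohort
    from scipy import stats

    cfg = CohortConfig(
        n_subjects=40,
        design=ts.DesignParams(n_identities=1, n_blocks=1),
        coupling_temporal=0.0,
        coupling_motor=0.0,
    )
    subs = list(iter_cohort(cfg, seed=45, with_eeg=False))
    anx = np.array([s.state_score for s in subs])
    mult = np.array([s.temporal_mult for s in subs])
    r, p = stats.pearsonr(anx, mult)
    assert p > 0.01  # no generative coupling


def test_cohort_coupling_recovered_in_generative_parameters():
    """True per-subject gains correlate with anxiety at the requested rho."""
    from threatsense.cohort import CohortConfig, iter_cohort
    from scipy import stats

    cfg = CohortConfig(
        n_subjects=200,
        design=ts.DesignParams(n_identities=1, n_blocks=1),
    )
    subs = list(iter_cohort(cfg, seed=46, with_eeg=False))
    anx = np.array([s.state_score for s in subs])
    mult = np.array([s.temporal_mult for s in subs])
    gain = np.array([s.motor_enc_gain for s in subs])
    r_t = stats.pearsonr(anx, mult).statistic
    r_m = stats.pearsonr(anx, gain).statistic
    assert r_t == pytest.approx(-0.5, abs=0.15)
    assert r_m == pytest.approx(0.5, abs=0.15)


def test_cohort_rejects_bad_inputs():
    from threatsense.cohort import CohortConfig

    with pytest.raises(ValueError, match="n_subjects"):
        CohortConfig(n_subjects=2).validate()
    with pytest.raises(ValueError, match="coupling"):
        CohortConfig(coupling_motor=1.5).validate()
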