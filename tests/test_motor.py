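"""Multitaper power, lateralization index, signed encoding, RT split."""

import numpy as np
import pandas as pd
import pytest

import threatsense as ts
from threatsense.io import EEGEpochs
from threatsense.motor import (
    LateralizationSeries,
    lateralization_index,
    multitaper_power,
    rt_median_split,
    rt_split_encoding,
    signed_encoding,
)


def _osc_eeg(freq=20.0, amp=1.0, sfreq=250.0, n_trials=8, dur=2.0, channels=("C3", "C4")):
    t = np.arange(int(dur * sfreq)) / sfreq - 0.5
    sig = amp * np.cos(2 * np.pi * freq * t)
    data = np.tile(sig, (n_trials, len(channels), 1))
    return EEGEpochs(data=data, times=t, sfreq=sfreq, channel_names=list(channels))


def test_sinusoid_power_concentrates_at_its_frequency():
    """A 20 Hz oscillation dominates the bins near 20 Hz.

    The transform smooths over +-(time_bandwidth/2)/window = 0.4 f Hz, so the
    check compares near-band against far-sideband power rather than a single
    peak bin.
    """
    tfr = multitaper_power(_osc_eeg(freq=20.0))
    ti = np.nanargmin(np.abs(tfr.times - 0.5))
    spec = np.nanmean(tfr.power[:, :, :, ti], axis=(0, 1))
    fi = int(np.argmax(spec))
    assert abs(tfr.freqs[fi] - 20.0) <= 6.0
    near = spec[np.abs(tfr.freqs - 20.0) <= 6].mean()
    # sidebands whose own smoothing bandwidth (0.4 f) cannot reach 20 Hz
    far = spec[tfr.freqs * 1.4 < 20.0].mean()
    assert near >= 10 * far


def test_power_scales_quadratically_with_amplitude():
    t1 = multitaper_power(_osc_eeg(amp=1.0))
    t2 = multitaper_power(_osc_eeg(amp=2.0))
    ti = np.nanargmin(np.abs(t1.times - 0.5))
    fi = np.argmin(np.abs(t1.freqs - 20.0))
    p1 = np.nanmean(t1.power[:, :, fi, ti])
    p2 = np.nanmean(t2.power[:, :, fi, ti])
    assert p2 / p1 == pytest.approx(4.0, rel=0.05)


def test_band_power_tracks_signal_variance():
    """Total in-band power scales with the variance of a band-limited signal."""
    rng = np.random.default_rng(0)
    from threatsense.eegsim import _band_limited_noise

    t = np.arange(500) / 250.0
    for scale in (1.0, 3.0):
        sig = scale * _band_limited_noise(rng, (6, 2, 500), 250.0, (8, 32))
        eeg = EEGEpochs(data=sig, times=t - 0.5, sfreq=250.0,
                        channel_names=["C3", "C4"])
        tfr = multitaper_power(eeg)
        if scale == 1.0:
            base = np.nanmean(tfr.power)
        else:
            assert np.nanmean(tfr.power) / base == pytest.approx(9.0, rel=0.25)


def test_white_noise_spectrum_roughly_flat():
    rng = np.random.default_rng(1)
    t = np.arange(1000) / 500.0
    eeg = EEGEpochs(data=rng.standard_normal((40, 1, 1000)), times=t - 0.5,
                    sfreq=500.0, channel_names=["C3"])
    tfr = multitaper_power(eeg)
    ti = np.nanargmin(np.abs(tfr.times - 0.5))
    spec = np.nanmean(tfr.power[:, 0, :, ti], axis=0)
    assert spec.max() / spec.min() < 2.0


def test_epoch_too_short_for_lowest_frequency():
    with pytest.raises(ValueError, match="shorter"):
        multitaper_power(_osc_eeg(dur=0.5))


def _fake_lat(index, times, mapping="anger_left"):
    return LateralizationSeries(index=index, times=times, pairs=(),
                                hand_mapping=mapping)


def test_lateralization_symmetric_power_gives_zero():
    eeg = _osc_eeg(channels=("C3", "CP3", "P3", "C4", "CP4", "P4"))
    tfr = multitaper_power(eeg)
    tr = pd.DataFrame({"response_hand_mapping": ["anger_left"] * eeg.n_trials})
    lat = lateralization_index(tfr, tr)
    assert np.allclose(lat.index[:, np.isfinite(lat.index[0])], 0.0, atol=1e-9)


def test_lateralization_mapping_swap_negates_exactly():
    rng = np.random.default_rng(2)
    eeg = _osc_eeg(channels=("C3", "CP3", "P3", "C4", "CP4", "P4"))
    eeg.data += 0.3 * rng.standard_normal(eeg.data.shape)
    tfr = multitaper_power(eeg)
    tr_l = pd.DataFrame({"response_hand_mapping": ["anger_left"] * eeg.n_trials})
    tr_r = pd.DataFrame({"response_hand_mapping": ["anger_right"] * eeg.n_trials})
    lat_l = lateralization_index(tfr, tr_l)
    lat_r = lateralization_index(tfr, tr_r)
    finite = np.isfinite(lat_l.index)
    assert np.array_equal(lat_l.index[finite], -lat_r.index[finite])


def test_lateralization_missing_homologue_raises():
    eeg = _osc_eeg(channels=("C3", "C4"))
    tfr = multitaper_power(eeg)
    tr = pd.DataFrame({"response_hand_mapping": ["anger_left"] * eeg.n_trials})
    with pytest.raises(KeyError, match="missing"):
        lateralization_index(tfr, tr)


def test_noiseless_ramp_recovers_programmed_slope():
    """Index exactly proportional to signed strength: beta equals the slope."""
    rng = np.random.default_rng(3)
    x = rng.integers(-7, 8, size=40).astype(float)
    times = np.linspace(0, 1, 50)
    slope_t = 0.25 * times
    lat = _fake_lat(np.outer(x, slope_t), times)
    tr = pd.DataFrame({"signed_strength": x})
    enc = signed_encoding(lat, tr)
    beta, se = enc["all"]
    assert np.allclose(beta, slope_t, atol=1e-10)


def test_signed_encoding_threat_split_onsets():
    """Programmed per-condition ramps are recovered from a noisy index."""
    rng = np.random.default_rng(4)
    d = ts.DesignParams(n_identities=12, n_blocks=1)
    tt = ts.generate_trial_table(d, seed=5)
    x = tt["signed_strength"].to_numpy(float)
    times = np.arange(-0.2, 1.0, 0.002)
    onset = np.where(tt["threat_label"] == "THREAT+", 0.2, 0.44)
    ramp = np.clip((times[None, :] - onset[:, None]) / 0.2, 0, 1)
    lat = _fake_lat(0.1 * x[:, None] * ramp + 0.3 * rng.standard_normal((len(tt), len(times))), times)
    enc = signed_encoding(lat, tt, split="threat")
    bp, _ = enc["THREAT+"]
    bm, _ = enc["THREAT-"]
    i_early = (times > 0.25) & (times < 0.4)
    assert bp[i_early].mean() > 3 * bm[i_early].mean()


def test_rt_split_balanced_within_level(subject_trials):
    fast, slow = rt_median_split(subject_trials)
    per = subject_trials.assign(fast=fast, slow=slow).groupby("morph_level")
    for _, g in per:
        assert abs(int(g["fast"].sum()) - int(g["slow"].sum())) <= 1
    # fast trials really are faster, within every level
    med = subject_trials.assign(fast=fast, slow=slow)
    for _, g in med.groupby("morph_level"):
        assert g.loc[g["fast"], "rt"].max() <= g.loc[g["slow"], "rt"].min() + 1e-12


def test_rt_split_small_level_dropped():
    tr = pd.DataFrame(
        {
            "rt": [0.4, 0.5, 0.6, 0.7, 0.2, 0.3],
            "morph_level": [1, 1, 1, 1, 2, 2],
            "signed_strength": [1, 1, 1, 1, 2, 2],
        }
    )
    with pytest.warns(UserWarning, match="dropping"):
        fast, slow = rt_median_split(tr, min_per_level=4)
    assert not fast[tr["morph_level"] == 2].any()


def test_rt_split_encoding_runs(subject_trials):
    times = np.arange(-0.2, 1.0, 0.01)
    rng = np.random.default_rng(6)
    x = subject_trials["signed_strength"].to_numpy(float)
    lat = _fake_lat(
        0.05 * x[:, None] * np.clip(times / 0.3, 0, 1)
        + 0.2 * rng.standard_normal((len(x), len(times))),
        times,
    )
    out = rt_split_encoding(lat, subject_trials)
    assert out["fast"][0].shape == times.shape
    assert np.isfinite(out["fast"][0]).all() and np.isfinite(out["slow"][0]).all()


def test_response_locked_alignment():
    """A ramp that peaks exactly at each trial's RT aligns at time zero."""
    from threatsense.motor import response_locked

    rng = np.random.default_rng(7)
    rt = rng.uniform(0.5, 1.2, size=30)
    times = np.arange(-0.2, 1.5, 0.01)
    # triangular bump centered on each trial's RT
    idx = np.maximum(0.0, 1 - np.abs(times[None, :] - rt[:, None]) / 0.1)
    lat = _fake_lat(idx, times)
    tr = pd.DataFrame({"rt": rt})
    rl = response_locked(lat, tr, window=(-0.4, 0.2), sfreq_out=100.0)
    i0 = np.argmin(np.abs(rl.times))
    # the apex sits between source samples; interpolation undershoots by
    # at most half a source sample of the 0.1 s flank
    assert np.nanmean(rl.index[:, i0]) == pytest.approx(1.0, abs=0.06)
    early = np.argmin(np.abs(rl.times + 0.4))
    assert np.nanmean(rl.index[:, early]) < 0.1


def test_lateralization_residual_orthogonal_and_scaled(subject_trials):
    from threatsense.motor import lateralization_residual

    rng = np.random.default_rng(8)
    x = subject_trials["signed_strength"].to_numpy(float)
    times = np.arange(-0.2, 1.0, 0.01)
    lat = _fake_lat(0.1 * x[:, None] + rng.standard_normal((len(x), len(times))), times)
    e = lateralization_residual(lat, subject_trials, 0.5)
    assert abs(np.corrcoef(e, x)[0, 1]) < 1e-10
    assert e.std() == pytest.approx(1.0, abs=1e-9)
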