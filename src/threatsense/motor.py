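"""Mu-beta (8-32 Hz) power, motor lateralization, and its emotion encoding.

Response preparation suppresses 8-32 Hz power over the motor cortex
contralateral to the responding hand.  Band power is estimated with a
multitaper transform (Slepian tapers, constant cycles per window, so the
window shortens with frequency).  The hand-referenced lateralization index
subtracts "anger-hand" spectral activity from "fear-hand" spectral activity
(contralateral-to-fear minus contralateral-to-anger hemisphere), so a
positive index marks preparation of the anger response and the index sign
predicts the upcoming choice.  Regressing the index on *signed* emotion
strength (-7 fear .. +7 anger) yields a motor encoding time course; the
RT-split analysis contrasts its onset between fast and slow responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EEGEpochs

DEFAULT_PAIRS = (("C3", "C4"), ("CP3", "CP4"), ("P3", "P4"))


@dataclass
class TFRPower:
    """Time-frequency power: trials x channels x freqs x times.

    Time points within half a taper window of an epoch edge are NaN (the
    window shrinks as cycles/frequency, so low frequencies lose more edge).
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channel_names: list[str]
    n_cycles: float
    n_tapers: int


@dataclass
class LateralizationSeries:
    """Trials x time hand-referenced motor lateralization index."""

    index: np.ndarray
    times: np.ndarray
    pairs: tuple
    hand_mapping: str


def multitaper_power(
    eeg: EEGEpochs,
    fmin: float = 8.0,
    fmax: float = 32.0,
    freq_step: float = 2.0,
    n_cycles: float = 5.0,
    n_tapers: int = 3,
    decim: int = 1,
    picks=None,
) -> TFRPower:
    """Multitaper spectral power in ``[fmin, fmax]``.

    Constant ``n_cycles`` per window across frequencies; power is averaged
    over tapers (time_bandwidth = n_tapers + 1).  ``decim`` downsamples the
    output time axis (power is smooth at the window scale).
    """
    from mne.time_frequency import tfr_array_multitaper

    freqs = np.arange(fmin, fmax + 1e-9, freq_step)
    epoch_len = eeg.times[-1] - eeg.times[0]
    max_win = n_cycles / fmin
    if epoch_len < max_win:
        raise ValueError(
            f"epoch ({epoch_len:.3f} s) shorter than the {max_win:.3f} s "
            f"window needed for {n_cycles} cycles at {fmin} Hz"
        )
    data = eeg.data
    names = list(eeg.channel_names)
    if picks is not None:
        idx = eeg.channel_index(picks)
        data = data[:, idx, :]
        names = list(picks)
    power = tfr_array_multitaper(
        np.asarray(data, float),
        sfreq=eeg.sfreq,
        freqs=freqs,
        n_cycles=n_cycles,
        time_bandwidth=float(n_tapers + 1),
        output="power",
        decim=decim,
        verbose="error",
    )
    times = eeg.times[::decim]
    # blank edge samples where the taper window overhangs the epoch
    for fi, f in enumerate(freqs):
        half = 0.5 * n_cycles / f
        bad = (times < eeg.times[0] + half) | (times > eeg.times[-1] - half)
        power[:, :, fi, bad] = np.nan
    return TFRPower(
        power=power,
        freqs=freqs,
        times=times,
        channel_names=names,
        n_cycles=n_cycles,
        n_tapers=n_tapers,
    )


def lateralization_index(
    tfr: TFRPower, trials: pd.DataFrame, pairs=DEFAULT_PAIRS
) -> LateralizationSeries:
    """Hand-referenced lateralization from homologue electrode pairs.

    Band-averages power over frequencies, averages the left and right
    triplets, and signs the left-right difference by the subject's hand
    mapping: the result is contralateral-to-'fear'-hand minus
    contralateral-to-'anger'-hand activity, positive for anger-hand
    preparation.  Swapping the mapping in the metadata negates the series
    exactly.
    """
    lookup = {c: i for i, c in enumerate(tfr.channel_names)}
    missing = [c for pair in pairs for c in pair if c not in lookup]
    if missing:
        raise KeyError(f"missing homologue channels: {missing}")
    mapping = trials["response_hand_mapping"].unique()
    if len(mapping) != 1:
        raise ValueError("hand mapping must be constant within subject")
    mapping = mapping[0]
    if mapping not in ("anger_left", "anger_right"):
        raise ValueError(f"unknown hand mapping {mapping!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN edge columns
        band = np.nanmean(tfr.power, axis=2)  # trials x ch x time
    left = band[:, [lookup[l] for l, _ in pairs], :].mean(axis=1)
    right = band[:, [lookup[r] for _, r in pairs], :].mean(axis=1)
    # anger_left => fear hand is right => contra(fear) is left hemisphere
    sign = 1.0 if mapping == "anger_left" else -1.0
    return LateralizationSeries(
        index=sign * (left - right),
        times=tfr.times,
        pairs=tuple(pairs),
        hand_mapping=mapping,
    )


def _ols_per_time(y: np.ndarray, x: np.ndarray):
    """Slope and SE of y(t) ~ x per time column; NaN columns stay NaN."""
    n = len(x)
    xc = x - x.mean()
    sxx = np.sum(xc**2)
    if sxx == 0:
        raise ValueError("regressor is constant")
    beta = (xc @ y) / sxx
    resid = y - np.outer(x - x.mean(), beta) - y.mean(axis=0)
    dof = max(n - 2, 1)
    sigma2 = np.sum(resid**2, axis=0) / dof
    se = np.sqrt(sigma2 / sxx)
    return beta, se


def signed_encoding(
    lat: LateralizationSeries,
    trials: pd.DataFrame,
    split: str | None = None,
) -> dict:
    """Per-time OLS slope of the lateralization index on signed strength.

    With ``split="threat"`` the regression runs separately for THREAT+ and
    THREAT- trials (neutral excluded).  Returns ``{label: (beta, se)}`` plus
    the time axis under ``"times"``; the unsplit result is under ``"all"``.
    """
    x = trials["signed_strength"].to_numpy(float)
    out = {"times": lat.times}
    if split is None:
        out["all"] = _ols_per_time(lat.index, x)
        return out
    if split != "threat":
        raise ValueError(f"unknown split {split!r}")
    labels = trials["threat_label"].to_numpy()
    for lab in ("THREAT+", "THREAT-"):
        mask = labels == lab
        if np.unique(np.abs(x[mask])).size < 2:
            raise ValueError(f"partition {lab} has < 2 strength levels")
        out[lab] = _ols_per_time(lat.index[mask], x[mask])
    return out


def rt_median_split(trials: pd.DataFrame, min_per_level: int = 4):
    """Fast/slow masks from a within-strength-level median split of RT.

    Splitting within each |strength| level removes the strength-RT confound
    ("median split informed by emotion strength").  Levels with fewer than
    ``min_per_level`` trials are dropped with a warning.  The split is
    balanced to within one trial per level.
    """
    rt = trials["rt"].to_numpy(float)
    fast = np.zeros(len(trials), bool)
    slow = np.zeros(len(trials), bool)
    for lev, idx in trials.groupby("morph_level").indices.items():
        if len(idx) < min_per_level:
            warnings.warn(f"dropping strength level {lev} with {len(idx)} trials")
            continue
        order = idx[np.argsort(rt[idx], kind="stable")]
        half = len(order) // 2
        fast[order[:half]] = True
        slow[order[half + (len(order) % 2):]] = True
        if len(order) % 2:  # odd: median trial joins the slow half
            slow[order[half]] = True
    return fast, slow


def response_locked(
    lat: LateralizationSeries,
    trials: pd.DataFrame,
    window: tuple[float, float] = (-1.0, 0.2),
    sfreq_out: float = 100.0,
) -> LateralizationSeries:
    """Re-epoch the lateralization index around each trial's response.

    Each trial's series is linearly interpolated onto a common grid of times
    relative to that trial's RT; grid points that fall outside the
    stimulus-locked epoch (or on NaN edge samples) are NaN.
    """
    rt = trials["rt"].to_numpy(float)
    n_out = int(round((window[1] - window[0]) * sfreq_out)) + 1
    rel = window[0] + np.arange(n_out) / sfreq_out
    out = np.full((len(rt), n_out), np.nan)
    src_t = lat.times
    for i, r in enumerate(rt):
        tq = r + rel
        row = lat.index[i]
        ok = np.isfinite(row)
        if ok.sum() < 2:
            continue
        inside = (tq >= src_t[ok][0]) & (tq <= src_t[ok][-1])
        out[i, inside] = np.interp(tq[inside], src_t[ok], row[ok])
    return LateralizationSeries(
        index=out, times=rel, pairs=lat.pairs, hand_mapping=lat.hand_mapping
    )


def lateralization_residual(
    lat: LateralizationSeries, trials: pd.DataFrame, time_point: float
) -> np.ndarray:
    """Per-trial index residual after signed-strength regression, z-scored.

    The motor analogue of the broadband residual score: what is left of the
    lateralization index at ``time_point`` once the programmed
    signed-strength encoding is regressed out, ready to enter the mediation
    models as ``e``.
    """
    ti = int(np.argmin(np.abs(lat.times - time_point)))
    if not lat.times[0] - 1e-9 <= time_point <= lat.times[-1] + 1e-9:
        raise ValueError("time point outside series")
    y = lat.index[:, ti]
    if not np.isfinite(y).all():
        raise ValueError("time point lies in the NaN edge region")
    x = trials["signed_strength"].to_numpy(float)
    slope, intercept = np.polyfit(x, y, 1)
    e = y - (slope * x + intercept)
    sd = e.std()
    return e / sd if sd > 0 else e


def rt_split_encoding(
    lat: LateralizationSeries,
    trials: pd.DataFrame,
    min_per_level: int = 4,
) -> dict:
    """Signed-strength encoding fitted separately for fast and slow trials."""
    fast, slow = rt_median_split(trials, min_per_level=min_per_level)
    x = trials["signed_strength"].to_numpy(float)
    out = {"times": lat.times}
    for name, mask in (("fast", fast), ("slow", slow)):
        out[name] = _ols_per_time(lat.index[mask], x[mask])
    return out
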