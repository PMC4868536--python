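"""Trial-wise regression of broadband EEG on emotion strength.

At every channel and time point, single-trial EEG amplitude is regressed on
per-trial predictors (primarily unsigned emotion strength 0-7; optionally
identity-level threat/trustworthiness ratings).  The slope time course is the
neural "encoding" of emotion information; its amplitude indexes neural
sensitivity.  Condition splits (THREAT+ vs THREAT-) quantify the contextual
gain, and the regression residuals feed the neural-choice mediation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EEGEpochs


@dataclass
class EncodingResult:
    """Per-channel/time OLS results.

    ``betas``/``se`` are (n_regressors, channels, time); ``intercept`` is
    (channels, time).  ``residuals`` (trials x kept-channels x time) are kept
    only for ``resid_channels`` to bound memory.
    """

    betas: np.ndarray
    se: np.ndarray
    intercept: np.ndarray
    regressors: list[str]
    channel_names: list[str]
    times: np.ndarray
    residuals: np.ndarray | None = None
    resid_channels: list[str] | None = None
    n_trials: int = 0

    def beta(self, name: str) -> np.ndarray:
        return self.betas[self.regressors.index(name)]

    def tvals(self, name: str) -> np.ndarray:
        i = self.regressors.index(name)
        return self.betas[i] / self.se[i]


@dataclass(frozen=True)
class ChannelSet:
    """Electrodes of interest with the statistic that selected them."""

    names: tuple[str, ...]
    scores: tuple[float, ...]
    window: tuple[float, float]
    statistic: str = "abs_mean_beta"


def _design_matrix(design: pd.DataFrame, zscore: bool) -> tuple[np.ndarray, list[str]]:
    X = design.to_numpy(float)
    names = list(design.columns)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant regressor(s): {bad}")
    if zscore:
        X = (X - X.mean(axis=0)) / sd
    Xfull = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(Xfull) < Xfull.shape[1]:
        raise ValueError(f"rank-deficient design; check columns {names}")
    return Xfull, names


def encode_glm(
    eeg: EEGEpochs,
    design: pd.DataFrame,
    zscore: bool = True,
    residual_channels=None,
) -> EncodingResult:
    """OLS of single-trial EEG on per-trial regressors, per channel and time.

    Parameters
    ----------
    design : DataFrame
        One column per regressor, one row per trial (aligned with ``eeg``).
        An intercept is always included.
    zscore : bool
        Standardize regressors within the call (per subject), making slope
        estimates unit-free and comparable across subjects.  Set False for
        raw-scale slopes.
    residual_channels : sequence of str, optional
        Channels whose residual time courses are retained (defaults to none).
    """
    n, n_ch, n_t = eeg.data.shape
    if len(design) != n:
        raise ValueError("design rows must match number of EEG trials")
    X, names = _design_matrix(design, zscore)
    p = X.shape[1]
    XtX_inv = np.linalg.inv(X.T @ X)
    pinv = XtX_inv @ X.T
    Y = eeg.data.reshape(n, n_ch * n_t)
    B = pinv @ Y  # (p, ch*t)
    resid = Y - X @ B
    dof = max(n - p, 1)
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    betas = B[1:].reshape(p - 1, n_ch, n_t)
    se_b = se[1:].reshape(p - 1, n_ch, n_t)
    intercept = B[0].reshape(n_ch, n_t)
    residuals = kept = None
    if residual_channels is not None:
        idx = eeg.channel_index(residual_channels)
        residuals = resid.reshape(n, n_ch, n_t)[:, idx, :].copy()
        kept = list(residual_channels)
    return EncodingResult(
        betas=betas,
        se=se_b,
        intercept=intercept,
        regressors=names,
        channel_names=list(eeg.channel_names),
        times=np.asarray(eeg.times),
        residuals=residuals,
        resid_channels=kept,
        n_trials=n,
    )


def condition_encoding(
    eeg: EEGEpochs,
    trials: pd.DataFrame,
    regressor: str = "morph_level",
    zscore: bool = True,
    correct_only: bool = False,
    residual_channels=None,
) -> dict[str, EncodingResult]:
    """Separate encoding GLMs for THREAT+ and THREAT- trials.

    Neutral trials carry no threat label and are excluded.  With
    ``correct_only`` the split is restricted to correctly categorized trials.
    """
    out = {}
    labels = trials["threat_label"].to_numpy()
    for lab in ("THREAT+", "THREAT-"):
        mask = labels == lab
        if correct_only:
            mask &= trials["correct"].to_numpy(float) == 1.0
        if mask.sum() == 0:
            raise ValueError(f"empty partition {lab}")
        sub = trials.loc[mask]
        if sub[regressor].nunique() < 2:
            raise ValueError(f"partition {lab} has < 2 strength levels")
        sub_eeg = EEGEpochs(
            data=eeg.data[mask],
            times=eeg.times,
            sfreq=eeg.sfreq,
            channel_names=eeg.channel_names,
            lock=eeg.lock,
        )
        out[lab] = encode_glm(
            sub_eeg,
            sub[[regressor]],
            zscore=zscore,
            residual_channels=residual_channels,
        )
    return out


def select_electrodes(
    group_betas: np.ndarray,
    times: np.ndarray,
    channel_names,
    window: tuple[float, float],
    k: int = 4,
) -> ChannelSet:
    """Rank channels by |group-mean slope| averaged over a time window.

    ``group_betas`` is (subjects, channels, time) or (channels, time).  Ties
    break deterministically by channel name.
    """
    betas = np.asarray(group_betas, float)
    if betas.ndim == 3:
        betas = betas.mean(axis=0)
    t0, t1 = window
    if t0 < times[0] - 1e-9 or t1 > times[-1] + 1e-9:
        raise ValueError("window outside epoch")
    cols = (times >= t0 - 1e-9) & (times <= t1 + 1e-9)
    score = np.abs(betas[:, cols].mean(axis=1))
    order = sorted(range(len(channel_names)), key=lambda i: (-score[i], channel_names[i]))
    top = order[: min(k, len(order))]
    return ChannelSet(
        names=tuple(channel_names[i] for i in top),
        scores=tuple(float(score[i]) for i in top),
        window=(float(t0), float(t1)),
    )


def extract_residual_score(
    result: EncodingResult, channels, time_point: float
) -> np.ndarray:
    """Per-trial residual score: channel-averaged residual at one time, z-scored.

    This is the stimulus-independent neural fluctuation ``e`` entering the
    neural-choice mediation models.  For noiseless (all-zero residual) input
    the score is identically zero.
    """
    if result.residuals is None:
        raise ValueError("residuals were not retained; refit with residual_channels")
    lookup = {c: i for i, c in enumerate(result.resid_channels)}
    missing = [c for c in channels if c not in lookup]
    if missing:
        raise KeyError(f"residuals not retained for channels {missing}")
    if not result.times[0] - 1e-9 <= time_point <= result.times[-1] + 1e-9:
        raise ValueError("time point outside epoch")
    ti = int(np.argmin(np.abs(result.times - time_point)))
    idx = [lookup[c] for c in channels]
    e = result.residuals[:, idx, ti].mean(axis=1)
    sd = e.std()
    # numerically-zero residuals (noiseless data) give identically-zero scores
    scale = max(np.abs(result.intercept).max(), np.abs(result.betas).max(), 1.0)
    if sd <= 1e-10 * scale:
        return np.zeros_like(e)
    return (e - e.mean()) / sd
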