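"""Neural-choice mediation: do EEG residuals bias or sensitize the decision?

Residual single-trial fluctuations ``e`` (EEG activity unexplained by emotion
strength) are entered into the probit choice model either additively, as a
stimulus-independent bias, or multiplicatively, as a gain on the emotion
evidence::

    additive:        P(anger) = Phi[w x + b + b_mod e]
    multiplicative:  P(anger) = Phi[(w + w_mod e) x + b]
    combined:        P(anger) = Phi[(w + w_mod e) x + b + b_mod e]

All three are linear in parameters under the probit link (predictors
{x, e, e*x}), so fitting is a probit regression; w and b are re-estimated
jointly with the modulators.  The printed mediation equations carry no lapse
term; a lapse fixed from the behavioral fit is available as an option.
Cross-validated evidence on shared folds feeds the same fixed/random-effects
model selection used for the behavioral variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .modelselect import ModelSelectionResult, exceedance_prob, fixed_effects_bf
from .psychometric import make_cv_folds

MEDIATION_VARIANTS = ("additive", "multiplicative", "combined")

_PCLIP = 1e-10


@dataclass
class MediationFit:
    """One probit mediation fit at a single time point."""

    variant: str
    w: float
    b: float
    w_mod: float | None
    b_mod: float | None
    se: dict[str, float]
    llf: float
    converged: bool
    n_trials: int


def _mediation_design(trials: pd.DataFrame, e: np.ndarray, variant: str):
    x = trials["signed_strength"].to_numpy(float)
    e = np.asarray(e, float)
    if e.shape != x.shape:
        raise ValueError("residual score must align with trials")
    cols = {"const": np.ones_like(x), "x": x}
    if variant in ("additive", "combined"):
        cols["e"] = e
    if variant in ("multiplicative", "combined"):
        cols["ex"] = e * x
    X = np.column_stack(list(cols.values()))
    y = (trials["choice"].to_numpy() == "anger").astype(float)
    return X, y, list(cols.keys())


def fit_mediation(
    trials: pd.DataFrame,
    e: np.ndarray,
    variant: str = "combined",
    fixed_lapse: float = 0.0,
) -> MediationFit:
    """Probit regression of choice on {x, e, e*x} per the mediation variant.

    ``e`` should be z-scored across trials (as produced by
    :func:`threatsense.encoding.extract_residual_score`); a clearly unscaled
    input raises.  With ``fixed_lapse`` > 0 the likelihood mixes in the
    behavioral lapse estimate while keeping the probit core.
    """
    if variant not in MEDIATION_VARIANTS:
        raise ValueError(f"unknown mediation variant {variant!r}")
    e = np.asarray(e, float)
    if e.std() > 0 and (abs(e.mean()) > 0.2 or not 0.5 < e.std() < 2.0):
        raise ValueError("residual score does not look z-scored")
    if e.std() == 0:
        # degenerate regressor: the model collapses to the plain psychometric
        # probit; modulators are exactly zero
        X, y, _ = _mediation_design(trials, e * 0, "plain")
        base = sm.Probit(y, X).fit(disp=0)
        return MediationFit(
            variant=variant,
            w=float(base.params[1]),
            b=float(base.params[0]),
            w_mod=0.0 if variant in ("multiplicative", "combined") else None,
            b_mod=0.0 if variant in ("additive", "combined") else None,
            se={"const": float(base.bse[0]), "x": float(base.bse[1])},
            llf=float(base.llf),
            converged=bool(base.mle_retvals.get("converged", True)),
            n_trials=len(y),
        )
    X, y, names = _mediation_design(trials, e, variant)
    converged = True
    if fixed_lapse == 0.0:
        model = sm.Probit(y, X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(disp=0, maxiter=200)
                converged = bool(res.mle_retvals.get("converged", True))
            except Exception:
                res = model.fit(disp=0, method="bfgs", maxiter=500)
                converged = False
        params, bse, llf = res.params, res.bse, float(res.llf)
    else:
        params, bse, llf, converged = _fit_lapsed_probit(X, y, fixed_lapse)
    if not np.all(np.isfinite(params)) or np.any(np.abs(params) > 50):
        converged = False  # perfect separation or runaway estimates
    pmap = dict(zip(names, params))
    smap = {k: float(v) for k, v in zip(names, bse)}
    return MediationFit(
        variant=variant,
        w=float(pmap["x"]),
        b=float(pmap["const"]),
        w_mod=float(pmap["ex"]) if "ex" in pmap else None,
        b_mod=float(pmap["e"]) if "e" in pmap else None,
        se=smap,
        llf=llf,
        converged=converged,
        n_trials=len(y),
    )


def _fit_lapsed_probit(X, y, lapse):
    from scipy.optimize import minimize

    def nll(beta):
        p = norm.cdf(X @ beta) * (1 - lapse) + 0.5 * lapse
        p = np.clip(p, _PCLIP, 1 - _PCLIP)
        return -np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))

    res = minimize(nll, np.zeros(X.shape[1]), method="BFGS")
    H_inv = res.hess_inv if res.hess_inv is not None else np.eye(X.shape[1])
    bse = np.sqrt(np.abs(np.diag(H_inv)))
    return res.x, bse, -float(res.fun), bool(res.success)


def mediation_loglik(fit: MediationFit, trials: pd.DataFrame, e: np.ndarray) -> float:
    """Held-out Bernoulli log-likelihood of choices under a mediation fit."""
    X, y, names = _mediation_design(trials, e, fit.variant)
    beta = [fit.b, fit.w]
    if "e" in names:
        beta.append(fit.b_mod)
    if "ex" in names:
        beta.append(fit.w_mod)
    p = np.clip(norm.cdf(X @ np.asarray(beta)), _PCLIP, 1 - _PCLIP)
    return float(np.sum(np.where(y > 0, np.log(p), np.log1p(-p))))


def mediation_cv_evidence(
    trials: pd.DataFrame,
    e: np.ndarray,
    variants=("additive", "multiplicative"),
    k: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """K-fold CV log-likelihood per mediation variant on shared folds."""
    fold = make_cv_folds(trials, k=k, seed=seed)
    e = np.asarray(e, float)
    out = {}
    for variant in variants:
        total = 0.0
        for f in range(k):
            tr = fold != f
            fit = fit_mediation(trials.loc[tr], e[tr], variant)
            total += mediation_loglik(fit, trials.loc[~tr], e[~tr])
        out[variant] = total
    return out


def mediation_timecourse(
    trials: pd.DataFrame,
    residuals: np.ndarray,
    times: np.ndarray,
    variant: str = "combined",
    time_mask=None,
) -> pd.DataFrame:
    """Independent mediation fits at each time point.

    ``residuals`` is trials x time (channel-averaged residual scores are
    z-scored per time point here).  Returns a tidy frame with per-time
    w_mod/b_mod estimates and SEs; time points are fitted independently, with
    no temporal regularization.
    """
    residuals = np.asarray(residuals, float)
    if residuals.shape != (len(trials), len(times)):
        raise ValueError("residuals must be trials x time")
    cols = range(len(times)) if time_mask is None else np.flatnonzero(time_mask)
    rows = []
    for ti in cols:
        e = residuals[:, ti]
        sd = e.std()
        e = (e - e.mean()) / sd if sd > 0 else np.zeros_like(e)
        fit = fit_mediation(trials, e, variant)
        rows.append(
            {
                "time": times[ti],
                "w": fit.w,
                "b": fit.b,
                "w_mod": fit.w_mod,
                "b_mod": fit.b_mod,
                "se_w_mod": fit.se.get("ex", np.nan),
                "se_b_mod": fit.se.get("e", np.nan),
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def select_mediation_model(evidence: pd.DataFrame, seed: int = 0) -> dict:
    """Fixed- and random-effects selection between mediation variants.

    ``evidence`` is subjects x variants (CV log-likelihood from shared
    folds).  Returns the winner, the pairwise fixed-effects log10 Bayes
    factor of the winner over the runner-up, and exceedance probabilities.
    """
    totals = evidence.sum(axis=0).sort_values(ascending=False)
    winner, runner = totals.index[0], totals.index[1]
    bf = fixed_effects_bf(evidence, winner, runner)
    sel: ModelSelectionResult = exceedance_prob(evidence, seed=seed)
    return {
        "winner": winner,
        "runner_up": runner,
        "log10_bf": bf.log10_bf,
        "exceedance_probs": sel.exceedance_probs,
        "expected_frequencies": sel.expected_frequencies,
    }
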