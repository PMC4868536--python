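"""Nested psychometric models of emotion categorization.

Choices are modelled as a noisy comparison of signed emotion strength
``x`` (-7 fear .. +7 anger) against a criterion, with a lapse mixture::

    P(anger) = Phi[w * x + b] * (1 - eps) + 0.5 * eps

where ``w`` is perceptual sensitivity, ``b`` an additive response bias and
``eps`` the proportion of random guesses.  Three nested variants formalize how
gaze context may act:

* ``null`` -- no contextual influence: single ``w``, single ``b``.
* ``bias`` -- gaze shifts the criterion toward the threat-signaling
  interpretation: ``b`` differs between direct and averted gaze.
* ``sensitivity`` -- gaze multiplicatively changes the perceptual gain for
  threat-signaling pairings: ``w`` differs between THREAT+ and THREAT-.

The lapse rate and (outside the bias variant) the bias are shared across
conditions.  Fitting is by maximum likelihood on response counts aggregated
over identical (strength, condition) cells, with analytic gradients and
seeded multi-start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .design import THREAT_PLUS

VARIANTS = ("null", "bias", "sensitivity")

_PCLIP = 1e-10


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of one psychometric variant.

    ``w`` is a scalar except for the sensitivity variant, where it is
    ``(w_plus, w_minus)`` for THREAT+/THREAT- pairings.  ``b`` is a scalar
    except for the bias variant, where it is ``(b_direct, b_averted)``.
    ``lapse`` is the guessing proportion in [0, 1].
    """

    variant: str = "null"
    w: float | tuple[float, float] = 0.4
    b: float | tuple[float, float] = 0.0
    lapse: float = 0.0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must lie in [0, 1]")
        w_pair = isinstance(self.w, (tuple, list))
        b_pair = isinstance(self.b, (tuple, list))
        if self.variant == "sensitivity" and not w_pair:
            raise ValueError("sensitivity variant needs w=(w_plus, w_minus)")
        if self.variant == "bias" and not b_pair:
            raise ValueError("bias variant needs b=(b_direct, b_averted)")
        if self.variant != "sensitivity" and w_pair:
            raise ValueError("only the sensitivity variant takes a w pair")
        if self.variant != "bias" and b_pair:
            raise ValueError("only the bias variant takes a b pair")

    @property
    def n_free(self) -> int:
        """Number of free parameters (w terms + b terms + lapse)."""
        return 3 if self.variant == "null" else 4


def _condition_wb(params: ObserverParams, threat, gaze):
    """Per-trial (w, b) arrays given the variant's condition dependence."""
    threat = np.asarray(threat, dtype=object)
    gaze = np.asarray(gaze, dtype=object)
    if params.variant == "sensitivity":
        w_plus, w_minus = params.w
        # neutral trials have x = 0, so w is inert there; use the mean
        w = np.where(
            threat == THREAT_PLUS,
            w_plus,
            np.where(threat == "THREAT-", w_minus, 0.5 * (w_plus + w_minus)),
        )
    else:
        w = np.broadcast_to(float(params.w), threat.shape).copy()
    if params.variant == "bias":
        b_direct, b_averted = params.b
        b = np.where(gaze == "direct", b_direct, b_averted)
    else:
        b = np.broadcast_to(float(params.b), threat.shape).copy()
    return w, b


def predict_choice_prob(params: ObserverParams, x, threat_label=None, gaze=None):
    """P(respond "anger") for signed strength ``x`` under ``params``.

    ``threat_label`` is required by the sensitivity variant and ``gaze`` by
    the bias variant; both default to condition-independent behavior.
    """
    x = np.asarray(x, dtype=float)
    shape = x.shape if x.shape else (1,)
    if threat_label is None:
        threat_label = np.full(shape, "neutral", dtype=object)
    if gaze is None:
        gaze = np.full(shape, "direct", dtype=object)
    w, b = _condition_wb(params, threat_label, gaze)
    p = norm.cdf(w * np.atleast_1d(x) + b) * (1.0 - params.lapse) + 0.5 * params.lapse
    return p if x.shape else float(p[0])


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one psychometric variant."""

    params: ObserverParams
    nll: float
    converged: bool
    n_trials: int

    @property
    def variant(self) -> str:
        return self.params.variant


# ---------------------------------------------------------------------------
# internal parameterization: theta = (w terms..., b terms..., logit(eps))

def _cells(trials: pd.DataFrame, variant: str):
    """Aggregate trials into (x, w-index, b-index) binomial cells."""
    df = trials
    choice = df["choice"].to_numpy()
    if not np.isin(choice, ("anger", "fear")).all():
        raise ValueError("trials must contain anger/fear choices")
    x = df["signed_strength"].to_numpy(float)
    if variant == "sensitivity":
        w_idx = np.where(df["threat_label"].to_numpy() == "THREAT-", 1, 0)
    else:
        w_idx = np.zeros(len(df), int)
    if variant == "bias":
        b_idx = np.where(df["gaze"].to_numpy() == "averted", 1, 0)
    else:
        b_idx = np.zeros(len(df), int)
    key = pd.DataFrame({"x": x, "wi": w_idx, "bi": b_idx, "k": choice == "anger"})
    g = key.groupby(["x", "wi", "bi"], sort=True)["k"].agg(["sum", "count"])
    cx = g.index.get_level_values("x").to_numpy(float)
    cw = g.index.get_level_values("wi").to_numpy(int)
    cb = g.index.get_level_values("bi").to_numpy(int)
    return cx, cw, cb, g["sum"].to_numpy(float), g["count"].to_numpy(float)


def _unpack(theta, variant):
    if variant == "sensitivity":
        w = theta[:2][None, :]
        b = theta[2:3][None, :]
        nw, nb = 2, 1
    elif variant == "bias":
        w = theta[:1][None, :]
        b = theta[1:3][None, :]
        nw, nb = 1, 2
    else:
        w = theta[:1][None, :]
        b = theta[1:2][None, :]
        nw, nb = 1, 1
    eps = 1.0 / (1.0 + np.exp(-theta[-1]))
    return w.ravel(), b.ravel(), eps, nw, nb


def _nll_grad(theta, variant, cx, cw, cb, ck, cn):
    w_all, b_all, eps, nw, nb = _unpack(theta, variant)
    w = w_all[cw]
    b = b_all[cb]
    z = w * cx + b
    Phi = norm.cdf(z)
    phi = norm.pdf(z)
    p = np.clip(Phi * (1 - eps) + 0.5 * eps, _PCLIP, 1 - _PCLIP)
    nll = -np.sum(ck * np.log(p) + (cn - ck) * np.log1p(-p))
    dldp = -(ck / p - (cn - ck) / (1 - p))
    common = dldp * (1 - eps) * phi
    grad = np.zeros_like(theta)
    for j in range(nw):
        grad[j] = np.sum(common[cw == j] * cx[cw == j])
    for j in range(nb):
        grad[nw + j] = np.sum(common[cb == j])
    deps = eps * (1 - eps)
    grad[-1] = np.sum(dldp * (0.5 - Phi)) * deps
    return nll, grad


_BOUND_W = 10.0
_BOUND_B = 10.0
_BOUND_A = 15.0


def _theta_to_params(theta, variant) -> ObserverParams:
    w_all, b_all, eps, _, _ = _unpack(theta, variant)
    w = tuple(map(float, w_all)) if variant == "sensitivity" else float(w_all[0])
    b = tuple(map(float, b_all)) if variant == "bias" else float(b_all[0])
    return ObserverParams(variant=variant, w=w, b=b, lapse=float(eps))


def fit_psychometric(
    trials: pd.DataFrame,
    variant: str = "null",
    n_starts: int = 10,
    seed: int = 0,
    init: np.ndarray | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one psychometric variant.

    Uses L-BFGS-B with analytic gradients on binomial response cells, a fixed
    sensible start plus ``n_starts`` seeded random restarts.  The lapse rate
    is fitted through a logit transform; w and b are box-bounded at +/-10 only
    to keep degenerate data (e.g. unanimous responses) finite -- a solution at
    a bound is reported as not converged.

    ``init`` optionally adds a warm-start vector (used by cross-validation).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    cx, cw, cb, ck, cn = _cells(trials, variant)
    if len(np.unique(cx)) < 2:
        raise ValueError("need at least 2 strength levels to fit")
    nw = 2 if variant == "sensitivity" else 1
    nb = 2 if variant == "bias" else 1
    npar = nw + nb + 1
    bounds = [(-_BOUND_W, _BOUND_W)] * nw + [(-_BOUND_B, _BOUND_B)] * nb + [
        (-_BOUND_A, _BOUND_A)
    ]
    rng = np.random.default_rng(seed)
    starts = [np.concatenate([np.full(nw, 0.3), np.zeros(nb), [-2.9]])]
    if init is not None:
        starts.append(np.asarray(init, float))
    for _ in range(n_starts):
        starts.append(
            np.concatenate(
                [
                    rng.uniform(0.05, 1.0, nw),
                    rng.normal(0.0, 0.5, nb),
                    [np.log(rng.uniform(0.01, 0.25) / (1 - 0.13))],
                ]
            )
        )
    best = None
    any_success = False
    for theta0 in starts:
        res = minimize(
            _nll_grad,
            theta0,
            args=(variant, cx, cw, cb, ck, cn),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
        )
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    at_bound = any(
        np.isclose(t, lo) or np.isclose(t, hi)
        for t, (lo, hi) in zip(theta[: nw + nb], bounds[: nw + nb])
    )
    converged = bool(any_success and not at_bound)
    return FitResult(
        params=_theta_to_params(theta, variant),
        nll=float(best.fun),
        converged=converged,
        n_trials=int(cn.sum()),
    )


def _params_to_theta(params: ObserverParams) -> np.ndarray:
    w = np.atleast_1d(np.asarray(params.w, float))
    b = np.atleast_1d(np.asarray(params.b, float))
    eps = np.clip(params.lapse, 1e-6, 1 - 1e-6)
    return np.concatenate([w, b, [np.log(eps / (1 - eps))]])


def trial_log_likelihood(params: ObserverParams, trials: pd.DataFrame) -> float:
    """Summed Bernoulli log-likelihood of observed choices under ``params``."""
    p = predict_choice_prob(
        params,
        trials["signed_strength"].to_numpy(float),
        trials["threat_label"].to_numpy(),
        trials["gaze"].to_numpy(),
    )
    p = np.clip(p, _PCLIP, 1 - _PCLIP)
    k = trials["choice"].to_numpy() == "anger"
    return float(np.sum(np.where(k, np.log(p), np.log1p(-p))))


def make_cv_folds(trials: pd.DataFrame, k: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified k-fold assignment shared across model variants.

    Trials are stratified by (emotion, gaze, morph level) and dealt
    round-robin within each shuffled stratum, so every fold sees every
    condition.  The assignment depends only on the trial table and seed --
    never on the model -- so evidence differences between variants are not
    partition noise.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(trials):
        raise ValueError("more folds than trials")
    rng = np.random.default_rng(seed)
    fold = np.empty(len(trials), int)
    offset = 0
    strata = trials.groupby(["emotion", "gaze", "morph_level"], sort=True).indices
    for key in sorted(strata):
        idx = rng.permutation(strata[key])
        fold[idx] = (np.arange(len(idx)) + offset) % k
        offset += len(idx)
    return fold


def cv_evidence(
    trials: pd.DataFrame,
    variant: str,
    k: int = 10,
    seed: int = 0,
    n_starts: int = 2,
) -> float:
    """K-fold cross-validated log-likelihood (model-evidence proxy).

    Each fold is held out in turn, the variant is refitted on the remainder
    (warm-started from the full-data fit) and the held-out trials' summed
    log-likelihood is accumulated.  Complexity is penalized implicitly: extra
    parameters only help if they generalize.
    """
    fold = make_cv_folds(trials, k=k, seed=seed)
    full = fit_psychometric(trials, variant, n_starts=n_starts, seed=seed)
    warm = _params_to_theta(full.params)
    total = 0.0
    for f in range(k):
        train = trials.loc[fold != f]
        test = trials.loc[fold == f]
        if len(test) == 0:
            continue
        fit = fit_psychometric(
            train, variant, n_starts=n_starts, seed=seed + 101 * (f + 1), init=warm
        )
        total += trial_log_likelihood(fit.params, test)
    return float(total)


def evidence_table(
    subject_trials: dict[str, pd.DataFrame],
    variants=VARIANTS,
    k: int = 10,
    seed: int = 0,
    n_starts: int = 2,
) -> pd.DataFrame:
    """Per-subject x per-variant CV log-likelihood table."""
    rows = {}
    for i, (sid, df) in enumerate(subject_trials.items()):
        rows[sid] = {
            v: cv_evidence(df, v, k=k, seed=seed + 977 * i, n_starts=n_starts)
            for v in variants
        }
    out = pd.DataFrame(rows).T
    out.index.name = "subject_id"
    return out


def summarize_behavior(trials: pd.DataFrame) -> pd.DataFrame:
    """Accuracy and mean correct RT per emotion x gaze x strength.

    Neutral trials (morph level 0) have no correct answer and are excluded.
    A ``threat_label`` aggregate over emotional trials is appended.
    """
    emo = trials[trials["morph_level"] > 0].copy()
    if emo["choice"].eq("").any():
        raise ValueError("trials must contain simulated or observed choices")
    emo["correct"] = emo["correct"].astype(float)

    def _agg(g):
        ok = g["correct"] == 1
        return pd.Series(
            {
                "accuracy": g["correct"].mean(),
                "mean_correct_rt": g.loc[ok, "rt"].mean(),
                "n": len(g),
            }
        )

    by_cell = (
        emo.groupby(["emotion", "gaze", "morph_level"])
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    by_threat = (
        emo.groupby("threat_label").apply(_agg, include_groups=False).reset_index()
    )
    by_threat["emotion"] = "all"
    by_threat["gaze"] = "all"
    by_threat["morph_level"] = -1
    by_cell["threat_label"] = threat_label_of(by_cell)
    return pd.concat([by_cell, by_threat], ignore_index=True)


def threat_label_of(df: pd.DataFrame):
    from .design import threat_label

    return threat_label(df["emotion"], df["gaze"])
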