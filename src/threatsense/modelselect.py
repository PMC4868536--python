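"""Bayesian model selection over subjects: fixed and random effects.

Model evidence per subject and model (here: cross-validated log-likelihood)
enters either a fixed-effects comparison -- all subjects share one model, so
group evidence is the product of subject evidences and two models compare by
their Bayes factor -- or a random-effects comparison that treats the
generating model as drawn per subject from an unknown population frequency
vector, inferred with a variational Dirichlet scheme.  Support for the
winning model is summarized by its exceedance probability, the posterior
probability that it is the most frequent model in the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma
from scipy.stats import beta as beta_dist

_LN10 = np.log(10.0)


@dataclass(frozen=True)
class FixedEffectsBF:
    """Fixed-effects Bayes factor between two models (log10 scale)."""

    model_a: str
    model_b: str
    log10_bf: float

    @property
    def bf(self) -> float:
        """Linear-scale Bayes factor; inf/0 beyond |log10| = 12."""
        if self.log10_bf > 12:
            return np.inf
        if self.log10_bf < -12:
            return 0.0
        return float(10.0**self.log10_bf)


def fixed_effects_bf(evidence: pd.DataFrame, model_a: str, model_b: str) -> FixedEffectsBF:
    """Bayes factor of ``model_a`` over ``model_b`` from per-subject evidence.

    ``evidence`` holds log model evidence (subjects x models); the group BF is
    exp of the summed per-subject evidence difference.
    """
    for m in (model_a, model_b):
        if m not in evidence.columns:
            raise ValueError(f"model {m!r} missing from evidence table")
    diff = evidence[model_a] - evidence[model_b]
    if diff.isna().any():
        raise ValueError("evidence missing for some subjects")
    return FixedEffectsBF(model_a, model_b, float(diff.sum() / _LN10))


@dataclass(frozen=True)
class ModelSelectionResult:
    """Random-effects model-selection summary."""

    models: tuple[str, ...]
    exceedance_probs: dict[str, float]
    expected_frequencies: dict[str, float]
    alpha: np.ndarray = field(repr=False)

    @property
    def winner(self) -> str:
        return max(self.exceedance_probs, key=self.exceedance_probs.get)


def _vb_dirichlet(logev: np.ndarray, alpha0: float = 1.0, tol: float = 1e-10,
                  max_iter: int = 10_000) -> np.ndarray:
    """Variational posterior Dirichlet(alpha) over model frequencies."""
    n, k = logev.shape
    alpha = np.full(k, alpha0)
    # stabilize per subject
    L = logev - logev.max(axis=1, keepdims=True)
    for _ in range(max_iter):
        w = L + (digamma(alpha) - digamma(alpha.sum()))
        w = np.exp(w - w.max(axis=1, keepdims=True))
        u = w / w.sum(axis=1, keepdims=True)
        new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(new - alpha)) < tol:
            alpha = new
            break
        alpha = new
    return alpha


def exceedance_prob(
    evidence: pd.DataFrame,
    alpha0: float = 1.0,
    n_samples: int = 200_000,
    seed: int = 0,
) -> ModelSelectionResult:
    """Random-effects exceedance probabilities from a subjects x models table.

    For two models the exceedance probability has a closed form under the
    Dirichlet posterior (a Beta tail); with more models it is estimated by
    seeded Monte-Carlo over Dirichlet draws.
    """
    if evidence.shape[1] < 1:
        raise ValueError("need at least one model")
    models = tuple(evidence.columns)
    if evidence.shape[1] == 1:
        return ModelSelectionResult(models, {models[0]: 1.0}, {models[0]: 1.0},
                                    np.array([1.0]))
    logev = evidence.to_numpy(float)
    if not np.isfinite(logev).all():
        raise ValueError("evidence table contains non-finite entries")
    alpha = _vb_dirichlet(logev, alpha0=alpha0)
    freq = alpha / alpha.sum()
    if len(models) == 2:
        # p1 ~ Beta(a1, a2); P(p1 > p2) = P(p1 > 1/2)
        p1 = float(beta_dist.sf(0.5, alpha[0], alpha[1]))
        pexc = np.array([p1, 1.0 - p1])
    else:
        rng = np.random.default_rng(seed)
        draws = rng.dirichlet(alpha, size=n_samples)
        pexc = np.bincount(draws.argmax(axis=1), minlength=len(models)) / n_samples
    return ModelSelectionResult(
        models,
        dict(zip(models, map(float, pexc))),
        dict(zip(models, map(float, freq))),
        alpha,
    )
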