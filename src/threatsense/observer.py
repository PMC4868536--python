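"""Simulated probit observer: choices and response times for a trial table."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .psychometric import ObserverParams, predict_choice_prob


@dataclass(frozen=True)
class RTModel:
    """Lognormal response-time generator.

    The median RT decreases linearly with absolute emotion strength
    (stronger evidence, faster decisions); log-RT has constant spread.
    RTs are clipped to the response deadline.
    """

    median_at_neutral: float = 0.95  # seconds
    slope_per_level: float = 0.05  # seconds of median decrease per |x| unit
    sigma: float = 0.25  # lognormal shape
    deadline: float = 2.0
    floor: float = 0.15

    def median(self, abs_strength):
        return np.maximum(
            self.median_at_neutral - self.slope_per_level * np.asarray(abs_strength),
            2 * self.floor,
        )


def simulate_observer(
    trials: pd.DataFrame,
    params: ObserverParams,
    rt_model: RTModel | None = None,
    seed: int = 0,
    extra_drive=None,
) -> pd.DataFrame:
    """Draw choices and RTs for every trial under a psychometric variant.

    ``extra_drive`` optionally adds a per-trial term inside the probit
    argument (used by the EEG generator to couple neural residuals into the
    decision); it must align with ``trials``.

    Returns a copy of ``trials`` with ``choice``, ``rt`` and ``correct``
    filled in.  ``correct`` is NaN for neutral trials (no right answer).
    """
    if rt_model is None:
        rt_model = RTModel()
    rng = np.random.default_rng(seed)
    out = trials.copy()
    x = out["signed_strength"].to_numpy(float)
    if extra_drive is None:
        p = predict_choice_prob(
            params, x, out["threat_label"].to_numpy(), out["gaze"].to_numpy()
        )
    else:
        from scipy.stats import norm

        from .psychometric import _condition_wb

        w, b = _condition_wb(
            params, out["threat_label"].to_numpy(), out["gaze"].to_numpy()
        )
        drive = np.asarray(extra_drive, float)
        if drive.shape != x.shape:
            raise ValueError("extra_drive must align with trials")
        p = (
            norm.cdf(w * x + b + drive) * (1.0 - params.lapse)
            + 0.5 * params.lapse
        )
    anger = rng.random(len(out)) < p
    out["choice"] = np.where(anger, "anger", "fear")
    med = rt_model.median(np.abs(x))
    rt = np.exp(np.log(med) + rt_model.sigma * rng.standard_normal(len(out)))
    out["rt"] = np.clip(rt, rt_model.floor, rt_model.deadline)
    emotional = out["morph_level"].to_numpy() > 0
    correct = np.where(
        emotional,
        (out["choice"].to_numpy() == out["emotion"].to_numpy()).astype(float),
        np.nan,
    )
    out["correct"] = correct
    return out
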