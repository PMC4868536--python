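"""Cohort simulation: many subjects with anxiety-coupled encoding gains.

Each subject receives a full factorial trial table, a probit observer with
THREAT+-enhanced sensitivity, and synthetic EEG.  Spielberger State-Trait
Anxiety Inventory (STAI) scores are drawn per subject and coupled to two
neural parameters with specified Pearson correlations:

* the THREAT+ minus THREAT- encoding-gain difference in the temporal group
  *decreases* with state anxiety (high-anxious subjects encode both negative
  emotions alike), and
* the THREAT+ motor encoding gain *increases* with state anxiety.

The construction is exact-in-expectation: the coupled quantity is built as
``rho * z_anxiety + sqrt(1 - rho^2) * noise`` on standardized scales, so the
generative correlation is known and recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import DesignParams, generate_trial_table
from .eegsim import GroundTruth, MotorConfig, SynthEEGConfig, simulate_eeg
from .io import EEGEpochs
from .observer import simulate_observer
from .psychometric import ObserverParams

STAI_MIN, STAI_MAX = 20.0, 80.0


@dataclass(frozen=True)
class AnxietyModel:
    """STAI score generator (healthy-adult range)."""

    state_mean: float = 30.5
    state_sd: float = 6.8
    trait_mean: float = 38.2
    trait_sd: float = 7.8

    def draw(self, rng, n):
        state = np.clip(rng.normal(self.state_mean, self.state_sd, n), STAI_MIN, STAI_MAX)
        trait = np.clip(rng.normal(self.trait_mean, self.trait_sd, n), STAI_MIN, STAI_MAX)
        return state, trait


@dataclass(frozen=True)
class CohortConfig:
    """Study-scale defaults: 24 subjects x 1080 trials."""

    n_subjects: int = 24
    design: DesignParams = field(default_factory=DesignParams)
    eeg: SynthEEGConfig = field(default_factory=SynthEEGConfig)
    anxiety: AnxietyModel = field(default_factory=AnxietyModel)
    #: Pearson correlation of state anxiety with the temporal THREAT+ minus
    #: THREAT- gain-multiplier difference (negative: difference shrinks with
    #: anxiety) and with the motor THREAT+ encoding gain.
    coupling_temporal: float = -0.5
    coupling_motor: float = 0.5
    #: between-subject SD of the temporal THREAT+ gain-multiplier difference
    #: and of the motor encoding gain (relative).  Chosen to emulate the wide
    #: per-subject spread of threat-gain differences seen in human cohorts,
    #: where individual differences span roughly zero to twice the mean.
    temporal_mult_sd: float = 0.35
    motor_gain_sd: float = 0.5

    def validate(self):
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        for c in (self.coupling_temporal, self.coupling_motor):
            if not -1.0 <= c <= 1.0:
                raise ValueError("coupling must lie in [-1, 1]")


@dataclass
class SubjectData:
    subject_id: str
    trials: pd.DataFrame
    eeg: EEGEpochs | None
    truth: GroundTruth | None
    state_score: float
    trait_score: float
    temporal_mult: float
    motor_enc_gain: float


def _coupled(rng, z_anchor, rho, n):
    """Standardized variate with Pearson correlation rho to ``z_anchor``."""
    return rho * z_anchor + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)


def iter_cohort(
    cfg: CohortConfig | None = None,
    seed: int = 0,
    with_eeg: bool = True,
):
    """Yield per-subject data lazily (EEG arrays are large).

    Hand mapping is counterbalanced across subjects.  All randomness derives
    from ``seed`` through spawned generators, so any prefix of the cohort is
    reproducible independently of how much of it is consumed.
    """
    if cfg is None:
        cfg = CohortConfig()
    cfg.validate()
    root = np.random.default_rng(seed)
    n = cfg.n_subjects
    state, trait = cfg.anxiety.draw(root, n)
    z_state = (state - state.mean()) / max(state.std(), 1e-12)

    base_mult = cfg.eeg.groups["temporal"].threat_plus_mult if "temporal" in cfg.eeg.groups else 1.5
    mean_diff = base_mult - 1.0
    diff = mean_diff + cfg.temporal_mult_sd * _coupled(
        np.random.default_rng(root.integers(2**31)), z_state, cfg.coupling_temporal, n
    )
    # individual differences may abolish or even invert the threat effect
    temporal_mult = np.clip(1.0 + diff, 0.2, None)

    base_motor = cfg.eeg.motor.enc_gain if cfg.eeg.motor is not None else MotorConfig().enc_gain
    motor_gain = base_motor * np.clip(
        1.0 + cfg.motor_gain_sd * _coupled(
            np.random.default_rng(root.integers(2**31)), z_state, cfg.coupling_motor, n
        ),
        0.1, None,
    )

    subject_seeds = root.integers(2**31, size=n)
    for s in range(n):
        sid = f"s{s + 1:02d}"
        mapping = "anger_left" if s % 2 == 0 else "anger_right"
        srng = np.random.default_rng(subject_seeds[s])
        trials = generate_trial_table(
            cfg.design, hand_mapping=mapping,
            seed=int(srng.integers(2**31)), subject_id=sid,
        )
        trials = simulate_observer(
            trials, cfg.eeg.observer, rt_model=cfg.eeg.rt_model,
            seed=int(srng.integers(2**31)),
        )
        eeg = truth = None
        if with_eeg:
            groups = dict(cfg.eeg.groups)
            if "temporal" in groups:
                groups["temporal"] = replace(
                    groups["temporal"], threat_plus_mult=float(temporal_mult[s])
                )
            motor = cfg.eeg.motor
            if motor is not None:
                motor = replace(motor, enc_gain=float(motor_gain[s]))
            scfg = replace(cfg.eeg, groups=groups, motor=motor)
            eeg, truth = simulate_eeg(trials, scfg, seed=int(srng.integers(2**31)))
            trials = truth.trials
        yield SubjectData(
            subject_id=sid,
            trials=trials,
            eeg=eeg,
            truth=truth,
            state_score=float(state[s]),
            trait_score=float(trait[s]),
            temporal_mult=float(temporal_mult[s]),
            motor_enc_gain=float(motor_gain[s]),
        )


def simulate_cohort(
    cfg: CohortConfig | None = None, seed: int = 0, with_eeg: bool = True
):
    """Materialize a cohort: list of SubjectData plus the anxiety table."""
    subjects = list(iter_cohort(cfg, seed=seed, with_eeg=with_eeg))
    anx = anxiety_table(subjects)
    return subjects, anx


def anxiety_table(subjects) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "state_score": [s.state_score for s in subjects],
            "trait_score": [s.trait_score for s in subjects],
            "true_temporal_mult": [s.temporal_mult for s in subjects],
            "true_motor_enc_gain": [s.motor_enc_gain for s in subjects],
        }
    )
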