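"""Factorial stimulus design and trial-table generation.

The emotion-categorization experiment crosses facial identity with displayed
emotion (anger or fear), parametric emotion strength (7 morph levels from
neutral), and gaze direction (direct or averted).  Each identity contributes
7 levels x 2 emotions x 2 gazes = 28 emotional stimuli plus 2 neutral ones
(one per gaze), and every stimulus is shown exactly once, partitioned into
blocks balanced in emotion, gaze, gender and morph level.

Gaze direction recontextualizes the displayed emotion: anger with direct gaze
and fear with averted gaze signal threat toward (or near) the observer and are
labelled THREAT+; the two complementary pairings are THREAT-.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EMOTIONS = ("anger", "fear")
GAZES = ("direct", "averted")
GENDERS = ("female", "male")

THREAT_PLUS = "THREAT+"
THREAT_MINUS = "THREAT-"
NEUTRAL = "neutral"

#: Column order of a canonical trial table.
TRIAL_COLUMNS = [
    "subject_id",
    "trial_index",
    "block",
    "identity",
    "gender",
    "emotion",
    "gaze",
    "morph_level",
    "signed_strength",
    "threat_label",
    "response_hand_mapping",
    "choice",
    "rt",
    "correct",
]


@dataclass(frozen=True)
class DesignParams:
    """Parameters of the factorial stimulus design.

    Defaults reproduce the full design: 36 identities (half female), 7 morph
    levels per emotion, 9 blocks -- 1080 trials of 120 per block.
    """

    n_identities: int = 36
    n_morph_levels: int = 7
    n_blocks: int = 9
    emotions: tuple[str, str] = EMOTIONS
    gazes: tuple[str, str] = GAZES

    @property
    def conditions_per_identity(self) -> int:
        # 2 emotions x 2 gazes x morph levels, plus one neutral per gaze
        return 2 * 2 * self.n_morph_levels + 2

    @property
    def n_trials(self) -> int:
        return self.n_identities * self.conditions_per_identity

    def validate(self) -> None:
        if self.n_identities < 1 or self.n_morph_levels < 1 or self.n_blocks < 1:
            raise ValueError("design fields must be positive")
        if self.n_trials % self.n_blocks:
            raise ValueError(
                f"total stimuli ({self.n_trials}) not divisible into "
                f"{self.n_blocks} blocks"
            )


def threat_label(emotion, gaze):
    """Threat pairing label for an (emotion, gaze) combination.

    Vectorized over array-likes; neutral expressions carry no threat label.
    """
    emotion = np.asarray(emotion, dtype=object)
    gaze = np.asarray(gaze, dtype=object)
    plus = ((emotion == "anger") & (gaze == "direct")) | (
        (emotion == "fear") & (gaze == "averted")
    )
    minus = ((emotion == "anger") & (gaze == "averted")) | (
        (emotion == "fear") & (gaze == "direct")
    )
    out = np.full(emotion.shape, NEUTRAL, dtype=object)
    out[plus] = THREAT_PLUS
    out[minus] = THREAT_MINUS
    if out.shape == ():
        return out[()]
    return out


def generate_trial_table(
    design: DesignParams | None = None,
    hand_mapping: str = "anger_left",
    seed: int = 0,
    subject_id: str = "s01",
) -> pd.DataFrame:
    """Enumerate every stimulus once and assign stimuli to balanced blocks.

    Blocks are built by stratified assignment: stimuli are grouped by
    (emotion, gaze, morph level, gender), each stratum is shuffled and dealt
    round-robin across blocks, and trial order is then shuffled within block.
    With the default design every stratum holds 18 stimuli (one per same-sex
    identity), so the 9 blocks are exactly balanced on all four factors.

    Parameters
    ----------
    design : DesignParams
        Factorial design; defaults to the full 36-identity design.
    hand_mapping : {"anger_left", "anger_right"}
        Response-hand assignment, constant within subject.
    seed : int
        Seeds the block shuffles; the stimulus set itself is deterministic.
    subject_id : str
        Identifier written into the table.

    Returns
    -------
    pandas.DataFrame
        One row per stimulus with the canonical :data:`TRIAL_COLUMNS`;
        ``choice`` is empty, ``rt``/``correct`` are NaN until an observer is
        simulated.
    """
    if design is None:
        design = DesignParams()
    design.validate()
    if hand_mapping not in ("anger_left", "anger_right"):
        raise ValueError(f"unknown hand_mapping {hand_mapping!r}")
    rng = np.random.default_rng(seed)

    rows = []
    for ident in range(design.n_identities):
        gender = GENDERS[ident % 2]
        name = f"id{ident:02d}"
        for emotion in design.emotions:
            for gaze in design.gazes:
                for level in range(1, design.n_morph_levels + 1):
                    rows.append((name, gender, emotion, gaze, level))
        for gaze in design.gazes:
            rows.append((name, gender, "neutral", gaze, 0))
    stim = pd.DataFrame(
        rows, columns=["identity", "gender", "emotion", "gaze", "morph_level"]
    )

    # stratified round-robin block assignment
    block_of = np.empty(len(stim), dtype=int)
    offset = 0
    strata = stim.groupby(
        ["emotion", "gaze", "morph_level", "gender"], sort=True
    ).indices
    for key in sorted(strata):
        idx = rng.permutation(strata[key])
        block_of[idx] = (np.arange(len(idx)) + offset) % design.n_blocks
        offset += len(idx)  # rotate remainders across strata

    stim["block"] = block_of + 1
    # shuffle trial order within each block
    order = np.concatenate(
        [
            rng.permutation(np.flatnonzero(block_of == b))
            for b in range(design.n_blocks)
        ]
    )
    stim = stim.iloc[order].reset_index(drop=True)

    sign = np.where(stim["emotion"] == "anger", 1, np.where(stim["emotion"] == "fear", -1, 0))
    stim["signed_strength"] = sign * stim["morph_level"]
    stim["threat_label"] = threat_label(stim["emotion"], stim["gaze"])
    stim["subject_id"] = subject_id
    stim["trial_index"] = np.arange(len(stim))
    stim["response_hand_mapping"] = hand_mapping
    stim["choice"] = ""
    stim["rt"] = np.nan
    stim["correct"] = np.nan
    return stim[TRIAL_COLUMNS]
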