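"""Synthetic epoched EEG with programmable encoding, coupling and motor structure.

The generator produces exactly the statistical structure the downstream
analyses assume, with every injected quantity recorded as ground truth:

* Broadband channel groups (temporal, centro-parietal, frontal) whose
  amplitude co-varies with unsigned emotion strength through a Gaussian gain
  time course, scaled by a THREAT+ multiplier on threat-signaling trials.
* A shared per-trial residual fluctuation per group, injected into the EEG
  along a fixed time profile and -- when coupling is enabled -- fed back into
  the observer's decision additively (b_mod) and/or multiplicatively with
  emotion strength (w_mod).  Choices are produced in two passes: residuals
  are drawn first, then choices are re-simulated from the mediation equation,
  so recovered modulators have a known ground truth.
* Motor channels carrying band-limited 8-32 Hz oscillations whose power is
  suppressed over the hemisphere contralateral to the chosen hand before the
  response, plus a signed-emotion-strength lateralization whose ramp onset
  depends on the threat condition (or on the trial's speed, for the RT-split
  analysis).

Scalp realism (topographies, volume conduction, artifacts) is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import EEGEpochs
from .observer import RTModel, simulate_observer
from .psychometric import ObserverParams


@dataclass(frozen=True)
class GroupConfig:
    """One broadband channel group with its encoding gain and coupling."""

    channels: tuple[str, ...]
    peak_time: float  # s, gain peak latency
    peak_width: float  # s, Gaussian SD of the gain time course
    amplitude: float  # a.u. per unsigned strength unit at the peak
    threat_plus_mult: float = 1.5  # gain multiplier on THREAT+ trials
    resid_amplitude: float = 1.0  # a.u. of the shared trial residual at peak
    w_mod_true: float = 0.0  # multiplicative residual->choice coupling
    b_mod_true: float = 0.0  # additive residual->choice coupling


@dataclass(frozen=True)
class MotorConfig:
    """Mu-beta motor generator: carrier band, preparation, signed encoding."""

    left_channels: tuple[str, ...] = ("C3", "CP3", "P3")
    right_channels: tuple[str, ...] = ("C4", "CP4", "P4")
    band: tuple[float, float] = (8.0, 32.0)
    base_amplitude: float = 1.0
    prep_gain: float = 0.5  # lateralization toward chosen hand at response
    prep_ramp: float = 0.3  # s over which preparation builds before RT
    enc_gain: float = 0.06  # lateralization per signed strength unit
    enc_ramp: float = 0.2  # s rise time of the encoding ramp
    onset_threat_plus: float = 0.20  # s, encoding onset on THREAT+ trials
    onset_threat_minus: float = 0.44  # s, encoding onset on THREAT- trials
    rt_split_onsets: tuple[float, float] | None = None  # (fast, slow) override
    noise_sd: float = 0.3


def default_groups() -> dict[str, GroupConfig]:
    return {
        "temporal": GroupConfig(
            channels=("TP7", "TP8", "P7", "P8"),
            peak_time=0.28, peak_width=0.05, amplitude=0.12,
        ),
        "centro_parietal": GroupConfig(
            channels=("CPz", "CP1", "CP2", "Pz"),
            peak_time=0.50, peak_width=0.08, amplitude=0.12,
            w_mod_true=0.1,
        ),
        "frontal": GroupConfig(
            channels=("Fz", "F1", "F2", "AFz"),
            peak_time=0.28, peak_width=0.05, amplitude=0.10,
        ),
    }


@dataclass(frozen=True)
class SynthEEGConfig:
    """Full configuration of one subject's synthetic EEG."""

    sfreq: float = 500.0
    epoch: tuple[float, float] = (-0.2, 1.0)
    noise_sd: float = 1.0
    groups: dict[str, GroupConfig] = field(default_factory=default_groups)
    motor: MotorConfig | None = None
    observer: ObserverParams | None = ObserverParams(
        variant="sensitivity", w=(0.45, 0.30), b=0.0, lapse=0.05
    )
    rt_model: RTModel = field(default_factory=RTModel)

    def validate(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        t0, t1 = self.epoch
        if t1 <= t0:
            raise ValueError("epoch window is empty")
        if self.motor is not None:
            for onset in (self.motor.onset_threat_plus, self.motor.onset_threat_minus):
                if not t0 <= onset <= t1:
                    raise ValueError("motor onset latency outside epoch window")

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.epoch[1] - self.epoch[0]) * self.sfreq)) + 1
        return self.epoch[0] + np.arange(n) / self.sfreq

    @property
    def channel_names(self) -> list[str]:
        names: list[str] = []
        for g in self.groups.values():
            names.extend(g.channels)
        if self.motor is not None:
            names.extend(self.motor.left_channels)
            names.extend(self.motor.right_channels)
        return names


@dataclass
class GroundTruth:
    """Everything injected by the generator, for recovery checks."""

    trials: pd.DataFrame
    times: np.ndarray
    gain_curves: dict[str, np.ndarray]  # per group: gain(t) at unit strength
    resid_profiles: dict[str, np.ndarray]
    e_true: dict[str, np.ndarray]  # per group: per-trial residual scores
    coupling: dict[str, tuple[float, float]]  # (w_mod_true, b_mod_true)
    lat_true: np.ndarray | None = None  # trials x time programmed lateralization
    motor_onsets: np.ndarray | None = None
    choices_resimulated: bool = False


def _gauss(times, peak, width):
    return np.exp(-0.5 * ((times - peak) / width) ** 2)


def deterministic_broadband(
    trials: pd.DataFrame, cfg: SynthEEGConfig, e_true: dict[str, np.ndarray]
) -> np.ndarray:
    """Noise-free broadband signal implied by config + residual record.

    In the noise_sd -> 0 limit the generated channels equal this exactly.
    """
    times = cfg.times
    strength = trials["morph_level"].to_numpy(float)
    tplus = (trials["threat_label"].to_numpy() == "THREAT+").astype(float)
    n = len(trials)
    n_bb = sum(len(g.channels) for g in cfg.groups.values())
    out = np.zeros((n, n_bb, len(times)))
    ci = 0
    for name, g in cfg.groups.items():
        gain = g.amplitude * _gauss(times, g.peak_time, g.peak_width)
        mult = 1.0 + (g.threat_plus_mult - 1.0) * tplus
        det = np.outer(strength * mult, gain)
        det += np.outer(e_true[name], g.resid_amplitude * _gauss(times, g.peak_time, g.peak_width))
        for _ in g.channels:
            out[:, ci, :] = det
            ci += 1
    return out


def _band_limited_noise(rng, shape, sfreq, band):
    """Unit-variance noise restricted to ``band`` Hz along the last axis."""
    n_t = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_t, d=1.0 / sfreq)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec *= mask
    sig = np.fft.irfft(spec, n=n_t, axis=-1)
    sd = sig.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return sig / sd


def _ramp(times, onset, dur):
    """0 before onset, linear rise over ``dur``, then 1 (vectorized)."""
    return np.clip((times[None, :] - onset[:, None]) / dur, 0.0, 1.0)


def _motor_onsets(trials: pd.DataFrame, motor: MotorConfig) -> np.ndarray:
    if motor.rt_split_onsets is not None:
        fast_on, slow_on = motor.rt_split_onsets
        rt = trials["rt"].to_numpy(float)
        onsets = np.full(len(trials), slow_on)
        for lev, idx in trials.groupby("morph_level").indices.items():
            order = idx[np.argsort(rt[idx], kind="stable")]
            onsets[order[: len(order) // 2]] = fast_on
        return onsets
    labels = trials["threat_label"].to_numpy()
    return np.where(labels == "THREAT+", motor.onset_threat_plus,
                    motor.onset_threat_minus)


def simulate_eeg(
    trials: pd.DataFrame, cfg: SynthEEGConfig, seed: int = 0
) -> tuple[EEGEpochs, GroundTruth]:
    """Generate one subject's epoched EEG for a trial table.

    Trials must contain simulated choices and RTs (the motor generator and
    the residual-choice coupling need them).  When any group couples its
    residual into the decision, choices and RTs are re-simulated from the
    mediation equation using ``cfg.observer`` -- the returned ground truth
    carries the updated trial table, which downstream analyses must use.
    """
    cfg.validate()
    if trials["choice"].eq("").any() or trials["choice"].isna().any():
        raise ValueError("trials must contain choices; run simulate_observer first")
    rng = np.random.default_rng(seed)
    times = cfg.times
    n = len(trials)

    e_true = {name: rng.standard_normal(n) for name in cfg.groups}
    coupling = {n_: (g.w_mod_true, g.b_mod_true) for n_, g in cfg.groups.items()}
    coupled = any(w != 0 or b != 0 for w, b in coupling.values())
    resim = False
    if coupled:
        if cfg.observer is None:
            raise ValueError("residual-choice coupling requires cfg.observer")
        x = trials["signed_strength"].to_numpy(float)
        drive = np.zeros(n)
        for name, g in cfg.groups.items():
            drive += g.w_mod_true * e_true[name] * x + g.b_mod_true * e_true[name]
        trials = simulate_observer(
            trials, cfg.observer, rt_model=cfg.rt_model,
            seed=int(rng.integers(2**31)), extra_drive=drive,
        )
        resim = True

    det = deterministic_broadband(trials, cfg, e_true)
    n_bb = det.shape[1]
    data = np.empty((n, len(cfg.channel_names), len(times)), dtype=np.float32)
    data[:, :n_bb, :] = det + cfg.noise_sd * rng.standard_normal(det.shape)

    gain_curves = {
        name: g.amplitude * _gauss(times, g.peak_time, g.peak_width)
        for name, g in cfg.groups.items()
    }
    resid_profiles = {
        name: g.resid_amplitude * _gauss(times, g.peak_time, g.peak_width)
        for name, g in cfg.groups.items()
    }

    lat_true = None
    onsets = None
    if cfg.motor is not None:
        m = cfg.motor
        mapping = trials["response_hand_mapping"].iloc[0]
        onsets = _motor_onsets(trials, m)
        x = trials["signed_strength"].to_numpy(float)
        rt = trials["rt"].to_numpy(float)
        choice_dir = np.where(trials["choice"].to_numpy() == "anger", 1.0, -1.0)
        # positive lat = anger-hand preparation (contra(fear) minus contra(anger)
        # band power), matching the hand-referenced lateralization index
        lat_true = (
            m.enc_gain * x[:, None] * _ramp(times, onsets, m.enc_ramp)
            + m.prep_gain * choice_dir[:, None] * _ramp(times, rt - m.prep_ramp, m.prep_ramp)
        )
        lat = np.clip(lat_true, -1.8, 1.8)
        # power_contra_fear = base^2 (1 + lat/2); power_contra_anger = 1 - lat/2
        env_cf = m.base_amplitude * np.sqrt(np.clip(1.0 + lat / 2.0, 0.02, None))
        env_ca = m.base_amplitude * np.sqrt(np.clip(1.0 - lat / 2.0, 0.02, None))
        if mapping == "anger_left":
            env_left, env_right = env_cf, env_ca  # contra(fear=right hand)=left
        else:
            env_left, env_right = env_ca, env_cf
        n_l = len(m.left_channels)
        n_r = len(m.right_channels)
        carrier = _band_limited_noise(rng, (n, n_l + n_r, len(times)), cfg.sfreq, m.band)
        motor_dat = np.empty((n, n_l + n_r, len(times)))
        motor_dat[:, :n_l, :] = env_left[:, None, :] * carrier[:, :n_l, :]
        motor_dat[:, n_l:, :] = env_right[:, None, :] * carrier[:, n_l:, :]
        motor_dat += m.noise_sd * rng.standard_normal(motor_dat.shape)
        data[:, n_bb:, :] = motor_dat

    eeg = EEGEpochs(
        data=data,
        times=times,
        sfreq=cfg.sfreq,
        channel_names=cfg.channel_names,
        lock="stimulus",
    )
    truth = GroundTruth(
        trials=trials,
        times=times,
        gain_curves=gain_curves,
        resid_profiles=resid_profiles,
        e_true=e_true,
        coupling=coupling,
        lat_true=lat_true,
        motor_onsets=onsets,
        choices_resimulated=resim,
    )
    return eeg, truth
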