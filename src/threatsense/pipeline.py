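"""End-to-end pipeline: simulate -> fit-behavior -> encode -> motor -> mediate -> groupstats.

A :class:`PipelineConfig` (YAML/JSON-serializable dict of stage toggles and
parameters, every random stage with an explicit seed) drives the stages in
dependency order into a run directory with one subfolder per stage.  Each
stage writes plain CSV/JSON (and HDF5 for EEG), and the resolved config plus
its hash are stored alongside so any number can be traced to config + seed.
Deterministic stages are bit-identical across reruns of the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from .cohort import CohortConfig, iter_cohort
from .design import DesignParams
from .eegsim import MotorConfig, SynthEEGConfig
from .encoding import condition_encoding, encode_glm, select_electrodes
from .groupstats import anxiety_analysis, bic_bayes_null, cluster_permutation
from .io import ensure_dir, write_anxiety_csv, write_eeg_h5, write_trials_csv
from .mediation import mediation_cv_evidence, select_mediation_model
from .modelselect import exceedance_prob, fixed_effects_bf
from .motor import lateralization_index, multitaper_power, signed_encoding
from .psychometric import evidence_table, fit_psychometric, summarize_behavior

log = logging.getLogger("threatsense")


@dataclass
class PipelineConfig:
    """Flat, serializable configuration of a full run."""

    out_dir: str = "runs/demo"
    seed: int = 0
    n_subjects: int = 4
    n_identities: int = 36
    sfreq: float = 500.0
    with_motor: bool = True
    cv_folds: int = 10
    n_perm: int = 1000
    encoding_peak: float = 0.28
    mediation_time: float = 0.50
    mediation_channels: tuple[str, ...] = ("CPz", "CP1", "CP2", "Pz")
    stages: tuple[str, ...] = (
        "simulate", "fit-behavior", "encode", "motor", "mediate", "groupstats"
    )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "mediation_channels"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(d["stages"])
        d["mediation_channels"] = list(d["mediation_channels"])
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def cohort_config(self) -> CohortConfig:
        eeg = SynthEEGConfig(
            sfreq=self.sfreq,
            motor=MotorConfig() if self.with_motor else None,
        )
        return CohortConfig(
            n_subjects=self.n_subjects,
            design=DesignParams(n_identities=self.n_identities),
            eeg=eeg,
        )


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = ensure_dir(config.out_dir)
    (out / "config.yaml").write_text(
        yaml.safe_dump({**config.to_dict(), "config_hash": config.config_hash})
    )
    done = set()
    for stage in config.stages:
        log.info("stage %s starting", stage)
        _STAGES[stage](config, out, done)
        done.add(stage)
        log.info("stage %s done", stage)
    return out


def _require(done, *needed):
    missing = [s for s in needed if s not in done]
    if missing:
        raise RuntimeError(f"missing upstream stage(s): {missing}")


def _stage_simulate(cfg: PipelineConfig, out: Path, done):
    d = ensure_dir(out / "simulate")
    subjects = list(iter_cohort(cfg.cohort_config(), seed=cfg.seed))
    for sub in subjects:
        write_trials_csv(d / f"{sub.subject_id}_trials.csv", sub.trials)
        write_eeg_h5(d / f"{sub.subject_id}_eeg.h5", sub.eeg)
    write_anxiety_csv(d / "anxiety.csv", cohort_mod.anxiety_table(subjects))


def _load_trials(out: Path):
    from .io import read_trials_csv

    d = out / "simulate"
    return {
        p.stem.replace("_trials", ""): read_trials_csv(p)
        for p in sorted(d.glob("*_trials.csv"))
    }


def _load_eeg(out: Path, sid: str):
    from .io import read_eeg_h5

    return read_eeg_h5(out / "simulate" / f"{sid}_eeg.h5")


def _stage_fit_behavior(cfg: PipelineConfig, out: Path, done):
    _require(done, "simulate")
    d = ensure_dir(out / "fit-behavior")
    trials = _load_trials(out)
    rows = []
    for sid, tr in trials.items():
        for variant in ("null", "bias", "sensitivity"):
            fit = fit_psychometric(tr, variant, seed=cfg.seed)
            p = fit.params
            w = p.w if isinstance(p.w, float) else None
            rows.append(
                {
                    "subject_id": sid, "variant": variant, "nll": fit.nll,
                    "converged": fit.converged,
                    "w": w,
                    "w_plus": None if w is not None else p.w[0],
                    "w_minus": None if w is not None else p.w[1],
                    "b": p.b if isinstance(p.b, float) else None,
                    "b_direct": None if isinstance(p.b, float) else p.b[0],
                    "b_averted": None if isinstance(p.b, float) else p.b[1],
                    "lapse": p.lapse,
                }
            )
        summarize_behavior(tr).to_csv(d / f"{sid}_summary.csv", index=False)
    pd.DataFrame(rows).to_csv(d / "fits.csv", index=False)
    ev = evidence_table(trials, k=cfg.cv_folds, seed=cfg.seed)
    ev.to_csv(d / "cv_evidence.csv")
    sel = exceedance_prob(ev, seed=cfg.seed)
    bf = fixed_effects_bf(ev, "sensitivity", "bias")
    (d / "model_selection.json").write_text(
        json.dumps(
            {
                "exceedance_probs": sel.exceedance_probs,
                "expected_frequencies": sel.expected_frequencies,
                "log10_bf_sensitivity_vs_bias": bf.log10_bf,
            },
            indent=2,
        )
    )


def _stage_encode(cfg: PipelineConfig, out: Path, done):
    _require(done, "simulate")
    d = ensure_dir(out / "encode")
    trials = _load_trials(out)
    gains = []
    betas_all = []
    for sid, tr in trials.items():
        eeg = _load_eeg(out, sid)
        res = encode_glm(eeg, tr[["morph_level"]], zscore=False,
                         residual_channels=list(cfg.mediation_channels))
        np.save(d / f"{sid}_residuals.npy", res.residuals)
        betas_all.append(res.beta("morph_level"))
        cond = condition_encoding(eeg, tr, zscore=False)
        win = (eeg.times >= cfg.encoding_peak - 0.02) & (eeg.times <= cfg.encoding_peak + 0.02)
        tch = [i for i, c in enumerate(eeg.channel_names) if c in ("TP7", "TP8", "P7", "P8")]
        gains.append(
            {
                "subject_id": sid,
                "threat_plus": cond["THREAT+"].beta("morph_level")[tch][:, win].mean(),
                "threat_minus": cond["THREAT-"].beta("morph_level")[tch][:, win].mean(),
            }
        )
    pd.DataFrame(gains).to_csv(d / "temporal_gains.csv", index=False)
    group = np.stack(betas_all)  # subjects x ch x time
    eeg0 = _load_eeg(out, next(iter(trials)))
    chans = select_electrodes(group, eeg0.times, eeg0.channel_names,
                              (cfg.encoding_peak - 0.05, cfg.encoding_peak + 0.05))
    (d / "channels_of_interest.json").write_text(json.dumps(list(chans.names)))
    np.save(d / "group_betas.npy", group)
    np.save(d / "times.npy", eeg0.times)


def _stage_motor(cfg: PipelineConfig, out: Path, done):
    _require(done, "simulate")
    if not cfg.with_motor:
        log.info("motor stage skipped (with_motor=False)")
        return
    d = ensure_dir(out / "motor")
    trials = _load_trials(out)
    rows = {}
    for sid, tr in trials.items():
        eeg = _load_eeg(out, sid)
        tfr = multitaper_power(
            eeg, picks=["C3", "CP3", "P3", "C4", "CP4", "P4"], decim=5
        )
        lat = lateralization_index(tfr, tr)
        enc = signed_encoding(lat, tr, split="threat")
        rows[sid] = {
            "times": enc["times"],
            "plus": enc["THREAT+"][0],
            "minus": enc["THREAT-"][0],
        }
    times = next(iter(rows.values()))["times"]
    plus = np.stack([r["plus"] for r in rows.values()])
    minus = np.stack([r["minus"] for r in rows.values()])
    np.save(d / "motor_times.npy", times)
    np.save(d / "encoding_threat_plus.npy", plus)
    np.save(d / "encoding_threat_minus.npy", minus)


def _stage_mediate(cfg: PipelineConfig, out: Path, done):
    _require(done, "simulate", "encode")
    d = ensure_dir(out / "mediate")
    trials = _load_trials(out)
    ev = {}
    for sid, tr in trials.items():
        resid = np.load(out / "encode" / f"{sid}_residuals.npy")
        times = np.load(out / "encode" / "times.npy")
        ti = int(np.argmin(np.abs(times - cfg.mediation_time)))
        e = resid[:, :, ti].mean(axis=1)
        e = (e - e.mean()) / e.std()
        ev[sid] = mediation_cv_evidence(tr, e, k=cfg.cv_folds, seed=cfg.seed)
    evd = pd.DataFrame(ev).T
    evd.to_csv(d / "mediation_evidence.csv")
    sel = select_mediation_model(evd, seed=cfg.seed)
    (d / "model_selection.json").write_text(json.dumps(sel, indent=2, default=float))


def _stage_groupstats(cfg: PipelineConfig, out: Path, done):
    _require(done, "simulate", "encode")
    d = ensure_dir(out / "groupstats")
    group = np.load(out / "encode" / "group_betas.npy")
    times = np.load(out / "encode" / "times.npy")
    tch = slice(0, 4)  # temporal group leads the channel list
    series = group[:, tch, :].mean(axis=1)
    res = cluster_permutation(series, times, n_perm=cfg.n_perm, seed=cfg.seed)
    clusters = [
        {"t_start": c.t_start, "t_end": c.t_end, "sign": c.sign,
         "mass": c.mass, "p_corrected": c.p_corrected}
        for c in res.clusters
    ]
    (d / "temporal_encoding_clusters.json").write_text(json.dumps(clusters, indent=2))
    gains = pd.read_csv(out / "encode" / "temporal_gains.csv")
    from .io import read_anxiety_csv

    anx = read_anxiety_csv(out / "simulate" / "anxiety.csv")
    if len(gains) >= 4:
        res_anx = anxiety_analysis(gains, anx)
        (d / "anxiety.json").write_text(
            json.dumps(
                {
                    "r": res_anx.correlation.r,
                    "p": res_anx.correlation.p,
                    "interaction_F": res_anx.interaction_F,
                    "interaction_p": res_anx.interaction_p,
                    "outliers": list(res_anx.correlation.outliers),
                },
                indent=2,
            )
        )
    diffs = (gains["threat_plus"] - gains["threat_minus"]).to_numpy()
    if len(diffs) >= 3 and diffs.std() > 0:
        bf = bic_bayes_null(diffs)
        (d / "threat_gain_bf.json").write_text(
            json.dumps({"bf10": bf.bf10, "interpretation": bf.interpretation})
        )


_STAGES = {
    "simulate": _stage_simulate,
    "fit-behavior": _stage_fit_behavior,
    "encode": _stage_encode,
    "motor": _stage_motor,
    "mediate": _stage_mediate,
    "groupstats": _stage_groupstats,
}
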