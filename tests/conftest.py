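import numpy as np
import pandas as pd
import pytest

import threatsense as ts


@pytest.fixture(scope="session")
def sens_params():
    """Sensitivity-variant observer with THREAT+-enhanced gain."""
    return ts.ObserverParams(variant="sensitivity", w=(0.45, 0.30), b=0.0, lapse=0.05)


@pytest.fixture(scope="session")
def subject_trials(sens_params):
    """One full 1080-trial subject simulated from the sensitivity variant."""
    tt = ts.generate_trial_table(seed=11, subject_id="s01")
    return ts.simulate_observer(tt, sens_params, seed=12)


@pytest.fixture(scope="session")
def cp_eeg(sens_params):
    """Centro-parietal-only EEG for one subject, with multiplicative coupling."""
    from threatsense.eegsim import SynthEEGConfig, default_groups

    groups = {"centro_parietal": default_groups()["centro_parietal"]}
    cfg = SynthEEGConfig(groups=groups, motor=None)
    tt = ts.generate_trial_table(seed=21, subject_id="s01")
    tr = ts.simulate_observer(tt, sens_params, seed=22)
    eeg, truth = ts.simulate_eeg(tr, cfg, seed=23)
    return eeg, truth, cfg
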