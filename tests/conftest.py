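import numpy as np
import pandas as pd
import pytest

from avchoice import AdditiveParams
from avchoice import synthetic as sy


@pytest.fixture(scope="session")
def true_params():
    return AdditiveParams(b=0.2, gamma=0.6, vR=3.0, vL=3.0, aR=2.0, aL=2.0)


@pytest.fixture(scope="session")
def behavior_trials(true_params):
    """Medium-sized additive-law behavioral dataset with RTs."""
    cfg = sy.BehaviorSimConfig(true_params=true_params, n_trials=6000, seed=11)
    trials = sy.gen_trial_schedule(cfg)
    return sy.simulate_choices(trials, true_params, seed=12,
                               rt_model=cfg.rt_model)


@pytest.fixture(scope="session")
def small_trials(true_params):
    cfg = sy.BehaviorSimConfig(true_params=true_params, n_trials=800, seed=21)
    trials = sy.gen_trial_schedule(cfg)
    return sy.simulate_choices(trials, true_params, seed=22,
                               rt_model=cfg.rt_model)


@pytest.fixture(scope="session")
def spike_population(behavior_trials):
    """Small simulated population on multisensory high-contrast trials."""
    t = behavior_trials
    ms = t[t["trial_type"].isin(["coherent", "conflict"])
           & ((t["vis_contrast_L"] + t["vis_contrast_R"]) >= 0.4)]
    ms = ms.iloc[:160]
    cfg = sy.NeuronSimConfig(n_neurons=8, seed=31)
    return sy.gen_population_spikes(ms, cfg)
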