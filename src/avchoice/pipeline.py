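"""End-to-end driver: synthetic generation -> behavior extraction ->
psychometrics -> inactivation map -> encoding/decoding -> accumulator,
producing a reproducible report bundle with an explicit seed per stage.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .psychometrics import AdditiveParams


@dataclass
class PipelineConfig:
    """Seeds, design constants and replication counts for every stage.

    The ``full`` profile uses full-scale replication counts; the default ``ci``
    profile scales them down so the whole pipeline runs in minutes on one
    core. Every stochastic stage has its own seed derived from ``seed``.
    """

    seed: int = 0
    out_dir: str = "avchoice_out"
    profile: str = "ci"                  # 'ci' | 'full'
    n_behavior_trials: int = 4000
    n_inactivation_trials: int = 8000
    n_neurons: int = 12
    n_spike_trials: int = 120
    n_surrogate_per_cond: int = 40
    n_subsample: int = 20
    n_shuffle: int = 50
    accumulator_epochs: int = 150
    true_params: dict = field(default_factory=lambda: asdict(AdditiveParams()))

    @classmethod
    def full_scale_defaults(cls, seed: int = 0, out_dir: str = "avchoice_out"):
        return cls(seed=seed, out_dir=out_dir, profile="full",
                   n_behavior_trials=31000, n_inactivation_trials=80000,
                   n_neurons=140, n_spike_trials=600,
                   n_surrogate_per_cond=360, n_subsample=25000,
                   n_shuffle=250000, accumulator_epochs=300)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if data.get("profile") == "full":
            base = cls.full_scale_defaults()
            for k, v in data.items():
                setattr(base, k, v)
            return base
        return cls(**data)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def _stage_seed(cfg: PipelineConfig, stage: str) -> int:
    # stable across processes (unlike builtin str hash)
    tag = zlib.crc32(stage.encode()) % 2**16
    return int(np.random.default_rng([cfg.seed, tag]).integers(2**31))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns (and writes) a manifest of results.

    Stages that cannot run under the configuration (e.g. zero neurons) are
    skipped and recorded as such. Any stage exception is re-raised with the
    stage name attached.
    """
    from . import accumulator as acc
    from . import behavior, encoding, inactivation, neural_stats, synthetic
    from . import psychometrics as psych

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config": asdict(cfg), "stages": {}}
    true_params = AdditiveParams(**cfg.true_params)

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                result = fn()
            except Exception as e:  # noqa: BLE001 - annotate and halt
                raise RuntimeError(f"pipeline stage {name!r} failed") from e
            result = result or {}
            result["elapsed_s"] = round(time.time() - t0, 3)
            manifest["stages"][name] = result
            return result
        return deco

    state = {}

    @stage("behavior_sim")
    def _():
        bcfg = synthetic.BehaviorSimConfig(
            true_params=true_params, n_trials=cfg.n_behavior_trials,
            seed=_stage_seed(cfg, "behavior_sim"))
        trials = synthetic.gen_trial_schedule(bcfg)
        trials = synthetic.simulate_choices(
            trials, true_params, seed=_stage_seed(cfg, "choices"),
            rt_model=bcfg.rt_model)
        traces = synthetic.gen_wheel_traces(
            trials, seed=_stage_seed(cfg, "wheel"))
        state["trials"], state["traces"] = trials, traces
        trials.to_csv(out / "trials.csv", index=False)
        return {"n_trials": len(trials), "seed": _stage_seed(cfg, "behavior_sim")}

    @stage("behavior_extract")
    def _():
        extracted = behavior.extract_trials(
            state["trials"].drop(columns=["choice", "rt_s", "timeout"]),
            state["traces"])
        filtered = behavior.filter_trials(extracted)
        summary = behavior.summarize_behavior(filtered)
        state["filtered"] = filtered
        summary["by_type"].to_csv(out / "behavior_by_type.csv", index=False)
        match = float(np.mean(extracted["choice"].to_numpy()
                              == state["trials"]["choice"].to_numpy()))
        return {"choice_recovery": match,
                "n_excluded": int(filtered["excluded"].sum())}

    @stage("psychometrics")
    def _():
        fit = psych.fit_ml(state["filtered"][~state["filtered"]["excluded"]],
                           "additive_parametric",
                           seed=_stage_seed(cfg, "psych"))
        cv = {fam: psych.cv_bits_per_trial(
                state["filtered"], fam, seed=_stage_seed(cfg, "psych_cv"),
                n_starts=3).cv_bits_per_trial
              for fam in ("additive_parametric", "auditory_only",
                          "visual_only")}
        state["psych_fit"] = fit
        with open(out / "psych_fit.json", "w") as fh:
            json.dump({"params": fit.params, "cv_bits": cv}, fh, indent=2)
        return {"params": fit.params, "cv_bits_per_trial": cv}

    @stage("inactivation")
    def _():
        from .design import default_site_grid
        grid = default_site_grid()
        icfg = synthetic.InactivationSimConfig(
            site_grid=grid,
            region_effects={"visual": {"vc": -1.5}},
            seed=_stage_seed(cfg, "inact_sim"))
        table = synthetic.gen_inactivation_dataset(
            true_params, icfg, n_trials=cfg.n_inactivation_trials,
            seed=_stage_seed(cfg, "inact_data"))
        site = next(s for s in grid if s.region == "visual")
        res = inactivation.shuffle_test_choice_shift(
            table, site, stimulus_type="unisensory_visual",
            n_subsample=cfg.n_subsample,
            n_shuffle_per=10, seed=_stage_seed(cfg, "inact_test"))
        return {"site": (site.ap_mm, site.ml_mm), "delta": res.observed,
                "p": res.p}

    if cfg.n_neurons > 0:
        @stage("encoding")
        def _():
            ncfg = synthetic.NeuronSimConfig(
                n_neurons=cfg.n_neurons, seed=_stage_seed(cfg, "neurons"))
            sub = state["filtered"].iloc[:cfg.n_spike_trials]
            sub = sub[sub["trial_type"].isin(["coherent", "conflict"])]
            pop = synthetic.gen_population_spikes(sub, ncfg)
            errs = []
            for nid in range(min(cfg.n_neurons, 6)):
                rates = encoding.rates_from_population(
                    pop, nid, bin_s=0.01)
                f = encoding.fit_kernels(rates, pop.trials,
                                         seed=_stage_seed(cfg, "kern"))
                errs.append(f.cv_error)
            state["pop"] = pop
            return {"mean_cv_error": float(np.mean(errs)),
                    "n_neurons_fit": len(errs)}

        @stage("accumulator")
        def _():
            ncfg = synthetic.NeuronSimConfig(
                n_neurons=cfg.n_neurons, seed=_stage_seed(cfg, "bank"))
            bank = synthetic.gen_psth_bank(ncfg)
            pop = acc.make_surrogates(
                bank, n_per_cond=cfg.n_surrogate_per_cond,
                seed=_stage_seed(cfg, "surrogate"))
            model = acc.Accumulator(
                epochs=cfg.accumulator_epochs,
                seed=_stage_seed(cfg, "train")).fit(pop)
            test = pop.x[model.test_idx_]
            outcomes = model.predict(test, pop.t)
            decided = outcomes["choice"].isin(["L", "R"])
            correct = np.mean(
                np.where(outcomes["choice"][decided] == "R", 1, -1)
                == pop.y[model.test_idx_][decided]) if decided.any() else np.nan
            return {"final_loss": float(model.loss_history_[-1]),
                    "held_out_accuracy": float(correct),
                    "frac_decided": float(decided.mean())}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
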