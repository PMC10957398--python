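"""Synthetic audiovisual datasets with the statistical structure the
analyses assume: trial schedules, additive-law choices, wheel traces,
kernel-structured Poisson spike trains, inactivation datasets, and
condition-wise PSTH banks.

Every generator is deterministic under a fixed seed. Defaults reproduce the
task design: trial-type ratio 10/10/5/5/1 (unisensory visual / unisensory
auditory / coherent / conflict / neutral), contrasts {10, 20, 40, 80}%,
azimuths {-60, 0, +60} degrees, and a 75% inactivation-trial fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior as _behavior
from .design import (AZIMUTHS, CONTRASTS, DEFAULT_TYPE_RATIO, TRIAL_TYPES,
                     LaserSite, classify_trial_type, default_site_grid,
                     validate_trials)
from .psychometrics import AdditiveParams


# -- behavioral configuration ----------------------------------------------

@dataclass
class RTModel:
    """Invented generative reaction-time model (plumbing, not a claim).

    rt = base - aud_advantage * [lateral sound] - contrast_slope * contrast
         + N(0, jitter_sd), truncated > min_rt.

    Defaults order the medians coherent < auditory < visual, matching the
    qualitative task structure (sounds are localized faster than gratings).
    """

    base_s: float = 0.22
    aud_advantage_s: float = 0.022
    contrast_slope_s: float = 0.05
    jitter_sd_s: float = 0.04
    min_rt_s: float = 0.03

    def __post_init__(self):
        if self.base_s <= 0 or self.min_rt_s <= 0:
            raise ValueError("latencies must be positive")


@dataclass
class BehaviorSimConfig:
    true_params: AdditiveParams = field(default_factory=AdditiveParams)
    contrast_set: tuple = CONTRASTS
    azimuth_set: tuple = AZIMUTHS
    type_ratio: tuple = DEFAULT_TYPE_RATIO
    n_trials: int = 2000
    rt_model: RTModel = field(default_factory=RTModel)
    seed: int = 0

    def __post_init__(self):
        r = np.asarray(self.type_ratio, float)
        if r.sum() <= 0 or (r < 0).any():
            raise ValueError("type_ratio must be nonnegative with positive sum")
        if not any(c > 0 for c in self.contrast_set):
            raise ValueError("contrast_set must contain a nonzero contrast")


def gen_trial_schedule(cfg: BehaviorSimConfig) -> pd.DataFrame:
    """Random trial schedule (no choices yet).

    Trial types are multinomial with probabilities proportional to
    ``type_ratio``; contrast is uniform over the nonzero contrast set;
    stimulus side is random on each trial.
    """
    if cfg.n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    probs = np.asarray(cfg.type_ratio, float)
    probs = probs / probs.sum()
    types = rng.choice(len(TRIAL_TYPES), size=cfg.n_trials, p=probs)
    contrasts = np.asarray([c for c in cfg.contrast_set if c > 0])
    lateral_az = np.asarray([a for a in cfg.azimuth_set if a != 0])

    VL = np.zeros(cfg.n_trials)
    VR = np.zeros(cfg.n_trials)
    az = np.zeros(cfg.n_trials)
    for i, ti in enumerate(types):
        tt = TRIAL_TYPES[ti]
        side = 1 if rng.random() < 0.5 else -1
        if tt in ("unisensory_visual", "coherent", "conflict"):
            c = rng.choice(contrasts)
            if side > 0:
                VR[i] = c
            else:
                VL[i] = c
        if tt == "unisensory_auditory":
            a = rng.choice(np.abs(lateral_az))
            az[i] = side * a
        elif tt == "coherent":
            az[i] = side * rng.choice(np.abs(lateral_az))
        elif tt == "conflict":
            az[i] = -side * rng.choice(np.abs(lateral_az))
    table = pd.DataFrame({
        "trial_id": np.arange(cfg.n_trials),
        "session_id": 0,
        "subject_id": 0,
        "vis_contrast_L": VL,
        "vis_contrast_R": VR,
        "aud_azimuth_deg": az,
        "trial_type": [TRIAL_TYPES[t] for t in types],
    })
    return validate_trials(table)


def simulate_choices(trials: pd.DataFrame, params: AdditiveParams,
                     seed: int = 0, rt_model: RTModel | None = None) -> pd.DataFrame:
    """Draw choices from the additive law: choice ~ Bernoulli(sigma(f+g+b)).

    If ``rt_model`` is given, target reaction times are also drawn.
    """
    rng = np.random.default_rng(seed)
    trials = validate_trials(trials).copy()
    pr = params.p_right(trials)
    right = rng.random(len(trials)) < pr
    trials["choice"] = np.where(right, "R", "L")
    trials["timeout"] = False
    if rt_model is not None:
        aud = (trials["aud_azimuth_deg"] != 0).to_numpy()
        contrast = (trials["vis_contrast_L"] + trials["vis_contrast_R"]).to_numpy()
        rt = (rt_model.base_s
              - rt_model.aud_advantage_s * aud
              - rt_model.contrast_slope_s * contrast
              + rng.normal(0, rt_model.jitter_sd_s, len(trials)))
        trials["rt_s"] = np.maximum(rt, rt_model.min_rt_s)
    return trials


def gen_wheel_traces(trials: pd.DataFrame, sampling_rate: float = 200.0,
                     threshold_deg: float = 30.0, seed: int = 0,
                     wiggle_prob: float = 0.0, t_pre: float = 0.1,
                     t_post: float = 1.6) -> dict:
    """Wheel traces consistent with each trial's choice and target RT.

    Non-timeout traces are still for at least 50 ms before the target RT,
    then move at constant velocity past the threshold in the choice
    direction. Timeout traces never cross the threshold within 1.5 s. With
    ``wiggle_prob``, a sub-threshold counter-rotation is injected well
    before the RT (it must not disturb RT detection).
    """
    if 1.0 / sampling_rate > 0.010:
        raise ValueError("sampling interval must be <= 10 ms for RT detection")
    rng = np.random.default_rng(seed)
    dt = 1.0 / sampling_rate
    t = np.arange(-t_pre, t_post + dt / 2, dt)
    traces = {}
    for row in trials.itertuples():
        pos = np.zeros_like(t)
        if row.choice != "timeout":
            rt = float(row.rt_s)
            if not rt > 0:
                raise ValueError("target RT must be positive")
            s = 1.0 if row.choice == "R" else -1.0
            vel = 1.5 * threshold_deg / 0.15  # crosses threshold in ~100 ms
            moving = t >= rt
            pos[moving] = s * np.minimum((t[moving] - rt) * vel,
                                         2.0 * threshold_deg)
            if wiggle_prob > 0 and rng.random() < wiggle_prob and rt > 0.12:
                # opposite-direction sub-threshold bump ending >=60 ms before RT
                w0 = rng.uniform(0.01, rt - 0.11)
                w1 = w0 + 0.04
                bump = (t >= w0) & (t < w1)
                pos[bump] += -s * 0.2 * threshold_deg * np.sin(
                    np.pi * (t[bump] - w0) / (w1 - w0))
        traces[row.trial_id] = _behavior.WheelTrace(t, pos)
    return traces


# -- spiking configuration --------------------------------------------------

@dataclass
class NeuronSimConfig:
    """Population of kernel-structured Poisson neurons.

    Per neuron, the firing rate on trial i is

        rate(t) = max(0, B + a_i A(t) + v_i s_i V(t) + a_i v_i N(t)
                         + M(t - tau_i) + c_i D(t - tau_i))

    with a_i, v_i, c_i in {-1, 0, +1} the auditory / visual / choice side
    codes (0 when the stimulus is absent or central) and s_i a contrast
    scaling (contrast/0.8)**0.6. Kernels are smooth bumps with per-class
    amplitudes; the 'naive' regime zeroes visual kernels and attenuates
    auditory ones, emulating recordings made before task training.
    """

    n_neurons: int = 40
    baseline_hz: tuple = (2.0, 10.0)        # uniform range
    amp_hz: dict = field(default_factory=lambda: dict(
        A=8.0, V=8.0, N=0.0, M=6.0, D=4.0))
    fraction_selective: dict = field(default_factory=lambda: dict(
        A=0.5, V=0.5, N=0.0, M=0.8, D=0.5))
    regime: str = "trained"                 # 'trained' | 'naive'
    naive_atten: float = 0.0                # auditory spatial gain when naive
    evoked_hz: float = 5.0                  # stimulus-evoked (non-spatial) bump
    aud_latency_s: float = 0.03
    vis_latency_s: float = 0.075            # auditory leads visual by 45 ms
    kernel_width_s: float = 0.12
    contrast_gamma: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.baseline_hz[0] < 0:
            raise ValueError("baseline rate must be non-negative")
        if self.regime not in ("trained", "naive"):
            raise ValueError("regime must be 'trained' or 'naive'")


def _bump(t, onset, width):
    """Smooth unit-amplitude bump starting at ``onset`` (half-sine)."""
    x = (t - onset) / width
    out = np.zeros_like(t)
    m = (x >= 0) & (x <= 1)
    out[m] = np.sin(np.pi * x[m])
    return out


@dataclass
class GroundTruthKernels:
    """Per-neuron kernels used to generate rates (for recovery tests)."""

    t_stim: np.ndarray
    t_move: np.ndarray
    B: np.ndarray      # (n_neurons, n_t_stim)
    A: np.ndarray
    V: np.ndarray
    N: np.ndarray
    M: np.ndarray      # (n_neurons, n_t_move)
    D: np.ndarray


def _make_kernels(cfg: NeuronSimConfig, rng) -> tuple[GroundTruthKernels, pd.DataFrame]:
    dt = 0.001
    t_stim = np.arange(-0.05, 0.400 + dt / 2, dt)
    t_move = np.arange(-0.200, 0.700 + dt / 2, dt)
    n = cfg.n_neurons
    atten = cfg.naive_atten if cfg.regime == "naive" else 1.0
    base = rng.uniform(*cfg.baseline_hz, n)
    hemi = np.where(rng.random(n) < 0.5, "left", "right")

    def amps(key, attenuation=1.0):
        sel = rng.random(n) < cfg.fraction_selective.get(key, 0.0)
        amp = rng.uniform(0.5, 1.0, n) * cfg.amp_hz.get(key, 0.0) * attenuation
        sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
        return np.where(sel, sign * amp, 0.0)

    aud_amp = amps("A", atten)
    vis_amp = amps("V", 0.0 if cfg.regime == "naive" else 1.0)
    nonadd_amp = amps("N", atten)
    move_amp = amps("M")
    dir_amp = amps("D")

    bump_a = _bump(t_stim, cfg.aud_latency_s, cfg.kernel_width_s)
    bump_v = _bump(t_stim, cfg.vis_latency_s, cfg.kernel_width_s)
    bump_m = _bump(t_move, -0.05, 0.3)
    evoked = rng.uniform(0.5, 1.0, n) * cfg.evoked_hz
    gt = GroundTruthKernels(
        t_stim=t_stim, t_move=t_move,
        B=base[:, None] + evoked[:, None] * bump_a[None, :],
        A=aud_amp[:, None] * bump_a[None, :],
        V=vis_amp[:, None] * bump_v[None, :],
        N=nonadd_amp[:, None] * bump_v[None, :],
        M=np.abs(move_amp)[:, None] * bump_m[None, :],
        D=dir_amp[:, None] * bump_m[None, :],
    )
    neurons = pd.DataFrame({
        "neuron_id": np.arange(n),
        "region": "MOs",
        "hemisphere": hemi,
        "ap_mm": rng.uniform(1.5, 3.0, n),
        "ml_mm": np.where(hemi == "right", 1.0, -1.0) * rng.uniform(0.3, 1.5, n),
        "depth_mm": rng.uniform(0.2, 1.2, n),
        "baseline_hz": base,
        "aud_amp_hz": aud_amp,
        "vis_amp_hz": vis_amp,
    })
    return gt, neurons


def _trial_codes(trials: pd.DataFrame):
    a = np.sign(trials["aud_azimuth_deg"].to_numpy(dtype=float))
    vsigned = (trials["vis_contrast_R"] - trials["vis_contrast_L"]).to_numpy()
    v = np.sign(vsigned)
    contrast = np.abs(vsigned)
    if "choice" in trials.columns:
        from .design import choice_to_sign
        c = np.nan_to_num(choice_to_sign(trials["choice"]))
    else:
        c = np.zeros(len(trials))
    return a, v, contrast, c


@dataclass
class PopulationData:
    """Spikes + metadata + generative ground truth for a simulated session."""

    spikes: pd.DataFrame          # neuron_id, trial_id, spike_time_s
    neurons: pd.DataFrame
    ground_truth: GroundTruthKernels
    trials: pd.DataFrame
    t_window: tuple = (-0.1, 0.8)


def trial_rate(gt: GroundTruthKernels, neuron: int, a: float, v: float,
               contrast: float, c: float, tau: float,
               t: np.ndarray, contrast_gamma: float = 0.6) -> np.ndarray:
    """Rectified kernel-sum rate for one neuron on one trial (oracle form)."""
    scale = (contrast / 0.8) ** contrast_gamma if contrast > 0 else 0.0
    r = np.interp(t, gt.t_stim, gt.B[neuron], left=gt.B[neuron, 0],
                  right=gt.B[neuron, 0])
    stim = (a * gt.A[neuron] + v * scale * gt.V[neuron]
            + a * v * gt.N[neuron])
    r = r + np.interp(t, gt.t_stim, stim, left=0, right=0)
    if np.isfinite(tau):
        mv = gt.M[neuron] + c * gt.D[neuron]
        r = r + np.interp(t - tau, gt.t_move, mv, left=0, right=0)
    return np.maximum(r, 0.0)


def gen_population_spikes(trials: pd.DataFrame, cfg: NeuronSimConfig,
                          t_window=(-0.1, 0.8), with_movement: bool = True
                          ) -> PopulationData:
    """Inhomogeneous-Poisson spike trains from the kernel forward model.

    Spikes are generated by thinning on a 1 ms lattice. Movement kernels are
    aligned to each trial's movement onset tau_i (the trial's rt_s); pass
    ``with_movement=False`` for passive-style data.
    """
    rng = np.random.default_rng(cfg.seed)
    gt, neurons = _make_kernels(cfg, rng)
    a, v, contrast, c = _trial_codes(trials)
    if with_movement and "rt_s" in trials.columns:
        taus = trials["rt_s"].to_numpy(dtype=float)
    else:
        taus = np.full(len(trials), np.nan)
    dt = 0.001
    t = np.arange(t_window[0], t_window[1], dt) + dt / 2
    rows_n, rows_t, rows_s = [], [], []
    tids = trials["trial_id"].to_numpy()
    for n in range(cfg.n_neurons):
        for i in range(len(trials)):
            rate = trial_rate(gt, n, a[i], v[i], contrast[i], c[i], taus[i],
                              t, cfg.contrast_gamma)
            counts = rng.poisson(rate * dt)
            if counts.sum():
                times = np.repeat(t, counts)
                rows_n.append(np.full(len(times), n))
                rows_t.append(np.full(len(times), tids[i]))
                rows_s.append(times)
    spikes = pd.DataFrame({
        "neuron_id": np.concatenate(rows_n) if rows_n else np.array([], int),
        "trial_id": np.concatenate(rows_t) if rows_t else np.array([], int),
        "spike_time_s": np.concatenate(rows_s) if rows_s else np.array([]),
    })
    return PopulationData(spikes=spikes, neurons=neurons, ground_truth=gt,
                          trials=trials.copy(), t_window=t_window)


# -- inactivation datasets --------------------------------------------------

@dataclass
class InactivationSimConfig:
    site_grid: list = field(default_factory=default_site_grid)
    laser_fraction: float = 0.75
    region_effects: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.laser_fraction <= 1:
            raise ValueError("laser_fraction must lie in [0, 1]")
        regions = {s.region for s in self.site_grid}
        unknown = set(self.region_effects) - regions
        if unknown:
            raise ValueError(f"region_effects for unknown regions: {unknown}")


def _shift_params(base: AdditiveParams, deltas: dict,
                  hemisphere: str) -> AdditiveParams:
    """Apply ipsi/contra deltas to left/right additive parameters.

    Deltas are expressed in the ipsi/contra frame of the inactivated
    hemisphere: 'b' positive pushes choices ipsilateral; 'vi'/'vc' and
    'ai'/'ac' shift the ipsi-/contralateral sensitivities.
    """
    d = {k: deltas.get(k, 0.0) for k in ("b", "vi", "vc", "ai", "ac")}
    p = base.as_dict()
    if hemisphere == "right":
        return AdditiveParams(b=p["b"] + d["b"], gamma=p["gamma"],
                              vR=p["vR"] + d["vi"], vL=p["vL"] + d["vc"],
                              aR=p["aR"] + d["ai"], aL=p["aL"] + d["ac"])
    return AdditiveParams(b=p["b"] - d["b"], gamma=p["gamma"],
                          vR=p["vR"] + d["vc"], vL=p["vL"] + d["vi"],
                          aR=p["aR"] + d["ac"], aL=p["aL"] + d["ai"])


def gen_inactivation_dataset(base: AdditiveParams, cfg: InactivationSimConfig,
                             n_trials: int = 20000, seed: int = 0,
                             behavior_cfg: BehaviorSimConfig | None = None,
                             laser_onset_range: tuple | None = None
                             ) -> pd.DataFrame:
    """Trial table with laser columns; choices drawn under shifted parameters.

    Laser trials (probability ``laser_fraction``) are assigned a uniform
    random site; if the site's region has an entry in ``region_effects``,
    choices are simulated under the ipsi/contra-shifted parameters,
    otherwise under ``base``. ``laser_onset_range`` (s) optionally draws a
    pulsed-laser onset per laser trial.
    """
    rng = np.random.default_rng(seed)
    bcfg = behavior_cfg or BehaviorSimConfig(n_trials=n_trials,
                                             seed=int(rng.integers(2**31)))
    bcfg.n_trials = n_trials
    trials = gen_trial_schedule(bcfg)
    laser = rng.random(n_trials) < cfg.laser_fraction
    site_idx = rng.integers(0, len(cfg.site_grid), n_trials)
    sites = [cfg.site_grid[i] for i in site_idx]
    trials["laser_on"] = laser
    trials["laser_ap_mm"] = np.where(laser, [s.ap_mm for s in sites], np.nan)
    trials["laser_ml_mm"] = np.where(laser, [s.ml_mm for s in sites], np.nan)
    trials["laser_region"] = np.where(
        laser, [s.region for s in sites], "none")
    trials["laser_hemisphere"] = np.where(
        laser, [s.hemisphere for s in sites], "none")
    if laser_onset_range is not None:
        trials["laser_onset_s"] = np.where(
            laser, rng.uniform(*laser_onset_range, n_trials), np.nan)

    pr = base.p_right(trials)
    for region, deltas in cfg.region_effects.items():
        for hemi in ("left", "right"):
            m = (laser & (trials["laser_region"] == region)
                 & (trials["laser_hemisphere"] == hemi)).to_numpy()
            if m.any():
                shifted = _shift_params(base, deltas, hemi)
                pr[m] = shifted.p_right(trials.loc[m])
    trials["choice"] = np.where(rng.random(n_trials) < pr, "R", "L")
    trials["timeout"] = False
    return trials


# -- PSTH banks --------------------------------------------------------------

ACCUMULATOR_CONTRASTS = (0.1, 0.2, 0.4, 0.8)


def default_bank_conditions(contrasts=ACCUMULATOR_CONTRASTS) -> list[dict]:
    """The accumulator's stimulus conditions: unisensory visual at each
    contrast L and R, unisensory auditory L and R, and coherent/conflict at
    the highest contrast."""
    conds = []
    cmax = max(contrasts)
    for c in contrasts:
        conds.append(dict(name=f"vis_L_{c:g}", vis_contrast_L=c,
                          vis_contrast_R=0.0, aud_azimuth_deg=0.0))
        conds.append(dict(name=f"vis_R_{c:g}", vis_contrast_L=0.0,
                          vis_contrast_R=c, aud_azimuth_deg=0.0))
    conds.append(dict(name="aud_L", vis_contrast_L=0.0, vis_contrast_R=0.0,
                      aud_azimuth_deg=-60.0))
    conds.append(dict(name="aud_R", vis_contrast_L=0.0, vis_contrast_R=0.0,
                      aud_azimuth_deg=60.0))
    conds.append(dict(name=f"coh_L_{cmax:g}", vis_contrast_L=cmax,
                      vis_contrast_R=0.0, aud_azimuth_deg=-60.0))
    conds.append(dict(name=f"coh_R_{cmax:g}", vis_contrast_L=0.0,
                      vis_contrast_R=cmax, aud_azimuth_deg=60.0))
    conds.append(dict(name=f"con_VL{cmax:g}_AR", vis_contrast_L=cmax,
                      vis_contrast_R=0.0, aud_azimuth_deg=60.0))
    conds.append(dict(name=f"con_VR{cmax:g}_AL", vis_contrast_L=0.0,
                      vis_contrast_R=cmax, aud_azimuth_deg=-60.0))
    return conds


@dataclass
class PSTHBank:
    """Condition-wise mean rate traces on a shared lattice.

    ``rates`` has shape (n_conditions, n_neurons, n_timebins) in Hz.
    """

    t: np.ndarray
    conditions: list          # list of dicts with name + stimulus fields
    rates: np.ndarray
    neurons: pd.DataFrame

    def condition_names(self):
        return [c["name"] for c in self.conditions]

    def to_json_dict(self) -> dict:
        return {c["name"]: {"t_s": self.t.tolist(),
                            "rate_hz": self.rates[i].tolist(),
                            **{k: v for k, v in c.items() if k != "name"}}
                for i, c in enumerate(self.conditions)}

    @classmethod
    def from_json_dict(cls, data: dict,
                       neurons: pd.DataFrame | None = None) -> "PSTHBank":
        names = list(data)
        t = np.asarray(data[names[0]]["t_s"])
        conditions, rates = [], []
        for name in names:
            entry = data[name]
            conditions.append({"name": name,
                               **{k: v for k, v in entry.items()
                                  if k not in ("t_s", "rate_hz")}})
            rates.append(np.asarray(entry["rate_hz"]))
        rates = np.stack(rates)
        if neurons is None:
            neurons = pd.DataFrame({"neuron_id": np.arange(rates.shape[1])})
        return cls(t=t, conditions=conditions, rates=rates, neurons=neurons)


def gen_psth_bank(cfg: NeuronSimConfig, conditions: list[dict] | None = None,
                  t_window=(-0.100, 0.300), bin_s: float = 0.010) -> PSTHBank:
    """Noise-free expected-rate PSTH bank on the window around stimulus onset.

    Auditory response onsets precede visual onsets by the configured
    latency offset; in the naive regime the left/right PSTHs are equal in
    expectation (visual kernels zero, no location information is injected
    beyond the attenuated auditory kernels — pass fraction_selective A=0 to
    remove it entirely).
    """
    if t_window[0] > -0.1 or t_window[1] < 0.3:
        raise ValueError("PSTH window must cover [-0.1, 0.3] s")
    conditions = conditions or default_bank_conditions()
    rng = np.random.default_rng(cfg.seed)
    gt, neurons = _make_kernels(cfg, rng)
    t = np.arange(t_window[0], t_window[1], bin_s) + bin_s / 2
    rates = np.zeros((len(conditions), cfg.n_neurons, len(t)))
    for ci, cond in enumerate(conditions):
        a = float(np.sign(cond["aud_azimuth_deg"]))
        vsigned = cond["vis_contrast_R"] - cond["vis_contrast_L"]
        v = float(np.sign(vsigned))
        contrast = abs(vsigned)
        for n in range(cfg.n_neurons):
            rates[ci, n] = trial_rate(gt, n, a, v, contrast, 0.0, np.nan, t,
                                      cfg.contrast_gamma)
    return PSTHBank(t=t, conditions=conditions, rates=rates, neurons=neurons)
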