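"""Shuffle-test inference for optogenetic inactivation experiments.

Two statistics are supported: the change in fraction of rightward choices at
an inactivated site (per stimulus type, stimuli mirrored to be effectively
leftward), and the change in additive-model parameters for an inactivated
region (ipsi/contra reparameterization, contrast exponent frozen at its
control-fit value). Both compare an observed subsample-averaged statistic
against a null built by reassigning laser/site labels within subject, and
report a two-sided rank-based p value (r+1)/(n+1)-style, which is never 0.

Also included: a sliding-window Fisher-exact analysis for pulsed
inactivation timing, and a from-scratch Fisher exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .design import choice_to_sign, validate_trials
from .psychometrics import PsychometricModel, to_ipsi_contra


# -- Fisher exact -----------------------------------------------------------

def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed table.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c
    rv = hypergeom(n, row1, col1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(np.clip(probs[probs <= p_obs * (1 + 1e-9)].sum(), 0.0, 1.0))


# -- helpers ----------------------------------------------------------------

def mirror_stimuli_leftward(trials: pd.DataFrame) -> pd.DataFrame:
    """Mirror trials so stimuli are effectively leftward.

    For trials whose stimulus (the visual stimulus on conflict trials) is on
    the right, swap left/right contrasts, negate azimuth and laser ML, and
    flip the choice.
    """
    t = trials.copy()
    vsigned = (t["vis_contrast_R"] - t["vis_contrast_L"]).to_numpy()
    az = t["aud_azimuth_deg"].to_numpy(dtype=float)
    stim_side = np.where(vsigned != 0, np.sign(vsigned), np.sign(az))
    flip = stim_side > 0
    vl, vr = t["vis_contrast_L"].to_numpy().copy(), t["vis_contrast_R"].to_numpy().copy()
    t.loc[flip, "vis_contrast_L"] = vr[flip]
    t.loc[flip, "vis_contrast_R"] = vl[flip]
    t.loc[flip, "aud_azimuth_deg"] = -az[flip]
    if "laser_ml_mm" in t.columns:
        t.loc[flip, "laser_ml_mm"] = -t.loc[flip, "laser_ml_mm"]
    if "laser_hemisphere" in t.columns:
        h = t.loc[flip, "laser_hemisphere"]
        t.loc[flip, "laser_hemisphere"] = h.map(
            {"left": "right", "right": "left"}).fillna(h)
    sgn = choice_to_sign(t["choice"])
    t.loc[flip, "choice"] = np.where(sgn[flip] > 0, "L", "R")
    return t


def _rank_p_two_sided(observed: float, null: np.ndarray) -> float:
    n = len(null)
    lo = (np.sum(null <= observed) + 1) / (n + 1)
    hi = (np.sum(null >= observed) + 1) / (n + 1)
    return float(min(1.0, 2 * min(lo, hi)))


@dataclass
class ShuffleResult:
    observed: float
    null: np.ndarray
    p: float
    n_per_cell: dict = field(default_factory=dict)

    @property
    def significant(self):
        return self.p < 0.05


# -- choice-shift shuffle test ----------------------------------------------

def _frac_right(choices) -> float:
    s = choice_to_sign(choices)
    return float(np.mean(s > 0))


def shuffle_test_choice_shift(trials: pd.DataFrame, site,
                              stimulus_type: str | None = None,
                              n_subsample: int = 25000,
                              n_shuffle_per: int = 10,
                              seed: int = 0,
                              mirror: bool = True) -> ShuffleResult:
    """Inactivation-induced change in fraction of rightward choices at a site.

    ``site`` is a (ap_mm, ml_mm) pair or a LaserSite. The observed statistic
    is the mean over subsamples (equalizing per-subject trial counts
    between the laser-at-site and non-laser cells) of
    frac_right(laser-at-site) - frac_right(non-laser). The null reassigns
    laser/non-laser labels within subject, ``n_shuffle_per`` shuffles per
    subsample iteration.
    """
    if n_shuffle_per <= 0 or n_subsample <= 0:
        raise ValueError("subsample and shuffle counts must be positive")
    ap, ml = (site.ap_mm, site.ml_mm) if hasattr(site, "ap_mm") else site
    t = validate_trials(trials, require_choice=True)
    if mirror:
        t = mirror_stimuli_leftward(t)
    if stimulus_type is not None:
        t = t[t["trial_type"] == stimulus_type]
    laser_on = t["laser_on"].to_numpy().astype(bool)
    at_site = laser_on & np.isclose(t["laser_ap_mm"], ap) \
        & np.isclose(t["laser_ml_mm"], ml)
    control = ~laser_on
    if at_site.sum() == 0:
        raise ValueError(f"no laser trials at site ({ap}, {ml})")
    t = t[at_site | control]
    is_site = at_site[at_site | control]
    rng = np.random.default_rng(seed)

    subj = t["subject_id"].to_numpy()
    right = choice_to_sign(t["choice"]) > 0
    by_subj = {}
    for s in np.unique(subj):
        on_idx = np.flatnonzero((subj == s) & is_site)
        off_idx = np.flatnonzero((subj == s) & ~is_site)
        n = min(len(on_idx), len(off_idx))
        if n > 0:
            by_subj[s] = (on_idx, off_idx, n)

    deltas = np.empty(n_subsample)
    null = np.empty(n_subsample * n_shuffle_per)
    k = 0
    for it in range(n_subsample):
        on_sel, off_sel = [], []
        for on_idx, off_idx, n in by_subj.values():
            on_sel.append(rng.choice(on_idx, n, replace=False))
            off_sel.append(rng.choice(off_idx, n, replace=False))
        on_sel = np.concatenate(on_sel)
        off_sel = np.concatenate(off_sel)
        deltas[it] = right[on_sel].mean() - right[off_sel].mean()
        pooled = np.concatenate([on_sel, off_sel])
        half = len(on_sel)
        for _ in range(n_shuffle_per):
            perm = rng.permutation(pooled)
            null[k] = right[perm[:half]].mean() - right[perm[half:]].mean()
            k += 1
    observed = float(np.mean(deltas))
    return ShuffleResult(observed=observed, null=null,
                         p=_rank_p_two_sided(observed, null),
                         n_per_cell={s: n for s, (_, _, n) in by_subj.items()})


# -- parameter-change shuffle test -------------------------------------------

_IC_PARAMS = ("b", "vi", "vc", "ai", "ac")


def _fit_ipsi_contra(t: pd.DataFrame, gamma: float, seed: int = 0,
                     n_starts: int = 2) -> dict:
    m = PsychometricModel(family="ipsi_contra", fixed={"gamma": gamma},
                          n_starts=n_starts, seed=seed)
    m.fit(t, t["choice_ipsi"])
    return m.params_


def _symmetrize_control(t: pd.DataFrame) -> pd.DataFrame:
    """Map control trials into the ipsi/contra frame of both hemispheres."""
    both = [to_ipsi_contra(t, "left"), to_ipsi_contra(t, "right")]
    return pd.concat(both, ignore_index=True)


def shuffle_test_param_change(trials: pd.DataFrame, region: str,
                              n_subsample: int = 2500,
                              n_shuffle_total: int = 25000,
                              seed: int = 0, gamma: float | None = None,
                              n_starts: int = 2) -> dict:
    """Change in ipsi/contra additive parameters under regional inactivation.

    Fits log p(I)/p(C) = b + (vi Vi**g - vc Vc**g) + (ai Ai - ac Ac) to
    control and region-laser trials (g frozen at the control-trial value)
    and compares each parameter change to a label-shuffled null. Returns
    {parameter: ShuffleResult}.
    """
    t = validate_trials(trials, require_choice=True)
    laser = t["laser_on"].to_numpy().astype(bool)
    in_region = laser & (t.get("laser_region", pd.Series("none", index=t.index))
                         == region).to_numpy()
    if in_region.sum() == 0:
        raise ValueError(f"no laser trials in region {region!r}")
    ctrl = t[~laser]
    las = t[in_region]
    if gamma is None:
        from .psychometrics import fit_ml
        gamma = fit_ml(ctrl, "additive_parametric",
                       n_starts=max(2, n_starts)).params["gamma"]

    rng = np.random.default_rng(seed)
    subj_c = ctrl["subject_id"].to_numpy()
    subj_l = las["subject_id"].to_numpy()
    n_by_subj = {s: min((subj_c == s).sum(), (subj_l == s).sum())
                 for s in np.unique(subj_l)}

    def one_fit_pair(ctrl_idx, las_idx, sd):
        c = _symmetrize_control(ctrl.iloc[ctrl_idx])
        l = to_ipsi_contra(las.iloc[las_idx],
                           las.iloc[las_idx]["laser_hemisphere"].to_numpy())
        pc = _fit_ipsi_contra(c, gamma, sd, n_starts)
        pl = _fit_ipsi_contra(l, gamma, sd, n_starts)
        return {k: pl[k] - pc[k] for k in _IC_PARAMS}

    def subsample_indices():
        ci, li = [], []
        for s, n in n_by_subj.items():
            if n == 0:
                continue
            ci.append(rng.choice(np.flatnonzero(subj_c == s), n, replace=False))
            li.append(rng.choice(np.flatnonzero(subj_l == s), n, replace=False))
        return np.concatenate(ci), np.concatenate(li)

    obs = {k: [] for k in _IC_PARAMS}
    for it in range(n_subsample):
        ci, li = subsample_indices()
        d = one_fit_pair(ci, li, seed + it)
        for k in _IC_PARAMS:
            obs[k].append(d[k])

    # null: pool a control+laser subsample, shuffle the laser label
    null = {k: [] for k in _IC_PARAMS}
    hemis = las["laser_hemisphere"].to_numpy()
    for sh in range(n_shuffle_total):
        ci, li = subsample_indices()
        merged = pd.concat([ctrl.iloc[ci], las.iloc[li]], ignore_index=True)
        perm = rng.permutation(len(merged))
        fake_ctrl = merged.iloc[perm[:len(ci)]]
        fake_las = merged.iloc[perm[len(ci):]].copy()
        fake_las["laser_hemisphere"] = rng.choice(hemis, len(fake_las))
        c = _symmetrize_control(fake_ctrl)
        l = to_ipsi_contra(fake_las, fake_las["laser_hemisphere"].to_numpy())
        pc = _fit_ipsi_contra(c, gamma, seed + 7919 + sh, n_starts)
        pl = _fit_ipsi_contra(l, gamma, seed + 7919 + sh, n_starts)
        for k in _IC_PARAMS:
            null[k].append(pl[k] - pc[k])

    out = {}
    for k in _IC_PARAMS:
        o = float(np.mean(obs[k]))
        nl = np.asarray(null[k])
        out[k] = ShuffleResult(observed=o, null=nl,
                               p=_rank_p_two_sided(o, nl))
    return out


def region_model_divergence(trials: pd.DataFrame, regionA: str, regionB: str,
                            n_subsample: int = 100, n_shuffle: int = 1000,
                            seed: int = 0, gamma: float | None = None,
                            n_starts: int = 2) -> ShuffleResult:
    """Do two inactivated regions shift behavior differently?

    Statistic: mean over subsamples of (within-region - inter-region)
    held-out log likelihood of the ipsi/contra additive model. The null
    shuffles the region label before the within/inter split. A zero
    statistic is expected when the two regions have identical effects.
    """
    t = validate_trials(trials, require_choice=True)
    laser = t["laser_on"].to_numpy().astype(bool)
    region_col = t["laser_region"].to_numpy()
    selA = laser & (region_col == regionA)
    selB = laser & (region_col == regionB)
    if gamma is None:
        from .psychometrics import fit_ml
        gamma = fit_ml(t[~laser], "additive_parametric",
                       n_starts=max(2, n_starts)).params["gamma"]
    rng = np.random.default_rng(seed)
    A = t[selA].reset_index(drop=True)
    B = t[selB].reset_index(drop=True)

    def ll(params, data):
        m = PsychometricModel(family="ipsi_contra")
        m.params_ = params
        return m.score(data, data["choice_ipsi"]) * len(data)

    def stat(A, B):
        # split each region's data in half: train/test
        vals = []
        for X, Y in ((A, B), (B, A)):
            px = rng.permutation(len(X))
            py = rng.permutation(len(Y))
            Xtr = to_ipsi_contra(X.iloc[px[:len(X) // 2]],
                                 X.iloc[px[:len(X) // 2]]["laser_hemisphere"].to_numpy())
            Xte = to_ipsi_contra(X.iloc[px[len(X) // 2:]],
                                 X.iloc[px[len(X) // 2:]]["laser_hemisphere"].to_numpy())
            Ytr = to_ipsi_contra(Y.iloc[py[:len(Y) // 2]],
                                 Y.iloc[py[:len(Y) // 2]]["laser_hemisphere"].to_numpy())
            n = min(len(Xte), len(Ytr))
            pwithin = _fit_ipsi_contra(Xtr, gamma, seed, n_starts)
            pinter = _fit_ipsi_contra(Ytr.iloc[:n], gamma, seed, n_starts)
            vals.append((ll(pwithin, Xte) - ll(pinter, Xte)) / max(1, len(Xte)))
        return float(np.mean(vals))

    obs = float(np.mean([stat(A, B) for _ in range(n_subsample)]))
    null = np.empty(n_shuffle)
    merged = pd.concat([A, B], ignore_index=True)
    for s in range(n_shuffle):
        perm = rng.permutation(len(merged))
        fA = merged.iloc[perm[:len(A)]]
        fB = merged.iloc[perm[len(A):]]
        null[s] = stat(fA.reset_index(drop=True), fB.reset_index(drop=True))
    # one-sided: within > inter indicates divergent effects
    p = float((np.sum(null >= obs) + 1) / (n_shuffle + 1))
    return ShuffleResult(observed=obs, null=null, p=p)


# -- pulsed-inactivation timing ----------------------------------------------

@dataclass
class PulseTimingResult:
    window_centers: np.ndarray
    delta_frac_right: np.ndarray
    fisher_p: np.ndarray
    significant: np.ndarray
    n_laser: np.ndarray


def pulse_timing_analysis(trials: pd.DataFrame, window_s: float = 0.070,
                          step_s: float = 0.010, alpha: float = 0.001,
                          min_laser_trials: int = 75,
                          mirror: bool = True) -> PulseTimingResult:
    """Sliding-window effect of pulsed inactivation on choice.

    Laser onsets are binned in a sliding boxcar of width ``window_s``; per
    window, the change in fraction of rightward choices vs non-laser trials
    is computed and tested with Fisher's exact test. A window is flagged
    significant if it, or both its neighbors, pass ``alpha``. Sessions with
    fewer than ``min_laser_trials`` laser trials are excluded.
    """
    t = validate_trials(trials, require_choice=True)
    counts = t[t["laser_on"]].groupby("session_id").size()
    ok_sessions = counts[counts >= min_laser_trials].index
    t = t[t["session_id"].isin(ok_sessions) | ~t["laser_on"]]
    t = t[t["session_id"].isin(ok_sessions)]
    if mirror:
        t = mirror_stimuli_leftward(t)
    laser = t["laser_on"].to_numpy().astype(bool)
    right = (choice_to_sign(t["choice"]) > 0)
    onset = t["laser_onset_s"].to_numpy(dtype=float)
    ctrl_R = int(right[~laser].sum())
    ctrl_L = int((~laser).sum() - ctrl_R)
    frac_ctrl = ctrl_R / max(1, ctrl_R + ctrl_L)

    lo = np.nanmin(onset[laser])
    hi = np.nanmax(onset[laser])
    centers = np.arange(lo + window_s / 2, hi - window_s / 2 + step_s / 2,
                        step_s)
    delta = np.full(len(centers), np.nan)
    pvals = np.full(len(centers), np.nan)
    nlas = np.zeros(len(centers), dtype=int)
    for i, cen in enumerate(centers):
        in_win = laser & (onset >= cen - window_s / 2) \
            & (onset < cen + window_s / 2)
        n = int(in_win.sum())
        nlas[i] = n
        if n == 0:
            continue
        las_R = int(right[in_win].sum())
        las_L = n - las_R
        delta[i] = las_R / n - frac_ctrl
        pvals[i] = fisher_exact_2x2(las_R, las_L, ctrl_R, ctrl_L)
    passed = np.where(np.isnan(pvals), False, pvals < alpha)
    sig = np.zeros(len(centers), dtype=bool)
    for i in range(len(centers)):
        left = passed[i - 1] if i > 0 else False
        right_n = passed[i + 1] if i < len(centers) - 1 else False
        sig[i] = passed[i] or (left and right_n)
    sig &= ~np.isnan(pvals)
    return PulseTimingResult(window_centers=centers, delta_frac_right=delta,
                             fisher_p=pvals, significant=sig, n_laser=nlas)
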