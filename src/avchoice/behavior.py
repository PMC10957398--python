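"""Choice and reaction-time extraction from wheel traces, trial filtering,
and behavioral summaries.

A choice is registered at the first time the wheel moves ~30 degrees from its
pre-stimulus position (rightward positive); trials with no crossing within
the 1.5 s response window are timeouts. The reaction time is the last
zero-crossing of wheel velocity before the choice threshold that follows at
least 50 ms of stillness (or counter-rotation) and is itself followed by at
least 50 ms of movement faster than 20% of the choice threshold per second.
Trials where no such timepoint exists, or where the wheel was already moving
within 10 ms of stimulus onset, are flagged rather than assigned an RT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import choice_to_sign, validate_trials

DEFAULT_THRESHOLD_DEG = 30.0
RESPONSE_WINDOW_S = 1.5


@dataclass
class WheelTrace:
    """Wheel position (degrees, rightward positive) vs time (s from onset)."""

    t: np.ndarray
    position: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if len(self.t) != len(self.position):
            raise ValueError("t and position lengths differ")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    def velocity(self) -> np.ndarray:
        """First-difference velocity (deg/s), assigned to the later sample."""
        v = np.zeros_like(self.position)
        v[1:] = np.diff(self.position) / np.diff(self.t)
        return v


def traces_from_df(df: pd.DataFrame) -> dict:
    """Long CSV format (trial_id, t_s, position_deg) -> {trial_id: WheelTrace}."""
    out = {}
    for tid, g in df.groupby("trial_id"):
        g = g.sort_values("t_s")
        out[tid] = WheelTrace(g["t_s"].to_numpy(), g["position_deg"].to_numpy())
    return out


def traces_to_df(traces: dict) -> pd.DataFrame:
    rows = [pd.DataFrame({"trial_id": tid, "t_s": tr.t,
                          "position_deg": tr.position})
            for tid, tr in traces.items()]
    return pd.concat(rows, ignore_index=True)


def detect_choice(trace: WheelTrace, threshold_deg: float = DEFAULT_THRESHOLD_DEG,
                  response_window_s: float = RESPONSE_WINDOW_S):
    """First threshold crossing of |position - position(0)| within the window.

    Returns ``(choice, crossing_time)`` with choice in {'L','R','timeout'}
    (crossing_time is None on timeout).
    """
    if trace.t[-1] < response_window_s:
        raise ValueError("trace shorter than the response window")
    pre = trace.t <= 0
    if not pre.any():
        raise ValueError("trace has no pre-stimulus samples")
    p0 = trace.position[pre][-1]
    in_win = (trace.t >= 0) & (trace.t <= response_window_s)
    disp = trace.position[in_win] - p0
    tt = trace.t[in_win]
    hit = np.abs(disp) >= threshold_deg
    if not hit.any():
        return "timeout", None
    i = int(np.argmax(hit))
    return ("R" if disp[i] > 0 else "L"), float(tt[i])


def detect_reaction_time(trace: WheelTrace, choice: str, crossing_time: float,
                         threshold_deg: float = DEFAULT_THRESHOLD_DEG,
                         still_s: float = 0.050, rate_frac: float = 0.20,
                         min_fast_s: float = 0.050, onset_guard_s: float = 0.010,
                         v_eps: float = 1e-6):
    """Reaction time: the qualifying velocity zero-crossing described above.

    Returns the RT in seconds, or None when the trial must be excluded
    (no qualifying crossing, or movement within ``onset_guard_s`` of onset).
    ``v_eps`` is the tolerance (deg/s) within which velocity counts as zero.
    """
    if choice == "timeout":
        raise ValueError("reaction time undefined for timeout trials")
    s = 1.0 if choice == "R" else -1.0
    v = trace.velocity()
    sv = s * v
    # movement already underway at stimulus onset -> excluded
    guard = (trace.t > 0) & (trace.t <= onset_guard_s)
    if np.any(np.abs(v[guard]) > v_eps):
        return None
    dt = trace.dt
    n_still = max(1, int(round(still_s / dt)))
    n_fast = max(1, int(round(min_fast_s / dt)))
    rate = rate_frac * threshold_deg  # deg/s
    still = sv <= v_eps          # at zero or opposite to choice direction
    candidates = []
    idx = np.flatnonzero((trace.t > 0) & (trace.t <= crossing_time))
    for i in idx:
        if still[i] or i < n_still:
            continue
        if not np.all(still[i - n_still:i]):
            continue
        j = min(i + n_fast, len(sv))
        # sustained movement: all samples toward the choice and the mean
        # speed over the window at/above the rate criterion (the sample
        # containing the zero-crossing is allowed to be partial)
        if np.all(sv[i:j] > v_eps) and np.mean(sv[i:j]) >= rate:
            candidates.append(i)
    if not candidates:
        return None
    return float(trace.t[candidates[-1]])


def extract_trials(trials: pd.DataFrame, traces: dict,
                   threshold_deg: float = DEFAULT_THRESHOLD_DEG,
                   response_window_s: float = RESPONSE_WINDOW_S) -> pd.DataFrame:
    """Fill choice / rt_s / timeout columns of a trial table from wheel traces."""
    trials = validate_trials(trials).copy()
    choices, rts, timeouts = [], [], []
    for tid in trials["trial_id"]:
        tr = traces[tid]
        choice, tcross = detect_choice(tr, threshold_deg, response_window_s)
        if choice == "timeout":
            choices.append("timeout")
            rts.append(np.nan)
            timeouts.append(True)
        else:
            rt = detect_reaction_time(tr, choice, tcross, threshold_deg)
            choices.append(choice)
            rts.append(np.nan if rt is None else rt)
            timeouts.append(False)
    trials["choice"] = choices
    trials["rt_s"] = rts
    trials["timeout"] = timeouts
    return trials


def filter_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Flag (never delete) trials excluded from behavioral analyses.

    Reasons: 'timeout'; 'repeat' (repeats following incorrect choices);
    'session_edge' (before/after the first/last three consecutive choices
    without a timeout); 'rt_undetectable' (non-timeout choice with no
    qualifying RT). Idempotent.
    """
    trials = validate_trials(trials, require_choice=True).copy()
    if "session_id" not in trials.columns:
        raise ValueError("trial table needs session_id ordering")
    reason = np.full(len(trials), "", dtype=object)
    is_timeout = (trials["choice"] == "timeout").to_numpy()

    for _, idx in trials.groupby("session_id", sort=False).indices.items():
        ok = ~is_timeout[idx]
        run = 0
        first_ok = None
        for k, good in enumerate(ok):
            run = run + 1 if good else 0
            if run == 3:
                first_ok = k - 2
                break
        run = 0
        last_ok = None
        for k in range(len(ok) - 1, -1, -1):
            run = run + 1 if ok[k] else 0
            if run == 3:
                last_ok = k + 2
                break
        if first_ok is None:
            reason[idx] = "session_edge"
            continue
        reason[idx[:first_ok]] = "session_edge"
        reason[idx[last_ok + 1:]] = "session_edge"

    open_mask = reason == ""
    reason[open_mask & is_timeout] = "timeout"
    open_mask = reason == ""
    if "repeat_flag" in trials.columns:
        reason[open_mask & trials["repeat_flag"].to_numpy().astype(bool)] = "repeat"
    open_mask = reason == ""
    if "rt_s" in trials.columns:
        undet = ~is_timeout & ~np.isfinite(
            trials["rt_s"].to_numpy(dtype=float))
        reason[open_mask & undet] = "rt_undetectable"
    trials["excluded"] = reason != ""
    trials["exclusion_reason"] = reason
    return trials


def _correct_side(row):
    """Rewarded side, or None when reward is random (conflict/neutral)."""
    tt = row["trial_type"]
    if tt == "unisensory_visual":
        return "R" if row["vis_contrast_R"] > 0 else "L"
    if tt == "unisensory_auditory":
        return "R" if row["aud_azimuth_deg"] > 0 else "L"
    if tt == "coherent":
        return "R" if row["aud_azimuth_deg"] > 0 else "L"
    return None


def summarize_behavior(trials: pd.DataFrame) -> dict:
    """Per-type and per-condition behavioral summary.

    Aggregation order per subject: statistic within each session, mean
    across sessions, then mean across mirror-symmetric presentations.
    Relative reaction time subtracts, per subject, the mean across stimulus
    types. Returns {'by_type': DataFrame, 'by_condition': DataFrame}.
    """
    t = validate_trials(trials, require_choice=True)
    if "excluded" in t.columns:
        t = t[~t["excluded"]]
    t = t[t["choice"] != "timeout"].copy()
    t["correct_side"] = t.apply(_correct_side, axis=1)
    t["correct"] = np.where(t["correct_side"].isna(), np.nan,
                            (t["choice"] == t["correct_side"]).astype(float))
    t["right"] = (choice_to_sign(t["choice"]) > 0).astype(float)

    per_sess = (t.groupby(["subject_id", "session_id", "trial_type"])
                .agg(frac_correct=("correct", "mean"),
                     median_rt=("rt_s", "median"),
                     n=("right", "size")).reset_index())
    by_type = (per_sess.groupby(["subject_id", "trial_type"])
               .agg(frac_correct=("frac_correct", "mean"),
                    median_rt=("median_rt", "mean"),
                    n=("n", "sum")).reset_index())
    rel = by_type.groupby("subject_id")["median_rt"].transform("mean")
    by_type["rel_rt"] = by_type["median_rt"] - rel

    per_cond = (t.groupby(["subject_id", "session_id", "vis_contrast_L",
                           "vis_contrast_R", "aud_azimuth_deg"])
                .agg(frac_right=("right", "mean"), n=("right", "size"))
                .reset_index())
    by_cond = (per_cond.groupby(["subject_id", "vis_contrast_L",
                                 "vis_contrast_R", "aud_azimuth_deg"])
               .agg(frac_right=("frac_right", "mean"), n=("n", "sum"))
               .reset_index())
    return {"by_type": by_type, "by_condition": by_cond}


def decode_side_from_wheel(trials: pd.DataFrame, traces: dict,
                           time_grid: np.ndarray, seed: int = 0) -> pd.DataFrame:
    """Cross-validated accuracy of predicting stimulus side from wheel velocity.

    For each unisensory modality and each timepoint, trials are subsampled to
    balance sides, split 2-fold, and a linear classifier on the scalar
    velocity predicts the side. Accuracies are averaged session -> subject.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold

    rng = np.random.default_rng(seed)
    trials = validate_trials(trials, require_choice=True)
    rows = []
    for modality, tt in (("auditory", "unisensory_auditory"),
                         ("visual", "unisensory_visual")):
        sub = trials[trials["trial_type"] == tt]
        for (subj, sess), g in sub.groupby(["subject_id", "session_id"]):
            if tt == "unisensory_auditory":
                side = (g["aud_azimuth_deg"] > 0).to_numpy()
            else:
                side = (g["vis_contrast_R"] > 0).to_numpy()
            n_per = min(side.sum(), (~side).sum())
            if n_per < 2:
                continue
            idx_r = rng.choice(np.flatnonzero(side), n_per, replace=False)
            idx_l = rng.choice(np.flatnonzero(~side), n_per, replace=False)
            use = np.concatenate([idx_r, idx_l])
            tids = g["trial_id"].to_numpy()[use]
            y = side[use]
            vel = np.stack([
                np.interp(time_grid, traces[tid].t[1:],
                          traces[tid].velocity()[1:]) for tid in tids])
            accs = np.empty(len(time_grid))
            skf = StratifiedKFold(2, shuffle=True, random_state=seed)
            for j in range(len(time_grid)):
                Xj = vel[:, [j]]
                correct = 0
                for tr_i, te_i in skf.split(Xj, y):
                    clf = LogisticRegression()
                    clf.fit(Xj[tr_i], y[tr_i])
                    correct += (clf.predict(Xj[te_i]) == y[te_i]).sum()
                accs[j] = correct / len(y)
            for j, tg in enumerate(time_grid):
                rows.append(dict(subject_id=subj, session_id=sess,
                                 modality=modality, t_s=tg, accuracy=accs[j]))
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    per_subj = (df.groupby(["subject_id", "modality", "t_s"])["accuracy"]
                .mean().reset_index())
    return (per_subj.groupby(["modality", "t_s"])["accuracy"]
            .mean().reset_index())


def passive_wheel_shuffle_test(traces: dict, onsets: dict,
                               n_shuffle: int = 1000, window_s: float = 0.5,
                               seed: int = 0) -> dict:
    """Shuffle test for stimulus-locked wheel movement in passive sessions.

    Observed statistic: mean over trials of |position(onset + window) -
    position(onset)|. The null randomizes the onset time within each trial.
    """
    if n_shuffle <= 0:
        raise ValueError("n_shuffle must be positive")
    rng = np.random.default_rng(seed)

    def stat(onset_map):
        vals = []
        for tid, tr in traces.items():
            o = onset_map[tid]
            p0 = np.interp(o, tr.t, tr.position)
            p1 = np.interp(o + window_s, tr.t, tr.position)
            vals.append(abs(p1 - p0))
        return float(np.mean(vals))

    observed = stat(onsets)
    null = np.empty(n_shuffle)
    for s in range(n_shuffle):
        rand = {tid: rng.uniform(tr.t[0], tr.t[-1] - window_s)
                for tid, tr in traces.items()}
        null[s] = stat(rand)
    p = (1 + np.sum(null >= observed)) / (n_shuffle + 1)
    return {"observed": observed, "null": null, "p": float(p),
            "significant": p < 0.05}
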