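"""Population decoding, choice-axis projection, and single-neuron
selectivity statistics (d', combined-conditions choice/stimulus probability,
On-Off / Right-Left classification, discrimination time).

Conventions: relative decoding accuracy is (raw - baseline) / (1 - baseline)
with the baseline from the training-fold majority class; ccCP/ccSP is the
fraction of within-condition trial pairs with different outcomes for which
the rate on the 'right' outcome trial exceeds the 'left' one (ties 0.5),
with a within-condition label-shuffle null; d' is the difference of means
over the mean of the standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

#: Standard analysis windows (s): stimulus-, pre-movement-, post-movement-aligned.
WINDOWS = {"stim": (0.0, 0.300), "premove": (-0.130, 0.0),
           "postmove": (0.150, 0.300)}


def window_average(rates: np.ndarray, t: np.ndarray, window) -> np.ndarray:
    """Time-average rates (..., n_t) over a window; returns (...,)."""
    m = (t >= window[0]) & (t <= window[1])
    if not m.any():
        raise ValueError("window contains no time bins")
    return np.asarray(rates)[..., m].mean(axis=-1)


# -- population decoding ----------------------------------------------------

@dataclass
class DecodeResult:
    raw_accuracy: float
    baseline_accuracy: float
    relative_accuracy: float
    n_neurons: int
    n_trials: int
    window: tuple
    n_repeats: int
    k: int


def decode_population(X: np.ndarray, labels, window=WINDOWS["stim"],
                      n_sub: int = 30, n_repeats: int = 5, k: int = 5,
                      seed: int = 0, min_trials_per_class: int = 25,
                      min_neurons: int = 30) -> DecodeResult:
    """Cross-validated linear-SVM decoding with relative accuracy.

    ``X`` is the (n_trials, n_neurons) matrix of window-averaged rates.
    Each repeat draws an ``n_sub``-neuron subset; accuracy is the k-fold CV
    fraction correct, and the baseline is a majority-class predictor fit on
    each training fold. Raises when class or neuron floors are not met.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < min_trials_per_class:
        raise ValueError(
            f"need >= {min_trials_per_class} trials per class, got {counts}")
    if X.shape[1] < min_neurons:
        raise ValueError(f"need >= {min_neurons} neurons, got {X.shape[1]}")
    rng = np.random.default_rng(seed)
    raw_accs, base_accs = [], []
    for rep in range(n_repeats):
        sub = rng.choice(X.shape[1], size=min(n_sub, X.shape[1]),
                         replace=False)
        Xs = X[:, sub]
        skf = StratifiedKFold(k, shuffle=True, random_state=seed + rep)
        correct = base_correct = 0
        for tr, te in skf.split(Xs, y):
            clf = LinearSVC(dual="auto")
            clf.fit(Xs[tr], y[tr])
            correct += int((clf.predict(Xs[te]) == y[te]).sum())
            maj = classes[np.argmax([(y[tr] == c).sum() for c in classes])]
            base_correct += int((y[te] == maj).sum())
        raw_accs.append(correct / len(y))
        base_accs.append(base_correct / len(y))
    raw = float(np.mean(raw_accs))
    base = float(np.mean(base_accs))
    rel = (raw - base) / (1 - base) if base < 1 else 0.0
    return DecodeResult(raw_accuracy=raw, baseline_accuracy=base,
                        relative_accuracy=float(rel), n_neurons=int(n_sub),
                        n_trials=len(y), window=tuple(window),
                        n_repeats=n_repeats, k=k)


# -- choice-axis projection --------------------------------------------------

def choice_axis_projection(x_t: np.ndarray, choices, conditions,
                           choice_window_rates: np.ndarray,
                           seed: int = 0) -> np.ndarray:
    """Cosine similarity of the population vector with the choice axis.

    ``x_t`` is (n_trials, n_neurons, n_t); ``choice_window_rates`` is the
    (n_trials, n_neurons) matrix averaged 0-100 ms after movement onset,
    from which the rightward/leftward mean vectors are built. For each
    stimulus condition the choice axis is computed from all *other*
    conditions (cross-validation), after balancing left/right trial counts.
    Returns S_c with shape (n_trials, n_t).
    """
    from .design import choice_to_sign
    x_t = np.asarray(x_t, dtype=float)
    cw = np.asarray(choice_window_rates, dtype=float)
    sgn = choice_to_sign(choices)
    cond = np.asarray(conditions)
    rng = np.random.default_rng(seed)
    out = np.full(x_t.shape[::2], np.nan)

    for c in np.unique(cond):
        held = cond == c
        train = ~held
        r_idx = np.flatnonzero(train & (sgn > 0))
        l_idx = np.flatnonzero(train & (sgn < 0))
        n = min(len(r_idx), len(l_idx))
        if n == 0:
            continue
        r_idx = rng.choice(r_idx, n, replace=False)
        l_idx = rng.choice(l_idx, n, replace=False)
        axis = cw[r_idx].mean(axis=0) - cw[l_idx].mean(axis=0)
        an = np.linalg.norm(axis)
        if an == 0:
            continue
        for i in np.flatnonzero(held):
            xn = np.linalg.norm(x_t[i], axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                out[i] = (x_t[i].T @ axis) / (xn * an)
    return out


# -- d' ----------------------------------------------------------------------

def dprime(x1, x2) -> float:
    """Discriminability index: (mu1 - mu2) / (0.5 * (sd1 + sd2))."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    denom = 0.5 * (x1.std(ddof=0) + x2.std(ddof=0))
    if denom == 0:
        return 0.0
    return float((x1.mean() - x2.mean()) / denom)


# -- combined-conditions choice/stimulus probability --------------------------

@dataclass
class CPResult:
    statistic: float
    null: np.ndarray
    p: float
    significant: bool
    n_pairs: int


def _cc_statistic(values, cond, outcome) -> tuple[float, int]:
    """Pairwise win fraction over within-condition pairs (ties = 0.5)."""
    total_pairs = 0
    favorable = 0.0
    for c in np.unique(cond):
        m = cond == c
        v = values[m]
        o = outcome[m]
        pos = v[o]
        neg = v[~o]
        if len(pos) == 0 or len(neg) == 0:
            continue
        ranks = rankdata(np.concatenate([pos, neg]))
        u = ranks[:len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
        favorable += u
        total_pairs += len(pos) * len(neg)
    if total_pairs == 0:
        return np.nan, 0
    return favorable / total_pairs, total_pairs


def combined_conditions_probability(values, condition_labels, outcome_labels,
                                    n_shuffle: int = 1000, seed: int = 0,
                                    alpha: float = 0.01) -> CPResult:
    """ccCP / ccSP with a within-condition shuffle null.

    ``outcome_labels`` is boolean (True = rightward choice for ccCP, or the
    controlled stimulus side for ccSP); the null shuffles outcomes within
    each condition. Significance: observed outside the
    [100*alpha/2, 100*(1-alpha/2)] percentiles of the null.
    """
    values = np.asarray(values, dtype=float)
    cond = np.asarray(condition_labels)
    outcome = np.asarray(outcome_labels, dtype=bool)
    stat, n_pairs = _cc_statistic(values, cond, outcome)
    if n_pairs == 0:
        return CPResult(statistic=np.nan, null=np.array([]), p=np.nan,
                        significant=False, n_pairs=0)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffle)
    for s in range(n_shuffle):
        shuffled = outcome.copy()
        for c in np.unique(cond):
            m = cond == c
            shuffled[m] = rng.permutation(shuffled[m])
        null[s], _ = _cc_statistic(values, cond, shuffled)
    lo, hi = np.percentile(null, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    sig = bool(stat < lo or stat > hi)
    p_lo = (np.sum(null <= stat) + 1) / (n_shuffle + 1)
    p_hi = (np.sum(null >= stat) + 1) / (n_shuffle + 1)
    return CPResult(statistic=float(stat), null=null,
                    p=float(min(1.0, 2 * min(p_lo, p_hi))),
                    significant=sig, n_pairs=n_pairs)


# -- On-Off / Right-Left classification ---------------------------------------

def _onoff_stat(pre: np.ndarray, post: np.ndarray) -> float:
    """max over time of PSTH(post) minus mean pre-stimulus rate."""
    return float(post.mean(axis=0).max() - pre.mean())


def classify_neuron(rates: np.ndarray, t: np.ndarray, sides: np.ndarray,
                    n_shuffle: int = 1000, seed: int = 0,
                    alpha: float = 0.02, pre_window=(-0.300, 0.0),
                    post_window=(0.0, 0.300)) -> dict:
    """On-Off and Right-Left selectivity flags for one neuron, one modality.

    ``rates`` is (n_trials, n_t) stimulus-aligned; ``sides`` is +-1 per
    trial. On-Off: max of the PSTH (0-300 ms) minus the mean pre-stimulus
    rate, null from per-trial random swaps of the pre/post windows,
    significant for either side at the 1st/99th percentile. Right-Left: max
    |PSTH_left - PSTH_right|, null from side-label shuffles.
    """
    rng = np.random.default_rng(seed)
    rates = np.asarray(rates, dtype=float)
    sides = np.asarray(sides, dtype=float)
    pre_m = (t >= pre_window[0]) & (t < pre_window[1])
    post_m = (t >= post_window[0]) & (t < post_window[1])
    nb = min(pre_m.sum(), post_m.sum())
    pre_idx = np.flatnonzero(pre_m)[-nb:]
    post_idx = np.flatnonzero(post_m)[:nb]

    onoff = False
    for side in (-1.0, 1.0):
        m = sides == side
        if not m.any():
            continue
        pre = rates[m][:, pre_idx]
        post = rates[m][:, post_idx]
        obs = _onoff_stat(pre, post)
        null = np.empty(n_shuffle)
        for s in range(n_shuffle):
            swap = rng.random(m.sum()) < 0.5
            p2 = np.where(swap[:, None], post, pre)
            q2 = np.where(swap[:, None], pre, post)
            null[s] = _onoff_stat(p2, q2)
        lo, hi = np.percentile(null, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        if obs < lo or obs > hi:
            onoff = True

    rightleft = False
    both = (sides == 1).any() and (sides == -1).any()
    if both:
        post = rates[:, post_idx]
        obs = float(np.abs(post[sides == -1].mean(axis=0)
                           - post[sides == 1].mean(axis=0)).max())
        null = np.empty(n_shuffle)
        for s in range(n_shuffle):
            perm = rng.permutation(sides)
            null[s] = float(np.abs(post[perm == -1].mean(axis=0)
                                   - post[perm == 1].mean(axis=0)).max())
        lo, hi = np.percentile(null, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        rightleft = bool(obs < lo or obs > hi)
    return {"onoff": onoff, "rightleft": rightleft}


# -- discrimination time -------------------------------------------------------

@dataclass
class DiscriminationResult:
    kind: str                     # 'onoff' | 'rightleft'
    time_s: float | None
    accuracy: float | None = None
    window_p: np.ndarray = field(default=None, repr=False)
    window_starts: np.ndarray = field(default=None, repr=False)


def _mw_p(x, y) -> float:
    if len(x) == 0 or len(y) == 0 or (np.ptp(np.concatenate([x, y])) == 0):
        return 1.0
    return float(mannwhitneyu(x, y, alternative="two-sided").pvalue)


def discrimination_time(rates: np.ndarray, t: np.ndarray, sides: np.ndarray,
                        kind: str = "rightleft", window_s: float = 0.050,
                        step_s: float = 0.005, alpha: float = 0.01,
                        n_consec: int = 3, max_time_s: float = 0.300,
                        pre_window=(-0.300, 0.0)) -> DiscriminationResult:
    """Earliest time a neuron's rate discriminates stimuli.

    Sliding windows of ``window_s`` stepped by ``step_s`` from stimulus
    onset; per window a Mann-Whitney U test across trials (left vs right
    rates for 'rightleft'; pre-stimulus vs in-window rates per side for
    'onoff', earliest over sides); significance requires ``n_consec``
    consecutive windows below ``alpha``. The reported time is the start of
    the first qualifying window; times past ``max_time_s`` are discarded.
    """
    rates = np.asarray(rates, dtype=float)
    sides = np.asarray(sides, dtype=float)
    starts = np.arange(0.0, max_time_s + step_s / 2, step_s)
    pre_m = (t >= pre_window[0]) & (t < pre_window[1])
    pre_rates = rates[:, pre_m].mean(axis=1)

    def window_vals(start):
        m = (t >= start) & (t < start + window_s)
        return rates[:, m].mean(axis=1)

    pvals = np.ones(len(starts))
    for i, s0 in enumerate(starts):
        w = window_vals(s0)
        if kind == "rightleft":
            pvals[i] = _mw_p(w[sides > 0], w[sides < 0])
        else:
            ps = []
            for side in (-1.0, 1.0):
                m = sides == side
                if m.any():
                    ps.append(_mw_p(w[m], pre_rates[m]))
            pvals[i] = min(ps) if ps else 1.0
    sig = pvals < alpha
    time = None
    for i in range(len(starts) - n_consec + 1):
        if sig[i:i + n_consec].all():
            time = float(starts[i])
            break
    if time is not None and time > max_time_s:
        time = None
    return DiscriminationResult(kind=kind, time_s=time, window_p=pvals,
                                window_starts=starts)


def posthoc_decoding_accuracy(rates: np.ndarray, t: np.ndarray,
                              sides: np.ndarray, time_s: float,
                              window_s: float = 0.100, k: int = 5,
                              seed: int = 0) -> float:
    """Relative SVM decoding accuracy 0-100 ms after the discrimination time."""
    x = window_average(rates, t, (time_s, time_s + window_s))[:, None]
    y = (np.asarray(sides) > 0).astype(int)
    if min((y == 0).sum(), (y == 1).sum()) < k:
        return np.nan
    skf = StratifiedKFold(k, shuffle=True, random_state=seed)
    correct = base = 0
    for tr, te in skf.split(x, y):
        clf = LinearSVC(dual="auto")
        clf.fit(x[tr], y[tr])
        correct += int((clf.predict(x[te]) == y[te]).sum())
        maj = int(np.mean(y[tr]) >= 0.5)
        base += int((y[te] == maj).sum())
    raw, b = correct / len(y), base / len(y)
    return float((raw - b) / (1 - b)) if b < 1 else 0.0
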