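"""Linear integrate-to-bound accumulator driven by surrogate spike trains.

Surrogate trials are Poisson spike-count arrays x(t) drawn from
condition-wise PSTHs (-100..300 ms around stimulus onset). The decision
variable integrates weighted activity,

    d(t) = d(t-1) + w . x(t),

and the model commits to a choice the first time |d| reaches a boundary
(sign gives left/right; the crossing time is the model reaction time).
Weights are time-independent, learned (never fit to behavior) by minimizing

    L = sum_{t<0} d(t)^2 + sum_{t>=0} max(0, 1 - y d(t))

with y = +-1 the target side (random on conflict trials), using Adam with
learning rate 0.01 for 300 epochs on 70% of trials; a hemisphere sign
constraint (left >= 0, right <= 0) may be enforced by projection.
Boundaries are trained at +-1 and then refined by grid search to match
target per-condition choice probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import PSTHBank


# -- surrogate populations --------------------------------------------------

@dataclass
class SurrogatePopulation:
    """Poisson spike-count trials with condition labels and targets."""

    x: np.ndarray                # (n_trials, n_neurons, n_t) counts per bin
    t: np.ndarray                # bin centers (s relative to stimulus onset)
    y: np.ndarray                # target decision variable, +-1
    condition_idx: np.ndarray    # (n_trials,) index into conditions
    conditions: list             # condition dicts (name + stimulus fields)
    neurons: pd.DataFrame
    bin_s: float


def make_surrogates(bank: PSTHBank, n_per_cond: int = 360,
                    bin_s: float = 0.010, seed: int = 0) -> SurrogatePopulation:
    """Independent Poisson counts per bin per neuron from the PSTH bank.

    Targets y are the stimulus side for unisensory and coherent conditions;
    on conflict conditions y is +-1 with equal probability.
    """
    rng = np.random.default_rng(seed)
    # resample bank rates onto the requested bin lattice
    t = np.arange(bank.t[0] - (bank.t[1] - bank.t[0]) / 2,
                  bank.t[-1], bin_s) + bin_s / 2
    n_cond, n_neur, _ = bank.rates.shape
    rates = np.empty((n_cond, n_neur, len(t)))
    for c in range(n_cond):
        for n in range(n_neur):
            rates[c, n] = np.interp(t, bank.t, bank.rates[c, n])
    xs, ys, cidx = [], [], []
    for c, cond in enumerate(bank.conditions):
        lam = rates[c] * bin_s
        counts = rng.poisson(lam[None, :, :].repeat(n_per_cond, axis=0))
        xs.append(counts)
        vsigned = cond["vis_contrast_R"] - cond["vis_contrast_L"]
        az = cond["aud_azimuth_deg"]
        is_conflict = vsigned != 0 and az != 0 and np.sign(vsigned) != np.sign(az)
        if is_conflict:
            y = rng.choice([-1.0, 1.0], n_per_cond)
        else:
            side = np.sign(vsigned) if vsigned != 0 else np.sign(az)
            y = np.full(n_per_cond, float(side))
        ys.append(y)
        cidx.append(np.full(n_per_cond, c))
    return SurrogatePopulation(
        x=np.concatenate(xs).astype(float), t=t, y=np.concatenate(ys),
        condition_idx=np.concatenate(cidx), conditions=list(bank.conditions),
        neurons=bank.neurons, bin_s=bin_s)


# -- model -------------------------------------------------------------------

@dataclass
class AccumOutcome:
    choice: str                  # 'L' | 'R' | 'none'
    rt_s: float | None
    trajectory: np.ndarray = field(default=None, repr=False)


def accumulator_loss(d: np.ndarray, y: float, pre_mask: np.ndarray) -> float:
    """Pre-stimulus MSE plus post-stimulus hinge loss of one trajectory."""
    pre = float(np.sum(d[pre_mask] ** 2))
    post = float(np.sum(np.maximum(0.0, 1.0 - y * d[~pre_mask])))
    return pre + post


class Accumulator:
    """Integrate-to-bound decision model (see module docstring).

    ``constraint_mask`` maps hemisphere labels to weight-sign constraints:
    pass the neurons' hemisphere array to constrain left-hemisphere weights
    to be >= 0 and right-hemisphere weights <= 0.
    """

    def __init__(self, lr: float = 0.01, epochs: int = 300,
                 train_frac: float = 0.7, seed: int = 0,
                 hemispheres: np.ndarray | None = None,
                 boundaries: tuple = (1.0, 1.0)):
        self.lr = lr
        self.epochs = epochs
        self.train_frac = train_frac
        self.seed = seed
        self.hemispheres = hemispheres
        self.boundaries = boundaries  # (theta_plus, theta_minus_magnitude)

    # -- dynamics --------------------------------------------------------
    def trajectories(self, x: np.ndarray) -> np.ndarray:
        """d(t) for a batch: cumulative sum of w . x(t)."""
        drive = np.einsum("ink,n->ik", np.asarray(x, dtype=float), self.w_)
        return np.cumsum(drive, axis=1)

    def run(self, x: np.ndarray, t: np.ndarray) -> AccumOutcome:
        """Run one trial; decision at the first boundary crossing at t >= 0."""
        d = self.trajectories(x[None])[0]
        th_p, th_m = self.boundaries
        eps = 1e-9  # tolerate accumulated floating-point error in cumsum
        eligible = t >= 0
        up = (d >= th_p * (1 - eps)) & eligible
        dn = (d <= -th_m * (1 - eps)) & eligible
        hit = up | dn
        if not hit.any():
            return AccumOutcome(choice="none", rt_s=None, trajectory=d)
        i = int(np.argmax(hit))
        return AccumOutcome(choice="R" if d[i] > 0 else "L",
                            rt_s=float(t[i]), trajectory=d)

    def decide(self, x: np.ndarray, t: np.ndarray):
        """Vectorized decisions for a batch; returns (choice, rt) arrays."""
        d = self.trajectories(x)
        return self._decide_from_traj(d, t, self.boundaries)

    @staticmethod
    def _decide_from_traj(d, t, boundaries):
        th_p, th_m = boundaries
        eps = 1e-9
        eligible = t >= 0
        up = (d >= th_p * (1 - eps)) & eligible
        dn = (d <= -th_m * (1 - eps)) & eligible
        hit = up | dn
        any_hit = hit.any(axis=1)
        first = np.argmax(hit, axis=1)
        choice = np.full(len(d), "none", dtype=object)
        rt = np.full(len(d), np.nan)
        rows = np.flatnonzero(any_hit)
        sign_at = np.sign(d[rows, first[rows]])
        choice[rows] = np.where(sign_at > 0, "R", "L")
        rt[rows] = t[first[rows]]
        return choice, rt

    # -- loss & gradient -------------------------------------------------
    def _loss_grad(self, C: np.ndarray, y: np.ndarray, pre: np.ndarray,
                   w: np.ndarray):
        """Mean loss over trials and its gradient.

        ``C`` is the cumulative count array (n_trials, n_neurons, n_t) so
        that d(t) = w . C(:, :, t); the loss is piecewise smooth in w and
        the gradient is exact away from the hinge kink.
        """
        d = np.einsum("ink,n->ik", C, w)
        pre_term = np.sum(d[:, pre] ** 2, axis=1)
        margin = 1.0 - y[:, None] * d[:, ~pre]
        post_term = np.sum(np.maximum(0.0, margin), axis=1)
        loss = float(np.mean(pre_term + post_term))
        coeff = np.zeros_like(d)
        coeff[:, pre] = 2.0 * d[:, pre]
        coeff[:, ~pre] = np.where(margin > 0, -y[:, None], 0.0)
        grad = np.einsum("ink,ik->n", C, coeff) / len(C)
        return loss, grad

    def loss(self, x: np.ndarray, y: np.ndarray, t: np.ndarray):
        """Mean loss of the current weights on a batch."""
        C = np.cumsum(np.asarray(x, dtype=float), axis=2)
        return self._loss_grad(C, np.asarray(y, float), t < 0, self.w_)[0]

    def loss_grad(self, x, y, t, w=None):
        C = np.cumsum(np.asarray(x, dtype=float), axis=2)
        w = self.w_ if w is None else w
        return self._loss_grad(C, np.asarray(y, float), t < 0, w)

    def _project(self, w):
        if self.hemispheres is None:
            return w
        h = np.asarray(self.hemispheres)
        w = w.copy()
        w[h == "left"] = np.maximum(w[h == "left"], 0.0)
        w[h == "right"] = np.minimum(w[h == "right"], 0.0)
        return w

    # -- training ---------------------------------------------------------
    def fit(self, pop: SurrogatePopulation):
        """Learn weights by Adam on the train split; boundaries stay +-1."""
        rng = np.random.default_rng(self.seed)
        n = len(pop.x)
        perm = rng.permutation(n)
        n_train = int(round(self.train_frac * n))
        self.train_idx_ = perm[:n_train]
        self.test_idx_ = perm[n_train:]
        C = np.cumsum(pop.x[self.train_idx_], axis=2)
        y = pop.y[self.train_idx_]
        pre = pop.t < 0
        w = np.zeros(pop.x.shape[1])
        m = np.zeros_like(w)
        v = np.zeros_like(w)
        b1, b2, eps = 0.9, 0.999, 1e-8
        history = []
        for ep in range(1, self.epochs + 1):
            loss, g = self._loss_grad(C, y, pre, w)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {ep}: {loss}")
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g ** 2
            mhat = m / (1 - b1 ** ep)
            vhat = v / (1 - b2 ** ep)
            w = w - self.lr * mhat / (np.sqrt(vhat) + eps)
            w = self._project(w)
            history.append(loss)
        self.w_ = w
        self.loss_history_ = np.asarray(history)
        return self

    def predict(self, x: np.ndarray, t: np.ndarray) -> pd.DataFrame:
        choice, rt = self.decide(np.asarray(x, dtype=float), t)
        return pd.DataFrame({"choice": choice, "rt_s": rt})

    # -- boundary fitting --------------------------------------------------
    def fit_boundaries(self, pop: SurrogatePopulation,
                       target_choice_probs: dict,
                       grid: np.ndarray | None = None,
                       use_test_split: bool = True):
        """Grid search (theta+, theta-) minimizing the MSE between model and
        target per-condition rightward-choice probabilities.

        In the search objective an undecided trial counts as probability 0.5
        (an uninformative choice), which keeps the search away from
        boundaries so high that nothing crosses.
        """
        if grid is None:
            grid = np.arange(0.2, 3.0 + 1e-9, 0.1)
        idx = self.test_idx_ if use_test_split and hasattr(self, "test_idx_") \
            else np.arange(len(pop.x))
        d = self.trajectories(pop.x[idx])
        cidx = pop.condition_idx[idx]
        names = [c["name"] for c in pop.conditions]
        targets = np.array([target_choice_probs[n] for n in names])
        best = None
        for th_p in grid:
            for th_m in grid:
                choice, _ = self._decide_from_traj(d, pop.t, (th_p, th_m))
                mse = 0.0
                for c in range(len(names)):
                    m = cidx == c
                    pr = (np.sum(choice[m] == "R")
                          + 0.5 * np.sum(choice[m] == "none")) / m.sum()
                    mse += (pr - targets[c]) ** 2
                mse = mse / len(names)
                if best is None or mse < best[0]:
                    best = (mse, th_p, th_m)
        self.boundaries = (float(best[1]), float(best[2]))
        self.boundary_mse_ = float(best[0])
        return self.boundaries


def subset_population(pop: SurrogatePopulation, idx) -> SurrogatePopulation:
    """Restrict a surrogate population to the given trial indices
    (e.g. a model's held-out split before behavioral evaluation)."""
    idx = np.asarray(idx)
    return SurrogatePopulation(
        x=pop.x[idx], t=pop.t, y=pop.y[idx],
        condition_idx=pop.condition_idx[idx], conditions=pop.conditions,
        neurons=pop.neurons, bin_s=pop.bin_s)


def simulate_inactivation(model: Accumulator, pop: SurrogatePopulation,
                          selector: np.ndarray, scale: float = 0.4
                          ) -> pd.DataFrame:
    """Run the trained model with selected neurons' activity scaled down.

    ``selector`` is a boolean mask over neurons (e.g. visual-left-preferring
    cells, or one hemisphere); ``scale=0.4`` emulates a 60% activity
    reduction. Returns the outcome table for all trials.
    """
    x = pop.x.copy()
    x[:, np.asarray(selector, bool), :] *= scale
    out = model.predict(x, pop.t)
    out["condition"] = [pop.conditions[c]["name"] for c in pop.condition_idx]
    return out


def outcomes_to_trials(pop: SurrogatePopulation, outcomes: pd.DataFrame
                       ) -> pd.DataFrame:
    """Map accumulator outcomes onto the canonical trial-table schema."""
    rows = []
    for i, c in enumerate(pop.condition_idx):
        cond = pop.conditions[c]
        rows.append(dict(trial_id=i, vis_contrast_L=cond["vis_contrast_L"],
                         vis_contrast_R=cond["vis_contrast_R"],
                         aud_azimuth_deg=cond["aud_azimuth_deg"],
                         choice=outcomes["choice"].iloc[i],
                         rt_s=outcomes["rt_s"].iloc[i],
                         timeout=outcomes["choice"].iloc[i] == "none"))
    return pd.DataFrame(rows)


def evaluate_vs_behavior(pop: SurrogatePopulation, outcomes: pd.DataFrame,
                         reference_log_odds: dict, n_shuffle: int = 100,
                         seed: int = 0, gamma: float | None = None) -> dict:
    """Compare accumulator behavior to a behavioral reference.

    Fits the additive psychometric model to the accumulator's decided
    trials and computes the MSE between its per-condition log-odds
    predictions and ``reference_log_odds`` (condition name -> log odds).
    The null refits after shuffling each trial's stimulus condition
    (n_shuffle times); p is the rank of the observed MSE in the null.
    Also reports relative median RT per stimulus type.
    """
    from .design import validate_trials
    from .psychometrics import fit_ml

    rng = np.random.default_rng(seed)
    trials = outcomes_to_trials(pop, outcomes)
    decided = trials[trials["choice"].isin(["L", "R"])].reset_index(drop=True)
    frac_undecided = 1 - len(decided) / len(trials)
    fixed = {"gamma": gamma} if gamma is not None else None

    cond_X = pd.DataFrame([dict(vis_contrast_L=c["vis_contrast_L"],
                                vis_contrast_R=c["vis_contrast_R"],
                                aud_azimuth_deg=c["aud_azimuth_deg"])
                           for c in pop.conditions])
    names = [c["name"] for c in pop.conditions]
    ref = np.array([reference_log_odds[n] for n in names])

    def mse_of(table):
        # identical optimizer configuration (incl. restart seed) for the
        # observed and every shuffled fit, so the comparison reflects the
        # data and not optimizer variability
        fit = fit_ml(table, "additive_parametric", fixed=fixed,
                     n_starts=6, seed=seed)
        lo = fit.model.log_odds(cond_X)
        return float(np.mean((lo - ref) ** 2)), fit

    observed, fit = mse_of(decided)
    null = np.empty(n_shuffle)
    stim_cols = ["vis_contrast_L", "vis_contrast_R", "aud_azimuth_deg",
                 "trial_type"]
    base = validate_trials(decided)
    for s in range(n_shuffle):
        shuf = base.copy()
        perm = rng.permutation(len(shuf))
        shuf[stim_cols] = shuf[stim_cols].to_numpy()[perm]
        null[s], _ = mse_of(shuf)
    p = float((np.sum(null <= observed) + 1) / (n_shuffle + 1))

    # relative median RT per stimulus type; undecided trials are censored
    # observations (treated as +inf, valid while their fraction is < 50%)
    t = validate_trials(trials)
    t = t.copy()
    t.loc[~t["choice"].isin(["L", "R"]), "rt_s"] = np.inf
    med = t.groupby("trial_type")["rt_s"].median()
    med = med[np.isfinite(med)]
    rel_rt = (med - med.mean()).to_dict()
    return {"mse": observed, "null_mse": null, "p": p, "fit": fit,
            "relative_rt": rel_rt, "frac_undecided": frac_undecided}
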