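"""Firing-rate estimation and ANOVA-style temporal-kernel encoding models.

A neuron's single-trial rate is decomposed as a sum of six temporal kernels

    F_i(t) = B(t) + a_i A(t) + v_i V(t) + a_i v_i N(t)
             + M(t - tau_i) + c_i D(t - tau_i)

with a_i, v_i, c_i = +-1 the auditory / visual / choice laterality codes and
tau_i the movement-onset time. B, A, V, N live on a stimulus-aligned lattice
(-50..400 ms); M, D on a movement-aligned lattice (-200..700 ms). The model
is a linear regression on lagged indicator columns, fit per neuron with
ridge (alpha = 10 by default) on half the trials; goodness is the
cross-validated mean-squared error E over 0..400 ms on held-out trials.
Dropping N gives the additive model; a variant fits one movement and one
direction kernel per audiovisual stimulus combination (8 movement kernels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator

STIM_WINDOW = (-0.050, 0.400)
MOVE_WINDOW = (-0.200, 0.700)
ERROR_WINDOW = (0.0, 0.400)


# -- rate estimation --------------------------------------------------------

@dataclass
class RateTraces:
    """Trials x time matrix of smoothed firing rates (Hz)."""

    t: np.ndarray
    rates: np.ndarray            # (n_trials, n_t)
    bin_s: float
    smooth_sd_s: float

    def psth(self) -> np.ndarray:
        return self.rates.mean(axis=0)


def half_gaussian_kernel(bin_s: float, sd_s: float) -> np.ndarray:
    """Causal half-Gaussian filter (mass at non-negative lags, unit sum)."""
    n = max(1, int(np.ceil(4 * sd_s / bin_s)))
    lags = np.arange(n + 1) * bin_s
    k = np.exp(-0.5 * (lags / sd_s) ** 2)
    return k / k.sum()


def estimate_rates(spike_times: list, t_window=(-0.1, 0.5),
                   bin_s: float = 0.002, smooth_sd_s: float = 0.060
                   ) -> RateTraces:
    """Bin spikes (2 ms default) and smooth with a causal half-Gaussian.

    ``spike_times`` is a sequence of per-trial spike-time arrays (s,
    stimulus-aligned). Smoothing conserves spike mass: a single spike
    becomes a causal bump integrating to one spike.
    """
    edges = np.arange(t_window[0], t_window[1] + bin_s / 2, bin_s)
    t = edges[:-1] + bin_s / 2
    k = half_gaussian_kernel(bin_s, smooth_sd_s)
    rates = np.zeros((len(spike_times), len(t)))
    for i, st in enumerate(spike_times):
        counts, _ = np.histogram(np.asarray(st, dtype=float), bins=edges)
        sm = np.convolve(counts, k)[:len(t)]
        rates[i] = sm / bin_s
    return RateTraces(t=t, rates=rates, bin_s=bin_s, smooth_sd_s=smooth_sd_s)


def rates_from_population(pop, neuron_id: int, t_window=(-0.1, 0.5),
                          bin_s: float = 0.002, smooth_sd_s: float = 0.060
                          ) -> RateTraces:
    """RateTraces for one neuron of a simulated PopulationData."""
    sp = pop.spikes[pop.spikes["neuron_id"] == neuron_id]
    by_trial = {tid: g["spike_time_s"].to_numpy()
                for tid, g in sp.groupby("trial_id")}
    trains = [by_trial.get(tid, np.array([]))
              for tid in pop.trials["trial_id"]]
    return estimate_rates(trains, t_window, bin_s, smooth_sd_s)


# -- kernel model -----------------------------------------------------------

def trial_codes(trials: pd.DataFrame):
    """Laterality codes a_i, v_i (stimulus) and c_i (choice), in {-1, +1}.

    Intended for multisensory trials where both stimuli are lateral; codes
    are 0 for absent/central stimuli (their kernel column is then zeroed).
    """
    from .design import choice_to_sign
    a = np.sign(trials["aud_azimuth_deg"].to_numpy(dtype=float))
    v = np.sign((trials["vis_contrast_R"] - trials["vis_contrast_L"])
                .to_numpy(dtype=float))
    if "choice" in trials.columns:
        c = np.nan_to_num(choice_to_sign(trials["choice"]))
    else:
        c = np.zeros(len(trials))
    return a, v, c


@dataclass
class KernelFit:
    """Fitted kernels with cross-validated error."""

    kernels: dict                # name -> (lag lattice, values)
    alpha: float
    cv_error: float              # E over ERROR_WINDOW on held-out trials
    variance_explained: float
    train_idx: np.ndarray = field(default=None, repr=False)
    model: "KernelEncoder" = field(default=None, repr=False)


class KernelEncoder(BaseEstimator):
    """Ridge regression of single-trial rates onto temporal kernels.

    Parameters
    ----------
    include_interaction : bool
        Include the non-additive N kernel (False gives the additive model).
    include_movement : bool
        Include movement-aligned M and D kernels (requires tau_i = rt_s).
    per_condition_movement : bool
        One movement and one direction kernel per audiovisual combination
        (8 movement-aligned kernels).
    alpha : float
        Ridge strength; 0 falls back to a pseudo-inverse solution (with a
        warning when the design is singular).
    """

    def __init__(self, include_interaction: bool = True,
                 include_movement: bool = True,
                 per_condition_movement: bool = False,
                 alpha: float = 10.0,
                 stim_window=STIM_WINDOW, move_window=MOVE_WINDOW,
                 max_tau_s: float = 0.300):
        self.include_interaction = include_interaction
        self.include_movement = include_movement
        self.per_condition_movement = per_condition_movement
        self.alpha = alpha
        self.stim_window = stim_window
        self.move_window = move_window
        self.max_tau_s = max_tau_s

    # design -------------------------------------------------------------
    def _lattices(self, bin_s):
        ns = int(round((self.stim_window[1] - self.stim_window[0]) / bin_s))
        stim_lags = self.stim_window[0] + (np.arange(ns) + 0.5) * bin_s
        nm = int(round((self.move_window[1] - self.move_window[0]) / bin_s))
        move_lags = self.move_window[0] + (np.arange(nm) + 0.5) * bin_s
        return stim_lags, move_lags

    def build_design(self, trials: pd.DataFrame, t: np.ndarray,
                     bin_s: float) -> tuple:
        """Sparse design matrix (n_trials * n_t rows) and block layout."""
        a, v, c = trial_codes(trials)
        stim_lags, move_lags = self._lattices(bin_s)
        blocks = [("B", np.ones(len(trials))), ("A", a), ("V", v)]
        if self.include_interaction:
            blocks.append(("N", a * v))
        move_blocks = []
        if self.include_movement:
            tau = trials["rt_s"].to_numpy(dtype=float)
            if self.per_condition_movement:
                combos = [(-1, -1), (-1, 1), (1, -1), (1, 1)]
                for (ac, vc) in combos:
                    sel = ((a == ac) & (v == vc)).astype(float)
                    if not sel.any():
                        raise ValueError(
                            f"no trials for audiovisual combination {(ac, vc)}")
                    move_blocks.append((f"M_a{ac}_v{vc}", sel))
                    move_blocks.append((f"D_a{ac}_v{vc}", sel * c))
            else:
                move_blocks = [("M", np.ones(len(trials))), ("D", c)]
        else:
            tau = np.full(len(trials), np.nan)

        n_tr, n_t = len(trials), len(t)
        ns, nm = len(stim_lags), len(move_lags)
        layout = [(name, ns) for name, _ in blocks] \
            + [(name, nm) for name, _ in move_blocks]
        col0 = np.cumsum([0] + [w for _, w in layout])
        rows, cols, vals = [], [], []
        # stimulus-aligned: output time t maps to lag bin directly
        stim_idx = np.round((t - self.stim_window[0]) / bin_s - 0.5).astype(int)
        valid_s = (stim_idx >= 0) & (stim_idx < ns)
        for bi, (name, code) in enumerate(blocks):
            nz = np.flatnonzero(code != 0)
            for i in nz:
                r = i * n_t + np.flatnonzero(valid_s)
                rows.append(r)
                cols.append(col0[bi] + stim_idx[valid_s])
                vals.append(np.full(valid_s.sum(), code[i]))
        for bj, (name, code) in enumerate(move_blocks):
            bi = len(blocks) + bj
            for i in range(n_tr):
                if code[i] == 0 or not np.isfinite(tau[i]):
                    continue
                lag_idx = np.round((t - tau[i] - self.move_window[0]) / bin_s
                                   - 0.5).astype(int)
                ok = (lag_idx >= 0) & (lag_idx < nm)
                rows.append(i * n_t + np.flatnonzero(ok))
                cols.append(col0[bi] + lag_idx[ok])
                vals.append(np.full(ok.sum(), float(code[i])))
        X = sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows),
                                    np.concatenate(cols))),
            shape=(n_tr * n_t, col0[-1]))
        return X, layout, (stim_lags, move_lags)

    # fitting ------------------------------------------------------------
    def fit(self, rates: RateTraces, trials: pd.DataFrame,
            split: np.ndarray | None = None, seed: int = 0):
        """Fit kernels on a random half (or given boolean ``split``) of trials.

        Movement models only use trials with tau_i < ``max_tau_s``.
        """
        trials = trials.reset_index(drop=True)
        Y = rates.rates
        if self.include_movement:
            tau = trials["rt_s"].to_numpy(dtype=float)
            keep = np.isfinite(tau) & (tau < self.max_tau_s)
            trials, Y = trials[keep].reset_index(drop=True), Y[keep]
        rng = np.random.default_rng(seed)
        n = len(trials)
        if split is None:
            split = np.zeros(n, dtype=bool)
            split[rng.choice(n, n // 2, replace=False)] = True
        X, layout, (stim_lags, move_lags) = self.build_design(
            trials, rates.t, rates.bin_s)
        n_t = len(rates.t)
        row_train = np.repeat(split, n_t)
        Xtr, ytr = X[row_train], Y[split].ravel()
        if self.alpha > 0:
            from sklearn.linear_model import Ridge
            reg = Ridge(alpha=self.alpha, fit_intercept=False)
            reg.fit(Xtr, ytr)
            coef = reg.coef_
        else:
            Xd = Xtr.toarray()
            if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
                warnings.warn("singular design without ridge; "
                              "using pseudo-inverse")
            coef, *_ = np.linalg.lstsq(Xd, ytr, rcond=None)
        self.coef_ = coef
        self.layout_ = layout
        self.stim_lags_ = stim_lags
        self.move_lags_ = move_lags
        self.bin_s_ = rates.bin_s
        self.t_ = rates.t
        self.split_ = split
        self.trials_ = trials
        # held-out error over the stated window
        Yhat = (X @ coef).reshape(Y.shape)
        win = (rates.t >= ERROR_WINDOW[0]) & (rates.t <= ERROR_WINDOW[1])
        test = ~split
        resid = Y[test][:, win] - Yhat[test][:, win]
        self.cv_error_ = float(np.mean(resid ** 2))
        denom = np.var(Y[test][:, win])
        self.variance_explained_ = float(1 - self.cv_error_ / denom) \
            if denom > 0 else 0.0
        return self

    @property
    def kernels_(self) -> dict:
        out = {}
        i = 0
        for name, width in self.layout_:
            lags = self.stim_lags_ if width == len(self.stim_lags_) \
                else self.move_lags_
            out[name] = (lags, self.coef_[i:i + width].copy())
            i += width
        return out

    def predict(self, trials: pd.DataFrame, t: np.ndarray | None = None
                ) -> np.ndarray:
        """Predicted rates (n_trials, n_t) from the fitted kernels."""
        t = self.t_ if t is None else t
        X, _, _ = self.build_design(trials.reset_index(drop=True), t,
                                    self.bin_s_)
        return (X @ self.coef_).reshape(len(trials), len(t))

    def predict_direct(self, trials: pd.DataFrame, t: np.ndarray | None = None
                       ) -> np.ndarray:
        """Pointwise kernel-sum prediction (oracle path, no design matrix)."""
        t = self.t_ if t is None else t
        a, v, c = trial_codes(trials)
        tau = trials["rt_s"].to_numpy(dtype=float) if self.include_movement \
            else np.full(len(trials), np.nan)
        ks = self.kernels_
        out = np.zeros((len(trials), len(t)))
        for i in range(len(trials)):
            for name, (lags, vals) in ks.items():
                if name == "B":
                    code = 1.0
                elif name == "A":
                    code = a[i]
                elif name == "V":
                    code = v[i]
                elif name == "N":
                    code = a[i] * v[i]
                elif name.startswith("M"):
                    code = 1.0
                    if "_a" in name:
                        ac, vc = name.split("_a")[1].split("_v")
                        code = float((a[i] == float(ac)) & (v[i] == float(vc)))
                elif name.startswith("D"):
                    code = c[i]
                    if "_a" in name:
                        ac, vc = name.split("_a")[1].split("_v")
                        code *= float((a[i] == float(ac)) & (v[i] == float(vc)))
                if code == 0:
                    continue
                if name[0] in "MD":
                    if not np.isfinite(tau[i]):
                        continue
                    rel = t - tau[i]
                else:
                    rel = t
                idx = np.round((rel - lags[0]) / self.bin_s_).astype(int)
                ok = (idx >= 0) & (idx < len(lags))
                out[i, ok] += code * vals[idx[ok]]
        return out


def fit_kernels(rates: RateTraces, trials: pd.DataFrame, alpha: float = 10.0,
                include_interaction: bool = True,
                include_movement: bool = True,
                per_condition_movement: bool = False,
                split=None, seed: int = 0) -> KernelFit:
    """Convenience wrapper returning a KernelFit."""
    enc = KernelEncoder(include_interaction=include_interaction,
                        include_movement=include_movement,
                        per_condition_movement=per_condition_movement,
                        alpha=alpha).fit(rates, trials, split=split, seed=seed)
    return KernelFit(kernels=enc.kernels_, alpha=alpha,
                     cv_error=enc.cv_error_,
                     variance_explained=enc.variance_explained_,
                     train_idx=enc.split_, model=enc)


def fit_passive_kernels(rates: RateTraces, trials: pd.DataFrame,
                        include_interaction: bool = True,
                        split=None, seed: int = 0) -> KernelFit:
    """Movement-free kernel model for passive stimulus presentation.

    F_i(t) = B + a_i A + v_i V (+ a_i v_i N). No regularization is used;
    callers should restrict to multisensory trials of a single contrast.
    """
    return fit_kernels(rates, trials, alpha=0.0,
                       include_interaction=include_interaction,
                       include_movement=False, split=split, seed=seed)


def kernels_to_frame(fits: list[KernelFit]) -> pd.DataFrame:
    """Tidy kernel table (neuron_id, kernel, t_s, value) for CSV export."""
    rows = []
    for nid, f in enumerate(fits):
        for name, (lags, vals) in f.kernels.items():
            rows.append(pd.DataFrame({"neuron_id": nid, "kernel": name,
                                      "t_s": lags, "value": vals}))
    return pd.concat(rows, ignore_index=True)


def kernels_from_frame(df: pd.DataFrame) -> dict:
    """Inverse of :func:`kernels_to_frame`: {neuron_id: {kernel: (t, v)}}."""
    out = {}
    for (nid, name), g in df.groupby(["neuron_id", "kernel"]):
        g = g.sort_values("t_s")
        out.setdefault(nid, {})[name] = (g["t_s"].to_numpy(),
                                         g["value"].to_numpy())
    return out


def kernel_summaries(fits: list[KernelFit], neurons: pd.DataFrame | None = None,
                     window=(0.0, 0.300), min_var: float = 0.02,
                     move_window=(-0.200, 0.400)) -> pd.DataFrame:
    """Per-neuron time-averaged kernel amplitudes for selected neurons.

    Keeps neurons whose fit explains at least ``min_var`` variance; reports
    signed and absolute time-averaged A and V amplitudes over ``window``
    and, when present, M/D amplitudes over ``move_window``.
    """
    rows = []
    for i, f in enumerate(fits):
        if f.variance_explained < min_var:
            continue
        row = {"neuron_id": i, "variance_explained": f.variance_explained}
        for name in ("A", "V"):
            lags, vals = f.kernels[name]
            m = (lags >= window[0]) & (lags <= window[1])
            row[f"{name}_mean"] = float(vals[m].mean())
            row[f"{name}_abs_mean"] = float(np.abs(vals[m]).mean())
        for name in ("M", "D"):
            if name in f.kernels:
                lags, vals = f.kernels[name]
                m = (lags >= move_window[0]) & (lags <= move_window[1])
                row[f"{name}_mean"] = float(vals[m].mean())
                row[f"{name}_abs_mean"] = float(np.abs(vals[m]).mean())
        if neurons is not None:
            meta = neurons.iloc[i]
            row["hemisphere"] = meta.get("hemisphere", "unknown")
        rows.append(row)
    return pd.DataFrame(rows)
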