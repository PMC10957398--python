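"""Psychometric model family for 2AFC audiovisual choices.

The central model is the additive law: the log odds of a rightward choice is
a sum of a visual-only function, an auditory-only function, and a bias,

    log p(R)/p(L) = b + (vR * VR**gamma - vL * VL**gamma) + (aR * AR - aL * AL)

where VR/VL are contrast fractions, AR/AL are indicators for a lateral
auditory stimulus, and sigma(log-odds) gives p(R). The family also contains
reduced models (bias-only, unisensory), non-additive alternatives (auditory
dominance, sensory bias, a fully saturated per-condition model), a
nonparametric-in-contrast additive variant, a five-azimuth extension, and an
ipsi/contra reparameterization used for inactivation analyses.

Models are fit by maximum likelihood (bounded quasi-Newton, multi-start) and
compared by cross-validated log2-likelihood gain over the bias-only model,
normalized per trial ("bits per trial").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold

from .design import AZIMUTHS, CONTRASTS, choice_to_sign, validate_trials

FAMILIES = (
    "bias_only",
    "visual_only",
    "auditory_only",
    "auditory_dominance",
    "sensory_bias",
    "additive_parametric",
    "additive_unconstrained",
    "full",
    "additive_5azimuth",
    "ipsi_contra",
)

#: Families whose log odds is linear in the parameters (convex likelihood).
_LINEAR_FAMILIES = {"bias_only", "auditory_only", "additive_unconstrained", "full"}

_GAMMA_BOUNDS = (0.01, 3.0)
_LOGODDS_BOUND = 20.0


@dataclass
class AdditiveParams:
    """Parameters of the additive psychometric law (right-positive).

    ``b`` is the log-odds bias, ``gamma`` the contrast exponent, ``vR/vL``
    visual sensitivities (log odds per contrast**gamma), ``aR/aL`` auditory
    sensitivities (log odds per lateral sound).
    """

    b: float = 0.0
    gamma: float = 0.6
    vR: float = 3.0
    vL: float = 3.0
    aR: float = 2.0
    aL: float = 2.0

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    def as_dict(self) -> dict:
        return {"b": self.b, "gamma": self.gamma, "vR": self.vR,
                "vL": self.vL, "aR": self.aR, "aL": self.aL}

    def log_odds(self, X: pd.DataFrame) -> np.ndarray:
        m = PsychometricModel(family="additive_parametric")
        return m._design_log_odds(self.as_dict(), X)

    def p_right(self, X: pd.DataFrame) -> np.ndarray:
        return expit(self.log_odds(X))


def _features(X: pd.DataFrame) -> dict:
    """Extract per-trial stimulus features used by every family."""
    VL = np.asarray(X["vis_contrast_L"], dtype=float)
    VR = np.asarray(X["vis_contrast_R"], dtype=float)
    az = np.asarray(X["aud_azimuth_deg"], dtype=float)
    AR = (az > 0).astype(float)
    AL = (az < 0).astype(float)
    vis = (VL > 0) | (VR > 0)
    aud = AR + AL > 0
    vis_side = np.sign(VR - VL)
    Tcoh = (vis & aud & (vis_side == np.sign(az))).astype(float)
    Tcon = (vis & aud & (vis_side != np.sign(az))).astype(float)
    return dict(VL=VL, VR=VR, az=az, AR=AR, AL=AL, Tcoh=Tcoh, Tcon=Tcon)


def param_names(family: str, contrast_set=CONTRASTS, azimuth_set=AZIMUTHS) -> list[str]:
    """Ordered free-parameter names for a family under a stimulus design."""
    contrasts = sorted(c for c in contrast_set if c > 0)
    lateral_az = sorted(a for a in azimuth_set if a != 0)
    if family == "bias_only":
        return ["b"]
    if family == "visual_only":
        return ["b", "gamma", "vR", "vL"]
    if family == "auditory_only":
        return ["b", "aR", "aL"]
    if family == "additive_parametric":
        return ["b", "gamma", "vR", "vL", "aR", "aL"]
    if family == "auditory_dominance":
        return ["b", "gamma", "vR", "vL", "aR", "aL", "acon"]
    if family == "sensory_bias":
        return ["b", "gamma", "vR", "vL", "aR", "aL", "vcon", "vcoh", "acon", "acoh"]
    if family == "additive_unconstrained":
        names = ["b"]
        for side in ("R", "L"):
            names += [f"v{side}_{c:g}" for c in contrasts]
        names += ["aR", "aL"]
        return names
    if family == "full":
        vis_conds = ["0"] + [f"{s}{c:g}" for s in ("L", "R") for c in contrasts]
        names = []
        for v in vis_conds:
            for a in azimuth_set:
                names.append(f"w_v{v}_a{a:g}")
        return names
    if family == "additive_5azimuth":
        names = ["b", "gamma", "vR", "vL"]
        names += [f"a{'R' if a > 0 else 'L'}{abs(a):g}" for a in lateral_az]
        return names
    if family == "ipsi_contra":
        return ["b", "gamma", "vi", "vc", "ai", "ac"]
    raise ValueError(f"unknown family {family!r}")


def _vis_cond_label(vl, vr, contrasts):
    if vl == 0 and vr == 0:
        return "0"
    side = "R" if vr > 0 else "L"
    c = vr if vr > 0 else vl
    return f"{side}{c:g}"


class PsychometricModel(BaseEstimator):
    """Maximum-likelihood psychometric model of 2AFC choices.

    Parameters
    ----------
    family : str
        One of :data:`FAMILIES`.
    contrast_set, azimuth_set : sequences
        The stimulus design; determines the parameter grid of the
        nonparametric families (and hence their parameter counts).
    fixed : dict or None
        Parameters frozen at given values (e.g. ``{"gamma": 0.6}`` when
        refitting inactivation trials, or ``{"acon": 0.0}`` for the strict
        auditory-dominance model).
    n_starts : int
        Random restarts of the bounded quasi-Newton optimizer (linear-in-
        parameter families are convex and use a single start).
    seed : int
        Seed for restart initialization.
    """

    def __init__(self, family: str = "additive_parametric",
                 contrast_set=CONTRASTS, azimuth_set=AZIMUTHS,
                 fixed: dict | None = None, n_starts: int = 10, seed: int = 0):
        self.family = family
        self.contrast_set = contrast_set
        self.azimuth_set = azimuth_set
        self.fixed = fixed
        self.n_starts = n_starts
        self.seed = seed

    # -- design helpers ---------------------------------------------------
    def _names(self):
        return param_names(self.family, self.contrast_set, self.azimuth_set)

    def _bounds(self, name):
        if name == "gamma":
            return _GAMMA_BOUNDS
        return (-_LOGODDS_BOUND, _LOGODDS_BOUND)

    def _design_log_odds(self, params: dict, X: pd.DataFrame) -> np.ndarray:
        f = _features(X)
        fam = self.family
        p = params
        if fam == "bias_only":
            return np.full(len(X), p["b"])
        if fam == "auditory_only":
            return p["b"] + p["aR"] * f["AR"] - p["aL"] * f["AL"]
        if fam == "visual_only":
            g = p["gamma"]
            return p["b"] + p["vR"] * f["VR"] ** g - p["vL"] * f["VL"] ** g
        if fam == "additive_parametric":
            g = p["gamma"]
            return (p["b"] + p["vR"] * f["VR"] ** g - p["vL"] * f["VL"] ** g
                    + p["aR"] * f["AR"] - p["aL"] * f["AL"])
        if fam == "auditory_dominance":
            g = p["gamma"]
            vis = p["vR"] * f["VR"] ** g - p["vL"] * f["VL"] ** g
            aud = p["aR"] * f["AR"] - p["aL"] * f["AL"]
            return p["b"] + (1 - f["Tcon"]) * vis + (1 - p["acon"] * f["Tcon"]) * aud
        if fam == "sensory_bias":
            g = p["gamma"]
            vis = p["vR"] * f["VR"] ** g - p["vL"] * f["VL"] ** g
            aud = p["aR"] * f["AR"] - p["aL"] * f["AL"]
            vgain = (1 - p["vcon"] * f["Tcon"]) * (1 - p["vcoh"] * f["Tcoh"])
            again = (1 - p["acon"] * f["Tcon"]) * (1 - p["acoh"] * f["Tcoh"])
            return p["b"] + vgain * vis + again * aud
        if fam in ("additive_unconstrained", "full"):
            names = self._names()
            theta = np.array([p[n] for n in names])
            D = self._linear_design(X, names)
            lo = D @ theta
            if fam == "full":
                seen = getattr(self, "cells_seen_", None)
                if seen is not None:
                    fallback = params.get("_fallback", 0.0)
                    unseen_cols = np.array([n not in seen for n in names])
                    is_unseen = (D[:, unseen_cols] != 0).any(axis=1)
                    lo = np.where(is_unseen, fallback, lo)
            return lo
        if fam == "additive_5azimuth":
            g = p["gamma"]
            lo = p["b"] + p["vR"] * f["VR"] ** g - p["vL"] * f["VL"] ** g
            for a in sorted(a for a in self.azimuth_set if a != 0):
                name = f"a{'R' if a > 0 else 'L'}{abs(a):g}"
                sgn = 1.0 if a > 0 else -1.0
                lo = lo + sgn * p[name] * (f["az"] == a)
            return lo
        if fam == "ipsi_contra":
            g = p["gamma"]
            VI = np.asarray(X["vis_contrast_I"], dtype=float)
            VC = np.asarray(X["vis_contrast_C"], dtype=float)
            AI = np.asarray(X["aud_I"], dtype=float)
            AC = np.asarray(X["aud_C"], dtype=float)
            return p["b"] + p["vi"] * VI ** g - p["vc"] * VC ** g \
                + p["ai"] * AI - p["ac"] * AC
        raise ValueError(f"unknown family {self.family!r}")

    def _linear_design(self, X: pd.DataFrame, names: list[str]) -> np.ndarray:
        """One-hot design matrix for the linear-in-parameters families."""
        f = _features(X)
        cols = {}
        if self.family in ("bias_only", "auditory_only",
                           "additive_unconstrained"):
            cols["b"] = np.ones(len(X))
            if self.family != "bias_only":
                cols["aR"] = f["AR"]
                cols["aL"] = -f["AL"]
            if self.family == "additive_unconstrained":
                for c in sorted(c for c in self.contrast_set if c > 0):
                    cols[f"vR_{c:g}"] = (np.abs(f["VR"] - c) < 1e-12).astype(float)
                    cols[f"vL_{c:g}"] = (np.abs(f["VL"] - c) < 1e-12).astype(float)
        elif self.family == "full":
            contrasts = sorted(c for c in self.contrast_set if c > 0)
            keys = pd.Series([
                f"w_v{_vis_cond_label(vl, vr, contrasts)}_a{az:g}"
                for vl, vr, az in zip(f["VL"], f["VR"], f["az"])])
            unknown = set(keys) - set(names)
            if unknown:
                raise ValueError(f"condition outside design: {unknown}")
            for n in names:
                cols[n] = (keys == n).to_numpy(dtype=float)
        else:
            raise ValueError(f"{self.family} has no linear design")
        return np.column_stack([cols[n] for n in names])

    # -- fitting ----------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None):
        """Fit by maximizing the Bernoulli likelihood of rightward choices.

        ``y`` may be 0/1 (right = 1), +-1, or 'L'/'R' labels; if omitted,
        ``X`` must carry a ``choice`` column.
        """
        if y is None:
            y = X["choice"]
        ysign = choice_to_sign(y)
        keep = np.isfinite(ysign)
        X = X.loc[np.asarray(keep)]
        yr = (ysign[keep] > 0).astype(float)

        names = self._names()
        fixed = dict(self.fixed or {})
        free = [n for n in names if n not in fixed]
        n_free = len(free)
        if len(X) < n_free:
            warnings.warn(
                f"fewer trials ({len(X)}) than free parameters ({n_free})")

        if self.family == "full":
            contrasts = sorted(c for c in self.contrast_set if c > 0)
            f = _features(X)
            self.cells_seen_ = {
                f"w_v{_vis_cond_label(vl, vr, contrasts)}_a{az:g}"
                for vl, vr, az in zip(f["VL"], f["VR"], f["az"])}
        else:
            self.cells_seen_ = None

        def unpack(theta):
            p = dict(fixed)
            p.update(zip(free, theta))
            return p

        linear = self.family in _LINEAR_FAMILIES
        if linear:
            names = self._names()
            D = self._linear_design(X, names)
            fixed_vec = np.array([fixed.get(n, 0.0) for n in names])
            free_cols = np.array([n not in fixed for n in names])
            offset = D[:, ~free_cols] @ fixed_vec[~free_cols] \
                if (~free_cols).any() else 0.0
            Dfree = D[:, free_cols]

            def nll(theta):
                lo = Dfree @ theta + offset
                val = float(np.sum(np.logaddexp(0.0, -lo) * yr
                                   + np.logaddexp(0.0, lo) * (1 - yr)))
                grad = Dfree.T @ (expit(lo) - yr)
                return val, grad
        else:
            def nll(theta):
                lo = self._design_log_odds(unpack(theta), X)
                # numerically stable -log-likelihood of Bernoulli(sigma(lo))
                return float(np.sum(np.logaddexp(0.0, -lo) * yr
                                    + np.logaddexp(0.0, lo) * (1 - yr)))

        bounds = [self._bounds(n) for n in free]
        rng = np.random.default_rng(self.seed)
        n_starts = 1 if linear else max(1, self.n_starts)
        best = None
        for s in range(n_starts):
            x0 = np.zeros(n_free)
            for j, n in enumerate(free):
                if n == "gamma":
                    x0[j] = 0.6 if s == 0 else rng.uniform(0.1, 2.0)
                elif s > 0:
                    x0[j] = rng.normal(0, 2)
            res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                           jac=linear)
            if best is None or res.fun < best.fun - 1e-9:
                best = res
        self.params_ = unpack(best.x)
        self.params_.pop("_fallback", None)
        if self.family == "full":
            # unseen condition cells fall back to the bias-only prediction
            eps = 0.5
            self.fallback_log_odds_ = float(logit(
                np.clip((yr.sum() + eps) / (len(yr) + 2 * eps), 1e-9, 1 - 1e-9)))
        self.loglik_ = -best.fun
        self.converged_ = bool(best.success)
        self.n_trials_ = len(X)
        if not self.converged_:
            warnings.warn(f"optimizer did not report convergence: {best.message}")
        return self

    def log_odds(self, X: pd.DataFrame) -> np.ndarray:
        p = dict(self.params_)
        if self.family == "full":
            p["_fallback"] = self.fallback_log_odds_
        return self._design_log_odds(p, X)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        pr = expit(self.log_odds(X))
        return np.column_stack([1 - pr, pr])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.where(self.log_odds(X) > 0, "R", "L")

    def score(self, X, y=None) -> float:
        """Mean log-likelihood (natural log) per trial on (X, y)."""
        if y is None:
            y = X["choice"]
        yr = (choice_to_sign(y) > 0).astype(float)
        lo = self.log_odds(X)
        ll = -(np.logaddexp(0.0, -lo) * yr + np.logaddexp(0.0, lo) * (1 - yr))
        return float(np.mean(ll))


# -- dataclasses -----------------------------------------------------------

@dataclass
class FitResult:
    """A fitted family member with optional cross-validated goodness."""

    family: str
    params: dict
    loglik: float
    n_trials: int
    converged: bool = True
    cv_bits_per_trial: float | None = None
    fold_bits: list = field(default_factory=list)
    seed: int | None = None
    model: PsychometricModel | None = None


def fit_ml(trials: pd.DataFrame, family: str = "additive_parametric",
           fixed: dict | None = None, n_starts: int = 10, seed: int = 0,
           contrast_set=None, azimuth_set=None) -> FitResult:
    """Maximum-likelihood fit of one family to a trial table."""
    trials = validate_trials(trials, require_choice=True)
    cs = contrast_set if contrast_set is not None else _infer_contrasts(trials)
    az = azimuth_set if azimuth_set is not None else _infer_azimuths(trials)
    m = PsychometricModel(family=family, contrast_set=cs, azimuth_set=az,
                          fixed=fixed, n_starts=n_starts, seed=seed).fit(trials)
    return FitResult(family=family, params=dict(m.params_), loglik=m.loglik_,
                     n_trials=m.n_trials_, converged=m.converged_, seed=seed,
                     model=m)


def _infer_contrasts(trials):
    vals = np.union1d(trials["vis_contrast_L"], trials["vis_contrast_R"])
    vals = sorted(float(v) for v in vals if v > 0)
    return tuple(vals) if vals else CONTRASTS


def _infer_azimuths(trials):
    return tuple(sorted(float(a) for a in np.unique(trials["aud_azimuth_deg"])))


def cv_bits_per_trial(trials: pd.DataFrame, family: str = "additive_parametric",
                      k: int = 5, seed: int = 0, fixed: dict | None = None,
                      n_starts: int = 10, contrast_set=None, azimuth_set=None,
                      train_mask=None) -> FitResult:
    """Cross-validated log2-likelihood gain over bias-only, per trial.

    Folds are stratified by stimulus condition; the bias-only reference is
    refit on every training fold. ``train_mask`` restricts which trials can
    enter training folds (e.g. unisensory-only training) while testing stays
    on all held-out trials.
    """
    trials = validate_trials(trials, require_choice=True).reset_index(drop=True)
    cs = contrast_set if contrast_set is not None else _infer_contrasts(trials)
    az = azimuth_set if azimuth_set is not None else _infer_azimuths(trials)
    cond = (trials["vis_contrast_L"].astype(str) + "_"
            + trials["vis_contrast_R"].astype(str) + "_"
            + trials["aud_azimuth_deg"].astype(str))
    yr = (choice_to_sign(trials["choice"]) > 0).astype(int)

    for attempt in range(5):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=seed + attempt)
        folds = list(skf.split(trials, cond))
        degenerate = any(len(np.unique(yr[tr])) < 2 for tr, _ in folds)
        if not degenerate:
            if attempt:
                warnings.warn(f"refolded {attempt}x to avoid degenerate folds")
            break
    fold_bits = []
    total_ll = 0.0
    n_total = 0
    for tr_idx, te_idx in folds:
        if train_mask is not None:
            tr_idx = tr_idx[np.asarray(train_mask)[tr_idx]]
        tr, te = trials.iloc[tr_idx], trials.iloc[te_idx]
        m = PsychometricModel(family=family, contrast_set=cs, azimuth_set=az,
                              fixed=fixed, n_starts=n_starts, seed=seed).fit(tr)
        m0 = PsychometricModel(family="bias_only").fit(tr)
        ll = m.score(te) * len(te)
        ll0 = m0.score(te) * len(te)
        fold_bits.append((ll - ll0) / (len(te) * np.log(2)))
        total_ll += ll
        n_total += len(te)
    return FitResult(family=family, params={}, loglik=total_ll, n_trials=n_total,
                     cv_bits_per_trial=float(np.mean(fold_bits)),
                     fold_bits=fold_bits, seed=seed)


def combine_subjects(tables: list[pd.DataFrame],
                     family: str = "additive_parametric",
                     n_repeats: int = 10, seed: int = 0,
                     fixed: dict | None = None, n_starts: int = 10) -> FitResult:
    """Pooled fit over subjects with per-repeat equal-n subsampling.

    Each repeat subsamples every subject down to the smallest subject's
    trial count, fits the family to the pooled subsample, and the reported
    parameters are the mean over repeats.
    """
    tables = [validate_trials(t, require_choice=True) for t in tables if len(t)]
    if not tables:
        raise ValueError("no subjects with trials")
    rng = np.random.default_rng(seed)
    n_min = min(len(t) for t in tables)
    all_params = []
    lls, ns = [], []
    pooled_all = pd.concat(tables, ignore_index=True)
    cs, az = _infer_contrasts(pooled_all), _infer_azimuths(pooled_all)
    for _ in range(max(1, n_repeats)):
        parts = []
        for t in tables:
            idx = rng.choice(len(t), size=n_min, replace=False)
            parts.append(t.iloc[idx])
        pooled = pd.concat(parts, ignore_index=True)
        r = fit_ml(pooled, family=family, fixed=fixed, n_starts=n_starts,
                   seed=int(rng.integers(2**31)), contrast_set=cs,
                   azimuth_set=az)
        all_params.append(r.params)
        lls.append(r.loglik)
        ns.append(r.n_trials)
    mean_params = {k: float(np.mean([p[k] for p in all_params]))
                   for k in all_params[0]}
    return FitResult(family=family, params=mean_params,
                     loglik=float(np.mean(lls)), n_trials=int(np.mean(ns)),
                     seed=seed)


def empirical_log_odds(trials: pd.DataFrame, gamma: float | None = None,
                       regularize: bool = True) -> pd.DataFrame:
    """Per-condition empirical log odds of rightward choice.

    Returns a table with one row per stimulus condition: counts nR/nL, the
    log odds log(nR/nL), and a linearized contrast axis
    x = sign(side) * contrast**gamma (if ``gamma`` given). One-sided cells
    are regularized by adding one trial in each direction.
    """
    trials = validate_trials(trials, require_choice=True)
    yr = choice_to_sign(trials["choice"])
    trials = trials.assign(_right=(yr > 0))
    rows = []
    for (vl, vr, az), g in trials.groupby(
            ["vis_contrast_L", "vis_contrast_R", "aud_azimuth_deg"]):
        nR = int(g["_right"].sum())
        nL = int(len(g) - nR)
        if (nR == 0 or nL == 0) and regularize:
            lo = np.log((nR + 1) / (nL + 1))
        elif nR == 0 or nL == 0:
            lo = np.nan
        else:
            lo = np.log(nR / nL)
        signed_c = vr - vl
        row = dict(vis_contrast_L=vl, vis_contrast_R=vr, aud_azimuth_deg=az,
                   n=len(g), nR=nR, nL=nL, log_odds=lo)
        if gamma is not None:
            row["x_contrast"] = np.sign(signed_c) * abs(signed_c) ** gamma
        rows.append(row)
    return pd.DataFrame(rows)


def neutral_pair_test(fit: FitResult, contrast_set=CONTRASTS,
                      azimuth_set=AZIMUTHS, tol: float = 0.05) -> pd.DataFrame:
    """Predicted p(R) at equal-and-opposite audiovisual pairings.

    Under the additive law, any conflict condition where the fitted visual
    pull exactly cancels the auditory pull must behave like a neutral trial:
    p(R) = sigma(b). Reports, per conflict condition, the predicted p(R),
    sigma(b), and whether they agree within ``tol``.
    """
    p = fit.params
    g = p["gamma"]
    b = p["b"]
    rows = []
    for c in sorted(x for x in contrast_set if x > 0):
        for az in (a for a in azimuth_set if a != 0):
            # conflict: visual opposite side of auditory
            if az > 0:
                lo = b + p["aR"] - p["vL"] * c ** g
                cancel = abs(p["aR"] - p["vL"] * c ** g) < 1e-6
            else:
                lo = b - p["aL"] + p["vR"] * c ** g
                cancel = abs(p["vR"] * c ** g - p["aL"]) < 1e-6
            pr = float(expit(lo))
            rows.append(dict(contrast=c, aud_azimuth_deg=az, p_right=pr,
                             p_neutral=float(expit(b)),
                             exact_cancellation=cancel,
                             within_tol=abs(pr - expit(b)) < tol))
    return pd.DataFrame(rows)


# -- conditional-independence audit ----------------------------------------

@dataclass
class ConditionLikelihoods:
    """p(V,A|S) vs the product of its marginals, under the reward rule."""

    joint: pd.DataFrame          # rows: S in {L,R}; columns: (V,A) cells
    product: pd.DataFrame        # p(V|S) * p(A|S)
    prior: dict
    tv_distance: float           # max over S of total-variation distance


def independence_audit(type_ratio=(10, 10, 5, 5, 1), contrast_set=CONTRASTS,
                       azimuth_set=AZIMUTHS) -> ConditionLikelihoods:
    """Audit whether the task design has conditionally independent channels.

    Enumerates the design distribution p(V,A) implied by the trial-type
    ratio (types -> uniform contrast, random side), derives p(V,A|S) via
    Bayes from the reward rule (S is the rewarded side; p(R|V,A)=1, 0, or
    0.5 for right, left, and conflict/neutral stimuli), and compares with
    the product of its marginals p(V|S)p(A|S).
    """
    ratio = np.asarray(type_ratio, dtype=float)
    if ratio.sum() <= 0 or (ratio < 0).any():
        raise ValueError("type_ratio must be nonnegative with positive sum")
    ptype = ratio / ratio.sum()
    contrasts = sorted(c for c in contrast_set if c > 0)
    lateral = sorted(a for a in azimuth_set if a != 0)
    # enumerate (V, A) cells: V is a signed contrast (0 = absent),
    # A an azimuth (0 = central)
    pVA = {}

    def add(v, a, prob):
        pVA[(v, a)] = pVA.get((v, a), 0.0) + prob

    nc, na = len(contrasts), len(lateral)
    # unisensory visual: side random, contrast uniform, auditory central
    for c in contrasts:
        for s in (-1, 1):
            add(s * c, 0.0, ptype[0] / (2 * nc))
    # unisensory auditory
    for a in lateral:
        add(0.0, a, ptype[1] / na)
    # coherent / conflict
    for c in contrasts:
        for a in lateral:
            v_coh = np.sign(a) * c
            add(v_coh, a, ptype[2] / (nc * na))
            add(-v_coh, a, ptype[3] / (nc * na))
    # neutral
    add(0.0, 0.0, ptype[4])

    cells = sorted(pVA)
    pR_given = {}
    for (v, a) in cells:
        if v == 0 and a == 0:
            pR_given[(v, a)] = 0.5
        elif v == 0:
            pR_given[(v, a)] = 1.0 if a > 0 else 0.0
        elif a == 0:
            pR_given[(v, a)] = 1.0 if v > 0 else 0.0
        elif np.sign(v) == np.sign(a):
            pR_given[(v, a)] = 1.0 if v > 0 else 0.0
        else:
            pR_given[(v, a)] = 0.5  # conflict

    prior = {"R": 0.5, "L": 0.5}
    joint = {}
    for S, pS in prior.items():
        row = {}
        for cell in cells:
            pSgiven = pR_given[cell] if S == "R" else 1 - pR_given[cell]
            row[cell] = pSgiven * pVA[cell] / pS
        joint[S] = row
    joint = pd.DataFrame(joint).T[cells]
    # product of marginals within each S row
    product = joint.copy()
    for S in joint.index:
        pV = {}
        pA = {}
        for (v, a) in cells:
            pV[v] = pV.get(v, 0.0) + joint.loc[S, (v, a)]
            pA[a] = pA.get(a, 0.0) + joint.loc[S, (v, a)]
        for cell in cells:
            product.loc[S, cell] = pV[cell[0]] * pA[cell[1]]
    tv = max(0.5 * np.abs(joint.loc[S] - product.loc[S]).sum()
             for S in joint.index)
    return ConditionLikelihoods(joint=joint, product=product, prior=prior,
                                tv_distance=float(tv))


# -- ipsi/contra helper -----------------------------------------------------

def to_ipsi_contra(trials: pd.DataFrame, laser_hemisphere) -> pd.DataFrame:
    """Reparameterize stimuli relative to an inactivated hemisphere.

    ``laser_hemisphere`` is 'left'/'right' (scalar or per-trial). Adds
    columns vis_contrast_I / vis_contrast_C and aud_I / aud_C, plus a
    ``choice_ipsi`` column (choice toward the inactivated hemisphere = 1)
    so the ipsi_contra family can be fit with standard machinery.
    """
    t = trials.copy()
    hemi = np.broadcast_to(np.asarray(laser_hemisphere, dtype=object),
                           (len(t),)).copy()
    right = hemi == "right"
    VL = np.asarray(t["vis_contrast_L"], float)
    VR = np.asarray(t["vis_contrast_R"], float)
    az = np.asarray(t["aud_azimuth_deg"], float)
    t["vis_contrast_I"] = np.where(right, VR, VL)
    t["vis_contrast_C"] = np.where(right, VL, VR)
    t["aud_I"] = np.where(right, az > 0, az < 0).astype(float)
    t["aud_C"] = np.where(right, az < 0, az > 0).astype(float)
    if "choice" in t.columns:
        sgn = choice_to_sign(t["choice"])
        ipsi = np.where(right, sgn > 0, sgn < 0)
        t["choice_ipsi"] = np.where(ipsi, "R", "L")  # 'R' == ipsilateral
    return t
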