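import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from avchoice import AdditiveParams, PsychometricModel
from avchoice import psychometrics as ps
from avchoice import synthetic as sy


def cond(vl=0.0, vr=0.0, az=0.0):
    return pd.DataFrame({"vis_contrast_L": [vl], "vis_contrast_R": [vr],
                         "aud_azimuth_deg": [az]})


class TestLogOdds:
    def test_bias_only_constant(self):
        m = PsychometricModel("bias_only")
        m.params_ = {"b": 0.7}
        X = pd.concat([cond(), cond(vr=0.8, az=60), cond(vl=0.4, az=-60)])
        assert np.allclose(m.log_odds(X), 0.7)

    def test_neutral_condition_gives_bias(self):
        m = PsychometricModel("additive_parametric")
        m.params_ = dict(b=0.3, gamma=0.6, vR=3, vL=3, aR=2, aL=2)
        assert m.log_odds(cond())[0] == pytest.approx(0.3)

    def test_additive_closed_form(self):
        m = PsychometricModel("additive_parametric")
        m.params_ = dict(b=0.2, gamma=0.6, vR=3, vL=3, aR=2, aL=2)
        lo = m.log_odds(cond(vr=0.8, az=60))[0]
        assert lo == pytest.approx(0.2 + 3 * 0.8 ** 0.6 + 2)

    def test_dominance_zeroes_visual_on_conflict(self):
        m = PsychometricModel("auditory_dominance")
        m.params_ = dict(b=0.0, gamma=0.6, vR=3, vL=3, aR=2, aL=2, acon=0.0)
        # conflict: visual right, auditory left -> only auditory term
        lo = m.log_odds(cond(vr=0.8, az=-60))[0]
        assert lo == pytest.approx(-2.0)
        # coherent keeps both
        lo = m.log_odds(cond(vr=0.8, az=60))[0]
        assert lo == pytest.approx(3 * 0.8 ** 0.6 + 2)

    def test_sensory_bias_nests_additive(self):
        pa = dict(b=0.1, gamma=0.6, vR=3, vL=2, aR=2, aL=1)
        m1 = PsychometricModel("additive_parametric")
        m1.params_ = pa
        m2 = PsychometricModel("sensory_bias")
        m2.params_ = dict(pa, vcon=0.0, vcoh=0.0, acon=0.0, acoh=0.0)
        X = pd.concat([cond(vr=0.4, az=60), cond(vl=0.8, az=60), cond(az=-60)])
        assert np.allclose(m1.log_odds(X), m2.log_odds(X))

    def test_parameter_counts(self):
        expected = {"additive_parametric": 6, "sensory_bias": 10,
                    "additive_unconstrained": 11, "full": 27,
                    "bias_only": 1, "visual_only": 4, "auditory_only": 3,
                    "auditory_dominance": 7, "ipsi_contra": 6}
        for fam, n in expected.items():
            assert len(ps.param_names(fam)) == n, fam
        # five-azimuth variant: two extra auditory parameters
        assert len(ps.param_names(
            "additive_5azimuth",
            azimuth_set=(-60, -30, 0, 30, 60))) == 8


class TestFitML:
    def test_parameter_recovery(self, true_params):
        cfg = sy.BehaviorSimConfig(true_params=true_params, n_trials=20000,
                                   seed=41)
        t = sy.gen_trial_schedule(cfg)
        t = sy.simulate_choices(t, true_params, seed=42)
        fit = ps.fit_ml(t, "additive_parametric", n_starts=3, seed=1)
        p = fit.params
        assert abs(p["b"] - true_params.b) < 0.1
        assert abs(p["aR"] - true_params.aR) < 0.1
        assert abs(p["aL"] - true_params.aL) < 0.1
        assert abs(p["vR"] - true_params.vR) / true_params.vR < 0.10
        assert abs(p["vL"] - true_params.vL) / true_params.vL < 0.10
        assert abs(p["gamma"] - true_params.gamma) / true_params.gamma < 0.10

    def test_coin_flip_data(self):
        rng = np.random.default_rng(0)
        t = sy.gen_trial_schedule(sy.BehaviorSimConfig(n_trials=4000, seed=2))
        t["choice"] = np.where(rng.random(len(t)) < 0.5, "R", "L")
        fit = ps.fit_ml(t, "additive_parametric", n_starts=3)
        assert abs(fit.params["b"]) < 0.15
        for k in ("vR", "vL", "aR", "aL"):
            assert abs(fit.params[k]) < 0.3

    def test_grid_oracle(self, small_trials):
        # coarse grid over (b, aR), others frozen at truth: the optimizer
        # must find a likelihood at least as good as the best grid point
        fixed = dict(gamma=0.6, vR=3.0, vL=3.0, aL=2.0)
        m = PsychometricModel("additive_parametric", fixed=fixed,
                              n_starts=3).fit(small_trials)
        yr = (small_trials["choice"] == "R").to_numpy().astype(float)

        def nll(b, aR):
            mm = PsychometricModel("additive_parametric")
            lo = mm._design_log_odds(dict(fixed, b=b, aR=aR), small_trials)
            return np.sum(np.logaddexp(0, -lo) * yr
                          + np.logaddexp(0, lo) * (1 - yr))

        grid_b = np.linspace(-1, 1, 5)
        grid_a = np.linspace(0, 4, 5)
        best = min((nll(b, a), b, a) for b in grid_b for a in grid_a)
        assert -m.loglik_ <= best[0] + 1e-6
        assert abs(m.params_["b"] - best[1]) <= 0.5
        assert abs(m.params_["aR"] - best[2]) <= 1.0

    def test_train_ll_nesting(self, small_trials):
        # richer families can only improve training likelihood
        lls = {}
        for fam in ("bias_only", "additive_parametric", "full"):
            lls[fam] = ps.fit_ml(small_trials, fam, n_starts=3).loglik
        assert lls["full"] >= lls["additive_parametric"] - 1e-6
        assert lls["additive_parametric"] >= lls["bias_only"] - 1e-6

    def test_reflection_equivariance(self, behavior_trials):
        t = behavior_trials
        mirrored = t.copy()
        mirrored["vis_contrast_L"] = t["vis_contrast_R"]
        mirrored["vis_contrast_R"] = t["vis_contrast_L"]
        mirrored["aud_azimuth_deg"] = -t["aud_azimuth_deg"]
        mirrored["choice"] = t["choice"].map({"R": "L", "L": "R"})
        f1 = ps.fit_ml(t, "additive_parametric", n_starts=3, seed=0).params
        f2 = ps.fit_ml(mirrored, "additive_parametric", n_starts=3,
                       seed=0).params
        assert f2["b"] == pytest.approx(-f1["b"], abs=0.05)
        assert f2["vR"] == pytest.approx(f1["vL"], abs=0.15)
        assert f2["aR"] == pytest.approx(f1["aL"], abs=0.1)

    def test_frozen_gamma_respected(self, small_trials):
        fit = ps.fit_ml(small_trials, "additive_parametric",
                        fixed={"gamma": 0.42}, n_starts=2)
        assert fit.params["gamma"] == 0.42


class TestCVBits:
    def test_bias_only_vs_itself_zero(self, small_trials):
        r = ps.cv_bits_per_trial(small_trials, "bias_only", seed=1)
        assert r.cv_bits_per_trial == pytest.approx(0.0, abs=1e-9)

    def test_true_model_beats_reductions(self, behavior_trials):
        bits = {fam: ps.cv_bits_per_trial(behavior_trials, fam, seed=3,
                                          n_starts=3).cv_bits_per_trial
                for fam in ("additive_parametric", "auditory_only",
                            "visual_only")}
        assert bits["additive_parametric"] > bits["auditory_only"]
        assert bits["additive_parametric"] > bits["visual_only"]

    def test_additive_at_least_full_on_additive_data(self, behavior_trials):
        add = ps.cv_bits_per_trial(behavior_trials, "additive_parametric",
                                   seed=5, n_starts=3).cv_bits_per_trial
        full = ps.cv_bits_per_trial(behavior_trials, "full",
                                    seed=5).cv_bits_per_trial
        assert add >= full - 0.01

    def test_unisensory_training_generalizes(self, behavior_trials):
        # additive model trained without multisensory trials predicts
        # them about as well as one trained on everything
        uni = behavior_trials["trial_type"].isin(
            ["unisensory_visual", "unisensory_auditory", "neutral"])
        r_all = ps.cv_bits_per_trial(behavior_trials, "additive_parametric",
                                     seed=7, n_starts=3)
        r_uni = ps.cv_bits_per_trial(behavior_trials, "additive_parametric",
                                     seed=7, n_starts=3,
                                     train_mask=uni.to_numpy())
        assert r_uni.cv_bits_per_trial == pytest.approx(
            r_all.cv_bits_per_trial, abs=0.03)


class TestCombineSubjects:
    def test_opposite_biases_cancel(self):
        tables = []
        for sign in (+1, -1):
            p = AdditiveParams(b=sign * 1.0)
            cfg = sy.BehaviorSimConfig(true_params=p, n_trials=3000,
                                       seed=50 + sign)
            t = sy.gen_trial_schedule(cfg)
            tables.append(sy.simulate_choices(t, p, seed=60 + sign))
        pooled = ps.combine_subjects(tables, n_repeats=3, seed=1, n_starts=3)
        assert abs(pooled.params["b"]) < 0.15

    def test_zero_trial_subject_excluded(self, small_trials):
        pooled = ps.combine_subjects([small_trials, small_trials.iloc[:0]],
                                     n_repeats=1, seed=1, n_starts=2)
        assert pooled.n_trials == len(small_trials)


class TestEmpiricalLogOdds:
    def test_balanced_cell_zero(self):
        t = pd.DataFrame({"vis_contrast_L": 0.0, "vis_contrast_R": 0.4,
                          "aud_azimuth_deg": 0.0,
                          "choice": ["R"] * 5 + ["L"] * 5})
        out = ps.empirical_log_odds(t)
        assert out["log_odds"].iloc[0] == pytest.approx(0.0)

    def test_eight_two_gives_log4(self):
        t = pd.DataFrame({"vis_contrast_L": 0.0, "vis_contrast_R": 0.4,
                          "aud_azimuth_deg": 0.0,
                          "choice": ["R"] * 8 + ["L"] * 2})
        out = ps.empirical_log_odds(t)
        assert out["log_odds"].iloc[0] == pytest.approx(np.log(4))

    def test_one_sided_cell_regularized(self):
        t = pd.DataFrame({"vis_contrast_L": 0.0, "vis_contrast_R": 0.4,
                          "aud_azimuth_deg": 0.0, "choice": ["R"] * 5})
        out = ps.empirical_log_odds(t)
        assert out["log_odds"].iloc[0] == pytest.approx(np.log(6))

    def test_linearized_contrast_axis(self):
        t = pd.DataFrame({"vis_contrast_L": [0.4, 0.0],
                          "vis_contrast_R": [0.0, 0.8],
                          "aud_azimuth_deg": 0.0,
                          "choice": ["L", "R"]})
        out = ps.empirical_log_odds(t, gamma=0.5)
        x = out.sort_values("vis_contrast_R")["x_contrast"].to_numpy()
        assert x[0] == pytest.approx(-0.4 ** 0.5)
        assert x[1] == pytest.approx(0.8 ** 0.5)


class TestNeutralPairs:
    def test_zero_bias_predicts_half(self):
        fit = ps.FitResult("additive_parametric",
                           dict(b=0.0, gamma=0.6, vR=3, vL=3, aR=2, aL=2),
                           0.0, 0)
        out = ps.neutral_pair_test(fit)
        assert np.allclose(out["p_neutral"], 0.5)

    def test_additive_data_matches_sigma_b(self, behavior_trials,
                                           true_params):
        fit = ps.fit_ml(behavior_trials, "additive_parametric", n_starts=3)
        out = ps.neutral_pair_test(fit)
        # the conflict condition closest to exact cancellation should sit
        # near sigma(b); verify empirically from the generator
        out["gap"] = (out["p_right"] - out["p_neutral"]).abs()
        closest = out.sort_values("gap").iloc[0]
        m = ((behavior_trials["trial_type"] == "conflict")
             & (behavior_trials[["vis_contrast_L", "vis_contrast_R"]]
                .max(axis=1) == closest["contrast"])
             & (behavior_trials["aud_azimuth_deg"] == closest["aud_azimuth_deg"]))
        emp = (behavior_trials.loc[m, "choice"] == "R").mean()
        n = m.sum()
        se = np.sqrt(emp * (1 - emp) / n)
        assert abs(emp - closest["p_neutral"]) < 3 * se + 0.02

    def test_dominance_world_violates_additivity(self):
        # under auditory dominance the conflict predictions deviate from
        # what an additive fit to dominance-generated data expects
        dom = PsychometricModel("auditory_dominance")
        dom.params_ = dict(b=0.0, gamma=0.6, vR=3, vL=3, aR=2, aL=2,
                           acon=0.0)
        cfg = sy.BehaviorSimConfig(n_trials=8000, seed=70)
        t = sy.gen_trial_schedule(cfg)
        rng = np.random.default_rng(71)
        pr = expit(dom.log_odds(t))
        t["choice"] = np.where(rng.random(len(t)) < pr, "R", "L")
        fit = ps.fit_ml(t, "additive_parametric", n_starts=3)
        # empirical conflict behavior: auditory side wins outright
        con = t[(t["trial_type"] == "conflict")
                & (t["vis_contrast_R"] == 0.8)]
        emp = (con["choice"] == "R").mean()  # auditory left on these
        pred = fit.model.predict_proba(con)[:, 1].mean()
        assert abs(emp - pred) > 0.05


class TestIndependenceAudit:
    def test_rows_normalized(self):
        res = ps.independence_audit()
        for S in ("L", "R"):
            assert res.joint.loc[S].sum() == pytest.approx(1.0)
            assert res.product.loc[S].sum() == pytest.approx(1.0)

    def test_task_design_not_independent(self):
        res = ps.independence_audit()
        assert res.tv_distance > 0.05

    def test_independent_design_distance_zero(self):
        # with visual and auditory each independently present/absent the
        # channels factorize... construct: only neutral trials
        res = ps.independence_audit(type_ratio=(0, 0, 0, 0, 1))
        assert res.tv_distance == pytest.approx(0.0, abs=1e-12)


class TestBayesConsistency:
    def test_additive_fit_attains_bayes_accuracy(self):
        # generative world with conditionally independent V and A channels:
        # S uniform; V | S and A | S discrete noisy observations. The
        # additive logistic rule is the Bayes rule; a fitted additive model
        # must reach Bayes accuracy within 1%.
        rng = np.random.default_rng(80)
        n = 20000
        S = rng.choice([-1, 1], n)
        # V in {-1, 0, 1}: correct side w.p. .55, zero w.p. .3, wrong .15
        V = np.array([rng.choice([s, 0, -s], p=[0.55, 0.30, 0.15])
                      for s in S])
        A = np.array([rng.choice([s, 0, -s], p=[0.65, 0.20, 0.15])
                      for s in S])
        t = pd.DataFrame({
            "vis_contrast_L": np.where(V < 0, 0.8, 0.0),
            "vis_contrast_R": np.where(V > 0, 0.8, 0.0),
            "aud_azimuth_deg": 60.0 * A,
            "choice": np.where(S > 0, "R", "L")})
        fit = ps.fit_ml(t, "additive_parametric", n_starts=3)
        pred = fit.model.log_odds(t) > 0
        acc_model = np.mean(np.where(pred, 1, -1) == S)
        # Bayes rule by enumeration of p(S | V, A)
        logit_v = np.log(0.55 / 0.15)
        logit_a = np.log(0.65 / 0.15)
        bayes = np.where(V * logit_v + A * logit_a >= 0, 1, -1)
        acc_bayes = np.mean(bayes == S)
        assert acc_model >= acc_bayes - 0.01
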