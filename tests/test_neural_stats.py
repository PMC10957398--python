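import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from avchoice import neural_stats as ns
from avchoice import synthetic as sy


class TestDprime:
    def test_identical_distributions_zero(self):
        x = np.random.default_rng(0).normal(5, 1, 200)
        assert ns.dprime(x, x) == 0.0

    def test_unit_case(self):
        rng = np.random.default_rng(1)
        x1 = rng.normal(1, 1, 100000)
        x2 = rng.normal(0, 1, 100000)
        assert ns.dprime(x1, x2) == pytest.approx(1.0, abs=0.03)

    def test_monte_carlo_vs_closed_form(self):
        rng = np.random.default_rng(2)
        mu1, mu2, s1, s2 = 3.0, 1.0, 2.0, 1.0
        x1 = rng.normal(mu1, s1, 50000)
        x2 = rng.normal(mu2, s2, 50000)
        expected = (mu1 - mu2) / (0.5 * (s1 + s2))
        assert ns.dprime(x1, x2) == pytest.approx(expected, abs=0.05)


class TestDecoding:
    def test_chance_when_labels_independent(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (120, 35))
        y = rng.choice([0, 1], 120)
        res = ns.decode_population(X, y, n_repeats=3, seed=1,
                                   min_trials_per_class=25)
        assert abs(res.relative_accuracy) < 0.25

    def test_separable_population_perfect(self):
        rng = np.random.default_rng(4)
        y = np.repeat([0, 1], 60)
        X = rng.normal(0, 0.1, (120, 35)) + y[:, None] * 3.0
        res = ns.decode_population(X, y, n_repeats=2, seed=1)
        assert res.relative_accuracy == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        y = np.repeat([0, 1], 60)
        X = rng.normal(0, 1, (120, 35)) + y[:, None] * 0.8
        r1 = ns.decode_population(X, y, n_repeats=2, seed=2)
        scales = rng.uniform(0.5, 2.0, 35)
        r2 = ns.decode_population(X * scales, y, n_repeats=2, seed=2)
        assert r1.relative_accuracy == pytest.approx(r2.relative_accuracy,
                                                     abs=0.15)

    def test_floors_enforced(self):
        X = np.zeros((30, 35))
        y = np.repeat([0, 1], 15)
        with pytest.raises(ValueError):
            ns.decode_population(X, y)  # too few trials per class
        X = np.zeros((60, 10))
        y = np.repeat([0, 1], 30)
        with pytest.raises(ValueError):
            ns.decode_population(X, y)  # too few neurons

    def test_regime_contrast(self):
        # trained-regime synthetic populations carry visual location
        # information; naive ones do not
        rels = {}
        for regime in ("trained", "naive"):
            cfg = sy.NeuronSimConfig(n_neurons=35, regime=regime, seed=6,
                                     fraction_selective=dict(A=0.6, V=0.6,
                                                             N=0, M=0, D=0))
            bank = sy.gen_psth_bank(cfg)
            names = bank.condition_names()
            rng = np.random.default_rng(7)
            X, y = [], []
            for label, cname in ((0, "vis_L_0.8"), (1, "vis_R_0.8"),
                                 (0, "vis_L_0.4"), (1, "vis_R_0.4")):
                lam = bank.rates[names.index(cname)]
                post = bank.t >= 0
                mean_rate = lam[:, post].mean(axis=1)
                for _ in range(30):
                    X.append(rng.poisson(mean_rate * 0.3) / 0.3)
                    y.append(label)
            res = ns.decode_population(np.array(X), np.array(y),
                                       n_repeats=3, seed=8)
            rels[regime] = res.relative_accuracy
        assert rels["trained"] > 0.5
        assert abs(rels["naive"]) < 0.25


class TestChoiceAxis:
    def test_parallel_vector_similarity_one(self):
        rng = np.random.default_rng(9)
        n_neur = 20
        muR = rng.uniform(1, 5, n_neur)
        muL = rng.uniform(1, 5, n_neur)
        axis = muR - muL
        n = 40
        choices = np.array(["R", "L"] * (n // 2))
        cond = np.repeat([0, 1], n // 2)
        cw = np.where((choices == "R")[:, None], muR, muL)
        x_t = np.tile(axis[None, :, None], (n, 1, 3))
        S = ns.choice_axis_projection(x_t, choices, cond, cw, seed=0)
        assert np.allclose(S[np.isfinite(S)], 1.0, atol=1e-9)

    def test_orthogonal_vector_similarity_zero(self):
        n_neur = 4
        muR = np.array([1.0, 0, 1, 0])
        muL = np.array([0.0, 1, 0, 1])
        axis = muR - muL
        orth = np.array([1.0, 1, 1, 1])
        assert abs(orth @ axis) < 1e-12
        n = 20
        choices = np.array(["R", "L"] * (n // 2))
        cond = np.repeat([0, 1], n // 2)
        cw = np.where((choices == "R")[:, None], muR, muL)
        x_t = np.tile(orth[None, :, None], (n, 1, 3))
        S = ns.choice_axis_projection(x_t, choices, cond, cw, seed=0)
        assert np.allclose(S[np.isfinite(S)], 0.0, atol=1e-9)

    def test_ramping_signal_diverges_before_movement(self):
        rng = np.random.default_rng(10)
        n, n_neur, n_t = 60, 15, 30
        t = np.linspace(-0.3, 0.0, n_t)
        choices = np.array(["R", "L"] * (n // 2))
        cond = rng.choice([0, 1], n)
        pref = rng.choice([-1.0, 1.0], n_neur)
        sgn = np.where(choices == "R", 1.0, -1.0)
        ramp = np.clip(t - t[0], 0, None) / (t[-1] - t[0])
        x_t = 5 + 2 * sgn[:, None, None] * pref[None, :, None] * ramp
        x_t += rng.normal(0, 0.3, x_t.shape)
        cw = x_t[:, :, -3:].mean(axis=2)
        S = ns.choice_axis_projection(x_t, choices, cond, cw, seed=1)
        gap = S[choices == "R"].mean(axis=0) - S[choices == "L"].mean(axis=0)
        assert gap[-1] > gap[2]
        assert gap[-1] > 0.5


class TestCombinedConditionsProbability:
    def brute_force(self, values, cond, outcome):
        pairs = 0
        wins = 0.0
        for c in np.unique(cond):
            idx = np.flatnonzero(cond == c)
            for i, j in itertools.product(idx, idx):
                if outcome[i] and not outcome[j]:
                    pairs += 1
                    if values[i] > values[j]:
                        wins += 1
                    elif values[i] == values[j]:
                        wins += 0.5
        return wins / pairs if pairs else np.nan

    def test_brute_force_oracle_exact(self):
        rng = np.random.default_rng(11)
        values = rng.integers(0, 5, 60).astype(float)  # many ties
        cond = rng.choice(["a", "b", "c"], 60)
        outcome = rng.random(60) < 0.5
        res = ns.combined_conditions_probability(values, cond, outcome,
                                                 n_shuffle=50, seed=1)
        assert res.statistic == pytest.approx(
            self.brute_force(values, cond, outcome), abs=1e-12)

    def test_mannwhitney_identity_single_condition(self):
        rng = np.random.default_rng(12)
        values = rng.normal(0, 1, 50)
        outcome = rng.random(50) < 0.5
        cond = np.zeros(50)
        res = ns.combined_conditions_probability(values, cond, outcome,
                                                 n_shuffle=50, seed=2)
        u = mannwhitneyu(values[outcome], values[~outcome]).statistic
        n_pairs = outcome.sum() * (~outcome).sum()
        assert res.statistic == pytest.approx(u / n_pairs, abs=1e-12)

    def test_outcome_independent_rate_near_half(self):
        rng = np.random.default_rng(13)
        values = rng.normal(5, 1, 200)
        cond = rng.choice([0, 1], 200)
        outcome = rng.random(200) < 0.5
        res = ns.combined_conditions_probability(values, cond, outcome,
                                                 n_shuffle=300, seed=3)
        assert abs(res.statistic - 0.5) < 0.1
        assert not res.significant

    def test_perfect_separation_gives_one(self):
        values = np.array([1.0] * 10 + [0.0] * 10)
        outcome = np.array([True] * 10 + [False] * 10)
        cond = np.zeros(20)
        res = ns.combined_conditions_probability(values, cond, outcome,
                                                 n_shuffle=200, seed=4)
        assert res.statistic == 1.0
        assert res.significant

    def test_no_valid_pairs_flagged(self):
        res = ns.combined_conditions_probability(
            np.ones(10), np.zeros(10), np.ones(10, dtype=bool),
            n_shuffle=10)
        assert np.isnan(res.statistic)
        assert res.n_pairs == 0


class TestClassifyNeuron:
    @staticmethod
    def make_rates(n_trials, n_t, fn, seed=0):
        rng = np.random.default_rng(seed)
        t = np.linspace(-0.3, 0.3, n_t)
        sides = rng.choice([-1.0, 1.0], n_trials)
        base = np.stack([np.broadcast_to(fn(t, s), t.shape).astype(float)
                         for s in sides])
        return base + rng.normal(0, 0.5, (n_trials, n_t)), t, sides

    def test_flat_neuron_no_flags(self):
        rates, t, sides = self.make_rates(60, 60, lambda t, s: 5.0, seed=20)
        flags = ns.classify_neuron(rates, t, sides, n_shuffle=200, seed=1)
        assert not flags["rightleft"]

    def test_calibrated_false_positive_rate(self):
        hits_rl = 0
        for k in range(40):
            rates, t, sides = self.make_rates(40, 60, lambda t, s: 5.0,
                                              seed=100 + k)
            flags = ns.classify_neuron(rates, t, sides, n_shuffle=100,
                                       seed=k)
            hits_rl += flags["rightleft"]
        # nominal 2% two-tailed: 40 datasets, 99% binomial CI -> <= 5
        assert hits_rl <= 5

    def test_onset_step_is_onoff_not_rightleft(self):
        rates, t, sides = self.make_rates(
            60, 60, lambda t, s: 5.0 + 4.0 * (t > 0), seed=21)
        flags = ns.classify_neuron(rates, t, sides, n_shuffle=200, seed=2)
        assert flags["onoff"]
        assert not flags["rightleft"]

    def test_lateralized_response_is_rightleft(self):
        rates, t, sides = self.make_rates(
            60, 60, lambda t, s: 5.0 + 4.0 * (t > 0) * (s > 0), seed=22)
        flags = ns.classify_neuron(rates, t, sides, n_shuffle=200, seed=3)
        assert flags["rightleft"]


class TestDiscriminationTime:
    @staticmethod
    def stepped(n_trials, step_t, snr=8.0, seed=0, lateral=True):
        rng = np.random.default_rng(seed)
        t = np.arange(-0.3, 0.45, 0.005)
        sides = np.tile([-1.0, 1.0], n_trials // 2)
        mu = np.zeros((n_trials, len(t)))
        for i, s in enumerate(sides):
            gate = (s > 0) if lateral else True
            mu[i] = 5.0 + snr * (t >= step_t) * gate
        return mu + rng.normal(0, 1.0, mu.shape), t, sides

    def test_step_at_100ms_recovered(self):
        rates, t, sides = self.stepped(60, 0.100, seed=30)
        res = ns.discrimination_time(rates, t, sides, kind="rightleft")
        assert res.time_s == pytest.approx(0.100, abs=0.055)

    def test_no_difference_gives_missing(self):
        rng = np.random.default_rng(31)
        t = np.arange(-0.3, 0.45, 0.005)
        rates = rng.normal(5, 1, (60, len(t)))
        sides = np.tile([-1.0, 1.0], 30)
        res = ns.discrimination_time(rates, t, sides, kind="rightleft")
        assert res.time_s is None

    def test_late_difference_capped(self):
        rates, t, sides = self.stepped(60, 0.350, seed=32)
        res = ns.discrimination_time(rates, t, sides, kind="rightleft")
        assert res.time_s is None

    def test_onoff_uses_prestim_reference(self):
        rates, t, sides = self.stepped(60, 0.080, seed=33, lateral=False)
        res = ns.discrimination_time(rates, t, sides, kind="onoff")
        assert res.time_s == pytest.approx(0.080, abs=0.055)

    def test_auditory_lead_recovered(self):
        # populations whose auditory kernels lead visual by a configured
        # offset: median rightleft discrimination times preserve the lead
        cfg = sy.NeuronSimConfig(n_neurons=30, seed=34, baseline_hz=(5, 10),
                                 amp_hz=dict(A=15, V=15, N=0, M=0, D=0),
                                 fraction_selective=dict(A=1, V=1, N=0,
                                                         M=0, D=0))
        bank = sy.gen_psth_bank(cfg, t_window=(-0.3, 0.4), bin_s=0.005)
        names = bank.condition_names()
        rng = np.random.default_rng(35)
        lead_times = {}
        for mod, (cl, cr) in (("aud", ("aud_L", "aud_R")),
                              ("vis", ("vis_L_0.8", "vis_R_0.8"))):
            times = []
            for nid in range(cfg.n_neurons):
                trials_per = 40
                lamL = bank.rates[names.index(cl), nid]
                lamR = bank.rates[names.index(cr), nid]
                dt = bank.t[1] - bank.t[0]
                rl = rng.poisson(lamL * dt, (trials_per, len(bank.t))) / dt
                rr = rng.poisson(lamR * dt, (trials_per, len(bank.t))) / dt
                rates = np.vstack([rl, rr])
                sides = np.r_[-np.ones(trials_per), np.ones(trials_per)]
                res = ns.discrimination_time(rates, bank.t, sides,
                                             kind="rightleft")
                if res.time_s is not None:
                    times.append(res.time_s)
            lead_times[mod] = np.median(times)
        lead = lead_times["vis"] - lead_times["aud"]
        expected = cfg.vis_latency_s - cfg.aud_latency_s
        assert lead == pytest.approx(expected, abs=0.030)


class TestPosthocDecoding:
    def test_separable_window_decodes(self):
        rates, t, sides = TestDiscriminationTime.stepped(60, 0.1, seed=40)
        acc = ns.posthoc_decoding_accuracy(rates, t, sides, 0.1, seed=1)
        assert acc > 0.8
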