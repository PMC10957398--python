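# avchoice

Analysis toolkit for two-alternative forced-choice (2AFC) audiovisual
localization experiments: a mouse turns a wheel to report whether a visual
grating and/or an auditory click train appeared on the left or right, while
cortical sites may be optogenetically silenced and frontal populations
recorded. The package is aimed at systems neuroscientists who want the full
computational pipeline of such a study — behavioral model comparison,
perturbation statistics, neural encoding models, and a neural-to-behavior
decision model — as tested, reusable code that runs end-to-end on synthetic
data with the same statistical structure.

## The models

**Additive psychometric law.** With conditionally independent visual and
auditory evidence, the optimal combination rule is additive in log odds:

    log p(R)/p(L) = b + (vR·VR^γ − vL·VL^γ) + (aR·AR − aL·AL),   p(R) = σ(·)

where VR/VL are contrast fractions, AR/AL lateral-sound indicators, and σ
the logistic function. `avchoice.psychometrics` implements this model and
its competitors (bias-only, unisensory, auditory-dominance, sensory-bias,
nonparametric-additive, fully saturated, five-azimuth, and an ipsi/contra
reparameterization for inactivation data), fit by maximum likelihood and
compared by cross-validated log₂-likelihood gain over bias-only
("bits/trial").

**Inactivation inference.** Shuffle tests for the change in rightward-choice
fraction at each laser site and for changes in the additive parameters per
inactivated region (γ frozen at its control value), plus a sliding-window
Fisher-exact analysis of pulsed-inactivation timing.

**Neural encoding.** Single-trial firing rates decomposed into six temporal
kernels, F_i(t) = B + a_i·A + v_i·V + a_i v_i·N + M(t−τ_i) + c_i·D(t−τ_i),
fit by ridge regression; dropping the interaction kernel N gives the
additive neural model, compared by cross-validated error.

**Population statistics.** Linear-SVM decoding with baseline-relative
accuracy, choice-axis cosine projection, d′, combined-conditions
choice/stimulus probability (ccCP/ccSP), On-Off / Right-Left classification
and sliding-window discrimination times.

**Accumulator.** Surrogate Poisson populations drawn from condition PSTHs
drive an integrate-to-bound model d(t) = d(t−1) + w·x(t); weights are
trained with a pre-stimulus MSE + post-stimulus hinge loss (Adam, lr 0.01,
300 epochs, 70/30 split), never fit to behavior, and the model's choices
and reaction times are compared with the additive behavioral law by a
condition-shuffle test.

## Worked example

```python
from avchoice import AdditiveParams, synthetic as sy, psychometrics as ps

truth = AdditiveParams(b=0.2, gamma=0.6, vR=3.0, vL=3.0, aR=2.0, aL=2.0)
cfg = sy.BehaviorSimConfig(true_params=truth, n_trials=20000, seed=1)
trials = sy.simulate_choices(sy.gen_trial_schedule(cfg), truth, seed=2)

fit = ps.fit_ml(trials, "additive_parametric", n_starts=3)
print({k: round(float(v), 3) for k, v in fit.params.items()})

cv = {fam: ps.cv_bits_per_trial(trials, fam, seed=3,
                                n_starts=3).cv_bits_per_trial
      for fam in ("additive_parametric", "auditory_only", "full")}
print({k: round(v, 4) for k, v in cv.items()})
```

prints (seed-exact)

```
{'b': 0.192, 'gamma': 0.59, 'vR': 3.079, 'vL': 2.92, 'aR': 1.96, 'aL': 1.99}
{'additive_parametric': 0.4011, 'auditory_only': 0.2151, 'full': 0.3981}
```

The fitted parameters recover the generating ones (bias and auditory
weights to ±0.1, visual weight and contrast exponent to a few percent), and
the additive model matches or beats the 27-parameter saturated model on
held-out data — extra non-additive parameters only add variance when the
generating process is additive.

A consolidated CLI mirrors the library (`avchoice simulate`, `extract`,
`fit`, `compare`, `inact-map`, `run`); `avchoice run --config cfg.yaml`
executes the full synthetic pipeline and writes a manifest with every seed.

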