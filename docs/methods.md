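# Methods

`avchoice` analyzes two-alternative forced-choice (2AFC) audiovisual
localization behavior and the frontal-cortex activity that supports it. This
note documents the models, the synthetic data that exercises them, the
numerical choices, and what passing tests do and do not establish.

## The additive psychometric law

If visual evidence V and auditory evidence A are conditionally independent
given the stimulus side S, Bayes' rule makes the log odds of a rightward
choice additive:

    log p(R|V,A)/p(L|V,A) = f(V) + g(A) + b,       p(R) = sigma(f + g + b)

with sigma the logistic function. The parametric workhorse models f as a
signed power of contrast and g as signed indicator weights:

    log p(R)/p(L) = b + vR*VR^gamma - vL*VL^gamma + aR*AR - aL*AL

Free parameters: bias `b`, contrast exponent `gamma` (power-law contrast
saturation), visual sensitivities `vR, vL` (log odds per contrast^gamma),
auditory sensitivities `aR, aL` (log odds per lateral sound). Contrast is a
fraction in [0, 1]; right is positive everywhere (azimuth, choice, log odds).

The family also contains:

- **bias_only** (1 parameter), **auditory_only** (3), **visual_only** (4);
- **auditory_dominance** (7; an extra conflict gain `acon`, or its strict
  variant with `acon` frozen at 0): the visual term is silenced on
  audiovisual conflict trials;
- **sensory_bias** (10): separate visual and auditory gain factors on
  coherent and conflict trials, nesting the additive model at zero gains;
- **additive_unconstrained** (11 under the standard design): one free weight
  per signed contrast level plus two auditory weights — additivity without
  the power-law assumption;
- **full** (27 = 9 visual conditions x 3 auditory locations): one weight per
  stimulus-condition cell, the saturated non-additive alternative. Cells
  absent from a training fold predict the bias-only log odds;
- **additive_5azimuth** (8): distinct weights for +-30 and +-60 degree
  sounds in the extended design;
- **ipsi_contra** (6): the same additive law written relative to an
  inactivated hemisphere (`vi, vc, ai, ac`), used for inactivation analyses.

**Fitting.** Bernoulli maximum likelihood with a bounded quasi-Newton
optimizer (L-BFGS-B): `gamma` in (0.01, 3], all log-odds parameters in
[-20, 20], ten random restarts by default (non-convex families only).
Families whose log odds is linear in the parameters (bias-only,
auditory-only, unconstrained, full) are convex and are fit in a single run
through a one-hot design matrix with an analytic gradient. A coarse grid
search serves as an independent optimizer oracle in the tests.

**Model comparison.** 5-fold cross-validation, folds stratified by stimulus
condition; the score is the mean over folds of
(LL(model) - LL(bias-only)) / (n_test * ln 2) — bits/trial, with the
bias-only reference refit on each training fold. Degenerate folds (a
training fold with only one choice class) trigger refolding with a new seed.

**Multi-subject pooling** subsamples every subject to the smallest subject's
trial count, fits, and repeats (default 10 repeats), reporting mean
parameters. **Empirical log odds** per condition are log(nR/nL), with one
trial added in each direction when a cell is one-sided, plotted against the
linearized axis sign(side)*contrast^gamma.

**Conditional-independence audit.** The task's reward rule (the rewarded
side is deterministic for unisensory/coherent stimuli, random for
conflict/neutral) defines p(S|V,A); Bayes inversion of the enumerated design
distribution gives p(V,A|S), which is compared against the product of its
marginals by total-variation distance. Under the 10/10/5/5/1 trial-type
ratio the channels are *not* conditionally independent (distance > 0), which
is exactly why additive behavior indicates a heuristic rather than full
Bayesian inference.

## Behavior extraction

A choice is the sign of the first excursion of the wheel 30 degrees (the
per-session threshold) from its pre-stimulus position within a 1.5 s
response window; no crossing is a timeout. The reaction time is the last
velocity zero-crossing before that threshold crossing which (a) follows at
least 50 ms of velocity at zero or opposite to the choice, and (b) is
followed by at least 50 ms of sustained movement toward the choice whose
mean speed is at least 20% of the threshold per second (the sample
containing the zero-crossing may be partial). Trials with movement within
10 ms of stimulus onset, or with no qualifying crossing, are flagged
`rt_undetectable`. Velocity is the first difference at the native sampling
interval (no smoothing); "zero velocity" admits a configurable epsilon
(default 1e-6 deg/s, i.e. exact zeros); ties resolve to the later sample.

Trial filters flag, never delete: timeouts; repeats following incorrect
choices; session edges (trials before/after the first/last three
consecutive non-timeout choices); undetectable RTs. Summaries aggregate
within session, then across sessions, then across mirror-symmetric
conditions; relative reaction time subtracts each subject's mean across
stimulus types.

## Inactivation statistics

**Choice-shift test.** Trials are canonicalized so stimuli are effectively
leftward (the visual stimulus on conflict trials), making the analysis
reflection-invariant. The statistic is the mean over subsamples —
equalizing each subject's trial counts between the laser-at-site and
non-laser cells, drawn without replacement — of the difference in fraction
of rightward choices. The null reassigns laser/site labels within subject
(10 shuffles per subsample iteration); p is the two-sided rank
(r+1)/(n+1)-style, never exactly 0. Replication defaults are the full-scale
values (25,000 subsamples x 10 shuffles); tests and the acceptance script
scale these down (tens of subsamples, hundreds of null points), which
changes resolution but not calibration.

**Parameter-change test.** The additive model is rewritten ipsi/contra to
the inactivated hemisphere, with `gamma` frozen at its non-inactivation
value. Control trials have no inactivated hemisphere, so they are mapped
into both hemispheres' frames (symmetrized duplication); laser trials use
their site's hemisphere. The per-parameter change (b, vi, vc, ai, ac)
between the laser and control fits is compared to a label-shuffled null.

**Region divergence.** For two inactivated regions, the mean difference
between within-region and inter-region held-out log likelihood, against a
region-label-shuffled null (one-sided: divergent effects make the
within-region fit better). Bonferroni correction across region pairs is the
caller's responsibility.

**Pulse timing.** Laser onsets are binned in a sliding 70 ms boxcar; per
window, a 2x2 Fisher exact test (laser-in-window / control x right / left
choices) at alpha = 0.001, with a window flagged significant if it, or both
its neighbors, pass. Sessions with fewer than 75 laser trials are excluded.
The Fisher test is implemented directly from the hypergeometric
distribution (two-sided: summing probabilities not exceeding the observed
table's) and is checked against full enumeration and scipy.

## Temporal-kernel encoding model

Single-trial firing rates (2 ms bins, causal half-Gaussian smoothing with
60 ms SD, unit mass, support at non-negative lags only) are decomposed as

    F_i(t) = B(t) + a_i A(t) + v_i V(t) + a_i v_i N(t)
             + M(t - tau_i) + c_i D(t - tau_i)

with a_i, v_i, c_i = +-1 the auditory, visual, and choice laterality codes
and tau_i the movement onset. B, A, V, N live on -50..400 ms
(stimulus-aligned); M, D on -200..700 ms (movement-aligned). Only trials
with tau_i < 300 ms enter movement models. The regression is ridge with a
single strength alpha = 10 applied to all kernels, on raw-Hz rates, trained
on a random half of trials; the reported error E is the mean squared error
on held-out trials over 0..400 ms. alpha = 0 (the passive, movement-free
variant) falls back to a minimum-norm pseudo-inverse with a warning when
the design is singular. The design-matrix prediction is verified exactly
against a direct pointwise kernel-sum oracle. Kernel summaries time-average
A and V over 0..300 ms (signed and absolute) for neurons whose additive fit
explains at least 2% variance; movement kernels over -200..400 ms.
Baseline normalization (dividing by the mean rate 0-700 ms before onset) is
exposed as an option for depth analyses.

## Population and single-neuron statistics

- **Decoding**: linear SVM on window-averaged rates (stimulus 0-300 ms,
  pre-movement -130-0 ms, post-movement 150-300 ms), 30-neuron subsets, 5
  repeats, 5-fold CV; floors of 25 trials per class and 30 neurons.
  Relative accuracy = (raw - baseline)/(1 - baseline), baseline from the
  training-fold majority class. Visual decoding restricts to high contrast.
- **Choice axis**: cosine similarity of the population vector with
  mu_R - mu_L (choice means 0-100 ms after movement onset), cross-validated
  by holding out the within-condition data and balancing choice counts.
- **d'** = (mu1 - mu2) / (0.5 (sd1 + sd2)) on window-averaged rates.
- **ccCP/ccSP**: fraction of within-condition trial pairs with different
  outcomes in which the rate on the "right" trial is higher (ties 0.5),
  computed via midranks (exactly the pooled Mann-Whitney U over pair
  counts); the null shuffles outcome labels within condition (1000
  shuffles); significant outside the 0.5/99.5 percentiles. For ccSP the
  controlled variables (other stimulus, choice) define the condition cells;
  matched choice counts per cell are the caller's responsibility.
- **On-Off / Right-Left classification**: On-Off statistic is the PSTH
  maximum (0-300 ms) minus the mean pre-stimulus rate (-300-0 ms), null
  from per-trial random pre/post window swaps; Right-Left uses the maximum
  absolute PSTH difference with side-label shuffles; both at the 1st/99th
  percentiles, either side sufficing for On-Off.
- **Discrimination time**: sliding 50 ms windows, 5 ms steps, Mann-Whitney
  U (tie-corrected; scipy's exact/asymptotic switching) at p < 0.01, three
  consecutive significant windows required; the reported time is the first
  window's *start*; times beyond 300 ms are discarded. Post-hoc decoding
  uses the 100 ms after the discrimination time.

## Integrate-to-bound accumulator

Surrogate trials are independent Poisson counts per 10 ms bin (5 ms in the
reduced test configuration) drawn from condition PSTHs on -100..300 ms; 360
trials per condition at full scale. Conditions: unisensory visual at 10, 20,
40, 80% contrast left and right, unisensory auditory left and right, and
coherent/conflict at 80%. Targets y are the stimulus side; on conflict
trials y is +-1 with equal probability.

The decision variable accumulates from the trace start (pre-stimulus bins
included — the loss explicitly penalizes pre-stimulus excursions):
d(t) = d(t-1) + w.x(t), with time-independent weights w. The training loss

    L = sum_{t<0} d(t)^2 + sum_{t>=0} max(0, 1 - y d(t))

is piecewise smooth in w; its gradient is computed in closed form (the
cumulative count array C(t) makes d linear in w) and verified against
finite differences. Optimization is Adam (lr 0.01, standard decay rates,
300 epochs, full batch) on 70% of trials; behavioral evaluation uses the
held-out 30% — evaluating on training trials lets even an uninformative
population "explain" behavior through memorized noise. A hemisphere
constraint (left weights >= 0, right <= 0) is enforced by projection after
each step.

Choices are the sign of d at its first boundary crossing at t >= 0
(boundaries +-1 during training); the crossing time is the model RT; no
crossing is an undecided trial. Crossing detection tolerates 1e-9 relative
floating-point slack so the constant-drift identity (crossing bin =
ceil(theta/mu)) holds exactly. Boundaries are then refined by grid search
minimizing the MSE between model and target per-condition rightward-choice
probabilities; in that objective an undecided trial counts as probability
0.5, which keeps the search away from boundaries so high that nothing
crosses.

Two evaluation choices deserve emphasis:

- **Undecided trials and RT medians.** Per-type median RTs treat undecided
  trials as right-censored (+inf), valid while their fraction is below 50%.
  Simply dropping them biases the comparison: weak-drive conditions lose
  their slow tail and their median shifts spuriously early (in our
  simulations, enough to invert the coherent-vs-auditory ordering).
  Undecided trials are still excluded from choice-probability MSEs, with
  their fraction reported.
- **Behavioral comparison.** The additive model is fit to the accumulator's
  decided trials; the statistic is the MSE between its per-condition
  log-odds predictions and the reference (behavioral) log odds, against a
  null that shuffles each trial's stimulus condition (100 refits). The
  observed and every null fit use the identical optimizer configuration,
  including the restart seed, so the comparison reflects the data rather
  than optimizer variability.

Inactivation is simulated by scaling selected neurons' counts by 0.4 (a 60%
activity reduction) before running the already-trained model: visual-left
preferring cells for a visual-cortex simulation, one hemisphere for a
frontal simulation (lateralized effects require the sign-constrained
variant, since stimulus preferences are bilaterally distributed).

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure the analyses assume:
trial types in ratio 10/10/5/5/1, contrasts {10, 20, 40, 80}%, azimuths
{-60, 0, +60} degrees, choices from the additive law, a 75% inactivation
fraction over a bilateral AP x ML site grid (the printed coordinate sets
give 64 products; the named-region subsets are the coordinate triplets, and
an explicit site list can be supplied), wheel traces that are still then
ramp past threshold, and Poisson spikes from rectified kernel sums
(thinning on a 1 ms lattice). The reaction-time generator
(base 0.22 s, auditory advantage 0.022 s, contrast slope 0.05 s/unit,
Gaussian jitter 0.04 s, truncated at 0.03 s) is invented plumbing whose only
purpose is to order coherent < auditory < visual and exercise the RT
extraction; it makes no claim about real latency distributions. Kernel
shapes are half-sine bumps (auditory onset 30 ms, visual 75 ms, width
120 ms, movement kernels rising 50 ms before movement onset), visual
amplitude scaled by (contrast/0.8)^0.6; the naive regime zeroes visual
kernels and attenuates auditory spatial kernels (default to zero, i.e.
location-uninformative, while keeping a non-spatial evoked response).

Not emulated: correlated (non-Poisson) spiking, realistic wheel
biomechanics, eye/body-movement covariates, session nonstationarity, lapse
behavior. Passing tests therefore establish internal consistency —
estimators recover what the generators planted, tests are calibrated on
exchangeable nulls, oracles agree — not that real data satisfy the models'
assumptions.

## Problem sizes

Replication defaults in function signatures are the full-scale values
(25,000 subsamples, 250,000 null points, 1,000 shuffles, 360 surrogate
trials per condition). The test suite and `scripts/acceptance.py` run the
same code at sizes chosen for a single core: 2,000-24,000 behavioral
trials, 5-12 recovery/selection seeds, 30-40 null datasets for calibration,
60 encoding neurons, 100-150 surrogate trials per condition, 40-100 null
refits. These sizes widen Monte-Carlo error but leave every statistic's
definition unchanged.

## Known limitations

- The parameter-change shuffle test symmetrizes control trials across
  hemispheres; if real control behavior were strongly asymmetric this
  would shrink the apparent bias change. The alternative (fitting the
  standard L/R model to controls) is a one-line substitution.
- Shuffles are performed within subject; across-subject reassignment is a
  documented alternative the null does not currently implement.
- The full model's unseen-cell fallback uses a regularized empirical bias,
  which slightly favors the full model on sparse designs.
- Discrimination times are window starts; window centers would shift every
  estimate by half a window without affecting differences.
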