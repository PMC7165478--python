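# Methods

`wmarc` implements a family of Bayesian observer models for a rewarded
working-memory task, together with the machinery needed to fit them,
compare them, and validate the whole pipeline on synthetic experiments.

## Task and generative model

On each trial the observer sees four colors drawn from a wheel of 360
equidistant hues, and after a delay reports (i) an estimate of a probed
color and (ii) a symmetric "arc" around that estimate — a rewarded
confidence interval. A hit (true color inside the arc) earns
`points(A) = 100·(180 − A)/180` for arc half-size `A` degrees; a miss earns
0. Two stimulus regimes exist: uniform sessions, and von Mises sessions in
which colors concentrate around a participant-specific prior mean with
concentration 1.422 (circular SD 60°).

The generative model for one non-lapse trial:

1. **Encoding.** Precision `κ ~ Gamma(mean, scale)` varies across trials
   (shape = mean/scale); the memory is `m ~ VM(s, κ)`. A fixed-precision
   variant replaces the gamma by a single constant `κ_const`.
2. **Represented uncertainty `κ*`.** *Known*: `κ* = κ`. *No-Knowledge*:
   `κ* = κ_fixed` (free). *Limited*: `κ* = 0` if `κ < κ_threshold`, else
   `κ_fixed` (both free). `κ*` is what the observer *believes* about their
   noise; the memory sample itself is always corrupted by the true `κ`.
3. **Posterior.** `VM(m, κ*)` is combined with the believed stimulus prior
   `VM(μ_p, κ_w)` by the von Mises resultant-vector product. In uniform
   sessions, and under prior-use codes that ignore the prior, the prior is
   uniform (`κ_w = 0` — a first-class value, no epsilon floor).
4. **Estimate.** A draw from the posterior raised to a power `p`
   (equivalently `VM(μ_post, p·κ_post)`): `p` is estimation noise.
5. **Arc.** Expected utility `EU(A) = p(hit|A) · points(A)^α` with risk
   attitude `α`, where `p(hit|A)` is the posterior mass within `±A` of the
   posterior mean (the tractability approximation: the observer integrates
   around their posterior mean, not their sampled estimate, so the arc
   depends only on the posterior width). The reported arc is a softmax
   draw, `P(A) ∝ exp(EU(A)/T)`, on a 1°-step grid of 181 half-sizes.
6. **Lapses.** With probability `λ` the trial carries no memory
   information: the estimate is uniform and the arc follows the expected
   utility of the uniform posterior — unless the prior-use code says
   lapse trials use the believed prior, in which case the prior plays the
   role of the posterior in steps 4–5.

Prior-use codes `YY/YN/NY/NN` give whether the believed prior enters
non-lapse / lapse trials; `TT` is `YY` with `κ_w` pinned to the true
stimulus concentration 1.422. Free-parameter counts: Known 6,
No-Knowledge 7, Limited 8, Fixed-precision 5; plus one for a free `κ_w`
(`YY/YN/NY` in joint uniform+von Mises fits).

The reward rule is implemented as the decreasing linear map from 100
points at `A = 0` to 0 at `A = 180`; this is the only form consistent with
a 0–100 point scale and a linear decrease.

## Likelihood

The density of a response pair is

```
p(est, arc | s) = λ · p_lapse(est) · p_lapse(arc)
    + (1−λ) · E_κ ∫ p(m|s,κ) · VM(est; μ_post, p·κ_post) · P(arc | κ_post) dm
```

per (degree × degree) cell: estimate densities are per degree; the arc
likelihood is the softmax bin mass divided by the bin width (a proper
density, so models with different grids remain comparable).

Numerical choices:

- **κ marginalization**: equal-weight gamma stratification with each
  stratum evaluated at its conditional mean (computed from the shape+1
  incomplete-gamma identity). Centroid placement is first-order exact
  within strata; with the default 100 strata, doubling the grid changes
  the log-likelihood by ~0.03 per 1,000 trials. Plain quantile midpoints
  were measured to converge an order of magnitude more slowly.
- **m marginalization**: periodic trapezoid rule on an equispaced circular
  grid (360 points by default), spectrally accurate for these smooth
  integrands. Where the believed prior is uniform the arc factor does not
  depend on `m` and the memory integral collapses to a circular
  convolution of the encoding and estimation kernels; this fast path is
  asserted against the general prior-frame path to 1e-8 in the tests.
- **Fitting acceleration** (`LikelihoodConfig.fast()`): 16 κ strata, a
  120-point memory grid, FFT-tabulated estimate marginals interpolated at
  0.125°, and arc log-policies interpolated across 64 posterior-width
  nodes. This preset sits within a few millinats per trial of the default
  quadrature; in cross-validated comparisons the bias is shared by all
  models and cancels to first order.
- **Underflow**: the mixture density is floored at 1e-300 before the log;
  with `λ > 0` the lapse branch already guarantees a finite density.
  Bessel ratios use exponentially scaled `I0/I1` so arbitrarily large κ
  cannot overflow.
- Internal computation is in radians; every public interface speaks
  degrees, the unit of the task.

Correctness is gated primarily by a Monte-Carlo oracle: `exp(trial_loglik)`
is compared against 10⁶-draw simulation histograms, cell by cell, on the
3-binomial-SE scale, across random parameter sets for every model variant;
and by exact normalization of the density over the full response grid.

## Fitting

Maximum likelihood per participant, by multi-start Nelder–Mead in a
box-transformed space (scaled logit per parameter, so positives are
effectively log-transformed near their lower bounds and the lapse rate is
logit-like on [1e-4, 0.5]). Starts are drawn log-uniformly inside
plausible ranges spanning the behaviorally sensible regimes; bounds are
generous (e.g. `gamma_mean ∈ [0.05, 200]`, `T ∈ [0.01, 1000]`). 50 starts
by default; studies in the tests use fewer, documented per study. Fits are
deterministic given a seed. If no start produces a finite optimum the
result is flagged `converged=False` rather than silently returning a
best-so-far.

## Model comparison

10-fold cross-validated log-likelihood (LLcv), summed over folds, with
fold assignment stratified by condition so joint fits always train on both
stimulus regimes. Because participants complete different numbers of
trials, the summed LLcv is divided by the participant's trial count and
multiplied by the mean trial count across participants. AIC/BIC are
provided from full-data fits. Differences between models are summarized by
the across-participant mean with BCa bootstrap confidence intervals
(10,000 resamples by default). Random-effects Bayesian model selection
uses the variational Dirichlet scheme (Stephan et al. 2009,
*NeuroImage* 46:1004–17) on the per-participant LLcv as log evidence;
exceedance probabilities come from seeded Dirichlet Monte-Carlo, checked
against a direct sampling oracle. The hierarchical-vs-single-model Bayes
factor compares the variational bound on the hierarchical marginal
likelihood with the best single model's summed evidence; with one model it
is exactly 1. This construction is the package's own and is not claimed to
replicate any particular published number.

Cross-validation can optionally warm-start each fold fit from the
participant's full-data optimum (`warm_start=True`); this suppresses
optimizer noise at reduced cost, affects all compared models identically,
and is used by the scaled-down model-recovery studies.

## Synthetic experiments

The generator emulates the study's structure: 12 participants, 645 uniform
trials (sessions 1 and 4) and 561 von Mises trials (sessions 2 and 3)
each, display set size 4, colors sampled i.i.d. with replacement, probe
uniform over the four items, prior mean drawn uniformly per participant
and stored in the table. Ground-truth parameters for recovery studies are
drawn uniformly from documented realistic ranges (`gamma_mean ∈ [2, 20]`,
`gamma_scale ∈ [0.5, 5]`, `p ∈ [0.5, 4]`, `T ∈ [1, 20]`, `α ∈ [0.5, 1.5]`,
`λ ∈ [0.01, 0.1]`, `κ_w ∈ [0.2, 2]`; the analogous constants for the
No-Knowledge/Limited/Fixed variants are `κ_fixed ∈ [2, 20]`,
`κ_threshold ∈ [0.5, 5]`, `κ_const ∈ [2, 20]`, chosen to span the same
precision regimes as the gamma ranges).

What the generator does *not* emulate: sequential effects, learning or
training of the prior, reaction times, color-space perceptual
nonuniformity, and any stimulus-driven encoding heterogeneity (encoding
precision is independent of the stimulus value). Passing tests therefore
demonstrate the internal consistency and statistical power of the
pipeline under the model's own assumptions — not that real observers obey
the model.

## Study sizes in the test suite

Everything stochastic is seeded. The suite runs scaled-down versions of
the validation studies chosen to keep the whole run within a practical
serial budget: parameter recovery uses 12 participants × 1,206 trials
(Known, 10 starts) and 4 participants for the joint YY fits;
model-recovery confusion studies use 6 participants × 600 uniform trials
(encoding family) or 5 participants × (240 uniform + 450 von Mises) joint
trials (prior-use family), 2-fold LLcv with warm-started fold fits and
fixed representative generating observers in the high-dispersion
precision regime; the Monte-Carlo likelihood oracle uses 12 parameter
sets per variant × 10⁶ draws × 2 response cells. With ~200 3-SE cell
comparisons a few excursions are expected by chance, so that gate
requires ≥98% of cells within 3 SE and all within 5 SE.

## Known limitations

- **Nested-model confusion.** Several family members are exactly nested at
  the optimum: fixed precision is the Known model with a degenerate gamma;
  No-Knowledge is the Limited model with a sub-support threshold; the
  prior-ignoring NN code is YY with `κ_w → 0`. Data generated by the
  simpler member can only be assigned to it by the cross-validation
  overfitting penalty of the richer member (~0.5–1 nat at k = 2), which is
  of the same order as the across-participant noise of the LLcv difference
  and is further damped by the derivative-free optimizer's implicit early
  stopping. Model-recovery confusion matrices therefore reliably separate
  non-nested directions (margins of 5–20 nats in the test suite) but can
  leave one nested row within a fraction of a nat of a tie at any
  practical study size. The Limited variant has a second, sharper
  identifiability hazard: its below-threshold branch (uniform estimate,
  uniform-utility arc) is behaviorally identical to a lapse trial, so
  unless the threshold leaves substantial mass on both sides — enough that
  lapse-mimicry would require a lapse rate above its bound — Limited data
  is nearly indistinguishable from No-Knowledge data in uniform sessions.
  The model-recovery study's generating threshold sits at the 60th
  percentile of the precision distribution for exactly this reason.
- The Limited variant's threshold makes its likelihood only piecewise
  smooth in `κ_threshold`; the multi-start derivative-free optimizer
  handles this but needs more starts than the smooth variants.
- `κ_w` trades off against the estimation exponent at realistic trial
  counts; its recovery tolerance (±30% median) reflects that intrinsic
  identifiability limit rather than optimizer failure.
- The hierarchical Bayes factor depends on a variational bound, which is
  conservative for the hierarchical model.
- Exceedance probabilities are Monte-Carlo estimates; their accuracy
  scales as n_samples^(−1/2).
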