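# Methods

## The problem

Studies of unconscious processing typically (a) measure each
participant's awareness of a masked stimulus with an objective test —
here a two-alternative forced-choice (2AFC) discrimination task whose
chance accuracy is 0.5 — and (b) measure an *effect score*, the
difference in some behavioral response between two experimental
conditions. Participants whose awareness score falls below an exclusion
threshold are declared "unaware", and a group-level effect in that
subsample is taken as evidence of unconscious processing.

The selection step is the problem. Awareness scores are noisy binomial
estimates, so the subsample selected as "unaware" contains truly aware
participants whose measurement error happened to push them below the
threshold. If aware participants carry larger (conscious) effects, the
selected group's mean effect is biased upward even when truly unaware
participants have no effect at all — a regression-to-the-mean (RttM)
artifact. The NPB (nonparametric bootstrap) test implemented in
`npbtest.npb` asks whether an observed group effect exceeds what RttM
alone could generate, without assuming any parametric relation between
awareness and effects.

## The NPB procedure

Let `h` be the initial exclusion threshold. In `auto` mode it is the
critical proportion of a two-sided binomial test against chance:
`h = q/n` where `n = round(mean awareness-trial count)` and `q` is the
smallest count with `BinomCDF(q; n, 0.5) >= 1 - alpha/2` (97.5th
percentile at the default `alpha = 0.05`). A `fixed` mode accepts a
researcher-chosen threshold in (0.5, 1].

**Step 1 — adjusted threshold.** With `delta = h - 0.5`, count
awareness scores in the negative interval `[0.5 - delta, 0.5)` (N−) and
the positive interval `[0.5, 0.5 + delta]` (N+; chance itself counts as
positive). Truly unaware participants are binomially symmetric around
chance, so surplus on the positive side signals contamination by aware
participants, summarized as `S = (N+/N−)² − 1`. If `S <= 0` the
threshold is kept; otherwise it is lowered to
`h_adj = h − S · 2/sqrt(4n)`, i.e. by S times two chance-level standard
deviations of an n-trial awareness score. When `N− = 0` while
`N+ > 0` the ratio is undefined; we substitute `N− = 1`, the largest
finite (most conservative) asymmetry for the observed N+. `h_adj` is
deliberately not clamped at 0.5 — if it falls below every score, no
participant is nullified and the null distribution is built entirely
from intact effects, which is conservative for this test.

**Step 2 — surrogate data.** Participants with score `<= h_adj` are
treated as truly unaware; their effects are nullified by permuting the
condition labels of their effect trials (zero expected effect,
marginals preserved). Participants above `h_adj` keep their observed
effects. Every participant's awareness score is then re-drawn from
`Binomial(n_i, observed score_i)/n_i` with their own trial count,
regenerating the measurement error that produces misclassification.

**Step 3 — decision.** Each surrogate iteration includes the
participants whose re-drawn score is strictly below the *initial*
threshold and averages their surrogate effects; 1,000 iterations (500
in the large simulation grids here) give the null distribution of
RttM-driven effects. The observed effect — the mean effect score over
participants strictly below `h` — is compared one-sidedly:
`p = (1 + #{null >= observed}) / (iterations + 1)`, significant at
`p < 0.05` (the 95th-percentile rule; the add-one convention keeps p
strictly positive). Tie handling is asymmetric by design: inclusion at
the initial threshold is strict (`< h`, matching the binomial test's
rejection region), classification at the adjusted threshold is
inclusive (`<= h_adj`).

Degenerate surrogate iterations whose inclusion set is empty are
re-drawn, up to 100 rounds, then reported as an analysis error; with
realistic samples this path is never taken. One master `Generator`
seeds the whole test and is consumed in a fixed order (bootstrap block,
then per-participant permutation blocks, then redraws), so identical
dataset + config yields a bit-identical result.

The test is a group-level decision only — it cannot classify an
individual participant as aware or unaware — and it tests a one-sided
alternative (effect larger than RttM could produce).

## Generative model for validation

`npbtest.simulate` generates trial-level datasets with a known ground
truth:

- A fraction `frac_unaware` of the `n_participants` (165 by default;
  round-half-up, unaware participants listed first) has true awareness
  exactly 0.5. The rest draw `0.5 + |Normal(0, sigma)|` with
  `sigma = 0.15` (mean aware accuracy `0.5 + sigma·sqrt(2/pi) ≈ 0.62`),
  clipped at 1.0 so values remain interpretable as accuracies.
- True effects, in Cohen's d units, are `d_unconscious` (0 or 0.2) for
  everyone plus, for aware participants only, a conscious component
  `f(a)` anchored at `f(0.5) = 0` and `f(1) = d_max = 1.2`. Five
  monotone shapes are provided via `u = (a − 0.5)/0.5`: linear `u`,
  quadratic `u²`, square root `sqrt(u)`, exponential
  `(e^{3u} − 1)/(e³ − 1)`, and a rescaled logistic with steepness 10.
  The shape constants (3 and 10) are fixed, exposed choices: steep
  enough to distinguish the shapes visually across `u ∈ [0, 1]` while
  preserving the anchors.
- Observed awareness is `Binomial(n_trials, true accuracy)`. Observed
  effect trials are generated per trial so the permutation step has
  labels to permute: `n_eff/2` trials per condition, means
  `± true_d/2`, per-trial SD `sqrt(n_eff)/2`. That SD makes the
  participant-level effect score exactly `Normal(true_d, 1)`: d is a
  standardized participant-level effect, which is what the default
  sample size presumes (165 = smallest n with 80% one-sided one-sample
  t-test power at d = 0.2, inflated by 1/0.95 for the ~5% of
  chance-level participants a binomial exclusion threshold falsely
  removes). Tying the trial noise to the trial count keeps the
  participant-level noise scale fixed while the number of trials — a
  manipulated factor — varies.
- The effect-trial count defaults to the awareness-trial count (a
  single "number of trials" factor).

What the generator does *not* emulate: heterogeneous effect metrics
(RTs vs accuracies), within-participant response autocorrelation,
non-Gaussian trial noise, unequal condition counts, or aware
participants with below-chance true accuracy. Passing simulation tests
therefore certify the statistical machinery under the stated model, not
robustness to those real-data features.

`run_experiment` crosses cells of this model, runs the NPB test on each
replicate dataset and tallies rejection rates with Monte-Carlo SE
`sqrt(r(1−r)/R)`. Per-replicate seeds derive from each cell's seed;
replicates whose observed effect is undefined count as non-rejections
and are tallied separately. The validation runs shipped in the tests
and `scripts/acceptance.py` use 300 replicates per cell and 500 NPB
iterations — the point where Monte-Carlo error (SE ≈ 1.3 percentage
points at a 5% rate) is small against the bands being checked.

## Reliability analysis

`split_half_reliability` randomly splits each participant's awareness
trials into two near-equal halves (odd counts split ceil/floor), takes
each half's accuracy with its own denominator, correlates the halves
across participants (Pearson) and applies the Spearman–Brown prophecy
correction `2r/(1 + r)`, summarizing over 5,000 splits by default with
a 2.5/97.5-percentile CI. Splits in which either half has zero variance
across participants have no defined correlation; they are scored 0 and
counted rather than dropped, because dropping them biases the mean
upward precisely in the near-chance samples of interest. The
acceptability threshold is the conventional 0.7.

The accompanying simulation (`reliability_simulation`) draws
awareness-only samples under the generative model across unaware
fractions and trial counts. It reproduces the diagnostic pattern: with
fully unaware samples, true scores carry no between-participant
variance, so reliability is distributed around zero at every trial
count — low reliability is the *expected signature* of effective
masking, not evidence of a bad measure.

## Power planning

`npbtest.power` computes exact binomial detection power (no normal
approximation): the one-sided critical count is the smallest `c` with
`P(X >= c | n, 0.5) <= alpha`, and power is `P(X >= c | n, p_true)`.
Because exact power is non-monotone in n (sawtooth as the rejection
region jumps), `min_trials_for_power` scans every n and returns the
first crossing. The one-sided convention is adopted because it is the
exclusion test the simulation framework uses and it reproduces the
design points 23 (accuracy 0.8), 213 (0.6) and 866 (0.55) trials for
90% power. `t_test_sample_size` wraps the noncentral-t one-sample power
of `statsmodels` with the exclusion-rate inflation described above.

## Numerical notes and limitations

- The NPB surrogate loop is vectorized across iterations (one binomial
  block; one row-shuffle block per nullified participant, exploiting
  that a label permutation only re-selects which responses carry label
  A), which is what makes 300-replicate grids tractable on one core.
- All empirical claims in the README are outputs of the shipped code
  paths at the stated seeds; rejection-rate bands are Monte-Carlo
  estimates with the SEs printed beside them.
- Reported p-values are lower-bounded at `1/(iterations+1)`; with few
  iterations the test is conservative near the decision boundary.
- The split-half CI describes variability across random splits of one
  sample, not sampling variability across studies.
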