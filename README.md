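# npbtest

Nonparametric bootstrap (NPB) testing of unconscious-processing effects
against a regression-to-the-mean (RttM) null.

## The problem this package addresses

Unconscious-processing studies select participants as "unaware" when
their score on an objective awareness test (typically 2AFC
discrimination, chance = 0.5) falls below a threshold, then test for a
group-level effect — a condition difference in some behavioral
response — within that subsample. Because awareness scores are noisy,
the selected subsample contains truly aware participants whose
measurement error pushed them below the threshold; if awareness and
effects are related, their conscious effects inflate the subsample mean
even when no unconscious effect exists. This regression-to-the-mean
artifact can manufacture "unconscious" effects out of nothing.

The NPB test decides whether an observed subsample effect exceeds what
RttM alone could produce, making no assumptions about the form of the
awareness–effect relation:

1. From the initial threshold *h* (the two-sided binomial-test critical
   value by default), measure the asymmetry of awareness scores around
   chance, *S* = (N₊/N₋)² − 1, and derive a stricter threshold
   *h*_adj = *h* − *S*·2/√(4n) (when *S* > 0) below which participants
   are almost certainly unaware.
2. Build surrogate datasets: permute condition labels (nullifying the
   effect) for participants at or below *h*_adj, keep everyone else's
   effect, and re-draw every awareness score from
   Binomial(nᵢ, observed scoreᵢ)/nᵢ.
3. Each surrogate iteration averages the effects of participants whose
   re-drawn score falls below *h*; the observed effect is significant
   if it exceeds the 95th percentile of these RttM-driven null effects
   (add-one permutation p-value).

The package also ships the machinery to validate and plan such
analyses: a trial-level synthetic-data generator with known ground
truth, Monte-Carlo type-I/power experiment grids, split-half
(Spearman–Brown) reliability analysis of awareness measures, and exact
binomial power / t-test sample-size calculators.

## Worked example

Simulate a study in which all 60 participants are truly unaware but
carry a genuine unconscious effect of d = 0.2, then test it:

```bash
$ cat sim.yaml
n_participants: 60
frac_unaware: 1.0
d_unconscious: 0.2
n_awareness_trials: 100

$ npb simulate --config sim.yaml --seed 7 --out demo.csv --truth truth.csv
$ npb test demo.csv --iterations 1000 --seed 1 --out result.json
h=0.6000 S=-0.1900 h_adj=0.6000 included=57 nullified=58
observed_effect=0.240918 p=0.0480 significant=True
```

Reading the output: with 100 awareness trials the automatic initial
threshold is 0.60 (binomial critical proportion). The awareness scores
are slightly *negatively* asymmetric around chance (S = −0.19), so no
adjustment is needed (h_adj = h); 58 participants score at or below
h_adj and have their effects nullified in the surrogate data, and 57
fall strictly below h and form the observed subsample, whose mean
effect is 0.24. That observed effect exceeds the 95th percentile of
1,000 RttM-driven null effects (p = 0.048): the effect is unlikely to
be a selection artifact — as it should be, since the simulated ground
truth contains a real unconscious effect.

`result.json` holds every quantity above plus the full null-effect
vector; a `result.json.manifest.json` records the resolved
configuration and seed for exact reproduction.

Power planning from the same toolbox — the minimum number of 2AFC
trials for a one-sided binomial test (α = .05) to detect an aware
participant with true accuracy 0.8 at 90% power:

```bash
$ npb power --accuracy 0.8 --target 0.9
23
```

The same query at accuracy 0.6 returns 213, and at 0.55, 866 — near-
chance awareness needs an order of magnitude more trials to detect.

The library mirrors the CLI: `npbtest.npb_test`, `simulate_dataset`,
`run_experiment`, `split_half_reliability`, `min_trials_for_power`,
`t_test_sample_size`.

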