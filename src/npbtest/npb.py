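"""Nonparametric bootstrap (NPB) test for regression-to-the-mean (RttM).

When participants are selected post hoc as "unaware" by a noisy 2AFC
awareness measure, the selected group contains truly aware participants
whose measurement error pushed them below the exclusion threshold.
Their (conscious) effects then contaminate the group-level effect — the
regression-to-the-mean threat. The NPB test asks whether an observed
group effect exceeds what RttM alone could produce, in three steps:

1. *Adjusted threshold.* Start from an initial exclusion threshold ``h``
   (by default the 97.5th percentile of the chance binomial
   distribution, i.e. the two-sided binomial-test critical value).
   Count included participants in the equal-width intervals just below
   and just above chance; asymmetry toward the positive side signals
   contamination by aware participants, quantified as
   ``S = (N+/N-)^2 - 1``. When ``S > 0`` the threshold is lowered to
   ``h_adj = h - S * 2/sqrt(4n)`` (S times two chance-level SDs of the
   mean awareness score over ``n`` trials); otherwise ``h_adj = h``.
2. *Surrogate data.* Participants at or below ``h_adj`` are treated as
   truly unaware and their effects are nullified by permuting each
   trial's condition label; participants above ``h_adj`` keep their
   observed effects. Every participant's awareness score is then
   re-drawn from Binomial(n_trials, observed score)/n_trials,
   re-creating the measurement error that drives misclassification.
3. *Decision.* Each surrogate iteration includes the participants whose
   re-drawn awareness score falls below the *initial* threshold and
   averages their (surrogate) effect scores, yielding one draw from the
   null distribution of RttM-driven effects. The observed effect is
   compared against this distribution one-sidedly; the test is
   significant when the observed effect exceeds the null's 95th
   percentile (add-one permutation p-value, so p is never exactly 0).

The test is a group-level decision; it says nothing about whether any
individual participant was aware.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import AnalysisError, ParticipantRecord, StudyDataset, ValidationError

__all__ = [
    "NPBConfig",
    "NPBResult",
    "initial_threshold",
    "asymmetry_S",
    "adjusted_threshold",
    "classify_participants",
    "nullify_effect",
    "bootstrap_awareness",
    "surrogate_effect",
    "npb_test",
]


@dataclass(frozen=True)
class NPBConfig:
    """Parameters of the NPB test.

    ``two_sided_alpha`` controls the automatic initial threshold (the
    97.5th binomial percentile at the default 0.05); the significance
    decision itself is one-sided at the 95th percentile of the null.
    """

    initial_threshold_mode: str = "auto"  # "auto" | "fixed"
    fixed_h: float | None = None
    two_sided_alpha: float = 0.05
    n_iterations: int = 1000
    seed: int = 0
    inclusion_rule: str = "strict_below"
    decision_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.initial_threshold_mode not in ("auto", "fixed"):
            raise ValidationError("initial_threshold_mode must be 'auto' or 'fixed'")
        if not 0.0 < self.two_sided_alpha < 1.0:
            raise ValidationError("two_sided_alpha must lie in (0, 1)")
        if self.n_iterations < 100:
            raise ValidationError("n_iterations must be at least 100")
        if self.initial_threshold_mode == "fixed":
            if self.fixed_h is None or not 0.5 < self.fixed_h <= 1.0:
                raise ValidationError("fixed_h must lie in (0.5, 1] when mode='fixed'")
        if self.inclusion_rule != "strict_below":
            raise ValidationError("only the 'strict_below' inclusion rule is supported")


@dataclass
class NPBResult:
    """Full audit trail of one NPB run."""

    h: float
    delta: float
    n_pos: int
    n_neg: int
    S: float
    h_adj: float
    avg_awareness_trials: float
    observed_effect: float
    null_effects: np.ndarray
    p_value: float
    significant: bool
    n_included_observed: int
    n_truly_unaware_classified: int

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["null_effects"] = np.asarray(self.null_effects).tolist()
        return d


# --- Step 1: thresholds -------------------------------------------------


def initial_threshold(avg_trials: float, two_sided_alpha: float = 0.05) -> float:
    """Critical proportion of a two-sided binomial test against chance.

    Returns ``q / round(avg_trials)`` where ``q`` is the smallest count
    with ``BinomCDF(q; round(avg_trials), 0.5) >= 1 - alpha/2``.
    """
    if avg_trials < 1:
        raise ValidationError("avg_trials must be >= 1")
    n = int(round(avg_trials))
    target = 1.0 - two_sided_alpha / 2.0
    # ppf gives the smallest q with CDF(q) >= target
    q = int(stats.binom.ppf(target, n, 0.5))
    return q / n


def asymmetry_S(awareness_scores: np.ndarray, h: float) -> tuple[int, int, float]:
    """Count scores in the chance-symmetric intervals and form S.

    With ``delta = h - 0.5``, the negative interval is
    ``[0.5 - delta, 0.5)`` and the positive interval ``[0.5, 0.5 + delta]``
    (chance itself belongs to the positive half; scores outside the band
    are not counted). ``S = (N+/N-)^2 - 1``: zero for a symmetric
    distribution, positive when aware participants contaminate the
    positive half. ``N- = 0`` with ``N+ > 0`` is treated as ``N- = 1``,
    the most conservative finite value.
    """
    if h <= 0.5:
        raise ValidationError("initial threshold h must exceed 0.5")
    scores = np.asarray(awareness_scores, dtype=np.float64)
    delta = h - 0.5
    n_neg = int(np.count_nonzero((scores >= 0.5 - delta) & (scores < 0.5)))
    n_pos = int(np.count_nonzero((scores >= 0.5) & (scores <= 0.5 + delta)))
    if n_pos == 0 and n_neg == 0:
        warnings.warn("no awareness scores within the chance band; S set to 0")
        return 0, 0, 0.0
    denom = n_neg if n_neg > 0 else 1
    S = (n_pos / denom) ** 2 - 1.0
    return n_pos, n_neg, S


def adjusted_threshold(h: float, S: float, n: float) -> float:
    """Lower ``h`` by S times two chance-level SDs of the mean score.

    The SD of a chance-level awareness score over ``n`` trials is
    ``sqrt(0.25/n) = 1/sqrt(4n)``; the adjustment subtracts
    ``S * 2/sqrt(4n)``. No adjustment when ``S <= 0``. The result is
    deliberately not clamped at 0.5: an adjusted threshold below every
    score simply means no participant is nullified, which is
    conservative by construction.
    """
    if h <= 0.5:
        raise ValidationError("initial threshold h must exceed 0.5")
    if n < 1:
        raise ValidationError("n must be >= 1")
    if S <= 0:
        return h
    return h - S * 2.0 / np.sqrt(4.0 * n)


# --- Step 2: surrogate-data building blocks -----------------------------


def classify_participants(
    dataset: StudyDataset, h_adj: float
) -> tuple[list[int], list[int]]:
    """Partition participant indices by the adjusted threshold.

    ``truly_unaware``: awareness score <= h_adj (ties go to unaware);
    ``potentially_aware``: the rest. Exhaustive and disjoint.
    """
    truly_unaware, potentially_aware = [], []
    for i, p in enumerate(dataset.participants):
        (truly_unaware if p.awareness_score <= h_adj else potentially_aware).append(i)
    return truly_unaware, potentially_aware


def nullify_effect(record: ParticipantRecord, rng: np.random.Generator) -> ParticipantRecord:
    """Permute the condition labels of a participant's effect trials.

    Destroys any condition-response association (average permuted effect
    score is zero) while preserving the responses and the multiset of
    labels.
    """
    return record.with_conditions(rng.permutation(record.effect_condition))


def bootstrap_awareness(score: float, n_trials: int, rng: np.random.Generator) -> float:
    """Re-draw an awareness score from Binomial(n_trials, score)/n_trials."""
    if not 0.0 <= score <= 1.0:
        raise ValidationError("score must lie in [0, 1]")
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    return float(rng.binomial(n_trials, score)) / n_trials


@dataclass
class _StudyArrays:
    """Flat array view of a dataset, precomputed once per test."""

    scores: np.ndarray          # observed awareness score per participant
    n_trials: np.ndarray        # awareness trial count per participant
    effects: np.ndarray         # observed effect score per participant
    responses: list[np.ndarray] # effect responses, A-labeled trials first
    n_a: np.ndarray             # number of A-labeled effect trials
    n_b: np.ndarray

    @classmethod
    def from_dataset(cls, dataset: StudyDataset) -> "_StudyArrays":
        scores, n_trials, effects, responses, n_a, n_b = [], [], [], [], [], []
        for p in dataset.participants:
            is_a = p.effect_condition == "A"
            scores.append(p.awareness_score)
            n_trials.append(p.n_awareness_trials)
            effects.append(p.effect_score)
            responses.append(np.concatenate([p.effect_response[is_a], p.effect_response[~is_a]]))
            n_a.append(int(is_a.sum()))
            n_b.append(int((~is_a).sum()))
        return cls(
            scores=np.array(scores),
            n_trials=np.array(n_trials, dtype=np.int64),
            effects=np.array(effects),
            responses=responses,
            n_a=np.array(n_a, dtype=np.int64),
            n_b=np.array(n_b, dtype=np.int64),
        )


def _surrogate_null(
    arrays: _StudyArrays,
    unaware: np.ndarray,
    h: float,
    n_iterations: int,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> np.ndarray:
    """Draw ``n_iterations`` values from the RttM null distribution.

    Per iteration: every participant's awareness score is re-drawn
    binomially; truly-unaware participants' effect scores are replaced
    by a fresh label-permutation draw; the iteration's value is the mean
    surrogate effect over participants whose re-drawn score is strictly
    below ``h``. Iterations with an empty inclusion set are re-drawn
    (bounded retries).

    Vectorized over iterations: one binomial block, then one permutation
    block per truly-unaware participant. A label permutation only moves
    which responses carry label A, so the permuted effect score is
    ``X/nA - (T - X)/nB`` with ``X`` the sum of a uniformly random
    nA-subset of the responses — realised by row-wise shuffles.
    """
    m = arrays.scores.size
    B = n_iterations
    boot = rng.binomial(arrays.n_trials, arrays.scores, size=(B, m)) / arrays.n_trials
    include = boot < h

    eff = np.broadcast_to(arrays.effects, (B, m)).copy()
    for j in unaware:
        resp = arrays.responses[j]
        na, nb = int(arrays.n_a[j]), int(arrays.n_b[j])
        perm = rng.permuted(np.tile(resp, (B, 1)), axis=1)
        x = perm[:, :na].sum(axis=1)
        eff[:, j] = x / na - (resp.sum() - x) / nb

    counts = include.sum(axis=1)
    null = (eff * include).sum(axis=1) / np.maximum(counts, 1)

    bad = np.flatnonzero(counts == 0)
    retries = 0
    while bad.size > 0:
        if retries >= max_retries:
            raise AnalysisError(
                "surrogate iteration produced an empty inclusion set "
                f"after {max_retries} redraws"
            )
        # redraw only the failed iterations, continuing the same stream
        boot_b = rng.binomial(arrays.n_trials, arrays.scores, size=(bad.size, m)) / arrays.n_trials
        include_b = boot_b < h
        eff_b = np.broadcast_to(arrays.effects, (bad.size, m)).copy()
        for j in unaware:
            resp = arrays.responses[j]
            na, nb = int(arrays.n_a[j]), int(arrays.n_b[j])
            perm = rng.permuted(np.tile(resp, (bad.size, 1)), axis=1)
            x = perm[:, :na].sum(axis=1)
            eff_b[:, j] = x / na - (resp.sum() - x) / nb
        counts_b = include_b.sum(axis=1)
        null[bad] = (eff_b * include_b).sum(axis=1) / np.maximum(counts_b, 1)
        bad = bad[counts_b == 0]
        retries += 1
    return null


def surrogate_effect(
    dataset: StudyDataset,
    partition: tuple[list[int], list[int]],
    h: float,
    rng: np.random.Generator,
) -> float:
    """One draw from the RttM null distribution (see :func:`_surrogate_null`)."""
    if h <= 0.5:
        raise ValidationError("initial threshold h must exceed 0.5")
    arrays = _StudyArrays.from_dataset(dataset)
    unaware = np.asarray(partition[0], dtype=np.int64)
    return float(_surrogate_null(arrays, unaware, h, 1, rng)[0])


# --- Step 3: the test ---------------------------------------------------


def npb_test(dataset: StudyDataset, config: NPBConfig | None = None) -> NPBResult:
    """Run the full three-step NPB test on a study dataset.

    The observed effect is the mean effect score over participants whose
    awareness score is strictly below the initial threshold. The
    p-value uses the add-one permutation convention
    ``(1 + #{null >= observed}) / (n_iterations + 1)`` and the test is
    significant one-sidedly at ``decision_alpha`` (the 95th-percentile
    rule at the default 0.05).
    """
    config = config or NPBConfig()
    arrays = _StudyArrays.from_dataset(dataset)

    if config.initial_threshold_mode == "auto":
        h = initial_threshold(dataset.avg_awareness_trials, config.two_sided_alpha)
    else:
        h = float(config.fixed_h)  # type: ignore[arg-type]

    included = arrays.scores < h
    if not included.any():
        raise AnalysisError("no participants below initial threshold")
    observed_effect = float(arrays.effects[included].mean())

    n_pos, n_neg, S = asymmetry_S(arrays.scores, h)
    n_avg = dataset.avg_awareness_trials
    h_adj = adjusted_threshold(h, S, n_avg)

    unaware_idx, _aware_idx = classify_participants(dataset, h_adj)
    unaware = np.asarray(unaware_idx, dtype=np.int64)

    rng = np.random.default_rng(config.seed)
    null = _surrogate_null(arrays, unaware, h, config.n_iterations, rng)

    b = int(np.count_nonzero(null >= observed_effect))
    p_value = (1.0 + b) / (config.n_iterations + 1.0)

    return NPBResult(
        h=h,
        delta=h - 0.5,
        n_pos=n_pos,
        n_neg=n_neg,
        S=S,
        h_adj=h_adj,
        avg_awareness_trials=n_avg,
        observed_effect=observed_effect,
        null_effects=null,
        p_value=p_value,
        significant=p_value < config.decision_alpha,
        n_included_observed=int(included.sum()),
        n_truly_unaware_classified=int(unaware.size),
    )
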