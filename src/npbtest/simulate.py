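"""Trial-level synthetic data generator and Monte-Carlo experiment runner.

The generative model mixes truly unaware participants, whose true 2AFC
awareness accuracy is exactly chance (0.5), with aware participants
whose true accuracy is 0.5 + |Normal(0, sigma)| — a half-normal shifted
to chance, clipped at 1.0 (sigma = 0.15 by default, expected aware mean
0.5 + sigma*sqrt(2/pi) ≈ 0.62). Observed awareness is binomially
sampled over the configured number of trials.

Each participant's true effect, in Cohen's d units on the participant
scale, is the sum of an unconscious component (d_unconscious, shared by
everyone) and — for aware participants only — a conscious component
that grows monotonically with true awareness up to d_max at full
awareness, through one of five anchored relation shapes (linear,
exponential, quadratic, logistic, square root).

Effect trials are generated at trial level so the condition labels the
NPB permutation step needs actually exist: half the trials carry
condition A with mean +d/2, half condition B with mean -d/2, with a
per-trial SD of sqrt(n_eff)/2 so that the participant's effect score
(mean A - mean B) is distributed Normal(d, 1). The unit participant-
level SD puts d on the conventional Cohen's d scale, which is what the
default sample size of 165 (80% one-sided t-test power at d = 0.2,
inflated for 5% expected exclusions) presumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import ParticipantRecord, StudyDataset, ValidationError
from .npb import NPBConfig, npb_test
from .datamodel import AnalysisError

__all__ = [
    "SimConfig",
    "ExperimentResult",
    "RELATIONS",
    "sample_true_awareness",
    "relation_effect",
    "simulate_participant",
    "simulate_dataset",
    "run_experiment",
]

RELATIONS = ("linear", "exponential", "quadratic", "logistic", "square_root")

_EXP_K = 3.0
_LOGISTIC_K = 10.0


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one simulation cell."""

    n_participants: int = 165
    frac_unaware: float = 1.0
    sigma_aware: float = 0.15
    d_unconscious: float = 0.0
    d_max: float = 1.2
    relation: str = "linear"
    n_awareness_trials: int = 200
    n_effect_trials: int | None = None  # defaults to n_awareness_trials
    seed: int = 0
    n_replicates: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_unaware <= 1.0:
            raise ValidationError("frac_unaware must lie in [0, 1]")
        if self.sigma_aware <= 0:
            raise ValidationError("sigma_aware must be positive")
        if self.d_unconscious < 0 or self.d_max < self.d_unconscious:
            raise ValidationError("require d_max >= d_unconscious >= 0")
        if self.relation not in RELATIONS:
            raise ValidationError(f"relation must be one of {RELATIONS}")
        if self.n_awareness_trials < 2 or self.effect_trials < 2:
            raise ValidationError("trial counts must be >= 2")
        if self.effect_trials % 2 != 0:
            raise ValidationError("n_effect_trials must be even (half per condition)")

    @property
    def effect_trials(self) -> int:
        return self.n_effect_trials if self.n_effect_trials is not None else self.n_awareness_trials


@dataclass
class ExperimentResult:
    """Rejection rates per simulation cell, with per-replicate p-values."""

    table: pd.DataFrame
    p_values: dict[tuple, np.ndarray]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def sample_true_awareness(
    n: int, frac_unaware: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """True 2AFC accuracies: chance for the unaware, shifted half-normal else.

    The first ``round(n * frac_unaware)`` entries (round half up) are
    exactly 0.5; the rest are 0.5 + |Normal(0, sigma)| clipped at 1.0.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    n_unaware = int(math.floor(n * frac_unaware + 0.5))
    out = np.full(n, 0.5)
    n_aware = n - n_unaware
    if n_aware > 0:
        out[n_unaware:] = np.minimum(0.5 + np.abs(rng.normal(0.0, sigma, n_aware)), 1.0)
    return out


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def relation_effect(a, relation: str, d_max: float = 1.2):
    """Conscious effect component as a function of true awareness.

    Each shape is a monotone non-decreasing map anchored at
    ``f(0.5) = 0`` and ``f(1) = d_max``, parameterized through
    ``u = (a - 0.5)/0.5``. Accepts scalars or arrays.
    """
    a_arr = np.asarray(a, dtype=np.float64)
    if np.any(a_arr < 0.5) or np.any(a_arr > 1.0):
        raise ValidationError("true awareness must lie in [0.5, 1]")
    u = (a_arr - 0.5) / 0.5
    if relation == "linear":
        out = d_max * u
    elif relation == "quadratic":
        out = d_max * u ** 2
    elif relation == "square_root":
        out = d_max * np.sqrt(u)
    elif relation == "exponential":
        k = _EXP_K
        out = d_max * (np.exp(k * u) - 1.0) / (np.exp(k) - 1.0)
    elif relation == "logistic":
        k = _LOGISTIC_K
        lo = _logistic(-k / 2.0)
        hi = _logistic(k / 2.0)
        out = d_max * (_logistic(k * (u - 0.5)) - lo) / (hi - lo)
    else:
        raise ValidationError(f"unknown relation {relation!r}")
    return out if np.ndim(a) else float(out)


def simulate_participant(
    true_a: float,
    true_d: float,
    n_aw: int,
    n_eff: int,
    rng: np.random.Generator,
    participant_id: str = "p0",
) -> ParticipantRecord:
    """Generate one participant's trial-level data.

    Awareness: ``n_aw`` Bernoulli(true_a) trials. Effect: ``n_eff/2``
    trials per condition with means ±true_d/2 and per-trial SD
    sqrt(n_eff)/2, so the effect score is Normal(true_d, 1).
    """
    if n_aw < 2 or n_eff < 2:
        raise ValidationError("trial counts must be >= 2")
    if n_eff % 2 != 0:
        raise ValidationError("n_eff must be even")
    half = n_eff // 2
    trial_sd = math.sqrt(n_eff) / 2.0
    awareness = rng.binomial(1, true_a, n_aw)
    resp_a = rng.normal(true_d / 2.0, trial_sd, half)
    resp_b = rng.normal(-true_d / 2.0, trial_sd, half)
    return ParticipantRecord(
        participant_id=participant_id,
        awareness_correct=awareness,
        effect_condition=np.array(["A"] * half + ["B"] * half),
        effect_response=np.concatenate([resp_a, resp_b]),
    )


def simulate_dataset(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[StudyDataset, pd.DataFrame]:
    """Generate a full study dataset plus its latent truth table.

    The truth table records, per participant, the true awareness, the
    true total effect (unconscious + conscious component) and the
    unaware flag — the ground truth simulations validate against.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_participants
    n_unaware = int(math.floor(n * config.frac_unaware + 0.5))
    true_a = sample_true_awareness(n, config.frac_unaware, config.sigma_aware, rng)
    unaware_flag = np.arange(n) < n_unaware
    conscious = np.zeros(n)
    if (~unaware_flag).any():
        conscious[~unaware_flag] = relation_effect(
            true_a[~unaware_flag], config.relation, config.d_max
        )
    true_d = config.d_unconscious + conscious

    records = [
        simulate_participant(
            true_a[i], true_d[i], config.n_awareness_trials, config.effect_trials,
            rng, participant_id=f"p{i:04d}",
        )
        for i in range(n)
    ]
    truth = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "true_awareness": true_a,
            "true_effect": true_d,
            "unaware": unaware_flag,
        }
    )
    return StudyDataset(participants=records), truth


def run_experiment(
    grid: list[SimConfig],
    npb_config: NPBConfig | None = None,
    decision_alpha: float = 0.05,
    progress: bool = False,
) -> ExperimentResult:
    """Monte-Carlo rejection rates of the NPB test over a grid of cells.

    Per cell, ``n_replicates`` datasets are generated and tested;
    the rejection rate is the fraction with p < ``decision_alpha``
    (one-sided), with Monte-Carlo SE ``sqrt(r(1-r)/n_replicates)``.
    Replicates where the observed effect is undefined (no participant
    below the initial threshold) count as non-rejections and are
    tallied separately. Per-replicate seeds derive deterministically
    from each cell's seed.
    """
    npb_config = npb_config or NPBConfig()
    rows = []
    p_values: dict[tuple, np.ndarray] = {}
    for cell in grid:
        master = np.random.default_rng(cell.seed)
        pvals = np.full(cell.n_replicates, np.nan)
        n_undefined = 0
        for rep in range(cell.n_replicates):
            data_seed, test_seed = master.integers(2 ** 31, size=2)
            data_rng = np.random.default_rng(int(data_seed))
            dataset, _truth = simulate_dataset(cell, data_rng)
            try:
                res = npb_test(dataset, replace(npb_config, seed=int(test_seed)))
                pvals[rep] = res.p_value
            except AnalysisError:
                n_undefined += 1
            if progress and (rep + 1) % 50 == 0:
                print(f"  cell {cell.relation}/{cell.frac_unaware}/"
                      f"{cell.n_awareness_trials}t: {rep + 1}/{cell.n_replicates}")
        rej = np.nansum(pvals < decision_alpha)
        rate = float(rej) / cell.n_replicates
        key = (cell.relation, cell.frac_unaware, cell.n_awareness_trials, cell.d_unconscious)
        p_values[key] = pvals
        rows.append(
            {
                "relation": cell.relation,
                "frac_unaware": cell.frac_unaware,
                "n_trials": cell.n_awareness_trials,
                "d_unconscious": cell.d_unconscious,
                "n_replicates": cell.n_replicates,
                "rejection_rate": rate,
                "mc_se": math.sqrt(rate * (1.0 - rate) / cell.n_replicates),
                "n_undefined": n_undefined,
            }
        )
    return ExperimentResult(table=pd.DataFrame(rows), p_values=p_values)
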