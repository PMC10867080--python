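"""Split-half reliability of awareness measures, Spearman–Brown corrected.

Split-half reliability randomly divides each participant's awareness
trials into two halves, correlates the per-half accuracies across
participants, and corrects the half-test correlation to full length
with the Spearman–Brown prophecy formula 2r/(1+r). Crucially, when a
sample consists of truly unaware participants, the true scores carry no
between-participant variability, so the correlation is driven entirely
by random measurement error and reliability is expected to center on
zero — low reliability is then a signature of effective masking, not of
a bad measure. The simulation here reproduces that behavior across
unaware-fraction and trial-count grids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import StudyDataset, ValidationError

__all__ = [
    "ReliabilityResult",
    "spearman_brown",
    "split_half_reliability",
    "reliability_simulation",
]

ACCEPTABLE_RELIABILITY = 0.7


@dataclass
class ReliabilityResult:
    """Summary of corrected split-half correlations across random splits."""

    mean_corrected_r: float
    ci_low: float
    ci_high: float
    n_splits: int
    n_degenerate: int
    acceptable: bool
    corrected_r: np.ndarray  # full per-split vector

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "corrected_r"}
        return d


def spearman_brown(r: float) -> float:
    """Prophecy correction 2r/(1+r) of a half-test correlation."""
    if not -1.0 <= r <= 1.0:
        raise ValidationError("correlation must lie in [-1, 1]")
    if r == -1.0:
        raise ValidationError("Spearman-Brown correction is undefined at r = -1")
    return 2.0 * r / (1.0 + r)


def _split_halves(
    trials: np.ndarray, n_splits: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random near-equal splits of one participant's 0/1 trial vector.

    Returns per-split accuracies of each half, shape (n_splits,).
    Odd counts split ceil/floor with random assignment; each half uses
    its own denominator.
    """
    n = trials.size
    n1 = (n + 1) // 2
    perm = rng.permuted(np.tile(trials, (n_splits, 1)), axis=1)
    return perm[:, :n1].mean(axis=1), perm[:, n1:].mean(axis=1)


def _rowwise_pearson(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r between matching rows; flags rows with zero variance."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = (xc ** 2).sum(axis=1)
    sy = (yc ** 2).sum(axis=1)
    degenerate = (sx == 0) | (sy == 0)
    denom = np.sqrt(sx * sy)
    denom[degenerate] = 1.0
    r = (xc * yc).sum(axis=1) / denom
    r[degenerate] = 0.0
    return r, degenerate


def _split_half_from_matrix(
    trials_by_participant: list[np.ndarray], n_splits: int, rng: np.random.Generator
) -> ReliabilityResult:
    n_participants = len(trials_by_participant)
    half1 = np.empty((n_splits, n_participants))
    half2 = np.empty((n_splits, n_participants))
    for j, trials in enumerate(trials_by_participant):
        half1[:, j], half2[:, j] = _split_halves(trials, n_splits, rng)

    r, degenerate = _rowwise_pearson(half1, half2)
    # r = -1 would make the correction blow up; with binary accuracies it
    # only occurs in degenerate two-participant edge cases — score it 0.
    invalid = r <= -1.0
    corrected = np.zeros(n_splits)
    ok = ~degenerate & ~invalid
    corrected[ok] = 2.0 * r[ok] / (1.0 + r[ok])
    n_degenerate = int((degenerate | invalid).sum())

    mean_r = float(corrected.mean())
    ci_low, ci_high = np.percentile(corrected, [2.5, 97.5])
    return ReliabilityResult(
        mean_corrected_r=mean_r,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_splits=n_splits,
        n_degenerate=n_degenerate,
        acceptable=mean_r >= ACCEPTABLE_RELIABILITY,
        corrected_r=corrected,
    )


def split_half_reliability(
    dataset: StudyDataset, n_splits: int = 5000, rng: np.random.Generator | None = None
) -> ReliabilityResult:
    """Split-half reliability of a dataset's awareness measure.

    Per split, each participant's awareness trials are randomly
    partitioned into two near-equal halves and the per-half accuracies
    are correlated across participants (Pearson), then Spearman–Brown
    corrected. Splits where either half-vector has zero variance across
    participants yield an undefined correlation; they are scored 0 and
    counted in ``n_degenerate`` rather than dropped, since dropping
    would bias near-chance samples upward. The 95% CI is the 2.5/97.5
    percentile of the corrected values across splits.
    """
    if len(dataset) < 3:
        raise ValidationError("split-half reliability needs at least 3 participants")
    if n_splits < 1:
        raise ValidationError("n_splits must be >= 1")
    for p in dataset.participants:
        if p.n_awareness_trials < 2:
            raise ValidationError(
                f"participant {p.participant_id!r} has fewer than 2 awareness trials"
            )
    rng = rng if rng is not None else np.random.default_rng()
    trials = [p.awareness_correct.astype(np.float64) for p in dataset.participants]
    return _split_half_from_matrix(trials, n_splits, rng)


def reliability_simulation(
    frac_unaware_grid=(0.0, 0.25, 0.5, 0.75, 1.0),
    n_trials_grid=(30, 50, 200, 500),
    n_participants: int = 165,
    sigma_aware: float = 0.15,
    n_replicates: int = 100,
    n_splits: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Distribution of corrected reliability over a simulation grid.

    Awareness-only simulation: per cell, ``n_replicates`` samples of
    ``n_participants`` are drawn under the generative awareness model
    (chance for the unaware fraction, shifted half-normal otherwise;
    binomial observed trials), and split-half reliability is computed
    for each. Returns one row per cell with the mean, quantiles and the
    fraction of replicates reaching the 0.7 acceptability threshold.
    """
    from .simulate import sample_true_awareness  # local to avoid cycle

    master = np.random.default_rng(seed)
    rows = []
    for frac in frac_unaware_grid:
        for n_trials in n_trials_grid:
            rng = np.random.default_rng(int(master.integers(2 ** 31)))
            means = np.empty(n_replicates)
            for rep in range(n_replicates):
                true_a = sample_true_awareness(n_participants, frac, sigma_aware, rng)
                trials_mat = (
                    rng.random((n_participants, n_trials)) < true_a[:, None]
                ).astype(np.float64)
                res = _split_half_from_matrix(list(trials_mat), n_splits, rng)
                means[rep] = res.mean_corrected_r
            rows.append(
                {
                    "frac_unaware": frac,
                    "n_trials": n_trials,
                    "n_replicates": n_replicates,
                    "mean_r": float(means.mean()),
                    "q05": float(np.percentile(means, 5)),
                    "q95": float(np.percentile(means, 95)),
                    "frac_acceptable": float((means >= ACCEPTABLE_RELIABILITY).mean()),
                }
            )
    return pd.DataFrame(rows)
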