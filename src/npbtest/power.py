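"""Exact binomial detection power and t-test sample-size planning.

How many 2AFC trials does it take for a one-sided binomial test against
chance (p = 0.5) to detect an aware participant? Exact binomial sums —
no normal approximation — because the sawtooth non-monotonicity of
exact power in n matters near the usual design points (e.g. 23 trials
for 90% power at accuracy 0.8, but 213 at 0.6 and 866 at 0.55).

Also provides the one-sample noncentral-t sample-size helper used to
size group-level designs, with an inflation factor for expected
post-hoc exclusions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.power import TTestPower

from .datamodel import AnalysisError, ValidationError

__all__ = [
    "PowerCurve",
    "binomial_critical_count",
    "binomial_power",
    "min_trials_for_power",
    "t_test_sample_size",
    "power_curve",
]


@dataclass
class PowerCurve:
    """Exact binomial detection power over a grid of trial counts."""

    n_grid: np.ndarray
    critical_counts: np.ndarray
    power: np.ndarray
    accuracy: float
    alpha: float
    sidedness: str = "one_sided"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"n": self.n_grid, "critical_count": self.critical_counts, "power": self.power}
        )


def binomial_critical_count(n: int, alpha: float = 0.05) -> int:
    """Smallest c with P(X >= c | X ~ Binomial(n, 0.5)) <= alpha.

    May equal n + 1 when no attainable rejection region exists (then
    power is 0 for every true accuracy).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must lie in (0, 1)")
    # isf returns the largest k with P(X > k) > alpha (i.e. sf(k) > alpha),
    # so k + 1 is the smallest count whose upper tail is <= alpha.
    return int(stats.binom.isf(alpha, n, 0.5)) + 1


def binomial_power(n: int, p_true: float, alpha: float = 0.05) -> float:
    """Exact one-sided power P(X >= c | X ~ Binomial(n, p_true))."""
    if not 0.5 < p_true <= 1.0:
        raise ValidationError("p_true must lie in (0.5, 1] for detection power")
    c = binomial_critical_count(n, alpha)
    if c > n:
        return 0.0
    return float(stats.binom.sf(c - 1, n, p_true))


def min_trials_for_power(
    p_true: float, target: float = 0.9, alpha: float = 0.05, n_max: int = 5000
) -> int:
    """Smallest trial count whose exact binomial power reaches ``target``.

    Exact power is non-monotone in n (the rejection region jumps), so
    every n is checked and the first crossing is returned.
    """
    if not 0.0 < target < 1.0:
        raise ValidationError("target power must lie in (0, 1)")
    best = 0.0
    for n in range(1, n_max + 1):
        pw = binomial_power(n, p_true, alpha)
        if pw >= target:
            return n
        best = max(best, pw)
    raise AnalysisError(
        f"no n <= {n_max} reaches power {target}; best achieved {best:.4f}"
    )


def t_test_sample_size(
    d: float,
    power: float = 0.8,
    alpha: float = 0.05,
    exclusion_rate: float = 0.0,
) -> int:
    """Sample size of a one-sided one-sample t test, inflated for exclusions.

    Finds the smallest n whose noncentral-t power reaches ``power`` for
    effect size ``d`` (Cohen's d), then divides by (1 - exclusion_rate)
    and rounds up to cover participants expected to be excluded post
    hoc. E.g. d = 0.2, 80% power, alpha .05, 5% exclusions -> 165.
    """
    if d <= 0:
        raise ValidationError("d must be positive")
    if not 0.0 < power < 1.0:
        raise ValidationError("power must lie in (0, 1)")
    if not 0.0 <= exclusion_rate < 1.0:
        raise ValidationError("exclusion_rate must lie in [0, 1)")
    solver = TTestPower()
    n = 2
    while solver.power(effect_size=d, nobs=n, alpha=alpha, alternative="larger") < power:
        n += 1
        if n > 10 ** 6:  # pragma: no cover - d>0 always terminates far earlier
            raise AnalysisError("sample-size scan did not converge")
    return math.ceil(n / (1.0 - exclusion_rate))


def power_curve(
    n_min: int, n_max: int, p_true: float, alpha: float = 0.05
) -> PowerCurve:
    """Exact power evaluated at every n in [n_min, n_max]."""
    if n_min < 1 or n_max < n_min:
        raise ValidationError("need 1 <= n_min <= n_max")
    grid = np.arange(n_min, n_max + 1)
    crit = np.array([binomial_critical_count(int(n), alpha) for n in grid])
    power = np.array([binomial_power(int(n), p_true, alpha) for n in grid])
    return PowerCurve(
        n_grid=grid, critical_counts=crit, power=power, accuracy=p_true, alpha=alpha
    )
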