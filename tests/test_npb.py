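"""Unit and property tests for the NPB test's building blocks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from npbtest import (
    AnalysisError,
    NPBConfig,
    ValidationError,
    adjusted_threshold,
    asymmetry_S,
    bootstrap_awareness,
    classify_participants,
    initial_threshold,
    npb_test,
    nullify_effect,
    surrogate_effect,
)

from conftest import make_dataset, make_record


# --- initial threshold --------------------------------------------------


def brute_force_threshold(n, alpha):
    """Independent oracle: scan the binomial CDF for the smallest q."""
    target = 1 - alpha / 2
    cdf = 0.0
    for q in range(n + 1):
        cdf += stats.binom.pmf(q, n, 0.5)
        if cdf >= target:
            return q / n
    raise AssertionError


@pytest.mark.parametrize("avg_trials, expected", [(100, 0.60), (200, 0.57)])
def test_initial_threshold_matches_cdf_scan(avg_trials, expected):
    assert initial_threshold(avg_trials, 0.05) == pytest.approx(expected)
    assert initial_threshold(avg_trials, 0.05) == pytest.approx(
        brute_force_threshold(avg_trials, 0.05)
    )


@pytest.mark.parametrize("n", [17, 50, 123, 400])
def test_initial_threshold_agrees_with_oracle(n):
    for alpha in (0.01, 0.05, 0.2):
        assert initial_threshold(n, alpha) == pytest.approx(brute_force_threshold(n, alpha))


def test_initial_threshold_monotone_in_alpha():
    alphas = [0.01, 0.05, 0.2, 0.5, 0.9, 0.99]
    hs = [initial_threshold(100, a) for a in alphas]
    assert all(h1 >= h2 for h1, h2 in zip(hs, hs[1:]))
    assert hs[-1] >= 0.5


def test_initial_threshold_rejects_fractional_trials_below_one():
    with pytest.raises(ValidationError):
        initial_threshold(0.5)


# --- asymmetry and adjusted threshold -----------------------------------


def test_asymmetry_symmetric_case():
    scores = np.array([0.48, 0.46, 0.44, 0.52, 0.54, 0.5])
    # delta = 0.07: negative [0.43, 0.5), positive [0.5, 0.57]; 0.5 is positive
    n_pos, n_neg, S = asymmetry_S(scores, h=0.57)
    assert (n_pos, n_neg, S) == (3, 3, 0.0)


@pytest.mark.parametrize(
    "pos, neg, expected_S",
    [([0.5, 0.52], [0.48], 3.0), ([0.5], [0.48, 0.46], -0.75)],
)
def test_asymmetry_squared_ratio(pos, neg, expected_S):
    scores = np.array(pos + neg)
    n_pos, n_neg, S = asymmetry_S(scores, h=0.55)
    assert (n_pos, n_neg) == (len(pos), len(neg))
    assert S == pytest.approx(expected_S)


def test_asymmetry_empty_negative_half_substitutes_one():
    n_pos, n_neg, S = asymmetry_S(np.array([0.5, 0.51, 0.52]), h=0.55)
    assert n_neg == 0
    assert S == pytest.approx(3 ** 2 - 1)


def test_asymmetry_empty_band_warns_and_returns_zero():
    with pytest.warns(UserWarning):
        n_pos, n_neg, S = asymmetry_S(np.array([0.9, 0.1]), h=0.55)
    assert (n_pos, n_neg, S) == (0, 0, 0.0)


@given(
    scores=st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=40),
    h=st.floats(0.51, 0.99),
)
@settings(max_examples=100, deadline=None)
def test_asymmetry_matches_interval_membership_oracle(scores, h):
    scores = np.array(scores)
    delta = h - 0.5
    neg = sum(1 for s in scores if 0.5 - delta <= s < 0.5)
    pos = sum(1 for s in scores if 0.5 <= s <= 0.5 + delta)
    if pos == 0 and neg == 0:
        return
    n_pos, n_neg, S = asymmetry_S(scores, h)
    assert (n_pos, n_neg) == (pos, neg)
    assert S == pytest.approx((pos / (neg if neg else 1)) ** 2 - 1)


@pytest.mark.parametrize(
    "h, S, n, expected",
    [(0.65, 0.0, 100, 0.65), (0.65, 1.0, 100, 0.55), (0.65, -0.75, 100, 0.65)],
)
def test_adjusted_threshold_formula(h, S, n, expected):
    assert adjusted_threshold(h, S, n) == pytest.approx(expected)


@given(h=st.floats(0.51, 0.99), S=st.floats(-1, 50), n=st.floats(1, 1e4))
@settings(max_examples=100, deadline=None)
def test_adjusted_never_exceeds_initial(h, S, n):
    h_adj = adjusted_threshold(h, S, n)
    assert h_adj <= h
    if S <= 0:
        assert h_adj == h
    elif S > 1e-12:  # below this the adjustment underflows double precision
        assert h_adj < h


# --- classification and nullification -----------------------------------


def test_classification_ties_go_to_unaware():
    ds = make_dataset([0.5, 0.5, 0.55, 0.6], n_trials=20)
    unaware, aware = classify_participants(ds, h_adj=0.55)
    assert unaware == [0, 1, 2]
    assert aware == [3]


def test_classification_all_below():
    ds = make_dataset([0.5, 0.5, 0.5], n_trials=20)
    unaware, aware = classify_participants(ds, h_adj=0.55)
    assert len(unaware) == 3 and aware == []


def test_classification_threshold_below_all_scores():
    ds = make_dataset([0.5, 0.55, 0.6], n_trials=20)
    unaware, aware = classify_participants(ds, h_adj=0.45)
    assert unaware == [] and len(aware) == 3


def test_nullify_preserves_label_multiset_and_responses(rng):
    rec = make_record(conditions="AABBAB", awareness=(1, 0),
                      responses=(1.0, 2.0, 3.0, 4.0, 5.0, 6.0))
    out = nullify_effect(rec, rng)
    assert sorted(out.effect_condition) == sorted(rec.effect_condition)
    np.testing.assert_array_equal(out.effect_response, rec.effect_response)
    np.testing.assert_array_equal(out.awareness_correct, rec.awareness_correct)


def test_nullify_has_zero_mean_effect(rng):
    rec = make_record(conditions="AAABBB", awareness=(1, 0),
                      responses=(3.0, -1.0, 2.5, 0.5, -2.0, 4.0))
    draws = np.array([nullify_effect(rec, rng).effect_score for _ in range(10_000)])
    se = draws.std() / np.sqrt(draws.size)
    assert abs(draws.mean()) < 3 * se


def test_nullify_constant_responses_give_zero_effect(rng):
    rec = make_record(conditions="AABB", responses=(2.0, 2.0, 2.0, 2.0))
    assert nullify_effect(rec, rng).effect_score == 0.0


# --- awareness bootstrap ------------------------------------------------


def test_bootstrap_degenerate_scores(rng):
    assert all(bootstrap_awareness(1.0, 50, rng) == 1.0 for _ in range(20))
    assert all(bootstrap_awareness(0.0, 50, rng) == 0.0 for _ in range(20))


def test_bootstrap_matches_binomial_moments(rng):
    draws = np.array([bootstrap_awareness(0.6, 200, rng) for _ in range(10_000)])
    exp_sd = np.sqrt(0.6 * 0.4 / 200)
    assert abs(draws.mean() - 0.6) < 3 * exp_sd / np.sqrt(draws.size)
    assert draws.std() == pytest.approx(exp_sd, rel=0.1)


# --- surrogate iterations ----------------------------------------------


def test_surrogate_with_nothing_nullified_returns_group_mean(rng):
    # all scores 0 -> bootstrapped scores are always 0 < h, and with an
    # empty unaware partition no effect is permuted
    ds = make_dataset([0.0, 0.0, 0.0], n_trials=20, effects=[1.0, 2.0, 3.0], rng=rng)
    partition = ([], [0, 1, 2])
    val = surrogate_effect(ds, partition, h=0.6, rng=rng)
    assert val == pytest.approx(ds.effect_scores.mean())


def test_surrogate_all_nullified_centers_on_zero(rng):
    ds = make_dataset([0.0] * 6, n_trials=20, n_eff=20, effects=[2.0] * 6, rng=rng)
    partition = (list(range(6)), [])
    draws = np.array([surrogate_effect(ds, partition, h=0.6, rng=rng)
                      for _ in range(2000)])
    se = draws.std() / np.sqrt(draws.size)
    assert abs(draws.mean()) < 3 * se


def test_surrogate_inclusion_probability_tracks_binomial_tail(rng):
    # a single bootstrapped participant straddles h: inclusion frequency
    # across iterations should match P(X/n < h)
    ds = make_dataset([0.55, 0.0], n_trials=20, n_eff=40, effects=[4.0, 0.0], rng=rng)
    partition = ([1], [0])
    h = 0.6
    draws = np.array([surrogate_effect(ds, partition, h, rng=rng) for _ in range(3000)])
    # participant 0 keeps a large positive effect; iterations including it
    # have a clearly larger value than iterations averaging only p1's null
    included = draws > 1.0
    expect = stats.binom.cdf(int(np.ceil(h * 20)) - 1, 20, 0.55)
    se = np.sqrt(expect * (1 - expect) / draws.size)
    assert abs(included.mean() - expect) < 4 * se


# --- the full test ------------------------------------------------------


def test_npb_is_deterministic(rng):
    ds = make_dataset([0.5, 0.45, 0.55, 0.5, 0.6], n_trials=20,
                      effects=[0.5, 0.1, -0.2, 0.3, 0.9], rng=rng)
    cfg = NPBConfig(n_iterations=200, seed=42)
    r1, r2 = npb_test(ds, cfg), npb_test(ds, cfg)
    assert r1.p_value == r2.p_value
    assert r1.observed_effect == r2.observed_effect
    np.testing.assert_array_equal(r1.null_effects, r2.null_effects)


def test_npb_result_internal_consistency(rng):
    ds = make_dataset([0.5, 0.45, 0.55, 0.5, 0.6], n_trials=20, rng=rng)
    res = npb_test(ds, NPBConfig(n_iterations=150, seed=3))
    assert res.delta == res.h - 0.5
    assert res.h_adj <= res.h
    assert res.null_effects.size == 150
    assert 0 < res.p_value <= 1


def test_npb_all_zero_responses_not_significant():
    ds = make_dataset([0.5, 0.45, 0.55, 0.5], n_trials=20)
    for p in ds.participants:
        p.effect_response = np.zeros_like(p.effect_response)
    res = npb_test(ds, NPBConfig(n_iterations=300, seed=0))
    assert res.observed_effect == 0.0
    assert res.p_value > 0.05


def test_npb_errors_when_no_participant_below_threshold():
    ds = make_dataset([0.95, 0.9, 1.0], n_trials=20)
    with pytest.raises(AnalysisError, match="below initial threshold"):
        npb_test(ds, NPBConfig(initial_threshold_mode="fixed", fixed_h=0.65,
                               n_iterations=100, seed=0))


def test_npb_fixed_threshold_mode(rng):
    ds = make_dataset([0.5, 0.45, 0.55, 0.6], n_trials=20, rng=rng)
    res = npb_test(ds, NPBConfig(initial_threshold_mode="fixed", fixed_h=0.65,
                                 n_iterations=100, seed=0))
    assert res.h == 0.65


def test_config_validation():
    with pytest.raises(ValidationError):
        NPBConfig(n_iterations=50)
    with pytest.raises(ValidationError):
        NPBConfig(initial_threshold_mode="fixed", fixed_h=0.4)
    with pytest.raises(ValidationError):
        NPBConfig(two_sided_alpha=0.0)


def test_null_p_values_stochastically_dominate_uniform():
    """Under fully null data the NPB p-value ECDF at .05 stays near or below .05."""
    from npbtest import SimConfig, run_experiment

    reps = 80
    grid = [SimConfig(n_participants=40, frac_unaware=1.0, d_unconscious=0.0,
                      n_awareness_trials=50, seed=97, n_replicates=reps)]
    res = run_experiment(grid, NPBConfig(n_iterations=200, seed=0))
    pvals = res.p_values[("linear", 1.0, 50, 0.0)]
    ecdf_05 = float((pvals < 0.05).mean())
    assert ecdf_05 <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)
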