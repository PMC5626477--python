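"""Day aggregation, paired permutation inference, subsets, Welch, retention."""

from itertools import product
from math import comb

import numpy as np
import pandas as pd
import pytest

from covertnf.connectivity import ConnectivityRecord
from covertnf.learning import (
    aggregate_by_day,
    day_contrast_permutation,
    group_interaction,
    paired_changes,
    retention_analysis,
    sign_flip_permutation_p,
    subset_robustness,
)


def rec(sid, day, idx, rtype, r12, r1c=0.0, r2c=0.0):
    return ConnectivityRecord(sid, day, idx, rtype, r12, r1c, r2c)


def day_records(sid, day, composites):
    """2 rest-pre, feedback runs carrying the given composites, 2 rest-post."""
    out = [rec(sid, day, 0, "rest", 0.5), rec(sid, day, 1, "rest", 0.5)]
    out += [rec(sid, day, 2 + i, "feedback", c) for i, c in enumerate(composites)]
    n = len(out)
    out += [rec(sid, day, n, "rest", 0.7), rec(sid, day, n + 1, "rest", 0.7)]
    return out


def exhaustive_sign_flip_p(diffs):
    """Exact paired-permutation p by full 2^n sign enumeration (oracle)."""
    diffs = np.asarray(diffs, dtype=float)
    obs = abs(diffs.mean())
    n = diffs.size
    stats = [
        abs(np.mean(np.array(signs) * diffs)) for signs in product((-1, 1), repeat=n)
    ]
    return np.mean([s >= obs - 1e-12 for s in stats])


# --- aggregation -----------------------------------------------------------


def test_feedback_mean_and_first2():
    records = day_records("s1", "day1", [0.1, 0.2, 0.3, 0.4])
    full = aggregate_by_day(records, scope="feedback_all")
    assert full.composite.iloc[0] == pytest.approx(0.25)
    first2 = aggregate_by_day(records, scope="feedback_first2")
    assert first2.composite.iloc[0] == pytest.approx(0.15)
    assert first2.n_runs.iloc[0] == 2


def test_rest_pre_isolated_from_feedback_runs():
    base = day_records("s1", "day1", [0.1, 0.2, 0.3, 0.4])
    perturbed = day_records("s1", "day1", [0.9, 0.9, 0.9, 0.9])
    a = aggregate_by_day(base, scope="rest_pre")
    b = aggregate_by_day(perturbed, scope="rest_pre")
    pd.testing.assert_frame_equal(a, b)
    assert a.r_t1t2.iloc[0] == pytest.approx(0.5)  # pre runs only, not post (0.7)


def test_missing_scope_runs_listed():
    records = [rec("s1", "day1", 0, "rest", 0.5)]
    with pytest.raises(ValueError, match=r"\('s1', 'day1'\)"):
        aggregate_by_day(records, scope="feedback_all")


def test_fisher_z_switch_changes_scale():
    records = day_records("s1", "day1", [0.5, 0.5, 0.5, 0.5])
    raw = aggregate_by_day(records, scope="feedback_all")
    z = aggregate_by_day(records, scope="feedback_all", use_fisher_z=True)
    assert z.r_t1t2.iloc[0] == pytest.approx(np.arctanh(0.5))
    assert raw.r_t1t2.iloc[0] == pytest.approx(0.5)


# --- permutation test ------------------------------------------------------


def summaries_from_changes(changes, day_a="day1", day_b="day4"):
    rows = []
    for i, ch in enumerate(changes):
        rows.append({"subject_id": f"s{i:02d}", "day": day_a, "scope": "feedback_all",
                     "r_t1t2": 0.0, "r_t1c": 0.0, "r_t2c": 0.0, "composite": 0.0,
                     "n_runs": 4})
        rows.append({"subject_id": f"s{i:02d}", "day": day_b, "scope": "feedback_all",
                     "r_t1t2": ch, "r_t1c": 0.0, "r_t2c": 0.0, "composite": ch,
                     "n_runs": 4})
    return pd.DataFrame(rows)


def test_constant_positive_change_attains_minimum_p():
    summ = summaries_from_changes([0.2] * 17)
    res = day_contrast_permutation(summ, "day1", "day4", n_iterations=5000, seed=1)
    assert res.mean_change == pytest.approx(0.2)
    # only all-plus and all-minus sign patterns reach |mean| >= 0.2
    assert res.p_value == pytest.approx(1 / 5001, abs=5e-4)
    assert res.p_value >= 1 / 5001


def test_zero_observed_change_gives_p_near_one():
    summ = summaries_from_changes([0.0] * 10)
    res = day_contrast_permutation(summ, "day1", "day4", n_iterations=500, seed=2)
    assert res.p_value == 1.0


def test_monte_carlo_p_matches_exhaustive_enumeration():
    rng = np.random.default_rng(3)
    for _ in range(5):
        diffs = rng.standard_normal(10) * 0.1 + 0.05
        exact = exhaustive_sign_flip_p(diffs)
        mc = sign_flip_permutation_p(diffs, n_iterations=4000, seed=4)
        tol = 4 * np.sqrt(exact * (1 - exact) / 4000) + 1e-3
        assert mc == pytest.approx(exact, abs=tol)


def test_permutation_p_invariant_to_rescaling():
    diffs = np.array([0.1, 0.3, -0.05, 0.2, 0.15, 0.25, -0.1, 0.05])
    p1 = sign_flip_permutation_p(diffs, n_iterations=1000, seed=5)
    p2 = sign_flip_permutation_p(diffs * 37.5, n_iterations=1000, seed=5)
    assert p1 == p2


def test_small_iteration_count_refused():
    with pytest.raises(ValueError, match=">= 100"):
        sign_flip_permutation_p(np.ones(5), n_iterations=50)


def test_one_tailed_option():
    summ = summaries_from_changes([0.2] * 8)
    two = day_contrast_permutation(summ, "day1", "day4", n_iterations=1000, seed=6)
    one = day_contrast_permutation(
        summ, "day1", "day4", n_iterations=1000, seed=6, alternative="greater"
    )
    assert one.p_value <= two.p_value


# --- subsets ---------------------------------------------------------------


def test_subset_count_matches_binomial_coefficient():
    summ = summaries_from_changes(list(np.linspace(0.1, 0.3, 12)))
    res = subset_robustness(summ, "day1", "day4", subset_size=10, n_iterations=200, seed=7)
    assert res.n_subsets == comb(12, 10) == 66


def test_homogeneous_changes_make_every_subset_identical():
    summ = summaries_from_changes([0.2] * 12)
    res = subset_robustness(summ, "day1", "day4", subset_size=10, n_iterations=500, seed=8)
    assert res.mean_change_range == pytest.approx((0.2, 0.2))
    assert res.fraction_significant == 1.0


def test_subset_equal_to_cohort_is_single_full_group():
    summ = summaries_from_changes([0.1] * 10)
    res = subset_robustness(summ, "day1", "day4", subset_size=10, n_iterations=200, seed=9)
    assert res.n_subsets == 1
    assert res.table.mean_change.iloc[0] == pytest.approx(0.1)


def test_combinatorial_guard_refuses_without_sampling_flag():
    summ = summaries_from_changes([0.1] * 30)
    with pytest.raises(ValueError, match="allow_sampling"):
        subset_robustness(summ, "day1", "day4", subset_size=15,
                          n_iterations=200, max_subsets=1000)


# --- Welch interaction -----------------------------------------------------


def test_welch_worked_example():
    res = group_interaction([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert res.t_statistic == pytest.approx(-3.674, abs=1e-3)
    assert res.df == pytest.approx(4.0, abs=1e-9)
    assert res.p_value == pytest.approx(0.0213, abs=1e-3)


def test_identical_groups_give_t_zero_p_one():
    res = group_interaction([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    assert res.t_statistic == 0.0
    assert res.p_value == 1.0


def test_welch_type_one_error_with_unequal_variances(rng):
    hits = 0
    n_rep = 500
    for _ in range(n_rep):
        g1 = rng.standard_normal(20) * 3.0
        g2 = rng.standard_normal(8) * 0.5
        if group_interaction(g1, g2).p_value < 0.05:
            hits += 1
    assert 0.02 < hits / n_rep < 0.09


# --- retention -------------------------------------------------------------


def summaries_with_followup(day1, day4, follow):
    rows = []
    for i, (a, b, f) in enumerate(zip(day1, day4, follow)):
        for day, v in (("day1", a), ("day4", b), ("followup", f)):
            rows.append({"subject_id": f"s{i:02d}", "day": day,
                         "scope": "feedback_first2", "r_t1t2": v, "r_t1c": 0.0,
                         "r_t2c": 0.0, "composite": v, "n_runs": 2})
    return pd.DataFrame(rows)


def test_full_retention_reported_degenerate():
    summ = summaries_with_followup([0.0] * 6, [0.2] * 6, [0.2] * 6)
    weeks = {f"s{i:02d}": 5.0 + i for i in range(6)}
    res = retention_analysis(summ, weeks, n_iterations=200)
    assert np.allclose(res.retention, 1.0)
    assert res.pearson_r is None
    assert res.degenerate is not None


def test_linear_decay_gives_perfect_negative_correlation():
    weeks = np.array([5.0, 15.0, 25.0, 35.0, 45.0, 55.0])
    retention = 1.0 - 0.01 * weeks
    summ = summaries_with_followup([0.0] * 6, [0.2] * 6, list(0.2 * retention))
    res = retention_analysis(summ, {f"s{i:02d}": w for i, w in enumerate(weeks)},
                             n_iterations=200)
    assert res.pearson_r == pytest.approx(-1.0, abs=1e-9)


def test_zero_training_change_excluded_with_count():
    summ = summaries_with_followup([0.0, 0.0, 0.0, 0.0, 0.1],
                                   [0.2, 0.25, 0.3, 0.15, 0.1],
                                   [0.1, 0.2, 0.25, 0.1, 0.1])
    weeks = {f"s{i:02d}": 10.0 + i * 3 for i in range(5)}
    res = retention_analysis(summ, weeks, n_iterations=200)
    assert res.n_excluded == 1
    assert len(res.retention) == 4
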