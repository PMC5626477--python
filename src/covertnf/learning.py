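"""Day-level aggregation and group inference for the learning analyses.

Learning is assessed as the change in per-subject mean connectivity between
training days.  Aggregation scopes mirror the study design: all four
feedback runs of a day (``feedback_all``), only the first two
(``feedback_first2``, for comparison with the abbreviated follow-up
session), or the rest runs collected strictly before (``rest_pre``) or after
(``rest_post``) that day's feedback.

Inference is by paired day-label permutation: under the null, each subject's
two day labels are exchangeable, so the null distribution of the mean change
is built by independently sign-flipping each subject's difference.  P-values
are add-one smoothed (never exactly zero) and two-tailed by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from covertnf.connectivity import ConnectivityRecord

SCOPES = ("feedback_all", "feedback_first2", "rest_pre", "rest_post")
MEASURES = ("r_t1t2", "r_t1c", "r_t2c", "composite")


def records_to_frame(records: Sequence[ConnectivityRecord]) -> pd.DataFrame:
    """Tidy per-run table of correlations, Fisher z values and composites."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "day": [r.day for r in records],
            "run_index": [r.run_index for r in records],
            "run_type": [r.run_type for r in records],
            "r_t1t2": [r.r_t1t2 for r in records],
            "r_t1c": [r.r_t1c for r in records],
            "r_t2c": [r.r_t2c for r in records],
            "z_t1t2": [r.z_t1t2 for r in records],
            "z_t1c": [r.z_t1c for r in records],
            "z_t2c": [r.z_t2c for r in records],
            "composite": [r.composite for r in records],
        }
    )


def _scope_filter(day_frame: pd.DataFrame, scope: str) -> pd.DataFrame:
    fb = day_frame[day_frame.run_type == "feedback"]
    if scope == "feedback_all":
        return fb
    if scope == "feedback_first2":
        return fb.nsmallest(2, "run_index")
    rest = day_frame[day_frame.run_type == "rest"]
    if fb.empty:
        first_fb = np.inf
    else:
        first_fb = fb.run_index.min()
    if scope == "rest_pre":
        return rest[rest.run_index < first_fb]
    if scope == "rest_post":
        return rest[rest.run_index > first_fb]
    raise ValueError(f"unknown scope {scope!r}; expected one of {SCOPES}")


def aggregate_by_day(
    records: Sequence[ConnectivityRecord] | pd.DataFrame,
    scope: str = "feedback_all",
    use_fisher_z: bool = False,
) -> pd.DataFrame:
    """One summary row per subject x day: mean r per pair and mean composite.

    ``use_fisher_z`` switches the aggregation (and hence every downstream
    group statistic) from raw correlations to Fisher-z values; the ROI-level
    convention is raw r.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    cols = ["z_t1t2", "z_t1c", "z_t2c"] if use_fisher_z else ["r_t1t2", "r_t1c", "r_t2c"]
    rows = []
    missing = []
    for (sid, day), g in frame.groupby(["subject_id", "day"], sort=True):
        sel = _scope_filter(g, scope)
        if sel.empty:
            missing.append((sid, day))
            continue
        m = sel[cols].mean()
        composite = m.iloc[0] - (m.iloc[1] + m.iloc[2]) / 2.0
        rows.append(
            {
                "subject_id": sid,
                "day": day,
                "scope": scope,
                "r_t1t2": m.iloc[0],
                "r_t1c": m.iloc[1],
                "r_t2c": m.iloc[2],
                "composite": composite,
                "n_runs": len(sel),
            }
        )
    if missing:
        raise ValueError(f"no runs matching scope {scope!r} for (subject, day): {missing}")
    return pd.DataFrame(rows)


def paired_changes(
    summaries: pd.DataFrame, day_a: str, day_b: str, measure: str = "composite"
) -> pd.Series:
    """Per-subject ``day_b - day_a`` change in a summary measure."""
    if measure not in summaries.columns:
        raise ValueError(f"unknown measure {measure!r}")
    wide = summaries.pivot(index="subject_id", columns="day", values=measure)
    for day in (day_a, day_b):
        if day not in wide.columns:
            raise ValueError(f"no summaries for day {day!r}")
    missing = wide.index[wide[[day_a, day_b]].isna().any(axis=1)].tolist()
    if missing:
        raise ValueError(f"subjects missing a day in ({day_a}, {day_b}): {missing}")
    return wide[day_b] - wide[day_a]


@dataclass(frozen=True)
class DayContrastResult:
    day_a: str
    day_b: str
    measure: str
    mean_change: float
    p_value: float
    n_iterations: int
    alternative: str
    n_subjects: int
    seed: int


def sign_flip_permutation_p(
    diffs: np.ndarray,
    n_iterations: int = 5000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> float:
    """Paired permutation p for mean(diffs) by per-subject sign flips."""
    if n_iterations < 100:
        raise ValueError("n_iterations must be >= 100 for a usable permutation p")
    diffs = np.asarray(diffs, dtype=float)
    obs = diffs.mean()
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_iterations, diffs.size)) * 2 - 1
    null = (signs * diffs).mean(axis=1)
    # tolerance keeps exact ties (e.g. the identity permutation) stable
    # under rescaling of the measure
    tol = 1e-12 * max(np.abs(diffs).max(), 1e-300)
    if alternative == "two-sided":
        hits = np.abs(null) >= abs(obs) - tol
    elif alternative == "greater":
        hits = null >= obs - tol
    elif alternative == "less":
        hits = null <= obs + tol
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float((1 + hits.sum()) / (n_iterations + 1))


def day_contrast_permutation(
    summaries: pd.DataFrame,
    day_a: str,
    day_b: str,
    measure: str = "composite",
    n_iterations: int = 5000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> DayContrastResult:
    """Paired day-contrast permutation test on per-subject summaries.

    The null exchanges each subject's two day labels independently, i.e.
    sign-flips that subject's change.  ``mean_change`` is ``day_b - day_a``.
    """
    diffs = paired_changes(summaries, day_a, day_b, measure)
    p = sign_flip_permutation_p(
        diffs.to_numpy(), n_iterations=n_iterations, seed=seed, alternative=alternative
    )
    return DayContrastResult(
        day_a=day_a,
        day_b=day_b,
        measure=measure,
        mean_change=float(diffs.mean()),
        p_value=p,
        n_iterations=n_iterations,
        alternative=alternative,
        n_subjects=diffs.size,
        seed=seed,
    )


@dataclass
class SubsetRobustnessResult:
    subset_size: int
    n_subsets: int
    table: pd.DataFrame  # one row per subset: members, mean_change, p_value
    alpha: float
    fraction_significant: float
    mean_change_range: tuple[float, float]
    n_iterations: int
    seed: int


def subset_robustness(
    summaries: pd.DataFrame,
    day_a: str,
    day_b: str,
    measure: str = "composite",
    subset_size: int = 10,
    alpha: float = 0.05,
    n_iterations: int = 1000,
    seed: int = 0,
    allow_sampling: bool = False,
    max_subsets: int = 10**6,
) -> SubsetRobustnessResult:
    """Re-run the day contrast on every subject subset of a given size.

    Guards against combinatorial explosion: if C(n, k) exceeds ``max_subsets``
    the call refuses unless ``allow_sampling`` draws that many subsets at
    random instead.  Permutation p-values are computed for all subsets at
    once (vectorised sign-flip null per chunk).
    """
    diffs = paired_changes(summaries, day_a, day_b, measure)
    n = diffs.size
    if n < subset_size:
        raise ValueError(f"need >= {subset_size} subjects, have {n}")
    n_total = comb(n, subset_size)
    rng = np.random.default_rng(seed)
    if n_total > max_subsets:
        if not allow_sampling:
            raise ValueError(
                f"C({n},{subset_size}) = {n_total} subsets exceeds {max_subsets}; "
                "pass allow_sampling=True to draw a random sample instead"
            )
        idx = np.stack(
            [rng.choice(n, size=subset_size, replace=False) for _ in range(max_subsets)]
        )
    else:
        idx = np.array(list(combinations(range(n), subset_size)))
    values = diffs.to_numpy()[idx]  # (n_subsets, k)
    means = values.mean(axis=1)
    p = np.empty(len(idx))
    chunk = 2000
    for lo in range(0, len(idx), chunk):
        v = values[lo : lo + chunk]
        signs = rng.integers(0, 2, size=(n_iterations, subset_size)) * 2 - 1
        null = (signs @ v.T) / subset_size  # (n_iter, chunk)
        hits = (np.abs(null) >= np.abs(v.mean(axis=1))[None, :]).sum(axis=0)
        p[lo : lo + chunk] = (1 + hits) / (n_iterations + 1)
    subjects = diffs.index.to_numpy()
    table = pd.DataFrame(
        {
            "members": [tuple(subjects[i]) for i in idx],
            "mean_change": means,
            "p_value": p,
        }
    )
    return SubsetRobustnessResult(
        subset_size=subset_size,
        n_subsets=len(idx),
        table=table,
        alpha=alpha,
        fraction_significant=float((p < alpha).mean()),
        mean_change_range=(float(means.min()), float(means.max())),
        n_iterations=n_iterations,
        seed=seed,
    )


@dataclass(frozen=True)
class GroupInteractionResult:
    t_statistic: float
    df: float
    p_value: float
    mean_diff: float


def group_interaction(
    changes_group1: Sequence[float], changes_group2: Sequence[float]
) -> GroupInteractionResult:
    """Welch two-sample t-test (unequal variances) on per-subject changes.

    Used for the arm interaction: trained-arm change vs control-arm change
    with different sample sizes.  Both groups constant with equal means
    yields t = 0, p = 1 by convention.
    """
    g1 = np.asarray(changes_group1, dtype=float)
    g2 = np.asarray(changes_group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs n >= 2")
    if g1.var(ddof=1) == 0 and g2.var(ddof=1) == 0:
        if g1.mean() == g2.mean():
            return GroupInteractionResult(0.0, float(g1.size + g2.size - 2), 1.0, 0.0)
        return GroupInteractionResult(
            float(np.inf) * np.sign(g1.mean() - g2.mean()),
            float(g1.size + g2.size - 2),
            0.0,
            float(g1.mean() - g2.mean()),
        )
    res = stats.ttest_ind(g1, g2, equal_var=False)
    return GroupInteractionResult(
        t_statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        mean_diff=float(g1.mean() - g2.mean()),
    )


@dataclass
class RetentionResult:
    retention: pd.Series  # per-subject retention fraction
    elapsed_weeks: pd.Series
    pearson_r: float | None
    p_value: float | None
    n_excluded: int
    degenerate: str | None


def retention_analysis(
    summaries: pd.DataFrame,
    elapsed_weeks: Mapping[str, float],
    measure: str = "composite",
    day_a: str = "day1",
    day_b: str = "day4",
    followup: str = "followup",
    n_iterations: int = 5000,
    seed: int = 0,
) -> RetentionResult:
    """Correlate the retention fraction with elapsed time since training.

    Retention fraction is (followup - day_a) / (day_b - day_a): 1 means full
    maintenance of the training change.  Subjects with zero training change
    (undefined fraction) are excluded and counted.
    """
    train = paired_changes(summaries, day_a, day_b, measure)
    follow = paired_changes(summaries, day_a, followup, measure)
    keep = train != 0
    n_excluded = int((~keep).sum())
    retention = (follow[keep] / train[keep]).rename("retention")
    weeks = pd.Series(dict(elapsed_weeks), dtype=float).reindex(retention.index)
    if weeks.isna().any():
        raise ValueError(
            f"elapsed_weeks missing subjects: {weeks.index[weeks.isna()].tolist()}"
        )
    if retention.std() == 0 or weeks.std() == 0:
        return RetentionResult(retention, weeks, None, None, n_excluded,
                               "zero variance in retention or elapsed time")
    from covertnf.connectivity import permutation_pvalue_correlation

    r = float(np.corrcoef(retention, weeks)[0, 1])
    p = permutation_pvalue_correlation(
        retention.to_numpy(), weeks.to_numpy(), n_iterations=n_iterations, seed=seed
    )
    return RetentionResult(retention, weeks, r, p, n_excluded, None)
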