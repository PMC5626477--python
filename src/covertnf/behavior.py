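"""Brain-behavior analysis: change scores, outlier exclusion, correlations.

Behavior change is scored pre minus post, so a positive change is a symptom
reduction.  Because the parent-report scales were not designed for short
test-retest intervals, subjects whose change exceeds three standard
deviations of an independent test-retest reference distribution are flagged
as outliers; the correlation analyses are run both with and without them.

The correlation of connectivity change with behavior change uses Pearson r
with a permutation p-value (subject-label shuffling).  Partial correlations
(controlling for baseline behavior, baseline rest, or the change on the
non-social control scale) residualise both variables on the covariates and
correlate the residuals, with the permutation run on the residuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from covertnf.connectivity import permutation_pvalue_correlation


def flag_outliers(
    table: pd.DataFrame,
    reference_changes: Sequence[float],
    column: str = "srs_change",
    sd_multiplier: float = 3.0,
) -> pd.DataFrame:
    """Flag subjects whose change lies outside mean +/- k*SD of a reference.

    The reference is an independent test-retest change sample (n >= 10) that
    calibrates how much change is plausible in the absence of intervention.
    Returns a copy with ``outlier_flag`` and ``outlier_reason`` columns.
    """
    ref = np.asarray(reference_changes, dtype=float)
    if ref.size < 10:
        raise ValueError("reference sample must have n >= 10")
    sd = ref.std(ddof=1)
    if sd == 0:
        raise ValueError("reference sample has zero standard deviation")
    mean = ref.mean()
    lo, hi = mean - sd_multiplier * sd, mean + sd_multiplier * sd
    out = table.copy()
    vals = out[column].to_numpy(dtype=float)
    flagged = (vals < lo) | (vals > hi)
    out["outlier_flag"] = flagged
    out["outlier_reason"] = [
        f"{column}={v:g} outside [{lo:g}, {hi:g}]" if f else "" for v, f in zip(vals, flagged)
    ]
    return out


@dataclass(frozen=True)
class CorrelationResult:
    r: float | None
    p_value: float | None
    n: int
    degenerate: str | None = None


@dataclass
class BrainBehaviorResult:
    with_outliers: CorrelationResult
    without_outliers: CorrelationResult
    n_excluded: int


def _pearson_perm(
    x: np.ndarray, y: np.ndarray, n_iterations: int, seed: int
) -> CorrelationResult:
    if x.std() == 0 or y.std() == 0:
        return CorrelationResult(None, None, x.size, "zero variance in a variable")
    r = float(np.corrcoef(x, y)[0, 1])
    p = permutation_pvalue_correlation(x, y, n_iterations=n_iterations, seed=seed)
    return CorrelationResult(r, p, x.size)


def brain_behavior_correlation(
    connectivity_changes: Sequence[float],
    behavior_changes: Sequence[float],
    outlier_flags: Sequence[bool] | None = None,
    n_iterations: int = 5000,
    seed: int = 0,
) -> BrainBehaviorResult:
    """Pearson r of connectivity change vs behavior change, permutation p.

    Run twice — including and excluding flagged outliers — and both results
    reported, since the exclusion decision itself can drive the effect.
    """
    x = np.asarray(connectivity_changes, dtype=float)
    y = np.asarray(behavior_changes, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples required")
    flags = (
        np.zeros(x.size, dtype=bool)
        if outlier_flags is None
        else np.asarray(outlier_flags, dtype=bool)
    )
    keep = ~flags
    if keep.sum() < 5:
        raise ValueError("need >= 5 paired observations after exclusion")
    return BrainBehaviorResult(
        with_outliers=_pearson_perm(x, y, n_iterations, seed),
        without_outliers=_pearson_perm(x[keep], y[keep], n_iterations, seed),
        n_excluded=int(flags.sum()),
    )


def _residualize(v: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(v)), covariates])
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_brain_behavior(
    connectivity_changes: Sequence[float],
    behavior_changes: Sequence[float],
    covariates: np.ndarray | pd.DataFrame,
    n_iterations: int = 5000,
    seed: int = 0,
) -> CorrelationResult:
    """Partial correlation controlling for one or more covariates.

    Both variables are residualised on the covariates (with intercept) and
    the residuals correlated; the permutation p shuffles the behavior
    residuals.  Equivalent to the closed-form partial-correlation formula.
    """
    x = np.asarray(connectivity_changes, dtype=float)
    y = np.asarray(behavior_changes, dtype=float)
    names = None
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        cov = covariates.to_numpy(dtype=float)
    else:
        cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    n, k = cov.shape
    if n != x.size or n != y.size:
        raise ValueError("covariates must be aligned with the paired samples")
    if n <= k + 2:
        raise ValueError(f"need n > n_covariates + 2 (n={n}, covariates={k})")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        label = names if names is not None else f"{k} covariate column(s)"
        raise ValueError(f"covariate matrix is rank deficient (collinear): {label}")
    rx = _residualize(x, cov)
    ry = _residualize(y, cov)
    # residuals that are numerically zero relative to the variable's scale
    if rx.std() <= 1e-10 * max(x.std(), 1.0) or ry.std() <= 1e-10 * max(y.std(), 1.0):
        return CorrelationResult(None, None, n, "zero residual variance")
    r = float(np.corrcoef(rx, ry)[0, 1])
    p = permutation_pvalue_correlation(rx, ry, n_iterations=n_iterations, seed=seed)
    return CorrelationResult(r, p, n)
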