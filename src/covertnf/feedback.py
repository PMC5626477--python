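"""Streaming two-point feedback decision engine.

At every TR the engine compares the latest sample of each ROI mean signal to
the previous one and notes the trend (increase/decrease).  Feedback fires
when the two target ROIs trend together and the control ROI trends the
opposite way — a two-point proxy for "target-target correlation up,
target-control correlation down" that needs no window of history.

The published rule is stated as ratios of increments being positive
(targets agree) and negative (control opposes); we implement the
algebraically equivalent sign comparison, which avoids 0/0.  An increment of
exactly zero — measure-zero for continuous signals but possible in synthetic
or quantised data — never fires (conservative tie rule).

Score bookkeeping mirrors the task's covert game: each fired decision
reveals one puzzle piece; a board holds 25 pieces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isnan
from typing import Sequence

import numpy as np

from covertnf.cohort import RoiRun

BOARD_SIZE = 25


class FeedbackInputError(ValueError):
    """A sample required by the decision rule is missing or NaN."""


@dataclass(frozen=True)
class FeedbackDecision:
    """One TR's decision: the three signal increments and whether it fired."""

    tr_index: int
    trend_target1: float
    trend_target2: float
    trend_control: float
    fired: bool


@dataclass
class FeedbackLog:
    """Per-run decision trace plus cumulative puzzle-board bookkeeping."""

    subject_id: str
    day: str
    run_index: int
    decisions: list[FeedbackDecision] = field(default_factory=list)
    board_size: int = BOARD_SIZE

    @property
    def pieces_revealed(self) -> int:
        return sum(d.fired for d in self.decisions)

    @property
    def boards_completed(self) -> int:
        return self.pieces_revealed // self.board_size

    @property
    def fired_fraction(self) -> float:
        if not self.decisions:
            return float("nan")
        return self.pieces_revealed / len(self.decisions)


def decide_feedback(
    prev: Sequence[float], curr: Sequence[float], tr_index: int = 0
) -> FeedbackDecision:
    """Apply the two-point rule to one pair of consecutive samples.

    Fires iff sign(d_target1) == sign(d_target2) != sign(d_control) with all
    three increments nonzero.
    """
    if len(prev) != 3 or len(curr) != 3:
        raise FeedbackInputError(f"TR {tr_index}: expected 3 ROI samples")
    for v in (*prev, *curr):
        if v is None or isnan(float(v)):
            raise FeedbackInputError(f"TR {tr_index}: missing/NaN ROI sample")
    d1 = float(curr[0]) - float(prev[0])
    d2 = float(curr[1]) - float(prev[1])
    dc = float(curr[2]) - float(prev[2])
    s1, s2, sc = np.sign(d1), np.sign(d2), np.sign(dc)
    fired = bool(s1 != 0 and s1 == s2 and sc == -s1)
    return FeedbackDecision(tr_index, d1, d2, dc, fired)


def run_feedback_session(run: RoiRun) -> FeedbackLog:
    """Stream a whole run through the rule, strictly causally.

    Produces exactly ``n_tr - 1`` decisions; the decision at TR ``t`` uses
    only samples up to ``t``, so truncating the run never changes earlier
    decisions.
    """
    log = FeedbackLog(run.subject_id, run.day, run.run_index)
    series = run.series
    prev = series[0]
    for t in range(1, series.shape[0]):
        curr = series[t]
        log.decisions.append(decide_feedback(prev, curr, tr_index=t))
        prev = curr
    return log


def _window_covariances(series: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window (length k, stride 1) sample covariances of
    (target1, target2) and (target1, control).  The sign of a window's
    Pearson r equals the sign of its covariance, which is all the k-point
    score needs."""
    x, y, c = series[:, 0], series[:, 1], series[:, 2]

    def roll(a: np.ndarray) -> np.ndarray:
        cs = np.concatenate([[0.0], np.cumsum(a)])
        return cs[k:] - cs[:-k]

    sx, sy, sc_ = roll(x), roll(y), roll(c)
    sxy, sxc = roll(x * y), roll(x * c)
    cov_xy = sxy - sx * sy / k
    cov_xc = sxc - sx * sc_ / k
    return cov_xy, cov_xc


def kpoint_agreement_score(run: RoiRun, k: int) -> float:
    """Fraction of windows satisfying the trained-state pattern.

    ``k = 2`` reproduces the streaming rule exactly (score equals the fired
    fraction of :func:`run_feedback_session`).  For ``k`` in 3..6 the score
    generalises it to sliding windows of length ``k``: a window counts when
    its within-window Pearson r(target1, target2) is positive and
    r(target1, control) is negative.
    """
    if not 2 <= k <= 6:
        raise ValueError(f"k must be in 2..6, got {k}")
    if run.n_tr < k:
        raise ValueError(f"run has {run.n_tr} TRs, needs at least k={k}")
    if k == 2:
        d = np.diff(run.series, axis=0)
        s = np.sign(d)
        fired = (s[:, 0] != 0) & (s[:, 0] == s[:, 1]) & (s[:, 2] == -s[:, 0])
        return float(fired.mean())
    cov_xy, cov_xc = _window_covariances(run.series, k)
    return float(((cov_xy > 0) & (cov_xc < 0)).mean())
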