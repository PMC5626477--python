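"""Offline connectivity metrics and validation of the two-point proxy.

The offline measure of learning is the pairwise Pearson correlation of the
three ROI mean signals, its Fisher z-transform (atanh), and the composite
difference measure

    composite = r(target1, target2) - (r(target1, control) + r(target2, control)) / 2

which rises both when the trained target-target coupling rises and when the
target-control couplings fall.  ``validate_proxy`` checks that the streaming
two-point score is a faithful stand-in for the full-run Pearson correlation
by correlating the two across a collection of runs, with a permutation
p-value from run-label shuffling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from covertnf.cohort import ROI_NAMES, RoiRun
from covertnf.feedback import kpoint_agreement_score


class DegenerateSeriesError(ValueError):
    """An ROI series has zero variance; correlation is undefined."""


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher z-transform, atanh(r)."""
    return np.arctanh(r)


def composite_measure(r_t1t2: float, r_t1c: float, r_t2c: float) -> float:
    """Target-target correlation minus the mean of the two target-control ones."""
    return r_t1t2 - (r_t1c + r_t2c) / 2.0


@dataclass(frozen=True)
class ConnectivityRecord:
    """One run's pairwise correlations, Fisher z values and composite."""

    subject_id: str
    day: str
    run_index: int
    run_type: str
    r_t1t2: float
    r_t1c: float
    r_t2c: float

    @property
    def z_t1t2(self) -> float:
        return float(fisher_z(self.r_t1t2))

    @property
    def z_t1c(self) -> float:
        return float(fisher_z(self.r_t1c))

    @property
    def z_t2c(self) -> float:
        return float(fisher_z(self.r_t2c))

    @property
    def composite(self) -> float:
        return composite_measure(self.r_t1t2, self.r_t1c, self.r_t2c)


def pairwise_connectivity(run: RoiRun) -> ConnectivityRecord:
    """Full-run Pearson correlations of the three ROI pairs."""
    if run.n_tr < 3:
        raise ValueError("need n_tr >= 3 for a meaningful correlation")
    sd = run.series.std(axis=0)
    scale = np.maximum(np.abs(run.series).max(axis=0), 1.0)
    for name, s, sc in zip(ROI_NAMES, sd, scale):
        if s <= 1e-12 * sc:
            raise DegenerateSeriesError(f"ROI {name!r} series is constant")
    c = np.corrcoef(run.series, rowvar=False)
    return ConnectivityRecord(
        subject_id=run.subject_id,
        day=run.day,
        run_index=run.run_index,
        run_type=run.run_type,
        r_t1t2=float(c[0, 1]),
        r_t1c=float(c[0, 2]),
        r_t2c=float(c[1, 2]),
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def permutation_pvalue_correlation(
    x: np.ndarray,
    y: np.ndarray,
    n_iterations: int = 5000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> float:
    """Permutation p-value for a Pearson correlation by shuffling ``y``.

    Vectorised: with both variables standardised, each permuted r is a dot
    product.  Add-one smoothed so p is never exactly zero.
    """
    if n_iterations < 100:
        raise ValueError("n_iterations must be >= 100")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    obs = float(xs @ ys / n)
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_iterations, n)), axis=1)
    r_null = (ys[perms] @ xs) / n
    if alternative == "two-sided":
        hits = np.abs(r_null) >= abs(obs)
    elif alternative == "greater":
        hits = r_null >= obs
    elif alternative == "less":
        hits = r_null <= obs
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float((1 + hits.sum()) / (n_iterations + 1))


def validate_proxy(
    runs: Sequence[RoiRun],
    k: int = 2,
    n_iterations: int = 5000,
    seed: int = 0,
) -> dict:
    """Correlate the per-run two-point score with the offline Pearson r.

    Returns per-run scores and correlations, the across-run Pearson
    correlation between the proxy score and r(target1, target2), and a
    run-label permutation p-value.  Also reported per subject (when runs
    carry >= 3 runs of a subject) since pooled and within-subject validation
    can differ.
    """
    if len(runs) < 10:
        raise ValueError("need at least 10 runs to validate the proxy")
    proxy = np.array([kpoint_agreement_score(r, k) for r in runs])
    pearson = np.array([pairwise_connectivity(r).r_t1t2 for r in runs])
    out: dict = {
        "k": k,
        "n_runs": len(runs),
        "proxy_scores": proxy,
        "pearson_r_t1t2": pearson,
    }
    if proxy.std() == 0 or pearson.std() == 0:
        out["proxy_pearson_correlation"] = None
        out["permutation_p"] = None
        out["degenerate"] = "zero variance in proxy scores or Pearson r"
        return out
    out["proxy_pearson_correlation"] = _pearson(proxy, pearson)
    out["permutation_p"] = permutation_pvalue_correlation(
        proxy, pearson, n_iterations=n_iterations, seed=seed
    )
    by_subject: dict[str, float | None] = {}
    subjects = {r.subject_id for r in runs}
    for sid in sorted(subjects):
        idx = [i for i, r in enumerate(runs) if r.subject_id == sid]
        if len(idx) >= 3 and proxy[idx].std() > 0 and pearson[idx].std() > 0:
            by_subject[sid] = _pearson(proxy[idx], pearson[idx])
    if len(by_subject) > 1:
        out["within_subject_correlations"] = by_subject
        out["within_subject_mean"] = float(np.mean(list(by_subject.values())))
    return out
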