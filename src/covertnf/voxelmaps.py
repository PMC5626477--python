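"""Voxelwise differential-correlation change maps with cluster correction.

For each subject and feedback run, every voxel's time series is correlated
with the mean seed-ROI series (and optionally a reference ROI), Fisher
z-transformed, and the difference z(seed) - z(reference) taken; run maps are
averaged per day and the day_a average subtracted from the day_b average.
A positive voxel value means the voxel became differentially more coupled to
the seed than to the reference between the two days.

Group inference is a one-sample t-test across subjects per voxel, corrected
for familywise error by a cluster-size permutation test: under the paired
null the two day labels are exchangeable per subject, which for the change
map is exactly a per-subject sign flip.  The null distribution of the
maximum supra-threshold cluster size (6-neighbour connectivity, positive and
negative clusters separately) is built at several voxelwise p thresholds,
each yielding its own minimum significant cluster size, and the final mask
is the union of voxels surviving at any threshold.

Voxels inside the seed or reference sphere correlate with themselves by
construction; they are flagged and excluded from peak reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from covertnf.cohort import VoxelCohort

DEFAULT_THRESHOLDS = (0.05, 0.01, 0.005, 0.001, 0.0005)
#: faces-only 3-D connectivity (6 neighbours)
_STRUCTURE = ndimage.generate_binary_structure(3, 1)
_Z_CAP = 0.999999


def _corr_with_seed(data2d: np.ndarray, seed_series: np.ndarray) -> np.ndarray:
    """Pearson r of every voxel (rows) with one series; constant rows -> NaN."""
    x = data2d - data2d.mean(axis=1, keepdims=True)
    s = seed_series - seed_series.mean()
    xn = np.linalg.norm(x, axis=1)
    sn = np.linalg.norm(s)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x @ s) / (xn * sn)
    r[xn == 0] = np.nan
    return r


def _run_zmap(
    run: np.ndarray, seed_mask: np.ndarray, reference_mask: np.ndarray | None
) -> np.ndarray:
    shape = run.shape[:3]
    flat = run.reshape(-1, run.shape[3]).astype(float)
    seed_series = flat[seed_mask.ravel()].mean(axis=0)
    r = _corr_with_seed(flat, seed_series)
    z = np.arctanh(np.clip(r, -_Z_CAP, _Z_CAP))
    if reference_mask is not None:
        ref_series = flat[reference_mask.ravel()].mean(axis=0)
        r_ref = _corr_with_seed(flat, ref_series)
        z = z - np.arctanh(np.clip(r_ref, -_Z_CAP, _Z_CAP))
    return z.reshape(shape)


@dataclass
class VoxelChangeMap:
    """Per-subject day-contrast grid with its masks and undefined-voxel count."""

    data: np.ndarray  # 3-D grid of z-scale change values (NaN where undefined)
    seed_mask: np.ndarray
    reference_mask: np.ndarray | None
    flagged_mask: np.ndarray  # seed (and reference) voxels: self-correlation
    n_undefined: int


def seed_change_map(
    day_a_runs: Sequence[np.ndarray],
    day_b_runs: Sequence[np.ndarray],
    seed_mask: np.ndarray,
    reference_mask: np.ndarray | None = None,
) -> VoxelChangeMap:
    """Day-contrast map of (differential) seed correlation for one subject.

    ``day_*_runs`` are 4-D grids (x, y, z, t); per run the voxelwise Fisher-z
    (differential) correlation with the seed mean series is computed, run
    maps are averaged within day, and ``mean(day_b) - mean(day_a)`` returned.
    """
    if not day_a_runs or not day_b_runs:
        raise ValueError("need at least one run per day")
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    za = np.mean([_run_zmap(r, seed_mask, reference_mask) for r in day_a_runs], axis=0)
    zb = np.mean([_run_zmap(r, seed_mask, reference_mask) for r in day_b_runs], axis=0)
    change = zb - za
    flagged = seed_mask.copy()
    if reference_mask is not None:
        flagged = flagged | reference_mask
    return VoxelChangeMap(
        data=change,
        seed_mask=seed_mask,
        reference_mask=reference_mask,
        flagged_mask=flagged,
        n_undefined=int(np.isnan(change).sum()),
    )


def subject_change_map(
    cohort: VoxelCohort,
    subject_idx: int,
    day_a: str = "day1",
    day_b: str = "day4",
    seed_roi: str = "target1",
    reference_roi: str | None = "control",
    run_indices: Sequence[int] | None = None,
) -> VoxelChangeMap:
    """Convenience wrapper generating a synthetic subject's feedback runs."""
    if run_indices is None:
        run_indices = cohort.feedback_run_indices()
    seed_mask = cohort.roi_masks[seed_roi]
    ref_mask = cohort.roi_masks[reference_roi] if reference_roi else None
    runs_a = [cohort.run(subject_idx, day_a, i) for i in run_indices]
    runs_b = [cohort.run(subject_idx, day_b, i) for i in run_indices]
    return seed_change_map(runs_a, runs_b, seed_mask, ref_mask)


def group_ttest_map(change_grids: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t (against 0) and two-tailed p per voxel across subjects.

    Voxels undefined (NaN) in any subject are excluded (NaN in both outputs).
    """
    x = np.stack([np.asarray(g, dtype=float) for g in change_grids])
    if x.shape[0] < 3:
        raise ValueError("need >= 3 subjects for a group t-test")
    n = x.shape[0]
    valid = ~np.isnan(x).any(axis=0)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    t[~valid] = np.nan
    p[~valid] = np.nan
    return t, p


def _max_cluster_size(mask: np.ndarray) -> int:
    lab, nlab = ndimage.label(mask, structure=_STRUCTURE)
    if nlab == 0:
        return 0
    return int(np.bincount(lab.ravel())[1:].max())


def _signed_max_cluster(t_grid: np.ndarray, tcrit: float) -> int:
    pos = _max_cluster_size(t_grid > tcrit)
    neg = _max_cluster_size(t_grid < -tcrit)
    return max(pos, neg)


def _min_significant_size(null_sizes: np.ndarray, alpha: float) -> int:
    """Smallest cluster size s with add-one permutation p <= alpha."""
    n = null_sizes.size
    allowed = int(np.floor(alpha * (n + 1) - 1))
    if allowed < 0:
        return int(null_sizes.max()) + 1  # alpha unattainably small
    if allowed >= n:
        return 1
    srt = np.sort(null_sizes)
    return int(srt[n - allowed - 1]) + 1


@dataclass
class ClusterCorrectionResult:
    thresholds: tuple[float, ...]
    n_permutations: int
    alpha: float
    connectivity: str
    min_cluster_sizes: Mapping[float, int]
    null_max_sizes: Mapping[float, np.ndarray]
    union_mask: np.ndarray
    clusters: pd.DataFrame
    t_grid: np.ndarray
    seed: int

    @property
    def any_survivor(self) -> bool:
        return bool(self.union_mask.any())


def cluster_permutation_correct(
    change_grids: Sequence[np.ndarray],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    n_permutations: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
    exclude_mask: np.ndarray | None = None,
) -> ClusterCorrectionResult:
    """Multi-threshold cluster-size permutation correction of a group map.

    The paired null (day labels exchangeable within subject) is realised as
    independent per-subject sign flips of the change grids — exact for a
    day_b - day_a contrast.  For each voxelwise p threshold the null maximum
    supra-threshold cluster size determines the minimum significant size;
    the union mask collects voxels surviving at any threshold.
    ``exclude_mask`` voxels (seed/reference spheres) are dropped from peak
    reporting, never from clustering.
    """
    if len(change_grids) < 5:
        raise ValueError("need >= 5 subjects for cluster permutation correction")
    if not thresholds:
        raise ValueError("thresholds must be nonempty")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    x = np.stack([np.asarray(g, dtype=float) for g in change_grids])
    n, shape = x.shape[0], x.shape[1:]
    flat = np.nan_to_num(x.reshape(n, -1))
    ssq = (flat**2).sum(axis=0)
    tcrits = {p: float(stats.t.ppf(1.0 - p / 2.0, df=n - 1)) for p in thresholds}

    def t_from_signs(signs: np.ndarray) -> np.ndarray:
        m = (signs @ flat) / n
        var = np.clip((ssq / n - m**2) * n / (n - 1), 1e-30, None)
        return (m / np.sqrt(var / n)).reshape(shape)

    rng = np.random.default_rng(seed)
    null: dict[float, np.ndarray] = {p: np.empty(n_permutations) for p in thresholds}
    for i in range(n_permutations):
        signs = rng.integers(0, 2, size=n) * 2 - 1
        t_perm = t_from_signs(signs)
        for p in thresholds:
            null[p][i] = _signed_max_cluster(t_perm, tcrits[p])

    min_sizes = {p: _min_significant_size(null[p], alpha) for p in thresholds}
    t_obs = t_from_signs(np.ones(n))

    union = np.zeros(shape, dtype=bool)
    rows = []
    cid = 0
    for p in thresholds:
        for sign, mask in (
            (1, t_obs > tcrits[p]),
            (-1, t_obs < -tcrits[p]),
        ):
            lab, nlab = ndimage.label(mask, structure=_STRUCTURE)
            for j in range(1, nlab + 1):
                members = lab == j
                size = int(members.sum())
                if size < min_sizes[p]:
                    continue
                union |= members
                peak_candidates = members.copy()
                if exclude_mask is not None:
                    peak_candidates &= ~exclude_mask
                if peak_candidates.any():
                    tv = np.where(peak_candidates, np.abs(t_obs), -np.inf)
                    peak = np.unravel_index(int(np.argmax(tv)), shape)
                    peak_t = float(t_obs[peak])
                else:
                    peak, peak_t = None, float("nan")
                cid += 1
                rows.append(
                    {
                        "cluster_id": cid,
                        "threshold": p,
                        "sign": sign,
                        "size": size,
                        "peak_index": peak,
                        "peak_t": peak_t,
                    }
                )
    clusters = pd.DataFrame(
        rows, columns=["cluster_id", "threshold", "sign", "size", "peak_index", "peak_t"]
    )
    return ClusterCorrectionResult(
        thresholds=tuple(thresholds),
        n_permutations=n_permutations,
        alpha=alpha,
        connectivity="6-neighbour (faces only)",
        min_cluster_sizes=min_sizes,
        null_max_sizes=null,
        union_mask=union,
        clusters=clusters,
        t_grid=t_obs,
        seed=seed,
    )
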