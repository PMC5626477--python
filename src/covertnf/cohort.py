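"""Seeded synthetic cohorts with programmable connectivity trajectories.

The generator emulates the data structure of a multi-day covert neurofeedback
study: per subject and day, a sequence of resting and feedback runs, each a
270-sample time series (TR = 2 s) for three ROIs — two training targets and
one control.  Inter-ROI correlations follow a programmable day-by-day
trajectory (e.g. an ASD-like arm with low target–target and elevated
target1–control coupling at baseline that moves toward the trained pattern,
or a TD-like arm with no programmed change).  Signals are latent multivariate
Gaussian innovations, AR(1)-filtered per ROI with a common coefficient (which
preserves the innovation correlation structure), plus slow sinusoidal and
linear drift and white innovation noise.

A small voxel-grid counterpart assigns voxels to three spherical "networks"
around the ROI centres; voxels share their network's latent signal plus voxel
noise, and inter-network latent correlations follow a per-day coupling
trajectory.  A behavioral generator links a per-subject change score to the
programmed connectivity change with a configurable slope and noise.

Everything is deterministic given a spec and seed: each run draws from an
independent stream keyed by ``(seed, subject, day, run)``, so regenerating
any subset reproduces it bit for bit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

ROI_NAMES = ("target1", "target2", "control")
#: pair order used throughout: (t1,t2), (t1,c), (t2,c)
PAIR_NAMES = ("t1t2", "t1c", "t2c")
PAIR_INDEX = ((0, 1), (0, 2), (1, 2))

#: Talairach coordinates (mm) of the study's 4-mm spherical ROIs:
#: left superior temporal sulcus, left somatosensory cortex, and a right
#: inferior parietal control region.  Used when masking user-supplied volumes
#: with a real affine; the synthetic grid uses grid-local centres instead.
TALAIRACH_ROI_CENTERS_MM = {
    "target1": (-49.0, -29.0, 0.0),
    "target2": (-54.0, 14.0, 39.0),
    "control": (49.0, -50.0, 42.0),
}

DEFAULT_DAYS = ("day1", "day2", "day3", "day4", "followup")


class CohortSpecError(ValueError):
    """Raised when a cohort specification is internally inconsistent."""


# ---------------------------------------------------------------------------
# correlation-matrix helpers


def pairs_to_matrix(r_t1t2: float, r_t1c: float, r_t2c: float) -> np.ndarray:
    """Assemble the 3x3 ROI correlation matrix from its three free entries."""
    m = np.eye(3)
    m[0, 1] = m[1, 0] = r_t1t2
    m[0, 2] = m[2, 0] = r_t1c
    m[1, 2] = m[2, 1] = r_t2c
    return m


def matrix_to_pairs(m: np.ndarray) -> tuple[float, float, float]:
    return float(m[0, 1]), float(m[0, 2]), float(m[1, 2])


def is_valid_correlation(m: np.ndarray, tol: float = 1e-10) -> bool:
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        return False
    if not np.allclose(m, m.T, atol=1e-12):
        return False
    if not np.allclose(np.diag(m), 1.0, atol=1e-12):
        return False
    return float(np.linalg.eigvalsh(m)[0]) >= -tol


def nearest_psd(m: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Nearest-PSD repair by eigenvalue clipping, rescaled to unit diagonal."""
    m = np.asarray(m, dtype=float)
    w, v = np.linalg.eigh((m + m.T) / 2.0)
    w = np.clip(w, eig_floor, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


# ---------------------------------------------------------------------------
# specs


def _default_baseline() -> np.ndarray:
    # ASD-like baseline: weak target-target coupling, elevated target1-control.
    return pairs_to_matrix(0.10, 0.25, 0.05)


def _linear_deltas(
    total: tuple[float, float, float],
    days: Sequence[str] = DEFAULT_DAYS,
    training_days: int = 4,
) -> dict[str, tuple[float, float, float]]:
    """Linear day1->day4 ramp toward ``total``; follow-up holds the day4 level."""
    out: dict[str, tuple[float, float, float]] = {}
    for i, day in enumerate(days):
        f = min(i, training_days - 1) / (training_days - 1)
        out[day] = tuple(f * t for t in total)
    return out


@dataclass
class CohortSpec:
    """Specification of one synthetic study arm.

    Defaults reproduce the study's structure: 270 TRs per run at TR = 2 s,
    per day 2 pre-feedback rest runs, 4 feedback runs and 2 post-feedback
    rest runs, over four training days plus a follow-up session.  The default
    trajectory is the ASD-like trained arm: target1-target2 correlation rises
    by +0.11 from day1 to day4, target1-control falls by -0.13 and
    target2-control by -0.03, i.e. a composite-measure change of +0.19.
    """

    n_subjects: int = 17
    group_label: str = "ASD-like"
    days: tuple[str, ...] = DEFAULT_DAYS
    runs_per_day: Mapping[str, int] = field(
        default_factory=lambda: {"rest_pre": 2, "feedback": 4, "rest_post": 2}
    )
    n_tr: int = 270
    tr_seconds: float = 2.0
    baseline_corr: np.ndarray = field(default_factory=_default_baseline)
    day_deltas: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: _linear_deltas((0.11, -0.13, -0.03))
    )
    ar_coeff: float = 0.3
    drift_amplitude: float = 0.2
    noise_sd: float = 1.0
    #: SD of the per-subject multiplicative scale on day_deltas (mean 1);
    #: gives the cohort responders and non-responders.  0 = homogeneous.
    subject_scale_sd: float = 0.5
    seed: int = 0
    repair_non_psd: bool = False

    @classmethod
    def asd_like(cls, **kw) -> "CohortSpec":
        return cls(**kw)

    @classmethod
    def td_like(cls, n_subjects: int = 10, **kw) -> "CohortSpec":
        """Control arm: neurotypical-like baseline, no programmed change."""
        kw.setdefault("group_label", "TD-like")
        kw.setdefault("baseline_corr", pairs_to_matrix(0.35, 0.0, 0.0))
        kw.setdefault("day_deltas", {d: (0.0, 0.0, 0.0) for d in DEFAULT_DAYS})
        return cls(n_subjects=n_subjects, **kw)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise CohortSpecError("n_subjects must be >= 1")
        if self.n_tr < 2:
            raise CohortSpecError("n_tr must be >= 2")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise CohortSpecError("ar_coeff must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise CohortSpecError("noise_sd must be positive")
        for phase in ("rest_pre", "feedback", "rest_post"):
            if phase not in self.runs_per_day:
                raise CohortSpecError(f"runs_per_day missing phase {phase!r}")

    def day_correlations(self) -> tuple[dict[str, np.ndarray], list[str]]:
        """Per-day target correlation matrices; second element lists repaired days.

        Raises :class:`CohortSpecError` naming the first offending day when a
        day's implied matrix is not a valid correlation matrix and repair is
        disabled.
        """
        out: dict[str, np.ndarray] = {}
        repaired: list[str] = []
        base = np.asarray(self.baseline_corr, dtype=float)
        for day in self.days:
            delta = self.day_deltas.get(day, (0.0, 0.0, 0.0))
            b = matrix_to_pairs(base)
            m = pairs_to_matrix(*(bi + di for bi, di in zip(b, delta)))
            if not is_valid_correlation(m):
                if not self.repair_non_psd:
                    raise CohortSpecError(
                        f"correlation matrix for {day!r} is not positive "
                        f"semidefinite (pairs={matrix_to_pairs(m)}); enable "
                        "repair_non_psd for nearest-PSD repair"
                    )
                m = nearest_psd(m)
                repaired.append(day)
            out[day] = m
        return out, repaired


@dataclass
class RoiRun:
    """One run's three-ROI time series plus run metadata.

    ``series`` is ``n_tr x 3`` in the order (target1, target2, control).
    ``run_index`` orders runs within a day: pre-feedback rest runs first,
    then feedback runs, then post-feedback rest runs.
    """

    subject_id: str
    day: str
    run_index: int
    run_type: str  # "rest" | "feedback"
    series: np.ndarray

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2 or self.series.shape[1] != 3:
            raise ValueError("series must be an n_tr x 3 array")
        if self.series.shape[0] < 2:
            raise ValueError("series must have n_tr >= 2")
        if np.isnan(self.series).any():
            raise ValueError("series contains missing values")

    @property
    def n_tr(self) -> int:
        return self.series.shape[0]


@dataclass
class RoiCohort:
    """All runs of one arm, plus the spec and PSD-repair provenance."""

    spec: CohortSpec
    runs: list[RoiRun]
    repaired_days: list[str]

    @property
    def subject_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.runs:
            seen.setdefault(r.subject_id, None)
        return list(seen)

    def select(
        self,
        subject_id: str | None = None,
        day: str | None = None,
        run_type: str | None = None,
    ) -> list[RoiRun]:
        out = self.runs
        if subject_id is not None:
            out = [r for r in out if r.subject_id == subject_id]
        if day is not None:
            out = [r for r in out if r.day == day]
        if run_type is not None:
            out = [r for r in out if r.run_type == run_type]
        return out


# ---------------------------------------------------------------------------
# ROI time-series synthesis

_BURN_IN = 100


def _run_stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


def _synth_series(
    rng: np.random.Generator,
    corr: np.ndarray,
    n_tr: int,
    ar: float,
    drift_amplitude: float,
    noise_sd: float,
) -> np.ndarray:
    """One run: correlated AR(1) signals with unit variance plus drift."""
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(3))
    innov = rng.standard_normal((n_tr + _BURN_IN, 3)) @ chol.T
    if ar > 0:
        x = lfilter([1.0], [1.0, -ar], innov, axis=0)
        x = x[_BURN_IN:] * np.sqrt(1.0 - ar**2)
    else:
        x = innov[_BURN_IN:]
    x = x * noise_sd
    if drift_amplitude > 0:
        t = np.arange(n_tr)[:, None] / n_tr
        freq = rng.uniform(0.5, 2.0, size=3)
        phase = rng.uniform(0.0, 2.0 * np.pi, size=3)
        slope = rng.uniform(-1.0, 1.0, size=3)
        drift = np.sin(2.0 * np.pi * freq * t + phase) + slope * (2.0 * t - 1.0)
        x = x + drift_amplitude * noise_sd * drift
    return x


def _day_run_layout(spec: CohortSpec) -> list[tuple[int, str]]:
    layout: list[tuple[int, str]] = []
    idx = 0
    for phase, rt in (("rest_pre", "rest"), ("feedback", "feedback"), ("rest_post", "rest")):
        for _ in range(int(spec.runs_per_day[phase])):
            layout.append((idx, rt))
            idx += 1
    return layout


def generate_roi_cohort(spec: CohortSpec) -> RoiCohort:
    """Generate one arm's full set of :class:`RoiRun` objects.

    Empirical inter-ROI correlations converge (in expectation over runs) to
    the day's programmed matrix; an equal AR(1) coefficient across ROIs
    preserves the programmed innovation correlations, and drift dilutes them
    only by the documented factor ``1 / (1 + drift_power)``.
    """
    spec.validate()
    day_corr, repaired = spec.day_correlations()
    layout = _day_run_layout(spec)
    base_pairs = matrix_to_pairs(np.asarray(spec.baseline_corr, dtype=float))
    runs: list[RoiRun] = []
    for s in range(spec.n_subjects):
        sid = f"{spec.group_label.split('-')[0].lower()}{s + 1:02d}"
        if spec.subject_scale_sd > 0:
            scale = float(
                1.0 + spec.subject_scale_sd * _run_stream(spec.seed, 4201, s).standard_normal()
            )
            subj_corr = {}
            for day in spec.days:
                delta = spec.day_deltas.get(day, (0.0, 0.0, 0.0))
                m = pairs_to_matrix(
                    *(b + scale * d for b, d in zip(base_pairs, delta))
                )
                # per-subject scaling can push an extreme responder's matrix
                # slightly outside the PSD cone; repair silently (safety net,
                # independent of the spec-level repair switch)
                subj_corr[day] = m if is_valid_correlation(m) else nearest_psd(m)
        else:
            subj_corr = day_corr
        for d, day in enumerate(spec.days):
            for run_index, run_type in layout:
                rng = _run_stream(spec.seed, s, d, run_index)
                series = _synth_series(
                    rng,
                    subj_corr[day],
                    spec.n_tr,
                    spec.ar_coeff,
                    spec.drift_amplitude,
                    spec.noise_sd,
                )
                runs.append(RoiRun(sid, day, run_index, run_type, series))
    return RoiCohort(spec=spec, runs=runs, repaired_days=repaired)


# ---------------------------------------------------------------------------
# voxel-grid cohort


def sphere_mask(
    shape: tuple[int, int, int],
    center_mm: Sequence[float],
    radius_mm: float,
    voxel_size_mm: float,
) -> np.ndarray:
    """Boolean mask of voxels whose centres lie within ``radius_mm`` of a point.

    The grid affine is diagonal: voxel (i,j,k) has its centre at
    ``(i,j,k) * voxel_size_mm``.
    """
    grids = np.meshgrid(*(np.arange(n) * voxel_size_mm for n in shape), indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_mm))
    return d2 <= radius_mm**2


def _default_voxel_centers() -> tuple[tuple[float, float, float], ...]:
    # grid-local centres (mm), well separated inside the default 24^3 grid
    v = 3.2
    return (
        (6 * v, 6 * v, 12 * v),
        (17 * v, 6 * v, 12 * v),
        (12 * v, 17 * v, 12 * v),
    )


@dataclass
class VoxelGridSpec:
    """Small 3-D grid with three spherical ROI/network assignments.

    Each of the three networks is a sphere of ``network_radius_mm`` around an
    ROI centre; the 4-mm ROI sphere sits inside it.  Voxels in a network share
    the network's latent signal plus white voxel noise; background voxels are
    independent noise.  ``baseline_coupling``/``day_deltas`` program the
    inter-network latent correlations per day, in the same (net1-net2,
    net1-control, net2-control) pair order as the ROI cohort.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.2
    roi_centers: tuple[tuple[float, float, float], ...] = field(
        default_factory=_default_voxel_centers
    )
    roi_radius_mm: float = 4.0
    network_radius_mm: float = 8.0
    baseline_coupling: np.ndarray = field(default_factory=lambda: np.eye(3))
    day_deltas: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)
    voxel_noise_sd: float = 0.5

    def validate(self) -> None:
        for c in self.roi_centers:
            for x, n in zip(c, self.grid_shape):
                lo = x - self.network_radius_mm
                hi = x + self.network_radius_mm
                if lo < -self.voxel_size_mm / 2 or hi > (n - 0.5) * self.voxel_size_mm:
                    need = int(np.ceil(2 * self.network_radius_mm / self.voxel_size_mm)) + 1
                    raise CohortSpecError(
                        f"grid {self.grid_shape} too small for a sphere of "
                        f"{self.network_radius_mm} mm at {c}; each axis needs "
                        f">= {need} voxels around the centre"
                    )

    def roi_masks(self) -> dict[str, np.ndarray]:
        masks = {
            name: sphere_mask(self.grid_shape, c, self.roi_radius_mm, self.voxel_size_mm)
            for name, c in zip(ROI_NAMES, self.roi_centers)
        }
        self._check_masks(masks, self.roi_centers)
        return masks

    def network_masks(self) -> dict[str, np.ndarray]:
        names = ("network1", "network2", "control_network")
        masks = {
            name: sphere_mask(self.grid_shape, c, self.network_radius_mm, self.voxel_size_mm)
            for name, c in zip(names, self.roi_centers)
        }
        self._check_masks(masks, self.roi_centers)
        return masks

    def _check_masks(self, masks, centers) -> None:
        total = np.zeros(self.grid_shape, dtype=int)
        for (name, m), c in zip(masks.items(), centers):
            if not m.any():
                raise CohortSpecError(f"mask {name!r} is empty")
            ci = tuple(int(round(x / self.voxel_size_mm)) for x in c)
            if not m[ci]:
                raise CohortSpecError(f"centre voxel of {name!r} not inside its mask")
            total += m.astype(int)
        if (total > 1).any():
            raise CohortSpecError("spherical masks overlap; move the centres apart")

    def network_assignment(self) -> np.ndarray:
        """Integer label grid: 0 background, 1..3 the three networks."""
        lab = np.zeros(self.grid_shape, dtype=np.int16)
        for i, m in enumerate(self.network_masks().values(), start=1):
            lab[m] = i
        return lab

    def day_couplings(self, days: Iterable[str]) -> dict[str, np.ndarray]:
        out = {}
        base = np.asarray(self.baseline_coupling, dtype=float)
        for day in days:
            delta = self.day_deltas.get(day, (0.0, 0.0, 0.0))
            b = matrix_to_pairs(base)
            m = pairs_to_matrix(*(bi + di for bi, di in zip(b, delta)))
            if not is_valid_correlation(m):
                raise CohortSpecError(f"coupling matrix for {day!r} is not PSD")
            out[day] = m
        return out


class VoxelCohort:
    """Lazy collection of per-(subject, day, run) 4-D grids plus masks.

    Runs are synthesised on demand (and deterministically) because a full
    voxel cohort would not fit in memory; ``run()`` always returns the same
    array for the same key.
    """

    def __init__(self, vspec: VoxelGridSpec, cspec: CohortSpec):
        vspec.validate()
        cspec.validate()
        self.vspec = vspec
        self.cspec = cspec
        self.labels = vspec.network_assignment()
        self.roi_masks = vspec.roi_masks()
        self.network_masks = vspec.network_masks()
        self._couplings = vspec.day_couplings(cspec.days)
        self._layout = _day_run_layout(cspec)

    def feedback_run_indices(self) -> list[int]:
        return [i for i, rt in self._layout if rt == "feedback"]

    def run(self, subject_idx: int, day: str, run_index: int) -> np.ndarray:
        """One 4-D grid, shape ``grid_shape + (n_tr,)``, float32."""
        d = list(self.cspec.days).index(day)
        rng = _run_stream(self.cspec.seed, 7001, subject_idx, d, run_index)
        n_tr = self.cspec.n_tr
        ar = self.cspec.ar_coeff
        chol = np.linalg.cholesky(self._couplings[day] + 1e-12 * np.eye(3))
        innov = rng.standard_normal((n_tr + _BURN_IN, 3)) @ chol.T
        if ar > 0:
            lat = lfilter([1.0], [1.0, -ar], innov, axis=0)[_BURN_IN:]
            lat *= np.sqrt(1.0 - ar**2)
        else:
            lat = innov[_BURN_IN:]
        flat_labels = self.labels.ravel()
        data = rng.standard_normal((flat_labels.size, n_tr)).astype(np.float32)
        for k in (1, 2, 3):
            sel = flat_labels == k
            data[sel] = (
                lat[:, k - 1][None, :] + self.vspec.voxel_noise_sd * data[sel]
            ).astype(np.float32)
        return data.reshape(self.vspec.grid_shape + (n_tr,))


def generate_voxel_cohort(vspec: VoxelGridSpec, cspec: CohortSpec) -> VoxelCohort:
    """Build the lazy voxel-grid cohort for one arm."""
    return VoxelCohort(vspec, cspec)


# ---------------------------------------------------------------------------
# synthetic behavior


@dataclass
class SyntheticBehaviorSpec:
    """Programmed linear link between connectivity change and behavior change.

    ``slope`` is in scale points per unit composite-correlation change;
    the defaults (slope 30, noise 4.5 points, reference SD 5) put the
    programmed population correlation in the moderate range typical of
    brain-behavior effects given the default cohort's connectivity-change
    spread (~0.1), with genuine changes only rarely crossing the 3-SD
    reference band.  Injected outliers are placed ``outlier_magnitude_sd``
    reference SDs below the reference mean so the downstream 3-SD rule flags
    exactly those rows.
    """

    slope: float = 30.0
    noise_sd: float = 4.5
    n_outliers: int = 0
    seed: int = 0
    reference_mean: float = 0.0
    reference_sd: float = 5.0
    outlier_magnitude_sd: float = 6.0


def generate_reference_changes(
    n: int = 50, mean: float = 0.0, sd: float = 5.0, seed: int = 0
) -> np.ndarray:
    """Synthetic stand-in for an independent test-retest change sample."""
    rng = np.random.default_rng([seed, 9101])
    return mean + sd * rng.standard_normal(n)


def generate_behavior(
    connectivity_changes: Mapping[str, float] | pd.Series,
    spec: SyntheticBehaviorSpec,
) -> pd.DataFrame:
    """Per-subject pre/post SRS and BRIEF scores linked to connectivity change.

    SRS change is ``slope * connectivity_change + noise``; change scores are
    pre minus post, so a positive change is symptom reduction.  BRIEF change
    is independent noise of the same scale (the non-social control measure).
    """
    changes = pd.Series(dict(connectivity_changes), dtype=float)
    rng = np.random.default_rng([spec.seed, 9102])
    n = len(changes)
    srs_change = spec.slope * changes.to_numpy()
    if spec.noise_sd > 0:
        srs_change = srs_change + spec.noise_sd * rng.standard_normal(n)
    brief_change = spec.noise_sd * rng.standard_normal(n)
    injected = np.zeros(n, dtype=bool)
    if spec.n_outliers > 0:
        if spec.n_outliers > n:
            raise ValueError("n_outliers exceeds cohort size")
        idx = rng.choice(n, size=spec.n_outliers, replace=False)
        srs_change = srs_change.copy()
        srs_change[idx] = spec.reference_mean - spec.outlier_magnitude_sd * spec.reference_sd
        injected[idx] = True
    srs_pre = 70.0 + 8.0 * rng.standard_normal(n)
    brief_pre = 65.0 + 8.0 * rng.standard_normal(n)
    return pd.DataFrame(
        {
            "subject_id": changes.index,
            "srs_pre": srs_pre,
            "srs_post": srs_pre - srs_change,
            "srs_change": srs_change,
            "brief_pre": brief_pre,
            "brief_post": brief_pre - brief_change,
            "brief_change": brief_change,
            "injected_outlier": injected,
        }
    ).set_index("subject_id")
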