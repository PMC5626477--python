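"""Synthetic-cohort generator: determinism, correlation targeting, PSD safety."""

import numpy as np
import pytest

from covertnf.cohort import (
    CohortSpec,
    CohortSpecError,
    SyntheticBehaviorSpec,
    VoxelGridSpec,
    generate_behavior,
    generate_reference_changes,
    generate_roi_cohort,
    generate_voxel_cohort,
    is_valid_correlation,
    nearest_psd,
    pairs_to_matrix,
    sphere_mask,
)


def _long_run_spec(**kw):
    kw.setdefault("n_subjects", 1)
    kw.setdefault("days", ("day1",))
    kw.setdefault("day_deltas", {})
    kw.setdefault("runs_per_day", {"rest_pre": 0, "feedback": 1, "rest_post": 0})
    kw.setdefault("n_tr", 10000)
    kw.setdefault("subject_scale_sd", 0.0)
    kw.setdefault("drift_amplitude", 0.0)
    kw.setdefault("ar_coeff", 0.0)
    return CohortSpec(**kw)


def test_identity_correlation_yields_near_zero_empirical_r():
    spec = _long_run_spec(baseline_corr=np.eye(3), seed=1)
    run = generate_roi_cohort(spec).runs[0]
    c = np.corrcoef(run.series, rowvar=False)
    off = c[np.triu_indices(3, 1)]
    assert np.all(np.abs(off) < 0.05)


def test_programmed_correlation_recovered_at_large_n():
    spec = _long_run_spec(baseline_corr=pairs_to_matrix(0.9, 0.0, 0.0), seed=2)
    run = generate_roi_cohort(spec).runs[0]
    r = np.corrcoef(run.series[:, 0], run.series[:, 1])[0, 1]
    assert r == pytest.approx(0.9, abs=0.02)


def test_same_spec_same_seed_is_bit_identical():
    spec = CohortSpec(n_subjects=2, days=("day1", "day4"), seed=3)
    a = generate_roi_cohort(spec)
    b = generate_roi_cohort(spec)
    for ra, rb in zip(a.runs, b.runs):
        assert ra.series.tobytes() == rb.series.tobytes()
        assert (ra.subject_id, ra.day, ra.run_index) == (rb.subject_id, rb.day, rb.run_index)


def test_different_seed_differs():
    kw = dict(n_subjects=1, days=("day1",), seed=4)
    a = generate_roi_cohort(CohortSpec(**kw))
    kw["seed"] = 5
    b = generate_roi_cohort(CohortSpec(**kw))
    assert not np.array_equal(a.runs[0].series, b.runs[0].series)


def test_run_layout_counts_and_types():
    coh = generate_roi_cohort(CohortSpec(n_subjects=1, days=("day1",), seed=6))
    runs = coh.select(day="day1")
    assert len(runs) == 8
    assert [r.run_type for r in sorted(runs, key=lambda r: r.run_index)] == (
        ["rest"] * 2 + ["feedback"] * 4 + ["rest"] * 2
    )


def test_non_psd_request_rejected_naming_day():
    spec = CohortSpec(
        n_subjects=1,
        days=("day1", "day4"),
        baseline_corr=pairs_to_matrix(0.9, -0.9, 0.8),
        day_deltas={},
        seed=7,
    )
    with pytest.raises(CohortSpecError, match="day1"):
        generate_roi_cohort(spec)


def test_non_psd_request_repaired_when_enabled():
    spec = CohortSpec(
        n_subjects=1,
        days=("day1",),
        baseline_corr=pairs_to_matrix(0.9, -0.9, 0.8),
        day_deltas={},
        repair_non_psd=True,
        subject_scale_sd=0.0,
        seed=8,
        n_tr=50,
    )
    coh = generate_roi_cohort(spec)
    assert coh.repaired_days == ["day1"]
    m, _ = spec.day_correlations()
    assert is_valid_correlation(m["day1"])


def test_nearest_psd_repair_preserves_unit_diagonal():
    bad = pairs_to_matrix(0.95, -0.95, 0.9)
    fixed = nearest_psd(bad)
    assert np.allclose(np.diag(fixed), 1.0)
    assert np.linalg.eigvalsh(fixed)[0] >= -1e-10


# --- voxel grid ------------------------------------------------------------


def test_sphere_mask_voxel_count_for_default_geometry():
    # 4 mm radius on a 3.2 mm lattice: centre plus the six face neighbours
    m = sphere_mask((9, 9, 9), (4 * 3.2, 4 * 3.2, 4 * 3.2), 4.0, 3.2)
    assert 1 <= int(m.sum()) <= 19
    assert int(m.sum()) == 7


def test_voxel_masks_disjoint_and_centred():
    vspec = VoxelGridSpec()
    masks = list(vspec.roi_masks().values())
    total = sum(m.astype(int) for m in masks)
    assert total.max() == 1
    labels = vspec.network_assignment()
    assert set(np.unique(labels)) == {0, 1, 2, 3}


def test_grid_too_small_for_sphere_raises_with_minimum():
    vspec = VoxelGridSpec(grid_shape=(4, 4, 4), roi_centers=((3.2, 3.2, 3.2),) * 3)
    with pytest.raises(CohortSpecError, match="needs >="):
        vspec.validate()


def test_background_voxel_independent_of_network():
    vspec = VoxelGridSpec()
    cspec = CohortSpec(
        n_subjects=1,
        days=("day1",),
        runs_per_day={"rest_pre": 0, "feedback": 1, "rest_post": 0},
        day_deltas={},
        n_tr=10000,
        ar_coeff=0.0,
        seed=9,
    )
    vc = generate_voxel_cohort(vspec, cspec)
    data = vc.run(0, "day1", 0)
    net1_mean = data[vc.network_masks["network1"]].mean(axis=0)
    bg_idx = np.argwhere(vc.labels == 0)[0]
    bg = data[tuple(bg_idx)]
    assert abs(np.corrcoef(bg, net1_mean)[0, 1]) < 0.05


def test_programmed_coupling_increase_recovered():
    vspec = VoxelGridSpec(day_deltas={"day4": (0.3, 0.0, 0.0)})
    cspec = CohortSpec(
        n_subjects=10,
        days=("day1", "day4"),
        runs_per_day={"rest_pre": 0, "feedback": 2, "rest_post": 0},
        day_deltas={},
        seed=10,
    )
    vc = generate_voxel_cohort(vspec, cspec)
    diffs = []
    for s in range(10):
        for ri in vc.feedback_run_indices():
            by_day = {}
            for day in ("day1", "day4"):
                d = vc.run(s, day, ri)
                m1 = d[vc.network_masks["network1"]].mean(axis=0)
                m2 = d[vc.network_masks["network2"]].mean(axis=0)
                by_day[day] = np.corrcoef(m1, m2)[0, 1]
            diffs.append(by_day["day4"] - by_day["day1"])
    assert np.mean(diffs) == pytest.approx(0.3, abs=0.05)


def test_voxel_run_deterministic():
    vspec = VoxelGridSpec()
    cspec = CohortSpec(n_subjects=1, days=("day1",), day_deltas={}, n_tr=20, seed=12)
    vc = generate_voxel_cohort(vspec, cspec)
    assert vc.run(0, "day1", 2).tobytes() == vc.run(0, "day1", 2).tobytes()


# --- behavior --------------------------------------------------------------


def test_behavior_noiseless_is_exactly_linear():
    changes = {f"s{i}": 0.01 * i for i in range(12)}
    spec = SyntheticBehaviorSpec(slope=30.0, noise_sd=0.0, seed=13)
    table = generate_behavior(changes, spec)
    r = np.corrcoef(list(changes.values()), table["srs_change"])[0, 1]
    assert r == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(table["srs_change"], 30.0 * np.array(list(changes.values())))
    # change convention: positive change = post below pre
    assert np.allclose(table["srs_pre"] - table["srs_post"], table["srs_change"])


def test_behavior_null_slope_gives_near_zero_correlation():
    rng = np.random.default_rng(14)
    changes = {f"s{i}": v for i, v in enumerate(rng.standard_normal(1000))}
    table = generate_behavior(changes, SyntheticBehaviorSpec(slope=0.0, noise_sd=1.0, seed=15))
    r = np.corrcoef(list(changes.values()), table["srs_change"])[0, 1]
    assert abs(r) < 0.08


def test_injected_outliers_exceed_reference_band():
    changes = {f"s{i}": 0.0 for i in range(15)}
    spec = SyntheticBehaviorSpec(n_outliers=2, seed=16)
    table = generate_behavior(changes, spec)
    ref = generate_reference_changes(
        mean=spec.reference_mean, sd=spec.reference_sd, seed=17
    )
    band = ref.mean() - 3 * ref.std(ddof=1)
    assert int(table["injected_outlier"].sum()) == 2
    assert (table.loc[table["injected_outlier"], "srs_change"] < band).all()
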