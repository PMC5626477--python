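"""Change maps, group t-test, sign-flip null, cluster correction."""

import numpy as np
import pytest

from covertnf.cohort import CohortSpec, VoxelGridSpec, generate_voxel_cohort
from covertnf.voxelmaps import (
    cluster_permutation_correct,
    group_ttest_map,
    seed_change_map,
    subject_change_map,
)

SHAPE = (10, 10, 10)


def _mask_at(*voxels):
    m = np.zeros(SHAPE, dtype=bool)
    for v in voxels:
        m[v] = True
    return m


def _random_runs(rng, n_runs, n_tr=60):
    return [rng.standard_normal(SHAPE + (n_tr,)) for _ in range(n_runs)]


@pytest.fixture(scope="module")
def vox_rng():
    return np.random.default_rng(31)


def test_reference_equal_to_seed_gives_identically_zero_map(vox_rng):
    seed = _mask_at((2, 2, 2), (2, 2, 3))
    m = seed_change_map(
        _random_runs(vox_rng, 2), _random_runs(vox_rng, 2), seed, seed
    )
    assert np.allclose(m.data, 0.0)


def test_swapping_seed_and_reference_negates_map(vox_rng):
    seed = _mask_at((2, 2, 2))
    ref = _mask_at((7, 7, 7))
    a1, a2 = _random_runs(vox_rng, 2), _random_runs(vox_rng, 2)
    fwd = seed_change_map(a1, a2, seed, ref)
    rev = seed_change_map(a1, a2, ref, seed)
    assert np.allclose(fwd.data, -rev.data, atol=1e-12)


def test_voxel_identical_to_seed_changes_zero(vox_rng):
    runs_a = _random_runs(vox_rng, 1)
    runs_b = _random_runs(vox_rng, 1)
    seed = _mask_at((0, 0, 0))
    m = seed_change_map(runs_a, runs_b, seed)
    # r = 1 both days, z capped identically, so the change vanishes
    assert m.data[0, 0, 0] == pytest.approx(0.0, abs=1e-9)
    assert m.flagged_mask[0, 0, 0]


def test_constant_voxel_marked_undefined(vox_rng):
    runs_a = _random_runs(vox_rng, 1)
    runs_b = _random_runs(vox_rng, 1)
    runs_a[0][5, 5, 5, :] = 2.0
    m = seed_change_map(runs_a, runs_b, _mask_at((1, 1, 1)))
    assert np.isnan(m.data[5, 5, 5])
    assert m.n_undefined == 1


def test_group_ttest_trivial_cases():
    zeros = [np.zeros(SHAPE) for _ in range(5)]
    t, p = group_ttest_map(zeros)
    assert np.all(np.isnan(t) | (t == 0))
    rng = np.random.default_rng(32)
    grids = [np.full(SHAPE, 0.2) + 1e-6 * rng.standard_normal(SHAPE) for _ in range(17)]
    t, p = group_ttest_map(grids)
    assert np.all(p < 1e-10)


def test_group_ttest_null_calibrated(vox_rng):
    grids = [vox_rng.standard_normal(SHAPE) for _ in range(12)]
    _, p = group_ttest_map(grids)
    assert np.mean(p < 0.05) == pytest.approx(0.05, abs=0.02)


def test_sign_flip_equals_recomputing_from_swapped_days(vox_rng):
    """Permuting one subject's day labels is exactly a sign flip of its map."""
    runs_a, runs_b = _random_runs(vox_rng, 2), _random_runs(vox_rng, 2)
    seed, ref = _mask_at((1, 1, 1)), _mask_at((8, 8, 8))
    fwd = seed_change_map(runs_a, runs_b, seed, ref)
    swapped = seed_change_map(runs_b, runs_a, seed, ref)
    assert np.allclose(fwd.data, -swapped.data, atol=1e-12)


def test_single_threshold_union_equals_that_mask(vox_rng):
    grids = [
        np.full(SHAPE, 0.5) + 0.1 * vox_rng.standard_normal(SHAPE) for _ in range(8)
    ]
    res = cluster_permutation_correct(grids, thresholds=(0.05,), n_permutations=200, seed=2)
    assert res.thresholds == (0.05,)
    surviving = np.zeros(SHAPE, dtype=bool)
    from scipy import ndimage, stats

    tcrit = stats.t.ppf(1 - 0.05 / 2, 7)
    for sign_mask in (res.t_grid > tcrit, res.t_grid < -tcrit):
        lab, n = ndimage.label(sign_mask, ndimage.generate_binary_structure(3, 1))
        for j in range(1, n + 1):
            if (lab == j).sum() >= res.min_cluster_sizes[0.05]:
                surviving |= lab == j
    assert np.array_equal(res.union_mask, surviving)


def test_cluster_guards():
    grids = [np.zeros(SHAPE)] * 4
    with pytest.raises(ValueError, match=">= 5 subjects"):
        cluster_permutation_correct(grids, n_permutations=200)
    grids = [np.zeros(SHAPE)] * 6
    with pytest.raises(ValueError, match=">= 100"):
        cluster_permutation_correct(grids, n_permutations=10)


def test_peak_reporting_excludes_seed_and_reference():
    rng = np.random.default_rng(33)
    effect = np.zeros(SHAPE)
    effect[4:7, 4:7, 4:7] = 0.5
    grids = [effect + 0.05 * rng.standard_normal(SHAPE) for _ in range(10)]
    excl = _mask_at((5, 5, 5))  # the would-be peak voxel
    res = cluster_permutation_correct(
        grids, thresholds=(0.05,), n_permutations=200, seed=3, exclude_mask=excl
    )
    assert len(res.clusters) > 0
    for peak in res.clusters.peak_index:
        assert peak is not None
        assert not excl[tuple(peak)]


def test_planted_effect_recovered_in_network2():
    vspec = VoxelGridSpec(day_deltas={"day4": (0.3, 0.0, 0.0)})
    cspec = CohortSpec(
        n_subjects=8,
        days=("day1", "day4"),
        runs_per_day={"rest_pre": 0, "feedback": 1, "rest_post": 0},
        day_deltas={},
        seed=34,
    )
    vc = generate_voxel_cohort(vspec, cspec)
    grids = [subject_change_map(vc, s).data for s in range(8)]
    res = cluster_permutation_correct(
        grids,
        n_permutations=200,
        seed=4,
        exclude_mask=vc.roi_masks["target1"] | vc.roi_masks["control"],
    )
    assert res.any_survivor
    top = res.clusters.sort_values("size", ascending=False).iloc[0]
    assert vc.network_masks["network2"][tuple(top.peak_index)]
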