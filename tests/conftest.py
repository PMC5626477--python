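import numpy as np
import pytest

from covertnf.cohort import CohortSpec, RoiRun, generate_roi_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-day trained cohort, small but with the full run layout."""
    spec = CohortSpec(
        n_subjects=4,
        days=("day1", "day4"),
        day_deltas={"day1": (0.0, 0.0, 0.0), "day4": (0.11, -0.13, -0.03)},
        subject_scale_sd=0.0,
        seed=11,
    )
    return generate_roi_cohort(spec)


def make_run(series, subject_id="s01", day="day1", run_index=0, run_type="feedback"):
    return RoiRun(subject_id, day, run_index, run_type, np.asarray(series, dtype=float))


@pytest.fixture
def white_noise_run(rng):
    return make_run(rng.standard_normal((270, 3)))
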