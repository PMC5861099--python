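import numpy as np
import pytest

from dynstates.dfc_windows import ParcelTimeSeries
from dynstates.synthetic_cohort import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ts(rng):
    """A 60 x 8 time series with generic region/network metadata."""
    values = rng.standard_normal((60, 8))
    region_ids = [f"r{i}" for i in range(8)]
    networks = {f"r{i}": f"net{i // 4 + 1}" for i in range(8)}
    return ParcelTimeSeries(
        values=values,
        region_ids=region_ids,
        network_labels=networks,
        subject_id="S1",
        run_id="v1r1",
        visit_id="v1",
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """A cached 16-region, 10-subject cohort shared by several tests."""
    spec = CohortSpec(
        n_regions=16,
        n_controls=5,
        n_patients=5,
        n_timepoints=60,
        fingerprint_sd=0.05,
        observation_noise_sd=0.05,
        seed=7,
    )
    subjects, truth = generate_cohort(spec)
    return spec, subjects, truth
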