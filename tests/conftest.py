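import numpy as np
import pytest

from mtpa.classify import SplitSpec, datasets_from_dfc, datasets_from_static, run_all_connections
from mtpa.fls import FlsConfig, fls_all_pairs, static_fc
from mtpa.pipeline import preprocess_pair
from mtpa.simulate import CohortSpec, simulate_cohort

PLANTED = ((0, 1), (2, 3))


@pytest.fixture(scope="session")
def planted_spec():
    return CohortSpec(
        n_subjects=60,
        n_regions=10,
        n_frames=120,
        baseline_coupling=0.2,
        modulation_amplitude=0.5,
        planted_pairs=PLANTED,
        engagement_sd=0.2,
        noise_sd=0.3,
        seed=11,
        n_behavior_measures=8,
    )


@pytest.fixture(scope="session")
def planted_cohort(planted_spec):
    recordings, behavior = simulate_cohort(planted_spec)
    return recordings, behavior


@pytest.fixture(scope="session")
def planted_processed(planted_cohort):
    recordings, _ = planted_cohort
    return [preprocess_pair(t, r) for t, r in recordings]


@pytest.fixture(scope="session")
def planted_tensors(planted_processed):
    return [fls_all_pairs(rec, FlsConfig()) for pair in planted_processed for rec in pair]


@pytest.fixture(scope="session")
def planted_dfc_results(planted_tensors):
    return run_all_connections(datasets_from_dfc(planted_tensors), SplitSpec(seed=5))


@pytest.fixture(scope="session")
def planted_static_results(planted_processed):
    static = [
        (rec.subject_id, rec.condition, *static_fc(rec))
        for pair in planted_processed
        for rec in pair
    ]
    return run_all_connections(datasets_from_static(static), SplitSpec(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
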