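import numpy as np
import pytest

from fchybrid import CohortTruth, PipelineConfig, build_frequency_grid
from fchybrid.pipeline import simulate_records


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    """Desk-scale configuration matching the default synthetic cohort."""
    return PipelineConfig(n_roi=20, tr=2.0)


@pytest.fixture(scope="session")
def small_grid(small_config):
    return build_frequency_grid(small_config)


@pytest.fixture(scope="session")
def tiny_truth() -> CohortTruth:
    """A minimal cohort spec for fast end-to-end tests (6 ROIs, pair (0, 3))."""
    return CohortTruth(n_roi=6, n_asd=6, n_tc=6, planted_pairs=((0, 3),))


@pytest.fixture(scope="session")
def tiny_records(tiny_truth):
    """FC records for the tiny cohort (computed once per session)."""
    records, config = simulate_records(tiny_truth, seed=321)
    return records, config


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
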