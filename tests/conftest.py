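import numpy as np
import pytest

from cnascanner.pipeline import PipelineParams, analyze_cohort
from cnascanner.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """50 Mb cohort with one event of each depth-visible type plus control."""
    cfg = SimConfig(seed=3, genome_length=50_000_000)
    plans = {
        "c_loss": [("loss_1_0", 2_000_000)],
        "c_gain": [("gain_2_1", 2_000_000)],
        "c_loh": [("cnloh_2_0", 3_000_000)],
    }
    return simulate_cohort(cfg, plans)


@pytest.fixture(scope="session")
def small_cohort_result(small_cohort):
    return analyze_cohort(small_cohort, PipelineParams(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
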