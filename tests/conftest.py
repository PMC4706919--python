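import numpy as np
import pytest

from longconn.connectome import build_fc_stack
from longconn.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_null_cohort():
    """Tiny cohort with no planted effect (12 vs 8 subjects, 30 nodes)."""
    cfg = SimulationConfig(
        n_nodes=30,
        n_controls=12,
        n_patients=8,
        n_blocks=3,
        effect_type="none",
        seed=101,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_null_stack(small_null_cohort):
    return build_fc_stack(small_null_cohort.timeseries, small_null_cohort.design)


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with a clean 10-edge planted group effect (zero fill-in)."""
    cfg = SimulationConfig(
        n_nodes=60,
        n_controls=12,
        n_patients=8,
        n_blocks=4,
        effect_type="group",
        effect_edges=10,
        effect_delta_z=0.2,
        seed=202,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_stack(planted_cohort):
    return build_fc_stack(planted_cohort.timeseries, planted_cohort.design)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
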