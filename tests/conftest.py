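import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

import gencorrect as gc


@pytest.fixture(scope="session")
def panels():
    return gc.load_snp_panel()


@pytest.fixture(scope="session")
def panel_map(panels):
    return {p.biomarker: p for p in panels}


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size synthetic cohort shared by read-only tests."""
    return gc.simulate_cohort(gc.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_corrected(default_cohort):
    return gc.correct_levels(default_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for IO and structural tests."""
    return gc.simulate_cohort(gc.SimulationConfig(n_subjects=300, seed=5))
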