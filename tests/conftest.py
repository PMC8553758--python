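import pytest
from hypothesis import HealthCheck, settings

from mdm2pgx import (
    AnalysisConfig,
    SimulationSpec,
    dichotomize,
    generate_panel,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def default_panel(config):
    """One default synthetic panel (237 lines, spec defaults, seed 0)."""
    spec = SimulationSpec()
    bundle, truth = generate_panel(spec, config)
    return spec, bundle, truth


@pytest.fixture(scope="session")
def default_dichotomy(default_panel, config):
    _, bundle, _ = default_panel
    cutoff, labels = dichotomize(bundle.sensitivity, config)
    ic50 = bundle.sensitivity.set_index("cl_id")["abs_ic50_uM"]
    return cutoff, labels, ic50
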