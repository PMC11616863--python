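import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_quarter():
    """A small synthetic quarter with ground truth, shared across tests."""
    from pvsignal.synthetic import SyntheticConfig, generate

    cfg = SyntheticConfig(n_reports=3000, seed=42)
    tables, truth = generate(cfg)
    return tables, truth


@pytest.fixture(scope="session")
def cohort(small_quarter):
    """Deduplicated target/background cohorts of the small quarter."""
    from pvsignal.faers import build_cohort, deduplicate_tables

    tables, truth = small_quarter
    deduped = deduplicate_tables(tables)
    target, background = build_cohort(deduped, ["cilostazol", "pletal"])
    return target, background, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)
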