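import pytest
from hypothesis import HealthCheck, settings

from ivfcea import StrategyParams, TwinCounting, load_base_case

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Published per-strategy aggregates the base case is calibrated to:
#: (expected cost per couple in euros, cumulative live births per couple).
PUBLISHED_AGGREGATES = {
    "eSET": (14896.0, 0.314),
    "DxSET": (16687.0, 0.43),
    "DET": (18952.0, 0.473),
}


@pytest.fixture(scope="session")
def base_config():
    return load_base_case()


@pytest.fixture
def costs(base_config):
    return base_config.costs


def make_strategy(**overrides) -> StrategyParams:
    """A valid single-transfer strategy with convenient defaults."""
    fields = dict(
        name="test",
        p_ongoing_fresh=0.3,
        p_ongoing_frozen=0.1,
        p_frozen_available=0.8,
        p_twin_given_ongoing=0.2,
        p_twin_frozen=None,
        p_live_given_ongoing=0.9,
        p_complication=0.25,
        tested_fraction=0.0,
        count_twins_as=TwinCounting.CHILDREN,
    )
    fields.update(overrides)
    return StrategyParams(**fields)
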