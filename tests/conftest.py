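import pytest

from phytofoundry import designer, fixtures

DEFAULT_SEED = 42


@pytest.fixture(scope="session")
def fixture_registry():
    """The 37-part toolkit registry with synthetic sequences (seed 42)."""
    return fixtures.generate_registry_fixture(fixtures.FixtureConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def screen():
    """Registry + design spec of the 11 CDS x 8 configuration screen."""
    return fixtures.design_fixture(fixtures.FixtureConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def screen_orders(screen):
    registry, spec = screen
    return designer.expand_design(spec, registry)


@pytest.fixture(scope="session")
def screen_constructs(screen, screen_orders):
    registry, _ = screen
    return [designer.assemble_order(order, registry) for order in screen_orders]
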