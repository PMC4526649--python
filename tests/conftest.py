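"""Shared fixtures: synthetic worlds at two scales.

Worlds are generated programmatically (no stored data); the small world
matches the generator's default study conditions, the tiny world trades
realism for speed in unit tests.
"""

from dataclasses import replace

import pytest

from bevpool import WorldConfig, make_world, simulate_surveys


@pytest.fixture(scope="session")
def tiny_config() -> WorldConfig:
    return replace(
        WorldConfig(),
        n_super_regions=2,
        n_regions=3,
        n_countries=6,
        age_bands=((20, 50), (50, 100)),
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_config):
    return make_world(tiny_config)


@pytest.fixture(scope="session")
def tiny_survey(tiny_world):
    return simulate_surveys(tiny_world)


@pytest.fixture(scope="session")
def default_world():
    return make_world(WorldConfig(seed=7))


@pytest.fixture(scope="session")
def default_survey(default_world):
    return simulate_surveys(default_world)
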