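import numpy as np
import pytest

from tempmort.config import SyntheticConfig
from tempmort.synthetic import (
    generate_response_table,
    generate_warming,
    generate_world,
)


@pytest.fixture
def tiny_config():
    """Five-country world, default (study-scale) noise."""
    return SyntheticConfig(n_countries=5, seed=123)


@pytest.fixture
def noiseless_config():
    """Five-country world with zero response noise: y is the exact model mean."""
    return SyntheticConfig(n_countries=5, seed=123, sigma_country=0.0, sigma_obs=0.0)


@pytest.fixture
def tiny_world(tiny_config):
    return generate_world(tiny_config)


@pytest.fixture
def tiny_warming(tiny_world, tiny_config):
    return generate_warming(
        tiny_world,
        pattern_spread=tiny_config.pattern_spread,
        seed=tiny_config.seed + 2,
    )


@pytest.fixture
def tiny_responses(tiny_world, tiny_warming, tiny_config):
    return generate_response_table(tiny_world, tiny_warming, tiny_config)


@pytest.fixture
def noiseless_responses(noiseless_config):
    world = generate_world(noiseless_config)
    warming = generate_warming(world, seed=noiseless_config.seed + 2)
    return world, warming, generate_response_table(world, warming, noiseless_config)


@pytest.fixture
def study_bundle():
    """Study-scale bundle: 23 countries x 4 RCPs x 2 periods, default noise."""
    cfg = SyntheticConfig(seed=7)
    world = generate_world(cfg)
    warming = generate_warming(world, seed=cfg.seed + 2)
    responses = generate_response_table(world, warming, cfg)
    return cfg, world, warming, responses


def replicate_bundle(seed: int, **overrides):
    """One synthetic replicate at the default study conditions."""
    cfg = SyntheticConfig(seed=seed, **overrides)
    world = generate_world(cfg)
    warming = generate_warming(
        world, pattern_spread=cfg.pattern_spread, seed=seed + 2
    )
    responses = generate_response_table(
        world, warming, cfg, np.random.default_rng(seed + 1)
    )
    return cfg, world, warming, responses
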