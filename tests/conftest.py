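"""Shared fixtures: small designs and seeded planted-IBD panels."""

import pytest

from pairplan import (
    CallerConfig,
    enumerate_subsets,
    plant_segments,
    random_planting,
    simulate_panel,
)


@pytest.fixture(scope="session")
def design4():
    return enumerate_subsets(4)


@pytest.fixture(scope="session")
def design25():
    return enumerate_subsets(25)


def make_planted_panel(n, n_segments, seed, markers=2000,
                       length_range=(8.0, 12.0)):
    """A seeded panel with ``n_segments`` planted IBD segments on disjoint
    haplotypes, each long enough (>= threshold + one seeding window) to be
    guaranteed-callable."""
    panel = simulate_panel(n, markers, seed=seed)
    pairs, lengths = random_planting(n, n_segments, length_range, seed=seed + 1)
    return plant_segments(panel, pairs, lengths, seed=seed + 2)


@pytest.fixture(scope="session")
def planted_panel50():
    return make_planted_panel(50, 10, seed=7)


@pytest.fixture(scope="session")
def default_config():
    return CallerConfig()
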