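"""Shared fixtures: ground truths and one deep synthetic dataset per session."""

import pytest

from codamc import relative_activity_capture
from codamc.fixtures import make_ground_truth
from codamc.synth import ChannelDesign, LibraryConfig, generate_dataset


@pytest.fixture(scope="session")
def line1():
    return make_ground_truth("LINE1_rbz")


@pytest.fixture(scope="session")
def or4k15():
    return make_ground_truth("OR4K15_rbz")


@pytest.fixture(scope="session")
def toy():
    return make_ground_truth("toy_hairpin")


@pytest.fixture(scope="session")
def line1_counts(line1):
    """Full-coverage doped capture dataset on the LINE-1 fixture."""
    return generate_dataset(line1, LibraryConfig(seed=11), ChannelDesign(), seed=11)


@pytest.fixture(scope="session")
def line1_table(line1_counts):
    return relative_activity_capture(line1_counts)
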