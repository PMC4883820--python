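"""Shared fixtures: the calibrated domain profile and synthetic references."""

import numpy as np
import pytest

from kinominer import synthetic_data
from kinominer.domain_scan import build_profile


@pytest.fixture(scope="session")
def profile():
    """The calibrated profile built from the shipped seed alignment."""
    return build_profile(synthetic_data.seed_alignment())


@pytest.fixture(scope="session")
def consensi():
    return synthetic_data.group_consensi()


@pytest.fixture(scope="session")
def ref_catalog():
    return synthetic_data.generate_reference_catalog(seed=991)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
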