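"""Shared fixtures: one rendered phantom and its preprocessing chain.

Image generation and wax extraction are the slow steps, so they are
session-scoped; tests must not mutate fixture arrays in place.
"""

import numpy as np
import pytest

from phantomqc import preprocess as pp
from phantomqc.phantom_synth import (DEFAULT_LAYOUT, generate_phantom,
                                     make_device_profiles)


@pytest.fixture(scope="session")
def profiles():
    return make_device_profiles(8, seed=7)


@pytest.fixture(scope="session")
def profile(profiles):
    # a 100 um FFDM system
    return profiles[0]


@pytest.fixture(scope="session")
def phantom_pair(profile):
    """Standard-dose acquisition: (PhantomImage, GroundTruth)."""
    return generate_phantom(profile, 1.0, seed=3)


@pytest.fixture(scope="session")
def clean_pair(profile):
    """Noiseless limit (infinite dose)."""
    return generate_phantom(profile, float("inf"), seed=3)


@pytest.fixture(scope="session")
def wax(phantom_pair):
    image, _ = phantom_pair
    crop, _ = pp.extract_phantom(image)
    return pp.orient_by_largest_mass(pp.extract_wax_area(crop))


@pytest.fixture(scope="session")
def layout():
    return DEFAULT_LAYOUT


@pytest.fixture(scope="session")
def subimages(phantom_pair):
    image, _ = phantom_pair
    return pp.preprocess_image(image, seed=0, source_id="fixture")
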