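"""Shared fixtures: probe geometries, pulse model and matched-filter template.

``geometry`` is the full default configuration; ``small_geometry`` trades
imaging depth and line count for speed and is used wherever the physics
under test does not depend on the full frame size.
"""

import numpy as np
import pytest

from fohtrack.geometry import ProbeGeometry
from fohtrack.pipeline import make_template
from fohtrack.simulator import PulseModel

SAMPLE_RATE_HZ = 1.0e7


@pytest.fixture(scope="session")
def geometry():
    return ProbeGeometry()


@pytest.fixture(scope="session")
def small_geometry():
    return ProbeGeometry(n_scan_lines=64, imaging_depth_mm=160.0)


@pytest.fixture(scope="session")
def pulse_model():
    return PulseModel()


@pytest.fixture(scope="session")
def sample_rate():
    return SAMPLE_RATE_HZ


@pytest.fixture(scope="session")
def template(pulse_model):
    return make_template(pulse_model, SAMPLE_RATE_HZ)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230517)
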