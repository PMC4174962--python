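"""Shared fixtures.

Field solves are the expensive part of the suite, so solved lead fields at
a reduced "test" resolution are session-scoped and shared between modules.
The coarsening factor trades accuracy for runtime; every physical check
that depends on it (conservation, orderings) holds at any resolution.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import fesim as f
from fesim.anatomy import AnatomyParams, generate_pseudo_anatomy
from fesim.field import discretize, scaled_mesh, solve_unit_field
from fesim.fiber import StimulusWaveform, build_fiber, node_positions_m

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Mesh-spacing factor for test-resolution solves (cells ~ factor^-3).
TEST_MESH_FACTOR = 1.7


@pytest.fixture(scope="session")
def coarse_mesh():
    return scaled_mesh(TEST_MESH_FACTOR)


@pytest.fixture(scope="session")
def cm1():
    return f.cm_model("1")


@pytest.fixture(scope="session")
def pm1():
    return f.pm_model("1")


@pytest.fixture(scope="session")
def cm1_electrodes(cm1):
    return f.place_electrodes(cm1, "anterior", 9.0, 4.0)


@pytest.fixture(scope="session")
def cm1_domain(cm1, cm1_electrodes, coarse_mesh):
    return discretize(cm1, cm1_electrodes, resolution_level=0, mesh=coarse_mesh)


@pytest.fixture(scope="session")
def cm1_solution(cm1_domain):
    return solve_unit_field(cm1_domain)


@pytest.fixture(scope="session")
def cm1_profile_12um(cm1, cm1_electrodes, cm1_solution):
    """Nodal lead-field profile for the standard 12 μm fibre at 5 mm depth."""
    placement = f.FiberPlacement("anterior", 5.0, 12.0)
    fiber = build_fiber(12.0)
    nodes = node_positions_m(cm1, placement, cm1_electrodes, fiber)
    return fiber, cm1_solution.sample_fiber_profile(nodes)


@pytest.fixture(scope="session")
def pseudo_am_pair():
    """Full pseudo-anatomy and its inclusion-ablated variant (same seed)."""
    full = generate_pseudo_anatomy(AnatomyParams(seed=7))
    ablated = generate_pseudo_anatomy(
        AnatomyParams(seed=7, include_vessel=False, include_nerve=False))
    return full, ablated


@pytest.fixture(scope="session")
def waveform():
    return StimulusWaveform()
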