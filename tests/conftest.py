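"""Shared fixtures: a small phantom with electrodes, and helpers.

The small setup (~10k elements) keeps forward/inverse cycles to a couple
of seconds while leaving the electrode geometry and tissue heterogeneity
intact.
"""

import numpy as np
import pytest

from eitherm.forward import build_pattern
from eitherm.mesh import ConductivityField
from eitherm.phantom import PhantomSpec, build_phantom, place_electrodes
from eitherm.tissues import default_tissue_table


@pytest.fixture(scope="session")
def table():
    return default_tissue_table()


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(target_elements=8000)


@pytest.fixture(scope="session")
def small_setup(small_spec, table):
    """(spec, table, mesh, sigma_lf) with 16 electrodes placed."""
    mesh, sigma = build_phantom(small_spec, table)
    place_electrodes(mesh, 16, 2)
    return small_spec, table, mesh, sigma


@pytest.fixture(scope="session")
def pattern16():
    return build_pattern(16, 7, current=1e-3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
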