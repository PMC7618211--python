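"""Shared fixtures: lookup tables, meshes and a synthetic subject.

Expensive artefacts (paced lookup tables, the reference subject) are
session-scoped and generated programmatically at collection time.
"""

import numpy as np
import pytest

from cardiotwin.cells import CellModelParams, build_lookup
from cardiotwin.geometry import (
    generate_idealized_biventricle,
    generate_slab,
    place_electrodes,
)
from cardiotwin.subjects import make_synthetic_subject


@pytest.fixture(scope="session")
def cell_params():
    return CellModelParams()


@pytest.fixture(scope="session")
def small_table(cell_params):
    """Narrow lookup table (200-260 ms) at reduced pacing for unit tests."""
    return build_lookup(
        cell_params, apd_bounds=(200.0, 260.0), n_beats=12, n_initial=24,
        max_refine=150,
    )


@pytest.fixture(scope="session")
def wide_table(cell_params):
    """Lookup table covering the full inference APD range (178-302 ms)."""
    return build_lookup(
        cell_params, apd_bounds=(178.0, 302.0), n_beats=30, n_initial=48
    )


@pytest.fixture(scope="session")
def biventricle():
    return generate_idealized_biventricle(20, 14, 3)


@pytest.fixture(scope="session")
def small_slab():
    return generate_slab(6, 6, 4, 1.0)


@pytest.fixture(scope="session")
def slab_electrodes(small_slab):
    return place_electrodes(small_slab, 3.0)


@pytest.fixture(scope="session")
def subject(wide_table):
    """Deterministic synthetic subject on the shared biventricle scale."""
    return make_synthetic_subject(seed=5, counts=(20, 14, 3), table=wide_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
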