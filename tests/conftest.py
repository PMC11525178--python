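"""Shared fixtures.

The expensive artifacts — the 81-cell calibration sweep and the
representative large-compression solve — are computed once per session and
shared across the unit and acceptance tests that interrogate them.
"""

import warnings

import numpy as np
import pytest

from morphoforce.calibration import paper_grid, run_sweep
from morphoforce.materials import MaterialModel
from morphoforce.ring_fem import (
    ContactConfig,
    CylinderGeometry,
    build_ring_mesh,
    solve_diametral_compression,
)

#: representative sensor used throughout: printed cylinder of height 20 um,
#: outer diameter 180 um, wall 15 um, hydrogel E = 80 kPa
REP_GEO = dict(H=20.0, D=180.0, t=15.0)
REP_E = 80.0


@pytest.fixture(scope="session")
def sweep_records():
    """Full 3x3x3x3 sweep over the validated parameter ranges, flat plates,
    (96, 4) resolution."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_sweep(*paper_grid(3))


@pytest.fixture(scope="session")
def representative_solution():
    """Flat-plate compression of the representative cylinder to 25% of its
    width, with the full solution history."""
    geo = CylinderGeometry(**REP_GEO)
    mesh = build_ring_mesh(geo)
    solution, curve = solve_diametral_compression(
        mesh, MaterialModel(E=REP_E), ContactConfig(),
        max_narrowing=0.25 * geo.D)
    return mesh, solution, curve


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
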