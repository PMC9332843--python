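"""Shared fixtures.

The continuum solves are the expensive part of the suite, so the default
KcsA solve and the dielectric scan are computed once per session on the
reduced 0.5 Å grid and shared by the solver and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from permeakin.bikerman import default_params
from permeakin.geometry import default_kcsa_spec, make_geometry, reduced_grid
from permeakin.solver import epsilon_scan, line_density, solve_equilibrium

EPS_SCAN_VALUES = (10.0, 8.0, 6.0, 4.0, 2.0, 1.5)


@pytest.fixture(scope="session")
def kcsa_geometry():
    return make_geometry(default_kcsa_spec(), reduced_grid(0.5), eps_sf=1.5)


@pytest.fixture(scope="session")
def kcsa_state(kcsa_geometry):
    return solve_equilibrium(kcsa_geometry, default_params())


@pytest.fixture(scope="session")
def kcsa_density(kcsa_state, kcsa_geometry):
    return line_density(kcsa_state, kcsa_geometry)


@pytest.fixture(scope="session")
def eps_scan_results():
    return epsilon_scan(
        default_kcsa_spec(), reduced_grid(0.5), default_params(), EPS_SCAN_VALUES
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
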