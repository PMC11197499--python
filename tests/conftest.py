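"""Shared fixtures: small geometries and one coarse solved flow."""

import numpy as np
import pytest

from hemoshear.hemodynamics import (BloodProperties, BoundaryConditionSet,
                                    SolverConfig, solve_flow)
from hemoshear.meshing import tetrahedralize
from hemoshear.synthetic_vessels import make_centerline, make_vessel_surface

TUBE_RADIUS = 0.002   # m
TUBE_LENGTH = 0.03    # m


def reynolds_to_q(re, r, props):
    """Flow rate giving bulk Reynolds number *re* in a tube of radius *r*."""
    v = re * props.mu / (props.rho * 2 * r)
    return v * np.pi * r**2


@pytest.fixture(scope="session")
def blood():
    return BloodProperties()


@pytest.fixture(scope="session")
def straight_vessel():
    cl = make_centerline("straight", TUBE_LENGTH)
    return make_vessel_surface(cl, TUBE_RADIUS)


@pytest.fixture(scope="session")
def curved_vessel():
    cl = make_centerline("curved", 0.02, 0.012)
    return make_vessel_surface(cl, TUBE_RADIUS)


@pytest.fixture(scope="session")
def coarse_mesh(straight_vessel):
    """Fast ~5k-cell straight-tube mesh for unit tests."""
    return tetrahedralize(straight_vessel, 1.0e-3, near_wall_factor=0.5)


@pytest.fixture(scope="session")
def coarse_solution(coarse_mesh, blood):
    """Steady Re≈100 solve on the coarse mesh (shared across unit tests)."""
    q = reynolds_to_q(100, TUBE_RADIUS, blood)
    bc = BoundaryConditionSet(q_in=q, r_out=[1.2e9])
    sol = solve_flow(coarse_mesh, bc, blood, SolverConfig(mode="steady"))
    return sol, bc
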