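"""Shared fixtures: timebases, AIFs and a solved spherical-tumor benchmark."""

import numpy as np
import pytest

import dcecfm
from dcecfm.constants import TissueConstants
from dcecfm.domain import build_domain
from dcecfm.synthetic import ellipsoid_mask


@pytest.fixture(scope="session")
def times_2s():
    return np.arange(0.0, 300.0, 2.0)


@pytest.fixture(scope="session")
def aif_2s(times_2s):
    return dcecfm.generate_aif(times_2s)


@pytest.fixture(scope="session")
def constants():
    return TissueConstants()


@pytest.fixture(scope="session")
def sphere_solution(constants):
    """R = 10 mm spherical tumor with a 10-voxel normal shell on a 64^3
    1 mm grid, solved once and shared across tests."""
    mask = ellipsoid_mask((42, 42, 42), (1.0, 1.0, 1.0),
                          np.array([21.0] * 3), np.array([10.0] * 3))
    ktrans = np.where(mask, 0.2, np.nan)
    grid = build_domain(mask, (1.0, 1.0, 1.0), ktrans, dilation_voxels=10)
    assert grid.labels.shape == (64, 64, 64)
    pressure = dcecfm.solve_ifp(grid, constants)
    coeff = dcecfm.assemble_coefficients(grid, constants)
    velocity = dcecfm.compute_ifv(pressure, coeff.kh, grid.domain_mask)
    center = np.argwhere(grid.tumor_mask).mean(axis=0)
    return {"grid": grid, "pressure": pressure, "velocity": velocity,
            "center": center, "radius_mm": 10.0, "constants": constants}
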