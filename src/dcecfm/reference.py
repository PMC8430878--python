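"""Spherically-symmetric 1-D reference solution for benchmarking.

For a spherical tumor of radius R embedded in a concentric normal-tissue
shell, the pressure PDE reduces to a two-region radial ODE

    -(1/r^2) d/dr ( r^2 K_H dp/dr ) = g_v (p_eq - p) - g_L (p - p_L),

with regularity at r = 0 and a no-flux wall at the outer shell radius.  This
module solves it on a fine radial grid with a finite-volume tridiagonal
scheme — a discretization independent of the 3-D Cartesian solver — and is
used as the dimension-reduction benchmark for the voxel solve.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .constants import TissueConstants

__all__ = ["radial_two_region_pressure"]


def radial_two_region_pressure(tumor_radius_mm: float, shell_mm: float,
                               constants: TissueConstants | None = None,
                               h_mm: float = 0.02) -> tuple[np.ndarray, np.ndarray]:
    """Solve the two-region radial pressure profile.

    Parameters
    ----------
    tumor_radius_mm : tumor radius R, mm.
    shell_mm : normal-tissue shell thickness beyond R, mm.
    h_mm : radial cell size of the fine 1-D grid, mm.

    Returns
    -------
    r_mm : cell-center radii, mm.
    p : pressure at the cell centers, Pa.
    """
    if constants is None:
        constants = TissueConstants()
    if tumor_radius_mm <= 0 or shell_mm < 0:
        raise ValueError("radii must be positive")
    r_out = (tumor_radius_mm + shell_mm) * 1e-3
    rt = tumor_radius_mm * 1e-3
    h = h_mm * 1e-3
    n = int(round(r_out / h))
    r_faces = np.arange(n + 1) * h
    r_cent = 0.5 * (r_faces[:-1] + r_faces[1:])

    tumor = r_cent <= rt
    kh = np.where(tumor, constants.tumor.kh, constants.normal.kh)
    gv = np.where(tumor, constants.tumor.lp0 * constants.tumor.s_over_v,
                  constants.normal.lp0 * constants.normal.s_over_v)
    gl = np.where(tumor, 0.0, constants.normal.lymph_coeff)
    peq = np.where(tumor, constants.equilibrium_pressure("tumor"),
                   constants.equilibrium_pressure("normal"))

    # finite-volume: flux through interior face j+1/2 is
    # r^2 K_face (p_{j+1} - p_j)/h; cell volume factor is r_c^2 h
    k_face = 2.0 * kh[:-1] * kh[1:] / (kh[:-1] + kh[1:])
    w = r_faces[1:-1] ** 2 * k_face / h  # interior faces only; r=0 and r_out: no flux
    vol = r_cent**2 * h

    main = np.zeros(n)
    main[:-1] += w
    main[1:] += w
    main += vol * (gv + gl)
    A = sparse.diags([main, -w, -w], [0, -1, 1], format="csc")
    b = vol * (gv * peq + gl * constants.pl)
    p = spsolve(A, b)
    return r_cent * 1e3, p
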