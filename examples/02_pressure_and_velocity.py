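"""Solve interstitial fluid pressure and velocity on a spherical tumor.

Builds a 10 mm-radius tumor with a 10 mm normal-tissue margin on a 1 mm
grid, solves the Starling-source continuity PDE with a no-flux boundary, and
reports the tumor summary alongside the analytic Starling equilibrium.
"""

import numpy as np

import dcecfm
from dcecfm.synthetic import ellipsoid_mask

mask = ellipsoid_mask((42, 42, 42), (1.0, 1.0, 1.0),
                      np.array([21.0] * 3), np.array([10.0] * 3))
grid = dcecfm.build_domain(mask, (1.0, 1.0, 1.0),
                           np.where(mask, 0.14, np.nan), dilation_voxels=10)
constants = dcecfm.TissueConstants()
pressure = dcecfm.solve_ifp(grid, constants)
coeff = dcecfm.assemble_coefficients(grid, constants)
velocity = dcecfm.compute_ifv(pressure, coeff.kh, grid.domain_mask)
summ = dcecfm.summarize_fields(pressure, velocity, grid)

print(f"domain: {grid.labels.shape} voxels, {grid.tumor_mask.sum()} tumor + "
      f"{grid.normal_mask.sum()} normal-shell")
print(f"solver: {pressure.iterations} CG iterations, relative residual "
      f"{pressure.residual:.1e}, source/sink imbalance {pressure.conservation_ratio:.1e}")
print(f"tumor IFP {summ.mean_ifp_kpa:.2f} +/- {summ.sd_ifp_kpa:.2f} kPa "
      f"(Starling equilibrium {constants.equilibrium_pressure('tumor')/1000:.2f} kPa)")
print(f"tumor IFV {summ.mean_ifv:.2e} m/s; peak speed "
      f"{velocity.magnitude.max():.2e} m/s at the tumor rim")
print("The core plateaus near the Starling equilibrium and the pressure "
      "falls off sharply at the boundary, driving the outward Darcy flow.")
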