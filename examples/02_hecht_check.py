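"""Consistency control: the adjoint solver against the Hecht equation.

In a parallel-plate detector with a uniform field and no diffusion the
charge-collection efficiency has the Hecht closed form.  The adjoint
solver must reproduce it; the printed maximum relative deviation is the
numerical discretisation error of the upwind scheme.
"""

import numpy as np

from cztcam import (
    CrystalSpec, AnodeArraySpec, FieldConfig, CarrierParams, build_grid,
    solve_electric_potential, solve_weighting_potential, solve_adjoint_cie,
    hecht_cie,
)

crystal = CrystalSpec(width_x=6, width_y=6, thickness=5.0)
anodes = AnodeArraySpec(n_x=1, n_y=1, pitch=0.4, pad_size=0.4)
grid = build_grid(crystal, anodes, neighbourhood=1, step=0.1)

cfg = FieldConfig("A1", weighting_alternative="B1")
phi = solve_electric_potential(grid, crystal, cfg)
phi_k = solve_weighting_potential(grid, 0, cfg)
electron = CarrierParams(mobility=1000.0, lifetime=1.0, diffusion=0.0)
eta = solve_adjoint_cie(grid, phi, phi_k, electron)

mu_tau = electron.mobility * electron.lifetime * 1e-6   # cm^2/V
ref = hecht_cie(grid.z, crystal.thickness, mu_tau, field=120.0)
line = eta.values[2, 2, :]

print("depth z [mm]   adjoint   Hecht")
for k in range(0, grid.z.size, 10):
    print(f"   {grid.z[k]:5.2f}      {line[k]:.4f}   {ref[k]:.4f}")
rel = np.abs(line[:-1] - ref[:-1]) / ref[:-1]
print(f"max relative deviation over {line.size - 1} depth nodes: "
      f"{rel.max():.3%} (first-order upwinding error at a 0.1 mm step)")
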