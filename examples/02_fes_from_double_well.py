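"""Recover a known 1D free-energy profile with boundary-corrected metadynamics.

A Metropolis walker explores an asymmetric double well (barrier ~8 kT at
310 K) while Gaussian hills (0.1 kJ/mol, sigma 2, one per ps-equivalent step)
are deposited at its position.  The free energy is the negated time average
of the accumulated bias; the well free-energy difference is compared with
quadrature of the analytic potential.
"""

import numpy as np

from bemeta import constants as c
from bemeta import synthetic
from bemeta.bias import BiasGrid
from bemeta.exchange import Replica, run_bias_exchange
from bemeta.fes import GridSpec, fes_from_bias_history

kT = c.kT()
potential = synthetic.double_well_1d()

replica = Replica(
    "alpha_only",
    np.array([8.0]),
    BiasGrid((-5.0,), (42.0,), (2351,)),
    bias_dims=(0,),
)
result = run_bias_exchange([replica], potential, n_steps=30_000, stride=100, seed=1)

grid = GridSpec((0.0,), (32.0,), (161,))
fes = fes_from_bias_history(result.hills["alpha_only"], grid)

ax = grid.axes()[0]
p = np.exp(-fes.values / kT)
dF_est = -kT * np.log(p[ax < 16].sum() / p[ax >= 16].sum())

fine = np.linspace(0, 32, 6401)
bz = np.exp(-potential.energy_grid(fine) / kT)
dF_exact = -kT * np.log(
    np.trapezoid(bz[fine < 16], fine[fine < 16])
    / np.trapezoid(bz[fine >= 16], fine[fine >= 16])
)

print(f"hills deposited       : {len(result.hills['alpha_only'])}")
print(f"dF(left - right) est  : {dF_est / kT:6.2f} kT")
print(f"dF(left - right) exact: {dF_exact / kT:6.2f} kT")
print(f"absolute error        : {abs(dF_est - dF_exact) / kT:6.2f} kT")
print("\nThe estimate converges toward the quadrature value as the bias fills"
      "\nboth wells; at this length the error is typically a fraction of kT.")
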