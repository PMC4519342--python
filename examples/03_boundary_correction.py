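"""Why hills near a CV boundary need renormalising.

On a FLAT landscape over [0, 32] the time-averaged metadynamics bias should
be flat.  Plain Gaussian hills lose mass outside the domain, which distorts
the profile near 0; dividing each kernel by the in-domain Gaussian mass at
the evaluation point restores a uniform deposition flux and a flat profile.
"""

import numpy as np

from bemeta import constants as c
from bemeta import synthetic
from bemeta.bias import BiasGrid
from bemeta.exchange import Replica, run_bias_exchange
from bemeta.fes import GridSpec, fes_from_bias_history

kT = c.kT()
flat = synthetic.ToyPotential(wells=(), dim=1)
grid = GridSpec((0.0,), (32.0,), (161,))
ax = grid.axes()[0]

for corrected in (True, False):
    replica = Replica(
        "alpha_only",
        np.array([16.0]),
        BiasGrid((-5.0,), (42.0,), (2351,), corrected=corrected),
        bias_dims=(0,),
    )
    result = run_bias_exchange([replica], flat, n_steps=30_000, stride=1000, seed=7)
    fes = fes_from_bias_history(result.hills["alpha_only"], grid, corrected=corrected)
    dev = (fes.values - fes.values.mean()) / kT
    label = "corrected" if corrected else "plain    "
    print(
        f"{label}: max |deviation| = {np.max(np.abs(dev)):7.2f} kT "
        f"(within 1 sigma of 0: {np.max(np.abs(dev[ax <= 2.0])):7.2f} kT)"
    )

print("\nThe corrected profile stays flat to a fraction of kT all the way to"
      "\nthe wall; the plain-Gaussian control accumulates a large artifact"
      "\nnear 0, the behaviour the boundary correction exists to remove.")
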