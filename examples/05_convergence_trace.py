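"""Watch class free energies converge as the bias history accumulates.

Re-estimates the free-energy surface from truncated bias histories [0, t] and
reports the helix/strand/turn/bend free energies relative to coil at each
checkpoint -- the standard convergence diagnostic for bias-exchange runs.
"""

import numpy as np

from bemeta.config import PipelineConfig
from bemeta.fes import GridSpec, convergence_trace
from bemeta.pipeline import run_pipeline

config = PipelineConfig(n_steps=8000, output_stride=5, seed=5)
results = run_pipeline(config)

grid = GridSpec((0.0, 0.0), (32.0, 32.0), (160, 160))
checkpoints = np.linspace(800, config.n_steps, 8)
trace = convergence_trace(
    results["bias_exchange"].hills["both"], grid, results["frames"], checkpoints
)

print("time(ps-equiv)  " + "  ".join(f"{cls:>7s}" for cls in trace["classes"]))
for i, t in enumerate(trace["times"]):
    row = "  ".join(f"{trace['classes'][cls][i]:7.2f}" for cls in trace["classes"])
    print(f"{t:14.0f}  {row}")

print("\nValues are -ln(f_class / f_coil) in kT; a flattening trace indicates"
      "\nthe averaged bias (and hence the surface) has converged.")
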