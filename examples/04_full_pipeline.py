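"""Run the complete synthetic workflow and inspect its reports.

Four replicas (unbiased / alpha-biased / beta-biased / both) sample a toy
coil-helix-hairpin landscape; the free-energy surface comes from the
doubly-biased replica's time-averaged bias; the unbiased replica's frames are
decorated with synthetic chemical shifts and DSSP strings and reweighted into
secondary-structure fractions, class free energies versus coil (the analogue
of a per-force-field summary table), secondary-shift predictions, and
per-atom shift errors against a synthetic experimental table.
"""

from pathlib import Path

from bemeta.config import PipelineConfig
from bemeta.pipeline import run_pipeline

out_dir = Path("bemeta_demo")
config = PipelineConfig(n_steps=5000, output_stride=5, seed=2024)
results = run_pipeline(config, out_dir=out_dir)

print(f"reports written to {out_dir}/\n")

print("peptide-level secondary-structure fractions:")
for cls, val in results["peptide_fractions"].items():
    print(f"  {cls:7s} {val:6.3f}")

print("\nclass free energies relative to coil (kT at 310 K):")
for cls, val in results["class_free_energy_kt"].items():
    print(f"  {cls:7s} {val:6.2f}")

print("\nmean absolute secondary-shift error (ppm/residue):")
print(results["shift_errors"].round(3).to_string())

print("\nLow class free energies mean the structure is commonly adopted;"
      "\nthe shift errors measure how well the reweighted ensemble's NMR"
      "\npredictions match the (here, synthetic) experimental shifts.")
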