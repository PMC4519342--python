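"""Project ideal peptide backbones onto the (alpha_RMSD, beta_RMSD) plane.

Builds a 37-residue ideal helix, a 16-residue beta hairpin, an extended
chain, and a random coil, and prints their secondary-structure collective
variables.  alpha_RMSD counts 6-residue windows that superpose onto an ideal
helix fragment (up to 32 for a 37-mer); beta_RMSD counts antiparallel
two-segment fragments matching an ideal two-strand template.
"""

from bemeta.cv import alpha_rmsd, beta_rmsd_antiparallel
from bemeta.synthetic import build_ideal_structure

for kind, n_res in [
    ("alpha_helix", 37),
    ("beta_hairpin", 16),
    ("extended", 16),
    ("random_coil", 37),
]:
    s = build_ideal_structure(kind, n_res, seed=11)
    a = alpha_rmsd(s)
    b = beta_rmsd_antiparallel(s)
    print(f"{kind:12s} ({n_res} residues):  alpha_RMSD = {a:6.3f}   beta_RMSD = {b:6.3f}")

print(
    "\nAn ideal 37-mer helix saturates alpha_RMSD near its 32-window maximum;"
    "\nthe hairpin scores beta_RMSD ~ its number of in-register strand pairs."
    "\nCompact disordered coils pick up a nonzero beta_RMSD baseline from the"
    "\nswitching function's tails -- the same behaviour as the coil basin of"
    "\nthe molecular free-energy maps -- while helices score essentially zero."
)
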