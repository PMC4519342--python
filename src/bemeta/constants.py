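"""Physical constants, canonical geometry, and paper-default parameters.

Everything that downstream modules treat as "the" default lives here so that
structure builders, CV templates, and the pipeline configuration agree on a
single source of truth.
"""

import numpy as np

# --- thermodynamics ---------------------------------------------------------
KB_KJ_PER_MOL_K = 0.0083144621  # Boltzmann constant, kJ/mol/K
DEFAULT_TEMPERATURE_K = 310.0


def kT(temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy in kJ/mol (2.5775 kJ/mol at 310 K)."""
    return KB_KJ_PER_MOL_K * temperature_k


# --- backbone bond geometry (Angstrom / degrees) ----------------------------
# Standard peptide geometry used by every ideal-structure builder and by the
# CV fragment templates.  Single table so queries and templates agree.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521

ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.4
DIHEDRAL_C_N_CA_CB = -122.6  # improper fixing L-chirality
OMEGA_TRANS = 180.0

ANGSTROM_TO_NM = 0.1

# --- canonical dihedrals (degrees) ------------------------------------------
ALPHA_PHI, ALPHA_PSI = -57.0, -47.0
BETA_PHI, BETA_PSI = -139.0, 135.0

# Ramachandran boxes for the dihedral-based secondary-structure assigner
# (synthetic fixtures only; not a DSSP replacement).
HELIX_BOX = {"phi": (-100.0, -30.0), "psi": (-80.0, -5.0)}
BETA_BOX = {"phi": (-180.0, -90.0), "psi": (90.0, 180.0)}

# --- CV switching-function defaults -----------------------------------------
# The switching parameters are printed unitless as r0 = 0.8 with n = 8, m = 12;
# r0 is 0.8 Angstrom = 0.08 nm (fragment RMSDs of near-ideal secondary
# structure are ~0.05-0.1 nm, so 0.8 nm would saturate the switch).
SWITCH_R0_NM = 0.08
SWITCH_N = 8
SWITCH_M = 12

# Antiparallel-beta strand pairing
BETA_SEGMENT_MIN_SEPARATION = 5  # j >= i + 5 for segments (i..i+2, j..j+2)
BETA_STRAND_SEPARATION_NM = 0.48  # in-register CA-CA inter-strand distance

# --- metadynamics defaults (hill schedule, grids, boundaries, wall) ---------
HILL_HEIGHT_KJ_MOL = 0.1
HILL_SIGMA = 2.0
HILL_PACE_STEPS = 1            # one hill per ps-equivalent sampler step
CV_DOMAIN = (0.0, 32.0)        # boundary-correction domain for both CVs
BIAS_GRID_RANGE = (-5.0, 42.0)
BIAS_GRID_NODES_1D = 2351      # spacing 0.02
BIAS_GRID_NODES_2D = 471       # spacing 0.1; desk-scale default for 2D grids
HILL_TRUNCATION_SIGMAS = 6.0

WALL_POSITION_NM = 7.0
WALL_KAPPA = 100.0             # kJ/mol per nm^2

# --- free-energy-surface grid ------------------------------------------------
FES_GRID_NODES = 160           # 160 x 160 over [0, 32]^2

# --- canonical atom naming ---------------------------------------------------
BACKBONE_ATOMS = ("N", "CA", "CB", "C", "O")  # fragment extraction order
SHIFT_ATOMS = ("CA", "CB", "HA", "HN", "N", "CO")
ATOM_ALIASES = {"H": "HN", "C": "CO"}  # dialects normalised at the parsers

RIAPP_SEQUENCE = "KCNTATCATQRLANFLVRSSNNLGPVLPPTNVGSNTY"


def rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation about a unit axis (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle_rad) * K + (1.0 - np.cos(angle_rad)) * (K @ K)
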