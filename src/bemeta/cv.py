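"""Secondary-structure collective variables.

alpha_rmsd and antiparallel beta_rmsd count 6-residue backbone fragments that
superpose well onto an ideal alpha-helical / antiparallel beta-sheet template.
Each fragment contributes s(RMSD) where s is a rational switching function,
so the CV is a smooth, dimensionless "number of residues in that secondary
structure" (0..32 for a 37-mer helix).

Fragment convention: per residue the atoms N, CA, CB, C, O (CA substituted
for a missing CB, e.g. glycine), concatenated over the fragment's residues in
sequence order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial.transform import Rotation

from . import constants as c
from . import geometry


@dataclass(frozen=True)
class SwitchingParams:
    """Rational switching function s(r) = (1-(r/r0)^n) / (1-(r/r0)^m)."""

    r0: float = c.SWITCH_R0_NM  # nm
    n_exp: int = c.SWITCH_N
    m_exp: int = c.SWITCH_M

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if not (0 < self.n_exp < self.m_exp):
            raise ValueError("require 0 < n < m")


@dataclass
class BackboneStructure:
    """Per-residue backbone coordinates (nm) of a single frame."""

    residue_ids: np.ndarray
    atom_coords: list[dict[str, np.ndarray]]

    def __post_init__(self):
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if len(self.residue_ids) != len(self.atom_coords):
            raise ValueError("residue_ids and atom_coords length mismatch")
        if len(self.residue_ids) > 1 and not np.all(np.diff(self.residue_ids) == 1):
            raise ValueError("residues must be contiguous and ordered")
        for rid, atoms in zip(self.residue_ids, self.atom_coords):
            for name in ("N", "CA", "C", "O"):
                if name not in atoms:
                    raise ValueError(f"residue {rid} missing backbone atom {name}")
            for name, xyz in atoms.items():
                if not np.all(np.isfinite(xyz)):
                    raise ValueError(f"non-finite coordinate for residue {rid} atom {name}")

    @property
    def chain_length(self) -> int:
        return len(self.residue_ids)

    def residue_fragment_atoms(self, index: int) -> np.ndarray:
        """(5, 3) array of N, CA, CB, C, O for one residue (CB -> CA fallback)."""
        atoms = self.atom_coords[index]
        rows = []
        for name in c.BACKBONE_ATOMS:
            if name == "CB" and "CB" not in atoms:
                rows.append(atoms["CA"])
            else:
                rows.append(atoms[name])
        return np.asarray(rows, dtype=float)

    def fragment(self, residue_indices) -> np.ndarray:
        """Stacked fragment coordinates for the given residue indices."""
        return np.concatenate([self.residue_fragment_atoms(i) for i in residue_indices])

    def transformed(self, rotation: np.ndarray = None, translation=None) -> "BackboneStructure":
        """Rigidly moved copy (for invariance checks)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        moved = [{k: R @ v + t for k, v in res.items()} for res in self.atom_coords]
        return BackboneStructure(self.residue_ids.copy(), moved)


def from_residue_list(residues: list[dict[str, np.ndarray]]) -> BackboneStructure:
    return BackboneStructure(np.arange(1, len(residues) + 1), [dict(r) for r in residues])


@dataclass(frozen=True)
class FragmentTemplate:
    kind: str  # "ideal_alpha" | "ideal_antiparallel_beta"
    atom_coords: np.ndarray = field(repr=False)  # (n_atoms, 3), nm


@lru_cache(maxsize=None)
def ideal_alpha_template() -> FragmentTemplate:
    """Six-residue ideal helix fragment (phi=-57, psi=-47)."""
    residues = geometry.build_backbone([c.ALPHA_PHI] * 6, [c.ALPHA_PSI] * 6)
    coords = from_residue_list(residues).fragment(range(6))
    return FragmentTemplate("ideal_alpha", coords)


@lru_cache(maxsize=None)
def ideal_antiparallel_beta_template() -> FragmentTemplate:
    """Two in-register antiparallel 3-residue strands (phi=-139, psi=135)."""
    strand = geometry.periodic_strand(3)
    partner = geometry.antiparallel_partner(strand)
    residues = strand + partner
    coords = from_residue_list(residues).fragment(range(6))
    return FragmentTemplate("ideal_antiparallel_beta", coords)


def superposition_rmsd(frag_a: np.ndarray, frag_b: np.ndarray) -> float:
    """Minimal RMSD (nm) over all rigid rotations + translations (Kabsch)."""
    a = np.asarray(frag_a, dtype=float)
    b = np.asarray(frag_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("fragments must be (n, 3) arrays of equal shape")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 atoms")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite coordinates")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    # align_vectors solves Wahba's problem; rssd is the residual after rotation
    import warnings

    with warnings.catch_warnings():
        # degenerate (e.g. collinear) sets: the RMSD is still well defined
        # even when the optimal rotation is not unique
        warnings.simplefilter("ignore", UserWarning)
        _, rssd = Rotation.align_vectors(a, b)
    return float(rssd / np.sqrt(a.shape[0]))


def switching(r: float, params: SwitchingParams = SwitchingParams()) -> float:
    """Rational switch, continuous at r = r0 (limit n/m), range (0, 1]."""
    if r < 0:
        raise ValueError("distance must be non-negative")
    x = r / params.r0
    if x == 1.0:
        return params.n_exp / params.m_exp
    if x > 1e6:  # avoid overflow; asymptotically x^(n-m)
        return x ** (params.n_exp - params.m_exp)
    return (1.0 - x**params.n_exp) / (1.0 - x**params.m_exp)


def alpha_rmsd(
    structure: BackboneStructure,
    template: FragmentTemplate = None,
    params: SwitchingParams = SwitchingParams(),
) -> float:
    """Sum of s(RMSD to ideal helix) over all contiguous 6-residue windows."""
    if structure.chain_length < 6:
        raise ValueError("alpha_rmsd requires at least 6 residues")
    if template is None:
        template = ideal_alpha_template()
    total = 0.0
    for i in range(structure.chain_length - 5):
        frag = structure.fragment(range(i, i + 6))
        total += switching(superposition_rmsd(frag, template.atom_coords), params)
    return total


def beta_pairs(chain_length: int) -> list[tuple[int, int]]:
    """Admissible (i, j) segment starts, 0-based, for (i..i+2, j..j+2)."""
    min_sep = c.BETA_SEGMENT_MIN_SEPARATION
    return [
        (i, j)
        for i in range(chain_length - 2)
        for j in range(i + min_sep, chain_length - 2)
    ]


def beta_rmsd_antiparallel(
    structure: BackboneStructure,
    template: FragmentTemplate = None,
    params: SwitchingParams = SwitchingParams(),
) -> float:
    """Sum of s(RMSD to antiparallel template) over two-segment fragments.

    Fragments pair segments (i..i+2) and (j..j+2) with j >= i+5, i.e. at
    least a two-residue gap, each (i, j) counted once.
    """
    if structure.chain_length < 8:
        raise ValueError("beta_rmsd requires at least 8 residues")
    if template is None:
        template = ideal_antiparallel_beta_template()
    total = 0.0
    for i, j in beta_pairs(structure.chain_length):
        frag = structure.fragment([i, i + 1, i + 2, j, j + 1, j + 2])
        total += switching(superposition_rmsd(frag, template.atom_coords), params)
    return total


def compute_cvs(structure: BackboneStructure, params: SwitchingParams = SwitchingParams()):
    """(alpha_rmsd, beta_rmsd) of one structure."""
    return (
        alpha_rmsd(structure, params=params),
        beta_rmsd_antiparallel(structure, params=params),
    )
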