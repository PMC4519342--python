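"""Backbone construction from internal coordinates.

Chains are grown atom-by-atom with the standard natural-extension reference
frame (NeRF) placement: each atom is positioned from three previously placed
atoms given a bond length, bond angle and torsion.  All builders share the
bond-geometry table in :mod:`bemeta.constants`, so fragments extracted from a
built structure superpose exactly onto templates built from the same
dihedrals.

Coordinates are constructed in Angstrom and returned in nm.
"""

from __future__ import annotations

import math

import numpy as np

from . import constants as c


def place_atom(a, b, c_atom, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom D given A-B-C, |CD|, angle(B,C,D) and torsion(A,B,C,D)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c_atom = np.asarray(c_atom, float)
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)

    bc = c_atom - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-12:  # collinear reference; any perpendicular works
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        n_norm = np.linalg.norm(n)
    n = n / n_norm
    m = np.cross(bc, n)  # orientation such that the torsion is measured back exactly

    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            -bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c_atom + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle in degrees for four points."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


def build_backbone(phis, psis, omegas=None) -> list[dict[str, np.ndarray]]:
    """Build an n-residue backbone (N, CA, C, O, CB per residue) in nm.

    ``phis[0]`` is unused (the first residue has no preceding carbonyl);
    ``psis[-1]`` orients the final carbonyl oxygen.
    """
    phis = list(phis)
    psis = list(psis)
    n_res = len(phis)
    if len(psis) != n_res:
        raise ValueError("phis and psis must have equal length")
    if omegas is None:
        omegas = [c.OMEGA_TRANS] * n_res

    residues: list[dict[str, np.ndarray]] = []

    # seed residue in the xy-plane
    n1 = np.zeros(3)
    ca1 = np.array([c.BOND_N_CA, 0.0, 0.0])
    ang = math.radians(c.ANGLE_N_CA_C)
    c1 = ca1 + c.BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    residues.append({"N": n1, "CA": ca1, "C": c1})

    for i in range(1, n_res):
        prev = residues[i - 1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"], c.BOND_C_N, c.ANGLE_CA_C_N, psis[i - 1])
        ca_i = place_atom(prev["CA"], prev["C"], n_i, c.BOND_N_CA, c.ANGLE_C_N_CA, omegas[i])
        c_i = place_atom(prev["C"], n_i, ca_i, c.BOND_CA_C, c.ANGLE_N_CA_C, phis[i])
        residues.append({"N": n_i, "CA": ca_i, "C": c_i})

    for i, res in enumerate(residues):
        res["O"] = place_atom(
            res["N"], res["CA"], res["C"], c.BOND_C_O, c.ANGLE_CA_C_O, psis[i] + 180.0
        )
        res["CB"] = place_atom(
            res["C"], res["N"], res["CA"], c.BOND_CA_CB, c.ANGLE_N_CA_CB, c.DIHEDRAL_C_N_CA_CB
        )

    return [{k: v * c.ANGSTROM_TO_NM for k, v in res.items()} for res in residues]


def periodic_strand(n_res: int) -> list[dict[str, np.ndarray]]:
    """Exactly periodic idealised beta strand (nm).

    Residue ``k`` is residue ``k-1`` advanced by a 180-degree screw along the
    strand axis (rotation by pi about z plus a fixed rise), reproducing the
    beta pleat with zero net twist.  The base residue geometry comes from the
    NeRF extended chain, so the strand is locally realistic while being
    globally straight -- which makes antiparallel pairing exact and lets the
    hairpin builder and the beta CV template agree by construction.
    """
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    ext = build_backbone([c.BETA_PHI] * 2, [c.BETA_PSI] * 2)
    base = ext[0]
    ca0 = base["CA"]
    rel = {k: v - ca0 for k, v in base.items()}

    # strand axis = z; rise per residue from the extended chain's CA-CA step
    rise = float(np.linalg.norm(ext[1]["CA"] - ext[0]["CA"]))
    flip = np.diag([-1.0, -1.0, 1.0])  # rotation by pi about z

    residues = []
    for k in range(n_res):
        R = flip if (k % 2) else np.eye(3)
        origin = np.array([0.0, 0.0, k * rise])
        residues.append({name: origin + R @ v for name, v in rel.items()})
    return residues


def antiparallel_partner(
    strand: list[dict[str, np.ndarray]], separation_nm: float = None
) -> list[dict[str, np.ndarray]]:
    """Antiparallel in-register partner of a periodic strand.

    The partner is the strand rotated by pi about the x axis (so it runs
    against the original's direction) and offset sideways by the inter-strand
    separation; residue ``k`` of the partner sits opposite residue
    ``n-1-k`` of the original.
    """
    if separation_nm is None:
        separation_nm = c.BETA_STRAND_SEPARATION_NM
    n = len(strand)
    z_top = strand[-1]["CA"][2]
    Rx = np.diag([1.0, -1.0, -1.0])  # rotation by pi about x
    partner = []
    for res in strand:
        moved = {}
        for name, v in res.items():
            w = Rx @ v
            w = w + np.array([separation_nm, 0.0, z_top])
            moved[name] = w
        partner.append(moved)
    return partner


def backbone_dihedrals(residues: list[dict[str, np.ndarray]]):
    """(phi, psi) per residue in degrees; NaN where undefined (termini)."""
    n = len(residues)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    for i in range(n):
        if i > 0:
            phi[i] = dihedral(
                residues[i - 1]["C"], residues[i]["N"], residues[i]["CA"], residues[i]["C"]
            )
        if i < n - 1:
            psi[i] = dihedral(
                residues[i]["N"], residues[i]["CA"], residues[i]["C"], residues[i + 1]["N"]
            )
    return phi, psi
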