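"""Secondary-structure collective variables: switching, superposition, CVs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from bemeta import constants as c
from bemeta import cv, geometry, synthetic
from bemeta.cv import (
    BackboneStructure,
    SwitchingParams,
    alpha_rmsd,
    beta_pairs,
    beta_rmsd_antiparallel,
    superposition_rmsd,
    switching,
)


# --- switching function -------------------------------------------------------


@pytest.mark.parametrize(
    "r,expected",
    [
        (0.0, 1.0),
        (c.SWITCH_R0_NM, 8.0 / 12.0),          # analytic limit n/m at r = r0
        (2 * c.SWITCH_R0_NM, 255.0 / 4095.0),  # direct arithmetic
    ],
)
def test_switching_closed_form(r, expected):
    assert switching(r) == pytest.approx(expected, abs=1e-12)


def test_switching_monotone_and_bounded():
    rs = np.linspace(0.0, 1.0, 400)
    vals = np.array([switching(r) for r in rs])
    assert np.all(np.diff(vals) < 0)
    assert np.all(vals > 0) and vals[0] == 1.0


def test_switching_continuous_at_r0():
    p = SwitchingParams()
    eps = 1e-9
    for r in (p.r0 - eps, p.r0 + eps):
        assert switching(r, p) == pytest.approx(8 / 12, abs=1e-6)


def test_switching_rejects_negative_distance():
    with pytest.raises(ValueError):
        switching(-0.1)


def test_switching_params_validation():
    with pytest.raises(ValueError):
        SwitchingParams(r0=-1.0)
    with pytest.raises(ValueError):
        SwitchingParams(n_exp=12, m_exp=8)


# --- optimal-superposition RMSD -----------------------------------------------


def _brute_force_rmsd(a, b):
    """Independent oracle: minimise RMSD over rotations parametrised by
    rotation vectors, multi-start Nelder-Mead after centering."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    def objective(rotvec):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((a - b @ R.T) ** 2, axis=1)))

    best = np.inf
    rng = np.random.default_rng(0)
    for _ in range(12):
        x0 = rng.uniform(-np.pi, np.pi, 3)
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
        best = min(best, res.fun)
    return best


def test_rmsd_identity_and_rigid_motion(rng):
    frag = rng.normal(size=(10, 3))
    assert superposition_rmsd(frag, frag) == pytest.approx(0.0, abs=1e-10)
    R = c.rotation_matrix([0, 0, 1], np.pi / 2)
    moved = frag @ R.T + np.array([1.0, -2.0, 0.5])
    assert superposition_rmsd(frag, moved) == pytest.approx(0.0, abs=1e-10)


def test_rmsd_matches_brute_force_minimisation(rng):
    a = rng.normal(size=(4, 3))
    b = rng.normal(size=(4, 3))
    assert superposition_rmsd(a, b) == pytest.approx(_brute_force_rmsd(a, b), abs=1e-7)


def test_rmsd_symmetric(rng):
    a, b = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
    assert superposition_rmsd(a, b) == pytest.approx(superposition_rmsd(b, a), abs=1e-12)


def test_rmsd_input_validation(rng):
    with pytest.raises(ValueError):
        superposition_rmsd(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))
    # collinear points must not crash
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    assert superposition_rmsd(line, line) == pytest.approx(0.0, abs=1e-8)


# --- alpha_rmsd ---------------------------------------------------------------


def test_alpha_rmsd_ideal_helix(helix37):
    val = alpha_rmsd(helix37)
    assert 31.0 <= val <= 32.0  # 32 windows, each at RMSD ~ 0


def test_alpha_rmsd_single_template_window():
    frag = geometry.build_backbone([c.ALPHA_PHI] * 6, [c.ALPHA_PSI] * 6)
    s = cv.from_residue_list(frag)
    assert alpha_rmsd(s) == pytest.approx(1.0, abs=1e-9)


def test_alpha_rmsd_extended_chain_low():
    ext = synthetic.build_ideal_structure("extended", 6)
    assert alpha_rmsd(ext) < 0.5


def test_alpha_rmsd_short_chain_error():
    frag = geometry.build_backbone([c.ALPHA_PHI] * 5, [c.ALPHA_PSI] * 5)
    with pytest.raises(ValueError):
        alpha_rmsd(cv.from_residue_list(frag))


def _independent_alpha(structure):
    """Second code path: per-window evaluation with a hand-rolled Kabsch."""
    template = cv.ideal_alpha_template().atom_coords
    total = 0.0
    for i in range(structure.chain_length - 5):
        frag = structure.fragment(range(i, i + 6))
        a = frag - frag.mean(axis=0)
        b = template - template.mean(axis=0)
        H = b.T @ a
        U, S, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        rot = Vt.T @ np.diag([1, 1, d]) @ U.T
        rmsd = np.sqrt(np.mean(np.sum((a - b @ rot.T) ** 2, axis=1)))
        total += switching(rmsd)
    return total


def test_alpha_window_equivalence():
    coil = synthetic.build_ideal_structure("random_coil", 12, seed=5)
    assert alpha_rmsd(coil) == pytest.approx(_independent_alpha(coil), abs=1e-10)


def test_alpha_monotone_under_helix_to_coil_morph(helix37):
    coil = synthetic.build_ideal_structure("random_coil", 37, seed=0)
    values = []
    for lam in np.linspace(0.0, 1.0, 12):
        residues = [
            {k: (1 - lam) * h[k] + lam * coil.atom_coords[i][k] for k in h}
            for i, h in enumerate(helix37.atom_coords)
        ]
        values.append(alpha_rmsd(cv.from_residue_list(residues)))
    assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n_res=st.integers(8, 16))
def test_alpha_bounds_property(seed, n_res):
    s = synthetic.build_ideal_structure("random_coil", n_res, seed=seed)
    val = alpha_rmsd(s)
    assert 0.0 <= val <= n_res - 5


# --- beta_rmsd ----------------------------------------------------------------


def test_beta_pairs_hand_enumeration():
    # 8-mer: single admissible pair (segments 1..3 and 6..8, 1-based)
    assert beta_pairs(8) == [(0, 5)]
    # 10-mer hand enumeration
    assert beta_pairs(10) == [(0, 5), (0, 6), (0, 7), (1, 6), (1, 7), (2, 7)]


def test_beta_rmsd_ideal_hairpin_matches_enumeration_oracle(hairpin16):
    """Exhaustive fragment enumeration: the CV is dominated by the in-register
    antiparallel pairs (RMSD ~ 0); off-register pairs at RMSD ~ 2.5 r0 add a
    switching tail of ~9% of the count under this template convention."""
    template = cv.ideal_antiparallel_beta_template().atom_coords
    val = beta_rmsd_antiparallel(hairpin16)
    assert val >= 1.0
    # oracle: independent enumeration of composite-fragment RMSDs
    count, total = 0, 0.0
    for i, j in beta_pairs(hairpin16.chain_length):
        frag = hairpin16.fragment([i, i + 1, i + 2, j, j + 1, j + 2])
        r = superposition_rmsd(frag, template)
        total += switching(r)
        if r < c.SWITCH_R0_NM:
            count += 1
    # a 16-mer hairpin (7+2+7) has three exact in-register composite fragments
    assert count == 3
    assert val == pytest.approx(total, abs=1e-10)
    assert val == pytest.approx(count, rel=0.10)


def test_beta_rmsd_helix_low(helix37):
    assert beta_rmsd_antiparallel(helix37) < 0.5


def test_beta_rmsd_hairpin_alpha_low(hairpin16):
    assert alpha_rmsd(hairpin16) < 0.5


def test_beta_rmsd_short_chain_error():
    ext = synthetic.build_ideal_structure("extended", 7)
    with pytest.raises(ValueError):
        beta_rmsd_antiparallel(ext)


# --- rigid-motion invariance of both CVs --------------------------------------


@pytest.mark.parametrize("axis,angle", [([0, 0, 1], 0.7), ([1, 1, 0], 2.1)])
def test_cv_rigid_motion_invariance(hairpin16, axis, angle):
    R = c.rotation_matrix(axis, angle)
    moved = hairpin16.transformed(R, np.array([3.0, -1.0, 2.0]))
    assert alpha_rmsd(moved) == pytest.approx(alpha_rmsd(hairpin16), abs=1e-10)
    assert beta_rmsd_antiparallel(moved) == pytest.approx(
        beta_rmsd_antiparallel(hairpin16), abs=1e-10
    )


# --- BackboneStructure validation ---------------------------------------------


def test_structure_invariants():
    residues = geometry.build_backbone([c.ALPHA_PHI] * 6, [c.ALPHA_PSI] * 6)
    with pytest.raises(ValueError):
        BackboneStructure([1, 2, 4, 5, 6, 7], residues)  # non-contiguous
    broken = [dict(r) for r in residues]
    del broken[2]["O"]
    with pytest.raises(ValueError):
        BackboneStructure(range(1, 7), broken)
    bad = [dict(r) for r in residues]
    bad[0]["N"] = np.array([np.nan, 0.0, 0.0])
    with pytest.raises(ValueError):
        BackboneStructure(range(1, 7), bad)


def test_glycine_cb_fallback():
    residues = geometry.build_backbone([c.ALPHA_PHI] * 6, [c.ALPHA_PSI] * 6)
    no_cb = [dict(r) for r in residues]
    del no_cb[3]["CB"]
    s = cv.from_residue_list(no_cb)
    frag = s.residue_fragment_atoms(3)
    assert np.allclose(frag[2], frag[1])  # CB slot falls back to CA
    assert np.isfinite(alpha_rmsd(s))
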