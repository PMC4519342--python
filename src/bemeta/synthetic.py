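"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: analytic toy
potentials in CV space (standing in for the molecular free-energy landscape),
ideal/disordered peptide backbones for the CV module, and frame ensembles
with prescribed state populations, chemical-shift means and secondary-
structure strings for the reweighting module.

All generators are pure functions of their specification and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from . import constants as c
from . import cv as cv_mod
from . import geometry
from .reweight import FrameObservation


# --- toy potentials ----------------------------------------------------------


@dataclass(frozen=True)
class GaussianWell:
    depth: float           # kJ/mol, > 0 (wells point down)
    center: tuple          # CV-space point
    sigma: float           # width, CV units

    def __post_init__(self):
        if self.depth < 0 or self.sigma <= 0:
            raise ValueError("well depth must be >= 0 and sigma > 0")


@dataclass(frozen=True)
class ToyPotential:
    """Sum of Gaussian wells on [0, 32]^d; bounded below, analytic."""

    wells: tuple
    dim: int = 1

    def energy(self, x) -> float:
        """Potential energy at a scalar (1D) or length-d point, kJ/mol."""
        if self.dim == 1 and np.isscalar(x):
            u = 0.0
            for w in self.wells:
                dx = x - w.center[0]
                u -= w.depth * math.exp(-dx * dx / (2.0 * w.sigma**2))
            return u
        x = np.atleast_1d(np.asarray(x, float))
        u = 0.0
        for w in self.wells:
            d2 = np.sum((x - np.asarray(w.center)) ** 2)
            u -= w.depth * math.exp(-d2 / (2.0 * w.sigma**2))
        return float(u)

    def energy_grid(self, *axes) -> np.ndarray:
        """Vectorised energy over a meshgrid built from per-dimension axes."""
        mesh = np.meshgrid(*axes, indexing="ij")
        u = np.zeros(mesh[0].shape)
        for w in self.wells:
            d2 = sum((m - ci) ** 2 for m, ci in zip(mesh, w.center))
            u -= w.depth * np.exp(-d2 / (2.0 * w.sigma**2))
        return u


def double_well_1d(
    depth_a: float = 8.0 * c.kT(),
    depth_b: float = 6.0 * c.kT(),
    centers=(8.0, 24.0),
    sigma: float = 3.0,
) -> ToyPotential:
    """Asymmetric 1D double well; barrier ~ depth_a from the deeper minimum."""
    return ToyPotential(
        wells=(
            GaussianWell(depth_a, (centers[0],), sigma),
            GaussianWell(depth_b, (centers[1],), sigma),
        ),
        dim=1,
    )


def three_state_2d(
    coil=(1.5, 1.0),
    helix=(16.0, 0.8),
    hairpin=(0.8, 6.0),
    depths=(12.0, 9.0, 7.5),
    sigmas=(2.2, 2.2, 2.2),
) -> ToyPotential:
    """Coil / helix / hairpin basins on the (alpha_RMSD, beta_RMSD) plane."""
    wells = tuple(
        GaussianWell(d, ctr, s) for d, ctr, s in zip(depths, (coil, helix, hairpin), sigmas)
    )
    return ToyPotential(wells=wells, dim=2)


def exact_fes(potential: ToyPotential, axes, kT: float = None, marginal_axis: int = None):
    """Ground-truth free energy of a toy potential on a grid, min-shifted to 0.

    For CV-space potentials F(s) = U(s) up to a constant.  With
    ``marginal_axis`` set (2D potentials only), that coordinate is integrated
    out by trapezoidal quadrature of exp(-U/kT) on a fine grid.
    """
    axes = [np.asarray(a, float) for a in np.atleast_2d(axes)] if isinstance(axes, np.ndarray) else [
        np.asarray(a, float) for a in axes
    ]
    if marginal_axis is None:
        f = potential.energy_grid(*axes)
        return f - f.min()
    if potential.dim != 2:
        raise ValueError("marginalisation implemented for 2D potentials")
    if kT is None:
        kT = c.kT()
    keep = 1 - marginal_axis
    fine = np.linspace(c.CV_DOMAIN[0], c.CV_DOMAIN[1], 2001)
    grids = [None, None]
    grids[keep] = axes[0]
    grids[marginal_axis] = fine
    u = potential.energy_grid(*grids)
    boltz = np.exp(-u / kT)
    z = np.trapezoid(boltz, fine, axis=marginal_axis)
    f = -kT * np.log(z)
    return f - f.min()


# --- ideal and disordered backbones ------------------------------------------


def _turn_arc(start: np.ndarray, end: np.ndarray, n_turn: int) -> list[np.ndarray]:
    """CA anchor points on a raised arc bridging two strand tops."""
    points = []
    span = end - start
    for t in range(1, n_turn + 1):
        frac = t / (n_turn + 1)
        lift = math.sin(math.pi * frac) * 0.35  # nm, bulge above the strands
        points.append(start + frac * span + np.array([0.0, 0.0, lift]))
    return points


def build_ideal_structure(kind: str, n_res: int, seed: int = 0) -> cv_mod.BackboneStructure:
    """Backbone of a given secondary-structure archetype.

    kinds: ``alpha_helix``, ``beta_hairpin``, ``extended``, ``random_coil``.
    Random coils draw phi/psi uniformly from broad allowed Ramachandran boxes.
    """
    if n_res < 6:
        raise ValueError("need at least 6 residues")
    if kind == "alpha_helix":
        residues = geometry.build_backbone([c.ALPHA_PHI] * n_res, [c.ALPHA_PSI] * n_res)
    elif kind == "extended":
        residues = geometry.build_backbone([c.BETA_PHI] * n_res, [c.BETA_PSI] * n_res)
    elif kind == "beta_hairpin":
        if n_res < 8:
            raise ValueError("a hairpin needs at least 8 residues")
        n_strand = (n_res - 2) // 2
        if n_strand % 2 == 0:  # odd strands give exact in-register repeats
            n_strand -= 1
        n_turn = n_res - 2 * n_strand
        strand_a = geometry.periodic_strand(n_strand)
        strand_b = geometry.antiparallel_partner(strand_a)
        base = {k: v - strand_a[0]["CA"] for k, v in strand_a[0].items()}
        arc = _turn_arc(strand_a[-1]["CA"], strand_b[0]["CA"], n_turn)
        turn = [{k: v + p for k, v in base.items()} for p in arc]
        residues = strand_a + turn + strand_b
    elif kind == "random_coil":
        rng = np.random.default_rng(seed)
        # broad allowed region: mix of polyproline/beta-ish and alpha-ish draws
        phis, psis = [], []
        for _ in range(n_res):
            if rng.random() < 0.6:
                phis.append(rng.uniform(-180.0, -60.0))
                psis.append(rng.uniform(60.0, 180.0))
            else:
                phis.append(rng.uniform(-160.0, -50.0))
                psis.append(rng.uniform(-90.0, 30.0))
        residues = geometry.build_backbone(phis, psis)
    else:
        raise ValueError(f"unknown structure kind: {kind!r}")
    return cv_mod.from_residue_list(residues)


def assign_ss_dihedral(structure: cv_mod.BackboneStructure) -> str:
    """Minimal phi/psi-box secondary-structure assignment (fixtures only).

    H for the helix box, E for the beta box, C otherwise; termini (undefined
    phi or psi) are C.  This is a deliberately simple stand-in used to label
    synthetic structures; it is not a hydrogen-bond-based assignment.
    """
    phi, psi = geometry.backbone_dihedrals(structure.atom_coords)
    letters = []
    for p, s in zip(phi, psi):
        if not (np.isfinite(p) and np.isfinite(s)):
            letters.append("C")
        elif c.HELIX_BOX["phi"][0] < p < c.HELIX_BOX["phi"][1] and (
            c.HELIX_BOX["psi"][0] < s < c.HELIX_BOX["psi"][1]
        ):
            letters.append("H")
        elif c.BETA_BOX["phi"][0] < p < c.BETA_BOX["phi"][1] and (
            c.BETA_BOX["psi"][0] < s <= c.BETA_BOX["psi"][1]
        ):
            letters.append("E")
        else:
            letters.append("C")
    return "".join(letters)


# --- random-coil shifts and canonical secondary-shift offsets ----------------

# Approximate residue-type random-coil chemical shifts (ppm).  This is a
# synthetic stand-in table in the spirit of the standard random-coil sets used
# by shift predictors; values are typical literature magnitudes, adequate for
# exercising the subtraction/reweighting machinery with known ground truth.
RANDOM_COIL_SHIFTS = {
    #        CA     CB     HA    HN     N      CO
    "A": (52.5, 19.1, 4.32, 8.15, 123.8, 177.8),
    "C": (58.2, 28.0, 4.55, 8.23, 118.8, 174.6),
    "D": (54.2, 41.1, 4.64, 8.34, 120.4, 176.3),
    "E": (56.6, 29.9, 4.35, 8.42, 120.2, 176.6),
    "F": (57.7, 39.6, 4.62, 8.30, 120.3, 175.8),
    "G": (45.1, float("nan"), 3.96, 8.29, 108.8, 174.9),
    "H": (55.0, 29.0, 4.73, 8.42, 118.2, 174.1),
    "I": (61.1, 38.8, 4.17, 8.00, 119.9, 176.4),
    "K": (56.2, 33.1, 4.32, 8.29, 120.4, 176.6),
    "L": (55.1, 42.4, 4.34, 8.16, 121.8, 177.6),
    "M": (55.4, 32.9, 4.48, 8.28, 119.6, 176.3),
    "N": (53.1, 38.9, 4.74, 8.40, 118.7, 175.2),
    "P": (63.3, 32.1, 4.42, float("nan"), float("nan"), 177.3),
    "Q": (55.7, 29.4, 4.34, 8.32, 119.8, 176.0),
    "R": (56.0, 30.9, 4.34, 8.23, 120.5, 176.3),
    "S": (58.3, 63.8, 4.47, 8.31, 115.7, 174.6),
    "T": (61.8, 69.8, 4.35, 8.15, 113.6, 174.7),
    "V": (62.2, 32.9, 4.12, 8.03, 119.2, 176.3),
    "W": (57.5, 29.6, 4.66, 8.25, 121.3, 176.1),
    "Y": (57.9, 38.8, 4.55, 8.12, 120.3, 175.9),
}

# Canonical per-class secondary-shift offsets (ppm) used to give synthetic
# states distinguishable NMR signatures (positive CA offset = helical).
SECONDARY_SHIFT_OFFSETS = {
    "helix": {"CA": 2.6, "CB": -0.4, "HA": -0.35, "HN": -0.15, "N": -1.5, "CO": 1.8},
    "strand": {"CA": -1.5, "CB": 1.0, "HA": 0.35, "HN": 0.2, "N": 1.5, "CO": -1.4},
    "coil": {"CA": 0.0, "CB": 0.0, "HA": 0.0, "HN": 0.0, "N": 0.0, "CO": 0.0},
}


def random_coil_reference(sequence: str):
    """Random-coil reference table for a one-letter sequence."""
    import pandas as pd

    from .reweight import RandomCoilReference

    rows = []
    for aa in sequence:
        if aa not in RANDOM_COIL_SHIFTS:
            raise KeyError(f"no random-coil values for residue type {aa!r}")
        rows.append(RANDOM_COIL_SHIFTS[aa])
    table = pd.DataFrame(
        rows, columns=list(c.SHIFT_ATOMS), index=pd.RangeIndex(1, len(sequence) + 1, name="resid")
    )
    return RandomCoilReference(table)


def shift_means_for_ss(sequence: str, ss_string: str) -> dict:
    """Per-atom shift means: random coil plus the class offset of each residue."""
    from .reweight import classify_ss

    rc = random_coil_reference(sequence)
    means = {}
    for atom in c.SHIFT_ATOMS:
        base = rc.vector(atom).copy()
        for i, letter in enumerate(ss_string):
            cls = classify_ss(letter)
            offsets = SECONDARY_SHIFT_OFFSETS.get(cls, SECONDARY_SHIFT_OFFSETS["coil"])
            base[i] += offsets[atom]
        means[atom] = base
    return means


def riapp_demo_states(sequence: str = c.RIAPP_SEQUENCE, shift_noise_sd: float = 0.3):
    """Coil / helix / hairpin mixture mirroring the disordered-peptide picture.

    Populations follow the Boltzmann weights of the matching toy potential
    (:func:`three_state_2d`) only approximately; the reweighting pipeline is
    expected to recover the *potential's* populations, so these states define
    geometry/observables while the potential defines thermodynamics.
    """
    n = len(sequence)
    ss_coil = "C" * n
    ss_helix = "C" * 4 + "H" * 19 + "C" * (n - 23)
    ss_hairpin = "C" * 6 + "S" + "E" * 7 + "TT" + "E" * 7 + "S" + "C" * (n - 24)
    mk = lambda ss: shift_means_for_ss(sequence, ss)
    return (
        SyntheticState(0.70, (1.5, 1.0), (1.2, 0.8), mk(ss_coil), shift_noise_sd, ss_coil),
        SyntheticState(0.20, (16.0, 0.8), (1.5, 0.6), mk(ss_helix), shift_noise_sd, ss_helix),
        SyntheticState(0.10, (0.8, 6.0), (0.6, 1.2), mk(ss_hairpin), shift_noise_sd, ss_hairpin),
    )


# --- synthetic frame ensembles -----------------------------------------------


@dataclass(frozen=True)
class SyntheticState:
    """One mixture component of a synthetic ensemble."""

    population: float
    cv_mean: tuple           # (alpha, beta)
    cv_spread: tuple         # per-CV truncated-normal sd
    shift_means: dict = None  # atom -> per-residue ppm means (arrays)
    shift_noise_sd: float = 0.0
    ss_string: str = ""


@dataclass(frozen=True)
class SyntheticEnsembleSpec:
    states: tuple
    n_frames: int
    seed: int
    domain: tuple = c.CV_DOMAIN
    dt_ps: float = 10.0  # frame stride, ps

    def __post_init__(self):
        pops = [s.population for s in self.states]
        if abs(sum(pops) - 1.0) > 1e-9:
            raise ValueError("state populations must sum to 1")
        for s in self.states:
            if any(sp <= 0 for sp in s.cv_spread):
                raise ValueError("cv spreads must be positive")
            if any(not (self.domain[0] <= m <= self.domain[1]) for m in s.cv_mean):
                raise ValueError("cv means must lie in the domain")


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_frames(spec: SyntheticEnsembleSpec) -> list[FrameObservation]:
    """Draw i.i.d. frames from the state mixture.

    CVs are truncated Gaussians around each state's mean; shifts are state
    means plus Gaussian noise; the DSSP string is copied from the state.
    Draws are batched per state (one truncated-normal call per state and CV
    dimension), with the batch order fixed by the seed.
    """
    rng = np.random.default_rng(spec.seed)
    pops = np.array([s.population for s in spec.states])
    labels = rng.choice(len(spec.states), size=spec.n_frames, p=pops)
    lo, hi = spec.domain

    cvs = np.empty((spec.n_frames, len(spec.states[0].cv_mean)))
    noise = {}
    for k, state in enumerate(spec.states):
        idx = np.nonzero(labels == k)[0]
        for d, (m, sd) in enumerate(zip(state.cv_mean, state.cv_spread)):
            cvs[idx, d] = _truncated_normal(rng, m, sd, lo, hi, size=len(idx))
        if state.shift_means is not None and state.shift_noise_sd > 0:
            n_res = len(next(iter(state.shift_means.values())))
            noise[k] = {
                atom: state.shift_noise_sd
                * rng.standard_normal((len(idx), n_res))
                for atom in state.shift_means
            }

    counters = [0] * len(spec.states)
    frames = []
    for i, lab in enumerate(labels):
        state = spec.states[lab]
        shifts = None
        if state.shift_means is not None:
            j = counters[lab]
            shifts = {
                atom: np.asarray(means, float)
                + (noise[lab][atom][j] if lab in noise else 0.0)
                for atom, means in state.shift_means.items()
            }
            counters[lab] = j + 1
        frames.append(
            FrameObservation(
                time=i * spec.dt_ps,
                cv=tuple(cvs[i]),
                shifts=shifts,
                ss_string=state.ss_string or None,
                state_label=int(lab),
            )
        )
    return frames
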