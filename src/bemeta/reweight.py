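"""Boltzmann reweighting of per-frame observables on the CV grid.

Frames are binned by their (alpha_RMSD, beta_RMSD) pair onto the free-energy
grid; each bin's observable mean is weighted by the Boltzmann probability of
that bin's free energy.  This yields ensemble-averaged NMR secondary shifts,
per-residue secondary-structure fractions, class free energies relative to
coil, and the mean-absolute-error shift statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants as c
from .fes import GridSpec

SS_CLASSES = ("helix", "strand", "turn", "bend", "coil")

# DSSP letter -> class; anything else (blank, "~", "-", P, ...) is coil.
DSSP_CLASS_MAP = {
    "H": "helix",
    "G": "helix",
    "I": "helix",
    "E": "strand",
    "B": "strand",
    "T": "turn",
    "S": "bend",
}


def classify_ss(letter: str) -> str:
    return DSSP_CLASS_MAP.get(letter, "coil")


@dataclass
class FrameObservation:
    """One trajectory frame: CV pair plus optional shifts and DSSP string."""

    time: float
    cv: tuple
    shifts: dict = None          # atom name -> per-residue ppm array
    ss_string: str = None
    state_label: int = None      # synthetic ground truth, if known

    def __post_init__(self):
        self.cv = tuple(float(x) for x in np.atleast_1d(self.cv))
        if self.shifts is not None:
            self.shifts = {a: np.asarray(v, float) for a, v in self.shifts.items()}
            for a, v in self.shifts.items():
                # NaN marks a genuinely absent shift (Gly CB, Pro HN/N)
                if np.any(np.isinf(v)):
                    raise ValueError(f"infinite shift values for atom {a}")


def bin_and_average(frames, grid_spec: GridSpec, observable):
    """Per-bin arithmetic mean of an observable and per-bin frame counts.

    ``observable(frame)`` returns an array (or scalar) or None to skip the
    frame.  Returns ``(means, counts)`` keyed by node index tuples; counts
    sum to the number of contributing frames.
    """
    sums, counts = {}, {}
    for frame in frames:
        x = observable(frame)
        if x is None:
            continue
        x = np.asarray(x, float)
        key = grid_spec.index_of(frame.cv[: grid_spec.dim])
        if key in sums:
            sums[key] = sums[key] + x
            counts[key] += 1
        else:
            sums[key] = x.copy()
            counts[key] = 1
    if not counts:
        raise ValueError("observable absent from all frames")
    means = {k: s / counts[k] for k, s in sums.items()}
    return means, counts


def ensemble_average(bin_means: dict, probability: np.ndarray):
    """Probability-weighted average of per-bin means.

    The probability field is renormalised over the bins that both carry
    probability and contain frames; bins outside the intersection contribute
    nothing.
    """
    keys = [k for k in bin_means if probability[k] > 0]
    if not keys:
        raise ValueError("no overlap between populated bins and probability field")
    weights = np.array([probability[k] for k in keys])
    weights = weights / weights.sum()
    return sum(w * bin_means[k] for w, k in zip(weights, keys))


def empirical_probability(frames, grid_spec: GridSpec) -> np.ndarray:
    """Per-bin probability proportional to frame counts (plain, unreweighted).

    The weighting to use when the frame stream itself is the equilibrium
    ensemble (e.g. plain MD or a synthetic generator), rather than a biased
    trajectory reweighted through a free-energy surface.
    """
    p = np.zeros(tuple(grid_spec.n_nodes))
    for f in frames:
        p[grid_spec.index_of(f.cv[: grid_spec.dim])] += 1.0
    total = p.sum()
    if total == 0:
        raise ValueError("no frames to bin")
    return p / total


@dataclass
class RandomCoilReference:
    """Per-residue per-atom random-coil shifts (ppm)."""

    table: pd.DataFrame  # index resid, columns atom names

    def lookup(self, resid: int, atom: str) -> float:
        atom = c.ATOM_ALIASES.get(atom, atom)
        try:
            val = self.table.loc[resid, atom]
        except KeyError:
            raise KeyError(f"no random-coil reference for residue {resid}, atom {atom}")
        if pd.isna(val):
            raise KeyError(f"no random-coil reference for residue {resid}, atom {atom}")
        return float(val)

    def vector(self, atom: str) -> np.ndarray:
        atom = c.ATOM_ALIASES.get(atom, atom)
        return self.table[atom].to_numpy(dtype=float)


def secondary_shift(raw_shift, reference):
    """Secondary shift = raw - random-coil reference (elementwise).

    Positive CA secondary shifts indicate helical propensity, negative ones
    beta propensity; zero is random coil.
    """
    return np.asarray(raw_shift, float) - np.asarray(reference, float)


def apply_temperature_correction(shift_hn, coeff_ppb_per_k, t_ref: float, t_target: float):
    """Move an amide-proton shift from t_ref to t_target using ppb/K slopes."""
    return np.asarray(shift_hn, float) + np.asarray(coeff_ppb_per_k, float) * (
        (t_target - t_ref) / 1000.0
    )


def shift_error(pred, exp) -> float:
    """Mean absolute deviation (ppm/residue): (1/n) sum |pred_i - exp_i|.

    Missing experimental entries (NaN) are excluded pairwise with n reduced.
    """
    pred = np.asarray(pred, float)
    exp = np.asarray(exp, float)
    if pred.shape != exp.shape:
        raise ValueError("prediction and experiment must have equal length")
    mask = np.isfinite(pred) & np.isfinite(exp)
    if not mask.any():
        raise ValueError("no residues left after pairwise exclusion")
    return float(np.mean(np.abs(pred[mask] - exp[mask])))


def predict_ensemble_shifts(frames, grid_spec: GridSpec, probability: np.ndarray, atoms=None):
    """Reweighted raw-shift prediction per atom: DataFrame residue x atom."""
    if atoms is None:
        atoms = sorted({a for f in frames if f.shifts for a in f.shifts})
    if not atoms:
        raise ValueError("no frames carry chemical shifts")
    out = {}
    for atom in atoms:
        means, _ = bin_and_average(
            frames, grid_spec, lambda f, a=atom: None if f.shifts is None else f.shifts.get(a)
        )
        out[atom] = ensemble_average(means, probability)
    n_res = len(next(iter(out.values())))
    return pd.DataFrame(out, index=pd.RangeIndex(1, n_res + 1, name="resid"))


def _class_indicator(ss_string: str, class_map) -> np.ndarray:
    """(n_classes, n_res) one-hot class membership of a DSSP string."""
    ind = np.zeros((len(SS_CLASSES), len(ss_string)))
    for j, letter in enumerate(ss_string):
        cls = class_map.get(letter, "coil")
        ind[SS_CLASSES.index(cls), j] = 1.0
    return ind


def class_fractions(frames, grid_spec: GridSpec, probability: np.ndarray, class_map=None):
    """Reweighted secondary-structure fractions.

    Returns ``(per_residue, peptide)`` where per_residue is a DataFrame
    (residues x classes, rows summing to 1) and peptide maps each class to the
    mean fraction over residues.
    """
    if class_map is None:
        class_map = DSSP_CLASS_MAP
    means, _ = bin_and_average(
        frames,
        grid_spec,
        lambda f: None if f.ss_string is None else _class_indicator(f.ss_string, class_map),
    )
    avg = ensemble_average(means, probability)  # (n_classes, n_res)
    per_residue = pd.DataFrame(
        avg.T, columns=list(SS_CLASSES), index=pd.RangeIndex(1, avg.shape[1] + 1, name="resid")
    )
    peptide = {cls: float(avg[i].mean()) for i, cls in enumerate(SS_CLASSES)}
    return per_residue, peptide


def class_free_energy(fraction_class: float, fraction_coil: float, kT: float = 1.0):
    """-ln(f_class / f_coil), in units of kT; (+inf, True) for a zero fraction."""
    if fraction_coil <= 0:
        raise ValueError("coil fraction must be positive")
    if fraction_class < 0:
        raise ValueError("fractions must be non-negative")
    if fraction_class == 0.0:
        return math.inf, True
    return -math.log(fraction_class / fraction_coil), False
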