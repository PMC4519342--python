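"""Free-energy surfaces from the time-averaged metadynamics bias.

In metadynamics the accumulated bias converges (up to sign and an additive
constant) to the underlying free energy; averaging the bias over the whole
simulation time reduces the oscillation of the instantaneous estimate.  A
hill deposited at time t_k contributes to the bias for all t >= t_k, so the
time average over [t_start, t_end] of the cumulative bias is a single
weighted kernel sum with weight (t_end - max(t_k, t_start)) / (t_end -
t_start) per hill; this is computed exactly (no time discretisation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as c
from .bias import Hill, corrected_kernel_on_axes


@dataclass(frozen=True)
class GridSpec:
    """Regular node grid in CV space (1D or 2D)."""

    lower: tuple
    upper: tuple
    n_nodes: tuple

    @classmethod
    def fes_default(cls) -> "GridSpec":
        lo, hi = c.CV_DOMAIN
        n = c.FES_GRID_NODES
        return cls((lo, lo), (hi, hi), (n, n))

    @property
    def dim(self) -> int:
        return len(self.n_nodes)

    def axes(self) -> list[np.ndarray]:
        return [
            np.linspace(lo, hi, n)
            for lo, hi, n in zip(self.lower, self.upper, self.n_nodes)
        ]

    @property
    def spacing(self) -> tuple:
        return tuple(
            (hi - lo) / (n - 1) for lo, hi, n in zip(self.lower, self.upper, self.n_nodes)
        )

    def index_of(self, point) -> tuple:
        """Nearest-node bin index of a CV point (clipped to the grid)."""
        point = np.atleast_1d(np.asarray(point, float))
        idx = []
        for x, lo, dx, n in zip(point, self.lower, self.spacing, self.n_nodes):
            idx.append(int(np.clip(round((x - lo) / dx), 0, n - 1)))
        return tuple(idx)


@dataclass
class FreeEnergySurface:
    """Free energy on a node grid, kJ/mol, minimum shifted to zero.

    ``visited`` flags nodes inside the support of at least one hill;
    values at unvisited nodes are not meaningful and are excluded from all
    probability normalisations downstream.
    """

    grid: GridSpec
    values: np.ndarray          # kJ/mol
    visited: np.ndarray         # bool, same shape
    temperature_k: float = c.DEFAULT_TEMPERATURE_K

    @property
    def values_kt(self) -> np.ndarray:
        return self.values / c.kT(self.temperature_k)

    def shifted(self) -> "FreeEnergySurface":
        vals = self.values.copy()
        if self.visited.any():
            vals = vals - vals[self.visited].min()
        return FreeEnergySurface(self.grid, vals, self.visited.copy(), self.temperature_k)


def fes_from_bias_history(
    hills: list[Hill],
    grid_spec: GridSpec = None,
    t_start: float = 0.0,
    t_end: float = None,
    domain: tuple = c.CV_DOMAIN,
    truncation: float = c.HILL_TRUNCATION_SIGMAS,
    temperature_k: float = c.DEFAULT_TEMPERATURE_K,
    corrected: bool = True,
) -> FreeEnergySurface:
    """F(s) = -<V_bias(s, t)>_[t_start, t_end] + C, min over visited nodes = 0."""
    if not hills:
        raise ValueError("empty hill list")
    if grid_spec is None:
        grid_spec = GridSpec.fes_default()
    if t_end is None:
        t_end = max(h.time for h in hills)
    if t_start >= t_end:
        raise ValueError("t_start must be < t_end")

    axes = grid_spec.axes()
    avg_bias = np.zeros(tuple(grid_spec.n_nodes))
    visited = np.zeros_like(avg_bias, dtype=bool)
    span = t_end - t_start

    for hill in hills:
        if hill.time > t_end:
            continue
        weight = (t_end - max(hill.time, t_start)) / span
        kern, slices = corrected_kernel_on_axes(axes, hill, domain, truncation, corrected)
        if kern is None:
            continue
        avg_bias[slices] += weight * kern
        visited[slices] = True

    values = -avg_bias
    if visited.any():
        values = values - values[visited].min()
    return FreeEnergySurface(grid_spec, values, visited, temperature_k)


def probability_from_fes(fes: FreeEnergySurface, kT: float = None) -> np.ndarray:
    """Boltzmann probability per visited node, normalised to 1; 0 elsewhere."""
    if kT is None:
        kT = c.kT(fes.temperature_k)
    if not fes.visited.any():
        raise ValueError("all bins unvisited")
    p = np.zeros_like(fes.values)
    f = fes.values[fes.visited]
    w = np.exp(-(f - f.min()) / kT)
    p[fes.visited] = w / w.sum()
    return p


def convergence_trace(
    hills: list[Hill],
    grid_spec: GridSpec,
    frames,
    checkpoints,
    kT: float = None,
    class_map=None,
    level: str = "peptide",
    domain: tuple = c.CV_DOMAIN,
):
    """Class free energies vs coil, in kT, recomputed at each checkpoint.

    For each time t the FES is re-estimated from the bias history over [0, t],
    the frame ensemble is reweighted, and -ln(f_class / f_coil) reported per
    class.  Checkpoints before the first hill are skipped with a warning.
    """
    import warnings

    from .reweight import DSSP_CLASS_MAP, SS_CLASSES, class_fractions, class_free_energy

    if kT is None:
        kT = c.kT()
    if class_map is None:
        class_map = DSSP_CLASS_MAP

    first_hill = min(h.time for h in hills)
    times, rows = [], []
    for t in checkpoints:
        if t <= first_hill:
            warnings.warn(f"checkpoint {t} precedes the first hill; skipped")
            continue
        fes = fes_from_bias_history(hills, grid_spec, t_start=0.0, t_end=t, domain=domain)
        prob = probability_from_fes(fes, kT)
        _, peptide = class_fractions(frames, grid_spec, prob, class_map)
        row = {
            cls: class_free_energy(peptide[cls], peptide["coil"])[0]
            for cls in SS_CLASSES
            if cls != "coil"
        }
        times.append(t)
        rows.append(row)

    return {
        "times": np.asarray(times, float),
        "classes": {
            cls: np.array([r[cls] for r in rows]) for cls in (rows[0] if rows else {})
        },
    }
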