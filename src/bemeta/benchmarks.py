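"""Self-contained validation experiments with analytic ground truth.

Each function runs one end-to-end check of the methodology at desk scale --
free-energy recovery on a double well, boundary-correction flatness,
equilibrium sampling of the exchange driver, barrier-crossing enhancement,
reweighting parameter recovery -- and returns the measured numbers together
with the problem size.  The acceptance script and the test suite both call
these, so the published-parameter defaults (hill schedule, domain, grids)
are exercised exactly as configured.
"""

from __future__ import annotations

import filecmp
import tempfile
from pathlib import Path

import numpy as np

from . import constants as c
from . import synthetic
from .bias import BiasGrid
from .config import PipelineConfig
from .exchange import (
    ExchangeSchedule,
    Replica,
    count_barrier_crossings,
    run_bias_exchange,
)
from .fes import GridSpec, fes_from_bias_history, probability_from_fes
from .pipeline import run_pipeline
from .reweight import bin_and_average, class_fractions, empirical_probability, ensemble_average

GRID_1D = GridSpec((0.0,), (32.0,), (161,))


def _grid_1d(corrected=True):
    return BiasGrid((c.BIAS_GRID_RANGE[0],), (c.BIAS_GRID_RANGE[1],),
                    (c.BIAS_GRID_NODES_1D,), corrected=corrected)


def fes_double_well_recovery(seed: int = 0, n_steps: int = 100_000):
    """Metadynamics on an asymmetric 1D double well (barrier ~8 kT).

    Returns |estimated dF - exact dF| in kT, where dF is the left/right well
    free-energy difference from integrated Boltzmann weights; the exact value
    comes from quadrature of the analytic potential.
    """
    kT = c.kT()
    pot = synthetic.double_well_1d()
    rep = Replica("alpha_only", np.array([8.0]), _grid_1d(), bias_dims=(0,))
    res = run_bias_exchange([rep], pot, n_steps=n_steps, stride=100, seed=seed)
    fes = fes_from_bias_history(res.hills["alpha_only"], GRID_1D)
    ax = GRID_1D.axes()[0]
    left = ax < 16.0
    p = np.exp(-fes.values / kT)
    dF_est = -kT * np.log(p[left].sum() / p[~left].sum())

    fine = np.linspace(0, 32, 6401)
    bz = np.exp(-pot.energy_grid(fine) / kT)
    dF_exact = -kT * np.log(
        np.trapezoid(bz[fine < 16.0], fine[fine < 16.0])
        / np.trapezoid(bz[fine >= 16.0], fine[fine >= 16.0])
    )
    return {
        "error_kt": abs(dF_est - dF_exact) / kT,
        "dF_est_kt": dF_est / kT,
        "dF_exact_kt": dF_exact / kT,
        "n": n_steps,
    }


def boundary_flatness(seed: int = 0, n_steps: int = 100_000, corrected: bool = True):
    """Flat-potential metadynamics over [0, 32].

    Returns the max deviation (kT) of the time-averaged bias profile from its
    mean, over the whole domain and within 1 sigma of the boundary at 0.
    """
    kT = c.kT()
    flat = synthetic.ToyPotential(wells=(), dim=1)
    rep = Replica("alpha_only", np.array([16.0]), _grid_1d(corrected=corrected),
                  bias_dims=(0,))
    res = run_bias_exchange([rep], flat, n_steps=n_steps, stride=1000, seed=seed)
    fes = fes_from_bias_history(res.hills["alpha_only"], GRID_1D, corrected=corrected)
    ax = GRID_1D.axes()[0]
    dev = (fes.values - fes.values.mean()) / kT
    return {
        "max_dev_kt": float(np.max(np.abs(dev))),
        "max_dev_near_zero_kt": float(np.max(np.abs(dev[ax <= c.HILL_SIGMA]))),
        "n": n_steps,
    }


def frozen_bias_sampling(seed: int = 0, n_steps: int = 1_000_000):
    """Neutral-replica equilibrium under exchange with a frozen-biased partner.

    Hills are off; the partner carries a frozen bias cancelling the potential,
    so accepted swaps genuinely move states between very different marginals.
    Returns max_b |-kT ln p_hat(b) - U(b)| in kT over a 32-bin histogram.
    """
    kT = c.kT()
    pot = synthetic.ToyPotential(
        (synthetic.GaussianWell(2.0 * kT, (10.0,), 4.0),
         synthetic.GaussianWell(1.2 * kT, (24.0,), 3.0)),
        dim=1,
    )
    grid = _grid_1d()
    u_nodes = pot.energy_grid(grid.axes[0])
    grid.values = u_nodes.max() - u_nodes
    reps = [
        Replica("neutral", np.array([10.0])),
        Replica("alpha_only", np.array([24.0]), grid, bias_dims=(0,)),
    ]
    res = run_bias_exchange(reps, pot, ExchangeSchedule(100), n_steps=n_steps,
                            mc_moves_per_step=1, hill_height=0.0, stride=1, seed=seed)
    pos = np.array([f.cv[0] for f in res.frames["neutral"]])
    counts, edges = np.histogram(pos, bins=32, range=(0.0, 32.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    f_hat = -kT * np.log(counts / counts.sum())
    u = np.array([pot.energy(x) for x in centers])
    dev = f_hat - u
    dev -= dev.mean()
    return {"max_dev_kt": float(np.max(np.abs(dev)) / kT), "n": n_steps}


def crossing_enhancement(seed: int = 0, n_steps: int = 100_000):
    """Barrier crossings of the neutral replica: hills + exchange vs control.

    Two-replica layout on the 8 kT double well; the control is the same
    neutral sampler with no hills and no partner.
    """
    pot = synthetic.double_well_1d()
    reps = [
        Replica("neutral", np.array([8.0])),
        Replica("alpha_only", np.array([8.0]), _grid_1d(), bias_dims=(0,)),
    ]
    res_on = run_bias_exchange(reps, pot, ExchangeSchedule(100), n_steps=n_steps,
                               stride=10, seed=seed)
    res_off = run_bias_exchange([Replica("neutral", np.array([8.0]))], pot,
                                n_steps=n_steps, hill_height=0.0, stride=10, seed=seed)
    on = count_barrier_crossings([f.cv[0] for f in res_on.frames["neutral"]], 10.0, 22.0)
    off = count_barrier_crossings([f.cv[0] for f in res_off.frames["neutral"]], 10.0, 22.0)
    return {"crossings_biased": on, "crossings_control": off,
            "ratio": on / max(off, 1), "n": n_steps}


def reweight_oracle_agreement(seed: int = 0, n_frames: int = 10_000):
    """ensemble_average vs an independent brute-force frame-weighted sum."""
    rng = np.random.default_rng(seed)
    grid = GridSpec((0.0, 0.0), (32.0, 32.0), (160, 160))
    frames = synthetic.generate_frames(
        synthetic.SyntheticEnsembleSpec(
            (
                synthetic.SyntheticState(0.5, (5.0, 5.0), (2.0, 2.0),
                                         {"CA": rng.uniform(50, 60, 8)}, 0.3, "C" * 8),
                synthetic.SyntheticState(0.5, (20.0, 10.0), (2.0, 2.0),
                                         {"CA": rng.uniform(50, 60, 8)}, 0.3, "H" * 8),
            ),
            n_frames=n_frames,
            seed=seed + 1,
        )
    )
    means, counts = bin_and_average(frames, grid, lambda f: f.shifts["CA"])
    p = empirical_probability(frames, grid)
    fast = ensemble_average(means, p)
    total = np.zeros_like(fast)
    wsum = 0.0
    for f in frames:
        k = grid.index_of(f.cv)
        w = p[k] / counts[k]
        total += w * f.shifts["CA"]
        wsum += w
    brute = total / wsum
    return {"max_abs_diff": float(np.max(np.abs(fast - brute))), "n": n_frames}


def parameter_recovery(seed: int = 0, n_frames: int = 100_000):
    """Recover a 0.20 helix fraction and a +2.0 ppm helix-state CA offset."""
    n_res = 37
    coil_ca = np.full(n_res, 55.0)
    helix_ca = coil_ca + 2.0
    states = (
        synthetic.SyntheticState(0.80, (2.0, 1.0), (1.0, 0.8),
                                 {"CA": coil_ca}, 0.3, "C" * n_res),
        synthetic.SyntheticState(0.20, (16.0, 1.0), (1.0, 0.8),
                                 {"CA": helix_ca}, 0.3, "H" * n_res),
    )
    frames = synthetic.generate_frames(
        synthetic.SyntheticEnsembleSpec(states, n_frames=n_frames, seed=seed)
    )
    grid = GridSpec((0.0, 0.0), (32.0, 32.0), (160, 160))
    p = empirical_probability(frames, grid)
    _, peptide = class_fractions(frames, grid, p)
    helix_fraction = peptide["helix"]
    means, _ = bin_and_average(frames, grid, lambda f: f.shifts["CA"])
    ens_ca = ensemble_average(means, p)
    offset = float(np.mean(ens_ca - coil_ca) / helix_fraction)
    return {"helix_fraction": float(helix_fraction), "ca_offset_ppm": offset,
            "n": n_frames}


def demo_determinism(seed: int = 0, n_steps: int = 3000):
    """Two identically seeded demo-pipeline runs: 1.0 if all reports match."""
    cfg = PipelineConfig(n_steps=n_steps, output_stride=5, exchange_interval=50,
                         seed=seed)
    with tempfile.TemporaryDirectory() as tmp:
        dirs = [Path(tmp) / "a", Path(tmp) / "b"]
        for d in dirs:
            run_pipeline(cfg, out_dir=d)
        files = sorted(p.name for p in dirs[0].iterdir())
        match, mismatch, errors = filecmp.cmpfiles(dirs[0], dirs[1], files,
                                                   shallow=False)
    identical = not mismatch and not errors and set(match) == set(files)
    return {"identical": float(identical), "n": n_steps, "n_files": len(files)}
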