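"""Free-energy estimation from the time-averaged bias history."""

import math

import numpy as np
import pytest

from bemeta import constants as c
from bemeta import synthetic
from bemeta.bias import Hill, corrected_kernel
from bemeta.fes import (
    FreeEnergySurface,
    GridSpec,
    convergence_trace,
    fes_from_bias_history,
    probability_from_fes,
)
from bemeta.reweight import class_fractions, class_free_energy


GRID_1D = GridSpec((0.0,), (32.0,), (161,))


def test_single_hill_constant_bias_gives_well():
    hill = Hill((16.0,), 0.1, (2.0,), time=0.0)
    fes = fes_from_bias_history([hill], GRID_1D, t_end=100.0)
    ax = GRID_1D.axes()[0]
    expected = np.array([-corrected_kernel((x,), hill) for x in ax])
    expected -= expected[fes.visited].min()
    assert np.allclose(fes.values[fes.visited], expected[fes.visited], atol=1e-12)
    assert fes.values.min() == pytest.approx(0.0)
    # the well is ~0.1 kJ/mol deep at the hill center
    assert fes.values[fes.visited].max() == pytest.approx(0.1, abs=1e-3)


def test_piecewise_time_weights_match_hand_integral():
    """Hills only in [0, T/2]: hand-integrated weights (T-t_k)/T."""
    T = 100.0
    h1 = Hill((10.0,), 0.1, (2.0,), time=10.0)
    h2 = Hill((20.0,), 0.1, (2.0,), time=50.0)
    fes = fes_from_bias_history([h1, h2], GRID_1D, t_end=T)
    ax = GRID_1D.axes()[0]
    w1, w2 = (T - 10.0) / T, (T - 50.0) / T
    expected = -np.array(
        [w1 * corrected_kernel((x,), h1) + w2 * corrected_kernel((x,), h2) for x in ax]
    )
    expected -= expected[fes.visited].min()
    assert np.allclose(fes.values[fes.visited], expected[fes.visited], atol=1e-12)


def test_hills_before_t_start_carry_full_weight():
    h1 = Hill((10.0,), 0.1, (2.0,), time=5.0)
    fes = fes_from_bias_history([h1], GRID_1D, t_start=20.0, t_end=120.0)
    # deposited before the averaging window -> present for its whole span
    assert fes.values[fes.visited].max() == pytest.approx(0.1, abs=1e-3)


def test_fes_input_validation():
    with pytest.raises(ValueError):
        fes_from_bias_history([], GRID_1D)
    with pytest.raises(ValueError):
        fes_from_bias_history([Hill((1.0,), 0.1, (2.0,), time=0.0)], GRID_1D,
                              t_start=10.0, t_end=5.0)


def test_unvisited_bins_flagged_not_zero():
    hill = Hill((2.0,), 0.1, (0.5,), time=0.0)
    fes = fes_from_bias_history([hill], GRID_1D, t_end=10.0)
    assert fes.visited.any() and not fes.visited.all()
    p = probability_from_fes(fes)
    assert np.all(p[~fes.visited] == 0.0)
    assert p.sum() == pytest.approx(1.0)


# --- probability ----------------------------------------------------------------


def test_probability_two_bins_closed_form(kT):
    grid = GridSpec((0.0,), (1.0,), (2,))
    fes = FreeEnergySurface(grid, np.array([0.0, kT * math.log(2.0)]),
                            np.array([True, True]))
    p = probability_from_fes(fes, kT)
    assert p == pytest.approx([2 / 3, 1 / 3], rel=1e-12)


def test_probability_uniform_f():
    grid = GridSpec((0.0,), (4.0,), (5,))
    fes = FreeEnergySurface(grid, np.zeros(5), np.ones(5, bool))
    assert probability_from_fes(fes) == pytest.approx(np.full(5, 0.2))


def test_probability_offset_invariance(kT, rng):
    grid = GridSpec((0.0,), (9.0,), (10,))
    f = rng.uniform(0, 5, 10)
    fes1 = FreeEnergySurface(grid, f, np.ones(10, bool))
    fes2 = FreeEnergySurface(grid, f + 123.4, np.ones(10, bool))
    assert np.allclose(probability_from_fes(fes1), probability_from_fes(fes2), atol=1e-12)


def test_probability_all_unvisited_error():
    grid = GridSpec((0.0,), (1.0,), (2,))
    fes = FreeEnergySurface(grid, np.zeros(2), np.zeros(2, bool))
    with pytest.raises(ValueError):
        probability_from_fes(fes)


# --- synthetic-hill oracle: known landscape, known populations ------------------


def _two_state_setup(kT):
    """Hills that reproduce -U exactly (wells double as plain hills at t=0).

    Wells are deep (>= 7 kT) so the basin Boltzmann mass dominates the flat
    background; the analytic target integrates each basin over the region the
    frame ensemble populates (reweighting renormalises probability over
    populated bins, so mass outside them must not enter the oracle).
    """
    centers = ((6.0, 2.0), (20.0, 2.0))
    pot = synthetic.ToyPotential(
        (synthetic.GaussianWell(20.0, centers[0], 2.0),
         synthetic.GaussianWell(18.0, centers[1], 2.0)),
        dim=2,
    )
    hills = [Hill(w.center, w.depth, (w.sigma, w.sigma), time=0.0) for w in pot.wells]
    states = (
        synthetic.SyntheticState(0.6, centers[0], (1.2, 1.2), ss_string="C" * 8),
        synthetic.SyntheticState(0.4, centers[1], (1.2, 1.2), ss_string="H" * 8),
    )
    spec = synthetic.SyntheticEnsembleSpec(states, n_frames=20_000, seed=5)
    frames = synthetic.generate_frames(spec)

    def basin_mass(center, half=5.0):
        gx = np.linspace(max(center[0] - half, 0), min(center[0] + half, 32), 801)
        gy = np.linspace(max(center[1] - half, 0), min(center[1] + half, 32), 801)
        u = pot.energy_grid(gx, gy)
        return np.trapezoid(np.trapezoid(np.exp(-u / kT), gy, axis=1), gx)

    target = -math.log(basin_mass(centers[1]) / basin_mass(centers[0]))  # dF(helix), kT
    return pot, hills, frames, target


def test_two_state_class_free_energy_matches_quadrature(kT):
    pot, hills, frames, target = _two_state_setup(kT)
    grid = GridSpec((0.0, 0.0), (32.0, 32.0), (160, 160))
    fes = fes_from_bias_history(hills, grid, t_end=1.0, corrected=False)
    # estimator reproduces the potential itself on the grid
    u = pot.energy_grid(*grid.axes())
    assert np.allclose(fes.values, u - u.min(), atol=1e-9)
    prob = probability_from_fes(fes, kT)
    _, peptide = class_fractions(frames, grid, prob)
    df, _ = class_free_energy(peptide["helix"], peptide["coil"])
    assert df == pytest.approx(target, abs=0.2)


def test_refinement_consistency(kT):
    """Doubling the grid changes the class free energy by <= 0.1 kT."""
    _, hills, frames, _ = _two_state_setup(kT)
    dfs = []
    for n in (160, 320):
        grid = GridSpec((0.0, 0.0), (32.0, 32.0), (n, n))
        fes = fes_from_bias_history(hills, grid, t_end=1.0, corrected=False)
        prob = probability_from_fes(fes, kT)
        _, peptide = class_fractions(frames, grid, prob)
        dfs.append(class_free_energy(peptide["helix"], peptide["coil"])[0])
    assert abs(dfs[0] - dfs[1]) <= 0.1


def test_offset_invariance_of_downstream_quantities(kT):
    _, hills, frames, _ = _two_state_setup(kT)
    grid = GridSpec((0.0, 0.0), (32.0, 32.0), (160, 160))
    fes = fes_from_bias_history(hills, grid, t_end=1.0, corrected=False)
    shifted = FreeEnergySurface(grid, fes.values + 57.0, fes.visited, fes.temperature_k)
    p1, p2 = probability_from_fes(fes, kT), probability_from_fes(shifted, kT)
    assert np.allclose(p1, p2, atol=1e-12)
    _, pep1 = class_fractions(frames, grid, p1)
    _, pep2 = class_fractions(frames, grid, p2)
    assert pep1 == pytest.approx(pep2, abs=1e-12)


# --- convergence trace -----------------------------------------------------------


def test_trace_constant_for_stationary_bias(kT):
    _, hills, frames, _ = _two_state_setup(kT)
    grid = GridSpec((0.0, 0.0), (32.0, 32.0), (160, 160))
    trace = convergence_trace(hills, grid, frames, checkpoints=[10.0, 50.0, 100.0])
    vals = trace["classes"]["helix"]
    assert np.allclose(vals, vals[0], atol=1e-9)  # hills at t=0: full weight always


def test_trace_single_checkpoint_equals_full_estimate(kT):
    _, hills, frames, _ = _two_state_setup(kT)
    grid = GridSpec((0.0, 0.0), (32.0, 32.0), (160, 160))
    T = 100.0
    trace = convergence_trace(hills, grid, frames, checkpoints=[T])
    fes = fes_from_bias_history(hills, grid, t_end=T)
    prob = probability_from_fes(fes, kT)
    _, peptide = class_fractions(frames, grid, prob)
    expected = class_free_energy(peptide["helix"], peptide["coil"])[0]
    assert trace["classes"]["helix"][0] == pytest.approx(expected, rel=1e-9)


def test_trace_skips_checkpoints_before_first_hill(kT):
    _, hills, frames, _ = _two_state_setup(kT)
    hills = [Hill(h.center, h.height, h.sigma, time=50.0) for h in hills]
    grid = GridSpec((0.0, 0.0), (32.0, 32.0), (160, 160))
    with pytest.warns(UserWarning):
        trace = convergence_trace(hills, grid, frames, checkpoints=[10.0, 100.0])
    assert list(trace["times"]) == [100.0]


# --- exact_fes oracle -------------------------------------------------------------


def test_exact_fes_flat_zero():
    pot = synthetic.ToyPotential(wells=(), dim=1)
    f = synthetic.exact_fes(pot, [np.linspace(0, 32, 161)])
    assert np.allclose(f, 0.0)


def test_exact_fes_single_well_depth():
    pot = synthetic.ToyPotential((synthetic.GaussianWell(5.0, (16.0,), 2.0),), dim=1)
    ax = np.linspace(0, 32, 321)
    f = synthetic.exact_fes(pot, [ax])
    assert f[np.argmin(np.abs(ax - 16.0))] == pytest.approx(0.0, abs=1e-12)
    assert f[0] == pytest.approx(5.0, abs=1e-6)


def test_exact_fes_marginal_matches_fine_quadrature(kT):
    pot = synthetic.ToyPotential(
        (synthetic.GaussianWell(6.0, (8.0, 4.0), 2.0),
         synthetic.GaussianWell(4.0, (24.0, 10.0), 2.5)),
        dim=2,
    )
    ax = np.linspace(0, 32, 161)
    f = synthetic.exact_fes(pot, [ax], kT=kT, marginal_axis=1)
    # independent high-resolution quadrature
    fine = np.linspace(0, 32, 12001)
    u = pot.energy_grid(ax, fine)
    z = np.trapezoid(np.exp(-u / kT), fine, axis=1)
    ref = -kT * np.log(z)
    ref -= ref.min()
    assert np.allclose(f, ref, atol=1e-6)
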