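"""Bias-exchange sampling over toy CV-space dynamics.

A Metropolis random walk stands in for the MD integrator: each replica
carries its own history-dependent bias (none; along the first CV; along the
second; or along both), hills are deposited at the replica's current
position, and replicas periodically attempt to exchange configurations with
the standard bias-exchange Metropolis criterion evaluated on the bias
energies alone (the physical potential cancels because configurations swap
at equal temperature).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import constants as c
from .bias import BiasGrid, Hill
from .reweight import FrameObservation

REPLICA_IDS = ("neutral", "alpha_only", "beta_only", "both")
_BIAS_DIMS = {"neutral": (), "alpha_only": (0,), "beta_only": (1,), "both": (0, 1)}


@dataclass
class Replica:
    """One sampler box with its own bias grid(s)."""

    id: str
    state: np.ndarray
    grid: BiasGrid = None      # None for the neutral replica
    bias_dims: tuple = None

    def __post_init__(self):
        self.state = np.atleast_1d(np.asarray(self.state, float))
        if self.bias_dims is None:
            self.bias_dims = _BIAS_DIMS.get(self.id, ())
        if self.grid is None and self.bias_dims:
            raise ValueError(f"replica {self.id} biases {self.bias_dims} but has no grid")
        if self.grid is not None and self.grid.dim != len(self.bias_dims):
            raise ValueError("grid dimensionality must match the biased CVs")

    def bias_energy(self, state) -> float:
        if self.grid is None or not self.bias_dims:
            return 0.0
        sub = [state[d] for d in self.bias_dims]
        return self.grid.evaluate(sub if len(sub) > 1 else sub[0])


@dataclass(frozen=True)
class ExchangeSchedule:
    interval_steps: int = 100
    pair_selection: str = "neighbor_cycle"  # or "random_pair"
    temperature_k: float = c.DEFAULT_TEMPERATURE_K

    def __post_init__(self):
        if self.interval_steps < 1:
            raise ValueError("exchange interval must be >= 1 step")
        if self.pair_selection not in ("neighbor_cycle", "random_pair"):
            raise ValueError("unknown pair-selection scheme")


def swap_acceptance(bias_a_at_a, bias_a_at_b, bias_b_at_b, bias_b_at_a, kT) -> float:
    """min(1, exp[(V_a(x_a) + V_b(x_b) - V_a(x_b) - V_b(x_a)) / kT])."""
    if kT <= 0:
        raise ValueError("kT must be positive")
    delta = (bias_a_at_a + bias_b_at_b - bias_a_at_b - bias_b_at_a) / kT
    if delta >= 0:
        return 1.0
    return math.exp(delta)


def mc_step(state, rng, potential_energy, bias_energy, proposal_sigma, kT, domain=c.CV_DOMAIN):
    """One Metropolis step; out-of-domain proposals are rejected outright.

    Returns ``(new_state, accepted)``.  ``potential_energy`` and
    ``bias_energy`` are callables on full CV points.
    """
    lo, hi = domain
    proposal = state + rng.normal(0.0, proposal_sigma, size=state.shape)
    if np.any(proposal < lo) or np.any(proposal > hi):
        return state, False
    delta = (
        potential_energy(proposal)
        + bias_energy(proposal)
        - potential_energy(state)
        - bias_energy(state)
    )
    if delta <= 0 or rng.random() < math.exp(-delta / kT):
        return proposal, True
    return state, False


def make_standard_replicas(
    start=(1.0, 1.0),
    grid_nodes_1d: int = c.BIAS_GRID_NODES_1D,
    grid_nodes_2d: int = c.BIAS_GRID_NODES_2D,
    corrected: bool = True,
) -> list[Replica]:
    """The four-box layout: unbiased, alpha-biased, beta-biased, both."""
    lo, hi = c.BIAS_GRID_RANGE
    start = np.asarray(start, float)

    def grid_1d():
        return BiasGrid((lo,), (hi,), (grid_nodes_1d,), corrected=corrected)

    def grid_2d():
        return BiasGrid((lo, lo), (hi, hi), (grid_nodes_2d, grid_nodes_2d), corrected=corrected)

    return [
        Replica("neutral", start.copy()),
        Replica("alpha_only", start.copy(), grid_1d()),
        Replica("beta_only", start.copy(), grid_1d()),
        Replica("both", start.copy(), grid_2d()),
    ]


@dataclass
class BiasExchangeResult:
    frames: dict               # replica id -> list[FrameObservation]
    hills: dict                # replica id -> list[Hill]
    replicas: list
    swap_attempts: int = 0
    swaps_accepted: int = 0


def run_bias_exchange(
    replicas: list[Replica],
    potential,
    schedule: ExchangeSchedule = ExchangeSchedule(),
    n_steps: int = 10000,
    hill_pace: int = c.HILL_PACE_STEPS,
    hill_height: float = c.HILL_HEIGHT_KJ_MOL,
    hill_sigma: float = c.HILL_SIGMA,
    proposal_sigma: float = 0.5,
    mc_moves_per_step: int = 10,
    stride: int = 10,
    seed: int = 0,
    domain: tuple = c.CV_DOMAIN,
    extra_energy=None,
) -> BiasExchangeResult:
    """Interleave Metropolis moves, hill deposition, and swap attempts.

    One step is the ps-equivalent of the hill schedule (default: one hill per
    step in every biased replica).  ``mc_moves_per_step`` sets the toy
    integrator's granularity -- how many Metropolis moves make up one
    ps-equivalent -- mirroring the many MD integration steps between hill
    depositions; the sampler must decorrelate faster than the bias grows for
    metadynamics to stay in its quasi-equilibrium regime.

    Each replica owns an independent RNG stream; a separate stream drives
    pair selection and swap decisions, so trajectories are reproducible
    regardless of replica count.
    """
    kT = c.kT(schedule.temperature_k)
    lo, hi = domain
    n_rep = len(replicas)
    seeds = np.random.SeedSequence(seed).spawn(n_rep + 1)
    rngs = [np.random.default_rng(s) for s in seeds[:n_rep]]
    exchange_rng = np.random.default_rng(seeds[-1])

    def bare_energy(x):
        e = potential.energy(x)
        if extra_energy is not None:
            e += extra_energy(x)
        return e

    frames = {rep.id: [] for rep in replicas}
    hills = {rep.id: [] for rep in replicas}
    pair_cycle = [(k, k + 1) for k in range(n_rep - 1)]
    cycle_pos = 0
    attempts = accepted = 0

    # cached energies at the current state (refreshed on deposit and swap)
    e_pot = [bare_energy(rep.state) for rep in replicas]
    e_bias = [rep.bias_energy(rep.state) for rep in replicas]

    for step in range(1, n_steps + 1):
        for r, (rep, rng) in enumerate(zip(replicas, rngs)):
            moves = rng.normal(0.0, proposal_sigma, size=(mc_moves_per_step, rep.state.size))
            accept_u = rng.random(mc_moves_per_step)
            for k in range(mc_moves_per_step):
                proposal = rep.state + moves[k]
                if np.any(proposal < lo) or np.any(proposal > hi):
                    continue
                ep = bare_energy(proposal)
                eb = rep.bias_energy(proposal)
                delta = ep + eb - e_pot[r] - e_bias[r]
                if delta <= 0 or accept_u[k] < math.exp(-delta / kT):
                    rep.state = proposal
                    e_pot[r], e_bias[r] = ep, eb

        if hill_height > 0 and hill_pace > 0 and step % hill_pace == 0:
            for r, rep in enumerate(replicas):
                if rep.grid is None:
                    continue
                center = tuple(
                    float(np.clip(rep.state[d], lo, hi)) for d in rep.bias_dims
                )
                hill = Hill(center, hill_height, (hill_sigma,) * len(center), time=float(step))
                rep.grid.deposit(hill)
                hills[rep.id].append(hill)
                e_bias[r] = rep.bias_energy(rep.state)

        if n_rep > 1 and step % schedule.interval_steps == 0:
            if schedule.pair_selection == "neighbor_cycle":
                a, b = pair_cycle[cycle_pos % len(pair_cycle)]
                cycle_pos += 1
            else:
                a, b = sorted(exchange_rng.choice(n_rep, size=2, replace=False))
            ra, rb = replicas[a], replicas[b]
            bias_a_at_b = ra.bias_energy(rb.state)
            bias_b_at_a = rb.bias_energy(ra.state)
            prob = swap_acceptance(e_bias[a], bias_a_at_b, e_bias[b], bias_b_at_a, kT)
            attempts += 1
            if exchange_rng.random() < prob:
                ra.state, rb.state = rb.state.copy(), ra.state.copy()
                e_pot[a], e_pot[b] = e_pot[b], e_pot[a]
                e_bias[a], e_bias[b] = bias_a_at_b, bias_b_at_a
                accepted += 1

        if step % stride == 0:
            for rep in replicas:
                cv = tuple(rep.state) if rep.state.size > 1 else (float(rep.state[0]),)
                frames[rep.id].append(FrameObservation(time=float(step), cv=cv))

    return BiasExchangeResult(frames, hills, replicas, attempts, accepted)


def count_barrier_crossings(positions, left: float, right: float) -> int:
    """Transitions between two wells with hysteresis thresholds.

    A crossing is counted each time the walker, last seen at or beyond one
    threshold, reaches the opposite one; intermediate dithering between the
    thresholds does not count.
    """
    side = 0  # -1 left, +1 right, 0 undecided
    crossings = 0
    for x in np.asarray(positions, float).ravel():
        if x <= left:
            if side == 1:
                crossings += 1
            side = -1
        elif x >= right:
            if side == -1:
                crossings += 1
            side = 1
    return crossings
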