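"""Metadynamics bias: Gaussian hills, boundary correction, grids, walls.

Hills near a non-periodic CV boundary lose part of their mass outside the
accessible domain, which systematically under-deposits bias there and leaves
artifacts in the recovered free energy near the boundary.  The correction
used here divides the kernel by M(s), the fraction of a Gaussian's mass that
lies inside the domain when centred at the evaluation point s:

    K(s, c) = h * exp(-(s - c)^2 / 2 sigma^2) / M(s)   (per dimension)

Under uniform sampling the deposition flux integral(K(s, c) dc) over in-domain
centers is then exactly constant in s, so a flat landscape stays flat all the
way to the wall -- the flat profile is a stable fixed point of the
metadynamics feedback.  Far from the boundaries M(s) is 1 to machine
precision and the kernel is the plain Gaussian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from . import constants as c

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class Hill:
    """One deposited Gaussian hill in 1D or 2D CV space."""

    center: tuple            # CV-space point
    height: float            # kJ/mol
    sigma: tuple             # per-dimension width
    time: float = 0.0        # ps

    def __post_init__(self):
        object.__setattr__(self, "center", tuple(float(x) for x in np.atleast_1d(self.center)))
        object.__setattr__(self, "sigma", tuple(float(s) for s in np.atleast_1d(self.sigma)))
        if len(self.sigma) == 1 and len(self.center) > 1:
            object.__setattr__(self, "sigma", self.sigma * len(self.center))
        if self.height <= 0:
            raise ValueError("hill height must be positive")
        if any(s <= 0 for s in self.sigma):
            raise ValueError("hill sigma must be positive")
        if not all(math.isfinite(x) for x in self.center):
            raise ValueError("hill center must be finite")

    @property
    def dim(self) -> int:
        return len(self.center)


@dataclass(frozen=True)
class WallPotential:
    """Half-harmonic upper wall: 0 below the threshold, (kappa/2) dx^2 above."""

    position: float = c.WALL_POSITION_NM
    kappa: float = c.WALL_KAPPA

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")


def wall_energy(x: float, wall: WallPotential) -> float:
    """Energy (kJ/mol) of the half-harmonic wall at coordinate x."""
    dx = x - wall.position
    if dx <= 0:
        return 0.0
    return 0.5 * wall.kappa * dx * dx


def _in_domain_mass_1d(center: float, sigma: float, lo: float, hi: float) -> float:
    """Fraction of a unit Gaussian's mass inside [lo, hi]."""
    return 0.5 * (erf((hi - center) / (_SQRT2 * sigma)) - erf((lo - center) / (_SQRT2 * sigma)))


def in_domain_mass(hill: Hill, domain_lo, domain_hi) -> float:
    """Product over dimensions of the hill's in-domain Gaussian mass."""
    lo = np.broadcast_to(np.atleast_1d(domain_lo), (hill.dim,))
    hi = np.broadcast_to(np.atleast_1d(domain_hi), (hill.dim,))
    m = 1.0
    for ck, sk, lk, hk in zip(hill.center, hill.sigma, lo, hi):
        m *= _in_domain_mass_1d(ck, sk, lk, hk)
    return m


def corrected_kernel(point, hill: Hill, domain_lo=c.CV_DOMAIN[0], domain_hi=c.CV_DOMAIN[1]):
    """Boundary-corrected hill energy at a point: h * G(point - center) / M(point).

    M(point) is the product over dimensions of the in-domain Gaussian mass
    centred at the evaluation point (clamped into the domain); at a wall one
    dimension's mass is 1/2, so a hill sitting on the wall evaluates to twice
    its nominal height there.
    """
    lo = np.broadcast_to(np.atleast_1d(np.asarray(domain_lo, float)), (hill.dim,))
    hi = np.broadcast_to(np.atleast_1d(np.asarray(domain_hi, float)), (hill.dim,))
    if any(not (lk <= ck <= hk) for ck, lk, hk in zip(hill.center, lo, hi)):
        raise ValueError("hill center outside the correction domain")
    point = np.atleast_1d(np.asarray(point, float))
    z2 = sum((p - ck) ** 2 / sk**2 for p, ck, sk in zip(point, hill.center, hill.sigma))
    mass = 1.0
    for pk, sk, lk, hk in zip(point, hill.sigma, lo, hi):
        mass *= _in_domain_mass_1d(min(max(pk, lk), hk), sk, lk, hk)
    return hill.height * math.exp(-0.5 * float(z2)) / mass


def plain_kernel(point, hill: Hill) -> float:
    """Uncorrected Gaussian hill energy (the control near boundaries)."""
    point = np.atleast_1d(np.asarray(point, float))
    z2 = sum((p - ck) ** 2 / sk**2 for p, ck, sk in zip(point, hill.center, hill.sigma))
    return hill.height * math.exp(-0.5 * float(z2))


def corrected_kernel_on_axes(axes, hill: Hill, domain=c.CV_DOMAIN,
                             truncation: float = c.HILL_TRUNCATION_SIGMAS,
                             corrected: bool = True):
    """Separable evaluation of one hill on grid axes, truncated at +-trunc*sigma.

    Returns ``(kernel_array, slices)`` restricted to the truncation window, or
    ``(None, None)`` when the window misses the grid entirely.
    """
    lo_d, hi_d = domain
    factors, slices = [], []
    for ax, ck, sk in zip(axes, hill.center, hill.sigma):
        i0, i1 = np.searchsorted(ax, [ck - truncation * sk, ck + truncation * sk])
        if i0 >= i1:
            return None, None
        window = ax[i0:i1]
        factor = np.exp(-0.5 * ((window - ck) / sk) ** 2)
        if corrected:
            clamped = np.clip(window, lo_d, hi_d)
            mass = 0.5 * (
                erf((hi_d - clamped) / (_SQRT2 * sk)) - erf((lo_d - clamped) / (_SQRT2 * sk))
            )
            factor = factor / mass
        factors.append(factor)
        slices.append(slice(i0, i1))
    kern = factors[0]
    for f in factors[1:]:
        kern = np.multiply.outer(kern, f)
    return hill.height * kern, tuple(slices)


@dataclass
class BiasGrid:
    """Accumulated bias tabulated on a regular node grid (1D or 2D).

    The grid range deliberately exceeds the correction domain (default
    [-5, 42] vs [0, 32]) so that hill tails are stored without clipping.
    """

    lower: tuple = (c.BIAS_GRID_RANGE[0],)
    upper: tuple = (c.BIAS_GRID_RANGE[1],)
    n_nodes: tuple = (c.BIAS_GRID_NODES_1D,)
    domain_lo: float = c.CV_DOMAIN[0]
    domain_hi: float = c.CV_DOMAIN[1]
    truncation: float = c.HILL_TRUNCATION_SIGMAS
    corrected: bool = True
    values: np.ndarray = None
    clamp_centers: bool = True

    def __post_init__(self):
        self.lower = tuple(float(x) for x in np.atleast_1d(self.lower))
        self.upper = tuple(float(x) for x in np.atleast_1d(self.upper))
        self.n_nodes = tuple(int(n) for n in np.atleast_1d(self.n_nodes))
        if self.values is None:
            self.values = np.zeros(self.n_nodes)
        self._axes = [
            np.linspace(lo, hi, n) for lo, hi, n in zip(self.lower, self.upper, self.n_nodes)
        ]
        self._spacing = [
            (hi - lo) / (n - 1) for lo, hi, n in zip(self.lower, self.upper, self.n_nodes)
        ]

    @classmethod
    def default_2d(cls, corrected: bool = True) -> "BiasGrid":
        lo, hi = c.BIAS_GRID_RANGE
        n = c.BIAS_GRID_NODES_2D
        return cls((lo, lo), (hi, hi), (n, n), corrected=corrected)

    @property
    def dim(self) -> int:
        return len(self.n_nodes)

    @property
    def axes(self) -> list[np.ndarray]:
        return self._axes

    def copy(self) -> "BiasGrid":
        g = BiasGrid(
            self.lower, self.upper, self.n_nodes, self.domain_lo, self.domain_hi,
            self.truncation, self.corrected, self.values.copy(), self.clamp_centers,
        )
        return g

    def deposit(self, hill: Hill) -> None:
        """Add one hill to the tabulated bias (in place)."""
        if hill.dim != self.dim:
            raise ValueError("hill dimensionality does not match the grid")
        center = np.clip(hill.center, self.domain_lo, self.domain_hi) if self.clamp_centers else hill.center
        hill = Hill(tuple(np.atleast_1d(center)), hill.height, hill.sigma, hill.time)
        kern, slices = corrected_kernel_on_axes(
            self._axes, hill, (self.domain_lo, self.domain_hi), self.truncation, self.corrected
        )
        if kern is None:
            return
        self.values[slices] += kern

    def evaluate(self, point) -> float:
        """Multilinear interpolation of the tabulated bias; exact at nodes."""
        point = np.atleast_1d(np.asarray(point, float))
        idx, frac = [], []
        for x, lo, hi, dx, n in zip(point, self.lower, self.upper, self._spacing, self.n_nodes):
            if x < lo or x > hi:
                raise ValueError(f"point {x} outside grid range [{lo}, {hi}]")
            u = (x - lo) / dx
            i = min(int(u), n - 2)
            idx.append(i)
            frac.append(u - i)
        if self.dim == 1:
            i, f = idx[0], frac[0]
            v = self.values
            return float((1 - f) * v[i] + f * v[i + 1])
        (i, j), (fx, fy) = idx, frac
        v = self.values
        return float(
            (1 - fx) * (1 - fy) * v[i, j]
            + fx * (1 - fy) * v[i + 1, j]
            + (1 - fx) * fy * v[i, j + 1]
            + fx * fy * v[i + 1, j + 1]
        )
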