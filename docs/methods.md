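# Methods

## Scope and model

`bemeta` reconstructs, at desk scale, the free-energy and reweighting
analysis used to compare secondary-structure ensembles of disordered
peptides: secondary-structure collective variables (CVs), boundary-corrected
bias-exchange metadynamics, free-energy surfaces (FES) from the time-averaged
bias, and Boltzmann reweighting of per-frame NMR shifts and DSSP
assignments. The molecular-dynamics engine itself is out of scope; a
Metropolis random walk in CV space plays its role, driven by analytic toy
potentials whose free energies are known in closed form or by quadrature.
This substitution is what makes every stage falsifiable: each estimator is
tested against the exact answer for the landscape it sampled.

Energies are kept in kJ/mol internally; kT at 310 K (2.5775 kJ/mol,
k_B = 0.0083144621 kJ/mol/K) is applied only at reporting boundaries.

## Collective variables

α_RMSD sums, over every contiguous 6-residue window, a rational switching
function of the optimal-superposition RMSD between the window's backbone
atoms (N, CA, CB, C, O per residue; CA substitutes a missing CB) and an ideal
helical fragment. Antiparallel β_RMSD does the same over composite fragments
built from two 3-residue segments (i..i+2, j..j+2).

Conventions the reference CV definition leaves open, fixed here and used
consistently for templates and queries:

- **Switching parameters** r0 = 0.08 nm, n = 8, m = 12, no distance offset.
  The printed "0.8" is taken in Angstrom: fragment RMSDs of near-ideal
  secondary structure are 0.05–0.1 nm, so 0.8 nm would saturate the switch.
  The function is continued through r = r0 with its analytic limit n/m.
- **Templates from dihedrals**, not shipped coordinates: helix φ = −57°,
  ψ = −47°; strand φ = −139°, ψ = 135°, with one bond-geometry table shared
  by all builders. The antiparallel template is two exactly periodic
  3-residue strands (180° screw repeat) 0.48 nm apart, antiparallel and
  in register; the synthetic hairpin builder uses the same primitive, so the
  builder and the CV agree by construction.
- **Segment pairing**: j ≥ i + 5 (at least a two-residue gap), each unordered
  pair counted once. An 8-mer therefore has exactly one admissible pair.
- Equivalence with the historical reference implementation is *not* claimed;
  the CVs here are self-consistent, rigid-motion invariant (tested to
  1e-10), and bounded by the window count.

A consequence of the m − n = 4 tail of the switching function: compact
disordered structures accumulate a nonzero β_RMSD baseline (hundreds of
pairs at ~2.5 r0 contribute ~0.005 each), so "coil" occupies a band around
β ≈ 1–2.5 rather than the origin — matching the coil basins seen in
molecular free-energy maps. For an ideal 16-mer hairpin the CV is the number
of in-register fragments (three) plus ~9% of off-register tail.

## Metadynamics and the boundary correction

Hills have height 0.1 kJ/mol and σ = 2.0 CV units, deposited once per
ps-equivalent step; the bias is tabulated on a grid from −5 to 42 (2351 nodes
in 1D, spacing 0.02; 471 nodes per dimension by default in 2D, spacing 0.1 —
at σ = 2 the tabulation error is negligible at either spacing, and the
coarser 2D grid keeps the desk-scale demo fast) with kernels truncated at
6σ and multilinear interpolation between nodes.

CV domains are bounded ([0, 32] for both CVs). A plain Gaussian hill near a
wall leaves part of its mass outside the domain; the deposition flux under
uniform sampling then has a deficit at the wall, and the recovered landscape
develops large artifacts near 0. The correction used here divides the kernel
by the in-domain Gaussian mass at the **evaluation point**,

    K(s, c) = h · exp(−(s−c)²/2σ²) / M(s),
    M(s) = ½[erf((hi−s)/√2σ) − erf((lo−s)/√2σ)]   (per dimension),

under which the flux ∫K(s, c) dc over in-domain centers is exactly constant
in s: a flat landscape is a *stable* fixed point of the metadynamics
feedback all the way to the wall. Normalising instead by the mass at the
hill center — a form sometimes quoted — has no nonnegative stationary
deposition density near the wall and, in our flat-potential experiments,
oscillates with >20 kT boundary artifacts; the two forms coincide wherever
the evaluation point equals the center, including all standard spot checks
(a hill on a 1D wall evaluates to twice its height there, 4× in a 2D
corner). M is clamped to its wall value outside the domain, where the bias
is never physically evaluated. Hills whose centers drift marginally outside
the domain are clamped to the edge before deposition.

The half-harmonic upper wall (0 below the threshold, κ/2·Δx² above;
defaults 7.0 nm, 100 kJ/mol) is provided as the standard restraint form for
distance caps.

## Toy sampler and bias exchange

Each replica runs a Gaussian random-walk Metropolis sampler (proposal
σ = 0.5 CV units) on U(s) plus its own bias; proposals outside the domain
are rejected. One deposition step comprises `mc_moves_per_step` Metropolis
moves (default 10), mirroring the many integrator steps per picosecond in
MD: the sampler must decorrelate faster than the bias grows for
metadynamics to stay in its quasi-equilibrium regime, and with one move per
hill the deposition outruns diffusion and the bias roughens by tens of kT.

The four-replica layout biases nothing / α / β / both (1D grids for the
single-CV replicas, a 2D grid for the joint one). Swap attempts occur every
100 steps (neighbor-cycle pairing by default; random pairs available) with
the standard acceptance on bias energies only — the physical potential
cancels for equal-temperature configuration swaps. Hill deposition continues
on each replica's own grids after a swap. One RNG stream per replica plus
one for the exchange schedule makes trajectories bit-reproducible and
independent of replica count. Exchange interval, proposal width, and move
granularity are operational knobs with no counterpart in the published
parameter set; all live in the config.

## Free-energy surface estimation

F(s) = −(1/T)∫₀ᵀ V(s, t) dt + C. Because V is a cumulative sum of hills,
the time average is computed exactly as Σ_k w_k K_k with
w_k = (T − max(t_k, t_start))/(T − t_start) — no time discretisation. The
default averages from the beginning (t_start = 0); convergence is assessed
by traces of −ln(f_class/f_coil) recomputed over truncated histories [0, t]
rather than by a burn-in rule. All hills are treated uniformly regardless of
when grid storage would have been activated in an on-line run.

The FES is reported on a 160 × 160 grid over [0, 32]² (nodes double as
reweighting bins), minimum shifted to zero, in kJ/mol with a kT view at
310 K. Bins outside every hill's 6σ support are flagged unvisited and are
excluded from probability normalisation rather than assigned a ceiling
value — probabilities are renormalised over the visited/populated
intersection, so no weight is fabricated in unexplored regions. All
downstream quantities are invariant to an additive FES constant (tested to
1e-12).

## Reweighting

Frames (CV pair, optional per-residue shifts for CA, CB, HA, HN, N, CO,
optional DSSP string) are binned to the nearest FES node. Per-bin arithmetic
means of observables are combined as Σ_b p_b x̄_b with p_b ∝ exp(−F_b/kT)
renormalised over contributing bins; this equals a brute-force frame-weighted
sum when each frame carries its bin's probability share (tested to 1e-10).
For unbiased/synthetic ensembles, `empirical_probability` (bin counts) gives
the plain average instead.

Secondary shifts are raw minus random-coil reference; amide-proton values are
moved between temperatures as shift + coeff·ΔT/1000 with per-residue ppb/K
coefficients. The error statistic is the mean absolute deviation per residue,
with missing experimental entries dropped pairwise. DSSP letters group as
H/G/I → helix, E/B → strand, T → turn, S → bend, everything else
(including blanks and "~") → coil; per-residue class fractions sum to one
and the peptide-level fraction is their mean over residues. Class free
energies are −ln(f_class/f_coil) in kT; a zero class fraction reports +inf
with a flag rather than an exception. Atom-name dialects (H vs HN, C vs CO)
are normalised at the parsers; both N and CO are supported as first-class
atoms.

## Synthetic data

The generator defines the study conditions rather than adapting to them:

- **Toy potentials** are sums of Gaussian wells on [0, 32]^d. The standard
  1D benchmark is an asymmetric double well (depths 8 kT and 6 kT, σ = 3,
  centers 8 and 24 — an ~8 kT barrier from the deeper minimum); the 2D demo
  landscape has coil (12 kJ/mol deep, near the origin), helix (9 kJ/mol, at
  α ≈ 16) and hairpin (7.5 kJ/mol, at β ≈ 6) basins, echoing the qualitative
  layout of disordered-peptide free-energy maps. `exact_fes` returns the
  ground truth by construction or quadrature.
- **Ideal structures** (helix, hairpin, extended, seeded random coil) are
  built from canonical dihedrals with one bond-geometry table
  (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, standard angles). A φ/ψ-box
  assigner (helix φ ∈ (−100°, −30°), ψ ∈ (−80°, −5°); β φ ∈ (−180°, −90°),
  ψ ∈ (90°, 180°]) labels synthetic fixtures; it is not a hydrogen-bond DSSP.
- **Frame ensembles** mix states with prescribed populations, truncated-
  Gaussian CV clouds, per-residue shift means (random-coil table plus
  canonical helix/strand secondary-shift offsets, e.g. +2.6 ppm on helical
  Cα) with additive Gaussian noise (0.3 ppm default), and fixed DSSP
  strings. The bundled random-coil table holds typical literature magnitudes
  per residue type; it is a synthetic stand-in adequate for exercising the
  subtraction and recovery machinery, not a predictor's calibrated set.
  Missing shifts (Gly CB, Pro HN/N) are NaN and excluded pairwise.
- The demo "experimental" table is the population-weighted ground truth with
  0.05 ppm noise, amide protons stored at 278 K with a −7 ppb/K coefficient
  so the temperature correction is exercised end to end.

What the synthetic ensembles do **not** emulate: correlated frame-to-frame
dynamics, conformer-dependent shift predictions within a state, sequence-
dependent coil baselines beyond the residue-type table, and any real
force-field physics. Passing tests therefore validate the estimators and
bookkeeping — not the accuracy of any molecular model.

## Problem sizes and numerical choices

The validation experiments use 1e5 deposition steps (10 moves each) for
free-energy recovery and boundary flatness, 1e6 Metropolis steps for the
frozen-bias equilibrium check (32-bin histogram), 1e5 steps for crossing
enhancement, 1e4–1e5 frames for reweighting checks, and a 3000-step demo for
determinism — sizes at which each statistic's sampling noise sits well below
its acceptance band while the whole suite runs in minutes on one CPU.
Ties and degenerate inputs: frames bin to the nearest node with round-half-
even at midpoints; collinear fragments superpose without error (the RMSD is
well defined even when the rotation is not unique); x ≫ r0 switching values
use the asymptotic power law to avoid overflow; an empty hill list, inverted
time window, all-unvisited FES, zero coil fraction denominator, and
mismatched shift-vector lengths all raise immediately with named context.

## Known limitations

- The toy sampler has no inertia or solvent; kinetic quantities (crossing
  counts) are meaningful only as ratios between matched runs.
- The time-averaged-bias estimator is the only FES estimator provided (no
  well-tempered variant, no reweighting-based estimators, no error bars).
- CV gradients with respect to coordinates are not implemented (biasing acts
  in CV space); the parallel-β variant and per-residue CV decompositions are
  out of scope.
- The β_RMSD baseline for compact coils (switching-tail effect) means
  absolute β values near 1–2 should not be read as "one hairpin" without
  inspecting structures.
- With the default demo length (20 k steps) class free energies carry
  several tenths of kT of run-to-run spread, and rarer classes can be off by
  more than 1 kT; the convergence trace is the intended diagnostic, as in
  the cluster-scale workflow this mirrors. The validation benchmarks use
  longer 1D runs where the estimator is accurate to a fraction of kT.
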