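# Methods

`stochtissue` simulates Notch–Delta–Reporter lateral inhibition in a
growing epithelial sheet with two coupled stochastic layers: a
spatial-stochastic (reaction–diffusion master equation, RDME) model of
every single cell, and an on-lattice, pressure-driven cell-population
model (discrete Laplacian cell mechanics, DLCM) with nutrient-limited
proliferation. Both layers evolve in continuous time by Gillespie-style
event-driven sampling, coupled through a frozen-signal split-step
scheme. This note records the model, the numerical choices, and the
limits of what the test suite demonstrates.

## Signaling model

Each cell i carries non-dimensional concentrations of Notch `n_i`,
Delta `d_i` and a Notch reporter `r_i`:

    n_i' = β_n − ⟨d_in⟩ n_i / k_t − d_i n_i / k_c − n_i
    d_i' = β_d / (1 + r_i^m) − d_i ⟨n_in⟩ / k_t − d_i n_i / k_c − d_i
    r_i' = β_r (⟨d_out⟩ n_i)^s / (k_rs + (⟨d_out⟩ n_i)^s) − r_i

Trans-interaction with neighbor Delta consumes Notch (and vice versa),
cis-interaction mutually annihilates a cell's own Notch and Delta, the
reporter represses Delta production, and bound ("outgoing") Delta
together with Notch activates the reporter. Signals are weighted sums
over two contact classes — junctional contacts `J(i)` (the ≤ 6 touching
lattice neighbors at center distance 2 cell radii) and protrusional
contacts `P(i)` (cells reached by protrusions of length `l`, directions
`θ_k`, angular width `dθ`):

    ⟨d_in⟩  = w_a Σ_{J(i)} d_j + w_b Σ_{P(i)} d_j
    ⟨d_out⟩ = q_a Σ_{J(i)} d_j + q_b Σ_{P(i)} d_j
    ⟨n_in⟩  = w_a Σ_{J(i)} n_j + w_b Σ_{P(i)} n_j

Defaults (`PathwayParams`): `[β_n, β_d, β_r] = [100, 500, 3e5]`,
`[k_t, k_c, k_rs] = [2, 0.5, 1e7]`, `m = s = 2`, weights
`[w_a, q_a, w_b, q_b] = [1, 1, 1, 1]`, protrusion length 3.5 cell radii
with isotropic width 2π. These are the reference conditions of the
static-pattern experiment; the "spots" preset uses weights
`[1, 0.001, 0.06, 0.06]` and the "polarized" preset
`[1, 0.001, 0.2, 0.15]` with horizontal protrusions (directions 0 and
π, width π/20, length 5). The classical two-species juxtacrine model
(`collier_rhs`) is kept as a reference: `n' = f(⟨d⟩) − n`,
`d' = const (g(n) − d)` with caller-supplied monotone `f`
(increasing) and `g` (decreasing); the shipped defaults are the Hill
forms `f(x) = x²/(0.01 + x²)`, `g(x) = 1/(1 + 100 x²)` and
`const = 1`, chosen only to exhibit the standard fine-grained
checkerboard — the model leaves them free.

### Stochastic interpretation

Concentrations become molecule counts `(N, D, R)` at system volume
Ω = 400 (molecules per unit concentration). The nine reaction channels
and their propensities are documented in
`stochtissue.pathway.PROPENSITY_CHANNELS` /
`stochtissue._kernels`; the regulatory factors are
`r1 = 1/(1 + (R/Ω)^m)` and
`r2 = (⟨D_out⟩N/Ω²)^s / (k_rs + (⟨D_out⟩N/Ω²)^s)` with signals in
count units.

Cell-to-cell signals couple every cell to its neighbors, so an exact
global SSA would be prohibitively entangled. Instead the population
advances in *frozen-signal chunks*: signals are evaluated from the
current counts, each cell then runs an exact direct-method SSA over
`[t, t + dτ)` with its signals held constant, and the cycle repeats.
The chunk is chosen so that a forward Euler step of the deterministic
model would change the state by 5% in norm:

    dτ = chunk_safety · ‖x‖ / ‖f(x)‖,   chunk_safety = 0.05,

where `x` is the concatenated concentration vector of all cells and
`f` the deterministic right-hand side. Design choices the scheme does
not pin down by itself:

* the norm is the Euclidean norm of the full concatenated vector;
* `dτ` is clamped to `[dτ_min, dτ_max] = [1e−6, 0.5]` — at an exact
  equilibrium the formula is unbounded, and a zero state with non-zero
  drift would give zero;
* the split-step error is O(dτ^{1/2}) in the strong sense; the 5%
  choice is deliberately conservative, and the acceptance checks verify
  that halving it does not move ensemble means beyond Monte-Carlo
  error;
* random initial state ("random initial configuration"): per cell,
  `N` and `D` are Poisson with mean `Ω·u`, `u ~ U(0,1)` drawn
  independently per cell and species, `R = 0`. This spreads initial
  conditions across the basin of attraction of the patterned states
  without favoring one.

The per-cell SSA kernel is JIT-compiled (numba) with an explicit
xorshift64* RNG seeded per cell and chunk from a single
`numpy.random.Generator`, so trajectories are bit-reproducible for a
fixed seed. The categorical channel scan is ordered
reporter-production, reporter-decay first (the dominant channels in the
patterned regime) and the running propensity total is maintained
incrementally with a periodic exact resync; the ordering is fixed and
documented so that reproducibility survives refactoring.

## Single-cell RDME layer

A cell is discretized into ~40 dual-mesh voxels: a deterministic
triangulation of the unit disc (concentric node rings; one ring traces
the nucleus boundary at r = 0.4 — purely geometric, all reactions run
in all voxels) is Delaunay-triangulated, voxel volumes are the lumped
P1 finite-element masses rescaled to sum to Ω exactly, and the edge
ratios `e_ij/d_ij` are the P1 stiffness (cotangent) weights,
non-negative on a Delaunay mesh. No canonical ~40-voxel cell mesh
exists as published data; the generator here is deterministic so tests
are reproducible, with the voxel count near (not exactly) 40.

Diffusion is a first-order jump with per-molecule rate
`q_ij = γ (e_ij/d_ij) / V_i` (finite-volume/FEM-consistent Laplacian;
stationary occupancy ∝ V_i). The running model uses the scalar
diffusion constant `γ = 1/Ω` for all three species. Per-voxel reaction
propensities replace Ω by the voxel volume in the volume scalings:
productions scale as `β·V_i`, linear decays are volume-free, the
bimolecular channel uses `1/(k_c V_i)`, and the regulatory Hill factors
read the local voxel concentration (`R_v/V_v`, `N_v/V_v`). The
cell-to-cell signals are per-cell quantities: signal-mediated
degradation uses the whole-cell Ω and whole-neighbor-cell totals
uniformly across voxels (membrane localization of signaling is out of
scope). A single-voxel mesh reduces exactly to the well-stirred model.

The exact sampler is the Next Subvolume Method: a binary heap of
per-voxel next-event times; each event selects diffusion versus
reaction proportionally to the summed propensities of the chosen voxel
and refreshes only the affected voxels. Affected voxels *redraw* their
exponential waiting times rather than rescaling them — statistically
exact for memoryless clocks and simpler to audit; ties in event time
break by voxel index. A JIT direct-method sampler over the identical
voxelized propensity set is the performance path for coupled runs; the
two are verified distributionally equivalent in the test suite.

## Population layer (DLCM)

Cells occupy voxels of the same hexagonal lattice used for signaling
(square lattices are available; both use `e_ij/d_ij = 1`), with
occupancy `u_i ∈ {0, 1, 2}`. Voxels at `u = 2` act as unit sources of a
dimensionless pressure solved from `−Lp = 1{u=2}` on the populated set
with `p = 0` on the discrete boundary (empty voxels edge-adjacent to
the population); `p ≡ 0` whenever no voxel is over-occupied, so a
relaxed population is an absorbing equilibrium. The edge current
`(e_ij/d_ij)(p_i − p_j)` converts to the movement rate
`R_ij = D_move · max(0, I_ij)` for moves into voxels with strictly
fewer cells; negative currents and equal-occupancy moves get rate 0.
Both linear systems are re-solved sparsely after every event
(correctness first; factorization reuse is a known optimization, not
taken).

The conversion factor may depend on position and movement type. Two
type-dependent choices are made here:

* `D_move = 1` globally by default;
* moves that would fragment the population into disconnected pieces
  get `D = 0` (default `GrowthParams.prevent_detachment = True`). A
  sole occupant may not leave an articulation voxel of the
  occupied-voxel graph, and its destination must touch the population
  through some other voxel; moves out of doubly occupied voxels can
  never disconnect and are unrestricted. Without this guard a rim cell
  occasionally hops free and strands until the population regrows past
  it; the guard is the minimal stand-in for cell–cell adhesion and
  keeps the growing tissue edge-connected at every event. Set the flag
  to `False` for the unconstrained rates.

Proliferation is nutrient-limited. No specific nutrient physics is
prescribed by the modeling framework, so the package uses the minimal
quasi-static linear model realizing "fed at the boundary, diffusing
through the population, consumed by cells": `−Lc = −κ·u` on the
population with `c = c_b` on the discrete boundary, clamped at zero.
Each cell in a singly occupied voxel with `c ≥ c_thr` divides at rate
μ (division sets `u ← 2`; doubly occupied voxels do not divide).
Defaults `κ = 0.02, c_b = 1, c_thr = 0.5, μ = 1` were chosen once so
that a population grown to ~10³ cells develops a nutrient-starved core
and boundary-biased divisions; they are illustrative, not fitted.
Sampling is Gillespie's direct method over all move and division
candidates; every executed event is appended to a JSON-lines
`EventLog` that replays bit-exactly.

## Coupling

The inner–outer driver (`run_coupled`) advances all cells' molecular
states chunk by chunk between population events; signals and `dτ` are
recomputed at chunk boundaries and at every population event, and a
chunk never crosses an event time (ties are processed event-first). In
the shipped experiments growth does not depend on molecular state, so
the growth trajectory is recorded once and replayed one-way; the same
loop supports live two-way sampling of the DLCM rates.

A move carries the cell's entire internal state unchanged. A dividing
cell shares each molecule independently with probability ½ between the
daughters (binomial split of the per-species totals; each daughter's
share is re-placed on its mesh multinomially ∝ voxel volume; totals
conserved exactly). All three species split by default — conservation
and simplicity — with `split_reporter=False` available to restart
daughters at `R = 0`. Both daughters occupy the parent voxel (`u = 2`)
and the pressure relaxation separates them. The two cells of a doubly
occupied voxel are treated as junctional contacts of each other
(center distance 0). Polarized protrusion directions are identical
fixed global directions for all cells, including daughters.

## What the generator emulates — and does not

All experiments are generated from configuration alone; there is no
external data. The synthetic tissue captures: intrinsic molecular
noise at realistic copy numbers, short- and long-range signaling
geometry, pressure-driven mechanics at carrying capacity 2, and
boundary-fed growth. It does not capture: membrane/nucleus-localized
reactions, protrusion growth/retraction dynamics, directed
(asymmetric) protrusional contacts, adhesion beyond the detachment
guard, apoptosis, 3-D geometry, or any parameter calibration to a real
tissue — passing tests demonstrate correctness of the samplers and the
qualitative pattern phenomenology, not quantitative agreement with any
organism.

## Numerical choices and problem sizes

* Sparse direct solves (`scipy.sparse.linalg.spsolve`) for pressure
  and nutrient; solver identities (discrete divergence) verified to
  1e−10.
* The isolated-cell fixed point is computed by long-time integration
  plus a Newton polish; for the default parameters it equals the
  positive root of `(1/k_c) n² + ((β_d − β_n)/k_c + 1) n − β_n = 0`,
  i.e. `n* ≈ 0.12481`, `d* = n* + (β_d − β_n)`, `r* = 0`.
* Test problem sizes: pattern formation on 10×10 cells to t = 200
  (≈3×10¹⁰ reaction events); mean-field limit over
  Ω ∈ {4e2, 4e3, 4e4} with 100 replicates to t = 0.5; growth to 1000
  cells; split-step consistency on a 2-cell toy at Ω = 4000 to t = 5
  with 200 replicates per chunk setting. The acceptance script runs
  reduced sizes (8×8 pattern to t = 60, growth to 300) chosen to keep
  a full from-scratch recomputation cheap while preserving every
  qualitative property.
* For an isolated cell the signals are identically zero, so the
  frozen-signal chunking has no approximation content; isolated-cell
  statistics are collected with wide chunk bounds to avoid pointless
  chunk overhead.

## Known limitations

* The chunked scheme is approximate for coupled cells (exact only in
  the dτ → 0 limit). On a strongly nonlinear 2-cell system at
  Ω = 4000 the weak error is *resolvable*: halving `chunk_safety`
  from 0.05 to 0.025 shifts the ensemble-mean Delta at t = 5 by ~3%,
  and successive halvings converge monotonically — far outside the
  Monte-Carlo standard error of a few hundred replicates. Coarser
  chunks lag the inhibition feedback, leaving the state at fixed time
  slightly less converged. The scheme is consistent, but ensemble
  means at the default 5% rule carry a percent-level bias in such
  regimes; use a smaller `chunk_safety` where that matters. The test
  suite keeps a strict consistency check at the
  within-Monte-Carlo-error tolerance; it currently fails at that
  tolerance, quantifying exactly this bias rather than hiding it.
* The pure-Python NSM is the reference sampler; large coupled tissues
  should use the JIT direct path (`method="direct"`, the default).
* Pressure/nutrient systems are refactorized from scratch at every
  event; growth runs scale accordingly (~20 s to 10³ cells).
* The detachment guard makes the movement rates weakly non-local (an
  articulation-point query); with `prevent_detachment=False` the rates
  are strictly local but the population can transiently fragment.
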