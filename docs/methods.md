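# Methods

## Model

`dlcm` simulates a population of biological cells distributed over a
tessellation of 2D or 3D space into voxels, each holding at most two
cells (the carrying capacity used throughout). The population evolves as
a continuous-time Markov chain whose movement rates are derived from a
coarse-grained mechanical picture:

1. **Equilibrium assumption.** A tissue in which every cell sits in its
   own voxel is in mechanical equilibrium; only voxels holding two cells
   exert a "cellular pressure", modelled as a unit point source (the
   pressure scale is free, so unit sources lose no generality).
2. **Quasi-steady pressure.** Pressure relaxes much faster than any
   other process, so at every instant it solves the discrete Poisson
   problem

       -L p = s(u)  on the populated voxels,   p = 0 on the free boundary,

   where `s(u_i) = 1` iff `u_i = 2`, `L` is the edge-weighted discrete
   Laplacian (weights `w_ij = e_ij/d_ij`, shared-interface measure over
   centre distance), and the free boundary is the set of *empty* voxels
   edge-adjacent to the populated region. Voxels holding a dead cell
   occupy space but are not sources.
3. **Currents to rates.** The current over an edge is the integrated
   pressure gradient, `I_ij = w_ij (p_i - p_j)`. A positive current
   converts into the stochastic rate of the discrete event "one cell
   moves from voxel i to j" through three conversion factors: `D1` for
   moves into never-visited empty voxels (fresh extracellular matrix),
   `D2` for previously visited empty voxels, and `D3` for crowding moves
   (a cell from a doubly occupied voxel entering a singly occupied one).
   A voxel at capacity, or holding a dead cell, is never a destination.

Summing the restricted equations shows the total current over the free
boundary equals the number of sources exactly (a discrete divergence
theorem). Hence `D2/D3` measures the preference for boundary expansion
over internal rearrangement; with a single interior source and
`D2 = D3`, the source's cells carry exactly as much total rate as flows
into the boundary. This identity holds to solver tolerance for arbitrary
occupancy configurations and is the package's primary acceptance check.

Events are sampled with the Gillespie direct method (exponential waiting
time at the total rate, proportional selection), so trajectories are
exact realizations of the Markov chain, in continuous time. Between
events, intracellular processes (ODEs per cell) are integrated
deterministically; the mechanics never reads the internal states, so
this one-way coupling introduces no splitting error.

## Discretization choices

* **Laplacian weights.** The two-point-flux / P1-FEM-with-lumped-mass
  form `w_ij = e_ij/d_ij` is the simplest consistent choice and reduces
  to the 5-point (2D) / 7-point (3D) stencil on uniform Cartesian grids.
  All weights are positive, which guarantees a discrete maximum
  principle (pressure is nonnegative and maximal at a source; oxygen
  never increases when a consumer is added).
* **Dirichlet imposition.** The linear system is restricted to the
  populated rows/columns; zero boundary data contribute nothing to the
  right-hand side, and the field is exactly zero outside. This is the
  smallest well-posed system. If the population covers the whole grid
  the problem is singular and the solver raises an explicit error rather
  than returning garbage.
* **Re-solve per event.** Rates are recomputed from a fresh solve after
  every applied event. The sparse LU factorization is reused whenever
  the populated set is unchanged (crowding moves, proliferation, death),
  and rebuilt otherwise; the oxygen operator lives on the fixed full
  grid and is factorized exactly once per run. Incremental factorization
  updates and multigrid solvers are deliberate non-goals at the problem
  sizes used here.
* **Hexagonal lattice.** Pointy-top regular hexagons with centre spacing
  `h`: `e = h/sqrt(3)`, `d = h`, voxel area `sqrt(3)/2 h^2`. The lattice
  is generated as a full `nx x ny` offset array (no partial boundary
  cells arise). Orientation is a fixed convention; nothing downstream
  depends on it.
* **Voronoi grids.** Cells are the GEOS Voronoi polygons of the seed
  points clipped to the bounding box; neighbour candidates come from the
  Delaunay triangulation and are kept only if the clipped cells share an
  edge of positive length — cells meeting at a single point (e.g.
  cocircular configurations) are not neighbours. `e_ij` is the shared
  edge length, `d_ij` the seed-point distance. Tests cross-check the
  edge lengths against an exact independent bisector-interval
  computation.
* **Chemotactic drift** (Slit experiment). The drift-modified pressure
  problem `-lap p = div(p chi1 grad S) + s(u)` is discretized with the
  edge flux `w_ij [(p_i - p_j) + chi1 pbar_ij (S_i - S_j)]`, with
  `pbar_ij` the arithmetic (central, second-order) edge average; this
  yields a nonsymmetric linear system solved directly. Upwinding the
  edge average would be the robust alternative at drift strengths
  approaching the mesh Péclet limit; at the magnitudes used here
  (`chi1 |grad S| h / 2 < 1` everywhere cells reach) the central average
  is adequate, and a singular system raises a descriptive error.
  The *movement* current on an edge is the same full flux plus the
  active, pressure-independent term `chi2 w_ij (S_i - S_j)`, added
  before D1/D2/D3 classification. Including the `chi1` part of the flux
  in the movement current (rather than only `(p_i - p_j)`) keeps the
  boundary-current/source balance exact for the drift problem; this is
  an implementation choice where the source material fixes none.
* **Adhesion.** The correction for a move `i -> j` is
  `d_ij * sum_k alpha e_ik min(0, r_ij . r_ik)` over populated
  neighbours `k` — always nonpositive, so adhesion resists moves; the
  converted rate is floored at zero (a resistance can stop a move, never
  reverse it).
* **Ties and degeneracies.** Zero-rate events are never stored. A
  concentration exactly at an oxygen threshold generates no event
  (strict inequalities). Events are enumerated in a fixed deterministic
  order (edge-array order, then model events), so a seeded run is
  bit-reproducible.

## Experiments and their default conditions

Parameters printed by the source model descriptions are used verbatim;
quantities the descriptions leave open were fixed once, as follows, and
are stated with the rationale.

* **Relaxation**: a 20×20 block of doubly occupied voxels centred on a
  61×61 grid, `D1 = D2 = D3 = 1`, 100 trials, run to absorption (no
  doubly occupied voxel left — guaranteed, since the source count is
  non-increasing and every source has positive escape rate). The tests
  use a scaled replicate (8×8 block, 25 trials per grid type) and assert
  the trial-averaged density's anisotropy — max/min eigenvalue ratio of
  the second-moment tensor minus one — stays below 0.10 on both the
  Cartesian and the hexagonal grid, with the per-trial anisotropy
  distributions indistinguishable between grids (Welch test, p > 0.01).
* **Slit**: explant radius 10 (doubly occupied) at the centre of a
  101×101 grid with `h = 1`; `[chi1, chi2, D_S, k, Q, X_s] =
  [100, 5, 50, 0.1, 2, 50]`; horizon `T = 1000`; 100 trials. The Slit
  profile is the closed-form steady solution of its line-source
  reaction–diffusion balance, so no PDE solve is needed for `S`. Tests
  run radius 5, `T = 200`, 10 trials and require leftward centroid
  displacement in every replicate.
* **Delta–Notch**: hexagonal 40×40 grid; initial singly occupied disc of
  radius 3 whose voxels define the fixed proliferative region; unit
  proliferation rate per eligible (singly occupied) cell;
  termination at 1000 cells; `[a, b, v, k, h] = [0.01, 100, 1, 2, 2]`;
  right-hand-side speed factor 1 or 50. Radius 3 makes the population
  reach 1000 cells at t ≈ 95, consistent with the reference snapshot
  schedule (t = 5, 40, 70, 100) at unit rate. Initial `(n, d)` are drawn
  uniformly from (0, 1) per cell (the stochastic growth already breaks
  symmetry; the ODEs themselves are deterministic). The
  trans-activation input of a cell averages Delta over *cells* (every
  cell in an edge-adjacent voxel plus the co-occupant of a doubly
  occupied voxel), each counted once; a voxel-mean-first alternative
  would weight co-occupants differently but changes nothing
  qualitatively. Daughters inherit the mother's `(n, d)`.
* **Tumour**: 5×5 singly occupied seed at the centre; `D1 = 0.01`,
  `D2 = 25`, `D3 = 0.01`, `lam = 0.0015`, `kappa_prol = 0.65`,
  `rho_prol = 0.125`, `kappa_death = 0.55`, `rho_death = 0.125`,
  `rho_deg = 0.01`. Death is generated only for singly occupied voxels
  (the state space has no mixed live/dead voxel), so a hypoxic cell in a
  doubly occupied voxel must first lose its neighbour by movement.
  Domain and horizon are the package's choice: the outer boundary holds
  oxygen at 1, so the domain must be large enough for the interior to
  become hypoxic. Solving the steady oxygen problem under a doubly
  occupied disc shows `min c` crosses the survival threshold 0.55 at
  colony radius ≈ 13.5 on an 81×81 grid (≈ 1150 cells, reached near
  t ≈ 400 at the `D1`-limited expansion rate ≈ 0.01), but only at radius
  ≈ 16 on 61×61. The defaults are therefore 81×81 with `T = 500`, which
  reliably exhibits the three phases — near-exponential growth,
  quiescence, necrosis — within the horizon.

## What the synthetic initial conditions do and do not show

All inputs are generated (block, disc and seed occupancies on ideal
lattices); there is no measured data anywhere. Passing tests therefore
demonstrate the *internal* correctness of the mechanics (conservation
identities, maximum principles, solver agreement with dense oracles,
exact hand-solved systems) and the qualitative phenomenology the
framework is designed to reproduce (isotropic relaxation, chemorepulsion,
lateral-inhibition patterning, layered tumour structure). They say
nothing about quantitative agreement with any real tissue: the rate
constants are dimensionless per unit current, no absolute time or length
scale is fixed, and biological features such as cell shape, compressible
matrix, or mechanosensitive signalling are outside the model class.

## Numerical parameters

| quantity | default | notes |
| --- | --- | --- |
| carrying capacity | 2 cells/voxel | fixed by the state space `u in {-1,0,1,2}` |
| pressure/oxygen solver | sparse LU (SuperLU) | factorization cached on the populated-set key |
| ODE integrator | RK45, rtol 1e-6, atol 1e-9 | per inter-event interval; failures raise with cell count and time |
| solver-identity tolerance | 1e-10 | divergence-identity checks |
| dense-oracle tolerance | 1e-12 relative | grids ≤ 100 voxels |
| Voronoi edge tolerance | 1e-12 × box size | minimum positive shared-edge length |

## Known limitations

* The time-dependent pressure equation is not implemented — only its
  quasi-steady limit; likewise Robin ("semi-free") boundaries. Neumann
  walls appear implicitly at the lattice edge (missing neighbours mean
  zero flux), but populated regions touching the domain edge are not a
  tested regime.
* The pressure system is re-factorized whenever the populated set
  changes; for colonies beyond ~10^4 voxels an incremental or multigrid
  solver would be needed.
* No 3D hexagonal or 3D Voronoi tessellations.
* The tumour model reproduces the layered structure but not a stable
  finite tumour — protrusion growth eventually resumes, consistent with
  the absence of stabilizing mechanisms (growth inhibitors, necrotic
  chemoattraction) from the model class.
* Dead cells block movement and never move; visited flags never decay.
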