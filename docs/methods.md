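# Methods

`colonyrot` has two halves that meet at the phenomenon of coherent
angular motion (CAM) in freely expanding epithelial cell colonies: a
continuum active-nematic simulator of a rotating tissue droplet, and
an analysis pipeline for tracked-cell trajectories and colony-growth
curves, fed by seeded synthetic-data generators that emulate the
time-lapse experiments.

## Continuum model

The tissue is described by three coupled fields on a periodic 2D
lattice: the cell concentration `phi` (1 = tissue, 0 = free surface),
the nematic order tensor `Q = S(nn - I/2)` and the incompressible
velocity `u` of the suspension.

* **Q dynamics** (rotational diffusivity `gamma`): relaxation toward
  the free-energy minimum through the molecular field
  `H = -dF/dQ`, advection, and the generalized advection term
  `W(Q, E, Omega)` with flow-aligning parameter `lambda`.
* **Momentum balance** at density `rho`: driven by the divergence of
  the passive elastic stress (Ericksen plus the `lambda`- and
  antisymmetric `QH - HQ` terms) and the active stress.
* **Concentration**: advected Cahn–Hilliard dynamics with mobility
  `Gamma_phi` and chemical potential `mu = dF/dphi`.

The free energy is

    f = (C/2)(1 + Tr(Q.Q)/2)^2 + (B/2) phi^2 (1 - phi)^2
        + K_phi |grad phi|^2 + (K/2)|grad Q|^2 .

With `C > 0` the isotropic state is the bulk minimum, so nematic
order can only be generated by activity; the double well pins `phi`
to 0/1 and `K_phi` sets the interface tension and width
(`~ sqrt(K_phi/B)` lattice units).

**Sign and form conventions.** Three algebraic choices were genuinely
open and are fixed as follows, each with the alternative exposed in
config where meaningful:

1. The bulk nematic term is implemented with the stabilising sign
   (`+C/2(...)^2`); the destabilising sign is available via
   `FreeEnergyParams(stabilizing_bulk=False)` for sensitivity checks.
2. The trace correction of the generalized advection uses the
   standard 2D form `-2 lambda (Q + I/2) Tr(Q.E)`, and the stored
   `(xx, xy)` representation plus an explicit trace projection keep
   `Q` exactly traceless and symmetric at every step.  The conjugate
   elastic-stress term is `2 lambda (Q + I/2) Tr(Q.H)`.
3. The antisymmetric vorticity tensor is paired with `Q` so that a
   uniform director co-rotates at the local rotation rate of a rigid
   flow; this is verified against the closed-form rotating solution.

**Active stress.** The dipolar force density is exerted by the
cells, so the default active stress is concentration-weighted,
`Pi_a = zeta * phi * Q` with `zeta < 0` (extensile).  This localises
activity to the colony and is what makes colony size control the
onset of rotation: the total active drive grows with droplet area
while the elastic/rotational damping does not, so small droplets stay
isotropic and quiescent.  The unweighted form `Pi_a = zeta * Q`
(`ModelParams(active_coupling="uniform")`) lets activity act wherever
order exists; in practice it seeds order in the cell-free background,
drives bulk active turbulence and shreds the droplet within ~10^4
steps — useful as a control, not as a colony model.

## Numerics

* **Hybrid scheme.** D2Q9 lattice Boltzmann (BGK) for the flow with
  Guo forcing from the divergence of the deviatoric elastic + active
  stress; pressure and viscous stress come from the LB equation of
  state and collision operator and are not duplicated in the forcing.
  Q and phi advance by explicit central-difference Euler steps.
* **Substeps.** At the default parameters the Cahn–Hilliard
  biharmonic term is linearly unstable at `dt = 1` on the 5-point
  stencil (amplification `|1 - 64 * Gamma_phi * 2 K_phi| = 1.56` at
  the grid-scale mode), so the finite-difference fields take
  `n_substeps = 2` substeps of `dt = 1/2` per LB step.
* **Viscosity.** No viscosity value is part of the physical parameter
  set; the BGK relaxation time is a numerical choice.  The default
  `tau_lb = 0.6` (`eta = rho c_s^2 (tau_lb - 1/2) = 4/3`) keeps the
  active drive `~ lambda |zeta| / 2 eta` well above the passive
  damping `gamma C`, so order and rotation develop within desk-scale
  runs; at `tau_lb = 1` the margin is so thin that onset takes far
  longer than 2x10^4 steps at test-scale droplet sizes.  Results are
  reported as robust trends (onset, sign statistics, size dependence),
  not as `eta`-sensitive numbers.
* **Discrete gradient-flow consistency.** The gradient terms of the
  free-energy *density* are discretised with forward differences —
  the discretisation whose exact functional derivative is the compact
  5-point Laplacian used in `H` and `mu`.  Relaxational dynamics then
  decreases the discrete energy monotonically, and the
  perturbation-oracle tests match to machine precision plus O(eps^2).
* **Guards.** A Mach guard (|u| > 0.2), Q/phi blow-up bounds and
  non-finite checks abort a run with the step index; all are
  exercised in tests.
* **Backends.** Every operation exists as a composable NumPy function
  (the reference path); a fused numba kernel reproduces the reference
  path bitwise (asserted in tests) and is ~20x faster, making the
  property suite tractable on one CPU.

## Simulated study conditions (desk scale)

The physical parameter set is the lattice-unit set of the study:
`rho = 40`, `Gamma_phi = 0.2`, `gamma = 0.3`, `|zeta| = 0.01`,
`lambda = 0.7`, `K = 0.02`, `K_phi = 0.1`, `B = 0.01`, `C = 0.001`,
box 300x300.  The test suite runs a reduced configuration chosen once
so the whole property suite fits on a single CPU:

* rotation onset, persistence and conservation checks: 128x128 box,
  radius 20, 2x10^4 steps, fixed seeds;
* size dependence: radii {12, 20, 48} on 128x128 and 64 on 160x160
  (the margin rule — radius + 5 interface widths within half the
  box — forces the bigger box), two seeds per rotating radius;
* sign-symmetry sweep: 20 seeds on a 96x96 box at radius 20 with an
  adaptive early stop once |omega| exceeds 2x10^-5 for two
  consecutive 2000-step samples.  The droplet dynamics at this margin
  are box-size insensitive; the smaller sweep box only reduces cost.

Observed behaviour at these conditions: no rotation for radius 12
(order never saturates), sustained single-sign rotation with plateau
`|omega| ~ 1e-4` lattice rad/step for radius 20, weaker and less
coherent rotation at 48, and sign-incoherent turbulent-like motion at
64.  Both rotation signs occur across seeds with proportions
consistent with 1/2 (13/20 positive in the frozen sweep).

## Trajectory kinematics

Tracked positions (track id, cluster id, t in hours, x/y in um) are
decomposed per 2 h interval into the radial velocity `V_rho` (um/min)
and angular velocity `omega` (rad/h) about the per-frame cluster
centroid (arithmetic mean of tracked cells; a traced-contour centroid
can be supplied instead).  Angular steps are wrapped to (-pi, pi], so
the detectable |omega| is bounded by pi/interval (Nyquist property,
tested at the boundary); cells within 2 um of the centroid have
undefined angular velocity and are excluded from omega (kept for
V_rho).  Clusters are split into inner/outer regions by the radius at
the first analysed frame; region labels are fixed thereafter.
Cluster-level omega is the unweighted time average of the per-interval
population mean.  Image-convention input (y axis down) is flipped on
load with a flag so counterclockwise is positive.

## Growth analysis

* **Duplication time**: pooled through-origin regression of
  `log2(N/N0)` on elapsed time, `N0` pinned per cluster to its first
  observation, so `t_d` is the only adjustable parameter; the
  standard error of `t_d` follows from the slope error by the delta
  method.
* **Density profile**: `A_cell = A_cluster / N_cells` versus cluster
  area with a change-point summary at 2x10^4 um^2 (free-expansion
  threshold).
* **Critical area**: `A_c = 4 pi tau^2 v_rho^2`, hours and um/h
  internally, with an exact um/min -> um/h conversion layer.
* **Master curve**: the reference series is the one whose initial
  confluence is closest to the median; every other series is shifted
  in time by the offset minimising the summed squared difference of
  `log2 A_s` over the overlap (coarse grid scan, then golden-section
  refinement — the alignment procedure itself was an open design
  point; the noiseless closed form `shift = tau log2(A_s0 ratio)` is
  the anchor test).  Saturated frames (`A_s` at the cap) are excluded
  before fitting `A_s = A_s0 2^(t/tau)` with `tau` the only free
  parameter.

## Synthetic-data generators

The generators stand in for the time-lapse microscopy tables and
return `(data, ground truth)` deterministically per seed:

* **Coherent cluster**: cells uniform in an ellipse (defaults: 52
  cells, 84 um mean radius, aspect ratio 0.83), recentred so the
  sample mean is exactly the rotation centre, rotated rigidly at
  `omega0` (default magnitude 0.05 rad/h — an angular step of ~5.7
  degrees per 2 h frame, far inside the unwrapping bound) and
  expanded homothetically so the population-mean radial speed is
  exactly `v_rho` (default 0.04 um/min).  With zero noise the
  kinematics round trip is exact by construction.  An optional quota
  places an exact number of cells inside a given split radius, with a
  guard band so recentring cannot move cells across it.
* **Incoherent control**: per-cell independent zero-mean random walks
  in the cell's own polar coordinates, increment scales matched to
  the coherent generator's per-frame displacements.
* **Growth/confluence**: exponential laws with lognormal
  multiplicative noise; confluence capped at 1.
* **Noise model**: isotropic Gaussian positional error, default 1 um,
  standing in for manual-tracking jitter.  This is an assumption —
  the real error model of manual tracking is unknown.

What the generators do *not* emulate: cell division and death within
tracks, cluster merging, cell-shape information, spatially correlated
tracking errors, and the radial dependence of angular speed inside
real clusters (rigid rotation is exact in the coherent generator).
Passing tests therefore validate the *pipeline* — that the estimators
recover known ground truth under realistic sampling and noise — not
any claim about real tissue.

## Known limitations

* The simulator has no proliferation source term: colonies are
  initialised at fixed sizes, matching the simulation protocol
  (rotation versus size is scanned by initial radius, not by growth).
* Polar (vectorial) forces are out of scope by design, so interface
  polarity patterns cannot appear.
* Explicit Euler plus central advection limits the tolerable flow
  speeds; the Mach and blow-up guards make violations loud rather
  than silent.
* Plateau angular velocities at desk scale have large seed-to-seed
  variance; the size-dependence test compares seed-averaged plateaus
  at frozen seeds rather than asserting a universal curve.
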