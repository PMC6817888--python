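# Methods

## The model

`dpdshear` simulates a coarse-grained double-tailed phospholipid in explicit
water with dissipative particle dynamics (DPD).  A lipid is eleven soft
beads: a linear chain of `n_head = 3` hydrophilic head beads (H) carrying two
linear tails of `n_tail = 4` hydrophobic beads (T) each, both tails bonded to
the last head bead.  Water is a single bead species (W).  All quantities are
reduced: lengths in the cutoff r_c, energies in kBT, masses in the bead mass
m, time in tau = r_c sqrt(m/kBT).

Nonbonded beads closer than r_c interact through the three standard DPD
channels,

    F_C = a_ij w(r) r_hat,
    F_D = -gamma w(r)^2 (r_hat . v_ij) r_hat,
    F_R = sigma w(r) zeta_ij dt^(-1/2) r_hat,      w(r) = 1 - r/r_c,

with zeta_ij a symmetric unit Gaussian per pair per step.  The dissipative
and random channels form a momentum-conserving thermostat; the
fluctuation--dissipation relation sigma^2 = 2 gamma kBT is enforced by the
`InteractionTable` constructor.  Consecutive beads are joined by harmonic
bonds F = k_s (1 - r/r_s) r_hat and bending is controlled by harmonic angle
terms U = k_theta (theta - theta0)^2 with theta0 = pi for three consecutive
tail beads and theta0 = 2 pi/3 for the head-internal triples and the two
head--tail junction triples.  Mixed (H, T, T) triples and the through-branch
(T, H, T) triple carry no angle term; only the enumerated triples are
constrained, which keeps the two tails free to splay.

Integration is the Groot--Warren modified velocity Verlet (prediction weight
lambda = 0.65, the canonical value) at dt = 0.01 tau in the NVT ensemble
with full periodic boundaries.  The dissipative force is evaluated with the
lambda-predicted velocities; forces are computed once per step.

## Parameters and defaults

| parameter | default | units | meaning |
|---|---|---|---|
| rho | 3 | beads/r_c^3 | bead number density |
| a (compatible pairs) | 50 | kBT/r_c | H-H, T-T, W-W, H-W repulsion |
| a (incompatible pairs) | 200 | kBT/r_c | H-T, W-T repulsion |
| sigma | 3 | | noise amplitude (gamma = sigma^2/2 = 4.5) |
| k_s, r_s | 100, 0.7 | kBT/r_c^2, r_c | bond constant, rest length |
| k_theta | 6 | kBT/rad^2 | bending constant |
| dt | 0.01 | tau | time step |
| lambda | 0.65 | | velocity-prediction weight |
| L | 30 | r_c | production box edge (81 000 beads) |
| W | 5 / 2 / 1 | steps | swap interval (weak/moderate/strong shear) |
| n_slabs | 20 | | z-slabs for swaps and profiles |

The source text for this model states the repulsion amplitudes only as "200
for the hydrophilic type and 50 for the hydrophobic types", which does not
determine a unique pair matrix.  We assign a = 200 to the hydrophobically
incompatible pairs (H-T, W-T) and a = 50 to every compatible pair; this is
the assignment that drives the hydrophobic segregation the observed
morphologies require, and the matrix is a single config entry
(`a_like`/`a_unlike`) so alternatives are one-line changes.  The bending
constant k_theta is never printed in the source; 6 kBT/rad^2 (a common
choice for semi-flexible coarse-grained tails) is the default and is
likewise exposed in the config.

## Shear protocol

Steady shear is imposed by the reverse non-equilibrium momentum-swap (flip)
scheme: every W steps the bead with the most negative v_x in the slab at
z = 0 exchanges its x-velocity with the bead with the most positive v_x in
the slab at z = L_z/2.  With equal masses the swap conserves total momentum
and kinetic energy exactly while carrying a known momentum flux

    j_z(p_x) = p_x / (2 t L_x L_y)

across the z-planes (the factor 2 counts the two equivalent flux planes of
the periodic box).  The fluid answers with a sawtooth v_x(z) profile; the
branch slope is the shear rate gamma_dot = dv_x/dz, fitted by least squares
on each monotone branch with the two perturbed swap slabs excluded.  The
swap slabs sit at z = 0 and z = L_z/2: under periodicity z = 0 and z = L_z
are the same slab, and only the half-box separation produces the two linear
branches the method requires.  One bead pair is swapped per event.

Shear strength in a given box is set by the *measured* gamma_dot, not by W
alone: the same W produces a much higher shear rate in a smaller box
(fewer beads per slab area, same swap cadence).  Desk-scale experiments
therefore calibrate W against the fitted profile slope.

## Observables

* **Energies.**  Per-bead conservative pair energy sum (a_ij r_c/2)(1-r/r_c)^2
  (the antiderivative of F_C), bond energy (k_s r_s/2)(1-r/r_s)^2, angle
  energy k_theta (theta-theta0)^2, and kinetic energy; the total is their
  sum.  A plateau detector (sliding least-squares slope over a 200 tau
  window, tolerance 1e-4 per tau, both configurable) locates the stationary
  stage and its level.
* **Kinetic temperature** uses 3N - 3 degrees of freedom (centre-of-mass
  motion removed at initialization).
* **Gyration statistics.**  Each chain is unwrapped across periodic images
  by walking its bond graph (each bead placed at the minimum-image position
  relative to its already-placed bonded predecessor), then the squared
  gyration tensor is the second moment of bead positions about the chain
  mass centre.  The scalar R_g is the square root of the trace; <R_g> is the
  chain-mean of the per-chain scalars (not the root of the averaged
  squares), and the reported axis components <R_g,aa> are chain-means of
  sqrt(Rg2_aa).  The shape factor
  delta = 1 - 3 (L1L2 + L2L3 + L1L3)/(L1+L2+L3)^2 (on the eigenvalues Li of
  the squared tensor) is 0 for a sphere and 1 for a rod; note that an ideal
  planar ring gives delta = 0.25 by direct evaluation, although the source
  text associates "circular" with 0.5 — the implementation follows the
  formula.
* **Flow velocity.**  v_x is averaged within each z-slab (cancelling the
  thermal contribution, whose raw per-bead |v_x| mean would be
  sqrt(2/pi) ~ 0.8 at kBT = 1), and the slab means are folded by absolute
  value so the two counter-streaming halves add.  For an ideal sawtooth of
  branch slope gamma_dot this equals gamma_dot L_z / 8; at shear-free
  equilibrium it vanishes within slab sampling noise.  The saturation level
  is the mean over the final third of the window.
* **Aggregates.**  Connected components of the tail-bead contact graph
  (minimum-image distance below 1 r_c by default), via a periodic k-d tree
  and sparse graph components.

## Starting configurations

The generator emulates the study conditions: a periodic cube at rho = 3
(production edge L = 30 r_c, 81 000 beads) with lipid concentrations
phi_P in {0.35, 0.40, 0.45, 0.50} defined as the fraction of beads that
belong to chains; chain counts are rounded to nearest and the remainder
becomes water, so the realized phi_P deviates by at most one
chain-equivalent.  Three builders:

* `random_solution` — chains as random walks of step r_s (reflected at the
  box walls), waters uniform; the self-assembly starting point.
* `water_only` — thermostat and viscosity fixtures.
* `porous_cylinder` — an idealized pre-assembled state for scaled-down shear
  experiments: a lipid cylinder along z whose cross-section carries 3-6
  water-filled channels at the vertices of a regular polygon.  The outer
  radius is set by area balance so the annular tail matrix occupies the
  fraction phi_P of the cross-section; chains stand on the interfaces with
  heads on the water side, packed (bond spacings compressed to the matrix
  thickness) and left to relax — soft DPD cores need no overlap removal.
  This is an idealization for scaled tests, not a bead-for-bead reproduction
  of self-assembled states; full-scale work should self-assemble from
  random states.

What the generator does **not** emulate: self-assembled interface roughness
and thickness fluctuations, the multi-initial-state energy-selection
procedure of the full-scale study (supported instead through seed sweeps),
and any chemistry beyond the three-species coarse graining.  Desk-scale
tests passing therefore demonstrates the correctness of the mechanics,
thermostat, shear bookkeeping and statistics — not quantitative agreement
with the full-scale morphology diagram.

## Numerical choices

* **Counter-based pair noise.**  zeta_ij is generated by a splitmix64-style
  hash of (min(i,j), max(i,j), per-step seed) feeding a Box-Muller
  transform.  Noise is symmetric per pair, independent of pair-enumeration
  order — the cell-list and O(N^2) paths produce identical forces up to
  summation rounding — and runs are a pure function of (initial state,
  seed).  The per-step seed is run_seed * 2^31 + step.
* **Neighbor search.**  Beads are counting-sorted by cell each step and
  half-space cell neighbors are traversed over contiguous slices; boxes
  narrower than 3 r_c on any axis fall back to the O(N^2) loop.
* **Degenerate geometry.**  Exactly overlapping pairs (r < 1e-10) get a
  deterministic pseudo-random force direction and are logged; zero-length
  angle arms are rejected in standalone evaluation and skipped (counted)
  during dynamics; near-collinear angles clamp sin(theta) at 1e-8, where
  the force prefactor (theta - theta0)/sin(theta) is already finite for the
  theta0 = pi terms.
* **Tie-breaks.**  Slab index is floor(z n/L_z) clipped to [0, n-1]; the
  momentum swap takes the argmin/argmax x-velocity (first occurrence on
  ties, which transfers nothing when the extremes are equal).
* **Problem sizes.**  Desk-scale verification uses 3 000-bead water boxes
  (L = 10) for thermostat and viscosity checks and a 10 125-bead lipid box
  (L = 15, phi_P = 0.35) for shear-response checks, tens of thousands of
  steps each; these sizes give sub-percent temperature statistics and
  well-resolved velocity profiles while keeping any single check to a few
  minutes.  Full-scale (L = 30, 200 000+ steps) runs use the same code
  paths through the `sweep` CLI command and are intended as long batch
  jobs.

## Lamella orientation at desk scale

Sheared lamellar phases can orient with their normal along the velocity
gradient (z, "parallel": layers slide over each other) or along the
vorticity axis (y, "perpendicular").  In desk-scale boxes (L = 15) the
outcome is set by the initial condition and the imposed rate:

* a pre-formed cylinder with axis along z is translation-invariant along z;
  its collapse picks a slab normal in the x-y plane and shear preserves it,
  so chains end up elongated along y regardless of rate — the z-invariance
  cannot break in a box too small for the vesicle intermediates that do the
  breaking at full scale;
* shear-driven self-assembly from a random solution at the strongest study
  rate (gamma_dot ~ 0.06, swap interval calibrated per box since the same W
  drives a much higher rate in a smaller box) forms the gradient-normal
  lamella directly, reproducing the chain elongation along z
  (<R_gzz> > <R_gxx> ~ <R_gyy>) robustly across seeds;
* rates several times stronger than the study's strongest (e.g. W = 1 at
  L = 15 gives gamma_dot ~ 0.24) favor the perpendicular orientation.

Which orientation a single assembly run reaches is stochastic, but the two
steady states are not energetically equivalent: the gradient-normal lamella
has a distinctly lower conservative energy under shear (the vorticity-normal
sheet is strained in-plane by the velocity gradient).  The anisotropy
verification therefore follows the multi-initial-state protocol of the
study: several independent assembly replicas are run and the final
structure with the smaller stationary energy is selected before the chain
statistics are read off.  The porous-cylinder builder remains the scaled
stand-in for structural/relaxation tests and full-scale campaigns.

## Known limitations

* The repulsion-matrix reading and k_theta are assumptions (see above);
  results sensitive to them should be swept.
* Shape-factor semantics near flat structures differ from the source text's
  prose (0.25 vs 0.5 for "circular"); comparisons of absolute delta levels
  should keep that in mind.
* The momentum-swap thermostat interplay heats the fluid slightly above
  kBT = 1 at very strong imposed fluxes (a known property of the method);
  measured temperatures are reported alongside sheared observables.
* Whole-aggregate gyration (as opposed to per-chain) is not computed: in a
  periodic box a percolating aggregate has no well-defined unwrapped
  second moment.  Reported R_g statistics are per chain, which for this
  11-bead lipid lie around 1-1.4 r_c.
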