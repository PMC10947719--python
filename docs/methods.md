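# Methods

`microsim` is an individual-based simulator of microbial communities.
Cells are agents built from mass-points and sphere-swept volumes; they
grow by catalyzing reactions against their local solute environment,
divide stochastically, differentiate, and interact mechanically.
Compartments are either well-mixed (chemostat-like, scalar
concentrations) or spatially explicit (biofilm-like, gridded fields).
This note records the models implemented, the defaults and their
rationale, the numerical choices, and what the packaged test scenarios
do and do not demonstrate.

## Units

Internally everything is micrometres, femtograms and hours, chosen so
that cell-scale quantities are numbers of order one and the common
laboratory concentration unit is neutral: 1 g/L = 1 fg/µm³.  Protocol
files carry explicit units ("500 mg/L", "0.2 /h", "0.01 Pa s") that are
converted on load with full dimension checking; `microsim convert-units`
exposes the converter.

## Agents and morphology

A coccus is one mass-point with the radius of the equal-mass sphere,
r = (3V/4π)^(1/3), V = m/ρ.  A bacillus is two mass-points joined by a
spine spring; its sphere-swept volume is the spherocylinder
V = πr²ℓ + (4/3)πr³, which defines the mass↔length map at constant
radius.  Filaments are chains of bacillus agents connected by short
link springs, with torsion hinges (rest angle 180°) spanning each
junction so chains straighten; the hinge forces are the analytic
gradient of U = ½κ(θ−θ₀)², which makes net force and net torque vanish
identically over each point triple.

Division draws the daughter mass fraction from a normal distribution
with mean 50% of the mother mass and a user-set coefficient of
variation, truncated at ±2σ (rejection sampling from the root random
stream).  Masses are conserved exactly: the mother keeps the complement.
Coccus daughters are displaced by their radii in opposite random
directions; rod daughters split along the axis with the two new inner
points on either side of the old center of gravity, leaving residual
compression that the next mechanical relaxation resolves.  Filament
daughters stay linked, extending the chain (the link graph is always a
path).

Differentiation rules are logic expressions over agent aspects and the
local environment; on trigger, aspects of a named module are applied
atomically.  The filamentous life cycle uses this: a sphere extends into
a rod above a switch mass and rod divisions build the chain.

2D simulations extrude agents into a 1 µm virtual third dimension.  By
default densities are rescaled so that the 2D footprint radius equals
the radius of the equal-mass 3D sphere, and the sphere/circle
maximum-packing ratio √(2/3) ≈ 0.82 is available as a density
correction factor for translating 3D parameterizations to 2D.

## Mechanics

Inertia is negligible at cell scale (Re ≪ 1), so each mass-point moves
at its Stokes terminal velocity v = ΣF/(6πr_c µ_f).  Forces are:
Hertzian contact F = (4/3) r_eff E_eff ξ^{3/2} on overlapping bodies
(harmonic combinations for unequal radii/moduli; planes count as
infinite), linear springs F = kδl for rod spines and filament links,
and the torsion hinges above.  Contact detection treats every body as a
(possibly degenerate) sphere-swept segment, so one vectorized
segment-segment kernel covers sphere/rod pairs; boundary planes and
axis-aligned voxels have dedicated tests.  All gaps respect the
minimum-image convention on periodic axes.

Relaxation integrates the overdamped system with forward Euler or Heun
sweeps.  The internal pseudo-time step is capped three ways: a fixed
maximum, a displacement cap (default 0.1 µm per sweep), and a stability
cap 0.9·drag/k where the contact stiffness dF/dξ = 2 r_eff E_eff √ξ is
re-estimated each sweep from the current worst overlap, so steps grow
as contacts resolve.  Termination: residual net force per point below
tolerance (default 50 fN — orders of magnitude below typical contact
forces), or, in growth-jammed packings where the net force plateaus at
a small finite value, a maximum overlap within tolerance (default
0.05 µm) with a stalled residual; otherwise the iteration budget is
exhausted and the non-convergence is flagged in the mechanics log.
Free clusters relax to essentially zero force with the documented
exponential tail (verified in the over-compression scenario).

Defaults: E_eff source 10⁵ Pa per agent, viscosity 10⁻³ Pa s (water),
spine/link/torsion stiffness 10⁵ fN/µm (10⁻⁴ N/m), chosen so spring
forces at ~0.1 µm deflections match contact forces in magnitude.
Emergent biofilm density depends on the overlap/residual tolerances,
which is why both are surfaced in `RelaxationConfig` and logged per
call.

A legacy shoving algorithm is kept for comparison: overlapping sphere
pairs are displaced half-and-half along the center line until no pair
exceeds tolerance.  It rejects rods and filaments.

Neighbor search uses a quadtree/octree over agent bounding boxes with
periodic image queries (exactness against an O(n²) oracle is part of
the test suite).  The inner relaxation loop uses a uniform cell list
rebuilt only when positions drift beyond a slack margin, which is an
implementation detail behind the same correctness contract.

## Reactions and solutes

A reaction is a stoichiometry vector and a rate expression
(q_i = N_i·r, positive coefficients produce).  Rates are arbitrary
arithmetic expressions over solute concentrations, agent aspects and
named parameters, so Monod, double-Monod, inhibition or thermodynamic
forms are all protocol-level choices.  Concentrations are clamped to
zero before rate evaluation (with a warning) so kinetics stay physical
under small solver transients.

Well-mixed compartments integrate solutes, reactor volume and agent
masses jointly with an adaptive stiff solver (LSODA), including
per-flow dilution terms.  With matched in/outflow this is the standard
chemostat equation; with unmatched flows the volume ODE
dV/dt = ΣQ_in − ΣQ_out runs alongside and the inflow term takes the
mass-conserving form (Q/V)(S_in − S).  Cumulative in/out/production
audits are carried in the same integration so the mass balance
(in − out + production − accumulation = 0) can be checked to solver
tolerance at any time.  An outflow can retain agents (retentostat);
otherwise agents wash out stochastically with probability
1 − exp(−D·dt) per step.

Spatial compartments assume a pseudo-steady state for solutes: reaction
and diffusion equilibrate orders of magnitude faster than growth, so
each global step solves div(ω∇S) + q(S) = 0 at frozen biomass.
Discretization is voxel-centered finite volumes with harmonic-mean face
diffusivities (correct for diffusivity jumps at the biofilm boundary);
boundary types are solid (no-flux), Dirichlet, periodic and connected.
Nonlinear kinetics are handled by damped Picard iteration with a
diagonal finite-difference Newton linearization of ∂q/∂S (clipped to be
non-positive); iterates are clamped at zero inside the loop only, and
the returned field must satisfy the discrete balance to a relative
residual of 10⁻⁵ or the solve raises.  Linear systems use conjugate
gradients (the operator is symmetric negative-definite) with a sparse
direct fallback; pure-Neumann (closed-box) solutes are solved with the
mean pinned so total mass is conserved.  Agent-catalyzed rates enter
the voxel containing the agent's center of gravity (half-open voxels,
upper domain face belongs to the last voxel), and the converged
per-agent biomass rates drive the growth step.

A connected face is a Dirichlet boundary at the linked well-mixed
compartment's concentration; the diffusive flux through it (scaled by
the compartment's scale factor) is fed back into the linked reactor's
ODE as a source/sink, closing the two-compartment balance.

## Scheduling, reproducibility, snapshots

Each compartment's processes carry a time step and a priority; within a
global step they fire in order of (due time, priority, order of
definition).  The canonical biofilm step is: reactions+diffusion
(updates fields and agent masses), agent updates (division,
differentiation, washout), mechanical relaxation, reporting.  One root
random stream (PCG64) serves all stochastic draws in schedule order, so
a protocol plus a seed fixes the trajectory exactly.  Snapshots
serialize the full state — including the random-stream state and the
schedule — into the protocol schema; restarting from a snapshot
reproduces the uninterrupted run's inventories and subsequent random
draws exactly (tested).

## Verification scenarios

The packaged suite compares solver output against closed forms; the
acceptance script reports the maximum relative deviation (all scenarios
are well below the 0.02% working tolerance):

* Non-growing chemostat: inflow 500 mg/L, D = 0.1/h, fixed population
  consuming 10 mg/(L·h) → S* = S_in − u/D = 400 mg/L.
* Growing chemostat: µ_max = 0.2/h, K_s = 20 mg/L, Y = 0.25,
  D = 0.05/h, S_in = 2000 mg/L → S* = K_s·D/(µ_max−D) = 6.67 mg/L and
  X* = Y(S_in−S*) = 498.33 mg/L; a washout variant at 1.1× the critical
  dilution empties the reactor.
* 1D diffusion: linear profile (exact at nodes), parabolic profile
  under uniform zero-order consumption, first-order cosh profile.
* Thin cell layer: a 10 µm layer consuming 1.44 fg/(µm³·h) under a
  100 µm boundary layer with 2 mg/L bulk → surface concentration
  1.8 mg/L by flux continuity; a 10× thicker-biomass variant depletes
  oxygen at depth while the boundary-layer profile stays linear.
* Mechanical relaxation of an over-compressed cluster: the highest
  interaction force decays by orders of magnitude to convergence.

These parameter sets are package choices made so the closed-form
steady states equal the conventional reference values above; the
closed forms, not the simulator, define the expected numbers.

## Competition case studies and desk-scale variants

The competition scenarios pit a Rate Strategist (RS: µ_max doubled,
yield per O₂ halved) against a Yield Strategist (YS), constrained to
equal specific affinity (equal µ_max/K_O2 initial Monod slope); both
consume carbon and oxygen via double-Monod kinetics, with oxygen the
limiting resource diffusing from the top boundary.  Defaults follow the
classic setup (alternating equidistant founders at 5/10/50 cells per
strategy, 1 mg/L bulk oxygen, three weeks); these full-scale runs take
hours and are not exercised by the test suite.

The test suite runs *desk-scale variants*: a 48×40 µm 2D domain,
0.25 mg/L bulk oxygen (so flux limitation — the driver of the
density-dependent outcome — sets in within a 72 h horizon), 3 vs 12
founders per strategy.  At this scale the ensemble reproduces the
qualitative density ranking: the YS biomass share is consistently
higher at low founder density (segregated clusters convert the oxygen
flux at double efficiency) than at intermediate density (mixing lets
the faster RS pre-empt the flux).  Absolute winner flips, which in the
original require weeks of simulated growth, are out of desk-scale
reach; what the passing tests show is the direction and separation of
the density effect, not the final coexistence diagram.

The filament case gives one species a sphere→rod→filament life cycle in
a quasi-2D slab (periodic x/y, oxygen from the top).  Filament chains
measurably out-climb coccoid heaps (range expansion towards the
source), which is the mechanism behind the full-scale result that
filaments win regardless of strategy.  The desk-scale ensemble check
isolates morphology (identical kinetics for both species) and asserts
the front-height advantage plus a non-inferior biomass share; the
biomass-share flip itself again needs domain heights and durations far
beyond minutes-scale tests.

The nitrifying-biofilm benchmark ships as a parameterizable skeleton
(heterotrophs + nitrifiers over a connected bulk reactor, decay with
inactivation below 20% of division mass, shoving or force-based
spreading).  It deliberately has no default kinetics: users supply
their own parameter set, and a missing value raises an error listing
every unset parameter.  Its acceptance-level check is mass-balance
closure and the zero-biomass limit (bulk → inflow), not published
steady-state tables.

## What the synthetic scenarios do not show

All inputs are generated by spawners and protocol parameters; there is
no measurement noise, no real-geometry irregularity, and kinetic
parameters are illustrative.  Passing tests demonstrate internal
correctness (solvers against closed forms, exact invariants,
reproducibility) and the direction of the emergent competition effects
at reduced scale.  They do not calibrate any real organism, and 2D
variants inherit the documented 2D artifacts (virtual thickness,
packing-density differences, suppressed third-dimension transport).

## Known limitations

* No advection or fluid dynamics; transport is diffusive only.
* Filaments are unbranched chains; no motility or chemotaxis operators.
* EPS is representable only as inert spawned particles.
* The steady-state solver requires kinetics smooth enough for the
  damped Newton–Picard iteration; discontinuous switches inside rate
  expressions may need damping < 1.
* Shoving supports spheres only (by design, matching its lineage).
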