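# Methods

## Model overview

`veinadapt` simulates the adaptation of a vein graft's 2D cross section
after implantation into the arterial circulation. The cross section is a
Cartesian grid (step h, mm units, origin at the vessel axis) carrying three
closed Lagrangian membranes — lumen wall, internal elastic lamina (IEL),
external wall — that partition the domain into lumen, tunica intima, tunica
media and external support. SMCs are disc particles of radius R_SMC living
in the wall; the rest of the wall is ECM tracked as a gridded occupancy
density. Three sub-models are coupled by hourly time splitting:
mechanics (PDE), tissue plasticity (stochastic agents), tissue remodeling
(immersed-boundary particle transport).

### Mechanics

Blood flow is steady, fully developed axial flow: μΔw = −G_p on the lumen
with no-slip walls imposed by an Angot volume penalty (η = 1e-8) on the
full grid, and the pressure-gradient constant rescaled so ∫w dA equals the
prescribed flow rate (the circulation's constant-flow control; linearity
makes the rescaling exact). Wall shear at each lumen membrane point is the
one-sided normal derivative from a three-point quadratic fit at 2h/4h/6h
into the lumen; the fit is not forced through the membrane point, which
makes it insensitive to the O(h) penalty-interface offset. Two further
regularizations of the discrete shear: a five-point arc-length moving
average (shear sensing is nonlocal at the cell scale, and the average
removes grid staircase noise), and a renormalization of the mean to the
exact Poiseuille value 4μQ/(πr_eq³) of the area-equivalent circle. Without
the renormalization the O(h) estimator bias drifts as the membrane
roughens, and the rectifying nonlinearity F(τ) = max(0, (τ̄−τ)/τ̄) turns
that drift into spurious growth-factor production; with it the
basic solution stays balanced on any grid.

Wall stress uses the thick-cylinder (Lamé) closed form on the
area-equivalent annulus (a, b) with plane-strain energy density
U = (σ_r² + σ_θ² + σ_z² − 2ν(σ_rσ_θ + σ_θσ_z + σ_zσ_r))/2E, σ_z = ν(σ_r+σ_θ).
Defaults: p_internal = 13.3 kPa (≈100 mmHg), p_external = 0.4 kPa,
E = 600 kPa, ν = 0.45 — typical venous-tissue values; they enter the
biology only through the relative deviation Δσ/σ̄ and the inward/outward
energy comparison, so their absolute scale is uncritical.

The growth factor G solves the steady diffusion problem with Dirichlet
value F(τ_wall) on the lumen cells (value of the nearest membrane point,
penalty-anchored) and zero flux through all other region interfaces (face
conductivities vanish into non-wall cells). Only the steady profile feeds
the hourly biology, so the transient is never integrated; the diffusion
coefficient c is therefore a config placeholder with no effect on the
steady state. F is chosen as the clipped relative shear deficit: the basic
solution (τ = τ̄) gives G ≡ 0, a 50% shear drop gives G ≡ 0.5. The whole
field set is recomputed only when the Hausdorff distance between the old
and new lumen polylines exceeds tol = R_SMC (strict inequality, to avoid
recomputation chatter at exact equality; one radius — the strict end of
"of the order of an SMC diameter" — keeps the stale-shear lag between
updates from biasing the growth feedback).

### Tissue plasticity

Each SMC carries a 12 h mitotic clock and a 2 h ECM clock, initialized at
uniformly random phase at seeding so divisions desynchronize immediately
(synchronized clocks would fire in unphysical bursts). Every hour each
agent is interrogated in randomized order; completing clocks trigger
mutually exclusive draws — divide / die / nothing and produce / degrade /
nothing — with the probability laws listed in the README, all scaled by
the macrophage envelope A(t) = exp(−(t−T)/δT). As printed, the envelope
exceeds 1 before the peak time T; it is clamped at 1 for t < T (T is the
time of *maximum* macrophage activity) unless `allow_pre_peak_growth`
preserves the literal formula. The division gain α₅G applies in the
intima, the migration gain α₈G to medial agents adjacent to the IEL
(within 2·R_SMC), which cross only where the local membrane tension
reaches the IEL porosity threshold. Division and apoptosis are gated
per-layer (`division_layers`/`apoptosis_layers`, both intima-only by
default — proliferation is not activated in the media, and apoptosis is
paired with it so the media stays stable); ECM events are enabled in both
layers. Daughters are placed one cell diameter from the parent in a random
direction that stays inside the parent's layer (20 retries, then radially
inward).

Rate coefficients (α₁…α₈, in `data/defaults.yaml`) are calibration
constants. α₁ = α₂ = 0.05 make the basic solution stationary by
construction (division = apoptosis, production = degradation);
T = 168 h and δT = 336 h put peak inflammation at one week with a
two-week relaxation, so adaptation freezes after ~5 weeks; α₅ = 4.6 is
the intimal growth gain (the γ of the reduced system); α₆ = 0.5 keeps
the strain-energy feedback on ECM secondary; α₇ = 5e-4 yields a slow
media→intima migration trickle that does not deplete the media over a
4-month follow-up.

### Tissue remodeling

The wall and surroundings are one highly viscous incompressible medium on
a MAC staggered grid. Each hourly cycle runs the immersed-boundary
algorithm for a relaxation period δt (dimensionless relaxation unit,
default δt = 1 in 10 substeps; δt is a free model parameter). A substep:

1. spread membrane spring-tension forces to the velocity grids with the
   4-point cosine delta kernel (exact partition of unity; spreading and
   interpolation are exact adjoints);
2. predictor: semi-Lagrangian characteristics for convection, implicit
   (prefactorized) diffusion, explicit body force;
3. corrector: ΔΠ = (ρ/Δt)(∇·V* − s) with homogeneous Neumann walls and one
   pinned cell; the corrected velocity satisfies the discrete ∇·V = s
   identity to solver precision. The source field s carries one element
   area (πR_SMC² per SMC event, πR_ECM² per ECM event) per event cell,
   released uniformly over δt. The printed "2πR" unit of volume of the
   source elements is dimensionally a circumference and is read here as
   shorthand for the disc measure;
4. membranes, agents and the ECM density advect with the interpolated
   velocity; agents add their active motility velocity.

Because the box is closed and the medium incompressible, ∫s dA must
vanish. The wall-event net is therefore compensated by a uniform sink
placed either in the lumen or in the external support, selected each cycle
by the inward/outward energy criterion: trial perturbations of the lumen
area (one probe cell plus the net) are scored with the closed-form Lamé
annulus energy, and if the inward trial strictly lowers the energy the
*entire signed net* is accommodated on the lumen side (wall growth shrinks
the lumen, wall loss re-opens it); otherwise the external side absorbs it.
Routing the signed net — rather than only positive nets — is essential:
an asymmetric rule rectifies the zero-mean event noise of the balanced
basic solution into a spurious lumen drift. Under internal pressurization
the inward trial always wins (a thicker wall at smaller radius stores less
Lamé energy), which reproduces the physiological inward remodeling of
hyperplasia; no mass-conservation correction of the IBM scheme is applied
beyond this balance, the flow being viscous and low-Reynolds.

Active SMC motility Ẋ = V_S + V_E + V_G + V_R:

- V_S: same-layer pairwise repulsion, linear decay k_S·(1 − d/(2n_sR_SMC)),
  zero beyond 2n_s R_SMC (n_s = 2; a truncated Lennard-Jones-style profile
  is available behind `lennard_jones_repulsion` but the linear decay is
  the default used everywhere);
- V_E: matrix invasion — attraction toward ECM-occupied, cell-free grid
  cells within 2n_e R_SMC (n_e = 3), linear decay weighted by density;
- V_G: chemotaxis k_G ∇G;
- V_R: isotropic random walk with |V_R| δt ≤ R_SMC (a cell moves at most
  one radius per relaxation period).

Gains k_S, k_E, k_G (defaults.yaml) are set so a step's active
displacement is a fraction of R_SMC; they were chosen so the early-phase
motility study reproduces the expected qualitative ordering (random-only
motion leaves apoptosis holes; adding repulsion and then matrix invasion
progressively uniformizes the intimal distribution, measured by the
nearest-neighbor-distance CV). Agents that would cross a bounding
membrane have their active displacement reflected at the local tangent
(fallbacks: passive-only move, then stay put), except migration events,
which legitimately cross the IEL. Membrane rest lengths relax toward
current lengths each hour (`plastic_rate` = 1): membranes are elastic on
the relaxation timescale and plastic on the hourly one, which lets the
vessel remodel by ~40% of its circumference over months without storing
unbounded spring energy.

### Reduced dynamical system and calibration

The zero-dimensional counterpart keeps the radii triple (R, re, r) and the
mean-field limit of the agent rules: dA_I/dt = turnover·A(t)·γ·(Δτ/τ̄)·A_I,
with Δτ/τ̄ = max(0, 1 − (1−drop)(r₀/r)³) recomputed daily from Poiseuille
shear under constant (dropped) flow, growth accommodated inward (IEL
fixed, lumen loses area one-for-one), and explicit daily stepping.
turnover = (SMC fraction)·α₁/12 h·24 = 0.025/day is the agent-model
turnover, so the calibrated γ is directly comparable to α₅. The macrophage
envelope A(t) (daily analytic mean, same T/δT as the hybrid run) is
included because every hybrid probability law carries it; without the
envelope a single gain cannot represent the inflammation-limited dynamics.
Calibration minimizes the L2 distance between daily lumen-area
trajectories normalized to their initial value (lumen area per the results
convention; intimal-area mode is a one-line change in the objective),
using a real-coded genetic algorithm: population 40, 100 generations,
tournament-3 selection, blend crossover, Gaussian mutation with decaying
scale, elitism, 30-generation patience, fully seeded. The GA is
deliberately hand-rolled and never shares code with the simulators it
compares, so parameter-recovery tests are a genuine dual route.

## Synthetic data and what the tests show

There is no external data: the fixture generator builds the "basic
solution" (healthy vein at implantation) — concentric circular membranes
at radii 0.24/0.28/0.30 mm, 25% SMC / 75% ECM by wall area, rejection-
sampled disc packing with ≤10% radius overlap. This emulates the
idealized implantation state; it does not emulate non-circular lumens from
histology, anisotropic ECM fiber structure, macrophage particles, or 3D
effects, so passing tests demonstrate internal consistency and the
qualitative physiology of the model, not agreement with any particular
animal.

## Problem sizes and numerical choices

Default grid step h = 0.005 mm; the experiment presets use h = 0.0075 mm
(≈90×90 cells, ~225 SMCs) with 5 IBM substeps per hourly relaxation (4 in
the 4-month cross-validation preset) — resolution/substep choices at which
the trajectory statistics are grid-converged to well within the stochastic
run-to-run spread. The
acceptance script runs the cross-validation at a scaled-down study size
(5-run ensemble, 2-month follow-up) whose ensemble-mean noise is small
enough for the <2% cross-validation figure; the full study size (10 runs,
4 months) is the preset default. Linear solves use prefactorized sparse LU
(the grid is fixed per run); the pressure Poisson system is pinned at one
cell, exact for compatible right-hand sides; degradation events that find
less matrix than one element remove only what is available, with the
source field corrected to match. Ties in the inward/outward comparison do
nothing (the energy-neutral choice).

## Known limitations

- The ECM density is advected semi-Lagrangianly (non-conservative); mass
  bookkeeping of the wall is enforced through the source terms, not the
  density field.
- The thick-cylinder energy assumes a near-annular wall; strongly
  asymmetric late-phase geometries stretch that approximation (a
  finite-element wall model is out of scope).
- Medial agents are inert except for ECM turnover and migration;
  macrophages enter only through the activity envelope A(t).
- The reduced system models only the γ-driven intimal pathway actually
  exercised by the cross-validation scenario, not the full feedback
  network of the original zero-dimensional model; the module boundary
  allows swapping in a richer system.
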