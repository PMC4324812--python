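# Model and methods

`oxynet` simulates the earliest, avascular phase of solid-tumour growth in a
1 mm³ block of vascularised tissue: a microtumour seeded among a regular
pre-existing arteriolar bed coopts the host vessels, consumes the oxygen they
deliver, and destabilises them — dilation, leakiness, compression and
shear-stress-driven collapse — until the local oxygen landscape, not the
simulation, decides the tumour's fate. The model couples four submodels on a
shared cubic lattice (default 100×100×100 voxels, 10 µm lattice constant;
lattice nodes coincide with voxel centres):

1. **network haemodynamics** (Poiseuille flow with Starling leakage and a
   Darcy interstitium),
2. **chemical transport** (intravascular O2 advection with oxyhaemoglobin
   equilibrium, transvascular Fick flux, tissue diffusion–consumption;
   diagnostic ECM/MDE reaction–diffusion),
3. **a probabilistic cellular automaton** for tumour cell phenotypes,
4. **vessel dynamics** (cooption/dilation, compliance remodelling, collapse).

One outer step is 1.5 h of model time. Internally all lengths are µm, time
s, pressure mmHg and amount µmol (`oxynet.units` centralises conversions).

## Pre-existing network

Parallel arterioles run the full y-extent of the cube on a regular (x, z)
raster, 10 lattice units (100 µm) apart at baseline density. Each arteriole
is assigned one of three calibres — diameters 50/30/10 µm in proportions
10 %/20 %/70 % by the largest-remainder rule — so that the stated proportions
are met exactly whenever they divide the arteriole count. Capillaries
(diameter 8 µm) bridge adjacent arterioles as straight lattice paths: each
adjacent pair receives one Bernoulli(0.3) trial per 10-lattice-unit window
along y, at a uniformly random height within the window. This density was
chosen so that capillaries make up roughly a third of all segments, the
proportion consistent with their reported share of point-source oxygen
supply; it is exposed as `capillary_link_prob`.

The microvessel-density (MVD) multiplier rescales the *number* of arteriole
lines along x (count = round(base × multiplier), evenly spaced over the same
extent), leaving the capillary linking probability per pair untouched. At
multiplier 1.0 the layout is exactly the every-10th-coordinate raster.

Inlet is the y = max plane, outlet y = 0; flow is driven by a fixed
3.5 mmHg difference (outlet reference 15 mmHg — only the difference is
physical, the offset fixes the Starling balance point).

## Haemodynamics

Intravascular flow: flux conservation at every node with segment conductance
g = πR⁴/(8µΔl). Leakage follows Starling's law,
Q_t = 2πRΔl·L_p[(P_v − P_i) − σ_T(π_v − π_i)], lumped half-and-half onto the
segment's endpoint voxels (the midpoint of a lattice edge lies on their
shared face). Mature vessels carry the normal-tissue hydraulic permeability
L_p = 0.36×10⁻⁷ cm/(mmHg·s); the tumour value L_p^T = 2.8×10⁻⁷ applies to
fully dilated coopted vessels (below).

The interstitium obeys Darcy's law: −K∇²P_i = L_p(S/V)(P_v − P_i − σ_TΔπ)
with sources only in vessel-containing voxels, no-flux boundaries, solved by
conjugate gradients on the 7-point Laplacian (diagonal preconditioner,
warm-started). With no vessels the gauge is the zero-mean constant. The two
solves are Picard-alternated until node and voxel pressures stabilise to a
relative 10⁻⁶; with zero wall permeability the problem is decoupled and a
single pass is exact.

Blood rheology uses the Pries–Secomb in-vivo apparent-viscosity law
µ(D, H) and the logit phase-separation law at diverging bifurcations
(A, B, X₀ with the standard coefficients −13.29, 6.98, 0.964). Discharge
haematocrit propagates through the network in descending-pressure order
(pressure-driven flow is acyclic); at junctions with three or more outlets
each inherits the mixed value, and daughter haematocrits are capped at 0.95
with the excess returned to the sibling branch. Defaults: plasma viscosity
1.2 cP, inlet haematocrit 0.45.

Wall shear stress per segment is τ = |ΔP_v|·R/(2Δl). The collapse reference
f0 is the mean τ of order-3 arterioles of the *initial* network, frozen at
baseline (it characterises the pre-existing bed, not the remodelled one).

## Oxygen transport

Blood carries free O2 (concentration C_F) plus haemoglobin-bound O2 in local
equilibrium, C_B = 4H·C_Hb·SO2(C_F), with a Hill saturation curve
(P50 = 26 mmHg, n = 2.7, C_Hb = 20.3 mol/m³ of RBC; the Bunsen solubility
α = 1.27×10⁻¹⁵ µmol/(µm³·mmHg) converts partial pressures). The inlet
boundary is a fixed 100 mmHg free-O2 level; tissue oxygen is reported on the
normalised scale c* = C/C_inlet.

Wall flux is Fick's law, J = h·(C_in − C_ex), with a transfer velocity
proportional to the segment's hydraulic permeability, h = h_ref·L_p/L_p^normal
(h_ref = 5 µm/s for a mature vessel). Tying the O2 conductance to L_p makes
coopted, hyper-permeable vessels proportionally leakier to oxygen; the
absolute scale is a free parameter because a hydraulic permeability cannot
be converted to a gas-transfer velocity without a membrane model, and it is
exposed in the configuration.

Tissue free O2 diffuses (D_o = 10⁻⁵ cm²/s) and is consumed at zeroth order
by tumour cells only: γ per proliferating cell, γ/2 quiescent, γ/4 necrotic
(γ = 6.25×10⁻¹⁷ mol·cell⁻¹s⁻¹, i.e. ~60 µM/s in a 10 µm voxel — giving the
classic 60–100 µm penetration depth). Consumption is floored so a voxel
cannot go negative.

Because chemical transport is orders of magnitude faster than cell dynamics,
the oxygen subsystem is iterated to steady state within every outer step
using a 5 s inner step:

- **Intravascular:** vascular transit across the domain (~1 s) is below the
  inner step, so the vessel network is solved by a *steady upwind sweep* in
  descending-pressure (flow) order: inlet nodes carry the boundary
  concentration; at each node the total O2 flux of the feeders mixes
  flow-weighted and is inverted through the Hill equilibrium at the
  feeder-weighted haematocrit; along each segment the wall flux drains (or
  refills) the advected total. A time-stepping upwind advection operator
  with automatic CFL sub-stepping is also provided and agrees with the
  sweep in its steady limits.
- **Exchange into tissue:** each segment's wall conductance toward its two
  endpoint voxels is capped by the advective supply margin (a slow
  capillary cannot be drained past equilibrium with the tissue; the
  Hb-buffering secant slope, ≈300 near saturation, enters this cap), and
  the per-voxel update is *implicit*: the new voxel concentration is a
  convex combination of its old value and the vessel concentrations
  weighted by conductance. This is monotone for arbitrarily large
  conductances; explicit deposits oscillate whenever several segments share
  a junction voxel. A per-segment maximum principle clamps the outgoing
  vessel concentration to the range spanned by its upstream value and the
  local tissue, rescaling the conductances with the clamp so the
  vessel-side loss always equals the tissue-side gain; without the clamp
  the Hill inversion diverges when uptake in low-haematocrit capillaries
  pushes the total toward the saturation asymptote.
- **Tissue:** consumption (floored), then one backward-Euler diffusion step
  solved exactly in the DCT-II basis (the 7-point Neumann Laplacian is
  diagonal there), which is unconditionally stable, conserves the discrete
  mass and preserves positivity.

Iteration stops when the largest relative change of the tissue field per
inner step falls below `tol_chem` (default 10⁻⁶; the conservation checks use
10⁻¹⁰). The sequential sweep is refreshed every `sweep_every` (default 2)
inner iterations — the frozen exchange coefficients drift slowly — and the
cold-start guess is oxygenated tissue, which the guess-independence property
test licenses. At steady state total wall delivery balances total
consumption; per-segment delivery rates accumulate over the run for the
supply-by-order statistic.

ECM density (initially 1) is degraded exponentially by matrix-degrading
enzymes, which diffuse (implicitly), decay (exactly) and are produced by
tumour cells (µ_T, scaled 1 : 1/5 : 1/10 for P : Q : N) and by endothelial
voxels (µ_E). Their decay time 1/λ ≈ 6×10⁷ s exceeds any simulated horizon,
so "steady state" is not meaningful for them; they are advanced by the
1.5 h outer step once per step. These fields are diagnostic: no rule in
this model consumes them.

In the **point-source control mode** every non-collapsed segment deposits a
fixed amount of O2 per unit time into its endpoint voxels, bypassing
advection and wall flux; the supply-by-order statistic then reduces to
segment-count fractions.

## Tumour cell automaton

Each voxel holds at most one cell: proliferating (P), quiescent (Q) or
necrotic (N). Twenty P cells with uniformly random ages seed the central
5×5×5 region. Per step, in randomised sweep order, a live cell at
normalised oxygen c:

- necroses if c < θ_surv (default 0.05);
- else, if c ≥ θ_prol (default 0.3) and an empty von-Neumann neighbour
  exists, divides with probability T_age/T_TC (T_TC = 6 steps = 9 h): the
  parent is replaced by an age-1 daughter and a second age-1 daughter takes
  a uniformly chosen empty neighbour; on failure the age increments (capped
  at T_TC);
- otherwise it is quiescent (age retained), re-entering proliferation when
  both conditions recover.

Necrotic cells older than 30 steps (45 h) are cleared with probability 0.20
per step, freeing the voxel. The oxygen thresholds are not fixed by any
published value and are prominently configurable; the shipped defaults
produce central necrosis once the tumour outgrows its local supply.

## Vessel cooption, remodelling, collapse

A segment with at least one active (P or Q) tumour cell in or face-adjacent
to an endpoint voxel becomes *immature*: its radius grows at 0.4 µm/h up to
R_max = 20 µm, its wall permeability rises as L_p = L_p^T·R/R_max, and its
origin radius R0 tracks the dilated value. Immature segments then respond
to transmural pressure through the compliance law R = R0·((P_v − P_i +
P_c)/E)^b (E = 6.5 mmHg, b = 0.1, collapse pressure P_c = 2 mmHg); a
non-positive base collapses the segment outright. With the shipped boundary
pressures the interstitial pressure is bounded above by P_v − σ_TΔπ, so
compression collapse is essentially unreachable and collapse proceeds
through the shear-stress route — consistent with the observation that it is
the low-shear capillaries inside the tumour that die first.

The shear route: a segment *surrounded* by tumour (every face-adjacent
tissue voxel of both endpoints occupied, any phenotype — a deliberately
stronger predicate than the cooption trigger) with τ < 0.5·f0 accrues
low-WSS duration; each step it collapses with probability
min(1, 0.05 × duration), and the counter resets if τ recovers. Collapse is
absorbing: the segment leaves the flow graph permanently, and components
disconnected from both boundary planes are assigned zero flow.

## Simulation loop and reproducibility

Per step: haemodynamics → chemicals to steady state → cell update →
dilation → remodelling → WSS collapse (each stage individually switchable
for controlled experiments). Three independent RNG streams — network
construction, cell decisions, collapse draws — make each stochastic source
separately reproducible; identical configuration and seeds give
byte-identical step summaries (hash-checked in the tests).

Outputs: per-step CSV summaries (cell census, segment census by calibre,
plane statistics of c*, cumulative delivered O2 by vessel class), an events
log (cooption and collapse events), CSV network dumps, and HDF5 snapshots
of fields/cells/network with the configuration embedded. The reporting
statistics are the x-profile of y-averaged c* on the mid-z plane with its
plane average, and the fractional O2 supply per vessel class.

## What the synthetic data does and does not emulate

The generator produces an idealised, regular arteriolar lattice: straight
parallel vessels, discrete calibres, stochastic straight capillary bridges.
It reproduces the *statistical* features the model needs — calibre
proportions, inter-vessel spacing comparable to the O2 diffusion length,
MVD as a single dial — but none of the geometric irregularity of real
microvasculature (tortuosity, anastomotic loops, venous drainage,
image-derived topology). Passing tests therefore validate the coupled
solver and the qualitative MVD/oxygen relationships, not anatomical realism
or biological calibre of the predictions.

## Test and verification scales

The full 100³ grid is supported but slow (hours for hundreds of steps on
one core). The test suite asserts properties, not absolute values, and runs
at reduced scales: analytic oracles on single-vessel micro-networks;
conservation on the 30³ default network; the MVD-sensitivity and hypoxia
results on a 30³ grid, 8 steps, 3 seeds per density case (with `tol_chem`
10⁻⁵ and `sweep_every` 4 for those runs). Scripted desk-scale checks
recompute the necrotic clearance fraction (Monte-Carlo over 10⁵ cells) and
the cooption dilation rate from two-step micro-experiments.

## Known limitations

- Angiogenesis (VEGF-driven sprouting) is out of scope; the simulation
  covers the cooption phase only.
- ECM/MDE exert no feedback on cells or vessels (none is defined in this
  model); they are computed and reported.
- The wall O2 transfer velocity scale h_ref is a free parameter (see
  above); conclusions about absolute extraction fractions depend on it.
- Interstitial convection of oxygen is neglected (interstitial velocities
  are orders of magnitude below vascular ones — reported as a diagnostic,
  not asserted).
- The haematocrit sweep treats junctions with more than two outflows by
  proportional splitting; the logit law applies to two-daughter
  bifurcations only.
- Quiescent cells retain their age, so a long-quiescent cell divides
  promptly once conditions recover.
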