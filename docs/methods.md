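# Model and numerical methods

## Intracellular scale: the EGFR/PLCγ network

Each cell carries eleven state variables: glucose X0 (mM, inert — it appears
in the species table but in no kinetic equation, so it is carried with
dX0/dt = 0), free TGFα X1, free EGFR X2, the ligand–receptor complex X3, its
dimer X4, the phosphorylated dimer X5, PLCγ X6, the receptor–PLCγ complexes
X7/X8, phosphorylated PLCγ X9 and its inactivated form X10 (all nM). Nine
reactions connect them: seven mass-action (bimolecular association /
unimolecular dissociation) and two Michaelis–Menten dephosphorylation steps
with (K4, V4) and (K8, V8). One printed source lists the second enzymatic
rate as a product `V8·X9·(K8+X9)`; it is implemented as the quotient
`V8·X9/(K8+X9)` — the product form has units of nM³/s, while V8 is tabulated
as a maximal enzyme rate in nM/s, and the sibling reaction uses the
quotient form.

The dimeric species X4 and X5 carry two receptors and two ligands, and the
PLCγ-bound complexes X7/X8 are formed from X5, so three linear moieties are
conserved exactly by the scheme:

* EGFR: `X2 + X3 + 2(X4+X5+X7+X8)` = 100 nM
* PLCγ: `X6 + X7 + X8 + X9 + X10` = 10 nM
* TGFα: `X1 + X3 + 2(X4+X5+X7+X8)` = 9010.55 nM

Runge–Kutta schemes preserve linear first integrals exactly, so these sums
are conserved to roundoff by the fixed-step RK4 integrator regardless of dt;
the test suite asserts 1e-6 relative over an hour and observes ~1e-13. The
integrator clamps negative overshoot up to 1e-9 nM to zero after each step;
a larger undershoot or a non-finite value raises a stiffness error telling
the caller to reduce dt. Durations must be integer multiples of dt so that
splitting an integration across calls cannot change the result.

Micro-step choice: standalone `integrate_pathway` defaults to dt = 0.01 s.
Inside the simulation loop the default is dt = 0.05 s: the stiffest
linearized rate in the network is ligand binding, k1·X1 ≈ 27 s⁻¹ at the
tabulated X1, which puts dt = 0.05 s well inside the RK4 stability region
(|λ|dt ≈ 1.35) while keeping a 100-step, ~10³-cell run tractable on one CPU
core; both values are config-exposed (`ode.dt_s`).

## The phenotype switch

The decision statistic is the relative ("percentage") rate of change of X9
per agent step: `(X9(t) − X9(t−1h)) / X9(t−1h)` (an absolute-difference mode
is available behind `ode.rate_mode`). Species at exactly zero that grow are
flagged undefined and excluded from cohort averages; an undefined statistic
sends the cell down the proliferative branch. The published threshold
definition is circular — `Avg` averages over "cells switching phenotype",
which is only known after comparing to `Avg` — so it is resolved as: the
cohort is every cell whose cycle clock expires this step, and `Avg` is the
cohort mean. A cell strictly above the mean migrates; ties and below
proliferate (a lone decider therefore always proliferates).

Cell cycle: decisions fire every `cycle.decision_interval` steps (default 12
h — the source material states only "several time steps"). Migratory cells
attempt one Moore-neighborhood move every step; proliferative cells divide
only at decision time; a cell with no free neighbor quiesces and re-enters
decision-making as soon as a neighbor frees. Daughters inherit a copy of the
parent pathway state (reset-to-initial mode behind `daughter_reset`). No
death rule is active by default; the dead phenotype is reserved.

## Tissue scale

The chemoattractant field obeys `∂Y/∂t = D∇²Y − U + S` on the high-res
lattice. None of D, U, S, the boundary condition, or the initial profile is
given in the source material; the defaults, all config-exposed, are:

* `D = 1e-7 cm²/s` — a typical small-protein diffusivity in tissue;
* secretion 0.05 nM/s per cell; linear uptake `U = kᵤ·Y` with
  `kᵤ = 1e-5 s⁻¹` (a placeholder; large enough to matter over days, small
  enough that the piecewise-constant-per-hour uptake map can never drive
  the field negative);
* zero-flux boundaries (a closed tissue slice; Dirichlet-zero available);
* initial profile: a Gaussian TGFα bump with peak 9010.55 nM (the scale of
  the kinetic table's ligand pool), σ = ¼ of the lattice extent, centered at
  a configurable nutrient source. The default source sits off-center
  (fractional position 0.3, 0.3), like a nearby vessel: with the source
  co-located with the tumor the highest signaling rates occur in boxed-in
  interior cells, migration is structurally impossible, and the migratory
  curve stays at zero, contradicting the qualitative behavior the model is
  meant to produce. An offset source drives a gradient across the rim.

Receptor coupling: before each cell's hourly integration, its free-ligand
species is reconciled with the tissue, `X1 ← conversion_factor · Y[node]`
(default factor 1; both sides nM). The captured amount is recorded in the
uptake map and drained from the field smoothly over the following hour of
diffusion. Draining the node instantly was tried and rejected: it leaves
craters one node wide, and the Peaceman–Rachford explicit half-operator
(1 − 2a < 0 at the default a = D·dt/2dx² = 30) oscillates on such data,
producing O(100 nM) negative undershoots. With the smooth drain no shipped
configuration clamps; clamp events remain counted and exposed.

### ADI solver

One step is Peaceman–Rachford: implicit in x / explicit in y with source
`(S−U)·dt/2`, then the transpose. Each implicit half is a bank of constant-
coefficient tridiagonal systems, pre-factorized once and back-substituted
over all rows (the single-system Thomas solver is also exposed, with a
diagonal-dominance warning and zero-pivot error). Zero-flux uses the
mirror-edge (−1, 1) boundary row, making the discrete operator's column sums
zero, so total mass `ΣY·dx²` is conserved to roundoff. The scheme is
unconditionally stable and second-order in space and time; the tests verify
the analytic decay of the fundamental Dirichlet eigenmode to < 1%, and the
~4× error drop under dx-halving. Six 600 s sub-steps advance the field per
agent step. Operator splitting order (diffuse-then-react within each half)
is fixed; alternatives differ at O(dt²).

### Schwarz tiles

The tiled solver mirrors overlapping domain-decomposition formulations used
to parallelize ADI sweeps, expressed hardware-neutrally. Explicit halves are
local and computed globally (no decomposition error). Each implicit
tridiagonal solve is iterated with alternating (Gauss–Seidel) Schwarz
sweeps: every tile, expanded by the overlap, solves its line segments with
Dirichlet end data taken from the current global iterate, and writes back
including overlap. The fixed point satisfies the monolithic tridiagonal
equations, so the tiled step converges to the untiled one; the per-node
error contraction is the tridiagonal decay factor
`μ = ((1+2a) − √((1+2a)²−4a²)) / 2a`, so accuracy improves monotonically
with overlap width and iteration count (asserted on a Gaussian-bump
fixture). A whole-domain tile short-circuits to the monolithic code path,
bitwise.

## Dual-resolution lattice

Published spacings (62.5 μm coarse, 10 μm fine) imply a non-integer nesting
of 6.25; this implementation requires integer nesting and defaults to r = 6
(a 60 μm site), since sub-node alignment of the grids is otherwise
undefined. A coarse site is *dense* when its r×r node block is fully
occupied, *homogeneous* when it and all its Moore neighbors are dense
(4-connectivity behind a flag; lattice-edge sites never qualify), otherwise
*heterogeneous* if occupied. Homogeneous-cluster cells are frozen — no ODE,
no decisions — and deposit as one aggregated source spread uniformly over
the site footprint; they thaw automatically on reclassification. Cluster
maps carry the lattice version and refuse to serve stale occupancies.

## The hourly loop

Fixed sub-step order per simulated hour: deposit sources (including last
hour's receptor captures) → diffusion sub-steps → cluster reclassification →
receptor coupling + batched RK4 for heterogeneous-cluster cells → cohort
threshold → decisions and actions in a seed-randomized cell order (raster
order would impose a directional artifact) → record. All randomness descends
from one seed sequence split into fixed per-purpose streams (update order,
attraction noise), so runs are bitwise reproducible, replicates are
independent, and adding a consumer cannot perturb existing streams.
Checkpoint/restart is a deep copy of the simulation object; the tests assert
run(100) ≡ run(50)+restart+run(50).

## Synthetic data and what the tests show

No external data are required: the kinetic table supplies all constants, and
fixtures (disc tumors, Gaussian/sine fields, random occupancies) are pure
functions of their spec and seed. The default study conditions are a 120×120
node (1.2 mm) slice, 20×20 coarse sites, a radius-5 disc of proliferative
cells, 100 hourly steps, 10 replicates. The emulation captures the
qualitative phenomenology of glioma growth models of this family — growth from a compact seed, phenotype switching
against a population threshold, a quiescent interior with an active rim,
chemotactic spread toward the source — but not tissue mechanics, cell death,
metabolic coupling of the glucose pool, or calibrated physical rates for
D/U/S, so passing tests certify internal consistency and numerical
correctness, not clinical realism. Under the default seed geometry the
tumor does not pack a fully homogeneous (frozen) core within 100 h; the
homogeneous-cluster machinery is exercised by constructed dense occupancies
in the unit tests. Problem sizes in the shipped tests (10×10-site behavioral
runs, one 20×20-site 100-step run, 128×128 PDE grids) were chosen to keep
the default suite in the minutes range on a single core.

## Known limitations

* Integer lattice nesting only (r = 6 ≠ the published 6.25 ratio).
* D, U, S and the field profile are uncalibrated placeholders; absolute
  population counts and crossing times are therefore not comparable to the
  published figures, only the qualitative shapes are.
* The ODE solver is explicit; pathological kinetic parameters may require a
  much smaller `ode.dt_s` (the integrator fails loudly rather than silently
  losing accuracy).
* 2D only; one cell per node; no mechanics, adhesion or death.
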