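# Methods

This note records the scientific and numerical choices behind mesocell:
the model components, the parameters that matter (with units and
defaults), the reductions used in the bundled models, and what the tests
do and do not demonstrate.

Internal units are **µm / s / µM** throughout; configuration files may
use nM, mM, min, nm, … which are converted at load.  Amounts are carried
as µM·µm³ (≈ 602 molecules per unit), areas as µm² with per-area surface
densities in µM·µm.

## Chemistry: entities, rules, network generation

A species is a connected graph of simple-entity occurrences bonded at
declared binding sites; small molecules carry a single site and at most
one bond.  Identity is structural: two graphs are the same species iff
they are isomorphic respecting node entity names and edge site labels.
The canonical label realizing this is computed by iterative color
refinement followed by exhaustive minimization within refined color
classes — exact at any size, and effectively linear because chemical
complexes are nearly asymmetric (the only repeated constituents in the
bundled models are the two cAMP molecules on PKAR).

Rules are chains of ADD / BIND / REMOVE / RELEASE reactors with a closed
predicate set (has-part, lacks-part, site-free, site-occupied,
count-of-part), each predicate targeting either the primary reactant or
the BIND partner.  RELEASE terminates a chain.  Automatic binding-site
assignment succeeds only when exactly one declared site matches the
operand pair; ambiguity is an error, never a guess.  Network generation
iterates rule application over a growing pool to a fixpoint,
deduplicating species by canonical label and reactions by (substrates,
products, law, constants); complexes growing past `max_complex_size`
(default 16) raise a divergence error naming the offending rule, which
catches unbounded polymerization.

## Space and compartments

The simulation space is a pseudo-3D slice: an n×m grid of spacing Δs
with fixed height (default 1 µm; interior volume per point Δs²·height).
Raster images define the layout — one pixel per grid point, one region
per color; boundaries between differently colored areas become membrane
faces which block diffusive flux and may carry surface compartments
(face area = Δs², segment length times the grid step).  Membrane
species are per-area densities; conversions to interior concentrations
use the explicit area/volume factors at the interface.  Grid indices are
(row, col) with pixel (0,0) top-left; cell (i, j) owns
[jΔs,(j+1)Δs)×[iΔs,(i+1)Δs) in physical (x, y).

## Diffusion with restriction

The five-point stencil applies each neighbor's restriction coefficient
to its exchange term, exactly as the update rule is defined — not a
symmetric face mean.  Two consequences are documented and tested:

* Within a uniform-restriction region (and on unrestricted grids) the
  scheme conserves total amount to machine precision; across an
  interface of unequal nonzero restriction it is asymmetric — the
  outermost cells of a restricted region exchange with the open side at
  the open side's rate, and it is their own low r that attenuates flux
  onward.  A restricted region therefore shields points one-to-few cells
  deeper than its color boundary; the compartmentalization model makes
  this explicit by splitting its restricted block into a boundary shell
  and the measured core.
* A face bordering a fully non-diffusible point (r = 0) is closed in
  both directions, realizing the non-diffusible set exactly; membranes
  close faces regardless of r.

## Adaptive stepping and error control

Each module is advanced with the embedded Euler/midpoint pair
Δ¹ = Δt·f(t,c), Δ² = Δt·f(t+Δt/2, c+Δ¹/2); the accepted update uses Δ².
The per-module local error is ε = log₁₀(|Δ¹−Δ²|/|Δ²|), maximized over
the entities and grid points the module touches.  Note the formula
compares the *difference* of the two approximations to the midpoint
delta: written as a plain ratio of the deltas the expression could not
reproduce its own calibration (5 % error ↔ threshold log₁₀(0.05),
divergence mapping to positive values), so the difference form is used
and stated here once.  For a reaction, every participant shares the same
relative error (stoichiometry cancels), which the vectorized reaction
group exploits; semantics are identical to one module per reaction and
tested as such.

Controller policy, per candidate step: if any module exceeds τ_local the
step is halved, the interrupting module is refined until it passes, and
all modules rerun; if every relative error is below θ_local·10^τ_local
(linear-space scaling: 0.5 · 5 % = 2.5 %) the next step doubles, capped
at dt_max.  Negative concentrations reject the step (no clamping — that
would silently destroy conservation; a 1e-15 µM tolerance absorbs
round-off dust).  A deliberate refinement beyond the basic scheme:
after a rejection, increases are suppressed for `increase_cooldown`
(default 20) steps, which removes the accept/double/reject thrash that
otherwise wastes ~half of all attempts at stability-limited steps.

The total-error pass bounds module coupling: the summed delta defines a
half-step scaffold state, all modules are re-evaluated there, and the
deviation between the full-step and scaffold-based results — relative to
the resulting **concentration** — must stay below 10^τ_total.  Measuring
relative to the net delta instead is unusable: near equilibria the net
rate vanishes while module cross-terms do not, and the step collapses in
proportion to the distance from equilibrium (observed, and the reason
for this choice).  When the pass runs, the scaffold-based result is the
accepted update, which integrates inter-module coupling at second order.
The pass is skipped while its error is below the negligibility threshold
ν — read as a linear relative error, default 10^τ_total/10⁴ ≈ 5·10⁻⁶ —
re-armed by any step increase or after `backup_interval` (default 100)
steps.

Deltas below an absolute negligibility floor are not error-scored
(default 10⁻⁶ µM per step; the gridded models use 10⁻⁵ µM).  Without a
floor, far-field cells whose concentrations change by picomolar amounts
per step dominate the relative-error maximum and pin the step several
fold below what every observable requires; the floor expresses the
resolution below which changes are not physically meaningful.  All
scored deltas still satisfy the 5 % bound on every accepted step
(machine-checked in the tests).

Convergence order is 2 on smooth problems (estimated by successive step
halving, log₂ of the error-difference ratio); the controller is fully
deterministic for fixed configuration.

## Agents

Vesicles are discs with r < Δs, carrying membrane (per-area) and cargo
(per-volume) pools.  Spatial indexing assigns each vesicle its
perimeter-overlap fraction per grid cell — computed exactly by
partitioning the circle at every grid-line crossing angle and
classifying each arc at its midpoint (fractions sum to 1; validated
against a perimeter-sampling oracle).  Collisions use the discard
policy: a move that would overlap another vesicle (only local partners
are tested, via the cell index), cross a membrane face or barrier
polygon boundary, or leave the domain keeps the old position.
Displacement control: D(a) = log₁₀(‖Δp‖/d_ref) with d_ref = Δs/4
requests a step decrease above θ⁺ = 0 and allows increase below
θ⁻ = −1.  Polygon containment uses the even-odd rule with the
documented tie rule that boundary points count as inside.  Vesicle
Brownian motion is Δp = √(2·D_v·Δt)·ξ per coordinate (the Δt factor is
required for the ensemble MSD to equal 4·D_v·Δt at any step size — the
only dimensionally consistent reading).  Motor transport advances
v_m·Δt along the filament toward the designated end, rolling over
vertices and detaching at the end; the post-scission actin boost moves
orthogonal to the spawning membrane at v_b·c(clathrin).  Chance state
changes fire with p = f·Δt and request a smaller step if f·Δt > 1.

Endocytotic pits spawn as a Poisson process (rate k_p × membrane area),
absorb cargo from their face at k_c = c_cat/(c_cat+c_inh)·k_b — never
more than is present — and either abort at the deadline t_cp (returning
every collected molecule) or, having reached the required nascent-
vesicle density c_cp, mature for t_m and scission into a coated vesicle.
Fusion requires ≥ n_p Q/R-SNARE pairs (counts = ⌊density × area × 602⌋)
within the attachment distance d_a, runs for t_f, then merges membrane
species into the target face and cargo into the cis-side interior
compartment; amounts are conserved exactly.  Membrane cargo carries a
lateral-diffusion module (D = 0.05 µm²/s, standard membrane-protein
mobility); without lateral mobility a pit could only drain the single
face it sits on, which holds less than one vesicle's worth of cargo.

All randomness derives from the single run seed through named
substreams (Brownian, pits, chance), so modules can be toggled without
perturbing each other and reruns are bit-identical.

## The bundled PKA/AQP2 models

**Phosphorylation model** (well-mixed, 300 s).  The signalosome rule set
generates 39 species and 114 reactions: PKAR (anchored to AKAP18δ)
binds two cAMP at sites A and B and releases PKAC only when both are
occupied; free PKAC phosphorylates PKAR (weakening PKAC rebinding — the
positive feedback), AQP2-S256, and PDE4-S54 (tripling its cAMP
hydrolysis — the negative feedback); PP2B reverses all three.
Substrate phosphorylation is two-step (bind, then phosphorylate-and-
release) so substrates competitively trap free PKAC.  Hydrolysis is
elementary: PDE4 binds cAMP, converts it to AMP, releases it.  Printed
anchors: influx 50 nM/s basal and 200 nM/s stimulating; cAMP–PKAR
binding 0.07 µM⁻¹s⁻¹.  The remaining constants are physiological
placeholders (flagged in the shipped configs); the PP2B binding rate
(0.048 µM⁻¹s⁻¹) was calibrated once so the basal fixed point sits at the
documented basal S256 phospho-ratio of 0.46, and PP2B activity is a
direct rate parameter standing in for its calcium/calmodulin control,
which is not modeled.  PKA activity is reported as the free-PKAC
fraction of total PKAC (of the two plausible readings — free fraction
vs. substrate flux — the free fraction is implemented).

**Compartmentalization model** (30×30 grid, Δs = 1 µm, 300 s).  cAMP
(D = 32 µm²/s, scaled inside the storage region by the permeability
coefficient) enters at four basolateral nodes and is hydrolyzed by PDE4
(0.5 µM, k_cat = 6 s⁻¹, k_m = 2 µM, Michaelis–Menten — the one place the
config requests it; the quasi-steady-state diagnostic is reported)
pinned in the storage core.  The restricted block is 10 cells wide with
a 3-cell boundary shell around the measured core (see the stencil
section for why the shell, not the color boundary, is the barrier).
The hydrolysis strength was fixed once against the model's own paired
claims: with permeability 0.01 the cytosol/core fold ratio exceeds 10 at
300 s, while at permeability 1.0 the same sink leaves the field near
uniform (fold ≈ 1.2).  An optional membrane ring with evenly spaced
passages reproduces the barrier variants.

**Endocytosis model** (1 µm² apical patch = 100 faces at Δs = 0.1 µm,
with the CSK/SRC arm added to the network: 45 species, 122 reactions).
The patch membrane carries 5 µM·µm AQP2 (≈ 3000 molecules); pits spawn
at k_p = 0.2 s⁻¹µm⁻², collect at k_b = 1 s⁻¹ scaled by the
active/inhibited SRC balance, with t_cp = 30 s, c_cp = 5 µM·µm
(≈ 95 molecules on an r = 50 nm vesicle), t_m = 30 s.  PKA activation
phosphorylates CSK-S364; active CSK phosphorylates SRC-Y527 (inhibiting
it); reactivation is first-order (0.05 s⁻¹) with the phosphatase pool
folded into the rate.  Sweeping cAMP influx (20/100/400 nM/s) moves the
mean inhibited-SRC fraction from ~0.02 to ~0.7 and the productive pit
count monotonically down; pit lifetimes are bimodal (abortive at the
deadline, productive at collection + maturation).

**Full recycling model** (12×12 µm section, Δs = 1 µm, desk scale).
Storage block (permeability 0.01) with five AQP2 vesicles
(r = 0.3 µm, 5 µM·µm AQP2, 1 µM·µm R-SNARE), actin filaments to the
apical membrane (top row of faces, Q-SNAREs present), microtubules back,
and the printed stepped influx at four basolateral nodes (400 nM/s for
5 min, 200 nM/s to minute 15, 50 nM/s after; scaled-down runs shorten
the horizon, not the rates).  Two reductions keep the desk-scale model
tractable and exactly conservative: (1) the signalosome chemistry runs
as one well-mixed pool anchored in the storage region, exchanging cAMP
with each storage grid cell through a first-order, amount-conserving
equilibration module (k = 5 s⁻¹); (2) each vesicle's AQP2-S256
phospho-ratio follows pseudo-first-order kinetics
dρ/dt = k_p(1−ρ) − k_dρ with k_p = 0.75·k_bind·c(PKAC_free) and
k_d = ⅔·k_PP2B·c(PP2B_free) — the same productive-branch ratios as the
generated network — so AQP2 amounts live only on vesicles, membrane and
pits and are conserved to round-off through transport, fusion and
endocytosis.  Vesicles depart storage when ρ ≥ 0.75 (the stated
trigger, starting from the basal 0.46), ride actin to the apical
membrane, and fuse; each fusion appears as one discrete jump in the
permeability trace (a configurable linear factor, default 0.04 per
µM·µm of membrane AQP2, standing in for the full AQP2→water-permeability
conversion).  The recycling variant raises CSK/SRC dephosphorylation to
1 s⁻¹, reactivating SRC so productive pits resume and AQP2 returns
toward storage on microtubules; the activation variant keeps endocytosis
suppressed and the permeability elevated.

## What the tests show — and what they do not

Test problem sizes (chosen once as desk-scale study conditions): stiff
controller check at k = 1000 s⁻¹ over 0.05 s; diffusion recovery on a
41×41 grid over 0.8 s; 10⁴ Brownian steps at Δt = 0.1 s; phosphorylation
runs of 300 s; compartmentalization at 30×30 for 300 s; endocytosis
sweeps of 120 s; full-model variants of 150 s.  The full-resolution
40-minute recycling runs of the original study (≈ 100 CPU-hours) are out
of scope; the desk-scale variants reproduce the qualitative sequence
(activation, departure, fusion jumps, SRC-gated endocytosis) but not its
absolute timing, and several kinetic constants are placeholders rather
than measurements — conclusions about real renal principal cells should
rest on the printed anchors (diffusivities, influx program, thresholds)
and on the model structure, not on the placeholder values.  The
synthetic layouts (uniform grids, rectangular storage blocks, straight
filaments) exercise every code path but idealize real geometry; the
filament generator is a fixed-path stand-in, not a cytoskeleton growth
model.  Michaelis–Menten validity warnings are reported, not enforced.

## Known limitations

* The restriction stencil's interface asymmetry (above) means the
  effective barrier sits inside the restricted region; layouts thinner
  than ~3 cells restrict much less than their r suggests.
* The relative-error controller makes diffusion cost scale with the
  stiffest local mode (dt ≈ 2·10^τ/λ_max); long gridded runs are
  minutes, not seconds — inherent to the method, which trades speed for
  a per-step certified error bound.
* One membrane chain per model is assumed for lateral cargo diffusion
  (chain-ordered faces); branched membranes would need an adjacency-
  aware operator.
* Vesicle collision handling is discard-only (the variant the original
  comparison found equivalent in sparse settings); dense vesicle packing
  would be poorly served.
* No stochastic chemistry: reactions are deterministic mass action;
  copy-number noise matters only through the discrete agent layer
  (pits, fusion, state changes).
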