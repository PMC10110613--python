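# Methods

`woundsim` simulates the closure of a wound in an epithelial monolayer at
cellular resolution: each cell is an elastic continuum body, cells interact
across nanometre-scale junctions through cohesive traction–separation laws,
cells adhere to a rigid substrate through a second cohesive law, and closure
is driven by lamellipodial protrusion tractions at the wound edge.  The
coupled system is advanced with damped explicit dynamics (dynamic
relaxation).  This note records the model, its parameters, and the design
choices made where the physics or the numerics were genuinely open.

## Geometry

The monolayer is a square sheet (default 400 μm) of polygonal cells obtained
by Voronoi tessellation of `N = floor(L² / (π (d/2)²))` seed points
(d = 26 μm mean cell diameter → N = 301 at full scale).  Seeds are drawn
uniformly and relaxed with three Lloyd (centroidal Voronoi) iterations:
uniformly random tessellations have a broad cell-size distribution, while a
real epithelium — and the model sheet we emulate — is near-equiareal.  Each
polygon is offset inward by half the junction gap (10 nm) with a mitred
offset, so every shared Voronoi ridge becomes a pair of parallel opposing
faces 10 nm apart.  Polygon edges shorter than 2% of the cell diameter are
merged during the offset (the mitre fill is accepted only if it stays within
twice that length of the removed edge): near-degenerate Voronoi edges would
otherwise force a vanishing explicit time step without affecting the
physics.

A wound of target footprint area `A_w` is created by removing whole cells
nearest the domain centre, greedily by centroid distance with ties broken by
cell id, until the removed footprint first reaches `A_w`; the achieved area
(union of removed footprints) is recorded and always meets or exceeds the
target.

Cells are fan-triangulated about their centroid (added as a node) and
extruded through the thickness (default 10 μm — the midpoint of the 3–15 μm
range reported for epithelial monolayers; the exact value is otherwise
unconstrained) into one layer of 6-node wedge elements.  The substrate top
surface is z = 0; the monolayer bottom sits at the cell–substrate
equilibrium separation (1 nm).  Cells do not share nodes: all coupling is
through the interface laws.

## Bulk elasticity

Cells are isotropic St. Venant–Kirchhoff solids: S = λ tr(E) I + 2μ E with
E = ½(FᵀF − I), P = F S, parameterised by E = 0.2 kPa and ν = 0.45
(soft, nearly incompressible epithelial cytoplasm) and density
ρ = 2×10⁻³ ng/μm³.  The law is the minimal finite-strain extension of
linear elasticity, consistent with an internal virtual work written in
first Piola–Kirchhoff stress.  Element quadrature is a 3-point triangle
rule × 2-point Gauss through the thickness.  Units are μm–ng–ms, in which
force is pN and stress is Pa (1 nN/μm² = 1 kPa).

St. Venant–Kirchhoff material offers no barrier to element inversion; under
the strong protrusion loading individual wedge elements can invert
transiently.  The dynamics remain finite, so the solver continues and
inverted elements are excluded from stress summaries.

## Cohesive interfaces

Both interface families use the same piecewise law family: a normal law
with an exponential rising branch up to the critical separation δ_d (peaking
at the strength σ), a power-law softening branch to the cutoff δ_f, zero
beyond; repulsive below the equilibrium separation δ₀ (the rising branch is
evaluated as printed, with no cap on the repulsion — the time step control
absorbs it); and an odd tangential law with a Gaussian-type rise to the
critical slip and a signed power-law decay to its cutoff.

Defaults (cell–cell / cell–substrate): strengths 2 nN/μm² / 5 Pa; δ₀ 10 nm /
1 nm; critical separations 1 μm / 25 nm; cutoffs 2 μm / 60 nm; all shape
exponents 1.

Discretisation: of each opposing face pair, the lower-id cell's face is the
master.  Tractions are evaluated at 6 quadrature points of the slave face
(3-point rule on each fan triangle of the quad) and applied equal and
opposite through closest-point anchor weights on the master face, which
preserves global force balance exactly.  The normal separation is the
projection of the quadrature-point-to-anchor vector on the master face
normal; the slip is its in-plane complement.  Three robustness rules:

- **Interaction gate.** A quadrature point interacts only while its total
  separation from its master anchor is below the normal cutoff δ_fn.
  Obliquely paired faces otherwise read metre-scale "penetrations" at their
  far quadrature points through the unbounded repulsive branch.
- **Junction remodeling.** The pair list is refreshed every
  `refresh_every` steps (default 25) by a proximity search (opposing
  orientation, any quadrature point within δ_fn).  Surviving pairs keep
  their anchors while the slip is below the tangential critical separation
  δ_dt (elastic junctions); quadrature points whose slip has passed the
  peak are re-anchored at their current closest point — the bonds have
  yielded and re-bind in the new position, i.e. dynamic friction at the
  tangential strength.  Fully persistent anchors make the tissue brittle
  (any sustained shear localises, softens and ruptures whole junction
  rows); re-anchoring everything each refresh makes it liquid (junctional
  tension alone then rearranges the sheet and widens the wound).  The
  slip-threshold rule keeps small perturbations elastic while letting
  cells slide past one another at a bounded resistance, and was selected
  after observing both failure modes.
- **Substrate tangential slip.** The substrate is rigid, flat and fixed.
  Slip measured to the closest point of a flat plane is identically zero,
  so the tangential substrate law is inert during sliding; only the normal
  law loads the cell bottom faces (vertical equilibrium at 1 nm standoff).
  The tangential law is implemented and exercised in tests but does not
  resist migration — consistent with focal-adhesion turnover during
  crawling.

## Protrusion loading

Closure is driven by crawling.  Two force systems act, both configured in
nN/μm² (= kPa):

- **Wound edge.** Every cell bordering the gap extends one leading
  lamellipodium: of its gap-bounding free faces, the largest carries a
  traction (default 2 nN/μm²) along the face's in-plane outward normal —
  the crawling-front direction, which points toward the wound centre for a
  convex gap (the centroid direction is the fallback and orientation
  check).  The traction acts on the current face area, so a front that
  collapses stops pulling.  Loading one face per cell reflects a single
  lamellipodium and prevents cells surrounded by gap from being pulled
  apart in several directions at once.
- **Tug-of-war bulk.** Every other cell receives, on one randomly chosen
  lateral face, a traction of magnitude Uniform(0, 0.3) nN/μm² in a random
  in-plane direction, resampled every 500 steps from a seeded generator —
  the fluctuating tug-of-war of an active monolayer.

The protrusion magnitudes deserve a note.  The source description of the
lamellipodial drive quotes piconewton *forces*, but the virtual-work
statement integrates the protrusion as a traction over the cell edge
surface, and a total force of a few pN per face is three orders of
magnitude short of the work needed to close any gap against a 0.2 kPa
tissue (≈ E·t·A_w).  Measured lamellipodial traction stresses are of kPa
order, the same scale the junction strengths are quoted in (nN/μm²), so
this package reads the printed numerals as tractions in nN/μm².  With that
reading the edge drive exceeds the minimal closure requirement by roughly
an order of magnitude and closure proceeds.

## Time integration and dynamic relaxation

The semi-discrete equations M ü = F_p + F_cc + F_cs − F_int are integrated
with a damped central-difference (leapfrog) scheme with mass-proportional
damping c; the first step uses a half kick so constant-force trajectories
reproduce the ballistic closed form exactly.  Row-sum lumped masses are
used.  The stable increment is the CFL bound (safety × shortest element
edge / dilatational wave speed, default safety 0.15), further capped at
0.5/c.

Migration at cellular scales is overdamped, and the explicit dynamics is
used purely as a relaxation scheme, so c is chosen automatically as the
largest of three scales: near-critical damping of the stiffest cohesive
interface mode; near-critical damping of the slowest structural mode; and
the value that limits the steady drift of the most strongly driven nodes
(90th percentile of |F_p|/m) to `max_travel_per_refresh` (default 0.5 μm)
per pair-refresh interval, which keeps the cohesive bookkeeping ahead of
the migration.  Trace times are therefore solver-time units, meaningful
relative to one another (e.g. closure time ratios across wound sizes), not
wall-clock biology; mapping to minutes would require matching one reference
closure time.

Boundary conditions: the outer lateral boundary is free in-plane by default
(configurable to clamped).  At the reduced domain sizes used for desk-scale
experiments a clamped wall sits only a couple of cell rows from the wound
and closure stalls at about half the gap area (verified empirically); the
free boundary lets the surrounding tissue feed area toward the wound, as a
much larger monolayer would.  The top surface is free; the bottom is held
only by the substrate law.

## Gap measurement and closure

The gap is measured on the deformed mid-plane cell footprints (mean of the
bottom and top perimeter rings): footprints are dilated by half the
junction gap (sealing the nanometre junction slivers), united, and
subtracted from a neighbourhood of the initial wound; a morphological
opening with radius δ_fn/2 removes voids narrower than the cohesive cutoff
(opposing faces within 2 μm are inside the zipping range and effectively
sealed); the gap is the remaining void overlapping the initial wound
footprint, which may consist of several components as cells bridge the gap.

A run counts as closed when the measured gap falls below 5% of its initial
area or below half a mean cell footprint (≈265 μm² at the default cell
size), whichever is larger.  The absolute floor marks the
crawling-to-purse-string handoff: a remnant smaller than a cell cannot be
filled by cell migration, and in vivo such late-stage gaps close by
actomyosin purse-string contraction, a mechanism this crawling-only model
deliberately omits.  Closure experiments therefore use multi-cell wounds,
for which the floor is a modest fraction of the initial area; a
single-cell wound is degenerate under this definition.  Closure times are
linearly interpolated between trace records.

## Outputs and analysis

Each run records the gap area and a stress summary every `record_every`
steps (default 100): per-cell volume-weighted mean von Mises stress
(σ = J⁻¹PFᵀ averaged per element), the wound-edge versus interior
partition (edge cells are the owners of the currently loaded wound-edge
faces), and volume-weighted means of |σ_xx|, |τ_xy|, |τ_xz| (x, y in-plane,
z through-thickness).  Area-versus-time traces are fitted with a line
(ordinary least squares, full pre-closure window and first half) and an
exponential (regression on log area).  Sweeps over the initial gap area
reuse one tessellation and one bulk-force seed so differences are
attributable to the swept variable; runs that fail to close within the
step budget are censored out of fits with a warning.

## Synthetic-data scope

The generator produces idealised monolayers: convex, near-equiareal Voronoi
cells, a single central wound, homogeneous material and interface
parameters, no cell division, no purse-string cable, no chemical signalling
and no substrate compliance.  Passing tests therefore demonstrate the
mechanical closure behaviour of this idealised system — stress
concentration at the wound edge, the gap-size and protrusion-strength
trends — not quantitative agreement with any particular wound-healing
experiment.

## Desk-scale experiment sizes

The closure experiments in the test suite run a reduced 160 μm domain
(~48 cells), with wound targets of 500–2150 μm² removing one to four whole
cells so the achieved gap areas are strictly increasing across the sweep.
At this size the free outer boundary sits two to three cell rows from the
wound and can feed area inward before the tissue jams; each run completes
in roughly one to two minutes.

## Known limitations

- The closure kinetics are two-phase: a fast elastic advance of the first
  cell fronts, then a slow creep as the stretched fronts approach the
  stretch at which the St. Venant-Kirchhoff resistance balances the
  protrusion (λ ≈ 3 at the default drive).  The area-versus-time trace is
  therefore only roughly linear, and linear-fit R² over the early window
  typically falls short of 0.9.
- On domains much larger than the wound (wound below ~3% of the sheet
  area) the collective inward flow jams before the purse-string floor is
  reached and runs are censored; the working regime of the desk-scale
  experiments has the wound at 3–8% of the sheet.
- The drive/stiffness ratio (protrusion ≈ junction strength ≈ 10× E) makes
  the late stage of closure rough: cells deform strongly, elements can
  invert transiently, and gap traces are not strictly monotone between
  records.
- Stress localisation at the wound edge holds at the onset of closure;
  once the first fronts have advanced, the collective drag loads the bulk
  and the heavily stretched former fronts (reclassified as interior once
  their faces pair), and the edge/interior contrast fades or inverts.
- Quantities reported as stresses degrade in accuracy inside heavily
  distorted or inverted elements; summaries exclude inverted elements.
- Closure below the purse-string floor is not resolved.
- The substrate is rigid; durotaxis, substrate compliance and traction
  patterning are out of scope.
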