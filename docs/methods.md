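# Methods

This note documents the model implemented in `woundvertex`, the numerical
choices behind it, what the built-in tissue generator does and does not
emulate, and the known limitations of the dynamics.  Units are {nN, µm, s}
throughout; rates quoted per hour are converted at load time
(`ModelParams` accepts suffixed strings such as `"4/hr"` or `"2uN"`).

## Tissue mechanics

The monolayer is a shared-vertex polygonal complex.  The working energy
per cell is the completed-square vertex-model form

    E_i = K (A_i − A0)² + Γ (P_i − P0)²,

equivalent (up to the constant Γ P0² per cell) to the expanded form
K(A−A0)² + Γ P² + γ P with interfacial tension γ = −2 Γ P0; the package
exposes γ read-only and uses the completed-square form so that the
preferred perimeter — and hence the shape index p0 = P0/√A0 that controls
tissue rigidity — is an explicit parameter.  Forces are the exact analytic
gradient of the total energy (verified against central finite differences
at 1e-5 relative tolerance in the tests).  The outer tissue boundary is
free: boundary edges carry the same perimeter energy as interior edges and
no extra line tension.

Edges are adaptively refined each step: edges longer than L_max = 2 µm are
split at their midpoint (area-preserving), and two-valent vertices on
edges shorter than L_min = 0.5 µm are merged away, choosing the most
collinear removable endpoint so the boundary shape is preserved;
tri-cellular junctions are never removed.  The bounds straddle the T1
threshold L* = 1 µm and the substrate node spacing (≈1.39 µm), which keeps
focal adhesions evenly spread along cell boundaries.

**T1 neighbour exchanges.**  Because refinement subdivides interfaces, the
"edge" of the T1 rule is the whole junction-to-junction cell–cell
interface.  When an interface's total length drops below L*, its chain
midpoints are merged and the junction pair is offered a flip: the edge is
replaced by a perpendicular contact of the same length about the same
midpoint, the four surrounding cells are reconnected, and the junction
pair is locally relaxed (L-BFGS on the two vertices over the four affected
cells' energy plus their adhesion springs).  The flip is kept only if the
relaxed flipped state has strictly lower total mechanical energy than the
relaxed unflipped state; ties are rejected, and junctions of valence
other than three are never flipped.  Comparing *relaxed* states matters: at
frozen positions, rotating a ~1 µm edge always costs energy and no flip
would ever fire.  A configuration switch (`t1_enabled`) disables
intercalations without touching anything else.

The reported T1 rate counts interior flips plus wound-border edge
collapses: when a border edge between two junctions shrinks to zero
(operationally < L_min/4), its endpoints are merged and the border loop is
re-closed — the boundary form of a neighbour exchange, in which a cell is
squeezed off the leading edge.

## Substrate and adhesions

The substrate is a triangular lattice of Hookean springs with spacing set
by the node density ρ (a = √(2/(√3 ρ)) ≈ 1.39 µm at ρ = 0.6 µm⁻²) and
spring constant k_s = √3 E_s h_s/2, which gives the lattice a continuum
Young's modulus E_s and Poisson ratio 1/3.  `measure_moduli` verifies this
by a uniaxial-stress test of a 180×36 µm strip (force transmitted across
the mid-section; transverse strain in the middle third; both measured away
from the gripped ends): E is recovered within 1% and ν within 1.5%.  The
mesh covers the tissue bounding box plus a 20 µm margin whose outermost
node ring is pinned.  Free nodes move overdamped at F/µ, reusing the
per-vertex friction µ (the single friction scale of the model).

Each vertex carries at most one focal adhesion: a spring of stiffness k_f
to a substrate node, whose rest extension is the separation recorded at
binding.  Binding and unbinding are evaluated once per step from the
states at the *start* of the step, so the stationary bound fraction is the
two-state Markov duty ratio k_on/(k_on+k_off) = 0.952 at defaults (a
sequential update, in which a freshly detached vertex may rebind within
the same step, measurably inflates this).  Unbound vertices bind the
nearest node within a capture radius of two lattice spacings; unbound
border vertices of crawling cells bind protrusively, to the node nearest
x + δ v̂ with δ one lattice spacing.  The optional catch bond replaces the
constant k_off by the two-pathway law k0 e^(−f/f0) + k1 e^(+f/f1) (the
second exponent is positive — a bond that strengthens under moderate load;
the sign switch `catch_sign=-1` recovers a pure slip bond, and both forms
reduce to k0+k1 at zero force).  With the catch bond disabled and
identical seeds, trajectories are bitwise identical to constant-rate mode
because each stochastic subsystem draws from its own stream.

## Motility

Bulk cells carry polarity angles undergoing rotational diffusion
(variance 2 D_r Δt per step); a vertex feels the average of µ v0 p̂ over
its adjacent bulk cells, so an isolated bulk vertex drifts at v0.
Wound-border cells either crawl or contract.  A crawling cell's protrusion
direction bisects the angle subtended at its centroid by the two end
vertices of its contiguous wound-border run, oriented into the gap —
contact inhibition of locomotion: the cell protrudes into free space, not
into its neighbours.  The protrusion force f_p acts on unbound border
vertices only (`f_p (1−σ) v̂`) and has finite reach: attachment occurs by
protruding into the nearest substrate node, so the force stalls once the
vertex has advanced one lattice spacing beyond its detachment point, until
it rebinds.  Purse-string cells instead add a line tension γ_ps to their
wound-border edges.  Crawl→purse-string conversion is stochastic at rate
k_p and irreversible; the curvature-sensing variant instead reassigns
modes every step by comparing the signed local border curvature (inverse
circumradius of the border run's endpoints and midpoint, positive where
the wound is convex) against a threshold κ*.  κ* defaults to 0.05 µm⁻¹,
the order of the initial border curvature, and should be tuned per wound
shape (the closure-time-minimising threshold is shape dependent).

## Engine

Each step executes, in fixed order: adhesion kinetics; edge refinement and
border-edge collapse; wound-front fusion and sealing; T1 scan; mode
update; motion.  Motion is explicit forward Euler at Δt = 3.6 s with two
safeguards:

- **Sub-stepping.**  If any vertex would move further than L_min in one
  update (routine for protruding vertices, f_p Δt/µ = 1 µm, and for
  transiently sharp purse-string corners) the motion update is subdivided
  with force recomputation; this converges to the same overdamped dynamics
  and replaces a hard stability error, which would otherwise reject the
  default parameter set.  Substrate nodes advance once per step (their
  relaxation time µ/k_s ≈ 400 s is far slower than the sub-steps).
- **Contact handling.**  Opposing wound fronts have no excluded volume in
  a vertex model, so border vertices are speed-capped to at most 45% of
  their distance to the nearest non-neighbouring border vertex per step
  (both sides can approach geometrically but never cross), and vertices
  that come within L_min of each other across the gap fuse, pinching the
  wound loop in two.  Residual loops whose area falls below the closure
  threshold are sealed into a rosette.  Open wound area is the shoelace
  area summed over negatively-oriented border loops (a positively-oriented
  loop marks transient front overlap, not open wound).

Closure is declared when the total open area drops below A_close = 1 µm²
(or no border loop remains); runs hitting t_max (5 h default) are reported
censored.  A run is bitwise reproducible from (parameters, seed).

## Traction reconstruction and metrics

Substrate displacements are interpolated (piecewise linear on the node
triangulation) to a 2 µm square grid; strain is the symmetric gradient by
central differences; stress follows the thin-sheet (plane-stress)
isotropic law with E_s and ν = 1/3 — σ = (3/4)E_s ε + (3/8)E_s tr(ε) δ —
whose dilatational coefficient is the triangular lattice's true continuum
value (the plane-strain form, available as `law="plane_strain"`, doubles
it and measurably degrades agreement with the direct spring-force
readout).  The cell-applied traction balances the sheet-stress divergence,
T = −h_s ∇·σ, and the strain-energy density is U = ε:σ/2; the mean strain
energy is the time average of ∫ h_s U dA.  The independent cross-check —
net spring force per node over the area per node, with pinned-boundary
reactions masked — agrees with the grid pipeline to ~15% on smooth loads.
On live snapshots the adhesion loads are single-node point forces whose
displacement spikes lie below the grid resolution, so the grid field is a
faithful but ~2× amplitude-attenuated, smoothed version of the discrete
one; radially binned profiles agree in sign and shape.  For sign-sensitive
questions (e.g. when the border traction flips inward) the package also
provides `border_radial_load`, the exact net radial adhesion force under
the first row of cells.

Motion metrics use cell-centroid velocities over a configurable snapshot
baseline (`stride`); adhesion turnover puts uncorrelated jitter on single
60 s intervals, and a few-minute baseline recovers the coherent motion.
The effective friction µ_eff = ⟨F_r/v_r⟩ uses the median over snapshots
(the ratio is heavy-tailed when the border velocity passes through zero).
Guidance G is the fraction of velocity samples within ±π/2 of the
direction to the initial wound centre; C_vv(r) is the pair-binned
normalised velocity correlation with the decay length read off at 1/e
(sparse bins below the centroid spacing are skipped).

## The tissue generator

`generate_tissue` builds either a honeycomb (triangular-lattice seeds →
regular hexagons, shape index 3.7224) or a Lloyd-relaxed Voronoi
tessellation with mean cell area A0, then relaxes it to an energy
minimum.  `make_wound` removes every cell wholly or partly inside the
target outline (circle; ellipse of fixed area and variable aspect;
concave multi-lobed family R(φ) = R0(1 + a cos mφ) at fixed area),
projects the border vertices onto the outline, relaxes the tissue with
the border constrained to it, and sets border cells to crawl mode.  The
generator reproduces the study conditions (150 cells, 100 µm² cells,
15 µm circular wound by default) but not features of real monolayers such
as cell-size polydispersity beyond Voronoi disorder, division/death,
heterogeneous mechanics, or three-dimensional geometry — so passing tests
demonstrate properties of the model, not of MDCK monolayers.

## Problem sizes

The test suite runs scaled-down studies — 45–60 cells, 7–10 µm wounds,
3–4 fixed stochastic seeds, a 3 h simulated-time cap — so the whole suite
completes in minutes on one CPU; the acceptance script runs the
single-cell calibration at full scale and one default-sized (150-cell,
15 µm) closure to 30% of the initial wound area for the velocity
correlation.  Fixed seeds make every stochastic assertion deterministic.

## Known limitations

The equations of motion are integrated literally: explicit overdamped
Euler steps for every vertex.  The original study of this model family
ran quasi-static energy minimisation between kinetic events, and the two
schemes do not agree in the crawling regime: under literal integration an
unbound leading-edge vertex translates at f_p/µ ≈ 1000 µm/hr for its whole
unbound interval (~4.8% of the time at default kinetics), which — even
with the finite protrusion reach — ratchets a single cell forward at
~55–60 µm/hr instead of the calibrated 15 µm/hr, while purse-string
closure speeds are essentially unchanged.  Downstream consequences, all
on the crawling side of the balance:

- absolute closure times are shorter than published, and crawling-driven
  closure outpaces the mixed mode at the default wound size (the
  published optimum at intermediate k_p is not reproduced there, although
  purse-string-only closure is correctly the slowest);
- the leading edge drifts toward its forward-placed anchors faster than
  bonds turn over, so many front bonds are compressed and the net border
  traction points inward even while crawling — the published
  outward-then-inward traction flip and the negative crawling µ_eff are
  not reproduced;
- velocity fields decorrelate at the cell scale (elastic information
  spreads diffusively under per-vertex friction rather than system-wide
  per step), so the velocity correlation length is ~1 cell diameter
  rather than ~5.

These are properties of the integration scheme, not bugs; the
corresponding end-to-end tests state the published expectations and are
left failing by design, with the passing remainder (energetics, kinetics,
substrate elasticity, coverage kinetics, neighbour-exchange orderings,
curvature–velocity law, geometry dependence of closure) characterising
what the literal dynamics do reproduce.
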