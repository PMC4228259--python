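# Methods

`aneuflow` implements a retrospective aneurysm-hemodynamics workflow on
synthetic vascular geometries: measure the sac, virtually remove it, simulate
pulsatile flow in both the diseased and the repaired ("pre-aneurysm") lumen,
and compare wall shear stress (WSS), its surface gradient (WSSG), pressure,
velocity and the intra-saccular flow-pattern class between the two states.
This note records the models, the numerical choices, and what the synthetic
setting does and does not establish.

## Synthetic vasculature

Patient lumen reconstructions from rotational angiography are not publicly
available, so the study geometry is generated parametrically: a tube of
radius `parent_radius` (default 2 mm, a carotid-scale lumen) and centerline
arc length `parent_length` (30 mm), optionally bent over its central third as
a circular arc of curvature `centerline_curvature` (default 0.05 /mm), with a
spherical sac of radius `sac_radius` (3 mm) attached at mid-length on the
outer wall of the bend. The neck radius (default 1.8 mm) fixes the height of
the sphere centre above the wall via the chord relation; `sac_height_offset`
shifts it further. All lengths are millimetres, matching how aneurysm
morphometry is reported clinically.

The surface is the zero level set of a smooth union (polynomial smooth-min,
fillet scale 0.25·neck_radius) of the exact tube and sphere distance fields,
triangulated by marching cubes at pitch `mesh_edge_target` and then
Newton-projected onto the analytic level set, so vertex positions are exact
up to ~1e-6 mm and the only surface error is chordal. The seed jitters the
sampling lattice origin only: identical spec + seed is byte-reproducible, and
the analytic surface — hence the ground truth — never depends on the seed.
Ground-truth D (max sac diameter), H (height above the neck plane) and N
(neck diameter) come from the *unblended* sphere/plane closed forms; the
fillet perturbs the mesh only near the junction, within the measurement
tolerance used by the tests. The sac is placed on the outer bend because that
is where sidewall aneurysms arise and because a localized bend gives the
pre-aneurysm state a focal high-WSS site; on a straight parent tube the
"formation site versus adjacent artery" comparison would be a tie by
symmetry, telling us nothing.

Constructed intra-saccular velocity fields (for the flow-pattern classifier)
superpose Lamb–Oseen vortices at fixed seeded slots with a tanh-edged inflow
jet band of prescribed width and direction schedule on a 10 mm box. Both
ingredients are divergence-free analytically, and the vortex census and jet
width are known by construction. The slots are kept clear of the fan swept by
the tilted jet; with direction changes enabled this is guaranteed for up to
two concurrent vortices at jet widths ≤ 0.4 (more vortices still classify
correctly as type IV, but the per-step census may undercount a core the jet
overruns).

## Morphometry

The centerline is a maximal-inscribed-sphere path: Dijkstra over the interior
voxel graph weighted by inverse wall clearance squared, then per-point
golden-section maximization of (signed) wall clearance in the plane normal to
the path. The signed clearance (negative outside the lumen) and a tiny
movement penalty keep end points from drifting through the caps; the cap
neighbourhoods, where the nearest surface is the end cap rather than the
wall, are trimmed from the result. On a straight tube the recovered radius is
within 1% and the axis within a few hundredths of a millimetre.

The neck is found by scanning cross-sections perpendicular to the sac axis
(apex direction) from the apex toward the parent: the contour is the
minimal-perimeter section below the sac equator, bisection-refined toward the
tangency because the sac widens like a square root just above it. N is the
area-equivalent circle diameter of the contour's in-plane projection (a
non-circular orifice has no unique diameter); H is measured perpendicular to
the fitted neck plane and D parallel to it, and ratios are displayed at two
decimals, matching clinical reporting. Detection returns "absent" when no
wall region bulges 20% beyond the local lumen radius — the plain-tube and
repaired-vessel cases.

## Surface repair

Excision classifies *vertices*: the sac is the connected component of
above-neck-plane vertices containing the tallest protrusion near the contour.
Faces are cut purely from their vertices' classes, which keeps the cut
conforming even when a slightly tilted measured plane grazes the parent wall
elsewhere. The hole is then grown by two face rings past the junction flare
before filling, so the patch lands on clean parent wall.

Hole filling has three stages: (1) constrained planar triangulation of the
boundary loop with interior points at the local edge length (constraint edges
enforced by cavity re-triangulation, since staircase loops defeat plain
Delaunay); (2) a discrete biharmonic (thin-plate) solve for the patch with
`ring_depth` (default 3) rings of surrounding vertices as context — enough to
sense the local curvature trend without dragging in the far vessel; (3)
deterministic fixed-order normal-offset sweeps that reduce the variance of
the cotangent-weight discrete mean curvature over patch + context, with step
0.05·ℓ², an iteration cap of 150, a 1e-6 mm move tolerance, and best-iterate
tracking (the explicit flow eventually amplifies high-frequency modes; the
sweep stops once the variance objective stalls). Only patch vertices move.
A flat hole refills exactly flat; a cylinder hole refills to 0.03% of the
radius RMS and a spherical cap to 1.8% (the 2% acceptance band); a synthetic
sidewall aneurysm repairs to ~0.5% of the parent radius against the
generator's sac-free twin.

## Flow solver

Blood is incompressible and Newtonian with density 1060 kg/m³ and viscosity
3.5 mPa·s (community-standard constants), walls rigid. The inlet waveform is
a raised cosine between the printed diastolic and systolic Doppler speeds at
the given heart rate — the printed values fix the extremes and period, and
the shape between them is otherwise unconstrained, so the smoothest periodic
choice is used. The profile is parabolic by default (flat available), the
outlet is zero gauge pressure, one cardiac cycle is resolved with 100 steps,
and two cycles are run with the first discarded as transient wash-out.
Reported quantities are taken at peak systole (the waveform argmax, unique by
construction).

Spatial discretization is P1/P1 tetrahedra with the pressure stabilization
obtained by *exact static condensation of the MINI bubble*: the cubic bubble
decouples from the P1 velocities in the viscous term, so it condenses
elementwise into a pressure-Laplacian term with a derived, parameter-free
coefficient τ_T = V_T·(15120/840²)/(μ·Σᵢ|gᵢ|²). Time stepping is monolithic
semi-implicit: advection is integrated explicitly with CFL sub-cycling and
*streamline* artificial viscosity (ν = 0.5·|u|·h along the flow direction
only — it damps the along-stream oscillations of central advection but
vanishes for fully developed flow, so it does not act as extra physical
viscosity); the advected velocity then enters a coupled solve of the
viscous/pressure system whose matrix is constant in time and LU-factorized
once per run. There is no projection splitting error, the steady limit is
independent of the time step, and the discrete divergence constraint holds
at every step, which is what makes per-section flux imbalance stay below 1%.

Two volume meshers feed the solver. For quantitative verification, a
structured body-fitted tube mesh (O-grid disk sections extruded into prisms,
split into tets with a min-vertex diagonal rule) whose nodal pattern repeats
axially — fully developed flow then has no spurious discrete axial gradients.
On it, a steady Re = 100 run reproduces the Poiseuille centerline/mean ratio
within ~1%, the pressure drop within <1%, and WSS within ~1.5%, improving
under refinement. For general aneurysm geometry, a lattice mesher: interior
lattice nodes joined by Kuhn tetrahedra, boundary nodes projected onto the
exact surface, followed by short-edge and sliver collapses (slivers carry
near-singular basis gradients that poison both the CFL limit and the pressure
block). The lattice mesh is first-order at the wall, which is why the
retrospective comparisons on it are interpreted qualitatively (orderings and
ratios), not as patient-grade WSS magnitudes.

WSS is recovered per wall facet from a quadratic fit of the tangential
velocity sampled at two stations along the inward normal (no-slip pins the
fit at zero), which is markedly more accurate than a one-cell gradient on
tets. WSSG is the in-plane P1 gradient magnitude of the vertex-averaged WSS
magnitude — exactly zero for uniform fields, exact for linear ones, frame
invariant. Section statistics sample four evenly spaced angular stations of a
plane's wall intersection (and matching interior points for velocity) and
report mean ± sample (n−1) standard deviation; the "±" convention is stated
because the source material leaves it undefined.

## Flow-pattern taxonomy

The four-type classification combines jet-direction stability with the
vortex census over the cycle: stable direction + one persistent vortex (I);
stable + several persistent (II); direction change + one vortex (III);
direction change + vortex creation/destruction (IV). Vortices are counted as
clusters of Poincaré-index +1 critical cells of the in-plane velocity on a
sac cross-section slice — a stated computational proxy for the visual vortex
reading used clinically. "Direction change" is operationalized as a jet-axis
rotation exceeding 30° between any two steps (configurable; no angle is
printed in the source material). A varying census under a stable jet is
assigned to type IV, count instability being the hallmark of the unstable
family. The inflow jet is the neck-plane band at ≥50% of the peak neck
speed; its width over the transverse diameter of the widest sac
cross-section gives the jet fraction, and the spread of the jet
streamlines' wall-termination footprint over that section's contour length
gives the impaction fraction. "Narrowed" is strictly < 0.5 in both cases.

## Problem sizes

The shipped tests and the acceptance script run at desk scale by design:
verification tubes with 5–6 radial rings (~3–5 k nodes), retrospective runs
at 0.55 mm cells and 50 steps/cycle (~6 k nodes per state). These sizes
leave every oracle comfortably inside its tolerance while keeping the whole
study under a minute per state; refining them tightens the numbers
monotonically (tested at two levels).

## What the synthetic setting shows — and what it does not

Passing oracles establish that the measurement chain is consistent with
closed forms on analytic geometry, that the repair recovers a known parent
vessel, that the solver conserves mass and reproduces Poiseuille/quasi-steady
physics, and that the classifier is exact on fields with known structure.
The synthetic vessels are idealized: circular lumen, single smooth sidewall
sac, rigid walls, Newtonian blood, one inlet and one outlet. Real lumens are
tortuous and non-circular, necks are irregular, and patient WSS magnitudes
depend on geometry we do not have — so the patient-specific numbers printed
in the source study are not reproduction targets here, and the retrospective
comparison is validated at the level of its qualitative findings: WSS falls
from the (distal) neck to the dome at aneurysm status, and the formation
site carries distinctly elevated WSS relative to the adjacent parent artery
at pre-aneurysm status.

## Known limitations

- The lattice volume mesher is first-order at the wall; quantitative WSS on
  it is biased low in the sac where the flow is slow and coarse cells large.
- The classifier's vortex census reads one symmetry-plane slice; fully
  three-dimensional vortex tangles may be undercounted.
- Terminal/bifurcation aneurysms, lobulated sacs, non-Newtonian rheology and
  fluid–structure interaction are out of scope.
- The impaction-zone fraction divides a footprint extent by a contour
  length; a full-width plug jet therefore reads well below 1, and the
  fraction is meaningful mainly for comparisons at fixed geometry.
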