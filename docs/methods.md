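# Methods

## Model and scope

hemovox solves the incompressible Navier–Stokes equations

    ∇·u = 0,    ρ ∂u/∂t + ρ(u·∇)u + ∇P = μ∇²u

for Newtonian blood (defaults ρ = 1060 kg/m³, μ = 0.0035 Pa·s) in a lumen
segmented directly from a 3-D contrast volume. The voxel lattice of the
(ROI-cropped) image is the computational grid; typical angiogram spacing is
0.2–0.3 mm, which the phantoms mirror (0.25 mm default). Vessel walls are
rigid and stationary; rheology is Newtonian; outlets are traction-free.
Fluid–structure interaction, non-Newtonian models, lumped-element outlets
and distributed-memory parallelism are out of scope.

Geometry is carried in millimetres (image convention); the solver converts
to SI metres internally, in one place. Voxel indices are 0-based with voxel
`i` spanning `[i·Δx, (i+1)·Δx)` and cell centers at `(i+½)Δx`.

## Segmentation

Region growing from a user seed accepts face-connected (6-neighbor)
voxels with `I > I0`, optionally also `|I_nb − I_cur| < ΔI_max` on the
accepting edge. Face connectivity is chosen over 26-connectivity because
it cannot leak diagonally through a one-voxel wall. Growth is implemented
as whole-frontier (level-by-level) breadth-first search; since acceptance
depends only on the edge, the result is exactly the set of voxels
reachable from the seed, independent of visitation order — the test suite
verifies set equality with an independent queue-based flood fill.
Disconnected bright structures are never reached: clean-up is implicit.

Openings: per ROI face, masked boundary voxels are grouped into 2-D
4-connected components. The largest patch on the user-named face is the
inflow (several patches on that face trigger a logged warning); every
other patch is an outflow. A voxel lying on two ROI faces belongs to one
patch per face.

## Level-set wall geometry

`φ0 = I − I0` is positive in the lumen with the wall at `φ = 0`. One pass
of the separable 3×3×3 filter (per-axis weights ¼, ½, ¼; nearest-edge
padding) is applied by default before all geometric queries — it is
always-on for solver robustness rather than noise-conditional, with a
config flag to disable. The filter is linear, positivity-preserving, has
unit mass (constants are fixed points exactly), and repeated application
diffuses toward a constant.

Directional wall distances use the local linearization `d_a = φ/(∂φ/∂a)`
(central differences; one-sided at ROI boundaries), placing the wall at
`x_a − d_a`, so `d_a > 0` means the wall lies on the low-index side. A
direction is discarded when the gradient component is below 1e-8 of
`max|φ|/Δ` or the implied wall is beyond 1.5 spacings (a wall farther
than that is not this cell's wall in that direction); a cell with no
usable direction falls back to half a spacing and is logged. The formula
is exact to round-off for affine φ, which is the anchor property the unit
tests pin. With the phantoms' linear intensity ramp (width 2Δx) the
recovered wall radius is sub-voxel accurate (≈0.1 voxel in practice,
bound 0.5 voxel in the acceptance checks). Wall normals are `∇φ/|∇φ|`,
pointing into the lumen; zero-gradient cells are flagged NaN rather than
fabricated. The smoothed φ (not φ0) feeds both distances and normals,
consistently.

## Centerline frame and inflow

Near the inflow opening, the mask centroid of each of the first `depth`
slices (default 4) gives a center point; the tangent is the principal
direction of those points, oriented inward — a least-squares line that
reduces to the two-point difference at depth 2 and is noise-robust at
depth 4. In-plane radii follow by vector rejection `R′ = R − (R·s)s`
(orthogonal to machine precision), and `R′_max` is the discrete rim radius
— no circular cross-section is assumed.

The steady profile is `U0[1 − (|R′|/R′_max)²]s`. Oscillatory modes use the
rigid-tube Womersley solution per harmonic `n`:

    f_n(ξ) = (J0(Λ_n) − J0(Λ_n ξ)) / (J0(Λ_n) − 1),   Λ_n = i^{3/2}·Wo·√n,

normalized so `f_n(0) = 1`: the user-supplied amplitude of each harmonic
is its *centerline velocity* amplitude (the alternative — flow-rate
normalization — is a documented choice away; centerline amplitude keeps
the superposition independent of the opening's discrete area). `f_n(1)=0`
enforces a hard zero at the rim for all times, and the zero-mean carriers
make the period average equal the steady parabola identically. As
`Wo → 0` the mode shape degenerates to the quasi-steady parabola
(verified at Wo = 0.1 to within 1 %). The evaluator uses `scipy.special.jv`
with complex argument; the test oracle is an independently coded power
series.

## Flow solver

Staggered (MAC) arrangement: face-normal velocities, cell-centered
pressure. Per velocity component, each face node is classified FLUID
(both adjacent cells lumen — an unknown), CUT (between lumen and solid),
INFLOW/OUTFLOW (opening faces), or DEAD. Time advancement is a fractional
step:

* **Convection** — second-order central differences, explicit
  Adams–Bashforth-2 (forward Euler on the first step). Fully implicit
  convection would need a nonlinear solve that buys nothing at the
  aneurysm-scale Reynolds numbers targeted here.
* **Viscosity** — Crank–Nicolson; the implicit half is solved per
  component with a cached sparse LU factorization.
* **Pressure** — `∇²P = (ρ/Δt)∇·u*` over lumen cells, homogeneous Neumann
  at walls and inflow, `P = 0` Dirichlet at outflow faces; cached sparse
  LU. A configuration without any outflow is singular and is reported as
  such, not regularized.

**Sharp-interface wall closure.** A stencil leg crossing the wall at
distance `d` from the last fluid node (from the node-interpolated level
set) is closed by the boundary-face velocity

    d < Δ/2 :  U_BC = u_w + (u_near − u_w)(1 − Δ/(2d))
    d ≥ Δ/2 :  U_BC = u_w + (u_near − u_next)(Δ/2 − d)/Δ

(the second form is the mirrored ghost-point average), with `U_BC = u_w`
once `d < 0.05Δ` so the interpolation coefficient stays bounded in the
singular limit; `u_w = 0` for the rigid walls here. Both branches
reproduce any wall-vanishing linear profile exactly and agree at
`d = Δ/2`. Inside the operators the equivalent ghost-node value
`2U_BC − u_near` is folded algebraically into the matrix, so the closure
is implicit in the viscous solve as well. When the second fluid node does
not exist (one-cell-wide passages) the interpolation branch is used for
all `d`; legs whose level-set distance is invalid fall back to a wall on
the staircase face (`d = Δ/2`).

**Continuity at cut cells.** Wall-cut faces carry zero mass flux in the
discrete divergence and the Poisson operator — the wall is impermeable on
the staircase cell volume, while the sub-voxel wall position acts through
the momentum closure. This makes the projection exact: post-step
divergence vanishes at every lumen cell to solver precision, and summing
the divergence shows inflow flux = outflow flux to round-off
(≈1e-16 relative in the benchmarks). The prescribed outflow rescale to
match the inflow flux is kept but its factor is 1 + O(1e-15).

**Outflow.** Zero-gradient velocity is imposed *implicitly* (the outflow
neighbor value in a stencil is the node value itself); a lagged explicit
copy would contaminate the viscous operator with an O(Δt/Δ²) error, which
a diffusion-decay test exposed during development. Stored outflow values
are refreshed by copy for the divergence and output, then corrected by
the `P = 0` Dirichlet gradient in the projection.

**Time step.** Fixed `Δt` if configured; otherwise
`Δt = CFL·min(Δ/|u|_max, ρΔ²/(6μ))` with CFL 0.5, re-evaluated each step
but only re-factorizing the viscous matrices when the step actually
changes (shrink by 0.8 when violated, grow when the allowance doubles).
The viscous bound is an accuracy choice, not a stability requirement
(viscosity is implicit). With a fixed `Δt`, a measured convective CFL
above 1 is an error, reported with the measured value.

**Steady detection.** Relative L2 velocity change per characteristic time
`‖u^{n+1}−u^n‖/‖u^n‖ · T_char/Δt < tol` (default 1e-3), with `T_char`
defaulting to domain extent / inflow speed. Steady runs initialize by
extruding the inflow profile down the domain, which only shortens the
transient. Everything is deterministic: rerunning one configuration
reproduces outputs byte-for-byte.

**Linear solves.** Both the Crank–Nicolson systems and the Poisson system
use cached direct sparse LU factorizations rather than Krylov iteration.
At the grid sizes this package targets (≤ ~10^5 unknowns, static
geometry) a one-time factorization plus cheap triangular solves per step
is faster, has no iteration-count nondeterminism, and reduces the
"Poisson tolerance" to round-off; the configured tolerance is retained as
the reference scale for the divergence contract (post-step divergence
must stay below 10× it, and does by ~5 orders of magnitude).

## Post-processing

Wall pressure is the wall-adjacent cell value (zero normal pressure
gradient at a rigid wall). Velocity gradients at wall-adjacent cells use
the boundary-face velocity over half a spacing wherever a neighbor is
solid, written in the sign-consistent one-sided form
`(u_cell − U_face)/(Δ/2)` on the low side and its mirror on the high side;
with both neighbors solid the difference of the two face values over the
cell width is used; with both fluid, plain central differences. The face
values are rebuilt from cell-centered velocities with the same two-branch
closure the solver uses, so a linear shear field is recovered exactly.
WSS is the tangential traction `μ{∇u·n − ((∇u·n)·n)n}`; tangentiality to
the wall holds by construction and is asserted to 1e-10 relative on every
solver test. WSS lives on wall-adjacent cells; projection onto the wall
surface is a display-time operation with no effect on metrics.

Metrics: `τ* = |τ_w|/(ρU0²)` — dynamic-pressure normalization, the choice
under which physiological WSS magnitudes at U0 = 0.5 m/s land in the
0.001–0.1 range typical of normalized aneurysm-wall statistics; exposed
as a config option. "Variation" is the population standard deviation
(variance is a one-line switch). The aneurysm region must be supplied
explicitly — a phantom truth predicate, an index box, or a label volume;
no automatic ostium detection is attempted. The parent vessel diameter
for SR defaults to `2·R′_max` of the inflow rim (a mean-radius estimate
underestimates the diameter of a filled disc by a factor 2/3 and is not
used); it can be overridden.

## Phantoms: what they emulate, what they do not

Phantoms produce a bright lumen (default 1000) over a dark background
(default 0) with a clamped-linear intensity ramp of configurable width at
the wall (default 2 voxels) and optional i.i.d. Gaussian noise from a
seeded generator. The half-intensity level (I0 = 500, the package's
default operating threshold) lies exactly on the analytic surface, and
the linear ramp makes the sub-voxel wall position recoverable by linear
interpolation — deliberately matching the level-set scheme's assumptions.
Geometries: straight tube (arbitrary axis), torus-segment tube with
straight tangential extensions, tube + spherical sidewall sac (with an
analytic aneurysm-region predicate and a locally-planar-wall cap formula
for the union volume), and two disconnected vessels with component
labels.

They do **not** emulate X-ray physics (beam hardening, scatter), contrast
inhomogeneity along the vessel, patient motion, tapered or elliptical
lumina, or wall motion. Passing tests therefore demonstrate correctness
of the *algorithms* under the stated image model, not robustness to every
clinical artifact; the threshold choice on real angiograms remains an
expert decision.

## Verification problem sizes

The routine verification uses sizes chosen to run on one core in minutes:
Poiseuille regression in a tube of radius 10 voxels, length 40 voxels
(Δx = 0.25 mm, U0 = 0.01 m/s, Re_D ≈ 60); grid refinement of one 2 mm
tube at radii 6 and 12 voxels (observed L2 order ≈ 1.7 against the
nominal 2, wall cells degrading it locally); diffusion decay between
walls offset 0.3 voxel into the solid cells (rate within 0.5 % of
`exp(−νk²t)` with k from the *true* gap — the sub-voxel wall property in
isolation); and a sidewall-aneurysm pipeline run to steady state
(~36×40×40 voxels). A steady plane-channel benchmark is not included
because the voxel-opening boundary model has no lateral
symmetry/periodic condition; the offset-wall decay test exercises the
same sub-grid wall accuracy.

## Known limitations

* Observed convergence is between first and second order near walls; the
  ghost closure is linear-exact, so curvature of the velocity profile at
  the wall enters at O(Δ²) locally but cut-cell continuity is staircase.
* The inflow profile uses the discrete rim `R′_max`, which is slightly
  inside the analytic radius; at R = 10 voxels this costs ~3 % of
  centerline velocity against the continuum solution (visible in the
  Poiseuille L∞ figure).
* One inflow patch per run; multiple inflow patches on the named face are
  resolved by size with a warning.
* Openings must be resolvable on ROI faces; vessels leaving the ROI
  laterally through a corner produce small spurious patches that become
  outflows.
* No fresh-cell treatment: walls are static; moving-wall terms (`u_w`)
  exist in the closure but are exercised only with `u_w = 0`.
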