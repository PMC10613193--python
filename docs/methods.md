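# Methods

`aclfem` simulates anatomical single-bundle ACL reconstruction with
progressively flattened femoral tunnels: five finite-element models whose
femoral tunnel cross-sections share one area (the round 8-mm tunnel's
~50.27 mm²) while the aperture flattens into rounded rectangles of
rectangular length L = 2, 4, 6, 8 mm, radius R solving S = L·2R + πR².
Each model is pretensioned and driven through a lunge-style flexion
sequence (0°, 30°, 60°, 90°), and two outcomes are recorded: the maximal
principal Cauchy stress on the graft and the volume of cancellous bone
whose equivalent strain lies in the 1000–3000 microstrain bone-modelling
window (V₁₀₀₀₋₃₀₀₀).

## Constitutive models

**Graft** — nearly incompressible, transversely isotropic neo-Hookean:

    Ψ = (1/2D)·ln²J + C1·(Ī₁ − 3) + F₂(λ)

with J = det F, Ī₁ = J^(−2/3)·tr(FᵀF), C1 = 1.95 MPa, D = 0.00683 MPa⁻¹
(bulk modulus k = 1/D ≈ 146 MPa; units are MPa by consistency with the
bone modulus and stress outputs). A variant with the isochoric term
written as C1·(Ī₁² − 3) is available behind `squared_invariant` for
sensitivity checks; the linear-invariant form is the default because the
squared form does not vanish at the reference state. The fibre term
F₂(λ) is a standard toe-region family (no compressive resistance below
λ = 1, exponential toe, linear continuation) whose constants must be
supplied by the user; it is disabled by default, so all verification
targets exercise the fully specified matrix terms. Per-element fibre
directions follow the graft sweep tangent.

**Cancellous bone** — isotropic linear elastic, E = 389 MPa, ν = 0.3,
assembled as a constant small-strain stiffness inside the nonlinear
solve (bone strains stay O(10⁻³) under all study conditions). The
cortical shell and tibia are rigid.

## Discretization

The graft is meshed with fully integrated eight-node hexahedra (2×2×2
Gauss; the reduced-integration hybrid element of commercial practice is
replaced by full integration — the penalty bulk modulus k ≈ 146 MPa is
far from the incompressible locking regime). Cross-section quads come
from an elliptical square-to-disk map radially scaled onto the
rounded-rectangle boundary and rescaled so the discrete area equals the
analytic area exactly; the grid resolution derives from the
area-equivalent diameter, so all five family members share one mesh
topology. The bone block is meshed with four-node tetrahedra by carving
the tunnel from a graded tensor-product voxel grid (six positively
oriented tets per box), refined from 1.4 mm to 1.0 mm within 6 mm of the
tunnel entrances (the refinement radius is a configuration value; the
source study does not state one).

Reference element sizes are the study's (graft 1.0–1.2 mm, bone 1.4 mm);
a `scale_factor` in (0, 1] scales mesh density only, never geometry,
loads or kinematics. Pipeline defaults use 0.5 (a few hundred graft
hexahedra, a few thousand bone tets), which keeps the full five-model,
four-angle study under ~8 minutes on one CPU. The 5% stress-variation
mesh-sensitivity rule is applied on a pretension-state ladder that
refines the graft mesh stepwise (density factors 0.35/0.5/0.65) with
the bone grid held fixed — a one-factor design, because re-meshing the
voxel tunnel wall under the tie interface re-randomizes the peak.  The
rule is met between the two finest default levels (3.9% variation);
like any concentration-driven peak metric it is not convergent without
bound, and probes beyond the default ladder show larger swings.

## Two-step loading protocol

1. **Pretension** — femur and tibia fixed; a 50 N dead load on the
   graft's tibial end surface along the tibial tunnel axis, with the
   traction resultant normalised to 50 N exactly.
2. **Pose** — the tibia and the tibial-tunnel portion of the graft fixed
   at the pretensioned state; the femoral assembly (cancellous outer
   surface = rigid cortical shell, plus everything tied or attached to
   it) displaced incrementally to each 6DOF flexion pose, chained
   through the intermediate angles like the physical motion.

Newton–Raphson with adaptive load substepping (bisection on divergence),
a backtracking line search (contact makes full steps mildly divergent
near equilibrium), and direct sparse solves. The material tangent is
obtained by central differencing of the analytic second Piola–Kirchhoff
stress per Gauss point — one uniform implementation across the material
variants, verified against finite differences of the internal force.
Default tolerances: residual < 1e-8 × reference (library default), with
the contact-bearing pipeline using 1e-6 (≤ 1e-4 N on a 50 N load),
echoed into every configuration record.

## Interfaces

* **Bonded graft–tunnel contact**: node-to-facet tie springs (nearest
  projection, master = bone), 2×10³ N/mm per node, graded linearly from
  the aperture over a 12-mm ramp — an abrupt bond edge concentrates the
  killer-turn fold scale-free; the ramp gives the interface a physical
  compliance length. Assembly fails, listing the nodes, if any wall node
  projects farther than 2.5 mm.
* **Tibial tunnel**: frictionless rigid channel (smoothed normal-only
  penalty, 10³ N/mm per node) along the filleted path, opened to clear
  the flattened sections; active only while the tibial portion is free
  (step 1).
* **Femoral aperture rim**: rounded rigid bars (radius 2.5 mm, identical
  across the family) along the ridge axis at both aperture lips,
  attached to the femur; they bound how tightly the graft can wrap the
  aperture edge.
* Contact forces use a C¹ quadratic smoothing band (0.15 mm) and, for
  confining tubes, a sliding-curvature tangent term.

## Synthetic study conditions

The source subject's CT anatomy and dual-fluoroscopic kinematics are
unpublished, so the scene is a sagittal-plane idealization (x =
medial-lateral flexion axis, y proximal, z anterior): tibial aperture at
the origin with the tunnel 35° anterior of vertical; femoral aperture
27 mm up the native-ACL-length span; femoral tunnel 25° anterior of the
span into a 26-mm bone block; 20 mm of graft in each tunnel; aperture
turns filleted at a family-constant radius so the sweep stays valid and
the comparison is controlled. The flattened sections' long axis lies
medial-laterally (ridge-parallel: perpendicular to the sagittal bending
plane). Flexion rotates the femur about the posterior aperture lip (the
functional pulley of a near-isometric graft), with small coupled
anterior translation (0.02 mm/deg) and internal rotation (0.03 deg/deg)
and a near-isometric elongation schedule (0, +1, −0.5, +0.5 % of the
span at 0/30/60/90°) enforced by a translation correction and clipped to
configurable distraction bounds. The generator is deterministic for a
fixed (parameters, seed) pair; optional seeded jitter is off by default.

## What the synthetic model does and does not show

The packaged per-angle outcome tables are the published results of the
original subject-specific study and are used only for aggregation and
trend verification (their ten column mean ± SD pairs are reproduced
exactly with the sample, n−1, standard deviation — the population SD
does not reproduce the printed values). The simulation's absolute
stresses and volumes are **not** comparable to those tables: they depend
on the unpublished anatomy and in vivo kinematics.

A known limitation of the desk-scale sagittal idealization: the entire
flexion angle must be absorbed as bending of the free graft span, and at
60–90° this localizes into a fold at the bonded-interface boundary.
Folding is scale-free — a thinner section folds proportionally tighter,
and the flattened graft's wide wings add membrane stretching — so under
these conditions the flattened tunnels show *higher* peak graft stress
than the round tunnel, opposite to the published in vivo-driven result,
and the overloaded peritunnel bone leaves the 1000–3000 µε window at
flexed angles. The regime the original study operates in (an oblique
femoral tunnel nearly parallel to the flexion axis, so flexion mostly
twists the graft and distributes along its free length, with frictionless
aperture contact) was implemented and verified to be correct in
formulation, but its sliding-contact solves around the ~76° anatomic
killer turn exceed a desk compute budget by an order of magnitude; the
sagittal conditions were therefore frozen and the discrepancy is
reported, not hidden. Passing tests on this model validate the
machinery — geometry, meshing, constitutive laws, solver, metrics and
aggregation — not the clinical conclusion.

## Numerical choices and degenerate inputs

* Strain-window membership uses the closed interval [1000, 3000] µε
  (endpoint handling is unstated in the source) and an exactly rounded
  (`fsum`) volume sum, so it matches any-order brute-force accumulation.
* Element-constant (centroid) stress/strain evaluation is the default;
  Gauss-point fields are stored alongside.
* The 6DOF convention is an intrinsic flexion–adduction–internal-rotation
  Euler sequence (X-Z-Y) with translations along the fixed tibial axes;
  it is registered by name, travels with every pose, and gimbal-degenerate
  poses raise an explicit error rather than returning a non-unique
  answer.
* Degenerate configurations are supported where tests need them: a bone
  block without a tunnel, a graft without a bone (free pretension), zero
  tension (returns the reference state exactly).
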