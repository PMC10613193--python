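# aclfem

Finite-element simulation of anatomical single-bundle ACL reconstruction
with progressively flattened femoral tunnels.

Flattened ("rounded rectangular") femoral tunnels aim to cover more of
the ACL's direct insertion than the traditional round tunnel. `aclfem`
implements, as a tested and reusable pipeline, the finite-element
protocol used to study the biomechanical consequences: five knee models
whose femoral tunnel cross-sections share one area — a circle of
diameter 8 mm and four rounded rectangles (a rectangle of length *L*
capped by semicircles of radius *R*) with

    S = L·2R + π·R²,   S = π·(8/2)² ≈ 50.27 mm²,  L ∈ {2, 4, 6, 8} mm

— each carrying a nearly incompressible transversely isotropic
neo-Hookean graft

    Ψ = (1/2D)·ln²J + C1·(Ī₁ − 3) + F₂(λ),  C1 = 1.95 MPa, D = 0.00683 MPa⁻¹

bonded into linear-elastic cancellous bone (E = 389 MPa, ν = 0.3) under
a rigid cortical shell. Loading follows the two-step protocol: a 50 N
graft pretension with femur and tibia fixed, then a 6DOF femoral flexion
pose (lunge sequence 0°/30°/60°/90°) with the tibia and the tibial graft
portion fixed. Two outcomes are computed per model and angle: the
maximal principal Cauchy stress on the graft, and V₁₀₀₀₋₃₀₀₀ — the
volume of cancellous bone whose equivalent strain

    ε_eq = sqrt(½[(ε₁−ε₂)² + (ε₁−ε₃)² + (ε₂−ε₃)²])

lies in the 1000–3000 microstrain bone-modelling window.

The subject-specific anatomy and fluoroscopic kinematics behind the
original study are unpublished, so the package ships a synthetic-data
module that generates every input: the constant-area tunnel family, an
idealized bone block and graft sweep, deterministic lunge pose
sequences, and the study's published per-angle outcome tables as
checksum-pinned CSV fixtures (used for aggregation and trend tests, not
as simulation targets). See `docs/methods.md` for the model, its
assumptions, and what the synthetic desk-scale conditions do and do not
reproduce.

Audience: biomechanics researchers and students who want a transparent,
scriptable re-implementation of this class of tunnel-geometry FE studies
without commercial FE software.

## Worked example

The tunnel family (the geometric heart of the study):

```
$ aclfem geometry
Circular: L=0 mm R=4.0000 mm S=50.2655 mm^2 long=8.0000 short=8.0000
Rounded rectangular 1: L=2 mm R=3.4137 mm S=50.2655 mm^2 long=8.8274 short=6.8274
Rounded rectangular 2: L=4 mm R=2.9245 mm S=50.2655 mm^2 long=9.8490 short=5.8490
Rounded rectangular 3: L=6 mm R=2.5227 mm S=50.2655 mm^2 long=11.0454 short=5.0454
Rounded rectangular 4: L=8 mm R=2.1953 mm S=50.2655 mm^2 long=12.3906 short=4.3906
```

All five sections hold the round tunnel's area while the long axis grows
and the short axis shrinks — the controlled variable of the study.

Recomputing the published summary statistics from the packaged per-angle
tables (mean over 0/30/60/90° and sample standard deviation):

```
$ aclfem reproduce-tables
graft_stress (MPa):
                       mean    sd
Circular               3.93  0.60
Rounded rectangular 1  3.82  0.54
Rounded rectangular 2  3.43  0.44
Rounded rectangular 3  3.45  0.44
Rounded rectangular 4  3.05  0.43
strain_volume (mm^3):
                         mean      sd
Circular               179.06   89.62
Rounded rectangular 1  221.40  129.83
...
Rounded rectangular 4  295.71  162.59
```

These are the study's ten printed mean ± SD pairs: flatter tunnels show
lower average graft stress and larger beneficial-strain volume.

Running the desk-scale simulation itself (about 8 minutes for all five
models on one CPU; `--models` selects a subset):

```
$ aclfem simulate --scale 0.5 --seed 0 --outdir out \
      --models "Circular,Rounded rectangular 4"
```

writes per-angle outcome tables (`graft_stress.csv`,
`strain_volume.csv`), their column summaries, the synthetic lunge pose
profile, and a configuration echo into `out/`. On the default synthetic
conditions the circular model's peak graft stress rises from ~2.1 MPa at
0° to ~33 MPa at 90° as the killer-turn bend grows; the flattened models
fold at the bonded-interface boundary at deep flexion and exceed the
circular stresses there — the opposite ordering to the published
in vivo-driven study, a documented limitation of the sagittal desk-scale
stand-in kinematics (see `docs/methods.md`).

From Python the same pipeline is:

```python
from aclfem.synthetic import default_config
from aclfem.report import run_pipeline, summary_frame

cfg = default_config(scale=0.5, seed=0)
stress, volume, outcomes = run_pipeline(cfg, outdir="out")
print(summary_frame(stress))
```

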