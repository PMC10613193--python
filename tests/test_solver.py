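"""Solver verification: patch tests, single-element closed forms,
equilibrium, objectivity and energy consistency."""

import numpy as np
import pytest

from aclfem.errors import AssemblyError, ValidationError
from aclfem.geometry import BoneBlockSpec, CrossSection, TunnelSpec
from aclfem.kinematics import FlexionPose, RigidTransform
from aclfem.materials import (
    LinearElasticParams,
    NeoHookeanParams,
    cauchy_stress_hyper,
    small_strain_stress,
)
from aclfem.meshing import (
    Mesh,
    MeshSizeSpec,
    bone_block_mesh,
    extrude_graft_mesh,
)
from aclfem.solver import (
    FEModel,
    InterfaceConfig,
    SolverSettings,
    assemble_model,
    consistent_end_load,
    solve_pose,
    solve_pretension,
    solve_static,
)

GRAFT = NeoHookeanParams()
BONE = LinearElasticParams()
S8 = np.pi * 16.0


def hex_block_mesh(nx=2, ny=2, nz=2, size=1.0):
    """Small structured hex block for patch tests."""
    xs = np.arange(nx + 1) * size
    ys = np.arange(ny + 1) * size
    zs = np.arange(nz + 1) * size
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    hexes = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                hexes.append([
                    nid(i, j, k), nid(i + 1, j, k),
                    nid(i + 1, j + 1, k), nid(i, j + 1, k),
                    nid(i, j, k + 1), nid(i + 1, j, k + 1),
                    nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                ])
    return Mesh(
        nodes=nodes, element_type="hex8",
        elements=np.asarray(hexes),
        region=np.full(len(hexes), "graft"),
    )


def straight_graft_model(length=30.0, scale=0.5):
    sec = CrossSection.from_area(0.0, S8)
    path = np.array([[0.0, 0.0, 0.0], [0.0, length, 0.0]])
    mesh = extrude_graft_mesh(sec, path, MeshSizeSpec(scale_factor=scale))
    model = FEModel(graft=mesh, graft_material=GRAFT,
                    tibial_axis=np.array([0.0, -1.0, 0.0]))
    # hold the far (femoral) end, pull the near end
    top = np.unique(mesh.surfaces["graft_end_stop"])
    model.fixed_sets["femoral_end"] = top
    return model


def prescribe_linear_field(model, F_target, node_set=None):
    nodes = model.all_nodes()
    ids = np.arange(len(nodes)) if node_set is None else node_set
    dofs = (3 * ids[:, None] + np.arange(3)).ravel()
    disp = nodes[ids] @ (F_target - np.eye(3)).T

    def values(s):
        return (s * disp).ravel()

    return dofs, values


class TestPatchTests:
    def test_hex8_uniform_strain_patch(self):
        """Boundary-driven homogeneous deformation is reproduced exactly
        in the interior; stress matches the closed form."""
        mesh = hex_block_mesh(3, 3, 3)
        model = FEModel(graft=mesh, graft_material=GRAFT)
        lam = 1.05
        F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])
        # boundary nodes only; interior must follow
        on_bnd = np.any(
            (mesh.nodes == 0.0) | (mesh.nodes == 3.0), axis=1
        )
        bnd = np.nonzero(on_bnd)[0]
        dofs, vals = prescribe_linear_field(model, F, bnd)
        res = solve_static(model, dofs, vals)
        expect = mesh.nodes @ (F - np.eye(3)).T
        assert np.max(np.abs(res.displacements() - expect)) < 1e-8
        closed = cauchy_stress_hyper(F, GRAFT)
        assert np.max(np.abs(res.graft_stress - closed)) < 1e-7

    def test_tet4_uniform_strain_patch(self):
        blk = BoneBlockSpec(extents=(10.0, 10.0, 10.0), tunnel=None)
        mesh = bone_block_mesh(blk, MeshSizeSpec(scale_factor=0.3))
        graft = hex_block_mesh(1, 1, 1)   # placeholder deformable graft
        model = FEModel(graft=graft, graft_material=GRAFT,
                        bone=mesh, bone_material=BONE)
        eps = np.array([[1e-3, 2e-4, 0.0],
                        [2e-4, -3e-4, 1e-4],
                        [0.0, 1e-4, 5e-4]])
        F = np.eye(3) + eps
        off = model.n_bone_offset
        on_bnd = np.unique(mesh.surfaces["outer_surface"]) + off
        # also drive the tiny graft cube fully so it does not float
        gdofs = np.arange(3 * graft.n_nodes)
        bdofs, bvals = prescribe_linear_field(model, F, on_bnd)
        dofs = np.concatenate([gdofs, bdofs])

        def vals(s):
            return np.concatenate([
                s * (graft.nodes @ (F - np.eye(3)).T).ravel(),
                bvals(s),
            ])

        res = solve_static(model, dofs, vals)
        expect = model.all_nodes() @ (F - np.eye(3)).T
        assert np.max(np.abs(res.displacements() - expect)) < 1e-8
        closed = small_strain_stress(0.5 * (eps + eps.T), BONE)
        sig = small_strain_stress(res.bone_strain, BONE)
        assert np.max(np.abs(sig - closed)) < 1e-6

    def test_single_hex_uniaxial_matches_closed_form(self, unit_hex_mesh):
        model = FEModel(graft=unit_hex_mesh, graft_material=GRAFT)
        lam = 1.1
        F = np.diag([1 / np.sqrt(lam), 1 / np.sqrt(lam), lam])
        dofs, vals = prescribe_linear_field(model, F)
        res = solve_static(model, dofs, vals)
        closed = cauchy_stress_hyper(F, GRAFT)
        assert np.max(np.abs(res.graft_stress[0] - closed)) < 1e-6


class TestPretension:
    def test_load_resultant_is_exact(self):
        model = straight_graft_model()
        f = consistent_end_load(model, 50.0)
        resultant = f.reshape(-1, 3).sum(axis=0)
        assert np.allclose(resultant, [0.0, -50.0, 0.0], atol=1e-9)

    def test_zero_tension_zero_displacement(self):
        model = straight_graft_model()
        res = solve_pretension(model, 0.0)
        assert np.max(np.abs(res.u)) == 0.0

    def test_free_graft_mean_axial_stress(self):
        """50 N over the 50.27 mm^2 end: mean axial Cauchy stress near
        50/50.27 ~ 0.995 MPa (finite-strain geometry shifts it slightly)."""
        model = straight_graft_model()
        res = solve_pretension(model, 50.0)
        mean_ax = float(np.mean(res.graft_stress[:, 1, 1]))
        assert mean_ax == pytest.approx(50.0 / S8, rel=0.10)
        assert res.global_force_balance() < 1e-6

    def test_near_linearity_at_small_loads(self):
        model = straight_graft_model()
        r1 = solve_pretension(model, 0.5)
        r2 = solve_pretension(model, 1.0)
        ratio = np.linalg.norm(r2.u) / np.linalg.norm(r1.u)
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_energy_balance_within_one_percent(self):
        """Dissipationless quasi-statics: external work equals stored
        strain energy along the load path."""
        model = straight_graft_model()
        res = solve_pretension(
            model, 50.0,
            settings=SolverSettings(initial_substeps=16),
        )
        W = res.external_work
        U = res.strain_energy()
        assert W == pytest.approx(U, rel=0.01)


def tiny_scene(section=None):
    """Minimal graft + bone assembly: straight graft through a matching
    bone tunnel."""
    sec = section or CrossSection.from_area(0.0, S8)
    depth = 12.0
    path = np.array([[0.0, -15.0, 0.0], [0.0, depth, 0.0]])
    sizes = MeshSizeSpec(scale_factor=0.35)
    graft = extrude_graft_mesh(sec, path, sizes,
                               tibial_embed=10.0, femoral_embed=depth)
    tun = TunnelSpec(section=sec, length=12.0)
    blk = BoneBlockSpec(extents=(22.0, 22.0, 12.0), tunnel=tun)
    bone_local = bone_block_mesh(blk, sizes)
    from aclfem.meshing import transform_mesh

    M = np.array([[1.0, 0, 0], [0, 0, 1.0], [0, -1.0, 0]])
    bone = transform_mesh(bone_local, rotation=M,
                          translation=np.zeros(3))
    return assemble_model(graft, bone, graft_material=GRAFT,
                          bone_material=BONE,
                          tibial_axis=(0.0, -1.0, 0.0))


class TestAssembly:
    def test_matched_surfaces_fully_tied(self):
        model = tiny_scene()
        gwall = np.unique(model.graft.surfaces["femoral_tunnel_wall"])
        tied = {t[0] for t in model.ties}
        assert tied == set(gwall.tolist())

    def test_offset_meshes_raise_assembly_error(self):
        sec = CrossSection.from_area(0.0, S8)
        depth = 12.0
        path = np.array([[40.0, -15.0, 0.0], [40.0, depth, 0.0]])
        sizes = MeshSizeSpec(scale_factor=0.35)
        graft = extrude_graft_mesh(sec, path, sizes,
                                   femoral_embed=depth)
        bone = tiny_scene().bone
        with pytest.raises(AssemblyError):
            assemble_model(graft, bone, graft_material=GRAFT,
                           bone_material=BONE)

    def test_rigid_translation_gives_zero_internal_force(self):
        model = tiny_scene()
        t = np.array([0.7, -0.3, 1.1])
        u = np.tile(t, model.n_nodes)
        f, _ = model.internal_force_and_stiffness(u, need_K=False)
        assert np.max(np.abs(f)) < 1e-8


class TestPoseStep:
    @pytest.fixture(scope="class")
    def pretensioned(self):
        model = tiny_scene()
        res = solve_pretension(model, 20.0)
        return model, res

    def test_identity_pose_reproduces_pretension(self, pretensioned):
        model, prior = pretensioned
        pose = FlexionPose(0.0, RigidTransform.identity())
        res = solve_pose(model, pose, prior, tibial_embed=10.0)
        assert np.linalg.norm(res.u - prior.u) < 1e-8

    def test_rigid_translation_of_all_boundaries_strain_free(self):
        """Objectivity: translating femur and the fixed tibial portion
        together adds no strain anywhere."""
        model = tiny_scene()
        prior = solve_pretension(model, 20.0)
        t = np.array([0.5, 0.25, -0.4])
        pose = FlexionPose(30.0, RigidTransform(np.eye(3), t))
        # test mode: translate the tibial-fixed nodes too
        from aclfem.solver import tibial_portion_nodes

        graft_fix = tibial_portion_nodes(model, 10.0)
        gdofs = (3 * graft_fix[:, None] + np.arange(3)).ravel()
        outer = np.unique(model.bone.surfaces["outer_surface"])
        odofs = (3 * (outer + model.n_bone_offset)[:, None]
                 + np.arange(3)).ravel()
        dofs = np.concatenate([gdofs, odofs])
        base = np.concatenate([prior.u[gdofs],
                               prior.u[odofs]])

        def vals(s):
            return base + s * np.tile(t, len(dofs) // 3)

        res = solve_static(model, dofs, vals, u0=prior.u)
        du = (res.u - prior.u).reshape(-1, 3)
        assert np.max(np.abs(du - t)) < 1e-7
        assert np.max(np.abs(res.graft_stress - prior.graft_stress)) < 1e-6

    def test_pose_solve_balance(self, pretensioned):
        model, prior = pretensioned
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("X", 5, degrees=True).as_matrix()
        pose = FlexionPose(
            5.0, RigidTransform.about_point(R, (0.0, 5.0, 0.0))
        )
        res = solve_pose(model, pose, prior, tibial_embed=10.0)
        assert res.global_force_balance() < 1e-6

    def test_prior_must_be_converged_result(self, pretensioned):
        model, prior = pretensioned
        bad = type(prior)(model=model, u=prior.u, step="bogus",
                          residual_history=[])
        with pytest.raises(ValidationError):
            solve_pose(model, FlexionPose(0.0, RigidTransform.identity()),
                       bad)
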