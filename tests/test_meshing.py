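"""Structured meshing: volume conservation, refinement behaviour and the
5% mesh-sensitivity rule."""

import math

import numpy as np
import pytest

from aclfem.errors import (
    GeometryError,
    InvertedElementError,
    MeshingError,
    ValidationError,
)
from aclfem.geometry import BoneBlockSpec, CrossSection, TunnelSpec
from aclfem.meshing import (
    Mesh,
    MeshSizeSpec,
    bone_block_mesh,
    check_convergence,
    element_volume,
    element_volumes,
    extrude_graft_mesh,
    extrude_quad_mesh,
    fillet_path,
    section_quad_mesh,
    transform_mesh,
)

S8 = math.pi * 16.0
COARSE = MeshSizeSpec(scale_factor=0.5)


class TestElementVolume:
    def test_unit_cube_hex(self, unit_hex_mesh):
        assert element_volume(unit_hex_mesh, 0) == pytest.approx(1.0)

    def test_reference_tet(self, unit_tet_mesh):
        assert element_volume(unit_tet_mesh, 0) == pytest.approx(1.0 / 6.0)

    def test_affinely_mapped_cube_volume_is_det(self, unit_hex_mesh):
        rng = np.random.default_rng(3)
        A = np.eye(3) + 0.3 * rng.standard_normal((3, 3))
        if np.linalg.det(A) < 0:
            A[:, 0] *= -1
        m = transform_mesh(unit_hex_mesh, rotation=A)
        assert element_volume(m, 0) == pytest.approx(
            abs(np.linalg.det(A)), rel=1e-9
        )

    def test_inverted_element_reported_by_id(self, unit_tet_mesh):
        bad = Mesh(
            nodes=unit_tet_mesh.nodes,
            element_type="tet4",
            elements=unit_tet_mesh.elements[:, [0, 2, 1, 3]],
            region=np.array(["cancellous"]),
        )
        with pytest.raises(InvertedElementError) as e:
            element_volume(bad, 0)
        assert e.value.element_id == 0

    def test_bad_element_id(self, unit_tet_mesh):
        with pytest.raises(ValidationError):
            element_volume(unit_tet_mesh, 5)


class TestGraftExtrusion:
    def test_single_hex_unit_square_extrusion(self):
        pts = np.array([[-0.5, -0.5], [0.5, -0.5], [0.5, 0.5], [-0.5, 0.5]])
        quads = np.array([[0, 1, 2, 3]])
        bedges = np.array([[0, 1], [1, 2], [2, 3], [3, 0]])
        path = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        m = extrude_quad_mesh(pts, quads, bedges, path, axial_size=1.0)
        assert m.n_elements == 1
        assert element_volume(m, 0) == pytest.approx(1.0)

    @pytest.mark.parametrize("L", [0.0, 8.0])
    def test_straight_extrusion_volume(self, L):
        sec = CrossSection.from_area(L, S8)
        path = np.array([[0.0, 0.0, 0.0], [0.0, 40.0, 0.0]])
        m = extrude_graft_mesh(sec, path, COARSE,
                               long_axis_direction=(1, 0, 0))
        m.validate()
        assert element_volumes(m).sum() == pytest.approx(
            S8 * 40.0, rel=0.01
        )

    def test_end_facets_tagged(self):
        sec = CrossSection.from_area(0.0, S8)
        path = np.array([[0.0, 0.0, 0.0], [0.0, 30.0, 0.0]])
        m = extrude_graft_mesh(sec, path, COARSE)
        ends = m.surfaces["graft_end"]
        assert len(ends) == 2 * len(m.surfaces["graft_end_tibial"])

    def test_path_shorter_than_one_element(self):
        sec = CrossSection.from_area(0.0, S8)
        path = np.array([[0.0, 0.0, 0.0], [0.0, 0.5, 0.0]])
        with pytest.raises(MeshingError):
            extrude_graft_mesh(sec, path, COARSE)

    def test_filleted_bent_path_keeps_positive_volumes(self):
        sec = CrossSection.from_area(8.0, S8)
        path = np.array([[0.0, -20.0, 0.0], [0.0, 0.0, 0.0],
                         [20.0, 0.0, 0.0]])
        fp = fillet_path(path, 6.0, 1.5)
        m = extrude_graft_mesh(sec, fp, COARSE,
                               long_axis_direction=(0, 0, 1))
        m.validate()  # raises on any inverted element

    def test_scaling_by_k_scales_volumes_by_k_cubed(self):
        sec = CrossSection.from_area(2.0, S8)
        path = np.array([[0.0, 0.0, 0.0], [0.0, 20.0, 0.0]])
        m = extrude_graft_mesh(sec, path, COARSE)
        v = element_volumes(m)
        m2 = transform_mesh(m)
        m2.nodes = m2.nodes * 2.0
        assert np.allclose(element_volumes(m2), 8.0 * v)


class TestBoneBlock:
    def _block(self, with_tunnel=True, extents=(30.0, 30.0, 30.0)):
        tun = None
        if with_tunnel:
            tun = TunnelSpec(section=CrossSection.from_area(0.0, S8),
                             length=extents[2])
        return BoneBlockSpec(extents=extents, tunnel=tun)

    def test_block_minus_tunnel_volume(self):
        m = bone_block_mesh(self._block(), COARSE)
        m.validate()
        expected = 27000.0 - S8 * 30.0
        assert element_volumes(m).sum() == pytest.approx(expected, rel=0.02)

    def test_degenerate_no_tunnel_volume(self):
        m = bone_block_mesh(self._block(with_tunnel=False), COARSE)
        assert element_volumes(m).sum() == pytest.approx(27000.0, rel=1e-9)

    def test_entrance_zone_is_denser(self):
        m = bone_block_mesh(self._block(), COARSE)
        zone = m.element_sets["tunnel_entrance_zone"]
        inz = np.zeros(m.n_elements, bool)
        inz[zone] = True
        v = element_volumes(m)
        dens_in = inz.sum() / v[inz].sum()
        dens_out = (~inz).sum() / v[~inz].sum()
        assert dens_in > dens_out

    def test_tunnel_wall_facets_on_boundary(self):
        m = bone_block_mesh(self._block(), COARSE)
        m.validate()  # surface facets must lie on element boundaries
        assert len(m.surfaces["femoral_tunnel_wall"]) > 0

    def test_tunnel_wider_than_block_rejected(self):
        tun = TunnelSpec(section=CrossSection.from_area(0.0, S8), length=6.0)
        blk = BoneBlockSpec(extents=(6.0, 6.0, 6.0),
                            cortical_thickness=1.0, tunnel=tun)
        with pytest.raises(GeometryError):
            bone_block_mesh(blk, COARSE)

    def test_refinement_improves_volume(self):
        errs = []
        expected = 27000.0 - S8 * 30.0
        for scale in (0.35, 0.7):
            m = bone_block_mesh(
                self._block(), MeshSizeSpec(scale_factor=scale)
            )
            errs.append(abs(element_volumes(m).sum() - expected))
        assert errs[1] <= errs[0]


class TestSectionQuadMesh:
    @pytest.mark.parametrize("L", [0.0, 4.0, 8.0])
    def test_discrete_area_exact(self, L):
        sec = CrossSection.from_area(L, S8)
        pts, quads, _ = section_quad_mesh(sec, 1.5)
        p = pts[quads]
        x, y = p[..., 0], p[..., 1]
        area = 0.5 * np.sum(
            x * np.roll(y, -1, axis=1) - np.roll(x, -1, axis=1) * y
        )
        assert area == pytest.approx(S8, rel=1e-12)

    def test_same_topology_across_family(self, tunnel_family):
        shapes = {section_quad_mesh(s, 1.5)[1].shape
                  for s in tunnel_family}
        assert len(shapes) == 1


class TestConvergenceRule:
    def test_five_percent_rule(self):
        # |3.90 - 4.00| / 4.00 = 0.025 <= 0.05 -> converged at index 1
        assert check_convergence([4.00, 3.90, 3.88], 0.05) == 1

    def test_never_converged(self):
        assert check_convergence([1.0, 2.0, 4.0], 0.05) is None

    def test_zero_variation(self):
        assert check_convergence([5.0, 5.0], 0.05) == 1

    def test_singleton_rejected(self):
        with pytest.raises(ValidationError):
            check_convergence([1.0])
        with pytest.raises(ValidationError):
            check_convergence([])
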