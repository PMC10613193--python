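"""Outcome metrics: principal values, equivalent strain and the
mechanostat strain-window volume, each against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from aclfem.errors import DomainError, ValidationError
from aclfem.geometry import BoneBlockSpec
from aclfem.meshing import MeshSizeSpec, bone_block_mesh, element_volumes
from aclfem.postprocess import (
    equivalent_strain,
    principal_values,
    strain_window_volume,
)
from aclfem.synthetic import random_strain_field


@pytest.fixture(scope="module")
def bone_mesh():
    blk = BoneBlockSpec(extents=(20.0, 20.0, 20.0), tunnel=None)
    return bone_block_mesh(blk, MeshSizeSpec(scale_factor=0.35))


class TestPrincipalValues:
    def test_diagonal(self):
        assert np.allclose(principal_values(np.diag([3.0, 1.0, 2.0])),
                           [3.0, 2.0, 1.0])

    def test_pure_shear(self):
        t = np.zeros((3, 3))
        t[0, 1] = t[1, 0] = 0.5
        assert np.allclose(principal_values(t), [0.5, 0.0, -0.5])

    def test_identity(self):
        assert np.allclose(principal_values(np.eye(3)), 1.0)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(0)
        t = rng.standard_normal((3, 3))
        t = t + t.T
        Q = Rotation.random(random_state=rng).as_matrix()
        assert np.allclose(principal_values(Q @ t @ Q.T),
                           principal_values(t), atol=1e-10)

    def test_asymmetric_rejected(self):
        t = np.zeros((3, 3))
        t[0, 1] = 1.0
        with pytest.raises(ValidationError):
            principal_values(t)


class TestEquivalentStrain:
    def test_zeros(self):
        assert equivalent_strain(0.0, 0.0, 0.0) == 0.0

    @given(a=st.floats(-5000, 5000))
    @settings(max_examples=50, deadline=None)
    def test_hydrostatic_states_vanish(self, a):
        assert equivalent_strain(a, a, a) == pytest.approx(0.0, abs=1e-9)

    def test_printed_formula_value(self):
        # sqrt(0.5*(1000^2 + 3000^2 + 2000^2)) ~ 2645.75
        assert equivalent_strain(2000.0, 1000.0, -1000.0) == pytest.approx(
            2645.751311, rel=1e-9
        )

    @given(
        e=st.tuples(*[st.floats(-4000, 4000)] * 3),
        shift=st.floats(-2000, 2000),
    )
    @settings(max_examples=100, deadline=None)
    def test_hydrostatic_offset_invariance(self, e, shift):
        base = equivalent_strain(*e)
        shifted = equivalent_strain(*(x + shift for x in e))
        assert shifted == pytest.approx(base, rel=1e-6, abs=1e-6)

    def test_permutation_invariance(self):
        vals = (1500.0, -300.0, 800.0)
        ref = equivalent_strain(*vals)
        for perm in ((1, 0, 2), (2, 1, 0), (1, 2, 0)):
            assert equivalent_strain(*(vals[i] for i in perm)) == ref

    def test_non_finite_rejected(self):
        with pytest.raises(DomainError):
            equivalent_strain(np.nan, 0.0, 0.0)


class TestStrainWindowVolume:
    def test_all_in_window(self, bone_mesh):
        eps = np.full(bone_mesh.n_elements, 2000.0)
        V = strain_window_volume(bone_mesh, eps)
        assert V == pytest.approx(element_volumes(bone_mesh).sum())

    def test_all_below_window(self, bone_mesh):
        eps = np.full(bone_mesh.n_elements, 100.0)
        assert strain_window_volume(bone_mesh, eps) == 0.0

    def test_matches_brute_force_oracle(self, bone_mesh):
        eps = random_strain_field(bone_mesh, 0.0, 5000.0, seed=42)
        vols = element_volumes(bone_mesh)
        import math

        selected = [vols[i] for i in range(bone_mesh.n_elements)
                    if 1000.0 <= eps[i] <= 3000.0]
        assert strain_window_volume(bone_mesh, eps) == math.fsum(selected)

    def test_partition_of_region_volume(self, bone_mesh):
        eps = random_strain_field(bone_mesh, 0.0, 5000.0, seed=7)
        vols = element_volumes(bone_mesh)
        inside = strain_window_volume(bone_mesh, eps, 1000.0, 3000.0)
        below = vols[eps < 1000.0].sum()
        above = vols[eps > 3000.0].sum()
        assert inside + below + above == pytest.approx(
            vols.sum(), rel=1e-14
        )

    def test_window_monotonicity(self, bone_mesh):
        eps = random_strain_field(bone_mesh, 0.0, 5000.0, seed=9)
        narrow = strain_window_volume(bone_mesh, eps, 1200.0, 2800.0)
        wide = strain_window_volume(bone_mesh, eps, 1000.0, 3000.0)
        wider = strain_window_volume(bone_mesh, eps, 500.0, 4000.0)
        assert narrow <= wide <= wider

    def test_bad_window_rejected(self, bone_mesh):
        eps = np.zeros(bone_mesh.n_elements)
        with pytest.raises(ValidationError):
            strain_window_volume(bone_mesh, eps, 3000.0, 1000.0)


class TestSummaryRecord:
    def test_strain_volume_summary_invariants(self):
        from aclfem.postprocess import StrainVolumeSummary
        rec = StrainVolumeSummary(model="Circular", flexion_angle=30.0,
                                  window=(1000.0, 3000.0), V=187.47)
        assert rec.region == "cancellous"
        with pytest.raises(ValidationError):
            StrainVolumeSummary(model="x", flexion_angle=0.0,
                                window=(3000.0, 1000.0), V=1.0)
        with pytest.raises(ValidationError):
            StrainVolumeSummary(model="x", flexion_angle=0.0,
                                window=(1000.0, 3000.0), V=-1.0)

    def test_tensor_field_requires_symmetry(self, bone_mesh):
        from aclfem.postprocess import TensorField
        vals = np.zeros((bone_mesh.n_elements, 3, 3))
        TensorField(mesh=bone_mesh, values=vals, quantity="strain")
        vals[0, 0, 1] = 1.0
        with pytest.raises(ValidationError):
            TensorField(mesh=bone_mesh, values=vals, quantity="strain")
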