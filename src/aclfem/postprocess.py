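"""Outcome measures: maximal principal graft stress and the cancellous
strain-window volume.

The bone-modelling window follows the mechanostat: equivalent strains
between 1000 and 3000 microstrain are taken as beneficial for bone
formation; ``strain_window_volume`` integrates the cancellous volume whose
equivalent strain

    eps_eq = sqrt( 1/2 [ (e1-e2)^2 + (e1-e3)^2 + (e2-e3)^2 ] )

falls in the closed window.  Equivalent strain is a deviatoric measure:
adding the same hydrostatic strain to all three principal strains leaves
it unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError
from .meshing import Mesh, element_volumes

__all__ = [
    "TensorField",
    "StrainVolumeSummary",
    "principal_values",
    "max_principal_stress",
    "equivalent_strain",
    "strain_window_volume",
]

_SYM_TOL = 1e-8


@dataclass
class TensorField:
    """Per-element symmetric tensors on a mesh (stress MPa or strain)."""

    mesh: Mesh
    values: np.ndarray           # (ne, 3, 3)
    quantity: str                # 'stress' | 'strain'

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.mesh.n_elements, 3, 3):
            raise ValidationError(
                "tensor field must have one 3x3 entry per element"
            )
        if np.max(np.abs(v - np.swapaxes(v, -1, -2))) > 1e-10 * max(
            1.0, float(np.max(np.abs(v)))
        ):
            raise ValidationError("tensor field entries must be symmetric")
        self.values = v


@dataclass(frozen=True)
class StrainVolumeSummary:
    """One V_low-high record: model, flexion angle, window and volume."""

    model: str
    flexion_angle: float
    window: tuple          # (low, high) microstrain
    V: float               # mm^3
    region: str = "cancellous"

    def __post_init__(self):
        low, high = self.window
        if not low < high:
            raise ValidationError("window must satisfy low < high")
        if self.V < 0.0:
            raise ValidationError("volume must be non-negative")


def principal_values(tensor) -> np.ndarray:
    """Sorted (descending) real eigenvalues of a symmetric 3x3 tensor."""
    t = np.asarray(tensor, dtype=float)
    scale = max(1.0, float(np.max(np.abs(t))))
    if np.max(np.abs(t - np.swapaxes(t, -1, -2))) > _SYM_TOL * scale:
        raise ValidationError("tensor is not symmetric within tolerance")
    w = np.linalg.eigvalsh(0.5 * (t + np.swapaxes(t, -1, -2)))
    return w[..., ::-1]


def max_principal_stress(result, region: str = "graft"):
    """Largest principal Cauchy stress over a region of a solve result.

    Returns ``(value_MPa, element_id, location_mm)`` where the location is
    the deformed centroid of the critical element.
    """
    field = result.stress_field(region)
    mesh = result.region_mesh(region)
    if field.shape[0] == 0:
        raise ValidationError(f"region '{region}' has no elements")
    p1 = principal_values(field)[:, 0]
    eid = int(np.argmax(p1))
    u = result.region_displacements(region)
    xyz = (mesh.nodes + u)[mesh.elements[eid]].mean(axis=0)
    return float(p1[eid]), eid, xyz


def equivalent_strain(e1, e2, e3):
    """Scalar equivalent strain of three principal strains (same units in,
    same units out; pass microstrain to get microstrain)."""
    e1, e2, e3 = (np.asarray(e, dtype=float) for e in (e1, e2, e3))
    if not (np.all(np.isfinite(e1)) and np.all(np.isfinite(e2))
            and np.all(np.isfinite(e3))):
        raise DomainError("principal strains must be finite")
    return np.sqrt(
        0.5 * ((e1 - e2) ** 2 + (e1 - e3) ** 2 + (e2 - e3) ** 2)
    )


def equivalent_strain_tensor(strain) -> np.ndarray:
    """Equivalent strain of batched symmetric strain tensors (..., 3, 3)."""
    w = np.linalg.eigvalsh(np.asarray(strain, dtype=float))
    return equivalent_strain(w[..., 0], w[..., 1], w[..., 2])


def strain_window_volume(mesh: Mesh, strains, low: float = 1000.0,
                         high: float = 3000.0, region: str = "cancellous",
                         volumes: np.ndarray | None = None) -> float:
    """Volume (mm^3) of region elements with low <= eps_eq <= high.

    ``strains`` are per-element equivalent strains in microstrain; the
    window is closed on both ends.  ``volumes`` may pass precomputed
    element volumes to skip recomputation.
    """
    if not low < high:
        raise ValidationError("window must satisfy low < high")
    strains = np.asarray(strains, dtype=float)
    if strains.shape[0] != mesh.n_elements:
        raise ValidationError("one equivalent strain per element required")
    if volumes is None:
        volumes = element_volumes(mesh)
    mask = (mesh.region == region) & (strains >= low) & (strains <= high)
    # exactly-rounded sum: independent of accumulation order
    return math.fsum(volumes[mask])
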