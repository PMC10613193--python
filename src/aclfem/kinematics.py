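"""6DOF rigid kinematics of the femur relative to the tibia.

Coordinate convention (fixed tibial CS, right-handed, mm):

* x — medial-lateral (the flexion axis),
* y — proximal (up),
* z — anterior.

The default 6DOF convention, registered as ``"knee-xzy-intrinsic"``,
decomposes the rotation as an intrinsic X-Z-Y Euler sequence
(flexion about x, then adduction about the rotated z, then internal
rotation about the rotated y), with translations expressed along the
fixed tibial axes.  The convention name travels with every pose so
outputs are unambiguous.

In vivo fluoroscopic lunge kinematics are not published for this study;
``synthesize_lunge_profile`` generates a physiologically shaped stand-in:
flexion about a medial-lateral axis through a configurable centre near the
femoral tunnel aperture (near-isometry of the anatomic ACL attachment),
with small coupled anterior translation, internal rotation, and a bounded
graft-elongation (joint distraction) schedule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GimbalLockError, ValidationError

__all__ = [
    "RigidTransform",
    "FlexionPose",
    "LungeProfile",
    "LungeParams",
    "compose",
    "invert",
    "decompose_6dof",
    "recompose_6dof",
    "synthesize_lunge_profile",
    "CONVENTIONS",
]

CONVENTIONS = {
    # name -> scipy intrinsic Euler sequence (degrees); dof order is
    # (flexion, adduction, internal rotation, tx, ty, tz)
    "knee-xzy-intrinsic": "XZY",
}


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> R x + t (rotation 3x3, translation mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValidationError("rotation must be 3x3")
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-10:
            raise ValidationError("rotation must be orthonormal")
        if np.linalg.det(R) < 0.0:
            raise ValidationError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def about_point(cls, rotation, center) -> "RigidTransform":
        """Rotation about an arbitrary centre point."""
        R = np.asarray(rotation, dtype=float)
        c = np.asarray(center, dtype=float)
        return cls(R, c - R @ c)

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def is_identity(self, tol: float = 1e-10) -> bool:
        return (np.max(np.abs(self.rotation - np.eye(3))) < tol
                and np.max(np.abs(self.translation)) < tol)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """a after b: (a o b)(x) = a(b(x))."""
    return RigidTransform(
        a.rotation @ b.rotation, a.rotation @ b.translation + a.translation
    )


def invert(a: RigidTransform) -> RigidTransform:
    return RigidTransform(a.rotation.T, -a.rotation.T @ a.translation)


def decompose_6dof(transform: RigidTransform,
                   convention: str = "knee-xzy-intrinsic") -> np.ndarray:
    """Six scalars (3 rotations deg, 3 translations mm) for a pose.

    Raises :class:`GimbalLockError` when the middle Euler angle is within
    numerical reach of +/-90 deg (the decomposition loses a degree of
    freedom there) instead of returning a silently non-unique answer.
    """
    if convention not in CONVENTIONS:
        raise ValidationError(f"unknown 6DOF convention {convention!r}")
    seq = CONVENTIONS[convention]
    ang = Rotation.from_matrix(transform.rotation).as_euler(seq, degrees=True)
    if abs(math.cos(math.radians(ang[1]))) < 1e-7:
        raise GimbalLockError(
            f"middle angle {ang[1]:.6f} deg is gimbal-degenerate for "
            f"sequence {seq}"
        )
    return np.concatenate([ang, transform.translation])


def recompose_6dof(dof, convention: str = "knee-xzy-intrinsic"
                   ) -> RigidTransform:
    """Inverse of :func:`decompose_6dof`."""
    if convention not in CONVENTIONS:
        raise ValidationError(f"unknown 6DOF convention {convention!r}")
    dof = np.asarray(dof, dtype=float).reshape(6)
    R = Rotation.from_euler(
        CONVENTIONS[convention], dof[:3], degrees=True
    ).as_matrix()
    return RigidTransform(R, dof[3:])


@dataclass(frozen=True)
class FlexionPose:
    """One femoral pose at a named flexion angle."""

    flexion_angle: float
    transform: RigidTransform
    convention: str = "knee-xzy-intrinsic"

    @property
    def dof(self) -> np.ndarray:
        return decompose_6dof(self.transform, self.convention)

    def __post_init__(self):
        # round-trip check: the dof must reproduce the transform
        try:
            dof = self.dof
        except GimbalLockError:
            return  # pose is valid; only its Euler decomposition is not
        back = recompose_6dof(dof, self.convention)
        err = max(
            np.max(np.abs(back.rotation - self.transform.rotation)),
            np.max(np.abs(back.translation - self.transform.translation)),
        )
        if err > 1e-8:
            raise ValidationError(f"dof round-trip error {err:.2e}")


@dataclass(frozen=True)
class LungeParams:
    """Generator parameters for a synthetic lunge pose sequence.

    ``rotation_center`` sets where the flexion axis pierces the sagittal
    plane (near the femoral aperture makes the graft near-isometric);
    ``ap_translation_per_deg`` and ``ir_rotation_per_deg`` are small
    physiologic couplings; ``span_strain_targets`` schedules the graft
    attachment-to-attachment elongation (the lunge "distraction"), clipped
    to ``distraction_bounds``; ``jitter`` adds seeded noise (mm / deg) for
    robustness studies, default 0.
    """

    angles: tuple = (0.0, 30.0, 60.0, 90.0)
    flexion_axis: tuple = (1.0, 0.0, 0.0)
    rotation_center: tuple = (0.0, 0.0, 0.0)
    ap_translation_per_deg: float = 0.0
    ir_rotation_per_deg: float = 0.0
    femoral_attachment: tuple = (0.0, 14.0, -4.0)
    tibial_attachment: tuple = (0.0, 0.0, 0.0)
    span_strain_targets: tuple = (0.0, 0.0, 0.0, 0.0)
    distraction_bounds: tuple = (-0.1, 0.1)   # allowed span strain range
    jitter: float = 0.0

    def __post_init__(self):
        if len(self.angles) < 1:
            raise ValidationError("at least one flexion angle required")
        a = np.asarray(self.angles, dtype=float)
        if np.any(a < 0.0) or np.any(a > 150.0):
            raise ValidationError("flexion angles must lie in [0, 150] deg")
        if np.any(np.diff(a) <= 0.0):
            raise ValidationError("flexion angles must strictly increase")
        if a[0] != 0.0:
            raise ValidationError("the profile must start at 0 deg")
        if len(self.span_strain_targets) != len(self.angles):
            raise ValidationError(
                "span_strain_targets must match the number of angles"
            )


@dataclass(frozen=True)
class LungeProfile:
    """Ordered femoral poses over a lunge; provenance and seed recorded."""

    poses: tuple
    provenance: str = "synthetic"
    params: LungeParams | None = None
    seed: int | None = None

    def __post_init__(self):
        angles = [p.flexion_angle for p in self.poses]
        if np.any(np.diff(angles) <= 0.0):
            raise ValidationError("pose angles must strictly increase")
        if not self.poses[0].transform.is_identity(1e-9):
            raise ValidationError("the 0 deg reference pose must be identity")

    @property
    def angles(self) -> list:
        return [p.flexion_angle for p in self.poses]


def _axis_rotation(axis, deg):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.radians(deg) * axis).as_matrix()


def synthesize_lunge_profile(params: LungeParams, seed: int = 0
                             ) -> LungeProfile:
    """Deterministic synthetic 6DOF lunge pose sequence.

    For each flexion angle: rotate about the flexion axis through
    ``rotation_center`` (plus the coupled internal rotation about the
    proximal axis through the same centre), add the coupled anterior
    translation, then correct the translation along the graft span so the
    femoral-to-tibial attachment distance matches the scheduled span
    strain (clipped to the distraction bounds).  Identity at 0 deg.
    """
    rng = np.random.default_rng(seed)
    Ef = np.asarray(params.femoral_attachment, dtype=float)
    Pt = np.asarray(params.tibial_attachment, dtype=float)
    L0 = float(np.linalg.norm(Ef - Pt))
    poses = []
    for i, ang in enumerate(params.angles):
        if ang == 0.0:
            poses.append(FlexionPose(0.0, RigidTransform.identity()))
            continue
        jit = rng.normal(0.0, params.jitter, size=4) if params.jitter else \
            np.zeros(4)
        Rf = _axis_rotation(params.flexion_axis, ang + jit[0])
        Rir = _axis_rotation((0.0, 1.0, 0.0),
                             params.ir_rotation_per_deg * ang + jit[1])
        T = RigidTransform.about_point(Rf @ Rir, params.rotation_center)
        t = T.translation + np.array(
            [0.0, 0.0, params.ap_translation_per_deg * ang + jit[2]]
        )
        T = RigidTransform(T.rotation, t)
        # distraction correction along the deformed span direction
        target = float(np.clip(
            params.span_strain_targets[i] + jit[3] * 1e-3,
            *params.distraction_bounds,
        ))
        Ef_new = T.apply(Ef)
        span = Ef_new - Pt
        Ls = float(np.linalg.norm(span))
        if Ls > 1e-9:
            corr = (L0 * (1.0 + target) - Ls) * span / Ls
            T = RigidTransform(T.rotation, T.translation + corr)
        poses.append(FlexionPose(float(ang), T))
    return LungeProfile(
        poses=tuple(poses), provenance="synthetic", params=params, seed=seed
    )


def scale_pose(transform: RigidTransform, s: float) -> RigidTransform:
    """Geodesic interpolation towards a pose: scale the rotation angle and
    translation by s in [0, 1] (used for incremental pose application)."""
    rv = Rotation.from_matrix(transform.rotation).as_rotvec()
    R = Rotation.from_rotvec(s * rv).as_matrix()
    return RigidTransform(R, s * transform.translation)
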