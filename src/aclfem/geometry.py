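"""Tunnel cross-sections and idealized solids for flattened-tunnel ACL models.

The femoral tunnel family keeps the cross-sectional area of the round 8-mm
tunnel constant while flattening it into a "rounded rectangle": a rectangle
of length ``L`` capped by two semicircles of radius ``R``, so that

    S = L * 2R + pi * R**2.

``L = 0`` degenerates to a circle of radius ``R = sqrt(S/pi)``.  The long
axis (``L + 2R``) grows and the short axis (``2R``) shrinks as ``L``
increases, which is how a wider portion of the ACL direct insertion is
covered without changing graft volume.

All coordinates are millimetres, right-handed; tunnel axes are unit vectors
and extrusion is along the local +z of the tunnel frame.  Boundary polylines
are closed and counter-clockwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, ValidationError

__all__ = [
    "CrossSection",
    "TunnelSpec",
    "BoneBlockSpec",
    "GraftSpec",
    "solve_rounded_rectangle_radius",
    "make_tunnel_family",
    "cross_section_boundary",
    "section_ray_radius",
]

_AREA_RTOL = 1e-9


@dataclass(frozen=True)
class CrossSection:
    """A constant-area tunnel aperture: circle or rounded rectangle.

    Parameters are the rectangular-region length ``L`` (mm), the corner/end
    radius ``R`` (mm) and the cross-sectional area ``S`` (mm^2); the class
    validates the defining area relation on construction.
    """

    kind: str          # "circle" | "rounded_rectangle"
    L: float           # rectangular-region length, mm
    R: float           # corner/end radius, mm
    S: float           # cross-sectional area, mm^2

    def __post_init__(self):
        if self.kind not in ("circle", "rounded_rectangle"):
            raise ValidationError(f"unknown section kind {self.kind!r}")
        if (self.kind == "circle") != (self.L == 0.0):
            raise ValidationError("kind must be 'circle' iff L == 0")
        if self.R <= 0.0:
            raise ValidationError("R must be positive")
        area = self.L * 2.0 * self.R + math.pi * self.R**2
        if abs(area - self.S) > _AREA_RTOL * abs(self.S):
            raise ValidationError(
                f"S={self.S} inconsistent with L={self.L}, R={self.R} "
                f"(L*2R + pi*R^2 = {area})"
            )

    @property
    def long_axis(self) -> float:
        """L + 2R, mm."""
        return self.L + 2.0 * self.R

    @property
    def short_axis(self) -> float:
        """2R, mm."""
        return 2.0 * self.R

    @classmethod
    def from_area(cls, L: float, S: float) -> "CrossSection":
        R = solve_rounded_rectangle_radius(L, S)
        kind = "circle" if L == 0.0 else "rounded_rectangle"
        return cls(kind=kind, L=float(L), R=R, S=float(S))


def solve_rounded_rectangle_radius(L: float, S: float) -> float:
    """Radius of the rounded rectangle of rectangular length L and area S.

    Solves ``pi*R**2 + 2*L*R - S = 0`` for its unique positive root

        R = (-L + sqrt(L**2 + pi*S)) / pi

    which for ``L = 0`` reduces to the circle radius ``sqrt(S/pi)``.
    """
    if not np.isfinite(L) or L < 0.0:
        raise DomainError(f"L must be finite and non-negative, got L={L}")
    if not np.isfinite(S) or S <= 0.0:
        raise DomainError(f"S must be finite and positive, got S={S}")
    R = (-L + math.sqrt(L * L + math.pi * S)) / math.pi
    return R


def make_tunnel_family(round_diameter: float, L_values) -> list[CrossSection]:
    """The constant-area tunnel family: one circle plus flattened members.

    The first element is the round tunnel (L=0, diameter ``round_diameter``);
    each subsequent ``L`` produces a rounded rectangle of identical area.
    """
    if round_diameter <= 0.0:
        raise DomainError(
            f"round_diameter must be positive, got {round_diameter}"
        )
    L_values = [float(L) for L in L_values]
    if any(L < 0.0 for L in L_values):
        raise DomainError("L_values must be non-negative")
    if len(set(L_values)) != len(L_values) or 0.0 in L_values:
        raise ValidationError(
            "duplicate L values in tunnel family (the circle is L=0)"
        )
    S = math.pi * (round_diameter / 2.0) ** 2
    family = [CrossSection.from_area(0.0, S)]
    for L in sorted(L_values):
        family.append(CrossSection.from_area(L, S))
    return family


def section_ray_radius(section: CrossSection, theta) -> np.ndarray:
    """Distance from the section centre to its boundary along angle theta.

    The rounded rectangle (rectangle length L along local x, capped by
    radius-R semicircles) is star-shaped about its centre, so this is
    single-valued.  Vectorized over ``theta``.
    """
    theta = np.asarray(theta, dtype=float)
    c, s = np.cos(theta), np.sin(theta)
    L2, R = section.L / 2.0, section.R
    if L2 == 0.0:
        return np.full(theta.shape, R)
    # side region: |t*c| <= L/2 with t = R/|s|
    with np.errstate(divide="ignore"):
        t_side = R / np.abs(s)
    side = t_side * np.abs(c) <= L2
    # cap region: (t|c| - L/2)^2 + (t s)^2 = R^2, take the positive root
    b = -2.0 * L2 * np.abs(c)
    q = L2**2 - R**2
    disc = np.maximum(b * b - 4.0 * q, 0.0)   # side branch may go negative
    t_cap = (-b + np.sqrt(disc)) / 2.0
    return np.where(side, t_side, t_cap)


def cross_section_boundary(section: CrossSection, n_points: int) -> np.ndarray:
    """Closed counter-clockwise boundary polyline of a section, shape (n+1, 2).

    Two straight segments of length L joined by semicircular arcs of radius
    R; a pure circle when L = 0.  The first point is repeated at the end.
    """
    if n_points < 16:
        raise ValidationError(f"n_points must be >= 16, got {n_points}")
    L2, R = section.L / 2.0, section.R
    if L2 == 0.0:
        th = np.linspace(0.0, 2.0 * math.pi, n_points, endpoint=False)
        pts = np.column_stack([R * np.cos(th), R * np.sin(th)])
    else:
        perim_arc = math.pi * R          # each semicircular cap
        perim_side = section.L           # each straight side
        total = 2.0 * (perim_arc + perim_side)
        n_arc = max(4, int(round(n_points * perim_arc / total)))
        n_side = max(2, (n_points - 2 * n_arc) // 2)
        # right cap: theta -pi/2 -> pi/2 centred at (+L/2, 0)
        th_r = np.linspace(-math.pi / 2, math.pi / 2, n_arc, endpoint=False)
        cap_r = np.column_stack([L2 + R * np.cos(th_r), R * np.sin(th_r)])
        # top side: x from +L/2 to -L/2 at y = +R
        xs = np.linspace(L2, -L2, n_side, endpoint=False)
        top = np.column_stack([xs, np.full(n_side, R)])
        th_l = np.linspace(math.pi / 2, 3 * math.pi / 2, n_arc, endpoint=False)
        cap_l = np.column_stack([-L2 + R * np.cos(th_l), R * np.sin(th_l)])
        xs2 = np.linspace(-L2, L2, n_side, endpoint=False)
        bot = np.column_stack([xs2, np.full(n_side, -R)])
        pts = np.vstack([cap_r, top, cap_l, bot])
    return np.vstack([pts, pts[:1]])


def polygon_area(poly: np.ndarray) -> float:
    """Shoelace area of a closed 2D polyline (positive if counter-clockwise)."""
    x, y = poly[:-1, 0], poly[:-1, 1]
    xn, yn = poly[1:, 0], poly[1:, 1]
    return 0.5 * float(np.sum(x * yn - xn * y))


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValidationError("zero-length direction vector")
    return v / n


@dataclass(frozen=True)
class TunnelSpec:
    """A drilled tunnel: aperture section, axis, entrance point and length.

    Orientation metadata records the surgical convention: the femoral tunnel
    is perpendicular to the (idealized, planar) medial wall of the lateral
    condyle; the tibial tunnel is drilled at 15 deg in the front view and
    55 deg in the sagittal view.
    """

    section: CrossSection
    axis: tuple = (0.0, 0.0, 1.0)
    entrance_point: tuple = (0.0, 0.0, 0.0)
    length: float = 30.0
    orientation: str = "femoral_perpendicular_to_medial_wall"

    def __post_init__(self):
        ax = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(ax) - 1.0) > 1e-12:
            raise ValidationError("tunnel axis must have unit norm")
        if not self.length > 0.0:
            raise ValidationError("tunnel length must be positive")

    @property
    def axis_vec(self) -> np.ndarray:
        return np.asarray(self.axis, dtype=float)

    @property
    def entrance(self) -> np.ndarray:
        return np.asarray(self.entrance_point, dtype=float)


@dataclass(frozen=True)
class BoneBlockSpec:
    """Idealized femoral bone block with a through-tunnel.

    ``extents`` are the block dimensions (mm) in the tunnel-local frame
    (tunnel axis = local +z, entrance at local z=0); ``cortical_thickness``
    is the rigid cortical shell thickness measured from the outer surface.
    """

    extents: tuple = (30.0, 30.0, 30.0)
    cortical_thickness: float = 2.0
    tunnel: TunnelSpec | None = None

    def __post_init__(self):
        ext = np.asarray(self.extents, dtype=float)
        if np.any(ext <= 0.0):
            raise ValidationError("block extents must be positive")
        if not 0.0 < self.cortical_thickness < 0.5 * float(ext.min()):
            raise ValidationError(
                "cortical_thickness must be positive and smaller than half "
                "the minimum block extent"
            )


@dataclass(frozen=True)
class GraftSpec:
    """The soft-tissue graft: one section swept along a tunnel-to-tunnel path.

    The graft keeps the femoral-tunnel cross-section over its full length
    (graft volume constancy is the controlled variable); the round tibial
    tunnel is opened to clear flattened sections.  ``embedded_depth`` is how
    far the graft extends into each tunnel (default 20 mm).
    """

    section: CrossSection
    path: tuple = ()                 # polyline vertices, mm
    embedded_depth: float = 20.0
    long_axis_direction: tuple = (1.0, 0.0, 0.0)

    def __post_init__(self):
        pts = np.asarray(self.path, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
            raise ValidationError("graft path must be >=2 points in 3D")
        seg = np.diff(pts, axis=0)
        if np.any(np.linalg.norm(seg, axis=1) == 0.0):
            raise ValidationError("graft path has a zero-length segment")
        if _path_self_intersects(pts):
            raise ValidationError("graft path is self-intersecting")
        if self.embedded_depth <= 0.0:
            raise ValidationError("embedded_depth must be positive")

    @property
    def path_points(self) -> np.ndarray:
        return np.asarray(self.path, dtype=float)

    @property
    def path_length(self) -> float:
        pts = self.path_points
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _path_self_intersects(pts: np.ndarray, tol: float = 1e-9) -> bool:
    """Cheap simplicity check: non-adjacent segments must not come closer
    than ``tol`` to each other."""
    segs = [(pts[i], pts[i + 1]) for i in range(len(pts) - 1)]
    for i in range(len(segs)):
        for j in range(i + 2, len(segs)):
            if _segment_distance(*segs[i], *segs[j]) < tol:
                return True
    return False


def _segment_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between 3D segments [p0,p1] and [q0,q1]."""
    u, v, w = p1 - p0, q1 - q0, p0 - q0
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    den = a * c - b * b
    s = np.clip((b * e - c * d) / den, 0.0, 1.0) if den > 1e-14 else 0.0
    t = np.clip((b * s + e) / c, 0.0, 1.0) if c > 1e-14 else 0.0
    s = np.clip((b * t - d) / a, 0.0, 1.0) if a > 1e-14 else s
    return float(np.linalg.norm(w + s * u - t * v))
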