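"""Built-in structured meshing: hex graft extrusion and tet bone blocks.

The graft is meshed with eight-node hexahedra by sweeping an all-quad
cross-section mesh along its path; the cross-section quads come from an
elliptical square-to-disk map radially scaled onto the (star-shaped)
rounded-rectangle boundary, then rescaled so the discrete section area
equals the analytic area exactly.  The bone block is meshed with four-node
tetrahedra by carving the tunnel out of a graded tensor-product voxel grid
(six positively-oriented tets per box), refined around the tunnel entrances.

No external mesh generator is required; everything runs in-process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    GeometryError,
    InvertedElementError,
    MeshingError,
    ValidationError,
)
from .geometry import BoneBlockSpec, CrossSection, section_ray_radius

__all__ = [
    "Mesh",
    "MeshSizeSpec",
    "extrude_graft_mesh",
    "extrude_quad_mesh",
    "section_quad_mesh",
    "bone_block_mesh",
    "element_volume",
    "element_volumes",
    "check_convergence",
    "transform_mesh",
]

# natural coordinates of the hex8 nodes (VTK/Abaqus ordering)
HEX_XI = np.array(
    [
        [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
    ],
    dtype=float,
)
# outward-facing quad faces of a hex8
HEX_FACES = np.array(
    [[0, 3, 2, 1], [4, 5, 6, 7], [0, 1, 5, 4],
     [1, 2, 6, 5], [2, 3, 7, 6], [3, 0, 4, 7]]
)
# outward-facing tri faces of a tet4
TET_FACES = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])

_GP_1D = np.array([-1.0, 1.0]) / math.sqrt(3.0)


def hex_gauss_points() -> np.ndarray:
    """The 2x2x2 Gauss points in natural coordinates, shape (8, 3)."""
    g = _GP_1D
    pts = np.array([[a, b, c] for c in g for b in g for a in g])
    return pts


def hex_shape_gradients(xi: np.ndarray) -> np.ndarray:
    """dN_a/dxi at natural points ``xi`` (m,3) -> (m, 8, 3)."""
    xi = np.atleast_2d(xi)
    out = np.empty((xi.shape[0], 8, 3))
    for a in range(8):
        xa, ya, za = HEX_XI[a]
        out[:, a, 0] = 0.125 * xa * (1 + ya * xi[:, 1]) * (1 + za * xi[:, 2])
        out[:, a, 1] = 0.125 * ya * (1 + xa * xi[:, 0]) * (1 + za * xi[:, 2])
        out[:, a, 2] = 0.125 * za * (1 + xa * xi[:, 0]) * (1 + ya * xi[:, 1])
    return out


@dataclass
class Mesh:
    """Unstructured single-element-type mesh with region and surface tags.

    ``region`` assigns exactly one region name per element (graft,
    cancellous, cortical_shell); ``surfaces`` are named facet sets (node
    index tuples into ``nodes``); ``element_sets`` are named element-index
    sets; ``point_data`` carries per-node scalars (e.g. arc length along
    the graft path).
    """

    nodes: np.ndarray
    element_type: str               # 'hex8' | 'tet4'
    elements: np.ndarray
    region: np.ndarray
    surfaces: dict = field(default_factory=dict)
    element_sets: dict = field(default_factory=dict)
    point_data: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.region = np.asarray(self.region)
        if self.element_type not in ("hex8", "tet4"):
            raise ValidationError(f"unknown element type {self.element_type}")
        k = 8 if self.element_type == "hex8" else 4
        if self.elements.ndim != 2 or self.elements.shape[1] != k:
            raise ValidationError(
                f"{self.element_type} connectivity must be (ne, {k})"
            )
        if self.region.shape[0] != self.elements.shape[0]:
            raise ValidationError("region tag array must match element count")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def boundary_facets(self) -> set:
        """All element-boundary facets as frozensets of node ids."""
        faces = HEX_FACES if self.element_type == "hex8" else TET_FACES
        out = set()
        for conn in self.elements:
            for f in faces:
                out.add(frozenset(conn[f]))
        return out

    def validate(self):
        """Check the core invariants: finite coords, positive volumes,
        surface facets lying on element boundaries."""
        if not np.all(np.isfinite(self.nodes)):
            raise ValidationError("non-finite node coordinates")
        vols = element_volumes(self)
        if np.any(vols <= 0.0):
            eid = int(np.argmin(vols))
            raise InvertedElementError(eid, float(vols[eid]))
        bset = self.boundary_facets()
        for name, facets in self.surfaces.items():
            for f in np.atleast_2d(facets):
                if frozenset(f) not in bset:
                    raise ValidationError(
                        f"surface '{name}' facet {tuple(f)} is not an "
                        "element boundary facet"
                    )
        return self


@dataclass(frozen=True)
class MeshSizeSpec:
    """Target element sizes (mm) and the desk-scale coarsening factor.

    ``scale_factor`` in (0, 1] scales mesh *density*: effective element
    size is ``size / scale_factor``, so 1.0 reproduces the reference
    density (graft 1.0-1.2 mm, bone 1.4 mm, 1.0 mm refined around tunnel
    entrances) and smaller values coarsen for quick desk runs.
    """

    graft_size: float = 1.1
    bone_size: float = 1.4
    entrance_refined_size: float = 1.0
    refinement_radius: float = 6.0
    scale_factor: float = 1.0

    def __post_init__(self):
        for name in ("graft_size", "bone_size", "entrance_refined_size",
                     "refinement_radius"):
            if not getattr(self, name) > 0.0:
                raise ValidationError(f"{name} must be positive")
        if self.entrance_refined_size > self.bone_size:
            raise ValidationError("refined size must be <= bone size")
        if not 0.0 < self.scale_factor <= 1.0:
            raise ValidationError("scale_factor must be in (0, 1]")

    @property
    def eff_graft(self) -> float:
        return self.graft_size / self.scale_factor

    @property
    def eff_bone(self) -> float:
        return self.bone_size / self.scale_factor

    @property
    def eff_refined(self) -> float:
        return self.entrance_refined_size / self.scale_factor


# ----------------------------------------------------------------- graft hex

def section_quad_mesh(section: CrossSection, size: float):
    """All-quad mesh of a tunnel cross-section, area-exact.

    An n x n grid on [-1,1]^2 is mapped to the unit disk with the
    elliptical map, radially scaled onto the section boundary, then
    uniformly rescaled so the summed quad area equals ``section.S``
    exactly (the boundary polygon is inscribed, so raw area is biased
    low by O(1/n^2)).  Returns (points (np,2), quads (nq,4),
    boundary_edges (nb,2) counter-clockwise).

    The grid resolution is set from the area-equivalent diameter, so all
    members of a constant-area tunnel family share one mesh topology and
    differ only in node placement.
    """
    d_eq = 2.0 * math.sqrt(section.S / math.pi)
    n = max(4, int(round(d_eq / size)))
    u = np.linspace(-1.0, 1.0, n + 1)
    X, Y = np.meshgrid(u, u, indexing="ij")
    # elliptical square-to-disk map
    dx = X * np.sqrt(np.maximum(0.0, 1.0 - 0.5 * Y**2))
    dy = Y * np.sqrt(np.maximum(0.0, 1.0 - 0.5 * X**2))
    rho = np.hypot(dx, dy)
    th = np.arctan2(dy, dx)
    rb = section_ray_radius(section, th)
    with np.errstate(invalid="ignore"):
        scale = np.where(rho > 0, rb, 1.0)
    px = dx * scale
    py = dy * scale
    pts = np.column_stack([px.ravel(), py.ravel()])

    def nid(i, j):
        return i * (n + 1) + j

    quads = []
    for i in range(n):
        for j in range(n):
            quads.append([nid(i, j), nid(i + 1, j),
                          nid(i + 1, j + 1), nid(i, j + 1)])
    quads = np.asarray(quads, dtype=np.int64)
    # enforce counter-clockwise quads
    area = _quad_areas(pts, quads)
    flip = area < 0
    quads[flip] = quads[flip][:, ::-1]
    total = float(np.abs(area).sum())
    pts *= math.sqrt(section.S / total)

    # boundary edges, ordered counter-clockwise around the grid perimeter
    edges = []
    for j in range(n):                     # i = n side upward? walk perimeter
        edges.append((nid(n, j), nid(n, j + 1)))
    for i in range(n, 0, -1):
        edges.append((nid(i, n), nid(i - 1, n)))
    for j in range(n, 0, -1):
        edges.append((nid(0, j), nid(0, j - 1)))
    for i in range(n):
        edges.append((nid(i, 0), nid(i + 1, 0)))
    return pts, quads, np.asarray(edges, dtype=np.int64)


def _quad_areas(pts, quads):
    p = pts[quads]
    x, y = p[..., 0], p[..., 1]
    xn, yn = np.roll(x, -1, axis=1), np.roll(y, -1, axis=1)
    return 0.5 * np.sum(x * yn - xn * y, axis=1)


def fillet_path(path, radii, h: float) -> np.ndarray:
    """Blend every interior corner of a polyline with a circular arc.

    ``radii`` is a scalar or one radius per interior vertex; arcs are
    sampled at roughly ``h`` spacing.  Tangent offsets are clamped to
    45% of the adjacent segment lengths (shrinking the radius if needed)
    so fillets never overlap.  Sweeping a section whose half-thickness
    in the bending plane is below the fillet radius keeps all swept
    elements positively oriented.
    """
    path = np.asarray(path, dtype=float)
    ncorner = len(path) - 2
    radii = np.broadcast_to(np.asarray(radii, float), (ncorner,))
    out = [path[0]]
    for i in range(1, len(path) - 1):
        p_prev, p, p_next = out[-1], path[i], path[i + 1]
        u = p - p_prev
        lu = np.linalg.norm(u)
        u /= lu
        v = p_next - p
        lv = np.linalg.norm(v)
        v /= lv
        cosphi = float(np.clip(u @ v, -1.0, 1.0))
        phi = math.acos(cosphi)
        if phi < 1e-9:
            out.append(p)
            continue
        r = radii[i - 1]
        t_off = r * math.tan(phi / 2.0)
        t_max = 0.45 * min(lu, lv)
        if t_off > t_max:
            t_off = t_max
            r = t_off / math.tan(phi / 2.0)
        A = p - u * t_off
        axis = np.cross(u, v)
        axis /= np.linalg.norm(axis)
        center = A + r * np.cross(axis, u)
        narc = max(2, int(math.ceil(phi * r / h)))
        for j in range(narc + 1):
            ang = phi * j / narc
            out.append(center + _rodrigues(A - center, axis, ang))
    out.append(path[-1])
    return np.asarray(out)


def _resample_path(path: np.ndarray, h: float):
    """Stations along a polyline at ~h spacing, keeping the knots.

    Returns (points (m,3), tangents (m,3), arclength (m,))."""
    pts = [path[0]]
    s = [0.0]
    tans = []
    acc = 0.0
    for k in range(len(path) - 1):
        seg = path[k + 1] - path[k]
        L = float(np.linalg.norm(seg))
        nsub = max(1, int(round(L / h)))
        d = seg / L
        for i in range(1, nsub + 1):
            pts.append(path[k] + seg * (i / nsub))
            s.append(acc + L * i / nsub)
            tans.append(d)
        acc += L
    pts = np.asarray(pts)
    s = np.asarray(s)
    tans = np.asarray(tans)
    # nodal tangents: average adjacent segment directions
    tn = np.empty_like(pts)
    tn[0] = tans[0]
    tn[-1] = tans[-1]
    for i in range(1, len(pts) - 1):
        v = tans[i - 1] + tans[i]
        tn[i] = v / np.linalg.norm(v)
    return pts, tn, s


def _transport_frames(tangents: np.ndarray, e1_seed: np.ndarray):
    """Parallel-transport an in-plane frame along the station tangents."""
    m = tangents.shape[0]
    e1 = np.empty((m, 3))
    v = e1_seed - (e1_seed @ tangents[0]) * tangents[0]
    nv = np.linalg.norm(v)
    if nv < 1e-12:
        raise ValidationError("long-axis direction parallel to path tangent")
    e1[0] = v / nv
    for i in range(1, m):
        t0, t1 = tangents[i - 1], tangents[i]
        c = np.cross(t0, t1)
        sn = np.linalg.norm(c)
        if sn < 1e-14:
            e1[i] = e1[i - 1]
        else:
            axis = c / sn
            cs = float(np.clip(t0 @ t1, -1.0, 1.0))
            ang = math.atan2(sn, cs)
            e1[i] = _rodrigues(e1[i - 1], axis, ang)
        # re-orthogonalize against drift
        e1[i] -= (e1[i] @ t1) * t1
        e1[i] /= np.linalg.norm(e1[i])
    e2 = np.cross(tangents, e1)
    return e1, e2


def _rodrigues(v, axis, ang):
    return (v * math.cos(ang) + np.cross(axis, v) * math.sin(ang)
            + axis * (axis @ v) * (1 - math.cos(ang)))


def transport_seed_from_end(path, axial_size, e1_end) -> np.ndarray:
    """Start-of-path frame seed whose parallel transport reproduces
    ``e1_end`` on the final segment (inverse transport along the same
    stations the extrusion will use)."""
    path = np.asarray(path, dtype=float)
    _, T, _ = _resample_path(path, axial_size)
    e = np.asarray(e1_end, dtype=float)
    e = e - (e @ T[-1]) * T[-1]
    e /= np.linalg.norm(e)
    for i in range(len(T) - 1, 0, -1):
        t1, t0 = T[i], T[i - 1]
        c = np.cross(t1, t0)
        sn = np.linalg.norm(c)
        if sn >= 1e-14:
            axis = c / sn
            ang = math.atan2(sn, float(np.clip(t1 @ t0, -1, 1)))
            e = _rodrigues(e, axis, ang)
        e = e - (e @ t0) * t0
        e /= np.linalg.norm(e)
    return e


def extrude_quad_mesh(points2d, quads, bedges, path, axial_size,
                      long_axis_direction=(1.0, 0.0, 0.0)) -> Mesh:
    """Sweep an arbitrary quad mesh along a polyline path into hex8 elements.

    Cross-sections sit perpendicular to the path tangent in
    parallel-transported frames (no spurious twist); the local +x of the
    2D mesh follows ``long_axis_direction`` projected at the path start.
    """
    path = np.asarray(path, dtype=float)
    total = float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))
    if total < axial_size:
        raise MeshingError(
            f"path length {total:.3g} mm shorter than one axial element "
            f"({axial_size:.3g} mm)"
        )
    P, T, s = _resample_path(path, axial_size)
    e1, e2 = _transport_frames(T, np.asarray(long_axis_direction, float))
    npt2 = points2d.shape[0]
    m = P.shape[0]
    nodes = (P[:, None, :]
             + points2d[None, :, 0, None] * e1[:, None, :]
             + points2d[None, :, 1, None] * e2[:, None, :]).reshape(-1, 3)
    node_s = np.repeat(s, npt2)

    hexes = []
    for lay in range(m - 1):
        lo = lay * npt2
        hi = (lay + 1) * npt2
        for q in quads:
            hexes.append([lo + q[0], lo + q[1], lo + q[2], lo + q[3],
                          hi + q[0], hi + q[1], hi + q[2], hi + q[3]])
    hexes = np.asarray(hexes, dtype=np.int64)

    start_face = quads[:, ::-1].copy()            # outward normal = -t
    stop_face = quads + (m - 1) * npt2
    wall = []
    wall_s = []
    for lay in range(m - 1):
        lo, hi = lay * npt2, (lay + 1) * npt2
        for a, b in bedges:
            wall.append([lo + a, lo + b, hi + b, hi + a])
            wall_s.append(0.5 * (s[lay] + s[lay + 1]))
    wall = np.asarray(wall, dtype=np.int64)
    surfaces = {
        "graft_end_start": start_face,
        "graft_end_stop": stop_face,
        "graft_end": np.vstack([start_face, stop_face]),
        "graft_wall": wall,
    }
    mesh = Mesh(
        nodes=nodes,
        element_type="hex8",
        elements=hexes,
        region=np.full(len(hexes), "graft"),
        surfaces=surfaces,
        point_data={"path_arclength": node_s},
    )
    mesh.point_data["_wall_facet_s"] = np.asarray(wall_s)
    return mesh


def extrude_graft_mesh(section: CrossSection, path, sizes: MeshSizeSpec,
                       long_axis_direction=(1.0, 0.0, 0.0),
                       tibial_embed: float | None = None,
                       femoral_embed: float | None = None) -> Mesh:
    """Hex8 mesh of the graft swept along its path.

    The path runs tibial end -> femoral end.  If embed depths are given,
    lateral wall facets within ``tibial_embed`` of the start are tagged
    ``tibial_tunnel_wall`` and those within ``femoral_embed`` of the far
    end ``femoral_tunnel_wall``; end facets are tagged ``graft_end`` (with
    ``graft_end_tibial`` / ``graft_end_femoral`` aliases).
    """
    h = sizes.eff_graft
    pts2, quads, bedges = section_quad_mesh(section, h)
    mesh = extrude_quad_mesh(pts2, quads, bedges, path, h,
                             long_axis_direction)
    mesh.surfaces["graft_end_tibial"] = mesh.surfaces["graft_end_start"]
    mesh.surfaces["graft_end_femoral"] = mesh.surfaces["graft_end_stop"]
    ws = mesh.point_data.pop("_wall_facet_s")
    total = float(mesh.point_data["path_arclength"].max())
    wall = mesh.surfaces["graft_wall"]
    if tibial_embed is not None:
        mesh.surfaces["tibial_tunnel_wall"] = wall[ws <= tibial_embed]
    if femoral_embed is not None:
        mesh.surfaces["femoral_tunnel_wall"] = wall[ws >= total - femoral_embed]
    return mesh


# ----------------------------------------------------------------- bone tets

def graded_axis(lo: float, hi: float, coarse: float, fine: float,
                fine_intervals=()) -> np.ndarray:
    """1D grid from lo to hi with spacing ``fine`` inside the given
    intervals and ``coarse`` elsewhere; breakpoints are honoured exactly."""
    cuts = {lo, hi}
    for a, b in fine_intervals:
        a, b = max(lo, a), min(hi, b)
        if a < b:
            cuts.update((a, b))
    cuts = sorted(cuts)
    pts = [lo]
    for a, b in zip(cuts[:-1], cuts[1:]):
        mid = 0.5 * (a + b)
        h = fine if any(ia <= mid <= ib for ia, ib in fine_intervals) else coarse
        nsub = max(1, int(round((b - a) / h)))
        pts.extend(np.linspace(a, b, nsub + 1)[1:])
    return np.asarray(pts)


# six tets around the main diagonal of a cube whose vertices are indexed
# in binary order (bit0=x, bit1=y, bit2=z); all positively oriented
_CUBE_TETS = np.array([
    [0, 1, 3, 7], [0, 3, 2, 7], [0, 2, 6, 7],
    [0, 6, 4, 7], [0, 4, 5, 7], [0, 5, 1, 7],
])


def _section_distance(section: CrossSection, x, y, angle=0.0):
    """Distance from points to the section's medial axis minus nothing:
    the rounded rectangle is the locus distance <= R."""
    c, s = math.cos(angle), math.sin(angle)
    xr = c * x + s * y
    yr = -s * x + c * y
    return np.hypot(np.maximum(np.abs(xr) - section.L / 2.0, 0.0), yr)


def bone_block_mesh(block: BoneBlockSpec, sizes: MeshSizeSpec,
                    long_axis_angle: float = 0.0) -> Mesh:
    """Tet4 mesh of the bone block minus the through-tunnel.

    Built in the tunnel-local frame (tunnel axis = +z, entrance at z=0,
    block centred in x and y).  A tensor-product voxel grid, graded to
    ``entrance_refined_size`` within ``refinement_radius`` of the two
    tunnel entrances, is carved (voxel centres inside the tunnel dropped)
    and each surviving box is split into six tets.  Elements whose
    centroid lies within the refinement radius of an entrance are tagged
    ``tunnel_entrance_zone``.
    """
    ax, ay, az = (float(v) for v in block.extents)
    hc, hf, rr = sizes.eff_bone, sizes.eff_refined, sizes.refinement_radius
    tun = block.tunnel
    if tun is not None:
        half_long = tun.section.long_axis / 2.0
        if half_long >= min(ax, ay) / 2.0:
            raise GeometryError("tunnel aperture wider than the bone block")
        fx = [(-rr, rr)]
        fy = [(-rr, rr)]
        fz = [(0.0, rr), (az - rr, az)]
    else:
        fx = fy = fz = ()
    xs = graded_axis(-ax / 2, ax / 2, hc, hf, fx)
    ys = graded_axis(-ay / 2, ay / 2, hc, hf, fy)
    zs = graded_axis(0.0, az, hc, hf, fz)
    nx, ny, nz = len(xs), len(ys), len(zs)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    # voxel centres
    cx = 0.5 * (xs[:-1] + xs[1:])
    cy = 0.5 * (ys[:-1] + ys[1:])
    cz = 0.5 * (zs[:-1] + zs[1:])
    CX, CY, CZ = np.meshgrid(cx, cy, cz, indexing="ij")
    if tun is not None:
        dist = _section_distance(tun.section, CX, CY, long_axis_angle)
        keep = dist > tun.section.R
        if not np.any(~keep):
            raise GeometryError("tunnel does not intersect the block")
    else:
        keep = np.ones(CX.shape, dtype=bool)

    ii, jj, kk = np.nonzero(keep)
    # cube corners in bit order (bit0=x, bit1=y, bit2=z)
    corners = np.empty((len(ii), 8), dtype=np.int64)
    for b in range(8):
        di, dj, dk = b & 1, (b >> 1) & 1, (b >> 2) & 1
        corners[:, b] = nid(ii + di, jj + dj, kk + dk)
    tets = corners[:, _CUBE_TETS].reshape(-1, 4)

    # compact unused nodes
    used = np.unique(tets)
    remap = -np.ones(nodes.shape[0], dtype=np.int64)
    remap[used] = np.arange(len(used))
    tets = remap[tets]
    nodes = nodes[used]

    mesh = Mesh(
        nodes=nodes,
        element_type="tet4",
        elements=tets,
        region=np.full(len(tets), "cancellous"),
    )
    # fix orientation if any split came out negative (shouldn't, but cheap)
    vols = element_volumes(mesh)
    bad = vols < 0
    if np.any(bad):
        mesh.elements[bad] = mesh.elements[bad][:, [0, 1, 3, 2]]

    # classify boundary facets: outer block surface vs tunnel wall
    facets = _boundary_tris(tets)
    fc = nodes[facets].mean(axis=1)
    tol = 1e-9 + 1e-9 * max(ax, ay, az)
    on_outer = (
        (np.abs(fc[:, 0] - (-ax / 2)) < tol) | (np.abs(fc[:, 0] - ax / 2) < tol)
        | (np.abs(fc[:, 1] - (-ay / 2)) < tol) | (np.abs(fc[:, 1] - ay / 2) < tol)
        | (np.abs(fc[:, 2]) < tol) | (np.abs(fc[:, 2] - az) < tol)
    )
    mesh.surfaces["outer_surface"] = facets[on_outer]
    if tun is not None:
        mesh.surfaces["femoral_tunnel_wall"] = facets[~on_outer]
        # entrance-zone elements
        cent = nodes[tets].mean(axis=1)
        ent = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, az]])
        d = np.minimum(
            np.linalg.norm(cent - ent[0], axis=1),
            np.linalg.norm(cent - ent[1], axis=1),
        )
        mesh.element_sets["tunnel_entrance_zone"] = np.nonzero(d <= rr)[0]
    return mesh


def _boundary_tris(tets: np.ndarray) -> np.ndarray:
    """Facets appearing exactly once across all tets (original winding)."""
    tris = tets[:, TET_FACES].reshape(-1, 3)
    key = np.sort(tris, axis=1)
    _, inv, counts = np.unique(
        key, axis=0, return_inverse=True, return_counts=True
    )
    return tris[counts[inv] == 1]


def transform_mesh(mesh: Mesh, rotation=None, translation=None) -> Mesh:
    """Rigidly move a mesh (rotation 3x3 then translation); tags carry over."""
    nodes = mesh.nodes
    if rotation is not None:
        nodes = nodes @ np.asarray(rotation, float).T
    if translation is not None:
        nodes = nodes + np.asarray(translation, float)
    return Mesh(
        nodes=nodes,
        element_type=mesh.element_type,
        elements=mesh.elements.copy(),
        region=mesh.region.copy(),
        surfaces={k: np.array(v) for k, v in mesh.surfaces.items()},
        element_sets={k: np.array(v) for k, v in mesh.element_sets.items()},
        point_data={k: np.array(v) for k, v in mesh.point_data.items()},
    )


# ------------------------------------------------------------------ volumes

def _tet_volumes(nodes, tets):
    p = nodes[tets]
    return np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0


def _hex_volumes(nodes, hexes):
    gp = hex_gauss_points()
    dN = hex_shape_gradients(gp)            # (8gp, 8node, 3)
    p = nodes[hexes]                        # (ne, 8, 3)
    J = np.einsum("gai,naj->ngij", dN, p)   # (ne, 8gp, 3, 3)
    return np.linalg.det(J).sum(axis=1)     # unit gauss weights


def element_volumes(mesh: Mesh) -> np.ndarray:
    """Volumes of all elements, mm^3 (signed; validation flags negatives)."""
    if mesh.element_type == "tet4":
        return _tet_volumes(mesh.nodes, mesh.elements)
    return _hex_volumes(mesh.nodes, mesh.elements)


def element_volume(mesh: Mesh, element_id: int) -> float:
    """Volume of one element, mm^3; raises on inverted elements."""
    if not 0 <= element_id < mesh.n_elements:
        raise ValidationError(f"element id {element_id} out of range")
    if mesh.element_type == "tet4":
        v = float(_tet_volumes(mesh.nodes, mesh.elements[[element_id]])[0])
    else:
        v = float(_hex_volumes(mesh.nodes, mesh.elements[[element_id]])[0])
    if v <= 0.0:
        raise InvertedElementError(element_id, v)
    return v


# -------------------------------------------------------------- convergence

def check_convergence(metric_values, tol: float = 0.05):
    """First index whose relative change from its predecessor is <= tol.

    Implements the mesh-sensitivity rule: a metric (e.g. peak graft
    stress) is converged at refinement level i when
    ``|v[i] - v[i-1]| / |v[i-1]| <= tol`` (default 5%).  Returns the
    smallest such i >= 1, or None if the sequence never converges.
    """
    vals = [float(v) for v in metric_values]
    if len(vals) < 2:
        raise ValidationError("need at least two metric values")
    if not all(np.isfinite(vals)):
        raise ValidationError("metric values must be finite")
    for i in range(1, len(vals)):
        ref = abs(vals[i - 1])
        if ref == 0.0:
            if vals[i] == 0.0:
                return i
            continue
        if abs(vals[i] - vals[i - 1]) / ref <= tol:
            return i
    return None
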