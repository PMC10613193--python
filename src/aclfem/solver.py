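"""Quasi-static nonlinear FE solution of the two-step loading protocol.

Total-Lagrangian formulation: the hyperelastic hex8 graft carries finite
strains (2x2x2 quadrature), the linear-elastic tet4 cancellous bone is
assembled as a constant small-strain stiffness (bone strains are O(1e-3)
in all study conditions).  Bonded graft-to-tunnel-wall contact is a set of
node-to-facet tie springs (nearest projection, master = bone); the rigid
tibia is a frictionless channel (normal-only node-on-rigid-surface
penalty), active only in the pretension step; the rigid cortical shell
drives the cancellous outer surface directly.

Loading protocol:

1. ``solve_pretension`` — femur and tibia fixed, a 50 N dead load applied
   to the graft end surface along the tibial tunnel axis.
2. ``solve_pose`` — the tibia and the tibial-tunnel portion of the graft
   fixed at the pretensioned state; the femoral assembly displaced
   incrementally to the 6DOF flexion pose.

Newton-Raphson with adaptive load substepping (bisection on divergence)
and direct sparse solves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import (
    AssemblyError,
    ConvergenceError,
    InvertedConfigurationError,
    ValidationError,
)
from .kinematics import (
    FlexionPose,
    RigidTransform,
    compose,
    invert,
    scale_pose,
)
from .materials import (
    LinearElasticParams,
    NeoHookeanParams,
    cauchy_stress_batch,
    material_tangent,
    pk2_stress,
)
from .meshing import Mesh, hex_gauss_points, hex_shape_gradients

# width (mm) of the C1 contact-force smoothing band
_CONTACT_SMOOTHING = 0.15

__all__ = [
    "FEModel",
    "SolveResult",
    "InterfaceConfig",
    "SolverSettings",
    "RigidChannel",
    "assemble_model",
    "solve_pretension",
    "solve_pose",
    "solve_static",
]


@dataclass
class RigidChannel:
    """Frictionless rigid circular channel (normal-only penalty)."""

    node_ids: np.ndarray          # global node ids constrained by the wall
    point: np.ndarray             # a point on the channel axis, mm
    axis: np.ndarray              # unit axis direction
    radius: float                 # clear radius, mm
    penalty: float = 1e3          # MPa/mm-style penalty stiffness (N/mm/node)
    attached: str = "tibia"       # 'tibia' (static) | 'femur' (follows pose)

    def __post_init__(self):
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.point = np.asarray(self.point, dtype=float)
        a = np.asarray(self.axis, dtype=float)
        self.axis = a / np.linalg.norm(a)
        self._T = None

    def set_transform(self, T):
        """Rigid transform of the channel geometry (None = reference)."""
        self._T = T

    def _geometry(self):
        if self._T is None:
            return self.point, self.axis
        return self._T.apply(self.point), self._T.rotation @ self.axis

    def gaps_and_normals(self, x):
        """Penetration (positive outside the wall), outward normal,
        centre distance and local tangent for node positions x (n, 3)."""
        p0, d = self._geometry()
        rel = x - p0
        rho = rel - (rel @ d)[:, None] * d[None, :]
        rn = np.linalg.norm(rho, axis=1)
        pen = rn - self.radius
        with np.errstate(invalid="ignore"):
            n = np.where(rn[:, None] > 1e-12, rho / rn[:, None], 0.0)
        tan = np.broadcast_to(d, x.shape)
        return pen, n, rn, tan, np.ones(len(x))


@dataclass
class PathChannel:
    """Frictionless rigid surface swept along a polyline.

    ``mode='tube'``: a confining tunnel wall -- the section boundary
    (rounded rectangle of rectangular length ``L`` and wall radius
    ``R_wall``, long axis along ``e1``) swept along the path; nodes are
    pushed back inside when they stray out.  ``mode='obstacle'``: a
    convex bar of radius ``R_wall`` (e.g. the rounded aperture rim the
    graft wraps over); nodes are pushed away when they come closer than
    ``R_wall`` to the path.  Attached to the femur the geometry follows
    the flexion pose.
    """

    node_ids: np.ndarray
    points: np.ndarray            # polyline (m, 3)
    e1: np.ndarray                # long-axis direction (unit)
    L: float
    R_wall: float
    penalty: float = 1e3
    attached: str = "femur"
    mode: str = "tube"
    open_ends: bool = False   # tube only: no confinement past the ends

    def __post_init__(self):
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.points = np.asarray(self.points, dtype=float)
        e = np.asarray(self.e1, dtype=float)
        self.e1 = e / np.linalg.norm(e)
        self._T = None

    def set_transform(self, T):
        self._T = T

    def _geometry(self):
        if self._T is None:
            return self.points, self.e1
        return self._T.apply(self.points), self._T.rotation @ self.e1

    def gaps_and_normals(self, x):
        pts, e1 = self._geometry()
        a = pts[:-1]
        b = pts[1:]
        ab = b - a                                    # (m-1, 3)
        denom = np.einsum("ij,ij->i", ab, ab)
        # closest point on each segment for each node
        t = np.einsum("nsj,sj->ns", x[:, None, :] - a[None], ab) / denom
        t = np.clip(t, 0.0, 1.0)
        proj = a[None] + t[..., None] * ab[None]      # (n, m-1, 3)
        d2 = np.einsum("nsj,nsj->ns", x[:, None, :] - proj,
                       x[:, None, :] - proj)
        best = np.argmin(d2, axis=1)
        idx = np.arange(len(x))
        cp = proj[idx, best]
        tan = ab[best] / np.sqrt(denom[best])[:, None]
        rho = x - cp
        if self.mode == "tube":
            # a tube extends axially: drop the along-path component
            rho = rho - np.einsum("ij,ij->i", rho, tan)[:, None] * tan
        e2 = np.cross(tan, np.broadcast_to(e1, tan.shape))
        n2 = np.linalg.norm(e2, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            e2 = np.where(n2 > 1e-12, e2 / np.maximum(n2, 1e-12), 0.0)
        a1 = rho @ e1
        rest = rho - a1[:, None] * e1[None, :]
        if self.mode == "tube":
            a2 = np.einsum("ij,ij->i", rest, e2)
            rest_dir = np.sign(a2)[:, None] * e2
            a2 = np.abs(a2)
        else:
            # obstacle ends are spherical: keep the full residual vector
            a2 = np.linalg.norm(rest, axis=1)
            rest_dir = np.where(a2[:, None] > 1e-12,
                                rest / np.maximum(a2, 1e-12)[:, None], 0.0)
        q1 = np.sign(a1) * np.maximum(np.abs(a1) - self.L / 2.0, 0.0)
        dist = np.hypot(q1, a2)
        inv = np.where(dist > 1e-12, 1.0 / np.maximum(dist, 1e-12), 0.0)
        n_out = (q1 * inv)[:, None] * e1[None, :] \
            + (a2 * inv)[:, None] * rest_dir
        if self.mode == "tube":
            pen = dist - self.R_wall
            weight = np.ones(len(x))
            if self.open_ends:
                # confinement fades smoothly over the last 2 mm of the
                # bore and vanishes outside it
                seg_len = np.sqrt(denom)
                s_cum = np.concatenate([[0.0], np.cumsum(seg_len)])
                arcpos = s_cum[best] + t[idx, best] * seg_len[best]
                d_in = np.minimum(arcpos, s_cum[-1] - arcpos)
                weight = np.clip(d_in / 2.0, 0.0, 1.0)
            return pen, n_out, dist, tan, weight
        # obstacle: penetration grows as the node approaches the path
        return self.R_wall - dist, -n_out, dist, tan, np.ones(len(x))


@dataclass(frozen=True)
class InterfaceConfig:
    """How the graft talks to the bones.

    ``tie_stiffness`` is the bonded-contact spring constant per graft wall
    node (N/mm); ``tie_tolerance`` the largest admissible projection gap
    (mm) before assembly fails; ``channel_penalty`` the frictionless rigid
    channel stiffness (N/mm per node); ``channel_clearance`` extra radius
    added so the round tibial tunnel clears flattened graft sections.
    """

    tie_stiffness: float = 1.0e4
    tie_tolerance: float = 2.5
    channel_penalty: float = 1.0e3
    channel_clearance: float = 0.25


@dataclass(frozen=True)
class SolverSettings:
    """Newton-Raphson controls; echoed into results for reproducibility."""

    rtol: float = 1e-8
    atol: float = 1e-9
    max_iterations: int = 20
    initial_substeps: int = 4
    max_substeps: int = 256


@dataclass
class FEModel:
    """Assembled two-body model: graft (+ optional bone) with constraints.

    Node numbering is the graft mesh first, then the bone mesh offset by
    ``graft.n_nodes``.  Every deformable element has a material; tie and
    channel constraints reference global node ids.
    """

    graft: Mesh
    graft_material: NeoHookeanParams
    bone: Mesh | None = None
    bone_material: LinearElasticParams | None = None
    interface: InterfaceConfig = field(default_factory=InterfaceConfig)
    ties: list = field(default_factory=list)     # (gnode, fnodes(3), w(3))
    channels: list = field(default_factory=list)
    fixed_sets: dict = field(default_factory=dict)  # name -> global node ids
    tibial_axis: np.ndarray = field(
        default_factory=lambda: np.array([0.0, -1.0, 0.0])
    )
    fiber_dirs: np.ndarray | None = None         # per graft element

    # --- derived, built lazily -------------------------------------------
    _pre: dict = field(default_factory=dict, repr=False)

    @property
    def n_nodes(self) -> int:
        nb = self.bone.n_nodes if self.bone is not None else 0
        return self.graft.n_nodes + nb

    @property
    def n_bone_offset(self) -> int:
        return self.graft.n_nodes

    @property
    def ndof(self) -> int:
        return 3 * self.n_nodes

    def all_nodes(self) -> np.ndarray:
        if self.bone is None:
            return self.graft.nodes
        return np.vstack([self.graft.nodes, self.bone.nodes])

    # ------------------------------------------------------- precomputation
    def _precompute(self):
        if self._pre:
            return self._pre
        pre = {}
        g = self.graft
        gp = hex_gauss_points()
        dN = hex_shape_gradients(gp)                       # (8, 8, 3)
        Xe = g.nodes[g.elements]                           # (ne, 8, 3)
        J0 = np.einsum("nap,gaq->ngpq", Xe, dN)
        detJ0 = np.linalg.det(J0)
        if np.any(detJ0 <= 0):
            raise ValidationError("graft mesh has non-positive Jacobians")
        invJ0 = np.linalg.inv(J0)
        pre["dN_X"] = np.einsum("gaq,ngqp->ngap", dN, invJ0)
        pre["wdet"] = detJ0                                # unit weights
        dNc = hex_shape_gradients(np.zeros((1, 3)))        # centroid
        J0c = np.einsum("nap,gaq->ngpq", Xe, dNc)
        pre["dN_Xc"] = np.einsum("gaq,ngqp->ngap", dNc, np.linalg.inv(J0c))
        edof = (3 * g.elements[:, :, None]
                + np.arange(3)[None, None, :]).reshape(-1, 24)
        pre["edof"] = edof
        pre["Krows"] = np.repeat(edof, 24, axis=1).ravel()
        pre["Kcols"] = np.tile(edof, (1, 24)).ravel()

        K_const = sp.csr_matrix((self.ndof, self.ndof))
        if self.bone is not None:
            K_const = K_const + self._bone_stiffness()
        if self.ties:
            K_const = K_const + self._tie_stiffness_matrix()
        pre["K_const"] = K_const.tocsr()

        if self.fiber_dirs is not None:
            pre["fib_gp"] = np.broadcast_to(
                self.fiber_dirs[:, None, :], (g.n_elements, 8, 3)
            )
        else:
            pre["fib_gp"] = None
        self._pre = pre
        return pre

    def _bone_stiffness(self) -> sp.csr_matrix:
        b = self.bone
        mat = self.bone_material or LinearElasticParams()
        lam, mu = mat.lame_lambda, mat.lame_mu
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] += 2 * mu
        D[np.arange(3, 6), np.arange(3, 6)] = mu
        Xe = b.nodes[b.elements]                           # (ne, 4, 3)
        # gradients of linear shape functions
        T = Xe[:, 1:] - Xe[:, :1]                          # (ne, 3, 3)
        vol = np.linalg.det(T) / 6.0
        invT = np.linalg.inv(T)                            # rows: dxi/dx
        grads = np.empty((b.n_elements, 4, 3))
        grads[:, 1:] = np.swapaxes(invT, 1, 2)
        grads[:, 0] = -grads[:, 1:].sum(axis=1)
        Bm = np.zeros((b.n_elements, 6, 12))
        for a in range(4):
            gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
            Bm[:, 0, 3 * a] = gx
            Bm[:, 1, 3 * a + 1] = gy
            Bm[:, 2, 3 * a + 2] = gz
            Bm[:, 3, 3 * a] = gy
            Bm[:, 3, 3 * a + 1] = gx
            Bm[:, 4, 3 * a + 1] = gz
            Bm[:, 4, 3 * a + 2] = gy
            Bm[:, 5, 3 * a] = gz
            Bm[:, 5, 3 * a + 2] = gx
        Ke = np.einsum("n,nki,kl,nlj->nij", vol, Bm, D, Bm)
        edof = (3 * (b.elements + self.n_bone_offset)[:, :, None]
                + np.arange(3)[None, None, :]).reshape(-1, 12)
        rows = np.repeat(edof, 12, axis=1).ravel()
        cols = np.tile(edof, (1, 12)).ravel()
        K = sp.coo_matrix(
            (Ke.ravel(), (rows, cols)), shape=(self.ndof, self.ndof)
        )
        self._pre_bone_grads = (grads, vol)
        return K.tocsr()

    def _tie_stiffness_matrix(self) -> sp.csr_matrix:
        k0 = self.interface.tie_stiffness
        rows, cols, vals = [], [], []
        for tie in self.ties:
            gnode, fnodes, w = tie[0], tie[1], tie[2]
            k = k0 * (tie[3] if len(tie) > 3 else 1.0)
            idx = np.concatenate([[gnode], fnodes])
            coef = np.concatenate([[1.0], -np.asarray(w)])
            for d in range(3):
                dofs = 3 * idx + d
                block = k * np.outer(coef, coef)
                rows.append(np.repeat(dofs, len(dofs)))
                cols.append(np.tile(dofs, len(dofs)))
                vals.append(block.ravel())
        if not rows:
            return sp.csr_matrix((self.ndof, self.ndof))
        K = sp.coo_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.ndof, self.ndof),
        )
        return K.tocsr()

    # ----------------------------------------------------------- evaluation
    def graft_F(self, u: np.ndarray, at: str = "gauss") -> np.ndarray:
        """Deformation gradients on graft elements; 'gauss' (ne,8,3,3) or
        'centroid' (ne,1,3,3)."""
        pre = self._precompute()
        dN_X = pre["dN_X"] if at == "gauss" else pre["dN_Xc"]
        ue = u.reshape(-1, 3)[self.graft.elements]
        F = np.einsum("nai,ngaj->ngij", ue, dN_X)
        F += np.eye(3)
        return F

    def bone_small_strain(self, u: np.ndarray) -> np.ndarray:
        grads, _ = self._pre_bone_grads
        ue = u.reshape(-1, 3)[self.bone.elements + self.n_bone_offset]
        H = np.einsum("nai,naj->nij", ue, grads)
        return 0.5 * (H + np.swapaxes(H, 1, 2))

    def internal_force_and_stiffness(self, u: np.ndarray, need_K: bool = True):
        """Global internal force vector and (optionally) tangent stiffness
        at displacement u, including ties, bone and channel penalties."""
        pre = self._precompute()
        g = self.graft
        dN_X, wdet = pre["dN_X"], pre["wdet"]
        F = self.graft_F(u)
        C = np.einsum("ngki,ngkj->ngij", F, F)
        S = pk2_stress(C, self.graft_material, pre["fib_gp"])
        P = np.einsum("ngik,ngkj->ngij", F, S)
        fe = np.einsum("ng,ngij,ngaj->nai", wdet, P, dN_X)
        f = np.zeros(self.ndof)
        np.add.at(f, pre["edof"].ravel(), fe.reshape(-1, 24).ravel())
        f += pre["K_const"] @ u

        K = None
        if need_K:
            CC = material_tangent(C, self.graft_material, pre["fib_gp"])
            A = np.einsum("ngim,ngjr,ngmkrl->ngikjl", F, F, CC,
                          optimize=True)
            A += np.einsum("ij,ngkl->ngikjl", np.eye(3), S)
            Ke = np.einsum("ng,ngak,ngikjl,ngbl->naibj", wdet, dN_X, A,
                           dN_X, optimize=True)
            K = sp.coo_matrix(
                (Ke.reshape(-1, 24 * 24).ravel(),
                 (pre["Krows"], pre["Kcols"])),
                shape=(self.ndof, self.ndof),
            ).tocsr()
            K = K + pre["K_const"]

        for ch in self.channels:
            fc, Kc = self._channel_contribution(ch, u, need_K)
            f += fc
            if need_K and Kc is not None:
                K = K + Kc
        return f, K

    def _channel_contribution(self, ch, u, need_K):
        X = self.all_nodes()[ch.node_ids]
        x = X + u.reshape(-1, 3)[ch.node_ids]
        pen, normal, dist, tangent, weight = ch.gaps_and_normals(x)
        eps = _CONTACT_SMOOTHING
        active = (pen > 0) & (weight > 0)
        f = np.zeros(self.ndof)
        if not np.any(active):
            return f, None
        ids = ch.node_ids[active]
        nh = normal[active]
        p = pen[active]
        wgt = weight[active]
        # C1-smoothed penalty: quadratic blend over a small band
        mag = wgt * np.where(p < eps, p**2 / (2 * eps), p - eps / 2)
        dmag = wgt * np.where(p < eps, p / eps, 1.0)
        fn = ch.penalty * mag[:, None] * nh
        np.add.at(f.reshape(-1, 3), ids, fn)
        K = None
        if need_K:
            # normal stiffness + sliding-curvature term (rotation of the
            # contact normal as the node slides around the wall)
            nnT = np.einsum("ni,nj->nij", nh, nh)
            Kb = ch.penalty * dmag[:, None, None] * nnT
            if getattr(ch, "mode", "tube") == "tube":
                # sliding-curvature term (rotation of the normal as the
                # node slides around the wall); indefinite for convex
                # obstacles, so applied to confining tubes only
                th = tangent[active]
                Psec = (np.eye(3)[None]
                        - np.einsum("ni,nj->nij", th, th) - nnT)
                curv = (mag / np.maximum(dist[active], 1e-9))[:, None, None]
                Kb = Kb + ch.penalty * curv * Psec
            dofs = (3 * ids[:, None] + np.arange(3))
            rows = np.repeat(dofs, 3, axis=1).ravel()
            cols = np.tile(dofs, (1, 3)).ravel()
            K = sp.coo_matrix(
                (Kb.ravel(), (rows, cols)),
                shape=(self.ndof, self.ndof),
            ).tocsr()
        return f, K

    def channel_energy(self, u: np.ndarray) -> float:
        e = 0.0
        eps = _CONTACT_SMOOTHING
        for ch in self.channels:
            X = self.all_nodes()[ch.node_ids]
            x = X + u.reshape(-1, 3)[ch.node_ids]
            out = ch.gaps_and_normals(x)
            pen, wgt = out[0], out[4]
            p = np.maximum(pen, 0.0)
            w = np.where(p < eps, p**3 / (6 * eps),
                         0.5 * (p - eps / 2) ** 2 + eps**2 / 24)
            e += ch.penalty * float(np.sum(wgt * w))
        return e

    def strain_energy(self, u: np.ndarray) -> float:
        """Total stored energy: graft hyperelastic + bone + ties + channels
        (N*mm)."""
        pre = self._precompute()
        F = self.graft_F(u)
        J = np.linalg.det(F)
        I1b = J ** (-2.0 / 3.0) * np.einsum("ngii->ng", np.einsum(
            "ngki,ngkj->ngij", F, F))
        p = self.graft_material
        psi = np.log(J) ** 2 / (2 * p.D)
        if p.squared_invariant:
            psi = psi + p.C1 * (I1b**2 - 3.0)
        else:
            psi = psi + p.C1 * (I1b - 3.0)
        if p.fiber_term.enabled:
            a = pre["fib_gp"]
            lam = np.linalg.norm(np.einsum("ngij,ngj->ngi", F, a), axis=-1)
            psi = psi + p.fiber_term.energy(lam)
        e = float(np.sum(pre["wdet"] * psi))
        Kc = pre["K_const"]
        e += 0.5 * float(u @ (Kc @ u))
        e += self.channel_energy(u)
        return e


# -------------------------------------------------------------- solve result

@dataclass
class SolveResult:
    """Converged state of one loading step."""

    model: FEModel
    u: np.ndarray                      # (ndof,)
    step: str
    residual_history: list
    external_work: float = 0.0
    graft_stress: np.ndarray | None = None
    bone_strain: np.ndarray | None = None
    f_ext: np.ndarray | None = None
    bc_dofs: np.ndarray | None = None
    graft_stress_gp: np.ndarray | None = None

    def displacements(self) -> np.ndarray:
        return self.u.reshape(-1, 3)

    def region_mesh(self, region: str) -> Mesh:
        if region == "graft":
            return self.model.graft
        if region == "cancellous":
            return self.model.bone
        raise ValidationError(f"unknown region {region!r}")

    def region_displacements(self, region: str) -> np.ndarray:
        d = self.displacements()
        if region == "graft":
            return d[: self.model.graft.n_nodes]
        if region == "cancellous":
            return d[self.model.n_bone_offset:]
        raise ValidationError(f"unknown region {region!r}")

    def stress_field(self, region: str) -> np.ndarray:
        if region == "graft":
            return self.graft_stress
        raise ValidationError(f"stress field stored for 'graft' only")

    def strain_energy(self) -> float:
        return self.model.strain_energy(self.u)

    def reactions(self) -> np.ndarray:
        f_int, _ = self.model.internal_force_and_stiffness(
            self.u, need_K=False
        )
        fe = self.f_ext if self.f_ext is not None else 0.0
        r = f_int - fe
        out = np.zeros_like(self.u)
        if self.bc_dofs is not None:
            out[self.bc_dofs] = r[self.bc_dofs]
        return out

    def global_force_balance(self) -> float:
        """Relative force imbalance of the converged state.

        Sum of support reactions + sum of applied dead loads - net rigid
        channel force on the structure must vanish; the discrepancy is
        exactly the residual left on the free dofs, normalised by the
        applied/reaction magnitude.
        """
        f_int, _ = self.model.internal_force_and_stiffness(
            self.u, need_K=False
        )
        fe = self.f_ext if self.f_ext is not None else np.zeros_like(self.u)
        r = f_int - fe
        bc = self.bc_dofs if self.bc_dofs is not None else np.array([], int)
        mask = np.zeros(r.shape[0], dtype=bool)
        mask[bc] = True
        reactions = np.where(mask, r, 0.0).reshape(-1, 3).sum(axis=0)
        applied = fe.reshape(-1, 3).sum(axis=0)
        ch_net = np.zeros(3)
        for ch in self.model.channels:
            fc, _ = self.model._channel_contribution(ch, self.u, False)
            ch_net += fc.reshape(-1, 3).sum(axis=0)
        imbalance = reactions + applied - ch_net
        ref = max(float(np.abs(fe).sum()),
                  float(np.abs(np.where(mask, r, 0.0)).sum()), 1e-6)
        return float(np.linalg.norm(imbalance)) / ref


# ------------------------------------------------------------------- solves

def _finalize(model, u, step, history, f_ext, bc_dofs, work) -> SolveResult:
    Fg = model.graft_F(u, at="centroid")[:, 0]
    pre = model._precompute()
    fib = model.fiber_dirs
    stress = cauchy_stress_batch(Fg, model.graft_material, fib)
    Fgp = model.graft_F(u, at="gauss")
    fibgp = pre["fib_gp"]
    stress_gp = cauchy_stress_batch(Fgp, model.graft_material, fibgp)
    bone_eps = model.bone_small_strain(u) if model.bone is not None else None
    return SolveResult(
        model=model, u=u, step=step, residual_history=history,
        graft_stress=stress, graft_stress_gp=stress_gp,
        bone_strain=bone_eps, f_ext=f_ext, bc_dofs=bc_dofs,
        external_work=work,
    )


def solve_static(model: FEModel, bc_dofs, bc_values_fn, f_ext=None,
                 u0=None, settings: SolverSettings | None = None,
                 step: str = "static",
                 substep_callback=None) -> SolveResult:
    """Generic quasi-static solve with Newton-Raphson and substepping.

    ``bc_dofs`` are prescribed global dof indices; ``bc_values_fn(s)``
    gives their values at load factor s in [0, 1]; the dead load
    ``f_ext`` is scaled by s.  Starts from ``u0`` (zeros by default).
    """
    st = settings or SolverSettings()
    ndof = model.ndof
    f_ext = np.zeros(ndof) if f_ext is None else np.asarray(f_ext, float)
    bc_dofs = np.asarray(bc_dofs, dtype=np.int64)
    free = np.ones(ndof, dtype=bool)
    free[bc_dofs] = False
    free_idx = np.nonzero(free)[0]

    u = np.zeros(ndof) if u0 is None else u0.copy()
    u_prev = u.copy()
    history = []
    work = 0.0
    s = 0.0
    ds = 1.0 / st.initial_substeps
    ds_min = 1.0 / st.max_substeps
    fe_ref = float(np.linalg.norm(f_ext))

    while s < 1.0 - 1e-12:
        s_try = min(1.0, s + ds)
        if substep_callback is not None:
            substep_callback(s_try)
        u_try = u.copy()
        u_try[bc_dofs] = bc_values_fn(s_try)
        ok = False
        sub_hist = []
        try:
            fi, K = model.internal_force_and_stiffness(u_try)
            r = fi - s_try * f_ext
            r0 = float(np.linalg.norm(r[free_idx]))
            ref = max(s_try * fe_ref, r0)
            tol = st.rtol * ref + st.atol
            for it in range(st.max_iterations):
                rn = float(np.linalg.norm(r[free_idx]))
                sub_hist.append((s_try, it, rn))
                if rn <= tol:
                    ok = True
                    break
                Kff = K[free_idx][:, free_idx]
                du = spla.spsolve(Kff.tocsc(), -r[free_idx])
                if not np.all(np.isfinite(du)):
                    break
                # backtracking line search: non-smooth contact can make
                # the full Newton step mildly divergent near solution
                alpha = 1.0
                for _ in range(4):
                    u_cand = u_try.copy()
                    u_cand[free_idx] += alpha * du
                    fi_c, _ = model.internal_force_and_stiffness(
                        u_cand, need_K=False
                    )
                    r_c = fi_c - s_try * f_ext
                    if np.linalg.norm(r_c[free_idx]) < rn or alpha <= 0.126:
                        break
                    alpha *= 0.5
                u_try = u_cand
                fi, K = model.internal_force_and_stiffness(u_try)
                r = fi - s_try * f_ext
        except (InvertedConfigurationError, FloatingPointError,
                np.linalg.LinAlgError, RuntimeError):
            ok = False
        history.extend(sub_hist)
        if ok:
            # trapezoidal external work: dead load + prescribed-dof work
            fmid = 0.5 * (s + s_try) * f_ext
            work += float(fmid @ (u_try - u_prev))
            # reaction work on prescribed dofs
            fiA, _ = model.internal_force_and_stiffness(u_prev, need_K=False)
            fiB = fi
            rA = (fiA - s * f_ext)[bc_dofs]
            rB = (fiB - s_try * f_ext)[bc_dofs]
            work += float(
                0.5 * (rA + rB) @ (u_try - u_prev)[bc_dofs]
            )
            u_prev = u_try.copy()
            u = u_try
            s = s_try
            if len(sub_hist) <= 5:
                ds = min(ds * 1.5, 1.0)
        else:
            ds *= 0.5
            if ds < ds_min:
                raise ConvergenceError(
                    f"step '{step}' failed to converge at load factor "
                    f"{s_try:.4f}", history
                )
    return _finalize(model, u, step, history, f_ext, bc_dofs, work)


def consistent_end_load(model: FEModel, tension: float,
                        direction=None) -> np.ndarray:
    """Dead-load vector: ``tension`` N on the graft's tibial end facets
    along ``direction`` (default the model's tibial tunnel axis), with the
    resultant normalised to the target exactly."""
    d = np.asarray(
        direction if direction is not None else model.tibial_axis, float
    )
    d = d / np.linalg.norm(d)
    facets = model.graft.surfaces["graft_end_tibial"]
    f = np.zeros(model.ndof)
    fv = f.reshape(-1, 3)
    total_area = 0.0
    for q in facets:
        pts = model.graft.nodes[q]
        # split quad into two triangles; each triangle area shared by nodes
        for tri in ((0, 1, 2), (0, 2, 3)):
            a = 0.5 * np.linalg.norm(
                np.cross(pts[tri[1]] - pts[tri[0]], pts[tri[2]] - pts[tri[0]])
            )
            total_area += a
            for loc in tri:
                fv[q[loc]] += (a / 3.0) * d
    # normalise the resultant exactly to tension * d
    cur = fv.sum(axis=0) @ d
    f *= tension / cur
    return f


def solve_pretension(model: FEModel, tension: float = 50.0,
                     settings: SolverSettings | None = None) -> SolveResult:
    """Step 1: femur and tibia fixed; graft tensioned from its tibial end.

    The applied traction resultant equals ``tension`` along the tibial
    tunnel axis to machine precision; the tibial rigid channel (if any)
    is active.
    """
    bc_nodes = []
    if model.bone is not None:
        outer = np.unique(model.bone.surfaces["outer_surface"])
        bc_nodes.append(outer + model.n_bone_offset)
    for ids in model.fixed_sets.values():
        bc_nodes.append(np.asarray(ids, dtype=np.int64))
    if not bc_nodes:
        raise ValidationError("pretension requires at least one fixed set")
    nodes = np.unique(np.concatenate(bc_nodes))
    bc_dofs = (3 * nodes[:, None] + np.arange(3)).ravel()
    f_ext = consistent_end_load(model, tension) if tension != 0.0 else None
    return solve_static(
        model, bc_dofs, lambda s: np.zeros(len(bc_dofs)), f_ext,
        settings=settings, step="pretension",
    )


def tibial_portion_nodes(model: FEModel, tibial_embed: float) -> np.ndarray:
    """Graft nodes inside the tibial tunnel (path arc length <= embed)."""
    s = model.graft.point_data["path_arclength"]
    return np.nonzero(s <= tibial_embed + 1e-9)[0]


def solve_pose(model: FEModel, pose: FlexionPose, prior: SolveResult,
               tibial_embed: float = 20.0,
               settings: SolverSettings | None = None,
               from_pose: RigidTransform | None = None) -> SolveResult:
    """Step 2: tibia and tibial graft portion fixed at the pretensioned
    state; the femoral assembly moved incrementally to the 6DOF pose.

    ``from_pose`` is the femoral transform already reached by ``prior``
    (identity after pretension); the load path interpolates geodesically
    from it to the target pose, so successive flexion angles can be
    chained through the motion like the physical lunge.
    """
    if prior.step not in ("pretension", "pose"):
        raise ValidationError("prior must be a converged solve result")
    T_prev = from_pose if from_pose is not None else getattr(
        prior, "pose_transform", RigidTransform.identity()
    )
    graft_fix = tibial_portion_nodes(model, tibial_embed)
    gdofs = (3 * graft_fix[:, None] + np.arange(3)).ravel()
    u_prior = prior.u

    if model.bone is not None:
        outer = np.unique(model.bone.surfaces["outer_surface"])
        onodes = outer + model.n_bone_offset
        odofs = (3 * onodes[:, None] + np.arange(3)).ravel()
        X_outer = model.bone.nodes[outer]
    else:
        odofs = np.array([], dtype=np.int64)
        X_outer = np.zeros((0, 3))

    bc_dofs = np.concatenate([gdofs, odofs])
    g_vals = u_prior[gdofs]

    delta = compose(pose.transform, invert(T_prev))

    def pose_at(s):
        return compose(scale_pose(delta, s), T_prev)

    def bc_values(s):
        disp = (pose_at(s).apply(X_outer) - X_outer).ravel()
        return np.concatenate([g_vals, disp])

    def move_channels(s):
        T = pose_at(s)
        for ch in model.channels:
            if ch.attached == "femur":
                ch.set_transform(T)

    res = solve_static(
        model, bc_dofs, bc_values, f_ext=None, u0=u_prior,
        settings=settings, step="pose", substep_callback=move_channels,
    )
    move_channels(1.0)   # leave geometry at the target pose
    res.step = "pose"
    res.pose = pose
    res.pose_transform = pose.transform
    return res


# ---------------------------------------------------------------- assembly

def _project_point_triangle(p, a, b, c):
    """Closest point on triangle abc to p; returns (point, barycentric)."""
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a, np.array([1.0, 0.0, 0.0])
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b, np.array([0.0, 1.0, 0.0])
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        v = d1 / (d1 - d3)
        return a + v * ab, np.array([1 - v, v, 0.0])
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c, np.array([0.0, 0.0, 1.0])
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        w = d2 / (d2 - d6)
        return a + w * ac, np.array([1 - w, 0.0, w])
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return b + w * (c - b), np.array([0.0, 1 - w, w])
    den = va + vb + vc
    v, w = vb / den, vc / den
    return a + v * ab + w * ac, np.array([1 - v - w, v, w])


def assemble_model(graft_mesh: Mesh, bone_mesh: Mesh | None,
                   graft_material: NeoHookeanParams | None = None,
                   bone_material: LinearElasticParams | None = None,
                   interface: InterfaceConfig | None = None,
                   tibial_channel: RigidChannel | None = None,
                   tibial_axis=(0.0, -1.0, 0.0),
                   fiber_dirs: np.ndarray | None = None,
                   tie_scale: np.ndarray | None = None) -> FEModel:
    """Pair the graft and bone meshes into a constrained model.

    Every graft node on the ``femoral_tunnel_wall`` surface is tied to its
    nearest projection onto a bone tunnel-wall facet (master = bone) with
    a spring of ``interface.tie_stiffness``; nodes whose projection gap
    exceeds ``interface.tie_tolerance`` abort assembly with the offending
    list.  The rigid tibia enters as a frictionless channel, the rigid
    cortical shell as the (driven) cancellous outer surface.
    """
    interface = interface or InterfaceConfig()
    model = FEModel(
        graft=graft_mesh,
        graft_material=graft_material or NeoHookeanParams(),
        bone=bone_mesh,
        bone_material=bone_material or LinearElasticParams(),
        interface=interface,
        tibial_axis=np.asarray(tibial_axis, float),
        fiber_dirs=fiber_dirs,
    )
    if tibial_channel is not None:
        tibial_channel.penalty = interface.channel_penalty
        model.channels.append(tibial_channel)
    if bone_mesh is None:
        return model
    gwall = graft_mesh.surfaces.get("femoral_tunnel_wall")
    bwall = bone_mesh.surfaces.get("femoral_tunnel_wall")
    if gwall is None or bwall is None:
        raise AssemblyError(
            "femoral tunnel wall facets required on both graft and bone"
        )
    gnodes = np.unique(gwall)
    tris = bwall + model.n_bone_offset
    tri_pts = bone_mesh.nodes[bwall]
    unpaired = []
    for gn in gnodes:
        p = graft_mesh.nodes[gn]
        best = (np.inf, None, None)
        # coarse filter by facet centroid distance
        cen = tri_pts.mean(axis=1)
        d2 = np.einsum("ij,ij->i", cen - p, cen - p)
        for fi in np.argsort(d2)[:32]:
            q, w = _project_point_triangle(p, *tri_pts[fi])
            dist = float(np.linalg.norm(q - p))
            if dist < best[0]:
                best = (dist, fi, w)
        if best[0] > interface.tie_tolerance:
            unpaired.append((int(gn), best[0]))
            continue
        scale = 1.0 if tie_scale is None else float(tie_scale[gn])
        model.ties.append((int(gn), tris[best[1]], best[2], scale))
    if unpaired:
        raise AssemblyError(
            f"{len(unpaired)} graft wall nodes could not be tied within "
            f"tolerance {interface.tie_tolerance} mm: "
            + ", ".join(f"node {n} (gap {d:.2f} mm)" for n, d in unpaired[:10])
        )
    return model
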