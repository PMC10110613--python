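"""Cohesive-zone interaction laws for cell-cell junctions and cell-substrate adhesion.

Both interfaces follow the same family of piecewise traction-separation laws:
an exponential rising branch up to a critical separation (where the traction
peaks at the interface strength), a power-law softening branch, and a cutoff
beyond which the traction vanishes.  The normal law is repulsive below the
equilibrium separation δ₀; the tangential law is an odd function of the slip.

Internal units: lengths μm, tractions pN/μm² (≡ Pa), forces pN.
Strengths quoted in nN/μm² therefore carry a factor 1000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

try:  # optional JIT acceleration of the interface loops
    import numba

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

__all__ = [
    "CellCellCohesiveParams",
    "CellSubstrateCohesiveParams",
    "SeparationState",
    "PairSet",
    "traction_normal",
    "traction_tangential",
    "pair_kinematics",
    "assemble_interface_forces",
    "refresh_pairs",
]


def _check_ordering(delta0, dd, df, name):
    if not (0 <= delta0 < dd < df):
        raise ValueError(f"require 0 <= delta0 < delta_d < delta_f for {name}")


@dataclass(frozen=True)
class CellCellCohesiveParams:
    """Cell-cell junction law parameters.

    Defaults: strengths σ_c-c = τ_c-c = 2 nN/μm², equilibrium separation
    δ₀ = 10 nm, critical separations 1 μm, cutoffs 2 μm, unit shape exponents.
    """

    sigma_cc: float = 2000.0  # pN/μm²
    tau_cc: float = 2000.0
    delta0: float = 0.01  # μm
    delta_dn: float = 1.0
    delta_fn: float = 2.0
    delta_dt: float = 1.0
    delta_ft: float = 2.0
    qn: float = 1.0
    pn: float = 1.0
    qt: float = 1.0
    pt: float = 1.0

    def __post_init__(self):
        if self.sigma_cc <= 0 or self.tau_cc <= 0:
            raise ValueError("strengths must be positive")
        _check_ordering(self.delta0, self.delta_dn, self.delta_fn, "normal")
        if not (0 < self.delta_dt < self.delta_ft):
            raise ValueError("require 0 < delta_dt < delta_ft")
        if min(self.qn, self.pn, self.qt, self.pt) <= 0:
            raise ValueError("shape parameters must be positive")

    # normalized accessors shared by both parameter variants
    @property
    def sigma(self): return self.sigma_cc
    @property
    def tau(self): return self.tau_cc
    @property
    def delta_d_normal(self): return self.delta_dn
    @property
    def delta_f_normal(self): return self.delta_fn
    @property
    def delta_d_tan(self): return self.delta_dt
    @property
    def delta_f_tan(self): return self.delta_ft


@dataclass(frozen=True)
class CellSubstrateCohesiveParams:
    """Cell-substrate (focal adhesion) law parameters.

    Defaults: strengths σ_c-s = τ_c-s = 5 Pa, equilibrium separation 1 nm,
    critical separations 25 nm, detachment distances 60 nm.
    """

    sigma_cs: float = 5.0  # pN/μm²
    tau_cs: float = 5.0
    delta0: float = 1e-3  # μm
    delta_dv: float = 0.025
    delta_fv: float = 0.060
    delta_du: float = 0.025
    delta_fu: float = 0.060
    qn: float = 1.0
    pn: float = 1.0
    qt: float = 1.0
    pt: float = 1.0

    def __post_init__(self):
        if self.sigma_cs <= 0 or self.tau_cs <= 0:
            raise ValueError("strengths must be positive")
        _check_ordering(self.delta0, self.delta_dv, self.delta_fv, "normal")
        if not (0 < self.delta_du < self.delta_fu):
            raise ValueError("require 0 < delta_du < delta_fu")
        if min(self.qn, self.pn, self.qt, self.pt) <= 0:
            raise ValueError("shape parameters must be positive")

    @property
    def sigma(self): return self.sigma_cs
    @property
    def tau(self): return self.tau_cs
    @property
    def delta_d_normal(self): return self.delta_dv
    @property
    def delta_f_normal(self): return self.delta_fv
    @property
    def delta_d_tan(self): return self.delta_du
    @property
    def delta_f_tan(self): return self.delta_fu


@dataclass
class SeparationState:
    """Separation of one interface integration point.

    ``d_n`` is the signed separation along the master-face normal (positive
    when the faces are apart); ``d_t_vec`` is the in-plane slip vector.
    ``area_weight`` is the reference area carried by the point.
    """

    d_n: float
    d_t_vec: np.ndarray
    gauss_point: np.ndarray
    area_weight: float


# ---------------------------------------------------------------------------
# Scalar laws (vectorized over the separation argument)
# ---------------------------------------------------------------------------


def traction_normal(params, d):
    """Normal traction T_n(d) of the cohesive law (pN/μm²).

    Rising exponential branch up to the critical separation (negative, i.e.
    repulsive, below the equilibrium separation δ₀), power-law softening to
    the cutoff, zero beyond.  Total function of d; continuous at both
    breakpoints.
    """
    d = np.asarray(d, dtype=float)
    s, d0 = params.sigma, params.delta0
    dd, df = params.delta_d_normal, params.delta_f_normal
    x = (d - d0) / (dd - d0)
    rise = s * x * np.exp((1.0 - x) * params.qn)
    with np.errstate(invalid="ignore"):
        soft = s * np.where(d < df, ((df - d) / (df - dd)), 0.0) ** params.pn
    out = np.where(d <= dd, rise, np.where(d < df, soft, 0.0))
    return out if out.ndim else float(out)


def traction_tangential(params, d_t):
    """Tangential traction T_t(d_t) of the cohesive law (pN/μm²); odd in d_t."""
    d_t = np.asarray(d_t, dtype=float)
    t, dd, df = params.tau, params.delta_d_tan, params.delta_f_tan
    a = np.abs(d_t)
    rise = t * (d_t / dd) * np.exp((0.5 - d_t**2 / (2.0 * dd**2)) * params.qt)
    sign = np.sign(d_t)
    with np.errstate(invalid="ignore"):
        soft = t * sign * np.where(a < df, (df - a) / (df - dd), 0.0) ** params.pt
    out = np.where(a <= dd, rise, np.where(a < df, soft, 0.0))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Face quadrature and projection helpers
# ---------------------------------------------------------------------------

# 3-point (degree-2) triangle rule applied to both fan triangles of the quad
# [0,1,2,3] -> triangles (0,1,2) and (0,2,3); barycentric points (2/3,1/6,1/6)
_BARY = np.array([[4, 1, 1], [1, 4, 1], [1, 1, 4]]) / 6.0

QP_WEIGHTS = np.zeros((6, 4))
for _q in range(3):
    QP_WEIGHTS[_q, [0, 1, 2]] = _BARY[_q]
    QP_WEIGHTS[3 + _q, [0, 2, 3]] = _BARY[_q]


def _tri_areas(p0, p1, p2):
    return 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=-1)


def _quad_qp_area_weights(quads):
    """Reference area weight of each of the 6 quadrature points, (..., 6)."""
    a1 = _tri_areas(quads[..., 0, :], quads[..., 1, :], quads[..., 2, :])
    a2 = _tri_areas(quads[..., 0, :], quads[..., 2, :], quads[..., 3, :])
    return np.stack([a1, a1, a1, a2, a2, a2], axis=-1) / 3.0


def face_normals(quads):
    """Unit outward normals of lateral face quads [b0, b1, t1, t0]."""
    n = np.cross(quads[..., 2, :] - quads[..., 0, :],
                 quads[..., 3, :] - quads[..., 1, :])
    return n / np.linalg.norm(n, axis=-1, keepdims=True)


def closest_point_on_triangle(p, a, b, c):
    """Vectorized closest point on triangle (a, b, c) to point p.

    Returns (point, barycentric weights).  Standard region-wise projection.
    """
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("...i,...i->...", ab, ap)
    d2 = np.einsum("...i,...i->...", ac, ap)
    bp = p - b
    d3 = np.einsum("...i,...i->...", ab, bp)
    d4 = np.einsum("...i,...i->...", ac, bp)
    cp = p - c
    d5 = np.einsum("...i,...i->...", ab, cp)
    d6 = np.einsum("...i,...i->...", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    shape = p.shape[:-1]
    u = np.empty(shape)
    v = np.empty(shape)

    denom_face = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v_face = np.where(denom_face != 0, vb / denom_face, 0.0)
        w_face = np.where(denom_face != 0, vc / denom_face, 0.0)
        t_ab = np.clip(np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0), 0, 1)
        t_ac = np.clip(np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0), 0, 1)
        denom_bc = (d4 - d3) + (d5 - d6)
        t_bc = np.clip(np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0), 0, 1)

    # default: interior of face
    u[...] = v_face
    v[...] = w_face
    # vertex regions
    reg_a = (d1 <= 0) & (d2 <= 0)
    reg_b = (d3 >= 0) & (d4 <= d3)
    reg_c = (d6 >= 0) & (d5 <= d6)
    # edge regions
    reg_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    reg_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    reg_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)

    u = np.where(reg_bc, 1.0 - t_bc, u)
    v = np.where(reg_bc, t_bc, v)
    u = np.where(reg_ac, 0.0, u)
    v = np.where(reg_ac, t_ac, v)
    u = np.where(reg_ab, t_ab, u)
    v = np.where(reg_ab, 0.0, v)
    u = np.where(reg_c, 0.0, u)
    v = np.where(reg_c, 1.0, v)
    u = np.where(reg_b, 1.0, u)
    v = np.where(reg_b, 0.0, v)
    u = np.where(reg_a, 0.0, u)
    v = np.where(reg_a, 0.0, v)

    w0 = 1.0 - u - v
    point = w0[..., None] * a + u[..., None] * b + v[..., None] * c
    bary = np.stack([w0, u, v], axis=-1)
    return point, bary


def _anchor_on_quad(p, quad):
    """Closest point of quad [0,1,2,3] to p, as weights over the 4 quad nodes."""
    p1, b1 = closest_point_on_triangle(p, quad[..., 0, :], quad[..., 1, :], quad[..., 2, :])
    p2, b2 = closest_point_on_triangle(p, quad[..., 0, :], quad[..., 2, :], quad[..., 3, :])
    d1 = np.linalg.norm(p - p1, axis=-1)
    d2 = np.linalg.norm(p - p2, axis=-1)
    use1 = (d1 <= d2)[..., None]
    w = np.zeros(p.shape[:-1] + (4,))
    w1 = np.zeros_like(w)
    w1[..., [0, 1, 2]] = b1
    w2 = np.zeros_like(w)
    w2[..., [0, 2, 3]] = b2
    w = np.where(use1, w1, w2)
    return w


# ---------------------------------------------------------------------------
# Pair bookkeeping
# ---------------------------------------------------------------------------


class PairSet:
    """Active cell-cell junction pairs with frozen integration anchors.

    For every pair the lower-id cell's face is the master; tractions are
    integrated at 6 quadrature points of the slave face and applied
    equal-and-opposite through anchor weights on the master face.  Anchors
    (closest points on the master face) are frozen when a pair is created so
    tangential slip accumulates from the pairing configuration.
    """

    def __init__(self, mesh, slave, master, anchor_w, area_w):
        self.mesh = mesh
        self.slave = np.asarray(slave, dtype=np.int64)
        self.master = np.asarray(master, dtype=np.int64)
        self.anchor_w = anchor_w  # (P, 6, 4)
        self.area_w = area_w  # (P, 6)

    def __len__(self):
        return len(self.slave)

    @property
    def key_set(self):
        return set(zip(self.master.tolist(), self.slave.tolist()))

    @classmethod
    def from_faces(cls, mesh, face_a, face_b, u=None):
        """Build pairs from face index pairs; master = lower-id cell's face."""
        face_a = np.asarray(face_a, dtype=np.int64)
        face_b = np.asarray(face_b, dtype=np.int64)
        cell_a = mesh.face_cell[face_a]
        cell_b = mesh.face_cell[face_b]
        a_is_master = cell_a <= cell_b
        master = np.where(a_is_master, face_a, face_b)
        slave = np.where(a_is_master, face_b, face_a)
        pos = mesh.nodes if u is None else mesh.nodes + u
        squads = pos[mesh.lateral_faces[slave]]
        mquads = pos[mesh.lateral_faces[master]]
        qp = np.einsum("qa,pak->pqk", QP_WEIGHTS, squads)
        anchor_w = _anchor_on_quad(qp, mquads[:, None, :, :])
        area_w = _quad_qp_area_weights(squads)
        return cls(mesh, slave, master, anchor_w, area_w)

    @classmethod
    def initial(cls, mesh):
        jp = mesh.junction_face_pairs
        return cls.from_faces(mesh, jp[:, 0], jp[:, 1])

    def relax_slipping_anchors(self, u, slip_threshold):
        """Re-anchor quadrature points whose slip exceeds ``slip_threshold``.

        Models adhesion-bond turnover under sustained sliding: bonds that
        have yielded (slip past the tangential law's peak) re-bind at the
        current closest point, so junctions resist sliding like dynamic
        friction instead of softening to rupture, while small slips remain
        elastic.
        """
        if len(self) == 0:
            return
        d_n, d_t, _, qp = self.kinematics(u)
        slip = np.linalg.norm(d_t, axis=-1)
        mask = slip > slip_threshold
        if not mask.any():
            return
        pos = self.mesh.nodes + u
        mquads = pos[self.mesh.lateral_faces[self.master]]
        p_idx, q_idx = np.nonzero(mask)
        w = _anchor_on_quad(qp[p_idx, q_idx], mquads[p_idx])
        self.anchor_w[p_idx, q_idx] = w

    def kinematics(self, u):
        """Current separations at all quadrature points.

        Returns (d_n (P,6), d_t_vec (P,6,3), normals (P,6,3), qp (P,6,3)).
        """
        pos = self.mesh.nodes + u
        squads = pos[self.mesh.lateral_faces[self.slave]]
        mquads = pos[self.mesh.lateral_faces[self.master]]
        qp = np.matmul(QP_WEIGHTS, squads)  # (P, 6, 3)
        anchor = np.matmul(self.anchor_w, mquads)
        n = face_normals(mquads)[:, None, :]
        delta = qp - anchor
        d_n = (delta * n).sum(axis=-1)
        d_t = delta - d_n[..., None] * n
        return d_n, d_t, np.broadcast_to(n, delta.shape), qp


def pair_kinematics(mesh, state, pair) -> list[SeparationState]:
    """Separation states at the quadrature points of one junction pair.

    ``pair`` is a (face_a, face_b) index pair into ``mesh.lateral_faces``.
    """
    u = state.u if hasattr(state, "u") else np.asarray(state)
    ps = PairSet.from_faces(mesh, [pair[0]], [pair[1]])
    if _quad_qp_area_weights(mesh.nodes[mesh.lateral_faces[ps.slave]]).sum() <= 0:
        import warnings

        warnings.warn("degenerate (zero-area) face in pair; skipped")
        return []
    d_n, d_t, _, qp = ps.kinematics(u)
    return [
        SeparationState(
            d_n=float(d_n[0, q]),
            d_t_vec=d_t[0, q],
            gauss_point=qp[0, q],
            area_weight=float(ps.area_w[0, q]),
        )
        for q in range(d_n.shape[1])
    ]


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def _scatter(f_nodes, weights, forces, n_nodes, sign=1.0):
    """Accumulate forces (P,6,3) onto face nodes via weights (P,6,4)."""
    contrib = sign * np.matmul(weights.transpose(0, 2, 1), forces)
    idx = f_nodes.reshape(-1)
    out = np.zeros((n_nodes, 3))
    for k in range(3):
        out[:, k] = np.bincount(idx, weights=contrib[..., k].reshape(-1),
                                minlength=n_nodes)
    return out


if HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=True)
    def _t_normal(d, sigma, d0, dd, df, qn, pn):
        if d >= df:
            return 0.0
        if d <= dd:
            x = (d - d0) / (dd - d0)
            return sigma * x * np.exp((1.0 - x) * qn)
        return sigma * ((df - d) / (df - dd)) ** pn

    @numba.njit(cache=True, fastmath=True)
    def _t_tangential(s, tau, dd, df, qt, pt):
        # magnitude form (s >= 0)
        if s >= df:
            return 0.0
        if s <= dd:
            return tau * (s / dd) * np.exp((0.5 - s * s / (2.0 * dd * dd)) * qt)
        return tau * ((df - s) / (df - dd)) ** pt

    @numba.njit(cache=True, fastmath=True)
    def _cc_forces_jit(pos, faces, slave, master, anchor_w, area_w, qp_w,
                       sigma, tau, d0, ddn, dfn, ddt, dft, qn, pn, qt, pt, out):
        npair, nq = area_w.shape
        for p in range(npair):
            sf = faces[slave[p]]
            mf = faces[master[p]]
            # master normal from the quad diagonals
            d1x = pos[mf[2], 0] - pos[mf[0], 0]
            d1y = pos[mf[2], 1] - pos[mf[0], 1]
            d1z = pos[mf[2], 2] - pos[mf[0], 2]
            d2x = pos[mf[3], 0] - pos[mf[1], 0]
            d2y = pos[mf[3], 1] - pos[mf[1], 1]
            d2z = pos[mf[3], 2] - pos[mf[1], 2]
            nx = d1y * d2z - d1z * d2y
            ny = d1z * d2x - d1x * d2z
            nz = d1x * d2y - d1y * d2x
            nl = np.sqrt(nx * nx + ny * ny + nz * nz)
            if nl < 1e-30:
                continue
            nx /= nl; ny /= nl; nz /= nl
            for q in range(nq):
                qx = qy = qz = 0.0
                ax = ay = az = 0.0
                for a in range(4):
                    w = qp_w[q, a]
                    qx += w * pos[sf[a], 0]
                    qy += w * pos[sf[a], 1]
                    qz += w * pos[sf[a], 2]
                    wa = anchor_w[p, q, a]
                    ax += wa * pos[mf[a], 0]
                    ay += wa * pos[mf[a], 1]
                    az += wa * pos[mf[a], 2]
                dx = qx - ax; dy = qy - ay; dz = qz - az
                dn = dx * nx + dy * ny + dz * nz
                tx = dx - dn * nx; ty = dy - dn * ny; tz = dz - dn * nz
                s = np.sqrt(tx * tx + ty * ty + tz * tz)
                # gate: outside the cohesive zone no interaction
                if np.sqrt(dn * dn + s * s) >= dfn:
                    continue
                tn = _t_normal(dn, sigma, d0, ddn, dfn, qn, pn)
                tt = _t_tangential(s, tau, ddt, dft, qt, pt)
                aw = area_w[p, q]
                fx = -tn * nx * aw
                fy = -tn * ny * aw
                fz = -tn * nz * aw
                if s > 1e-12:
                    fx -= tt * tx / s * aw
                    fy -= tt * ty / s * aw
                    fz -= tt * tz / s * aw
                for a in range(4):
                    w = qp_w[q, a]
                    out[sf[a], 0] += w * fx
                    out[sf[a], 1] += w * fy
                    out[sf[a], 2] += w * fz
                    wa = anchor_w[p, q, a]
                    out[mf[a], 0] -= wa * fx
                    out[mf[a], 1] -= wa * fy
                    out[mf[a], 2] -= wa * fz


def assemble_cell_cell_forces(mesh, pairs: PairSet, u, cc_params):
    """Global cell-cell cohesive force vector F^{c-c}, shape (n_nodes, 3)."""
    n_nodes = mesh.n_nodes
    if len(pairs) == 0:
        return np.zeros((n_nodes, 3))
    if HAVE_NUMBA:
        pos = np.ascontiguousarray(mesh.nodes + u)
        out = np.zeros((n_nodes, 3))
        c = cc_params
        _cc_forces_jit(pos, mesh.lateral_faces, pairs.slave, pairs.master,
                       pairs.anchor_w, pairs.area_w, QP_WEIGHTS,
                       c.sigma, c.tau, c.delta0,
                       c.delta_d_normal, c.delta_f_normal,
                       c.delta_d_tan, c.delta_f_tan,
                       c.qn, c.pn, c.qt, c.pt, out)
        return out
    d_n, d_t, n_hat, _ = pairs.kinematics(u)
    slip = np.linalg.norm(d_t, axis=-1)
    # interaction gate: a quadrature point only interacts while its total
    # separation from the master face is below the normal cutoff distance;
    # distant points of obliquely paired faces are outside the cohesive zone
    active = np.hypot(d_n, slip) < cc_params.delta_f_normal
    t_n = np.where(active, traction_normal(cc_params, np.where(active, d_n, 0.0)), 0.0)
    t_t = np.where(active, traction_tangential(cc_params, slip), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_hat = np.where(slip[..., None] > 1e-12, d_t / slip[..., None], 0.0)
    # positive traction = attraction: pulls the slave toward the master and
    # resists slip
    f_qp = -(t_n[..., None] * n_hat + t_t[..., None] * t_hat) * pairs.area_w[..., None]
    slave_nodes = mesh.lateral_faces[pairs.slave]
    master_nodes = mesh.lateral_faces[pairs.master]
    qw = np.broadcast_to(QP_WEIGHTS, f_qp.shape[:2] + (4,))
    f = _scatter(slave_nodes, qw, f_qp, n_nodes)
    f += _scatter(master_nodes, pairs.anchor_w, f_qp, n_nodes, sign=-1.0)
    return f


if HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=True)
    def _cs_forces_jit(pos, tris, area_w, bary, sigma, d0, ddv, dfv, qn, pn, out):
        nb = len(tris)
        for b in range(nb):
            for q in range(3):
                z = (bary[q, 0] * pos[tris[b, 0], 2]
                     + bary[q, 1] * pos[tris[b, 1], 2]
                     + bary[q, 2] * pos[tris[b, 2], 2])
                tn = _t_normal(z, sigma, d0, ddv, dfv, qn, pn)
                fz = -tn * area_w[b]
                for a in range(3):
                    out[tris[b, a], 2] += bary[q, a] * fz


def assemble_cell_substrate_forces(mesh, u, cs_params, ref_area_w=None):
    """Global cell-substrate adhesion force vector F^{c-s} on bottom faces.

    The substrate is rigid and fixed at z = 0; the normal separation of a
    quadrature point is its height above the plane.  Tangential slip against
    a flat rigid plane measured to the closest surface point is identically
    zero, so only the normal law loads the nodes (the reaction is absorbed by
    the substrate).
    """
    n_nodes = mesh.n_nodes
    tris = mesh.bottom_faces
    pos = mesh.nodes + u
    p = pos[tris]  # (B, 3, 3)
    if ref_area_w is None:
        p0 = mesh.nodes[tris]
        ref_area_w = _tri_areas(p0[:, 0], p0[:, 1], p0[:, 2])[:, None] / 3.0
    if HAVE_NUMBA:
        out = np.zeros((n_nodes, 3))
        c = cs_params
        _cs_forces_jit(np.ascontiguousarray(pos), tris,
                       np.ascontiguousarray(np.asarray(ref_area_w).reshape(len(tris))),
                       _BARY,
                       c.sigma, c.delta0, c.delta_d_normal, c.delta_f_normal,
                       c.qn, c.pn, out)
        return out
    qp = np.matmul(_BARY, p)  # (B, 3qp, 3)
    d_v = qp[..., 2]
    t_n = traction_normal(cs_params, d_v)
    fz = -t_n * ref_area_w  # attraction pulls the cell down toward the plane
    contrib = fz @ _BARY  # (B, 3 nodes)
    out = np.zeros((n_nodes, 3))
    out[:, 2] = np.bincount(tris.reshape(-1), weights=contrib.reshape(-1),
                            minlength=n_nodes)
    return out


def assemble_interface_forces(mesh, state, cc_params, cs_params, pairs=None):
    """Assemble (F^{c-c}, F^{c-s}) for the current configuration."""
    u = state.u if hasattr(state, "u") else np.asarray(state)
    if pairs is None:
        pairs = PairSet.initial(mesh)
    f_cc = assemble_cell_cell_forces(mesh, pairs, u, cc_params)
    f_cs = assemble_cell_substrate_forces(mesh, u, cs_params)
    return f_cc, f_cs


# ---------------------------------------------------------------------------
# Pair refresh
# ---------------------------------------------------------------------------


def _face_qp_distance(quads_a, quads_b):
    """Minimum distance from quadrature points of one quad to the other quad.

    Symmetric in the two faces; a corner-touching neighbour is far from all
    quadrature points, so only genuinely overlapping opposing faces count.
    """
    best = None
    for qa, qb in ((quads_a, quads_b), (quads_b, quads_a)):
        qp = np.einsum("qa,pak->pqk", QP_WEIGHTS, qa)
        qb_ = qb[:, None, :, :]
        p1, _ = closest_point_on_triangle(
            qp, qb_[..., 0, :], qb_[..., 1, :], qb_[..., 2, :])
        p2, _ = closest_point_on_triangle(
            qp, qb_[..., 0, :], qb_[..., 2, :], qb_[..., 3, :])
        d = np.minimum(
            np.linalg.norm(qp - p1, axis=-1), np.linalg.norm(qp - p2, axis=-1)
        ).min(axis=1)
        best = d if best is None else np.minimum(best, d)
    return best


def refresh_pairs(mesh, state, cutoff, pairs: PairSet | None = None,
                  relax_slip: float | None = None) -> PairSet:
    """Update the junction pair list by proximity search over lateral faces.

    Pairs whose faces are farther apart than ``cutoff`` are removed; new pairs
    are added for face pairs of different cells that have approached within
    ``cutoff`` with opposing orientation, which lets junctional associations
    form between previously non-neighbouring cells.  Surviving pairs keep
    their integration anchors while the slip is small (elastic junctions);
    quadrature points whose slip has passed the tangential critical
    separation are re-anchored (``relax_slip`` distance, default δ_dt of the
    supplied cutoff scale — see :meth:`PairSet.relax_slipping_anchors`), and
    new pairs are anchored in the current configuration.  Deterministic
    given the state, and independent of cell ordering.
    """
    u = state.u if hasattr(state, "u") else np.asarray(state)
    pos = mesh.nodes + u
    cand = np.flatnonzero(~mesh.face_is_outer)
    quads = pos[mesh.lateral_faces[cand]]
    centroids = quads.mean(axis=1)
    half_diag = 0.5 * np.maximum(
        np.linalg.norm(quads[:, 2] - quads[:, 0], axis=-1),
        np.linalg.norm(quads[:, 3] - quads[:, 1], axis=-1),
    )
    tree = cKDTree(centroids)
    raw = tree.query_pairs(r=cutoff + 2.0 * half_diag.max(), output_type="ndarray")
    if len(raw):
        ia, ib = raw[:, 0], raw[:, 1]
        # per-pair bounding-sphere prefilter before the exact face test
        cd = np.linalg.norm(centroids[ia] - centroids[ib], axis=1)
        keep = cd < cutoff + half_diag[ia] + half_diag[ib]
        ia, ib = ia[keep], ib[keep]
        fa, fb = cand[ia], cand[ib]
        keep = mesh.face_cell[fa] != mesh.face_cell[fb]
        fa, fb = fa[keep], fb[keep]
        qa, qb = pos[mesh.lateral_faces[fa]], pos[mesh.lateral_faces[fb]]
        na, nb = face_normals(qa), face_normals(qb)
        # opposing orientation only; already-penetrated faces must also pair
        # so that the repulsive branch can push them apart
        opposing = np.einsum("pk,pk->p", na, nb) < -0.1
        close = _face_qp_distance(qa, qb) < cutoff
        keep = opposing & close
        fa, fb = fa[keep], fb[keep]
    else:
        fa = fb = np.array([], dtype=np.int64)

    # canonical (master, slave) keys
    ca, cb = mesh.face_cell[fa], mesh.face_cell[fb]
    m = np.where(ca <= cb, fa, fb)
    s = np.where(ca <= cb, fb, fa)
    new_keys = set(zip(m.tolist(), s.tolist()))

    if pairs is None:
        keys = sorted(new_keys)
        mm = np.array([k[0] for k in keys], dtype=np.int64)
        ss = np.array([k[1] for k in keys], dtype=np.int64)
        return PairSet.from_faces(mesh, mm, ss, u=u)

    kept_mask = np.array(
        [k in new_keys for k in zip(pairs.master.tolist(), pairs.slave.tolist())],
        dtype=bool,
    ) if len(pairs) else np.zeros(0, dtype=bool)
    added = sorted(new_keys - pairs.key_set)

    kept = PairSet(
        mesh,
        pairs.slave[kept_mask],
        pairs.master[kept_mask],
        pairs.anchor_w[kept_mask],
        pairs.area_w[kept_mask],
    )
    if relax_slip is not None:
        kept.relax_slipping_anchors(u, relax_slip)
    if added:
        mm = np.array([k[0] for k in added], dtype=np.int64)
        ss = np.array([k[1] for k in added], dtype=np.int64)
        fresh = PairSet.from_faces(mesh, mm, ss, u=u)
        return PairSet(
            mesh,
            np.concatenate([kept.slave, fresh.slave]),
            np.concatenate([kept.master, fresh.master]),
            np.concatenate([kept.anchor_w, fresh.anchor_w]),
            np.concatenate([kept.area_w, fresh.area_w]),
        )
    return kept
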