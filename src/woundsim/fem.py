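"""Finite-strain elastic wedge-element core and explicit dynamics.

Each epithelial cell is discretised into 6-node linear wedge (triangular
prism) elements.  The bulk is a St. Venant-Kirchhoff hyperelastic solid
(linear elasticity extended to finite strain through the Green-Lagrange
strain), parameterised by Young's modulus and Poisson's ratio.  The equations
of motion M ü = F_ext − F_int are integrated with a damped central-difference
scheme; mass-proportional damping turns the integration into dynamic
relaxation so the slow migration dynamics are quasi-static.

Unit system: μm-ng-ms, in which force is pN and stress is Pa exactly
(1 nN/μm² = 1 kPa = 1000 internal stress units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

try:  # optional JIT acceleration of the element loops
    import numba

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

__all__ = [
    "ElasticMaterial",
    "SimulationState",
    "StressField",
    "InvertedElementError",
    "DivergenceError",
    "wedge_shape",
    "WedgePrecomp",
    "precompute",
    "internal_force",
    "strain_energy",
    "lumped_mass",
    "stable_dt",
    "explicit_step",
]


class InvertedElementError(RuntimeError):
    pass


class DivergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class ElasticMaterial:
    """Isotropic elastic cell material.

    ``youngs_modulus`` is in kPa (epithelial cells are ~0.2 kPa soft),
    ``density`` in ng/μm³.
    """

    youngs_modulus: float = 0.2  # kPa
    poisson_ratio: float = 0.45
    density: float = 2e-3  # ng/μm³

    def __post_init__(self):
        if self.youngs_modulus <= 0:
            raise ValueError("youngs_modulus must be positive")
        if not (0 <= self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must be in [0, 0.5)")
        if self.density <= 0:
            raise ValueError("density must be positive")

    @property
    def E(self) -> float:
        """Young's modulus in internal stress units (pN/μm² = Pa)."""
        return 1000.0 * self.youngs_modulus

    @property
    def lame(self) -> tuple[float, float]:
        e, nu = self.E, self.poisson_ratio
        lam = e * nu / ((1 + nu) * (1 - 2 * nu))
        mu = e / (2 * (1 + nu))
        return lam, mu

    @property
    def dilatational_wave_speed(self) -> float:
        lam, mu = self.lame
        return float(np.sqrt((lam + 2 * mu) / self.density))


# ---------------------------------------------------------------------------
# Reference element
# ---------------------------------------------------------------------------

# triangle 3-point rule (degree 2) in area coordinates, weights on unit triangle
_TRI_PTS = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
_TRI_W = np.full(3, 1 / 6)
# 2-point Gauss on [0, 1] through the thickness
_ZETA = np.array([0.5 - 0.5 / np.sqrt(3.0), 0.5 + 0.5 / np.sqrt(3.0)])
_ZETA_W = np.full(2, 0.5)

QUAD_POINTS = np.array(
    [[xi, eta, z] for z in _ZETA for (xi, eta) in _TRI_PTS]
)
QUAD_WEIGHTS = np.array([tw * zw for zw in _ZETA_W for tw in _TRI_W])
N_QP = len(QUAD_POINTS)


def shape_functions(local: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linear wedge shape functions and local gradients at (ξ, η, ζ).

    Nodes 0-2 are the bottom triangle, 3-5 the top; ζ ∈ [0, 1].
    """
    xi, eta, zeta = local
    l = np.array([1 - xi - eta, xi, eta])
    n = np.concatenate([l * (1 - zeta), l * zeta])
    dl = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
    dn = np.zeros((6, 3))
    dn[:3, :2] = dl * (1 - zeta)
    dn[3:, :2] = dl * zeta
    dn[:3, 2] = -l
    dn[3:, 2] = l
    return n, dn


def wedge_shape(el_coords: np.ndarray, local: np.ndarray, element_id: int | None = None):
    """Shape values, material gradients and Jacobian determinant at a point.

    ``el_coords`` is the (6, 3) array of node coordinates.  Raises
    :class:`InvertedElementError` on a non-positive Jacobian.
    """
    n, dn = shape_functions(np.asarray(local, dtype=float))
    jac = el_coords.T @ dn  # dX/dlocal
    det = np.linalg.det(jac)
    if det <= 0:
        raise InvertedElementError(
            f"non-positive Jacobian in element {element_id}"
        )
    grad = dn @ np.linalg.inv(jac).T  # dN/dX
    return n, grad, det


# ---------------------------------------------------------------------------
# Precomputation
# ---------------------------------------------------------------------------


@dataclass
class WedgePrecomp:
    """Reference-configuration element data reused every step."""

    conn: np.ndarray  # (nel, 6)
    gradN: np.ndarray  # (nel, nqp, 6, 3)
    wdet: np.ndarray  # (nel, nqp) quadrature weight × |J|
    shapeN: np.ndarray  # (nqp, 6)


def precompute(mesh) -> WedgePrecomp:
    conn = mesh.elements
    coords = mesh.nodes[conn]  # (nel, 6, 3)
    nel = len(conn)
    gradN = np.empty((nel, N_QP, 6, 3))
    wdet = np.empty((nel, N_QP))
    shapeN = np.empty((N_QP, 6))
    for q, (local, w) in enumerate(zip(QUAD_POINTS, QUAD_WEIGHTS)):
        n, dn = shape_functions(local)
        shapeN[q] = n
        jac = np.einsum("eai,aj->eij", coords, dn)
        det = np.linalg.det(jac)
        bad = np.flatnonzero(det <= 0)
        if len(bad):
            raise InvertedElementError(
                f"non-positive reference Jacobian in element(s) {bad[:5].tolist()}"
            )
        inv = np.linalg.inv(jac)
        gradN[:, q] = np.einsum("aj,eji->eai", dn, inv)
        wdet[:, q] = w * det
    return WedgePrecomp(conn=conn, gradN=gradN, wdet=wdet, shapeN=shapeN)


# ---------------------------------------------------------------------------
# State and stress containers
# ---------------------------------------------------------------------------


@dataclass
class SimulationState:
    """Nodal kinematics, lumped mass and decomposed force vectors."""

    u: np.ndarray
    v: np.ndarray
    a: np.ndarray
    mass: np.ndarray  # (n,) ng
    t: float = 0.0
    step: int = 0
    f_int: np.ndarray | None = None
    f_p: np.ndarray | None = None
    f_cc: np.ndarray | None = None
    f_cs: np.ndarray | None = None

    @classmethod
    def zeros(cls, n_nodes: int, mass: np.ndarray) -> "SimulationState":
        z = np.zeros((n_nodes, 3))
        return cls(u=z.copy(), v=z.copy(), a=z.copy(), mass=mass)


@dataclass
class StressField:
    """Per-element volume-averaged stress measures."""

    deformation_gradient: np.ndarray  # (nel, 3, 3)
    piola: np.ndarray  # (nel, 3, 3) first Piola-Kirchhoff
    cauchy: np.ndarray  # (nel, 3, 3)
    von_mises: np.ndarray = field(default=None)  # filled by postprocess

    @property
    def jacobian(self) -> np.ndarray:
        return np.linalg.det(self.deformation_gradient)


# ---------------------------------------------------------------------------
# Internal force / energy
# ---------------------------------------------------------------------------


def _det33(f):
    return (
        f[..., 0, 0] * (f[..., 1, 1] * f[..., 2, 2] - f[..., 1, 2] * f[..., 2, 1])
        - f[..., 0, 1] * (f[..., 1, 0] * f[..., 2, 2] - f[..., 1, 2] * f[..., 2, 0])
        + f[..., 0, 2] * (f[..., 1, 0] * f[..., 2, 1] - f[..., 1, 1] * f[..., 2, 0])
    )


if HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=True)
    def _internal_force_jit(u, conn, gradN, wdet, lam, mu, out, check):
        """Element loop for F_int; returns the first inverted element or -1."""
        nel, nqp = wdet.shape
        h = np.empty((3, 3))
        e = np.empty((3, 3))
        p = np.empty((3, 3))
        for el in range(nel):
            for q in range(nqp):
                for i in range(3):
                    for j in range(3):
                        acc = 0.0
                        for a in range(6):
                            acc += u[conn[el, a], i] * gradN[el, q, a, j]
                        h[i, j] = acc
                f00 = h[0, 0] + 1.0; f01 = h[0, 1]; f02 = h[0, 2]
                f10 = h[1, 0]; f11 = h[1, 1] + 1.0; f12 = h[1, 2]
                f20 = h[2, 0]; f21 = h[2, 1]; f22 = h[2, 2] + 1.0
                if check:
                    det = (f00 * (f11 * f22 - f12 * f21)
                           - f01 * (f10 * f22 - f12 * f20)
                           + f02 * (f10 * f21 - f11 * f20))
                    if det <= 0.0:
                        return el
                # Green-Lagrange strain E = (FᵀF − I)/2
                e[0, 0] = 0.5 * (f00 * f00 + f10 * f10 + f20 * f20 - 1.0)
                e[1, 1] = 0.5 * (f01 * f01 + f11 * f11 + f21 * f21 - 1.0)
                e[2, 2] = 0.5 * (f02 * f02 + f12 * f12 + f22 * f22 - 1.0)
                e[0, 1] = 0.5 * (f00 * f01 + f10 * f11 + f20 * f21)
                e[0, 2] = 0.5 * (f00 * f02 + f10 * f12 + f20 * f22)
                e[1, 2] = 0.5 * (f01 * f02 + f11 * f12 + f21 * f22)
                e[1, 0] = e[0, 1]; e[2, 0] = e[0, 2]; e[2, 1] = e[1, 2]
                tr = e[0, 0] + e[1, 1] + e[2, 2]
                # P = F (λ tr(E) I + 2 μ E)
                for i in range(3):
                    fi0 = f00 if i == 0 else (f10 if i == 1 else f20)
                    fi1 = f01 if i == 0 else (f11 if i == 1 else f21)
                    fi2 = f02 if i == 0 else (f12 if i == 1 else f22)
                    for j in range(3):
                        s0 = 2.0 * mu * e[0, j]
                        s1 = 2.0 * mu * e[1, j]
                        s2 = 2.0 * mu * e[2, j]
                        if j == 0:
                            s0 += lam * tr
                        elif j == 1:
                            s1 += lam * tr
                        else:
                            s2 += lam * tr
                        p[i, j] = fi0 * s0 + fi1 * s1 + fi2 * s2
                w = wdet[el, q]
                for a in range(6):
                    n = conn[el, a]
                    out[n, 0] += w * (p[0, 0] * gradN[el, q, a, 0]
                                      + p[0, 1] * gradN[el, q, a, 1]
                                      + p[0, 2] * gradN[el, q, a, 2])
                    out[n, 1] += w * (p[1, 0] * gradN[el, q, a, 0]
                                      + p[1, 1] * gradN[el, q, a, 1]
                                      + p[1, 2] * gradN[el, q, a, 2])
                    out[n, 2] += w * (p[2, 0] * gradN[el, q, a, 0]
                                      + p[2, 1] * gradN[el, q, a, 1]
                                      + p[2, 2] * gradN[el, q, a, 2])
        return -1


def internal_force(mesh, state, mat: ElasticMaterial, precomp: WedgePrecomp | None = None,
                   return_stress: bool = False, check: bool = True):
    """Assemble F_int = ∫ P : δF dΩ for the St. Venant-Kirchhoff solid.

    F = I + ∂u/∂X per quadrature point; S = λ tr(E) I + 2μ E with
    E = ½(FᵀF − I); P = F S.  Returns the (n_nodes, 3) force vector, plus a
    :class:`StressField` when ``return_stress`` is set.
    """
    u = state.u if hasattr(state, "u") else np.asarray(state)
    pc = precomp if precomp is not None else precompute(mesh)
    lam, mu = mat.lame

    if HAVE_NUMBA and not return_stress:
        out = np.zeros((len(u), 3))
        bad = _internal_force_jit(
            np.ascontiguousarray(u), pc.conn, pc.gradN, pc.wdet, lam, mu, out, check)
        if bad >= 0:
            raise InvertedElementError(f"element {bad} inverted (det F <= 0)")
        return out

    u_el = u[pc.conn]  # (nel, 6, 3)
    # H[e,q] = u_elᵀ (3,6) @ gradN[e,q] (6,3); batched matmul with broadcast
    h = np.matmul(u_el.transpose(0, 2, 1)[:, None], pc.gradN)
    f = h + np.eye(3)
    if check:
        det = _det33(f)
        if np.any(det <= 0):
            bad = np.argwhere(det <= 0)[0]
            raise InvertedElementError(
                f"element {bad[0]} inverted (qp {bad[1]}, det F = "
                f"{det[bad[0], bad[1]]:.3e})"
            )
    e_gl = 0.5 * (np.matmul(f.transpose(0, 1, 3, 2), f) - np.eye(3))
    tr = e_gl[..., 0, 0] + e_gl[..., 1, 1] + e_gl[..., 2, 2]
    s = lam * tr[..., None, None] * np.eye(3) + 2.0 * mu * e_gl
    p = np.matmul(f, s)
    # f_el[e,a,i] = Σ_q w GP ᵀ: (nqp batch) gradN (6,3) @ Pᵀ (3,3)
    fa = np.matmul(pc.gradN, p.transpose(0, 1, 3, 2))  # (nel, nqp, 6, 3)
    f_el = (fa * pc.wdet[..., None, None]).sum(axis=1)

    n_nodes = len(u)
    out = np.zeros((n_nodes, 3))
    idx = pc.conn.reshape(-1)
    for k in range(3):
        out[:, k] = np.bincount(idx, weights=f_el[..., k].reshape(-1),
                                minlength=n_nodes)
    if not return_stress:
        return out

    vol = pc.wdet.sum(axis=1)
    f_avg = (f * pc.wdet[..., None, None]).sum(axis=1) / vol[:, None, None]
    p_avg = (p * pc.wdet[..., None, None]).sum(axis=1) / vol[:, None, None]
    j = _det33(f)
    sig_qp = np.matmul(p, f.transpose(0, 1, 3, 2)) / j[..., None, None]
    sig_avg = (sig_qp * pc.wdet[..., None, None]).sum(axis=1) / vol[:, None, None]
    return out, StressField(deformation_gradient=f_avg, piola=p_avg, cauchy=sig_avg)


def strain_energy(mesh, u, mat: ElasticMaterial, precomp: WedgePrecomp | None = None) -> float:
    """Total St. Venant-Kirchhoff strain energy (pN·μm)."""
    pc = precomp if precomp is not None else precompute(mesh)
    lam, mu = mat.lame
    u_el = np.asarray(u)[pc.conn]
    h = np.matmul(u_el.transpose(0, 2, 1)[:, None], pc.gradN)
    f = h + np.eye(3)
    e_gl = 0.5 * (np.matmul(f.transpose(0, 1, 3, 2), f) - np.eye(3))
    tr = e_gl[..., 0, 0] + e_gl[..., 1, 1] + e_gl[..., 2, 2]
    w = 0.5 * lam * tr**2 + mu * (e_gl * e_gl).sum(axis=(-2, -1))
    return float(np.sum(w * pc.wdet))


def lumped_mass(mesh, mat: ElasticMaterial, precomp: WedgePrecomp | None = None) -> np.ndarray:
    """Row-sum lumped nodal masses (ng); strictly positive, sums to ρ·V."""
    pc = precomp if precomp is not None else precompute(mesh)
    m_el = mat.density * np.einsum("qa,eq->ea", pc.shapeN, pc.wdet)
    n_nodes = mesh.n_nodes
    m = np.bincount(pc.conn.reshape(-1), weights=m_el.reshape(-1),
                    minlength=n_nodes)
    if np.any(m <= 0):
        raise ValueError("non-positive lumped mass; check mesh")
    return m


# ---------------------------------------------------------------------------
# Explicit integration
# ---------------------------------------------------------------------------


def stable_dt(mesh, mat: ElasticMaterial, safety: float = 0.5) -> float:
    """CFL-type stable increment: safety × min(edge length) / wave speed."""
    if not (0 < safety <= 1):
        raise ValueError("safety must be in (0, 1]")
    el = mesh.nodes[mesh.elements]  # (nel, 6, 3)
    edges = [(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3), (0, 3), (1, 4), (2, 5)]
    lmin = np.inf
    for a, b in edges:
        lmin = min(lmin, np.linalg.norm(el[:, a] - el[:, b], axis=1).min())
    return float(safety * lmin / mat.dilatational_wave_speed)


def explicit_step(state: SimulationState, f_ext: np.ndarray, f_int: np.ndarray,
                  dt: float, damping: float = 0.0,
                  fixed_mask: np.ndarray | None = None) -> SimulationState:
    """Advance one damped central-difference (leapfrog) step in place.

    Accelerations follow a = M⁻¹(F_ext − F_int) − c v with mass-proportional
    damping coefficient ``c`` (1/ms); velocities live at half steps.  The
    first step uses a half kick so constant-force trajectories reproduce the
    ballistic closed form exactly.
    """
    m = state.mass[:, None]
    a = (f_ext - f_int) / m
    c = damping
    if state.step == 0:
        # half kick, undamped start from rest
        v_new = state.v + 0.5 * dt * a
        v_new /= 1.0 + 0.5 * c * dt
    else:
        v_new = ((1.0 - 0.5 * c * dt) * state.v + dt * a) / (1.0 + 0.5 * c * dt)
    if fixed_mask is not None:
        v_new = np.where(fixed_mask, 0.0, v_new)
        a = np.where(fixed_mask, 0.0, a)
    state.u = state.u + dt * v_new
    state.v = v_new
    state.a = a
    state.t += dt
    state.step += 1
    if not np.all(np.isfinite(state.u)):
        raise DivergenceError(
            f"NaN/Inf in displacements at step {state.step}; "
            f"max |u| = {np.nanmax(np.abs(state.u)):.3e} μm"
        )
    return state
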