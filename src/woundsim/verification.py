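"""Solver verification problems with closed-form expectations.

The uniaxial patch test loads a single extruded hexagonal cell with equal and
opposite dead loads on its two x-facing lateral faces and relaxes to static
equilibrium with the damped explicit solver.  Stress and strain are reported
in the work-conjugate finite-strain pair (second Piola-Kirchhoff stress,
Green-Lagrange strain), for which the St. Venant-Kirchhoff law is exactly
linear, so the recovered modulus and Poisson ratio equal the material inputs
up to solver convergence.
"""

from __future__ import annotations

import numpy as np

from . import fem
from .geometry import MonolayerGeometry, MonolayerSpec, extrude_to_wedges

__all__ = ["hexagonal_cell_mesh", "uniaxial_patch_test"]


def hexagonal_cell_mesh(diameter: float = 26.0, thickness: float = 10.0):
    """One regular hexagonal cell, oriented with two faces normal to x."""
    r = 0.5 * diameter
    ang = np.radians(30.0 + 60.0 * np.arange(6))
    poly = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    spec = MonolayerSpec(domain_side=10.0 * diameter,
                         mean_cell_diameter=diameter, thickness=thickness)
    geom = MonolayerGeometry(
        spec=spec,
        seeds=np.zeros((1, 2)),
        footprints=[poly],
        cells=[poly],
        edge_partner=[[-2] * 6],  # all faces free
    )
    return extrude_to_wedges(geom, thickness=thickness, n_layers=1, z0=0.0)


def uniaxial_patch_test(mat: fem.ElasticMaterial, strain_target: float = 0.01,
                        max_steps: int = 200_000, rtol: float = 1e-9) -> dict:
    """Relax the hexagonal cell under uniaxial dead load; report E and ν.

    The nominal axial traction is ``E × strain_target``.  Returns the
    volume-averaged conjugate measures: ``modulus_kpa`` = S₁₁/E₁₁ in kPa and
    ``poisson`` = −E₂₂/E₁₁.
    """
    mesh = hexagonal_cell_mesh()
    pc = fem.precompute(mesh)
    mass = fem.lumped_mass(mesh, mat, pc)
    state = fem.SimulationState.zeros(mesh.n_nodes, mass)

    # identify the two lateral faces whose outward normals are ±x
    from .cohesive import face_normals

    quads = mesh.nodes[mesh.lateral_faces]
    normals = face_normals(quads)
    plus = np.flatnonzero(normals[:, 0] > 0.99)
    minus = np.flatnonzero(normals[:, 0] < -0.99)
    assert len(plus) == 1 and len(minus) == 1

    def face_area(f):
        q = quads[f[0]]
        return float(
            0.5 * np.linalg.norm(np.cross(q[1] - q[0], q[2] - q[0]))
            + 0.5 * np.linalg.norm(np.cross(q[2] - q[0], q[3] - q[0])))

    p11 = mat.E * strain_target
    f_ext = np.zeros((mesh.n_nodes, 3))
    for faces, sign in ((plus, +1.0), (minus, -1.0)):
        nodes = mesh.lateral_faces[faces[0]]
        f_ext[nodes, 0] += sign * p11 * face_area(faces) / 4.0

    c_d = mat.dilatational_wave_speed
    extent = float(np.ptp(mesh.nodes[:, 0]))
    damping = np.pi * c_d / extent
    dt = fem.stable_dt(mesh, mat, 0.3)

    scale = np.abs(f_ext).max()
    for _ in range(max_steps):
        f_int = fem.internal_force(mesh, state, mat, pc)
        fem.explicit_step(state, f_ext, f_int, dt, damping)
        if state.step % 200 == 0:
            res = np.abs(f_ext - f_int).max()
            if res < rtol * scale and np.abs(state.v).max() * dt < 1e-12:
                break

    _, field = fem.internal_force(mesh, state, mat, pc, return_stress=True)
    vols = mesh.element_volumes()
    f_avg = np.einsum("eij,e->ij", field.deformation_gradient, vols) / vols.sum()
    # conjugate measures from the volume-averaged deformation
    e_gl = 0.5 * (f_avg.T @ f_avg - np.eye(3))
    s_avg = np.einsum(
        "eij,e->ij",
        np.matmul(np.linalg.inv(field.deformation_gradient), field.piola),
        vols,
    ) / vols.sum()
    modulus = s_avg[0, 0] / e_gl[0, 0]
    poisson = -e_gl[1, 1] / e_gl[0, 0]
    return {
        "modulus_kpa": float(modulus / 1000.0),
        "poisson": float(poisson),
        "axial_strain": float(e_gl[0, 0]),
        "steps": state.step,
    }
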