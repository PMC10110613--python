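"""Lamellipodial protrusion loading.

Wound closure is driven by crawling: cells bordering the gap extend
lamellipodia and exert a traction directed at the wound centre on their free
(wound-edge) faces, while every other cell takes part in a global tug-of-war,
receiving a weak traction of random magnitude and direction on one randomly
chosen lateral face, resampled periodically.

Tractions are configured in nN/μm² (= kPa); the defaults carry the numerals
of the source protrusion model (edge 2, bulk 0-0.3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

__all__ = ["ProtrusionConfig", "ProtrusionState", "wound_edge_faces", "apply_protrusion"]

_KPA = 1000.0  # nN/μm² -> pN/μm²


@dataclass(frozen=True)
class ProtrusionConfig:
    """Protrusion loading parameters.

    ``edge_traction`` acts on each wound-edge face toward the wound centre;
    bulk tractions of magnitude Uniform(min, max) act on one random lateral
    face of every other cell in a random in-plane direction.
    """

    edge_traction: float = 2.0  # nN/μm²
    bulk_traction_max: float = 0.3  # nN/μm²
    bulk_traction_min: float = 0.0
    resample_every: int = 500
    edge_refresh_every: int = 100
    rng_seed: int = 0

    def __post_init__(self):
        if self.edge_traction < 0:
            raise ValueError("edge_traction must be >= 0")
        if not (0 <= self.bulk_traction_min <= self.bulk_traction_max):
            raise ValueError("require 0 <= bulk_traction_min <= bulk_traction_max")


def _free_faces(mesh, pairs=None):
    """Lateral faces with no cohesive partner and not on the outer wall."""
    if pairs is None:
        return np.flatnonzero(mesh.face_is_free)
    partnered = np.zeros(len(mesh.lateral_faces), dtype=bool)
    partnered[pairs.slave] = True
    partnered[pairs.master] = True
    return np.flatnonzero(~partnered & ~mesh.face_is_outer)


def wound_edge_faces(mesh, state, pairs=None, gap=None, adjacency_tol=2.0):
    """Faces bounding the current gap, and the gap centroid.

    A lateral face is a wound-edge face when it has no cohesive partner and
    lies within ``adjacency_tol`` (μm) of the gap region.  Returns
    ``(face_indices, centroid)``; when the wound is closed (no gap region)
    the set is empty and the centroid is ``None``.
    """
    from .postprocess import gap_region  # local import to avoid a cycle

    u = state.u if hasattr(state, "u") else np.asarray(state)
    if gap is None:
        gap, _, _ = gap_region(mesh, u)
    if gap is None or gap.is_empty:
        return np.array([], dtype=np.int64), None
    free = _free_faces(mesh, pairs)
    if len(free) == 0:
        return free, None
    pos = mesh.nodes + u
    centroids = pos[mesh.lateral_faces[free]].mean(axis=1)
    pts = shapely.points(centroids[:, :2])
    dist = shapely.distance(pts, gap)
    sel = free[dist < adjacency_tol]
    cen = np.array([gap.centroid.x, gap.centroid.y])
    return sel, cen


class ProtrusionState:
    """Cached nodal protrusion forces, refreshed on the configured schedule.

    The edge face set and gap centroid are refreshed every
    ``edge_refresh_every`` steps by the driver; bulk tug-of-war forces are
    resampled every ``resample_every`` steps from the seeded generator.
    """

    def __init__(self, mesh, cfg: ProtrusionConfig):
        self.mesh = mesh
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.rng_seed)
        # reference areas of lateral faces (two fan triangles)
        quads = mesh.nodes[mesh.lateral_faces]
        a1 = 0.5 * np.linalg.norm(
            np.cross(quads[:, 1] - quads[:, 0], quads[:, 2] - quads[:, 0]), axis=1)
        a2 = 0.5 * np.linalg.norm(
            np.cross(quads[:, 2] - quads[:, 0], quads[:, 3] - quads[:, 0]), axis=1)
        self.face_area = a1 + a2
        self.edge_faces = np.array([], dtype=np.int64)
        self.gap_centroid: np.ndarray | None = None
        self._bulk_face: np.ndarray | None = None
        self._bulk_force: np.ndarray | None = None

    def refresh_edges(self, u, pairs=None, gap=None):
        """Refresh the loaded leading faces: one lamellipodium per cell.

        Each wound-edge cell extends a single leading lamellipodium, so of a
        cell's gap-bounding faces only the largest (in the current
        configuration) carries the protrusion traction.
        """
        faces, cen = wound_edge_faces(self.mesh, u, pairs=pairs, gap=gap)
        self.gap_centroid = cen
        if len(faces) == 0:
            self.edge_faces = faces
            return
        pos = self.mesh.nodes + u
        q = pos[self.mesh.lateral_faces[faces]]
        area = 0.5 * (
            np.linalg.norm(np.cross(q[:, 1] - q[:, 0], q[:, 2] - q[:, 0]), axis=1)
            + np.linalg.norm(np.cross(q[:, 2] - q[:, 0], q[:, 3] - q[:, 0]), axis=1)
        )
        chosen = {}
        for f, a in zip(faces, area):
            c = int(self.mesh.face_cell[f])
            if c not in chosen or a > chosen[c][1]:
                chosen[c] = (int(f), float(a))
        self.edge_faces = np.array(sorted(f for f, _ in chosen.values()),
                                   dtype=np.int64)

    def resample_bulk(self):
        """Redraw the tug-of-war forces on one lateral face per bulk cell."""
        cfg, mesh = self.cfg, self.mesh
        edge_cells = set(mesh.face_cell[self.edge_faces].tolist())
        faces, forces = [], []
        for cid in mesh.cell_ids:
            if int(cid) in edge_cells:
                continue
            cell_faces = np.flatnonzero(mesh.face_cell == cid)
            f = int(self.rng.choice(cell_faces))
            mag = self.rng.uniform(cfg.bulk_traction_min, cfg.bulk_traction_max)
            ang = self.rng.uniform(0.0, 2.0 * np.pi)
            faces.append(f)
            forces.append(
                mag * _KPA * self.face_area[f] * np.array([np.cos(ang), np.sin(ang), 0.0]))
        self._bulk_face = np.array(faces, dtype=np.int64)
        self._bulk_force = np.array(forces).reshape(-1, 3)

    def nodal_forces(self, u) -> np.ndarray:
        """Assemble the global protrusion force vector F^p (pN).

        Wound-edge faces are loaded along their in-plane outward normal
        (the crawling-front direction; for a convex gap this points toward
        the wound centre), with the traction acting on the current face
        area so a front that collapses stops pulling.  The centroid
        direction is used as a fallback when a face normal has degenerated.
        """
        mesh, cfg = self.mesh, self.cfg
        out = np.zeros((mesh.n_nodes, 3))
        pos = mesh.nodes + u
        if len(self.edge_faces) and self.gap_centroid is not None and cfg.edge_traction > 0:
            from .cohesive import face_normals

            quads = mesh.lateral_faces[self.edge_faces]
            q = pos[quads]
            cen = q.mean(axis=1)
            to_gap = self.gap_centroid - cen[:, :2]
            nrm = face_normals(q)[:, :2]
            nlen = np.linalg.norm(nrm, axis=1)
            glen = np.linalg.norm(to_gap, axis=1)
            dirs = np.zeros((len(quads), 3))
            use_n = nlen > 0.2
            dirs[use_n, :2] = nrm[use_n] / nlen[use_n, None]
            fb = ~use_n & (glen > 1e-9)
            dirs[fb, :2] = to_gap[fb] / glen[fb, None]
            # never push away from the gap
            away = (dirs[:, :2] * to_gap).sum(axis=1) < 0
            dirs[away] *= -1.0
            area = 0.5 * (
                np.linalg.norm(np.cross(q[:, 1] - q[:, 0], q[:, 2] - q[:, 0]), axis=1)
                + np.linalg.norm(np.cross(q[:, 2] - q[:, 0], q[:, 3] - q[:, 0]), axis=1)
            )
            per_node = 0.25 * cfg.edge_traction * _KPA * area[:, None] * dirs
            for a in range(4):
                np.add.at(out, quads[:, a], per_node)
        if self._bulk_face is not None and len(self._bulk_face):
            quads = mesh.lateral_faces[self._bulk_face]
            per_node = 0.25 * self._bulk_force
            for a in range(4):
                np.add.at(out, quads[:, a], per_node)
        return out


def apply_protrusion(mesh, state, cfg: ProtrusionConfig, pairs=None) -> np.ndarray:
    """One-shot protrusion force assembly (edge set and bulk freshly drawn)."""
    u = state.u if hasattr(state, "u") else np.asarray(state)
    ps = ProtrusionState(mesh, cfg)
    ps.refresh_edges(u, pairs=pairs)
    ps.resample_bulk()
    return ps.nodal_forces(u)
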