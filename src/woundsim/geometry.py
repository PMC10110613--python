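"""Wounded epithelial-monolayer geometry and wedge-element mesh generation.

The monolayer is modelled as a square sheet of polygonal cells obtained by
Voronoi tessellation of relaxed random seeds.  Each cell polygon is shrunk
inward by half the junction gap so that neighbouring cells are separated by a
thin (nanometre-scale) cell-cell junction across which cohesive tractions act.
A wound is created by removing the cells nearest the domain centre until a
target footprint area is reached.  Finally each cell is fan-triangulated about
its centroid and extruded through the monolayer thickness into 6-node wedge
(triangular-prism) finite elements.

Unit conventions: all lengths are stored in micrometres.  The substrate top
surface is the plane z = 0; the monolayer occupies z in (z0, z0 + thickness]
where z0 is a nanometre-scale standoff equal to the equilibrium cell-substrate
separation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi, cKDTree
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union

__all__ = [
    "GeometryError",
    "MonolayerSpec",
    "MonolayerGeometry",
    "WedgeMesh",
    "generate_seeds",
    "build_voronoi_monolayer",
    "excise_wound",
    "extrude_to_wedges",
]


class GeometryError(RuntimeError):
    """Raised when geometry generation or meshing fails."""


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MonolayerSpec:
    """Parameters of the wounded-monolayer geometry.

    Parameters
    ----------
    domain_side:
        Side length of the square sheet (μm).
    mean_cell_diameter:
        Target mean equivalent-circle cell diameter (μm).  Sets the seed
        count ``N = floor(domain_side² / (π (d/2)²))``.
    junction_gap:
        Initial cell-cell junction separation (μm).  Default 10 nm.
    thickness:
        Monolayer thickness (μm); epithelial monolayers are reported between
        3 and 15 μm.
    wound_target_area:
        Target wound footprint area (μm²); 0 disables the wound.
    rng_seed:
        Seed of the random generator used for cell seeding.
    """

    domain_side: float = 400.0
    mean_cell_diameter: float = 26.0
    junction_gap: float = 0.01
    thickness: float = 10.0
    wound_target_area: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.domain_side > self.mean_cell_diameter > 0):
            raise ValueError("require domain_side > mean_cell_diameter > 0")
        if not (3.0 <= self.thickness <= 15.0):
            raise ValueError("thickness must lie in [3, 15] μm")
        if self.junction_gap <= 0:
            raise ValueError("junction_gap must be positive")
        if not (0 <= self.wound_target_area < self.domain_side**2):
            raise ValueError("wound_target_area must be in [0, domain_side²)")

    @property
    def n_seeds(self) -> int:
        r = 0.5 * self.mean_cell_diameter
        return int(np.floor(self.domain_side**2 / (np.pi * r**2)))


# ---------------------------------------------------------------------------
# Voronoi tessellation helpers
# ---------------------------------------------------------------------------


def _mirror_points(points: np.ndarray, side: float) -> np.ndarray:
    """Reflect seeds across the four domain walls.

    The Voronoi diagram of the augmented set restricted to the original seeds
    tiles the square exactly, so no explicit clipping is needed.
    """
    left = points * [-1.0, 1.0]
    right = points * [-1.0, 1.0] + [2.0 * side, 0.0]
    down = points * [1.0, -1.0]
    up = points * [1.0, -1.0] + [0.0, 2.0 * side]
    return np.vstack([points, left, right, down, up])


def _region_polygons(points: np.ndarray, side: float) -> list[np.ndarray]:
    """Voronoi cell polygon (CCW vertex array) for each seed."""
    n = len(points)
    vor = Voronoi(_mirror_points(points, side))
    polys: list[np.ndarray] = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:  # pragma: no cover - mirrored set is finite
            raise GeometryError(f"unbounded Voronoi region for seed {i}")
        verts = vor.vertices[region]
        # enforce counter-clockwise orientation
        if _signed_area(verts) < 0:
            verts = verts[::-1]
        polys.append(verts)
    return polys


def _signed_area(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _centroid(verts: np.ndarray) -> np.ndarray:
    x, y = verts[:, 0], verts[:, 1]
    xs, ys = np.roll(x, -1), np.roll(y, -1)
    cross = x * ys - xs * y
    a = 0.5 * cross.sum()
    cx = np.sum((x + xs) * cross) / (6.0 * a)
    cy = np.sum((y + ys) * cross) / (6.0 * a)
    return np.array([cx, cy])


def generate_seeds(spec: MonolayerSpec, relax_iters: int = 3) -> np.ndarray:
    """Draw and relax cell seed points.

    Seeds are drawn uniformly in the domain and relaxed with ``relax_iters``
    Lloyd (centroidal Voronoi) iterations so the resulting cells are
    near-equiareal, emulating the regular polygonal packing of an epithelium.

    Returns an ``(N, 2)`` array with ``N = floor(domain² / (π (d/2)²))``.
    """
    n = spec.n_seeds
    if n < 4:
        raise GeometryError(
            f"domain holds only {n} cells (< 4); enlarge domain_side "
            f"or reduce mean_cell_diameter"
        )
    rng = np.random.default_rng(spec.rng_seed)
    pts = rng.uniform(0.0, spec.domain_side, size=(n, 2))
    for _ in range(relax_iters):
        polys = _region_polygons(pts, spec.domain_side)
        pts = np.array([_centroid(p) for p in polys])
    return pts


# ---------------------------------------------------------------------------
# Monolayer construction
# ---------------------------------------------------------------------------

#: edge partner sentinel: the edge lies on the outer domain boundary
OUTER = -1
#: edge partner sentinel: the edge has no cohesive partner (wound / orphan)
FREE = -2


@dataclass
class MonolayerGeometry:
    """Planar cell layout with junction topology.

    ``footprints`` are the exact (tiling) Voronoi polygons; ``cells`` are the
    same polygons shrunk inward by half the junction gap.  ``edge_partner``
    maps every edge ``(cell, edge)`` to its opposing edge ``(other_cell,
    other_edge)`` across a junction, or to the sentinels ``OUTER`` / ``FREE``.
    """

    spec: MonolayerSpec
    seeds: np.ndarray
    footprints: list[np.ndarray]
    cells: list[np.ndarray]
    edge_partner: list[list[tuple[int, int] | int]]
    wound_cells: list[int] = field(default_factory=list)
    wound_boundary: np.ndarray | None = None
    wound_area: float = 0.0

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def surviving(self) -> list[int]:
        removed = set(self.wound_cells)
        return [c for c in range(self.n_cells) if c not in removed]

    @property
    def junction_pairs(self) -> list[tuple[int, int, int, int]]:
        """(cell_a, edge_a, cell_b, edge_b) with a < b, both surviving."""
        removed = set(self.wound_cells)
        pairs = []
        for c, partners in enumerate(self.edge_partner):
            if c in removed:
                continue
            for e, partner in enumerate(partners):
                if isinstance(partner, tuple):
                    j, ej = partner
                    if j > c and j not in removed:
                        pairs.append((c, e, j, ej))
        return pairs

    def partner_of(self, cell: int, edge: int) -> tuple[int, int] | int:
        partner = self.edge_partner[cell][edge]
        if isinstance(partner, tuple) and partner[0] in set(self.wound_cells):
            return FREE
        return partner

    def cell_areas(self) -> np.ndarray:
        return np.array([_signed_area(p) for p in self.cells])

    def equivalent_diameters(self) -> np.ndarray:
        """Diameter of the equal-area circle of every cell footprint."""
        areas = np.array([_signed_area(p) for p in self.footprints])
        return 2.0 * np.sqrt(areas / np.pi)


def _reflect_across_edge(p: np.ndarray, v0: np.ndarray, v1: np.ndarray) -> np.ndarray:
    d = v1 - v0
    t = np.dot(p - v0, d) / np.dot(d, d)
    foot = v0 + t * d
    return 2.0 * foot - p


def _inward_offset(
    verts: np.ndarray, h: float, min_edge: float = 0.0
) -> tuple[np.ndarray, list[int]]:
    """Offset a convex CCW polygon inward by ``h`` (mitred).

    Each offset edge shares the supporting-line direction of its original
    edge.  Edges that collapse under the offset are dropped, as are edges
    shorter than ``min_edge`` (a mesh-quality measure: near-degenerate
    Voronoi edges would otherwise force a vanishing explicit time step)
    provided the mitre fill stays within twice ``min_edge`` of the removed
    edge.  Returns the new vertex array and the list of surviving original
    edge indices (the k-th offset edge runs from new vertex k to k+1 and
    descends from original edge ``kept[k]``).
    """
    k = len(verts)
    d = np.roll(verts, -1, axis=0) - verts
    lengths = np.linalg.norm(d, axis=1)
    if np.any(lengths <= 0):
        raise GeometryError("degenerate polygon edge")
    dn = d / lengths[:, None]
    # inward normal of a CCW polygon edge
    n_in = np.stack([-dn[:, 1], dn[:, 0]], axis=1)
    active = list(range(k))
    guarded: set[int] = set()

    def intersect(i: int, j: int) -> np.ndarray:
        # intersection of the offset supporting lines of edges i and j
        p_i = verts[i] + h * n_in[i]
        p_j = verts[j] + h * n_in[j]
        a = np.array([[dn[i][0], -dn[j][0]], [dn[i][1], -dn[j][1]]])
        det = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
        if abs(det) < 1e-14:
            raise GeometryError("parallel adjacent polygon edges")
        rhs = p_j - p_i
        t = (rhs[0] * a[1, 1] - rhs[1] * a[0, 1]) / det
        return p_i + t * dn[i]

    for _ in range(2 * k):  # bounded removal sweeps
        m = len(active)
        if m < 3:
            raise GeometryError("polygon collapsed under junction-gap offset")
        new_verts = np.array(
            [intersect(active[i - 1], active[i]) for i in range(m)]
        )
        edge_vec = np.roll(new_verts, -1, axis=0) - new_verts
        proj = np.einsum("ij,ij->i", edge_vec, dn[active])
        forced = proj <= 1e-9
        short = (proj < min_edge) & ~forced
        short &= np.array([active[i] not in guarded for i in range(m)])
        if not forced.any() and not short.any():
            if _signed_area(new_verts) <= 0:
                raise GeometryError("polygon collapsed under junction-gap offset")
            return new_verts, active
        # remove the worst offender, guarding short-edge merges whose mitre
        # fill would stray far from the removed edge
        cand = np.flatnonzero(forced | short)
        i = cand[np.argmin(proj[cand])]
        if not forced[i]:
            e = active[i]
            vtx = intersect(active[i - 1], active[(i + 1) % m])
            mid = 0.5 * (verts[e] + verts[(e + 1) % k])
            if np.linalg.norm(vtx - mid) > max(2.0 * min_edge, 4.0 * h):
                guarded.add(e)
                continue
        del active[i]
    raise GeometryError("polygon offset did not converge")


def build_voronoi_monolayer(
    spec: MonolayerSpec, seeds: np.ndarray, min_edge: float | None = None
) -> MonolayerGeometry:
    """Tessellate the domain and carve the junction gaps.

    The Voronoi cells of the (relaxed) seeds tile the square exactly; each is
    then offset inward by ``junction_gap / 2`` so that the facing edges of
    every neighbouring pair are parallel and separated by ``junction_gap``.
    Opposing-edge records are built for every shared Voronoi ridge.
    ``min_edge`` (default 2% of the mean cell diameter) merges near-degenerate
    polygon edges for mesh quality.
    """
    if min_edge is None:
        min_edge = 0.02 * spec.mean_cell_diameter
    side = spec.domain_side
    seeds = np.asarray(seeds, dtype=float)
    if seeds.ndim != 2 or seeds.shape[1] != 2:
        raise ValueError("seeds must be an (N, 2) array")
    if np.any(seeds < 0) or np.any(seeds > side):
        raise ValueError("seeds must lie inside the domain")

    footprints = _region_polygons(seeds, side)
    all_pts = _mirror_points(seeds, side)
    tree = cKDTree(all_pts)
    n = len(seeds)

    # neighbour of each original edge: reflect the seed across the edge line;
    # the image is the neighbouring seed (or a mirrored ghost on a wall edge)
    raw_partner: list[list[int]] = []
    for c, poly in enumerate(footprints):
        k = len(poly)
        partners = []
        for e in range(k):
            img = _reflect_across_edge(seeds[c], poly[e], poly[(e + 1) % k])
            dist, j = tree.query(img)
            if dist > 1e-6 * side:  # pragma: no cover - exact tessellation
                raise GeometryError(f"edge {e} of cell {c}: no opposing seed found")
            partners.append(int(j))
        raw_partner.append(partners)

    # inward offset, tracking surviving edges
    cells: list[np.ndarray] = []
    kept_edges: list[list[int]] = []
    for c, poly in enumerate(footprints):
        try:
            offset, kept = _inward_offset(poly, 0.5 * spec.junction_gap, min_edge)
        except GeometryError as exc:
            raise GeometryError(
                f"cell {c} collapsed under the junction-gap offset; "
                f"regenerate seeds"
            ) from exc
        cells.append(offset)
        kept_edges.append(kept)

    # remap: original edge index -> final edge index (or -1 if dropped)
    edge_of: list[dict[int, int]] = [
        {orig: final for final, orig in enumerate(kept)} for kept in kept_edges
    ]

    edge_partner: list[list[tuple[int, int] | int]] = []
    for c in range(n):
        partners: list[tuple[int, int] | int] = []
        for final_e, orig_e in enumerate(kept_edges[c]):
            j = raw_partner[c][orig_e]
            if j >= n:
                partners.append(OUTER)
                continue
            # locate the reciprocal edge of cell j
            back = None
            for oe, pj in enumerate(raw_partner[j]):
                if pj == c:
                    back = edge_of[j].get(oe, -1)
                    break
            if back is None or back < 0:
                partners.append(FREE)
            else:
                partners.append((j, back))
        edge_partner.append(partners)

    return MonolayerGeometry(
        spec=spec,
        seeds=seeds,
        footprints=footprints,
        cells=cells,
        edge_partner=edge_partner,
    )


def excise_wound(geom: MonolayerGeometry, target_area: float) -> MonolayerGeometry:
    """Remove the cells nearest the domain centre to open a wound.

    Cells are removed greedily by centroid distance to the centre (ties broken
    by cell id) until the cumulative removed footprint area first reaches
    ``target_area``.  The achieved area (union of removed footprints) is
    recorded; it always meets or exceeds the target.
    """
    if target_area < 0:
        raise ValueError("target_area must be non-negative")
    if target_area > 0.5 * geom.spec.domain_side**2:
        raise GeometryError("wound target exceeds half the domain area")
    if target_area == 0:
        return dataclasses.replace(
            geom, wound_cells=[], wound_boundary=None, wound_area=0.0
        )

    center = np.array([geom.spec.domain_side / 2.0] * 2)
    centroids = np.array([_centroid(p) for p in geom.footprints])
    dist = np.linalg.norm(centroids - center, axis=1)
    order = np.lexsort((np.arange(geom.n_cells), dist))

    removed: list[int] = []
    cum = 0.0
    for c in order:
        removed.append(int(c))
        cum += _signed_area(geom.footprints[c])
        if cum >= target_area:
            break

    union = unary_union([Polygon(geom.footprints[c]) for c in removed])
    if union.geom_type == "MultiPolygon":  # keep the largest component outline
        outline = max(union.geoms, key=lambda g: g.area)
    else:
        outline = union
    boundary = np.asarray(outline.exterior.coords[:-1])
    return dataclasses.replace(
        geom,
        wound_cells=sorted(removed),
        wound_boundary=boundary,
        wound_area=float(union.area),
    )


# ---------------------------------------------------------------------------
# Extrusion to wedge elements
# ---------------------------------------------------------------------------


@dataclass
class WedgeMesh:
    """Extruded wedge-element mesh of the (possibly wounded) monolayer.

    Lateral faces are stored as quads ``[b0, b1, t1, t0]`` (bottom edge then
    top edge, outward orientation following the cell perimeter).  Bottom and
    top faces are the fan triangles of each cell at the lowest and highest
    node level.  ``junction_face_pairs`` indexes ``lateral_faces``.
    """

    nodes: np.ndarray  # (n, 3)
    elements: np.ndarray  # (m, 6)
    element_cell_id: np.ndarray  # (m,)
    lateral_faces: np.ndarray  # (f, 4)
    face_cell: np.ndarray  # (f,)
    face_edge: np.ndarray  # (f,)
    face_layer: np.ndarray  # (f,)
    face_is_outer: np.ndarray  # (f,) bool
    face_is_free: np.ndarray  # (f,) bool: no cohesive partner initially
    bottom_faces: np.ndarray  # (b, 3)
    bottom_cell: np.ndarray  # (b,)
    top_faces: np.ndarray  # (b, 3)
    junction_face_pairs: np.ndarray  # (p, 2) indices into lateral_faces
    perimeter_nodes: list[np.ndarray]  # per surviving cell: (n_layers+1, k)
    cell_ids: np.ndarray  # surviving cell ids, aligned with perimeter_nodes
    geom: MonolayerGeometry
    n_layers: int
    thickness: float
    z0: float

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def element_volumes(self) -> np.ndarray:
        """Exact prism volumes (triangle area × layer height per wedge)."""
        tri = self.nodes[self.elements[:, :3]][:, :, :2]
        a = 0.5 * np.abs(
            (tri[:, 1, 0] - tri[:, 0, 0]) * (tri[:, 2, 1] - tri[:, 0, 1])
            - (tri[:, 2, 0] - tri[:, 0, 0]) * (tri[:, 1, 1] - tri[:, 0, 1])
        )
        dz = self.nodes[self.elements[:, 3], 2] - self.nodes[self.elements[:, 0], 2]
        return a * dz

    def outer_boundary_nodes(self) -> np.ndarray:
        """Nodes on the outer (domain wall) lateral faces."""
        faces = self.lateral_faces[self.face_is_outer]
        return np.unique(faces)

    def face_quads(self, which: np.ndarray | None = None) -> np.ndarray:
        idx = self.lateral_faces if which is None else self.lateral_faces[which]
        return self.nodes[idx]

    def midplane_footprint(self, u: np.ndarray | None = None) -> list[np.ndarray]:
        """Deformed mid-plane (z = thickness/2) footprint polygon per cell.

        With the default single wedge layer the mid-plane vertex positions are
        the mean of the bottom and top perimeter rings.
        """
        pos = self.nodes if u is None else self.nodes + u
        out = []
        for ring in self.perimeter_nodes:
            bot = pos[ring[0], :2]
            top = pos[ring[-1], :2]
            out.append(0.5 * (bot + top))
        return out


def extrude_to_wedges(
    geom: MonolayerGeometry,
    thickness: float | None = None,
    n_layers: int = 1,
    z0: float = 1e-3,
) -> WedgeMesh:
    """Fan-triangulate each surviving cell and extrude it into wedge layers.

    Every cell polygon is triangulated about its centroid (added as a node)
    and extruded into ``n_layers`` wedge layers between ``z0`` and
    ``z0 + thickness``.  The node count per cell is ``(k + 1) (n_layers + 1)``
    for a ``k``-gon.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if thickness is None:
        thickness = geom.spec.thickness

    surviving = geom.surviving
    nodes: list[np.ndarray] = []
    elements: list[list[int]] = []
    el_cell: list[int] = []
    lat_faces: list[list[int]] = []
    face_cell: list[int] = []
    face_edge: list[int] = []
    face_layer: list[int] = []
    face_outer: list[bool] = []
    face_free: list[bool] = []
    bottom: list[list[int]] = []
    bottom_cell: list[int] = []
    top: list[list[int]] = []
    perimeter: list[np.ndarray] = []
    face_lookup: dict[tuple[int, int, int], int] = {}

    dz = thickness / n_layers
    offset = 0
    for c in surviving:
        poly = geom.cells[c]
        if not Polygon(poly).is_valid:
            raise GeometryError(f"cell {c}: non-simple polygon, cannot mesh")
        k = len(poly)
        cen = _centroid(poly)
        ring = np.empty((n_layers + 1, k), dtype=np.int64)
        cen_ids = np.empty(n_layers + 1, dtype=np.int64)
        for lv in range(n_layers + 1):
            z = z0 + lv * dz
            for i in range(k):
                ring[lv, i] = offset
                nodes.append(np.array([poly[i, 0], poly[i, 1], z]))
                offset += 1
            cen_ids[lv] = offset
            nodes.append(np.array([cen[0], cen[1], z]))
            offset += 1
        perimeter.append(ring)

        for lv in range(n_layers):
            for i in range(k):
                j = (i + 1) % k
                elements.append(
                    [
                        cen_ids[lv], ring[lv, i], ring[lv, j],
                        cen_ids[lv + 1], ring[lv + 1, i], ring[lv + 1, j],
                    ]
                )
                el_cell.append(c)
                partner = geom.partner_of(c, i)
                face_lookup[(c, i, lv)] = len(lat_faces)
                lat_faces.append(
                    [ring[lv, i], ring[lv, j], ring[lv + 1, j], ring[lv + 1, i]]
                )
                face_cell.append(c)
                face_edge.append(i)
                face_layer.append(lv)
                face_outer.append(partner == OUTER)
                face_free.append(partner == FREE)
                if lv == 0:
                    bottom.append([cen_ids[0], ring[0, i], ring[0, j]])
                    bottom_cell.append(c)
                    top.append(
                        [cen_ids[n_layers], ring[n_layers, i], ring[n_layers, j]]
                    )

    pairs = []
    for (a, ea, b, eb) in geom.junction_pairs:
        for lv in range(n_layers):
            pairs.append([face_lookup[(a, ea, lv)], face_lookup[(b, eb, lv)]])

    return WedgeMesh(
        nodes=np.array(nodes),
        elements=np.array(elements, dtype=np.int64),
        element_cell_id=np.array(el_cell, dtype=np.int64),
        lateral_faces=np.array(lat_faces, dtype=np.int64),
        face_cell=np.array(face_cell, dtype=np.int64),
        face_edge=np.array(face_edge, dtype=np.int64),
        face_layer=np.array(face_layer, dtype=np.int64),
        face_is_outer=np.array(face_outer, dtype=bool),
        face_is_free=np.array(face_free, dtype=bool),
        bottom_faces=np.array(bottom, dtype=np.int64),
        bottom_cell=np.array(bottom_cell, dtype=np.int64),
        top_faces=np.array(top, dtype=np.int64),
        junction_face_pairs=np.array(pairs, dtype=np.int64).reshape(-1, 2),
        perimeter_nodes=perimeter,
        cell_ids=np.array(surviving, dtype=np.int64),
        geom=geom,
        n_layers=n_layers,
        thickness=thickness,
        z0=z0,
    )
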