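"""Stress-field and wound-kinetics analysis.

Converts the first Piola-Kirchhoff element stresses to Cauchy and von Mises
measures, measures the wound gap area from the deformed mid-plane cell
footprints, partitions cells into wound-edge and interior populations, and
fits linear and exponential closure laws to area-versus-time traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union

from .fem import StressField

__all__ = [
    "StressSummary",
    "ClosureFit",
    "cauchy_and_von_mises",
    "gap_region",
    "gap_area",
    "edge_vs_interior",
    "fit_closure_law",
]


# ---------------------------------------------------------------------------
# Stress measures
# ---------------------------------------------------------------------------


def von_mises(sigma: np.ndarray) -> np.ndarray:
    """von Mises invariant √(3/2 dev(σ):dev(σ)) of (..., 3, 3) tensors."""
    tr = np.trace(sigma, axis1=-2, axis2=-1)
    dev = sigma - (tr / 3.0)[..., None, None] * np.eye(3)
    return np.sqrt(1.5 * np.einsum("...ij,...ij->...", dev, dev))


def cauchy_and_von_mises(field: StressField, strict: bool = True) -> np.ndarray:
    """Fill and return the per-element von Mises scalars of a stress field.

    The Cauchy tensor σ = J⁻¹ P Fᵀ is computed per quadrature point during
    assembly and volume-averaged per element; this validates J > 0 and
    reduces σ to the von Mises scalar.  With ``strict=False`` inverted
    elements yield NaN instead of raising, so running summaries can mask
    them.
    """
    bad = field.jacobian <= 0
    if np.any(bad):
        if strict:
            raise ValueError("non-positive deformation Jacobian in stress field")
        field.cauchy = np.where(bad[:, None, None], np.nan, field.cauchy)
    field.von_mises = von_mises(field.cauchy)
    return field.von_mises


# ---------------------------------------------------------------------------
# Gap measurement
# ---------------------------------------------------------------------------


def _footprint_polygons(mesh, u):
    gap = mesh.geom.spec.junction_gap
    polys = []
    for verts in mesh.midplane_footprint(u):
        p = Polygon(verts)
        if not p.is_valid:
            p = shapely.make_valid(p)
        # dilating by the half junction gap seals the nanometre-scale
        # junction slivers so only genuine gaps remain
        polys.append(p.buffer(0.5 * gap))
    return polys


def gap_region(mesh, u=None, search_radius=None, min_feature: float = 2.0):
    """Current wound gap as a polygon: (region, area, centroid).

    The deformed mid-plane cell footprints are united and subtracted from a
    neighbourhood of the initial wound; the connected void containing the
    initial wound centroid is the gap.  Returns ``(None, 0.0, None)`` when
    the monolayer has no wound or the gap has vanished.
    """
    geom = mesh.geom
    if geom.wound_boundary is None or geom.wound_area == 0.0:
        return None, 0.0, None
    if u is None:
        u = np.zeros((mesh.n_nodes, 3))
    wound = Polygon(geom.wound_boundary)
    seed_pt = wound.centroid
    if search_radius is None:
        search_radius = 2.0 * geom.spec.mean_cell_diameter
    side = geom.spec.domain_side
    region = wound.buffer(search_radius).intersection(box(0, 0, side, side))
    tissue = unary_union(_footprint_polygons(mesh, u))
    void = region.difference(tissue)
    if not void.is_empty and min_feature > 0:
        # morphological opening: stretched-junction seams narrower than the
        # cell-cell cohesive cutoff (``min_feature``) are inside the zipping
        # range and are not counted as open gap
        r = 0.5 * min_feature
        void = void.buffer(-r).buffer(r)
    if void.is_empty:
        return None, 0.0, None
    parts = list(void.geoms) if void.geom_type == "MultiPolygon" else [void]
    # the gap is the void overlapping the initial wound footprint; it may
    # split into several components as cells bridge across the gap
    overlapping = [p for p in parts if p.intersection(wound).area > 1e-6]
    if not overlapping:
        containing = [p for p in parts if p.contains(seed_pt)]
        if not containing:
            return None, 0.0, None
        overlapping = containing
    gap = unary_union(overlapping)
    return gap, float(gap.area), np.array([gap.centroid.x, gap.centroid.y])


def gap_area(mesh, state=None) -> float:
    """Wound gap area (μm²) in the (possibly deformed) configuration."""
    u = None
    if state is not None:
        u = state.u if hasattr(state, "u") else np.asarray(state)
    return gap_region(mesh, u)[1]


# ---------------------------------------------------------------------------
# Edge / interior stress partition
# ---------------------------------------------------------------------------


@dataclass
class StressSummary:
    """Wound-edge versus interior stress comparison at one snapshot."""

    cell_ids: np.ndarray
    cell_von_mises: np.ndarray  # volume-weighted mean per cell (Pa)
    edge_cells: np.ndarray
    interior_cells: np.ndarray
    edge_mean: float
    interior_mean: float
    mean_abs_sxx: float
    mean_abs_txy: float
    mean_abs_txz: float


def edge_vs_interior(mesh, field: StressField, edge_cells,
                     strict: bool = False) -> StressSummary:
    """Partition surviving cells into wound-edge and interior populations.

    ``edge_cells`` are the ids of cells adjacent to the gap (e.g. the owners
    of the current wound-edge faces).  Means are volume-weighted; stress
    components follow the convention x, y in-plane and z through-thickness.
    Inverted elements (if any) are excluded from the averages.
    """
    vm = cauchy_and_von_mises(field, strict=strict)
    vols = mesh.element_volumes()
    ok = np.isfinite(vm)
    cells = mesh.cell_ids
    cell_vm = np.full(len(cells), np.nan)
    for i, c in enumerate(cells):
        sel = (mesh.element_cell_id == c) & ok
        if sel.any():
            cell_vm[i] = np.average(vm[sel], weights=vols[sel])
    edge_cells = np.asarray(sorted(set(int(c) for c in edge_cells)), dtype=np.int64)
    is_edge = np.isin(cells, edge_cells)
    sig = field.cauchy
    w = np.where(ok, vols, 0.0)
    w = w / w.sum()

    def _mean(sel):
        vals = cell_vm[sel]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if len(vals) else np.nan

    return StressSummary(
        cell_ids=cells,
        cell_von_mises=cell_vm,
        edge_cells=cells[is_edge],
        interior_cells=cells[~is_edge],
        edge_mean=_mean(is_edge),
        interior_mean=_mean(~is_edge),
        mean_abs_sxx=float(np.nansum(w * np.abs(sig[:, 0, 0]))),
        mean_abs_txy=float(np.nansum(w * np.abs(sig[:, 0, 1]))),
        mean_abs_txz=float(np.nansum(w * np.abs(sig[:, 0, 2]))),
    )


# ---------------------------------------------------------------------------
# Closure-law fits
# ---------------------------------------------------------------------------


@dataclass
class ClosureFit:
    """Linear and exponential fits of a wound area trace."""

    slope: float
    intercept: float
    r2: float
    slope_half: float
    r2_half: float
    exp_rate: float
    exp_r2: float
    monotone: bool


def _ols(t, y):
    A = np.column_stack([t, np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(coef[0]), float(coef[1]), r2


def fit_closure_law(trace, rel_tol: float = 0.02) -> ClosureFit:
    """Fit A(t) with a line (full and first-half windows) and an exponential.

    ``trace`` may be a :class:`~woundsim.simulate.WoundTrace` or any object
    with ``times`` and ``areas`` arrays; only pre-closure points (area above
    1% of the initial area) enter the fits.  The exponential rate comes from
    a regression on log area.  A non-monotone trace (increases beyond
    ``rel_tol`` of the initial area) is flagged, not rejected.
    """
    t = np.asarray(trace.times, dtype=float)
    a = np.asarray(trace.areas, dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 trace points")
    pre = a > 0.01 * a[0]
    # keep a contiguous pre-closure prefix
    stop = len(a) if pre.all() else int(np.argmin(pre))
    t, a = t[:max(stop, 5)], a[:max(stop, 5)]

    slope, intercept, r2 = _ols(t, a)
    h = max(len(t) // 2, 5)
    slope_h, _, r2_h = _ols(t[:h], a[:h])
    pos = a > 0
    if pos.sum() >= 3:
        rate, _, exp_r2 = _ols(t[pos], np.log(a[pos]))
    else:
        rate, exp_r2 = np.nan, np.nan
    inc = np.diff(a)
    monotone = bool(np.all(inc <= rel_tol * a[0]))
    return ClosureFit(
        slope=slope, intercept=intercept, r2=r2,
        slope_half=slope_h, r2_half=r2_h,
        exp_rate=-rate if np.isfinite(rate) else np.nan, exp_r2=exp_r2,
        monotone=monotone,
    )
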