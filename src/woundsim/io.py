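"""File output: legacy-VTK snapshots, geometry JSON, trace CSV, run manifest.

Snapshots are written as ASCII legacy VTK unstructured grids (cell type 13,
wedge) with nodal displacement and per-element stress arrays, viewable in
ParaView.  The geometry file is a JSON document holding the cell polygons,
junction-pair topology and wound record, sufficient to rebuild the mesh.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import geometry

__all__ = ["write_vtk", "save_geometry", "load_geometry", "save_trace", "save_manifest"]


def write_vtk(path, mesh, u=None, point_data=None, cell_data=None, title="woundsim"):
    """Write the wedge mesh (optionally deformed by ``u``) as legacy VTK."""
    path = Path(path)
    pts = mesh.nodes if u is None else mesh.nodes + u
    elems = mesh.elements
    with open(path, "w") as fh:
        fh.write(f"# vtk DataFile Version 3.0\n{title}\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(pts)} double\n")
        np.savetxt(fh, pts, fmt="%.9g")
        fh.write(f"CELLS {len(elems)} {len(elems) * 7}\n")
        block = np.column_stack([np.full(len(elems), 6), elems])
        np.savetxt(fh, block, fmt="%d")
        fh.write(f"CELL_TYPES {len(elems)}\n")
        np.savetxt(fh, np.full(len(elems), 13), fmt="%d")
        if point_data:
            fh.write(f"POINT_DATA {len(pts)}\n")
            _write_arrays(fh, point_data)
        if cell_data:
            fh.write(f"CELL_DATA {len(elems)}\n")
            _write_arrays(fh, cell_data)
    return path


def _write_arrays(fh, arrays):
    for name, arr in arrays.items():
        arr = np.asarray(arr)
        if arr.ndim == 1:
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr, fmt="%.9g")
        else:
            fh.write(f"VECTORS {name} double\n")
            np.savetxt(fh, arr, fmt="%.9g")


def save_geometry(path, geom: geometry.MonolayerGeometry):
    """Serialise a monolayer geometry to JSON (reproducible, text-only)."""
    doc = {
        "spec": dataclasses.asdict(geom.spec),
        "seeds": geom.seeds.tolist(),
        "footprints": [p.tolist() for p in geom.footprints],
        "cells": [p.tolist() for p in geom.cells],
        "edge_partner": [
            [list(p) if isinstance(p, tuple) else p for p in partners]
            for partners in geom.edge_partner
        ],
        "wound_cells": geom.wound_cells,
        "wound_boundary": None
        if geom.wound_boundary is None
        else geom.wound_boundary.tolist(),
        "wound_area": geom.wound_area,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
    return Path(path)


def load_geometry(path) -> geometry.MonolayerGeometry:
    with open(path) as fh:
        doc = json.load(fh)
    return geometry.MonolayerGeometry(
        spec=geometry.MonolayerSpec(**doc["spec"]),
        seeds=np.array(doc["seeds"]),
        footprints=[np.array(p) for p in doc["footprints"]],
        cells=[np.array(p) for p in doc["cells"]],
        edge_partner=[
            [tuple(p) if isinstance(p, list) else p for p in partners]
            for partners in doc["edge_partner"]
        ],
        wound_cells=list(doc["wound_cells"]),
        wound_boundary=None
        if doc["wound_boundary"] is None
        else np.array(doc["wound_boundary"]),
        wound_area=float(doc["wound_area"]),
    )


def save_trace(path, trace):
    trace.to_dataframe().to_csv(path, index=False)
    return Path(path)


def save_manifest(path, cfg, extra=None):
    """JSON manifest with the fully resolved run configuration."""
    doc = {"config": dataclasses.asdict(cfg)}
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=str)
    return Path(path)
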