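"""TOML run configuration.

Tables mirror the parameter groups::

    [monolayer]        domain_side, mean_cell_diameter, junction_gap (μm), ...
    [material]         youngs_modulus (kPa), poisson_ratio, density (ng/μm³)
    [cohesive.cell_cell]       sigma, tau (nN/μm²), delta_0, delta_dn, ... (μm)
    [cohesive.cell_substrate]  sigma, tau (Pa), delta_0, delta_dv, ... (μm)
    [protrusion]       edge_traction, bulk_traction_max (nN/μm²), ...
    [solver]           dt_safety, damping, mass_scale, max_steps, ...
    [run]              closure_fraction, n_layers

Cohesive strengths are given in the units their sources quote (cell-cell in
nN/μm², cell-substrate in Pa) and converted to internal pN/μm² on load.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from .cohesive import CellCellCohesiveParams, CellSubstrateCohesiveParams
from .fem import ElasticMaterial
from .geometry import MonolayerSpec
from .loading import ProtrusionConfig
from .simulate import RunConfig, SolverConfig

__all__ = ["load_config"]

_CC_KEYS = {
    "sigma": ("sigma_cc", 1000.0),  # nN/μm² -> pN/μm²
    "tau": ("tau_cc", 1000.0),
    "delta_0": ("delta0", 1.0),
    "delta_dn": ("delta_dn", 1.0),
    "delta_fn": ("delta_fn", 1.0),
    "delta_dt": ("delta_dt", 1.0),
    "delta_ft": ("delta_ft", 1.0),
    "q_n": ("qn", 1.0),
    "p_n": ("pn", 1.0),
    "q_t": ("qt", 1.0),
    "p_t": ("pt", 1.0),
}

_CS_KEYS = {
    "sigma": ("sigma_cs", 1.0),  # Pa == pN/μm²
    "tau": ("tau_cs", 1.0),
    "delta_0": ("delta0", 1.0),
    "delta_dv": ("delta_dv", 1.0),
    "delta_fv": ("delta_fv", 1.0),
    "delta_du": ("delta_du", 1.0),
    "delta_fu": ("delta_fu", 1.0),
    "q_n": ("qn", 1.0),
    "p_n": ("pn", 1.0),
    "q_t": ("qt", 1.0),
    "p_t": ("pt", 1.0),
}


def _cohesive(table: dict, keymap: dict, cls):
    kwargs = {}
    for key, value in table.items():
        if key not in keymap:
            raise KeyError(f"unknown cohesive parameter '{key}'")
        field, scale = keymap[key]
        kwargs[field] = float(value) * scale
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Read a TOML file into a fully resolved :class:`RunConfig`."""
    with open(Path(path), "rb") as fh:
        doc = tomllib.load(fh)
    coh = doc.get("cohesive", {})
    run = doc.get("run", {})
    return RunConfig(
        monolayer=MonolayerSpec(**doc.get("monolayer", {})),
        material=ElasticMaterial(**doc.get("material", {})),
        cell_cell=_cohesive(coh.get("cell_cell", {}), _CC_KEYS, CellCellCohesiveParams),
        cell_substrate=_cohesive(
            coh.get("cell_substrate", {}), _CS_KEYS, CellSubstrateCohesiveParams),
        protrusion=ProtrusionConfig(**doc.get("protrusion", {})),
        solver=SolverConfig(**doc.get("solver", {})),
        closure_fraction=run.get("closure_fraction", 0.01),
        n_layers=run.get("n_layers", 1),
    )
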