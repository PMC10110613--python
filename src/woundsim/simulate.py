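"""Top-level wound-closure simulation driver and parameter sweeps.

Assembles M ü = F_ext − F_int with F_ext = F^p + F^{c-c} + F^{c-s} every
step, advances the damped explicit integrator, refreshes junction pairs and
the wound-edge face set on schedule, and records the wound-area trace until
the gap has closed (area below ``closure_fraction`` of its initial value) or
a step budget is exhausted.

The integration is dynamic relaxation: mass-proportional damping near the
critical value of the slowest structural mode keeps the migration
quasi-static, so trace times are reported in solver time units (ms of the
μm-ng-ms system) and are meaningful relative to one another (normalised
time), not as wall-clock biology.
"""

from __future__ import annotations

import copy
import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohesive, fem, geometry, loading, postprocess

__all__ = ["SolverConfig", "RunConfig", "WoundTrace", "run",
           "sweep_gap_sizes", "sweep_protrusion"]


@dataclass(frozen=True)
class SolverConfig:
    """Explicit integrator settings.

    ``damping`` is the mass-proportional coefficient c (1/ms); ``None``
    selects near-critical damping of the stiffest interface mode (junction
    cohesive stiffness against the typical nodal mass), which overdamps the
    slow structural modes and turns the integration into dynamic relaxation.
    ``mass_scale`` multiplies the density (stability control only; statics
    are unaffected).
    """

    dt_safety: float = 0.15
    damping: float | None = None
    mass_scale: float = 1.0
    max_steps: int = 200_000
    #: junction pair / protrusion refresh cadence (steps)
    refresh_every: int = 25
    #: gap measurement and trace recording cadence (steps)
    record_every: int = 100
    snapshot_every: int = 0
    #: bound on driven nodal travel per refresh interval (μm); keeps the
    #: cohesive pair bookkeeping ahead of the migration
    max_travel_per_refresh: float = 0.5

    def __post_init__(self):
        if not (0 < self.dt_safety <= 1):
            raise ValueError("dt_safety must be in (0, 1]")
        if self.mass_scale <= 0:
            raise ValueError("mass_scale must be positive")
        if self.refresh_every < 1:
            raise ValueError("refresh_every must be >= 1")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


@dataclass
class RunConfig:
    """Full configuration of a wound-closure run."""

    monolayer: geometry.MonolayerSpec = field(default_factory=geometry.MonolayerSpec)
    material: fem.ElasticMaterial = field(default_factory=fem.ElasticMaterial)
    cell_cell: cohesive.CellCellCohesiveParams = field(
        default_factory=cohesive.CellCellCohesiveParams)
    cell_substrate: cohesive.CellSubstrateCohesiveParams = field(
        default_factory=cohesive.CellSubstrateCohesiveParams)
    protrusion: loading.ProtrusionConfig = field(default_factory=loading.ProtrusionConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    #: the wound counts as closed when the measured gap falls below
    #: ``closure_fraction`` of its initial area or below
    #: ``purse_string_cell_fraction`` mean cell footprints, whichever is
    #: larger.  The absolute floor marks the crawling-to-purse-string
    #: handoff: a remnant gap smaller than a cell cannot be filled by cell
    #: migration and closes in vivo by actomyosin purse-string contraction,
    #: which this crawling-only model deliberately does not include.
    closure_fraction: float = 0.05
    purse_string_cell_fraction: float = 0.5
    n_layers: int = 1
    #: in-plane condition on the outer lateral boundary: "free" lets the
    #: surrounding tissue feed area toward the wound (recommended at reduced
    #: domain sizes, where a clamped wall a couple of cell rows from the
    #: wound over-confines the closure); "fixed" clamps it
    boundary: str = "free"

    def __post_init__(self):
        if not (0 < self.closure_fraction < 1):
            raise ValueError("closure_fraction must be in (0, 1)")
        if self.boundary not in ("free", "fixed"):
            raise ValueError("boundary must be 'free' or 'fixed'")


@dataclass
class WoundTrace:
    """Wound area and stress summaries versus time."""

    times: np.ndarray
    areas: np.ndarray
    steps: np.ndarray
    edge_mean_vm: np.ndarray
    interior_mean_vm: np.ndarray
    mean_abs_sxx: np.ndarray
    mean_abs_txy: np.ndarray
    mean_abs_txz: np.ndarray
    initial_area: float
    closure_time: float | None
    closed: bool
    diverged: bool = False
    diagnostic: str = ""

    @property
    def normalized_times(self) -> np.ndarray:
        ref = self.closure_time if self.closure_time else self.times[-1]
        return self.times / ref if ref else self.times

    def closure_time_at(self, fraction: float) -> float | None:
        """First time the area crosses ``fraction`` × initial area
        (linearly interpolated), or None if it never does."""
        thr = fraction * self.initial_area
        below = self.areas <= thr
        if not below.any():
            return None
        i = int(np.argmax(below))
        if i == 0:
            return float(self.times[0])
        a0, a1 = self.areas[i - 1], self.areas[i]
        t0, t1 = self.times[i - 1], self.times[i]
        frac = (a0 - thr) / (a0 - a1) if a0 > a1 else 1.0
        return float(t0 + frac * (t1 - t0))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.steps,
                "time": self.times,
                "area": self.areas,
                "edge_mean_vm": self.edge_mean_vm,
                "interior_mean_vm": self.interior_mean_vm,
                "mean_abs_sxx": self.mean_abs_sxx,
                "mean_abs_txy": self.mean_abs_txy,
                "mean_abs_txz": self.mean_abs_txz,
            }
        )


def _auto_damping(mesh, mat: fem.ElasticMaterial, cc, mass: np.ndarray,
                  solver: SolverConfig, drive_accel: float = 0.0) -> float:
    """Dynamic-relaxation damping coefficient (1/ms).

    Takes the largest of three scales: (i) near-critical damping of the
    stiffest cohesive interface mode (junction normal stiffness σ e^q /
    (δ_d − δ₀) on a quarter of the mean lateral face area against the mean
    nodal mass); (ii) near-critical damping of the slowest structural mode
    (π c_d / L); and (iii) the value that bounds the steady drift of the most
    strongly driven node to ``max_travel_per_refresh`` per refresh interval
    with a stable step, c = √(a_drive Δt_frac R / u_max) — this keeps the
    overdamped migration slow enough for the pair bookkeeping to follow.
    """
    k_area = cc.sigma * np.exp(cc.qn) / (cc.delta_d_normal - cc.delta0)
    quads = mesh.nodes[mesh.lateral_faces]
    a_face = np.linalg.norm(
        np.cross(quads[:, 1] - quads[:, 0], quads[:, 3] - quads[:, 0]), axis=1
    ).mean()
    omega = np.sqrt(k_area * a_face / 4.0 / mass.mean())
    c_d = mat.dilatational_wave_speed / np.sqrt(solver.mass_scale)
    ext = float(max(np.ptp(mesh.nodes[:, 0]), np.ptp(mesh.nodes[:, 1])))
    c = max(2.0 * omega, np.pi * c_d / max(ext, 1e-9))
    if drive_accel > 0:
        c_drive = np.sqrt(
            0.5 * drive_accel * solver.refresh_every / solver.max_travel_per_refresh)
        c = max(c, c_drive)
    return float(c)


def build_model(cfg: RunConfig, geom: geometry.MonolayerGeometry | None = None):
    """Generate (or reuse) the wounded geometry and extrude the mesh."""
    if geom is None:
        seeds = geometry.generate_seeds(cfg.monolayer)
        geom = geometry.build_voronoi_monolayer(cfg.monolayer, seeds)
        geom = geometry.excise_wound(geom, cfg.monolayer.wound_target_area)
    mesh = geometry.extrude_to_wedges(
        geom, n_layers=cfg.n_layers, z0=cfg.cell_substrate.delta0)
    return geom, mesh


def run(cfg: RunConfig, geom: geometry.MonolayerGeometry | None = None,
        snapshot_callback=None):
    """Run a wound-closure simulation.

    Returns ``(trace, state, mesh)``.  ``snapshot_callback(step, mesh, state,
    field)`` is invoked every ``solver.snapshot_every`` steps when set.
    A diverging run is returned with the partial trace and a diagnostic.
    """
    geom, mesh = build_model(cfg, geom)
    mat = cfg.material
    if cfg.solver.mass_scale != 1.0:
        mat = dataclasses.replace(mat, density=mat.density * cfg.solver.mass_scale)

    pc = fem.precompute(mesh)
    mass = fem.lumped_mass(mesh, mat, pc)
    state = fem.SimulationState.zeros(mesh.n_nodes, mass)

    # outer lateral boundary: optionally fixed in-plane, always free vertically
    fixed = np.zeros((mesh.n_nodes, 3), dtype=bool)
    if cfg.boundary == "fixed":
        fixed[mesh.outer_boundary_nodes(), :2] = True

    pairs = cohesive.PairSet.initial(mesh)
    prot = loading.ProtrusionState(mesh, cfg.protrusion)

    gap, area0, _ = postprocess.gap_region(mesh, None)
    prot.refresh_edges(state.u, pairs=pairs, gap=gap)
    prot.resample_bulk()
    f_p = prot.nodal_forces(state.u)

    dt = fem.stable_dt(mesh, mat, cfg.solver.dt_safety)
    damping = cfg.solver.damping
    if damping is None:
        acc = np.linalg.norm(f_p, axis=1) / mass
        loaded = acc[acc > 0]
        # robust drive scale: 90th percentile of the loaded nodes
        drive = float(np.percentile(loaded, 90)) if len(loaded) else 0.0
        damping = _auto_damping(mesh, cfg.material, cfg.cell_cell, mass,
                                cfg.solver, drive_accel=drive)
    dt = min(dt, 0.5 / damping) if damping > 0 else dt

    rec: dict[str, list] = {k: [] for k in (
        "t", "step", "area", "edge", "interior", "sxx", "txy", "txz")}

    # "wound edge" for the stress partition means geometric adjacency: a
    # cell whose footprint lies within half a cell diameter of the gap,
    # whether or not its lamellipodium is currently loaded
    edge_tol = 0.5 * cfg.monolayer.mean_cell_diameter

    def edge_cell_set(gap_geom):
        if gap_geom is None or gap_geom.is_empty:
            return np.array([], dtype=np.int64)
        import shapely

        pts = [shapely.Polygon(fp) for fp in mesh.midplane_footprint(state.u)]
        dist = np.array([gap_geom.distance(p) for p in pts])
        return mesh.cell_ids[dist < edge_tol]

    def record(area):
        _, sf = fem.internal_force(mesh, state, mat, pc, return_stress=True,
                                   check=False)
        summ = postprocess.edge_vs_interior(mesh, sf, edge_cell_set(gap))
        rec["t"].append(state.t)
        rec["step"].append(state.step)
        rec["area"].append(area)
        rec["edge"].append(summ.edge_mean)
        rec["interior"].append(summ.interior_mean)
        rec["sxx"].append(summ.mean_abs_sxx)
        rec["txy"].append(summ.mean_abs_txy)
        rec["txz"].append(summ.mean_abs_txz)
        return sf

    record(area0)
    closed = False
    diverged = False
    diagnostic = ""
    closure_time = None
    cutoff = cfg.cell_cell.delta_fn
    cell_area = np.pi * (0.5 * cfg.monolayer.mean_cell_diameter) ** 2
    closure_threshold = max(cfg.closure_fraction * area0,
                            cfg.purse_string_cell_fraction * cell_area)
    try:
        while state.step < cfg.solver.max_steps:
            if state.step > 0 and state.step % cfg.solver.record_every == 0:
                gap, area, _ = postprocess.gap_region(mesh, state.u)
                sf = record(area)
                if snapshot_callback and cfg.solver.snapshot_every and \
                        state.step % cfg.solver.snapshot_every == 0:
                    snapshot_callback(state.step, mesh, state, sf)
                if area0 > 0 and area <= closure_threshold:
                    closed = True
                    # linear interpolation to the crossing
                    a_prev, t_prev = rec["area"][-2], rec["t"][-2]
                    thr = closure_threshold
                    if a_prev > area:
                        frac = (a_prev - thr) / (a_prev - area)
                    else:
                        frac = 1.0
                    closure_time = t_prev + frac * (state.t - t_prev)
                    break
            if state.step > 0 and state.step % cfg.solver.refresh_every == 0:
                pairs = cohesive.refresh_pairs(
                    mesh, state, cutoff, pairs,
                    relax_slip=cfg.cell_cell.delta_dt)
                prot.refresh_edges(state.u, pairs=pairs, gap=gap)
                f_p = prot.nodal_forces(state.u)
            if state.step % cfg.protrusion.resample_every == 0 and state.step > 0:
                prot.resample_bulk()
                f_p = prot.nodal_forces(state.u)
            f_cc = cohesive.assemble_cell_cell_forces(mesh, pairs, state.u, cfg.cell_cell)
            f_cs = cohesive.assemble_cell_substrate_forces(mesh, state.u, cfg.cell_substrate)
            f_int = fem.internal_force(mesh, state, mat, pc, check=False)
            state.f_int, state.f_p, state.f_cc, state.f_cs = f_int, f_p, f_cc, f_cs
            fem.explicit_step(state, f_p + f_cc + f_cs, f_int, dt, damping, fixed)
    except fem.DivergenceError as exc:
        diverged = True
        diagnostic = str(exc)
        warnings.warn(f"run diverged: {exc}")

    trace = WoundTrace(
        times=np.array(rec["t"]),
        areas=np.array(rec["area"]),
        steps=np.array(rec["step"], dtype=np.int64),
        edge_mean_vm=np.array(rec["edge"]),
        interior_mean_vm=np.array(rec["interior"]),
        mean_abs_sxx=np.array(rec["sxx"]),
        mean_abs_txy=np.array(rec["txy"]),
        mean_abs_txz=np.array(rec["txz"]),
        initial_area=area0,
        closure_time=closure_time,
        closed=closed,
        diverged=diverged,
        diagnostic=diagnostic,
    )
    return trace, state, mesh


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------


def _base_geometry(cfg: RunConfig) -> geometry.MonolayerGeometry:
    seeds = geometry.generate_seeds(cfg.monolayer)
    return geometry.build_voronoi_monolayer(cfg.monolayer, seeds)


def sweep_gap_sizes(cfg: RunConfig, areas) -> tuple[pd.DataFrame, dict]:
    """Closure time versus initial gap area on one shared tessellation.

    Runs the same configuration for each target wound area and fits closure
    time against the achieved initial area by ordinary least squares.  Runs
    that do not close within the step budget are recorded as censored and
    excluded from the fit with a warning.
    """
    areas = list(areas)
    if len(areas) < 3:
        raise ValueError("need at least 3 wound areas")
    base = _base_geometry(cfg)
    rows = []
    for target in areas:
        g = geometry.excise_wound(copy.deepcopy(base), float(target))
        trace, _, _ = run(cfg, geom=g)
        rows.append(
            {
                "target_area": float(target),
                "initial_area": trace.initial_area,
                "closure_time": trace.closure_time if trace.closed else np.nan,
                "closed": trace.closed,
            }
        )
    df = pd.DataFrame(rows)
    ok = df["closed"]
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} run(s) did not close; censored and excluded from fit")
    fit = {"slope": np.nan, "intercept": np.nan, "r2": np.nan}
    if ok.sum() >= 2:
        x = df.loc[ok, "initial_area"].to_numpy()
        y = df.loc[ok, "closure_time"].to_numpy()
        slope, intercept, r2 = postprocess._ols(x, y)
        fit = {"slope": slope, "intercept": intercept, "r2": r2}
    return df, fit


def sweep_protrusion(cfg: RunConfig, tractions) -> pd.DataFrame:
    """Closure time versus wound-edge protrusion traction (nN/μm²).

    Identical geometry, wound and bulk-force seed for all runs so the
    differences are attributable to the swept traction.
    """
    tractions = list(tractions)
    if len(tractions) < 2:
        raise ValueError("need at least 2 traction values")
    base = _base_geometry(cfg)
    wounded = geometry.excise_wound(base, cfg.monolayer.wound_target_area)
    rows = []
    for trac in tractions:
        c = dataclasses.replace(
            cfg,
            protrusion=dataclasses.replace(cfg.protrusion, edge_traction=float(trac)),
        )
        trace, _, _ = run(c, geom=copy.deepcopy(wounded))
        rows.append(
            {
                "edge_traction": float(trac),
                "closure_time": trace.closure_time if trace.closed else np.nan,
                "closed": trace.closed,
                "initial_area": trace.initial_area,
            }
        )
    df = pd.DataFrame(rows)
    if not df["closed"].all():
        warnings.warn("some protrusion-sweep runs did not close (censored)")
    return df
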