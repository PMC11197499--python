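"""End-to-end run: synth → mesh → solve → wss → classify → register → stats.

One :class:`RunConfig` fully determines a run (given the code version);
every stage's artifact is written in its standard format so it can be
reloaded independently, and the summary carries a hash of the canonical
config serialization for reproducibility checks.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import hemodynamics as hd
from . import image_registration as reg
from . import meshing, synthetic_vessels as sv
from . import vessel_anatomy as va
from . import wall_shear as ws
from . import wss_statistics as wstat

logger = logging.getLogger(__name__)


class DegenerateResultError(RuntimeError):
    """The run completed but produced a degenerate (e.g. zero-flow) result."""


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, serializable to/from TOML/JSON."""

    seed: int = 0
    # geometry
    shape: str = "curved"            # straight | curved | s_curve
    length: float = 0.02             # m
    curve_radius: float = 0.012      # m
    base_radius: float = 0.002       # m
    plaque_wall: str | None = None   # ventral|dorsal|superior|inferior|None
    plaque_thickening: float = 0.5
    plaque_extent: float = 0.008     # m
    # meshing
    target_edge: float = 7.0e-4      # m, desk-scale default
    near_wall_factor: float = 0.3
    # physics
    density: float = 1.06e3          # kg/m³
    viscosity: float = 3.5e-3        # kg·m⁻¹·s⁻¹
    mean_velocity_weights: tuple = hd.MEAN_VELOCITY_WEIGHTS
    area_convention: str = "pi_r2"
    inflow_scale: float = 1.0        # multiplies the panel-derived Q_in
    # solver
    dt: float = 0.01
    t_end: float = 2.0
    tol_linear: float = 1e-4
    tol_nonlinear: float = 1e-6
    mode: str = "steady"
    # imaging
    grid_spacing_mm: tuple = sv.HRMRI_SPACING_MM
    # output
    outdir: str = "hemoshear_run"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mean_velocity_weights"] = list(self.mean_velocity_weights)
        d["grid_spacing_mm"] = list(self.grid_spacing_mm)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls(**d)
        cfg.mean_velocity_weights = tuple(cfg.mean_velocity_weights)
        cfg.grid_spacing_mm = tuple(cfg.grid_spacing_mm)
        return cfg

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))


def _solver_config(cfg: RunConfig) -> hd.SolverConfig:
    return hd.SolverConfig(dt=cfg.dt, t_end=cfg.t_end, tol_linear=cfg.tol_linear,
                           tol_nonlinear=cfg.tol_nonlinear, mode=cfg.mode)


def build_vessel(cfg: RunConfig) -> sv.VesselGeometry:
    cl = sv.make_centerline(cfg.shape, cfg.length, cfg.curve_radius, seed=cfg.seed)
    plaque = None
    if cfg.plaque_wall is not None:
        plaque = sv.PlaqueSpec(cfg.plaque_wall, cfg.length / 2, cfg.plaque_extent,
                               cfg.plaque_thickening)
    return sv.make_vessel_surface(cl, cfg.base_radius, plaque)


def derive_boundary_conditions(cfg: RunConfig) -> tuple:
    """(bc, panel, p_brachial): inflow from the first panel artery."""
    panel, p_brachial = sv.make_ultrasound_panel(4, cfg.seed)
    bc = hd.BoundaryConditionSet.from_measurement(
        panel[0], p_brachial, vessel_radius=cfg.base_radius,
        weights=cfg.mean_velocity_weights, area_convention=cfg.area_convention,
    )
    if cfg.inflow_scale != 1.0:
        q = bc.q_in * cfg.inflow_scale
        r_total, r_out = (hd.total_and_outlet_resistance(p_brachial, q, [bc.a_in])
                          if q > 0 else (0.0, [0.0]))
        bc = hd.BoundaryConditionSet(q_in=q, v_in=bc.v_in * cfg.inflow_scale,
                                     a_in=bc.a_in, r_out=r_out, r_total=r_total,
                                     p_brachial=p_brachial)
    return bc, panel, p_brachial


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage, write artifacts under ``cfg.outdir``, return summary.

    Raises :class:`hemoshear.hemodynamics.SolverError` on solver failure and
    completes (with a flagged summary) on degenerate zero-flow configs.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": cfg.to_dict(), "config_hash": cfg.config_hash(),
                     "stages": []}

    def stage(name):
        logger.info("stage: %s", name)
        summary["stages"].append(name)

    stage("synth")
    vessel = build_vessel(cfg)
    vessel.write_stl(out / "vessel.stl")
    vessel.write_ply(out / "vessel.ply")
    bc, panel, p_brachial = derive_boundary_conditions(cfg)
    sv.write_panel_csv(out / "ultrasound_panel.csv", panel, p_brachial)
    phantom = sv.make_image_phantom(vessel, cfg.grid_spacing_mm)
    phantom.write_nifti(out / "phantom.nii")

    stage("mesh")
    mesh = meshing.tetrahedralize(vessel, cfg.target_edge, cfg.near_wall_factor)
    mesh.write_vtu(out / "mesh.vtu")
    quality = meshing.mesh_quality(mesh)

    props = hd.BloodProperties(rho=cfg.density, mu=cfg.viscosity)
    scales = hd.CharacteristicScales()
    re_char, laminar = hd.reynolds(props, scales)
    re_run = props.rho * (bc.q_in / max(bc.a_in, 1e-300)) * 2 * cfg.base_radius / props.mu

    stage("solve")
    sol = hd.solve_flow(mesh, bc, props, _solver_config(cfg))
    sol.write_vtu_series(out, mesh)
    mass_residual = hd.check_mass_conservation(sol, mesh)

    stage("wss")
    field = ws.compute_wss(sol, mesh, props.mu)
    field.write_vtu(out / "wss.vtu", mesh)

    stage("classify")
    labels = va.label_walls(mesh, vessel.centerline)
    _write_labels(out / "wall_labels.vtu", mesh, labels)

    stage("register")
    transform = reg.GridTransform.from_grid(phantom)
    transform.to_json(out / "transform.json")
    wss_img, mask = reg.project_wss_to_image(field, transform, phantom.shape)
    wss_img.write_nifti(out / "wss_projected.nii")
    mask.write_nifti(out / "wss_validity_mask.nii")

    stage("stats")
    table = wstat.regional_wss_table(field, labels)
    table.to_csv(out / "regional_wss.csv", index=False)

    degenerate = bc.q_in == 0.0 or float(np.max(field.wss_magnitude)) == 0.0
    ratios: dict = {}
    if degenerate:
        ratios = {"error": "zero-flow result; WSS ratios undefined"}
    else:
        try:
            ratios["rwss_vi_ds"] = wstat.rwss_vi_ds(field, labels)
        except ValueError as e:
            ratios["rwss_vi_ds_error"] = str(e)
        try:
            ratios["rwss_inner_outer"] = wstat.rwss_inner_outer(field, labels)
        except ValueError as e:
            ratios["rwss_inner_outer_error"] = str(e)

    summary.update({
        "n_cells": quality.n_cells,
        "min_cell_volume_m3": quality.min_volume,
        "reynolds_characteristic": re_char,
        "laminar": bool(laminar),
        "reynolds_run": re_run,
        "q_in_m3_s": bc.q_in,
        "r_total_pa_s_m3": bc.r_total,
        "mass_conservation_residual": mass_residual,
        "mean_wall_wss_pa": float(np.average(field.wss_magnitude,
                                             weights=field.face_areas)),
        "ratios": ratios,
        "degenerate": bool(degenerate),
    })
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"config": cfg.to_dict(), "config_hash": cfg.config_hash(),
                   "artifacts": sorted(p.name for p in out.iterdir())},
                  fh, indent=2, sort_keys=True)
    return summary


def _write_labels(path, mesh: meshing.VolumeMesh, labels: va.WallRegionLabels) -> None:
    from . import vtkio

    faces = mesh.boundary_faces[labels.face_ids]
    vtkio.write_vtu(path, mesh.nodes, faces, vtkio.VTK_TRIANGLE,
                    cell_data={"segment_id": labels.segment.astype(np.int64),
                               "quadrant_id": labels.quadrant.astype(np.int64),
                               "curve_side_id": labels.curve_side.astype(np.int64)})
    with open(str(path) + ".legend.json", "w") as fh:
        json.dump(labels.legend(), fh)
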