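"""Run configuration schema and the seeded end-to-end pipeline.

A single YAML file describes one reproducible run: phantom, source
trajectory, detector ring, scan exposures, sinogram/reconstruction
settings, separation and analysis parameters, and the master seed.  Every
stage derives its own random stream from the master seed, so re-running a
config byte-reproduces all arrays.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError

from . import analysis as ana
from .forward_sim import (ListModeData, ScanConfig, merge_scans,
                          simulate_emission_scan, simulate_transmission_scan)
from .geometry import DetectorRing, SourceTrajectory
from .listmode import estimate_source_track, separate_events
from .phantoms import (AttenuationVolume, CylinderSpec, GridSpec,
                       MaterialTable, WATER_BOTTLE_1L, _cylinder_mask,
                       default_cavity_layout, make_cylinder_phantom,
                       make_head_phantom, make_insert_phantom,
                       make_uniform_activity)
from .recon import (MuMapResult, ReconConfig, SinogramGeometry,
                    reconstruct_mumap)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "run_pipeline", "make_fixtures",
           "PipelineResult", "bundled_config_path"]


class GridModel(BaseModel):
    size_mm: float = 200.0
    voxel_mm: float = 2.0

    def build(self) -> GridSpec:
        return GridSpec.default(self.size_mm, self.voxel_mm)


class PhantomModel(BaseModel):
    kind: Literal["cylinder", "water_bottle", "insert", "head", "none"]
    diameter_mm: Optional[float] = None
    height_mm: Optional[float] = None
    material: str = "water"
    cavity_diameters_mm: Sequence[float] = (5.0, 8.0, 9.5, 12.0, 16.0)
    cavity_ring_radius_mm: float = 36.0
    cavity_height_mm: float = 120.0
    teflon_diameter_mm: Optional[float] = 25.0
    teflon_height_mm: float = 120.0
    grid: GridModel = Field(default_factory=GridModel)

    def dims(self):
        """Object cylinder dimensions (mm) for downstream ROI masks."""
        if self.kind == "water_bottle":
            return WATER_BOTTLE_1L["diameter_mm"], WATER_BOTTLE_1L["height_mm"]
        if self.kind in ("cylinder", "insert"):
            d = self.diameter_mm if self.diameter_mm is not None else 130.0
            h = self.height_mm if self.height_mm is not None else 140.0
            return d, h
        return None

    def build(self, materials: MaterialTable | None = None):
        """Returns (AttenuationVolume | None, masks dict)."""
        grid = self.grid.build()
        materials = materials or MaterialTable()
        if self.kind == "none":
            return None, {}
        if self.kind == "head":
            vol, _ = make_head_phantom(grid, materials)
            return vol, {}
        d, h = self.dims()
        base = make_cylinder_phantom(d, h, self.material, grid, materials)
        if self.kind in ("cylinder", "water_bottle"):
            return base, {"object": base.values > 0}
        teflon = None
        if self.teflon_diameter_mm:
            teflon = CylinderSpec(diameter_mm=self.teflon_diameter_mm,
                                  height_mm=self.teflon_height_mm,
                                  center=(0.0, 0.0, 0.0), material="teflon")
        vol, masks = make_insert_phantom(
            base, teflon, list(self.cavity_diameters_mm),
            cavity_layout=default_cavity_layout(
                list(self.cavity_diameters_mm),
                self.cavity_ring_radius_mm, self.cavity_height_mm),
            materials=materials)
        masks["object"] = base.values > 0
        return vol, masks


class TrajectoryModel(BaseModel):
    helix_radius: float = 100.0
    z_start: float = -48.0
    z_end: float = 48.0
    pitch: float = 24.0
    speed: float = 300.0
    phase0: float = 0.0
    direction: int = 1
    mode: Literal["loop", "bounce"] = "loop"

    def build(self) -> SourceTrajectory:
        return SourceTrajectory(**self.model_dump())


class RingModel(BaseModel):
    preset: Optional[Literal["default", "desk"]] = "desk"
    ring_radius: Optional[float] = None
    n_rings: Optional[int] = None
    ring_spacing: Optional[float] = None
    crystals_per_ring: Optional[int] = None

    def build(self) -> DetectorRing:
        base = (DetectorRing.desk() if self.preset == "desk"
                else DetectorRing.default())
        kw = {}
        for f in ("ring_radius", "n_rings", "ring_spacing", "crystals_per_ring"):
            v = getattr(self, f)
            if v is not None:
                kw[f] = v
        if kw:
            base = DetectorRing(**{**{f: getattr(base, f) for f in
                                      ("ring_radius", "n_rings", "ring_spacing",
                                       "crystals_per_ring")}, **kw})
        return base


class ScanModel(BaseModel):
    activity_bq: float
    duration_s: float
    detection_efficiency: float = 1.0


class EmissionModel(BaseModel):
    enabled: bool = False
    activity_bq: float = 1.0e5
    duration_s: float = 60.0
    diameter_mm: float = 90.0
    height_mm: float = 120.0


class SinogramModel(BaseModel):
    n_radial: int = 101
    radial_width_mm: float = 2.0
    n_angles: int = 96
    max_ring_difference: Optional[int] = None

    def build(self) -> SinogramGeometry:
        return SinogramGeometry(n_radial=self.n_radial,
                                radial_width_mm=self.radial_width_mm,
                                n_angles=self.n_angles)


class ReconModel(BaseModel):
    n_pixels: int = 100
    pixel_size_mm: float = 2.0
    window: Literal["ramp", "hann"] = "hann"
    cutoff: float = 0.9
    zero_policy: Literal["pseudocount", "mask"] = "pseudocount"

    def build(self) -> ReconConfig:
        return ReconConfig(n_pixels=self.n_pixels,
                           pixel_size_mm=self.pixel_size_mm,
                           window=self.window, cutoff=self.cutoff)


class SeparationModel(BaseModel):
    source: Literal["track", "trajectory"] = "track"
    bin_width_s: float = 0.1
    threshold_pitch_factor: float = 2.0
    min_events_per_bin: int = 5


class AnalysisModel(BaseModel):
    roi_erosion_voxels: int = 2
    axial_trim_planes: int = 2
    contrast_threshold: float = 0.5


class RunConfig(BaseModel):
    seed: int = 0
    phantom: PhantomModel
    trajectory: TrajectoryModel = Field(default_factory=TrajectoryModel)
    ring: RingModel = Field(default_factory=RingModel)
    blank: ScanModel
    transmission: ScanModel
    emission: EmissionModel = Field(default_factory=EmissionModel)
    sinogram: SinogramModel = Field(default_factory=SinogramModel)
    recon: ReconModel = Field(default_factory=ReconModel)
    separation: SeparationModel = Field(default_factory=SeparationModel)
    analysis: AnalysisModel = Field(default_factory=AnalysisModel)
    output_dir: str = "runs/latest"


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run config; schema violations are
    reported with their field paths."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        locs = "; ".join(
            ".".join(str(p) for p in e["loc"]) + ": " + e["msg"]
            for e in err.errors())
        raise ValueError(f"invalid run config {path}: {locs}") from err


def bundled_config_path(name: str) -> Path:
    """Path of a packaged example config (e.g. ``water_bottle``)."""
    p = Path(__file__).parent / "configs" / f"{name}.yaml"
    if not p.exists():
        raise FileNotFoundError(f"no bundled config named {name!r}")
    return p


def _stage_seeds(master: int, n: int = 8):
    ss = np.random.SeedSequence(master)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


@dataclass
class PipelineResult:
    mumap: MuMapResult
    roi_reports: list
    cavity_table: Optional[object]      # pandas DataFrame for insert runs
    smallest_recovered_mm: Optional[float]
    separation_summary: Optional[object]
    provenance: dict


def _recon_grid_masks(cfg: RunConfig, grid: GridSpec):
    """Ground-truth object / cavity masks rebuilt on the reconstruction
    grid (the recon volume is aligned with the phantom by construction)."""
    dims = cfg.phantom.dims()
    masks = {}
    if dims is None:
        return masks
    d, h = dims
    masks["object"] = _cylinder_mask(grid, d, h)
    if cfg.phantom.kind == "insert":
        layout = default_cavity_layout(
            list(cfg.phantom.cavity_diameters_mm),
            cfg.phantom.cavity_ring_radius_mm, cfg.phantom.cavity_height_mm)
        for dd, spec in zip(cfg.phantom.cavity_diameters_mm, layout):
            masks[f"cavity_{dd:g}mm"] = _cylinder_mask(
                grid, spec.diameter_mm, spec.height_mm, spec.center)
        if cfg.phantom.teflon_diameter_mm:
            masks["teflon"] = _cylinder_mask(
                grid, cfg.phantom.teflon_diameter_mm,
                cfg.phantom.teflon_height_mm)
    return masks


def run_pipeline(config, output_dir=None, write_outputs: bool = True
                 ) -> PipelineResult:
    """Execute simulate -> separate -> reconstruct -> analyze for one config.

    ``config`` is a :class:`RunConfig` or a YAML path.  Writes the mu-map
    (NIfTI), ROI/cavity reports (CSV), the source track (CSV) and a
    provenance JSON into ``output_dir`` unless ``write_outputs=False``.
    """
    if not isinstance(config, RunConfig):
        config = load_config(config)
    cfg = config
    seeds = _stage_seeds(cfg.seed)
    out = Path(output_dir or cfg.output_dir)

    volume, _ = cfg.phantom.build()
    traj = cfg.trajectory.build()
    ring = cfg.ring.build()
    geom = cfg.sinogram.build()
    rcfg = cfg.recon.build()

    blank = simulate_transmission_scan(
        None, traj, ring,
        ScanConfig(activity_bq=cfg.blank.activity_bq,
                   duration_s=cfg.blank.duration_s, seed=seeds[0],
                   detection_efficiency=cfg.blank.detection_efficiency))
    trans = simulate_transmission_scan(
        volume, traj, ring,
        ScanConfig(activity_bq=cfg.transmission.activity_bq,
                   duration_s=cfg.transmission.duration_s, seed=seeds[1],
                   detection_efficiency=cfg.transmission.detection_efficiency))

    sep_summary = None
    track = None
    if cfg.emission.enabled:
        act = make_uniform_activity(cfg.emission.activity_bq,
                                    cfg.emission.diameter_mm,
                                    cfg.emission.height_mm,
                                    volume.grid if volume else None)
        emis = simulate_emission_scan(
            act, volume, ring,
            ScanConfig(activity_bq=cfg.emission.activity_bq,
                       duration_s=cfg.emission.duration_s, seed=seeds[2]))
        mixed = merge_scans(trans, emis)
    else:
        mixed = trans

    threshold = cfg.separation.threshold_pitch_factor * ring.crystal_pitch
    if cfg.separation.source == "trajectory":
        trans_sep, _, sep_summary = separate_events(mixed, traj, threshold)
    else:
        track = estimate_source_track(mixed, cfg.separation.bin_width_s,
                                      cfg.separation.min_events_per_bin)
        trans_sep, _, sep_summary = separate_events(mixed, track, threshold)

    result = reconstruct_mumap(
        blank, trans_sep, ring, geom, rcfg,
        max_ring_difference=cfg.sinogram.max_ring_difference,
        zero_policy=cfg.recon.zero_policy)

    masks = _recon_grid_masks(cfg, result.grid)
    reports = []
    cavity_df = None
    smallest = None
    if "object" in masks:
        roi = ana.eroded_cylinder_roi(masks["object"],
                                      cfg.analysis.roi_erosion_voxels,
                                      cfg.analysis.axial_trim_planes)
        reports.append(ana.roi_stats(result.values, roi, "object_eroded"))
        cavity_masks = {float(k.split("_")[1][:-2]): v
                        for k, v in masks.items() if k.startswith("cavity_")}
        if cavity_masks:
            from scipy import ndimage
            margin = np.zeros_like(roi)
            for m in cavity_masks.values():
                margin |= ndimage.binary_dilation(m, iterations=3)
            if "teflon" in masks:
                margin |= ndimage.binary_dilation(masks["teflon"], iterations=3)
            background = roi & ~margin
            cavity_df = ana.cavity_report(result.values, cavity_masks,
                                          background,
                                          cfg.analysis.contrast_threshold)
            rec = cavity_df[cavity_df["recovered"]]
            smallest = float(rec["diameter_mm"].min()) if len(rec) else None

    cfg_json = cfg.model_dump_json()
    provenance = {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "stage_seeds": seeds[:3],
        "n_events": {"blank": len(blank), "transmission": len(trans),
                     "mixed": len(mixed),
                     "separated_transmission": len(trans_sep)},
        "recon": result.provenance,
        "version": _package_version(),
    }
    result.provenance = provenance

    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
        result.to_nifti(out / "mumap.nii.gz")
        if track is not None:
            track.to_csv(out / "source_track.csv")
        if reports:
            import pandas as pd
            pd.DataFrame([vars(r) for r in reports]).to_csv(
                out / "roi_report.csv", index=False)
        if cavity_df is not None:
            cavity_df.to_csv(out / "cavity_report.csv", index=False)
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2)
        log.info("pipeline outputs written to %s", out)

    return PipelineResult(mumap=result, roi_reports=reports,
                          cavity_table=cavity_df,
                          smallest_recovered_mm=smallest,
                          separation_summary=sep_summary,
                          provenance=provenance)


def _package_version() -> str:
    try:
        from importlib.metadata import version
        return version("helix-txac")
    except Exception:  # pragma: no cover
        return "unknown"


def make_fixtures(out_dir) -> dict:
    """Write small deterministic test inputs and their manifest.

    Produces a tiny transmission scan (~1e4 decays), a matching blank, and
    a 4-channel 16x16 toy k-space set (CSV, real/imag columns).  Returns
    the manifest dict (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ring = DetectorRing(ring_radius=120.0, n_rings=4, ring_spacing=10.0,
                        crystals_per_ring=96)
    traj = SourceTrajectory(helix_radius=80.0, z_start=-15.0, z_end=15.0,
                            pitch=10.0, speed=200.0)
    grid = GridSpec.default(120.0, 4.0)
    vol = make_cylinder_phantom(60.0, 36.0, "water", grid)
    blank = simulate_transmission_scan(
        None, traj, ring, ScanConfig(activity_bq=2000.0, duration_s=5.0, seed=101))
    trans = simulate_transmission_scan(
        vol, traj, ring, ScanConfig(activity_bq=2000.0, duration_s=5.0, seed=102))
    blank.to_csv(out / "blank_events.csv")
    trans.to_csv(out / "transmission_events.csv")

    from .coil_eval import ImagingGrid, NoiseModel, make_loop_array, \
        simulate_multicoil_kspace
    g = ImagingGrid(n=16, pixel_mm=8.0)
    sens = make_loop_array(n_loops=4, array_radius_mm=80.0,
                           loop_radius_mm=40.0, grid=g)
    X, Y = g.coords()
    obj = (np.hypot(X, Y) < 50.0).astype(float)
    ks = simulate_multicoil_kspace(obj, sens, NoiseModel.white(4, 0.01), seed=103)
    import pandas as pd
    rows = []
    for c in range(ks.shape[0]):
        for iy in range(ks.shape[1]):
            for ix in range(ks.shape[2]):
                rows.append((c, iy, ix, ks[c, iy, ix].real, ks[c, iy, ix].imag))
    pd.DataFrame(rows, columns=["channel", "ky", "kx", "re", "im"]).to_csv(
        out / "toy_kspace.csv", index=False)

    manifest = {
        "files": sorted(p.name for p in out.iterdir()
                        if p.name != "manifest.json"),
        "blank_events": len(blank),
        "transmission_events": len(trans),
        "kspace_shape": list(ks.shape),
        "seeds": {"blank": 101, "transmission": 102, "kspace": 103},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
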