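"""End-to-end orchestration: volume -> mask -> geometry -> flow -> metrics.

Stages run in the order a user would perform them manually: crop the ROI,
grow the lumen from the seed, identify the openings, build the level-set
wall, construct the inflow profile on the centerline frame, run the flow
solver, and post-process wall shear stress and metrics. Any stage failure
aborts with the stage name and a machine-readable error code; every run
emits a manifest (config snapshot, per-stage timings, output hashes,
library versions) so deterministic stages can be reproduced exactly.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np

from . import geometry as geo
from . import image_io, inflow, postprocess, segmentation
from .image_io import IntensityVolume, PipelineConfig
from .solver import ImmersedBoundarySolver, SolverConfig

log = logging.getLogger("hemovox")

# CLI exit codes
EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_SEGMENTATION = 3
EXIT_SOLVER = 4


class StageError(RuntimeError):
    def __init__(self, stage: str, code: int, msg: str):
        super().__init__(f"[{stage}] {msg}")
        self.stage = stage
        self.code = code


@dataclass
class RunManifest:
    config: dict
    rng_seed: int
    timings: dict = dc_field(default_factory=dict)
    outputs: dict = dc_field(default_factory=dict)  # path -> sha256
    versions: dict = dc_field(default_factory=dict)

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _versions() -> dict:
    import platform

    import nibabel
    import scipy

    return {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "nibabel": nibabel.__version__,
    }


def run_pipeline(
    cfg: PipelineConfig,
    volume: Optional[IntensityVolume] = None,
    write_outputs: bool = True,
    precomputed_mask: Optional[np.ndarray] = None,
) -> dict:
    """Execute the full pipeline; returns a dict of in-memory results.

    ``volume`` may be passed directly (e.g. a phantom); otherwise
    ``cfg.volume_path`` is read. ``precomputed_mask`` (ROI-local, boolean)
    skips the region-growing stage so a saved segmentation can be reused.
    With ``write_outputs`` the mask, field file, metrics CSV, convergence
    log and manifest land in ``cfg.output_dir``.
    """
    t_start = {}
    manifest = RunManifest(
        config=json.loads(cfg.model_dump_json()), rng_seed=cfg.rng_seed,
        versions=_versions(),
    )

    def tic(stage):
        t_start[stage] = time.perf_counter()

    def toc(stage):
        manifest.timings[stage] = time.perf_counter() - t_start[stage]

    # -- input ---------------------------------------------------------------
    tic("input")
    if volume is None:
        if cfg.volume_path is None:
            raise StageError("input", EXIT_CONFIG, "no volume given (volume_path unset)")
        try:
            volume = image_io.read_intensity_volume(cfg.volume_path)
        except (OSError, ValueError) as e:
            raise StageError("input", EXIT_CONFIG, str(e)) from e
    try:
        image_io.validate_config_against_volume(cfg, volume)
    except ValueError as e:
        raise StageError("input", EXIT_CONFIG, str(e)) from e
    toc("input")

    # -- ROI + segmentation ----------------------------------------------------
    tic("segmentation")
    try:
        if cfg.roi is not None:
            roi = segmentation.RoiBox(*cfg.roi)
            vol = segmentation.extract_roi(volume, roi)
            seed = tuple(
                s - lo for s, (lo, _) in zip(cfg.seed_voxel, roi.ranges())
            )
        else:
            vol = volume
            seed = tuple(cfg.seed_voxel)
        if precomputed_mask is not None:
            lumen = segmentation.LumenMask(
                mask=precomputed_mask, seed=seed, threshold=cfg.threshold
            )
        else:
            lumen = segmentation.region_grow(
                vol, seed, cfg.threshold, gradient_cap=cfg.gradient_cap
            )
        patches = segmentation.identify_openings(lumen, vol.spacing, cfg.inflow_face)
    except ValueError as e:
        raise StageError("segmentation", EXIT_SEGMENTATION, str(e)) from e
    toc("segmentation")

    # -- geometry --------------------------------------------------------------
    tic("geometry")
    ls = geo.build_levelset(vol, cfg.threshold)
    if cfg.smooth_levelset:
        ls = geo.smooth_levelset(ls)
    wallgeom = geo.wall_distances(ls, lumen)
    inflow_patch = next(p for p in patches if p.role == "inflow")
    frame = geo.vessel_centerline(lumen, inflow_patch, vol.spacing, depth=cfg.centerline_depth)
    frame = geo.inplane_radius(frame, vol.spacing)
    toc("geometry")

    # -- inflow ----------------------------------------------------------------
    tic("inflow")
    if cfg.inflow.steady:
        profile = inflow.parabolic_profile(frame, cfg.inflow.U0)
    else:
        wo = inflow.womersley_number(
            frame.radial_max * 1e-3, cfg.density, cfg.inflow.f0, cfg.viscosity
        )
        profile = inflow.InflowProfile(
            frame=frame,
            U0=cfg.inflow.U0,
            f0=cfg.inflow.f0,
            wo=wo,
            harmonics=tuple(tuple(h) for h in cfg.inflow.harmonics),
        )
    face_bc = inflow.map_profile_to_faces(profile, lumen.mask, vol.spacing)
    toc("inflow")

    # -- solve -----------------------------------------------------------------
    tic("solve")
    scfg = SolverConfig(
        density=cfg.density,
        viscosity=cfg.viscosity,
        dt=cfg.dt,
        cfl=cfg.cfl,
        poisson_tol=cfg.poisson_tol,
        steady_tol=cfg.steady_tol,
        max_time=cfg.max_time,
        init="extrude" if cfg.inflow.steady else "zero",
    )
    try:
        solver = ImmersedBoundarySolver(
            lumen, ls, scfg, patches=patches, inflow_bc=face_bc
        )
        state = solver.run()
    except ValueError as e:
        raise StageError("solve", EXIT_SOLVER, str(e)) from e
    toc("solve")

    # -- postprocess -------------------------------------------------------------
    tic("postprocess")
    wf = postprocess.build_wall_field(state, lumen.mask, wallgeom, cfg.viscosity)
    if cfg.aneurysm_box is not None:
        region = postprocess.AneurysmRegion.from_box(lumen.mask, cfg.aneurysm_box)
    else:
        region = postprocess.AneurysmRegion(inside=lumen.mask.copy())
    metrics = postprocess.aneurysm_metrics(
        wf, state, region, cfg.inflow.U0, cfg.density
    )
    try:
        metrics.sr = postprocess.size_ratio(region, vol.spacing, frame=frame)
    except ValueError:
        metrics.sr = None
    toc("postprocess")

    results = {
        "volume": vol,
        "lumen": lumen,
        "patches": patches,
        "levelset": ls,
        "wallgeom": wallgeom,
        "frame": frame,
        "profile": profile,
        "solver": solver,
        "state": state,
        "wallfield": wf,
        "region": region,
        "metrics": metrics,
        "manifest": manifest,
    }

    if write_outputs:
        tic("output")
        outdir = Path(cfg.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_outputs(outdir, cfg, results, manifest)
        toc("output")
        manifest.save(outdir / "manifest.json")
    return results


def _write_outputs(outdir: Path, cfg: PipelineConfig, res: dict, manifest: RunManifest):
    vol: IntensityVolume = res["volume"]
    lumen = res["lumen"]
    state = res["state"]
    wf = res["wallfield"]
    solver = res["solver"]

    mask_path = outdir / "lumen_mask.nii.gz"
    image_io.write_intensity_volume(
        IntensityVolume(
            data=lumen.mask.astype(np.uint8), spacing=vol.spacing, origin=vol.origin
        ),
        mask_path,
    )

    wss_grid = np.zeros(lumen.mask.shape)
    wss_grid[tuple(wf.cells.T)] = wf.wss_mag
    fields_path = outdir / "fields.vti"
    image_io.write_field_output(
        fields_path,
        spacing=vol.spacing,
        origin=vol.origin,
        cell_arrays={
            "phi": res["levelset"].phi,
            "mask": lumen.mask.astype(float),
            "pressure": state.P,
            "velocity": state.cell_center_velocity(),
            "wss_magnitude": wss_grid,
        },
    )

    metrics_path = outdir / "metrics.csv"
    cfg_hash = hashlib.sha256(
        json.dumps(json.loads(cfg.model_dump_json()), sort_keys=True).encode()
    ).hexdigest()[:16]
    row = res["metrics"].as_row()
    row.update(
        config_hash=cfg_hash,
        grid_nx=lumen.mask.shape[0],
        grid_ny=lumen.mask.shape[1],
        grid_nz=lumen.mask.shape[2],
        lumen_cells=lumen.voxel_count,
        t_end=state.t,
        steps=solver.nstep,
    )
    with open(metrics_path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(row.keys()))
        w.writeheader()
        w.writerow(row)

    frame = res["frame"]
    centerline_path = outdir / "centerline.json"
    with open(centerline_path, "w") as fh:
        json.dump(
            {
                "face": frame.face,
                "centers_mm": frame.centers.tolist(),
                "tangent": frame.tangent.tolist(),
                "radial_max_mm": frame.radial_max,
                "n_patch_voxels": int(len(frame.patch_voxels)),
            },
            fh, indent=2,
        )

    log_path = outdir / "convergence.csv"
    with open(log_path, "w", newline="") as fh:
        if solver.history:
            w = csv.DictWriter(fh, fieldnames=list(solver.history[0].keys()))
            w.writeheader()
            w.writerows(solver.history)

    for p in (mask_path, fields_path, metrics_path, centerline_path, log_path):
        manifest.outputs[p.name] = _sha256(p)
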