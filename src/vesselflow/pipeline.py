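"""Config-driven pipeline runs tying the stages together reproducibly."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

import vesselflow
from vesselflow import io as vio
from vesselflow.corrmap import bin_rois, correlation_map
from vesselflow.flow import extract_kymograph, flow_trace, match_trace_to_3d, \
    remap_kymograph_3d, segment_diameter, skeletonize_stack
from vesselflow.metrics import common_threshold
from vesselflow.optics import AnnulusSpec, annulus_axial_profile
from vesselflow.preprocess import moving_average, register_rigid
from vesselflow.pupil import pupil_diameter_trace
from vesselflow.scene import SceneConfig, apply_motion, build_network, \
    render_bessel_projection, render_gaussian_stack, simulate_pupil

logger = logging.getLogger(__name__)

__all__ = ["load_config", "config_hash", "run_pipeline", "simulate_scene"]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _write_log(out_dir: Path, cfg: dict, seed: int) -> None:
    record = {
        "vesselflow_version": vesselflow.__version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "seed": seed,
        "config_hash": config_hash(cfg),
        "config": cfg,
    }
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(record, fh, indent=2, default=str)


def simulate_scene(cfg: dict, out_dir: Path, seed: int) -> dict:
    """Render a phantom (Bessel movie, structural stack, pupil video, truth CSV)."""
    scene_kwargs = dict(cfg.get("scene", {}))
    scene_kwargs["seed"] = seed
    config = SceneConfig(**scene_kwargs)
    network, truth = build_network(config)
    spec = AnnulusSpec(**cfg.get("annulus", {"na_outer": 0.4, "ratio": 0.92,
                                             "wavelength": 0.92, "refractive_index": 1.33}))
    profile = annulus_axial_profile(spec)
    bessel = render_bessel_projection(network, truth, profile, config)
    if config.motion_amplitude > 0:
        bessel, _ = apply_motion(bessel, config.motion_amplitude, seed=seed)
    stack = render_gaussian_stack(network, truth, config,
                                  z_step=cfg.get("z_step", 1.0))
    pupil_video, _ = simulate_pupil(truth, config)
    vio.write_movie(out_dir / "bessel.tif", bessel)
    vio.write_stack(out_dir / "gaussian_stack.tif", stack)
    vio.write_movie(out_dir / "pupil.tif", pupil_video)
    rows = []
    for seg in network:
        rows.append({
            "id": seg.id, "kind": seg.kind, "length_3d": seg.length,
            "speed": seg.speed, "sign": seg.sign,
            "mean_diameter": float(2 * seg.radius_t.mean()),
        })
    pd.DataFrame(rows).to_csv(out_dir / "truth.csv", index=False)
    return {"bessel": out_dir / "bessel.tif", "stack": out_dir / "gaussian_stack.tif",
            "pupil": out_dir / "pupil.tif", "truth": out_dir / "truth.csv"}


def run_pipeline(cfg: dict, out_dir, seed: int = 0) -> dict:
    """Run the stages requested in ``cfg['stages']`` in order.

    Supported stages: simulate, preprocess, correlate, pupil, flowspeed.
    Each stage failure aborts with a stage-labeled error.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = cfg.get("stages", ["simulate"])
    results: dict = {}
    artifacts: dict = {}
    for stage in stages:
        logger.info("running stage %s", stage)
        try:
            if stage == "simulate":
                artifacts.update(simulate_scene(cfg, out_dir, seed))
            elif stage == "preprocess":
                movie = vio.read_movie(artifacts.get("bessel", cfg.get("movie")),
                                       pixel_size=cfg.get("pixel_size"),
                                       frame_interval=cfg.get("frame_interval"))
                registered, shifts = register_rigid(movie)
                window = int(cfg.get("smooth_window", 5))
                registered = registered.with_data(moving_average(registered.data, window))
                vio.write_movie(out_dir / "registered.tif", registered)
                pd.DataFrame(shifts, columns=["dy", "dx"]).to_csv(
                    out_dir / "shifts.csv", index=False)
                artifacts["registered"] = out_dir / "registered.tif"
            elif stage == "correlate":
                movie = vio.read_movie(artifacts.get("registered", artifacts.get("bessel")),
                                       pixel_size=cfg.get("pixel_size"),
                                       frame_interval=cfg.get("frame_interval"))
                grid = bin_rois(movie, roi_px=int(cfg.get("roi_px", 16)))
                ref_rc = tuple(cfg.get("reference_roi", (0, 0)))
                reference = grid.traces[ref_rc[0], ref_rc[1]]
                cmap = correlation_map(grid, reference,
                                       max_lag=int(cfg.get("max_lag", 10)))
                _write_corr(out_dir / "correlation_map.csv", cmap)
                tifffile.imwrite(out_dir / "correlation_map.tif",
                                 cmap.cc.astype(np.float32))
                results["correlation_map"] = cmap
            elif stage == "pupil":
                video = vio.read_movie(artifacts.get("pupil", cfg.get("pupil_video")),
                                       pixel_size=cfg.get("pixel_size"),
                                       frame_interval=cfg.get("frame_interval"))
                trace = pupil_diameter_trace(video)
                pd.DataFrame({"t": trace.t, "width": trace.width,
                              "valid": trace.valid}).to_csv(
                    out_dir / "pupil_trace.csv", index=False)
                results["pupil_trace"] = trace
            elif stage == "flowspeed":
                results["flow"] = _flow_stage(cfg, artifacts, out_dir)
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as err:
            raise RuntimeError(f"stage '{stage}' failed: {err}") from err
    _write_log(out_dir, cfg, seed)
    return results


def _write_corr(path, cmap) -> None:
    rows, cols = cmap.cc.shape
    records = [
        {"row": r, "col": c, "cc": float(cmap.cc[r, c]), "lag": int(cmap.lag[r, c])}
        for r in range(rows) for c in range(cols)
    ]
    pd.DataFrame(records).to_csv(path, index=False)


def _cross_line(trace, shape, half_px: float = 8.0):
    """Cross-section line perpendicular to the trace at its midpoint."""
    pts = trace.points
    mid = pts[len(pts) // 2].astype(float)
    a, b = pts[0], pts[-1]
    d = b - a
    d = d / np.linalg.norm(d)
    n = np.array([-d[1], d[0]])
    h, w = shape
    p0 = np.clip(mid - half_px * n, [0, 0], [w - 1, h - 1])
    p1 = np.clip(mid + half_px * n, [0, 0], [w - 1, h - 1])
    return tuple(p0), tuple(p1)


def _flow_stage(cfg: dict, artifacts: dict, out_dir: Path) -> pd.DataFrame:
    movie = vio.read_movie(artifacts.get("bessel", cfg.get("movie")),
                           pixel_size=cfg.get("pixel_size"),
                           frame_interval=cfg.get("frame_interval"))
    stack = vio.read_stack(artifacts.get("stack", cfg.get("stack")),
                           pixel_size=cfg.get("pixel_size"),
                           z_step=cfg.get("z_step"))
    traces = vio.read_traces(cfg["traces"])
    bg = cfg.get("bg_region", (0, 8, 0, 8))
    mean_img = movie.data.mean(axis=0)
    threshold = common_threshold(stack.data.mean(axis=0), tuple(bg))
    skeleton = skeletonize_stack(stack, threshold)
    records = []
    for tr in traces:
        kymo = extract_kymograph(movie, tr)
        try:
            amap = match_trace_to_3d(tr, skeleton, stack.pixel_size, stack.z_step)
            kymo3d = remap_kymograph_3d(kymo, amap)
            length_3d = amap.total_3d_length
        except ValueError:
            kymo3d, length_3d = kymo, np.nan
        tifffile.imwrite(out_dir / f"kymograph_{tr.id}.tif",
                         kymo3d.data.astype(np.float32))
        result = flow_trace(kymo3d)
        try:
            diameter = segment_diameter(mean_img, _cross_line(tr, mean_img.shape),
                                        movie.pixel_size)
        except ValueError:
            diameter = np.nan
        records.append({
            "id": tr.id,
            "length_2d": float(tr.cum_length_px[-1] * movie.pixel_size),
            "length_3d": length_3d,
            "median_speed": result.median_speed,
            "n_blocks": result.block_speeds.size,
            "rejected": result.rejected,
            "reason": result.reason,
            "diameter": diameter,
        })
    df = pd.DataFrame(records)
    df.to_csv(out_dir / "flow_results.csv", index=False)
    return df
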