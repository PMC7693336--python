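"""TIFF and tabular I/O with explicit physical calibration.

Calibration is stored in ImageJ-style TIFF metadata (``spacing`` /
``finterval`` plus resolution tags).  Reading refuses to guess: missing
calibration raises unless an explicit override is supplied, and an
override always wins over tags (with a logged warning).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from vesselflow.core import Movie, Stack
from vesselflow.flow import Trace2D
from vesselflow.metrics import SegmentProbe

logger = logging.getLogger(__name__)

__all__ = [
    "write_movie",
    "read_movie",
    "write_stack",
    "read_stack",
    "read_traces",
    "write_traces",
    "read_probes",
]


def _check_grayscale(data: np.ndarray, path) -> np.ndarray:
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a grayscale multi-page TIFF (T/Z, Y, X); "
            f"got shape {data.shape} (RGB or multi-channel input is unsupported)"
        )
    return data


def _pixel_size_from_tags(tif: tifffile.TiffFile) -> float | None:
    page = tif.pages[0]
    tag = page.tags.get("XResolution")
    if tag is None:
        return None
    num, den = tag.value
    if num == 0:
        return None
    return den / num  # resolution stored as pixels per unit


def write_movie(path, movie: Movie) -> None:
    tifffile.imwrite(
        path,
        np.asarray(movie.data, dtype=np.float32),
        imagej=True,
        resolution=(1.0 / movie.pixel_size, 1.0 / movie.pixel_size),
        metadata={"unit": "um", "finterval": movie.frame_interval, "axes": "TYX"},
    )


def write_stack(path, stack: Stack) -> None:
    tifffile.imwrite(
        path,
        np.asarray(stack.data, dtype=np.float32),
        imagej=True,
        resolution=(1.0 / stack.pixel_size, 1.0 / stack.pixel_size),
        metadata={"unit": "um", "spacing": stack.z_step, "axes": "ZYX"},
    )


def read_movie(path, pixel_size: float | None = None,
               frame_interval: float | None = None) -> Movie:
    """Load a movie; explicit calibration overrides metadata tags."""
    with tifffile.TiffFile(path) as tif:
        data = _check_grayscale(tif.asarray(), path)
        meta = tif.imagej_metadata or {}
        tag_px = _pixel_size_from_tags(tif)
        tag_dt = meta.get("finterval")
    px = _resolve(path, "pixel_size", pixel_size, tag_px)
    dt = _resolve(path, "frame_interval", frame_interval, tag_dt)
    return Movie(data, pixel_size=px, frame_interval=dt)


def read_stack(path, pixel_size: float | None = None, z_step: float | None = None) -> Stack:
    """Load a z-stack; explicit calibration overrides metadata tags."""
    with tifffile.TiffFile(path) as tif:
        data = _check_grayscale(tif.asarray(), path)
        meta = tif.imagej_metadata or {}
        tag_px = _pixel_size_from_tags(tif)
        tag_dz = meta.get("spacing")
    px = _resolve(path, "pixel_size", pixel_size, tag_px)
    dz = _resolve(path, "z_step", z_step, tag_dz)
    return Stack(data, pixel_size=px, z_step=dz)


def _resolve(path, name: str, override: float | None, tag: float | None) -> float:
    if override is not None:
        if tag is not None and not np.isclose(override, tag):
            logger.warning("%s: %s override %g wins over metadata value %g",
                           path, name, override, tag)
        return float(override)
    if tag is None:
        raise ValueError(
            f"{path}: no {name} in metadata and no override supplied; "
            "calibration is required"
        )
    return float(tag)


def read_traces(path) -> list[Trace2D]:
    """Polyline traces from CSV columns (id, x, y), points ordered per id."""
    df = pd.read_csv(path)
    required = {"id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: trace CSV needs columns {sorted(required)}")
    traces = []
    for tid, grp in df.groupby("id", sort=True):
        traces.append(Trace2D(points=grp[["x", "y"]].to_numpy(), id=int(tid)))
    return traces


def write_traces(path, traces: list[Trace2D]) -> None:
    rows = [
        {"id": tr.id, "x": float(x), "y": float(y)}
        for tr in traces for x, y in tr.points
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_probes(path) -> list[SegmentProbe]:
    """Measurement probes from CSV: id, x0, y0, x1, y1, thickness,
    bg_r0, bg_r1, bg_c0, bg_c1."""
    df = pd.read_csv(path)
    probes = []
    for _, row in df.iterrows():
        bg = None
        if {"bg_r0", "bg_r1", "bg_c0", "bg_c1"}.issubset(df.columns):
            bg = (int(row.bg_r0), int(row.bg_r1), int(row.bg_c0), int(row.bg_c1))
        probes.append(SegmentProbe(
            p0=(float(row.x0), float(row.y0)),
            p1=(float(row.x1), float(row.y1)),
            thickness=int(row.get("thickness", 1)),
            bg_region=bg,
        ))
    return probes
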