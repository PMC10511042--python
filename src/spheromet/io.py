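"""Reading and writing movies, stacks, tables and metadata sidecars.

Movies and stacks travel as multi-page TIFF (page order frame-major, z
within frame for volumes), measurements as CSV, and calibration/parameters
as a JSON sidecar next to the images.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import Calibration, MaskMovie, TrajectorySet, VolumeMovie

__all__ = [
    "save_mask_movie", "load_mask_movie",
    "save_volume_movie", "load_volume_movie",
    "save_channels", "load_channel",
    "save_trajectories", "load_trajectories",
    "write_sidecar", "read_sidecar",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_sidecar(path: str | Path, calibration: Calibration, **extra) -> Path:
    path = Path(path)
    payload = {"calibration": calibration.to_dict(), **extra}
    out = _sidecar_path(path)
    out.write_text(json.dumps(payload, indent=2, default=_jsonable))
    return out


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return str(obj)


def read_sidecar(path: str | Path) -> dict:
    p = _sidecar_path(Path(path))
    return json.loads(p.read_text()) if p.exists() else {}


def save_mask_movie(path: str | Path, movie: MaskMovie, **extra) -> None:
    path = Path(path)
    tifffile.imwrite(path, movie.data.astype(np.uint8))
    write_sidecar(path, movie.calibration, kind="mask_movie",
                  shape=list(movie.data.shape), **extra)


def load_mask_movie(path: str | Path, interval_h: float | None = None) -> MaskMovie:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    meta = read_sidecar(path)
    cal = Calibration.from_dict(meta.get("calibration", {}))
    if interval_h is not None:
        cal = Calibration(cal.px_um, cal.z_um, interval_h * 3600.0)
    return MaskMovie(data > 0, cal)


def save_volume_movie(path: str | Path, movie: VolumeMovie, **extra) -> None:
    path = Path(path)
    # frame-major page order, z within frame
    tifffile.imwrite(path, movie.data.astype(np.float32))
    write_sidecar(path, movie.calibration, kind="volume_movie",
                  shape=list(movie.data.shape), **extra)


def load_volume_movie(path: str | Path, n_z: int | None = None) -> VolumeMovie:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 3:
        if n_z is None:
            meta = read_sidecar(path)
            shape = meta.get("shape")
            if shape and len(shape) == 4:
                n_z = shape[1]
        if n_z is None:
            raise ValueError("3D TIFF: pass n_z to unflatten (frame, z) pages")
        data = data.reshape(-1, n_z, *data.shape[1:])
    meta = read_sidecar(path)
    cal = Calibration.from_dict(meta.get("calibration", {}))
    return VolumeMovie(data, cal)


def save_channels(outdir: str | Path, channels: dict[str, np.ndarray],
                  calibration: Calibration | None = None, **extra) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, img in channels.items():
        p = outdir / f"{name}.tif"
        tifffile.imwrite(p, np.asarray(img, dtype=np.float32))
    write_sidecar(outdir / "channels.tif", calibration or Calibration(),
                  kind="channels", names=sorted(channels), **extra)


def load_channel(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))


def save_trajectories(path: str | Path, tracks: TrajectorySet) -> None:
    tracks.table.to_csv(Path(path), index=False)


def load_trajectories(path: str | Path, max_link_dist: float | None = None,
                      calibration: Calibration | None = None) -> TrajectorySet:
    return TrajectorySet(pd.read_csv(Path(path)), max_link_dist, calibration)
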