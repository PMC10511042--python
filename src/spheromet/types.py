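"""Core data containers shared across the analysis modules.

Conventions
-----------
* Array axes are ``(frame, z, y, x)`` for volumes and ``(frame, y, x)`` for
  mask movies; indices are 0-based and voxel centers sit at integer
  coordinates.
* All lengths are in pixels unless a :class:`Calibration` is applied.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Calibration",
    "MaskMovie",
    "VolumeMovie",
    "ContourPolygon",
    "CircularityTimeSeries",
    "PhaseSegmentation",
    "TrajectorySet",
]


@dataclass(frozen=True)
class Calibration:
    """Spatial/temporal calibration of a movie or stack.

    Parameters
    ----------
    px_um : float
        Lateral pixel size in micrometres per pixel.
    z_um : float
        Axial step in micrometres per z-slice.
    dt_s : float
        Time between frames in seconds.
    """

    px_um: float = 1.0
    z_um: float = 1.0
    dt_s: float = 3600.0

    @property
    def dt_h(self) -> float:
        return self.dt_s / 3600.0

    @property
    def z_aniso(self) -> float:
        """Axial-to-lateral voxel size ratio (multiply z-px by this to get
        lateral-px units)."""
        return self.z_um / self.px_um

    def to_dict(self) -> dict:
        return {"px_um": self.px_um, "z_um": self.z_um, "dt_s": self.dt_s}

    @classmethod
    def from_dict(cls, d: dict) -> "Calibration":
        return cls(**{k: d[k] for k in ("px_um", "z_um", "dt_s") if k in d})


@dataclass
class MaskMovie:
    """2D+t silhouette sequence, shape ``(frames, y, x)``; nonzero = foreground."""

    data: np.ndarray
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"MaskMovie expects (frames, y, x); got shape {self.data.shape}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def times_h(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.calibration.dt_h

    def __getitem__(self, i: int) -> np.ndarray:
        return self.data[i]


@dataclass
class VolumeMovie:
    """3D+t intensity stack, shape ``(frames, z, y, x)``."""

    data: np.ndarray
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"VolumeMovie expects (frames, z, y, x); got shape {self.data.shape}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.data[i]


class ContourPolygon:
    """Closed simple polygon with subpixel ``(y, x)`` vertices.

    Vertices are stored counter-clockwise in image coordinates (y down);
    the closing edge from last to first vertex is implicit.
    """

    def __init__(self, vertices: np.ndarray, calibration: Calibration | None = None):
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("ContourPolygon needs an (n>=3, 2) array of (y, x) vertices")
        # drop a duplicated closing vertex if present
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if v.shape[0] < 3:
            raise ValueError("degenerate polygon after removing duplicate closing vertex")
        self.vertices = v
        self.calibration = calibration or Calibration()
        if self.signed_area() < 0:  # enforce CCW in (y, x) with y down
            self.vertices = self.vertices[::-1].copy()

    def signed_area(self) -> float:
        y, x = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    @property
    def area(self) -> float:
        """Enclosed area (shoelace), px^2."""
        return abs(self.signed_area())

    @property
    def perimeter(self) -> float:
        """Polygon perimeter including the closing edge, px."""
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def scaled(self, factor: float) -> "ContourPolygon":
        return ContourPolygon(self.vertices * factor, self.calibration)

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass
class CircularityTimeSeries:
    """Per-frame circularity with times in hours.

    ``values`` may contain NaN for frames where measurement failed (empty
    mask); such frames are flagged, never interpolated.
    """

    times: np.ndarray
    values: np.ndarray
    smoothing: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")

    @property
    def n(self) -> int:
        return len(self.times)

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times, "circularity": self.values})


@dataclass
class PhaseSegmentation:
    """Latent / rising / static segmentation of a rounding time-series."""

    t_latent_end: float
    t_static_start: float
    labels: np.ndarray  # str per frame: "latent" | "rising" | "static"

    def __post_init__(self) -> None:
        if self.t_latent_end > self.t_static_start:
            raise ValueError("t_latent_end must be <= t_static_start")


class TrajectorySet:
    """Identity-linked detections over time.

    Wraps a long-format table with columns ``track_id, frame, z, y, x``
    (one row per detection). Within a track, frames strictly increase and
    no detection belongs to two tracks.
    """

    COLUMNS = ["track_id", "frame", "z", "y", "x"]

    def __init__(self, table: pd.DataFrame, max_link_dist: float | None = None,
                 calibration: Calibration | None = None):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"trajectory table missing columns: {missing}")
        self.table = table.sort_values(["track_id", "frame"]).reset_index(drop=True)
        self.max_link_dist = max_link_dist
        self.calibration = calibration or Calibration()
        self._validate()

    def _validate(self) -> None:
        g = self.table.groupby("track_id")["frame"]
        if (g.diff().dropna() <= 0).any():
            raise ValueError("frames must strictly increase within a trajectory")

    @property
    def track_ids(self) -> np.ndarray:
        return self.table["track_id"].unique()

    @property
    def n_tracks(self) -> int:
        return self.table["track_id"].nunique()

    @property
    def frames(self) -> np.ndarray:
        return np.sort(self.table["frame"].unique())

    def positions_at(self, frame: int) -> pd.DataFrame:
        """Positions of all tracks present in ``frame``, indexed by track_id."""
        sub = self.table[self.table["frame"] == frame]
        return sub.set_index("track_id")[["z", "y", "x"]]

    def shifted(self, dz: float, dy: float, dx: float) -> "TrajectorySet":
        t = self.table.copy()
        t["z"] += dz
        t["y"] += dy
        t["x"] += dx
        return TrajectorySet(t, self.max_link_dist, self.calibration)

    @classmethod
    def from_positions(cls, positions: np.ndarray, calibration: Calibration | None = None,
                       ids: Iterable[int] | None = None) -> "TrajectorySet":
        """Build from a dense ``(frames, n_cells, 3)`` ground-truth array."""
        positions = np.asarray(positions, dtype=float)
        n_frames, n_cells, _ = positions.shape
        ids = np.asarray(list(ids)) if ids is not None else np.arange(n_cells)
        rows = {
            "track_id": np.tile(ids, n_frames),
            "frame": np.repeat(np.arange(n_frames), n_cells),
            "z": positions[:, :, 0].ravel(),
            "y": positions[:, :, 1].ravel(),
            "x": positions[:, :, 2].ravel(),
        }
        return cls(pd.DataFrame(rows), calibration=calibration)

    def __len__(self) -> int:
        return len(self.table)
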