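"""Displacement-direction correlation of neighboring cells.

For a pair of neighboring cells the statistic ``r`` is the cosine of the
angle between their per-frame displacement vectors: +1 when they move in
parallel (coordinated sub-group motion), -1 when they move apart or pass
each other, and uniformly distributed on [-1, 1] for independent isotropic
3D motion. Aggregated over frames, a population with coherent sub-groups
shows a bimodal r distribution with peaks near +1 and a flat background
near 0.

Near-stationary cells have no defined direction; pairs where either
displacement magnitude falls below ``eps_motion`` are excluded and the
exclusions counted.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree, Delaunay

from .types import TrajectorySet

__all__ = [
    "displacement_vectors",
    "neighbor_pairs",
    "direction_correlation",
    "pair_correlation_table",
    "correlation_density_over_time",
    "fraction_above",
]

PAIR_COLUMNS = ["frame", "time_h", "id_a", "id_b", "r", "speed_a", "speed_b"]


def displacement_vectors(tracks: TrajectorySet, frame: int) -> pd.DataFrame:
    """Per-cell displacement from ``frame - 1`` to ``frame``.

    The axial (z) component is rescaled by the calibration's voxel
    anisotropy so vectors live in isotropic lateral-pixel units. Cells
    absent from either frame are excluded; the count of excluded cells is
    in ``attrs['n_excluded']``.
    """
    if frame < 1:
        raise ValueError("displacements need frame >= 1")
    prev = tracks.positions_at(frame - 1)
    curr = tracks.positions_at(frame)
    common = prev.index.intersection(curr.index)
    v = curr.loc[common] - prev.loc[common]
    v["z"] *= tracks.calibration.z_aniso
    v.columns = ["vz", "vy", "vx"]
    n_total = len(prev.index.union(curr.index))
    v.attrs["n_excluded"] = n_total - len(common)
    return v


@dataclass(frozen=True)
class NeighborRule:
    """How "neighboring" is decided.

    ``adaptive_radius`` pairs cells within ``alpha`` times the frame's
    median nearest-neighbor distance; ``delaunay`` uses the edges of the
    3D Delaunay triangulation; ``radius`` uses a fixed radius in px.
    """

    name: str = "adaptive_radius"
    alpha: float = 1.5
    radius: float | None = None

    def __post_init__(self) -> None:
        if self.name not in ("adaptive_radius", "delaunay", "radius"):
            raise ValueError("unknown neighbor rule")
        if self.name == "radius" and (self.radius is None or self.radius <= 0):
            raise ValueError("fixed-radius rule needs radius > 0")


def neighbor_pairs(positions: pd.DataFrame, rule: NeighborRule = NeighborRule()) -> set[tuple]:
    """Unordered neighboring id pairs for one frame's (z, y, x) positions."""
    ids = positions.index.to_numpy()
    pts = positions[["z", "y", "x"]].to_numpy(dtype=float)
    n = len(ids)
    if n < 2:
        return set()
    if rule.name == "delaunay":
        if n < 5:  # Delaunay in 3D needs >= 5 non-degenerate points
            return {(min(a, b), max(a, b)) for i, a in enumerate(ids)
                    for b in ids[i + 1:]}
        tri = Delaunay(pts)
        pairs = set()
        for simplex in tri.simplices:
            for i in range(4):
                for j in range(i + 1, 4):
                    a, b = ids[simplex[i]], ids[simplex[j]]
                    pairs.add((min(a, b), max(a, b)))
        return pairs
    tree = cKDTree(pts)
    if rule.name == "adaptive_radius":
        nn_dist, _ = tree.query(pts, k=2)
        radius = rule.alpha * float(np.median(nn_dist[:, 1]))
    else:
        radius = float(rule.radius)
    out = set()
    for i, j in tree.query_pairs(radius):
        a, b = ids[i], ids[j]
        out.add((min(a, b), max(a, b)))
    return out


def direction_correlation(v_a: np.ndarray, v_b: np.ndarray,
                          eps_motion: float = 0.3, mode: str = "cosine") -> float:
    """Correlation r of two displacement directions.

    ``cosine`` (default) is the cosine of the angle between the vectors;
    ``pearson`` is the componentwise Pearson correlation, offered for
    sensitivity analysis. Returns NaN when either magnitude is below
    ``eps_motion`` (direction undefined).
    """
    v_a = np.asarray(v_a, dtype=float)
    v_b = np.asarray(v_b, dtype=float)
    na, nb = np.linalg.norm(v_a), np.linalg.norm(v_b)
    if na < eps_motion or nb < eps_motion:
        return float("nan")
    if mode == "cosine":
        return float(np.clip(np.dot(v_a, v_b) / (na * nb), -1.0, 1.0))
    if mode == "pearson":
        a = v_a - v_a.mean()
        b = v_b - v_b.mean()
        den = np.linalg.norm(a) * np.linalg.norm(b)
        return float(np.dot(a, b) / den) if den > 0 else float("nan")
    raise ValueError("mode must be 'cosine' or 'pearson'")


def pair_correlation_table(tracks: TrajectorySet, rule: NeighborRule = NeighborRule(),
                           eps_motion: float = 0.3, mode: str = "cosine",
                           interval_h: float | None = None) -> pd.DataFrame:
    """Per-frame neighboring-pair r table for a whole trajectory set.

    Neighbors are determined from positions at the *current* frame;
    displacements compare the current frame with the previous one. Rows
    are emitted only when both magnitudes reach ``eps_motion``; the number
    of sub-threshold pairs dropped is reported in ``attrs['n_dropped']``.
    """
    dt_h = interval_h if interval_h is not None else tracks.calibration.dt_h
    rows, n_dropped = [], 0
    frames = tracks.frames
    for frame in frames[1:]:
        vel = displacement_vectors(tracks, int(frame))
        pos = tracks.positions_at(int(frame)).loc[vel.index]
        for a, b in sorted(neighbor_pairs(pos, rule)):
            va = vel.loc[a].to_numpy()
            vb = vel.loc[b].to_numpy()
            r = direction_correlation(va, vb, eps_motion, mode)
            if np.isnan(r):
                n_dropped += 1
                continue
            rows.append((int(frame), float(frame) * dt_h, a, b, r,
                         float(np.linalg.norm(va)), float(np.linalg.norm(vb))))
    out = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    out.attrs["n_dropped"] = n_dropped
    out.attrs["eps_motion"] = eps_motion
    out.attrs["rule"] = rule
    return out


def correlation_density_over_time(table: pd.DataFrame, r_bins: int = 40,
                                  t_bins: int = 20,
                                  normalization: str = "column") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2D histogram of r over time, normalized to [0, 1].

    ``column`` normalization rescales each time column by its own maximum
    (empty columns stay zero and are flagged via a warning-free zeros
    column); ``global`` divides by the overall maximum.

    Returns ``(density, t_edges, r_edges)`` with density shaped
    ``(t_bins, r_bins)``.
    """
    if table.empty:
        raise ValueError("empty pair-correlation table")
    if normalization not in ("column", "global"):
        raise ValueError("normalization must be 'column' or 'global'")
    h, t_edges, r_edges = np.histogram2d(
        table["time_h"], table["r"], bins=[t_bins, r_bins],
        range=[[table["time_h"].min(), table["time_h"].max()], [-1.0, 1.0]])
    if normalization == "global":
        m = h.max()
        return (h / m if m > 0 else h), t_edges, r_edges
    col_max = h.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(col_max > 0, h / col_max, 0.0)
    return out, t_edges, r_edges


def fraction_above(table: pd.DataFrame, r_min: float = 0.8,
                   window: tuple[float, float] | None = None) -> float:
    """Fraction of pair records with r > r_min inside a time window (hours)."""
    sel = table
    if window is not None:
        t0, t1 = window
        sel = table[(table["time_h"] >= t0) & (table["time_h"] <= t1)]
    if sel.empty:
        raise ValueError("no pair records in the requested window")
    return float((sel["r"] > r_min).mean())
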