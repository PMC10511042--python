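"""Synthetic spheroid-doublet fusion movies.

Two circular spheroid silhouettes coalesce: the programmed quantity is the
contact half-width w(t) (half the chord where the two discs meet). Given
radii r1, r2 and half-width w, the centers sit

    d(w) = sqrt(r1^2 - w^2) + sqrt(r2^2 - w^2)

apart, so the doublet long-axis length r1 + r2 + d(w) shrinks as the neck
grows, exactly as in a coalescing pair. w = 0 gives tangent discs (point
contact, length 2*(r1+r2)); w -> min(r1, r2) approaches full engulfment.
"""
from __future__ import annotations

import math
import warnings
from typing import Callable, Sequence

import numpy as np

from ..types import Calibration, MaskMovie
from .truth import GroundTruth

__all__ = ["generate_fusion_movie", "doublet_geometry"]


def doublet_geometry(r1: float, r2: float, w: float) -> tuple[float, float]:
    """(center distance, long-axis length) of a disc doublet with contact
    half-width ``w``."""
    w = min(w, min(r1, r2))
    d = math.sqrt(max(r1 * r1 - w * w, 0.0)) + math.sqrt(max(r2 * r2 - w * w, 0.0))
    return d, r1 + r2 + d


def generate_fusion_movie(radii: tuple[float, float],
                          neck_growth: Callable[[float], float] | Sequence[float],
                          frames: int, seed: int = 0, interval_h: float = 0.5,
                          angle_deg: float = 0.0,
                          ) -> tuple[MaskMovie, GroundTruth]:
    """Generate a mask movie of two fusing spheroids with known truth.

    Parameters
    ----------
    radii : (r1, r2)
        Disc radii in px, both > 0.
    neck_growth : callable or sequence
        Contact half-width vs time law: either ``w(t_h) -> px`` or a
        per-frame sequence of half-widths. Values exceeding the geometric
        maximum ``min(r1, r2)`` are clamped with a warning.
    frames : int
        Number of frames, >= 2; frame ``i`` is at ``i * interval_h`` hours.
    angle_deg : float
        Orientation of the doublet axis in the image plane.

    Returns
    -------
    (MaskMovie, GroundTruth)
        Ground truth holds the programmed contact length (full chord,
        ``2*w``) and doublet long-axis length per frame.
    """
    r1, r2 = radii
    if r1 <= 0 or r2 <= 0:
        raise ValueError("radii must be positive")
    if frames < 2:
        raise ValueError("need at least 2 frames")
    times = np.arange(frames) * interval_h
    if callable(neck_growth):
        w = np.array([float(neck_growth(t)) for t in times])
    else:
        w = np.asarray(neck_growth, dtype=float)
        if len(w) != frames:
            raise ValueError("neck-width sequence length must equal frames")
    if (w < 0).any():
        raise ValueError("neck half-widths must be >= 0")
    wmax = min(r1, r2)
    if (w > wmax).any():
        warnings.warn(f"neck half-width clamped to the geometric maximum {wmax:.1f} px")
        w = np.minimum(w, wmax)

    # canvas sized for the initial (longest) configuration at any angle;
    # odd side puts the canvas center on a pixel center
    _, len0 = doublet_geometry(r1, r2, float(w.min()))
    side = int(math.ceil(len0)) + 20
    side += 1 - side % 2
    cy = cx = (side - 1) / 2.0
    axis_on_grid = angle_deg % 180.0 == 0.0
    th = math.radians(angle_deg)
    ux, uy = math.cos(th), math.sin(th)

    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    movie = np.zeros((frames, side, side), dtype=bool)
    contact = np.empty(frames)
    length = np.empty(frames)
    for i in range(frames):
        d, ln = doublet_geometry(r1, r2, float(w[i]))
        contact[i] = 2.0 * float(w[i])
        length[i] = ln
        # centers placed so the union is centered on the canvas
        off = r1 - ln / 2.0  # signed offset of disc-1 center from canvas center
        c1 = (cy + off * uy, cx + off * ux)
        c2 = (c1[0] + d * uy, c1[1] + d * ux)
        if axis_on_grid:
            # snap the contact (radical) plane onto a pixel-center column so
            # the programmed neck width is exactly representable in the mask
            x_rp = c1[1] + math.sqrt(max(r1 * r1 - w[i] ** 2, 0.0)) * ux
            shift = round(x_rp) - x_rp
            c1 = (c1[0], c1[1] + shift)
            c2 = (c2[0], c2[1] + shift)
        m1 = (yy - c1[0]) ** 2 + (xx - c1[1]) ** 2 <= r1 * r1
        m2 = (yy - c2[0]) ** 2 + (xx - c2[1]) ** 2 <= r2 * r2
        movie[i] = m1 | m2

    cal = Calibration(dt_s=interval_h * 3600.0)
    truth = GroundTruth(
        true_contact_length=contact,
        true_doublet_length=length,
        params={"radii": (r1, r2), "frames": frames, "seed": seed,
                "interval_h": interval_h, "angle_deg": angle_deg,
                "half_widths": w.tolist()},
    )
    return MaskMovie(movie, cal), truth
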