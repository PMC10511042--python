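"""Synthetic rounding movies: an elongated cell mass that rounds up.

Each frame is a stadium silhouette whose analytic circularity follows the
programmed :class:`~spheromet.synthetic.kinetics.RoundingKinetics` curve.
Area is conserved over time (the cell mass rearranges, it does not grow),
so rounding shortens the long axis while thickening the short one. A fusion
jump appears as an instantaneous drop in elongation — the silhouette of two
just-merged parts collapsing into a single shorter mass.
"""
from __future__ import annotations

import math

import numpy as np

from ..types import Calibration, MaskMovie
from .kinetics import RoundingKinetics, aspect_to_circularity, stadium_elongation
from .truth import GroundTruth

__all__ = ["generate_rounding_movie", "render_stadium"]


def render_stadium(shape: tuple[int, int], center: tuple[float, float],
                   elongation: float, radius: float, angle_rad: float = 0.0) -> np.ndarray:
    """Render a filled stadium (capsule) as a boolean mask.

    The stadium is the set of points within ``radius`` of a central segment
    of length ``elongation * radius`` through ``center`` at ``angle_rad``.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = center
    # coordinates in the stadium frame
    ca, sa = math.cos(angle_rad), math.sin(angle_rad)
    u = (xx - cx) * ca + (yy - cy) * sa          # along axis
    v = -(xx - cx) * sa + (yy - cy) * ca         # across axis
    half = 0.5 * elongation * radius
    du = np.maximum(np.abs(u) - half, 0.0)
    dist = np.hypot(du, v)
    return dist <= radius


def generate_rounding_movie(aspect_ratio: float, kinetics: RoundingKinetics,
                            frames: int, seed: int, *,
                            final_radius: float = 40.0,
                            interval_h: float = 1.0,
                            random_orientation: bool = True) -> tuple[MaskMovie, GroundTruth]:
    """Generate a 2D+t mask movie of a rounding cell mass with known truth.

    Parameters
    ----------
    aspect_ratio : float
        Long:short axis ratio of the initial rounded rectangle, >= 1.
    kinetics : RoundingKinetics
        Programmed circularity curve. If ``kinetics.c0`` is None it is
        derived analytically from ``aspect_ratio``.
    frames : int
        Number of frames, >= 2; frame ``i`` is at time ``i * interval_h``.
    seed : int
        Seeds the (only) random choice, the in-plane orientation.
    final_radius : float
        Disc radius the mass would have at circularity 1, px. Sets scale;
        area ``pi * final_radius**2`` is conserved across frames.
    interval_h : float
        Frame interval in hours.

    Returns
    -------
    (MaskMovie, GroundTruth)
        Movie plus the programmed per-frame analytic circularity.
    """
    if aspect_ratio < 1:
        raise ValueError("aspect_ratio must be >= 1")
    if frames < 2:
        raise ValueError("need at least 2 frames")

    c0 = aspect_to_circularity(aspect_ratio)
    if kinetics.c0 is None:
        from dataclasses import replace
        kinetics = replace(kinetics, c0=c0)
    elif abs(kinetics.c0 - c0) > 1e-9:
        raise ValueError(
            f"kinetics.c0={kinetics.c0:.4f} inconsistent with aspect_ratio "
            f"(analytic c0={c0:.4f}); pass c0=None to derive it")

    rng = np.random.default_rng(seed)
    angle = float(rng.uniform(0, math.pi)) if random_orientation else 0.0

    times = np.arange(frames) * interval_h
    curve = kinetics.curve(times)

    area = math.pi * final_radius ** 2
    # canvas sized for the longest (initial) silhouette at any orientation
    u0 = stadium_elongation(float(curve.min()))
    rho0 = math.sqrt(area / (math.pi + 2 * u0))
    side = int(math.ceil(rho0 * (u0 + 2))) + 16
    center = ((side - 1) / 2.0, (side - 1) / 2.0)

    movie = np.zeros((frames, side, side), dtype=bool)
    for i, c in enumerate(curve):
        u = stadium_elongation(float(c))
        rho = math.sqrt(area / (math.pi + 2 * u))
        movie[i] = render_stadium((side, side), center, u, rho, angle)

    cal = Calibration(dt_s=interval_h * 3600.0)
    truth = GroundTruth(
        true_circularity=curve,
        params={"aspect_ratio": aspect_ratio, "frames": frames, "seed": seed,
                "final_radius": final_radius, "interval_h": interval_h,
                "angle_rad": angle, "c0": kinetics.c0, "c_inf": kinetics.c_inf,
                "t_latent": kinetics.t_latent, "t_static": kinetics.t_static,
                "jumps": list(kinetics.jumps)},
    )
    return MaskMovie(movie, cal), truth
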