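"""Spheroid contour morphometrics: circularity kinetics and phase structure.

Circularity (the CellProfiler "form factor") is ``4 * pi * A / P**2`` for a
projected silhouette of area A and perimeter P: 1 for a disc, lower for
anything elongated or rough. A rounding spheroid traces a characteristic
curve — flat (latent phase), rising, then flat again near the plateau
(static phase) — and part-fusion events show up as discrete upward jumps
during the rise.

Perimeter is measured on a subpixel iso-contour polygon, not on pixel-edge
counts: pixel-edge perimeters overestimate a disc's perimeter by up to
~27% and would bias circularity low. The binary mask is lightly Gaussian
smoothed before contouring so the marching-squares polygon tracks the true
boundary; with the default sigma a disc measures within ~0.5% of 1.
"""
from __future__ import annotations

import logging
import math
import warnings

import numpy as np
from scipy import ndimage
from skimage import measure

from .types import CircularityTimeSeries, ContourPolygon, MaskMovie, PhaseSegmentation

__all__ = [
    "extract_contour",
    "circularity",
    "circularity_timeseries",
    "segment_phases",
    "detect_jumps",
]

logger = logging.getLogger(__name__)


def extract_contour(mask: np.ndarray, smooth_sigma: float = 1.5,
                    opening_radius: int = 0) -> ContourPolygon:
    """Subpixel boundary polygon of the largest foreground component.

    Holes are filled and, when several components are present, only the
    largest is kept (logged). ``opening_radius`` > 0 applies a morphological
    opening first to shave off thin surface protrusions.

    Raises
    ------
    ValueError
        If the mask is empty.
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("empty mask: no foreground component")
    if opening_radius > 0:
        r = opening_radius
        yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
        mask = ndimage.binary_opening(mask, structure=(yy**2 + xx**2) <= r**2)
        if not mask.any():
            raise ValueError("mask vanished under protrusion-removal opening")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        logger.info("mask has %d components; keeping the largest (%d px)",
                    n, int(sizes[keep - 1]))
        mask = labels == keep
    mask = ndimage.binary_fill_holes(mask)

    # pad so components touching the border still produce a closed contour
    padded = np.pad(mask.astype(float), 1)
    if smooth_sigma > 0:
        padded = ndimage.gaussian_filter(padded, smooth_sigma)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("no iso-contour found (mask too small for smoothing?)")
    poly = max(contours, key=len) - 1.0  # undo padding offset
    return ContourPolygon(poly)


def circularity(contour: ContourPolygon) -> float:
    """Form factor 4*pi*A/P^2 of a closed polygon (1 for a circle)."""
    p = contour.perimeter
    if p <= 0:
        raise ValueError("zero-perimeter contour")
    return 4.0 * math.pi * contour.area / (p * p)


def circularity_timeseries(movie: MaskMovie, smoothing_h: float = 0.0,
                           smooth_sigma: float = 1.5,
                           opening_radius: int = 0) -> CircularityTimeSeries:
    """Per-frame circularity of the largest component of a mask movie.

    Frames with an empty mask yield NaN (flagged, never interpolated).
    ``smoothing_h`` > 0 applies a moving-median filter of that window to
    the returned values; the raw series is kept in the metadata.
    """
    times = movie.times_h()
    vals = np.empty(movie.n_frames)
    for i in range(movie.n_frames):
        try:
            vals[i] = circularity(extract_contour(movie[i], smooth_sigma, opening_radius))
        except ValueError:
            warnings.warn(f"frame {i}: empty mask, circularity flagged missing")
            vals[i] = np.nan
    meta = {"smooth_sigma": smooth_sigma, "opening_radius": opening_radius,
            "smoothing_h": smoothing_h, "raw_values": vals.copy()}
    if smoothing_h > 0:
        vals = moving_median(vals, times, smoothing_h)
    return CircularityTimeSeries(times, vals, smoothing=meta)


def moving_median(values: np.ndarray, times: np.ndarray, window_h: float) -> np.ndarray:
    """Centered moving median over a time window; NaNs are ignored."""
    out = np.empty_like(values, dtype=float)
    half = window_h / 2.0
    for i, t in enumerate(times):
        sel = values[(times >= t - half) & (times <= t + half)]
        sel = sel[np.isfinite(sel)]
        out[i] = np.median(sel) if sel.size else np.nan
    return out


def _smoothed_slope(series: CircularityTimeSeries, window_h: float) -> np.ndarray:
    v = moving_median(series.values, series.times, window_h)
    return np.gradient(v, series.times)


def segment_phases(series: CircularityTimeSeries, slope_eps: float = 0.005,
                   window_h: float = 3.0, plateau_tol: float = 0.05) -> PhaseSegmentation:
    """Split a rounding curve into latent / rising / static phases.

    The latent phase is the initial maximal run where the moving-median-
    smoothed slope stays below ``slope_eps`` (circularity/h) in magnitude;
    the static phase is the final such run whose values also sit within
    ``plateau_tol`` (fractional) of the final plateau; everything in
    between is the rising phase.
    """
    if series.n < 3:
        raise ValueError("need at least 3 frames to segment phases")
    t = series.times
    slope = _smoothed_slope(series, window_h)
    flat = np.abs(slope) < slope_eps

    i = 0
    while i < series.n and flat[i]:
        i += 1
    latent_end = i  # frames [0, latent_end) are latent

    finite = series.values[np.isfinite(series.values)]
    plateau = np.median(finite[-max(3, series.n // 10):])
    near_plateau = np.abs(series.values - plateau) <= plateau_tol * abs(plateau)
    j = series.n
    while j > latent_end and flat[j - 1] and near_plateau[j - 1]:
        j -= 1
    static_start = j  # frames [static_start, n) are static

    if latent_end >= series.n:
        warnings.warn("series is flat throughout; all-latent segmentation")
        static_start = series.n

    labels = np.array(["rising"] * series.n, dtype=object)
    labels[:latent_end] = "latent"
    labels[static_start:] = "static"
    t_latent_end = t[latent_end - 1] if latent_end > 0 else t[0]
    t_static_start = t[static_start] if static_start < series.n else t[-1]
    return PhaseSegmentation(float(t_latent_end), float(t_static_start), labels)


def detect_jumps(series: CircularityTimeSeries, min_step: float = 0.05,
                 mad_k: float = 5.0) -> list[tuple[float, float]]:
    """Discrete upward circularity jumps (part-fusion events).

    A frame-to-frame forward difference counts as a jump when it exceeds
    both ``min_step`` and ``mad_k`` times the median absolute deviation of
    the local differences (window of 15 frames). Returns ``(time_h, delta)``
    sorted by time.
    """
    v, t = series.values, series.times
    d = np.diff(v)
    jumps: list[tuple[float, float]] = []
    half = 7
    for i, di in enumerate(d):
        if not np.isfinite(di) or di < min_step:
            continue
        lo, hi = max(0, i - half), min(len(d), i + half + 1)
        local = np.delete(d[lo:hi], i - lo)
        local = local[np.isfinite(local)]
        mad = np.median(np.abs(local - np.median(local))) if local.size else 0.0
        if di > mad_k * mad:
            jumps.append((float(t[i + 1]), float(di)))
    return jumps
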