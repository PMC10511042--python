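"""3D nucleus detection and trajectory linking.

Detection follows the classic band-pass recipe: an anisotropic Difference
of Gaussians (small-sigma blur minus large-sigma blur, defaults 1.9/3.8 px
laterally and 0.7/1.4 px axially) emphasizes nucleus-sized blobs, local
maxima above a threshold become detections, and a per-axis quadratic fit
refines each maximum to subvoxel precision. Detections in consecutive
frames are then joined into trajectories by gated nearest-neighbor
assignment.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.filters import threshold_otsu

from .types import Calibration, TrajectorySet, VolumeMovie

__all__ = [
    "DoGParams",
    "dog_filter",
    "detect_nuclei",
    "detect_movie",
    "link_nearest_neighbor",
    "track_movie",
]

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = ["frame", "z", "y", "x", "score"]


@dataclass(frozen=True)
class DoGParams:
    """Sigmas of the two Gaussian kernels, per axis (z, y, x), in px."""

    sigma_small: tuple[float, float, float] = (0.7, 1.9, 1.9)
    sigma_large: tuple[float, float, float] = (1.4, 3.8, 3.8)

    def __post_init__(self) -> None:
        for s, l in zip(self.sigma_small, self.sigma_large):
            if not 0 < s < l:
                raise ValueError("need 0 < sigma_small < sigma_large componentwise")

    @property
    def blob_scale(self) -> tuple[float, float, float]:
        """Per-axis blob sigma the band-pass is matched to (geometric mean)."""
        return tuple(math.sqrt(s * l) for s, l in
                     zip(self.sigma_small, self.sigma_large))


def dog_filter(volume: np.ndarray, params: DoGParams = DoGParams()) -> np.ndarray:
    """Band-pass filter a single 3D frame: G(sigma_small) - G(sigma_large).

    Border handling is 'reflect'. The volume must span at least
    ``4 * sigma_large`` voxels along each axis so the band-pass response is
    meaningful anywhere in the output.
    """
    volume = np.asarray(volume, dtype=np.float32)
    if volume.ndim != 3:
        raise ValueError("dog_filter expects a 3D (z, y, x) volume")
    for ax, sl in enumerate(params.sigma_large):
        if volume.shape[ax] < 4 * sl:
            raise ValueError(
                f"axis {ax} has {volume.shape[ax]} voxels < 4*sigma_large={4 * sl:.1f}")
    lo = ndimage.gaussian_filter(volume, params.sigma_small, mode="reflect")
    hi = ndimage.gaussian_filter(volume, params.sigma_large, mode="reflect")
    return lo - hi


def _quadratic_offset(f_m: float, f_0: float, f_p: float) -> float:
    """Subvoxel peak offset from a 3-point parabola; 0 if degenerate."""
    denom = f_m - 2.0 * f_0 + f_p
    if denom >= -1e-12:  # not a proper maximum
        return 0.0
    off = 0.5 * (f_m - f_p) / denom
    return float(np.clip(off, -0.5, 0.5))


def _refine_centroid(filtered: np.ndarray, c0: np.ndarray,
                     widths: tuple[float, float, float],
                     n_iter: int = 5) -> np.ndarray:
    """Gaussian-weighted centroid of the positive band-pass response.

    Iterating recenters the (separable Gaussian) weight window on the
    current estimate, so the fixed point is the blob center; unlike a
    3-point parabola this uses the whole peak and is unbiased for
    symmetric blobs away from the volume border.
    """
    c = np.asarray(c0, dtype=float)
    ext = [max(2, int(math.ceil(3 * w))) for w in widths]
    for _ in range(n_iter):
        sl, grids = [], []
        for ax in range(3):
            a0 = max(0, int(round(c[ax])) - ext[ax])
            a1 = min(filtered.shape[ax], int(round(c[ax])) + ext[ax] + 1)
            sl.append(slice(a0, a1))
            grids.append(np.arange(a0, a1, dtype=float))
        zz, yy, xx = np.meshgrid(*grids, indexing="ij")
        w = np.exp(-((zz - c[0]) ** 2 / (2 * widths[0] ** 2)
                     + (yy - c[1]) ** 2 / (2 * widths[1] ** 2)
                     + (xx - c[2]) ** 2 / (2 * widths[2] ** 2)))
        num = np.clip(filtered[tuple(sl)], 0, None) * w
        tot = num.sum()
        if tot <= 0:
            break
        c = np.array([(zz * num).sum(), (yy * num).sum(), (xx * num).sum()]) / tot
    return c


def detect_nuclei(filtered: np.ndarray, threshold: float | None = None,
                  min_separation: tuple[float, float, float] = (2.0, 4.0, 4.0),
                  frame: int = 0,
                  refine_widths: tuple[float, float, float] | None = (1.0, 2.7, 2.7),
                  ) -> pd.DataFrame:
    """Local maxima of a DoG-filtered volume as subvoxel point detections.

    Parameters
    ----------
    filtered : 3D array
        Output of :func:`dog_filter`.
    threshold : float, optional
        Minimum DoG response. Default: Otsu's threshold computed on the
        positive responses (logged into the result's ``attrs``).
    min_separation : (z, y, x) px
        Anisotropic exclusion radius: of two maxima closer than this
        (ellipsoidal norm), only the stronger is kept.
    refine_widths : (z, y, x) px or None
        Gaussian window widths for iterative weighted-centroid subvoxel
        refinement (default: the blob scale of the default DoG). ``None``
        falls back to per-axis 3-point quadratic refinement.

    Returns
    -------
    DataFrame with columns (frame, z, y, x, score), strongest first.
    """
    filtered = np.asarray(filtered)
    if threshold is None:
        pos = filtered[filtered > 0]
        threshold = float(threshold_otsu(pos)) if pos.size >= 2 else np.inf
    sep = np.asarray(min_separation, dtype=float)
    if (sep <= 0).any():
        raise ValueError("min_separation must be positive")

    size = np.maximum(3, (2 * np.ceil(sep) + 1).astype(int))
    is_max = (filtered == ndimage.maximum_filter(filtered, size=size, mode="reflect"))
    cand = np.argwhere(is_max & (filtered > threshold))
    empty = pd.DataFrame(columns=DETECTION_COLUMNS).astype(
        {"frame": int, "z": float, "y": float, "x": float, "score": float})
    empty.attrs["threshold"] = threshold
    if cand.size == 0:
        return empty

    scores = filtered[tuple(cand.T)]
    order = np.argsort(scores)[::-1]
    cand, scores = cand[order], scores[order]

    # greedy suppression in the anisotropy-scaled metric
    scaled = cand / sep
    kept_idx: list[int] = []
    for i in range(len(cand)):
        if kept_idx:
            d = np.linalg.norm(scaled[kept_idx] - scaled[i], axis=1)
            if (d < 1.0).any():
                logger.debug("suppressed maximum at %s (within min_separation)", cand[i])
                continue
        kept_idx.append(i)

    rows = []
    shp = filtered.shape
    for i in kept_idx:
        c = cand[i].astype(float)
        if refine_widths is not None:
            c = _refine_centroid(filtered, c, refine_widths)
        else:
            for ax in range(3):
                j = cand[i][ax]
                if 0 < j < shp[ax] - 1:
                    idx_m = list(cand[i]); idx_m[ax] = j - 1
                    idx_p = list(cand[i]); idx_p[ax] = j + 1
                    c[ax] += _quadratic_offset(filtered[tuple(idx_m)], scores[i],
                                               filtered[tuple(idx_p)])
        rows.append((frame, c[0], c[1], c[2], float(scores[i])))
    out = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    out.attrs["threshold"] = threshold
    return out


def detect_movie(movie: VolumeMovie, params: DoGParams = DoGParams(),
                 threshold: float | None = None,
                 min_separation: tuple[float, float, float] = (2.0, 4.0, 4.0),
                 ) -> pd.DataFrame:
    """Run DoG detection on every frame; concatenated detection table."""
    frames = []
    for f in range(movie.n_frames):
        filt = dog_filter(movie[f], params)
        frames.append(detect_nuclei(filt, threshold, min_separation, frame=f,
                                    refine_widths=params.blob_scale))
    return pd.concat(frames, ignore_index=True)


def _match_frame_pair(prev: np.ndarray, curr: np.ndarray, max_link_dist: float,
                      method: str) -> list[tuple[int, int]]:
    """One-to-one matches (prev_idx, curr_idx) within the gating distance."""
    if len(prev) == 0 or len(curr) == 0:
        return []
    d = np.linalg.norm(prev[:, None, :] - curr[None, :, :], axis=2)
    if method == "greedy":
        # all candidate pairs sorted by ascending distance; stable tie-break
        # on (distance, prev index, curr index)
        pi, ci = np.nonzero(d <= max_link_dist)
        order = np.lexsort((ci, pi, d[pi, ci]))
        used_p, used_c, matches = set(), set(), []
        for k in order:
            p, c = int(pi[k]), int(ci[k])
            if p in used_p or c in used_c:
                continue
            used_p.add(p); used_c.add(c)
            matches.append((p, c))
        return matches
    if method == "optimal":
        big = max_link_dist * 1e6
        cost = np.where(d <= max_link_dist, d, big)
        ri, ci = linear_sum_assignment(cost)
        return [(int(p), int(c)) for p, c in zip(ri, ci) if d[p, c] <= max_link_dist]
    raise ValueError("method must be 'greedy' or 'optimal'")


def link_nearest_neighbor(detections: pd.DataFrame, max_link_dist: float,
                          method: str = "greedy",
                          calibration: Calibration | None = None) -> TrajectorySet:
    """Join per-frame detections into trajectories.

    Between each pair of consecutive frames, candidate links are considered
    in ascending distance and matched greedily one-to-one; links longer
    than ``max_link_dist`` are forbidden. Unmatched detections terminate or
    start trajectories. ``method='optimal'`` swaps the greedy pass for a
    minimum-total-distance assignment with the same gate.
    """
    if max_link_dist <= 0:
        raise ValueError("max_link_dist must be > 0")
    det = detections.sort_values(["frame"]).reset_index(drop=True)
    if det.empty:
        raise ValueError("no detections to link")
    frames = np.sort(det["frame"].unique())
    if len(frames) < 2:
        raise ValueError("need detections for at least 2 frames")

    by_frame = {f: det[det["frame"] == f].reset_index(drop=True) for f in frames}
    next_track = 0
    rows: list[tuple] = []
    # active: detection row index (within frame table) -> track id
    first = by_frame[frames[0]]
    active = {i: i for i in range(len(first))}
    next_track = len(first)
    for i in range(len(first)):
        rows.append((active[i], frames[0], first.at[i, "z"], first.at[i, "y"], first.at[i, "x"]))

    for fprev, fcurr in zip(frames[:-1], frames[1:]):
        prev_tab, curr_tab = by_frame[fprev], by_frame[fcurr]
        prev_xyz = prev_tab[["z", "y", "x"]].to_numpy()
        curr_xyz = curr_tab[["z", "y", "x"]].to_numpy()
        matches = _match_frame_pair(prev_xyz, curr_xyz, max_link_dist, method)
        new_active: dict[int, int] = {}
        for p, c in matches:
            if p in active:
                new_active[c] = active[p]
        for c in range(len(curr_tab)):
            if c not in new_active:
                new_active[c] = next_track
                next_track += 1
        for c, tid in new_active.items():
            rows.append((tid, fcurr, curr_tab.at[c, "z"], curr_tab.at[c, "y"],
                         curr_tab.at[c, "x"]))
        active = new_active

    table = pd.DataFrame(rows, columns=TrajectorySet.COLUMNS)
    return TrajectorySet(table, max_link_dist=max_link_dist, calibration=calibration)


def track_movie(movie: VolumeMovie, params: DoGParams = DoGParams(),
                threshold: float | None = None,
                min_separation: tuple[float, float, float] = (2.0, 4.0, 4.0),
                max_link_dist: float = 5.0, method: str = "greedy") -> TrajectorySet:
    """Detect nuclei in every frame and link them: the full tracking pipeline."""
    det = detect_movie(movie, params, threshold, min_separation)
    return link_nearest_neighbor(det, max_link_dist, method, calibration=movie.calibration)
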