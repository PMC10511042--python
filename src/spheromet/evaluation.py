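"""Scoring detection, tracking and correlation output against ground truth.

These helpers compare pipeline output with a generator's programmed truth:
detection precision/recall by tolerance-gated one-to-one matching, link
identity accuracy (do consecutive-frame links stay on the same true cell?)
and the mean absolute error of the neighbor-pair correlation r.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .correlation import direction_correlation
from .types import TrajectorySet

__all__ = [
    "match_points",
    "detection_precision_recall",
    "link_identity_accuracy",
    "pair_r_mae",
]


def match_points(detected: np.ndarray, truth: np.ndarray,
                 tol: tuple[float, float, float] = (1.5, 1.0, 1.0)) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of detected to true (z, y, x) points.

    Distances are scaled per axis by ``tol`` (so a match requires the
    scaled distance <= 1); pairs are taken in ascending distance.
    """
    if len(detected) == 0 or len(truth) == 0:
        return []
    scale = np.asarray(tol, dtype=float)
    d = np.linalg.norm((detected[:, None, :] - truth[None, :, :]) / scale, axis=2)
    di, ti = np.nonzero(d <= 1.0)
    order = np.argsort(d[di, ti])
    used_d, used_t, out = set(), set(), []
    for k in order:
        a, b = int(di[k]), int(ti[k])
        if a in used_d or b in used_t:
            continue
        used_d.add(a); used_t.add(b)
        out.append((a, b))
    return out


def detection_precision_recall(detections: pd.DataFrame, truth_positions: np.ndarray,
                               tol: tuple[float, float, float] = (1.5, 1.0, 1.0),
                               ) -> tuple[float, float]:
    """Precision and recall of a detection table vs (frames, n, 3) truth."""
    tp = fp = fn = 0
    for f in range(truth_positions.shape[0]):
        det = detections[detections["frame"] == f][["z", "y", "x"]].to_numpy()
        matches = match_points(det, truth_positions[f], tol)
        tp += len(matches)
        fp += len(det) - len(matches)
        fn += truth_positions.shape[1] - len(matches)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall


def _frame_mapping(tracks: TrajectorySet, truth_positions: np.ndarray, frame: int,
                   tol: tuple[float, float, float]) -> dict[int, int]:
    pos = tracks.positions_at(frame)
    det = pos.to_numpy()
    matches = match_points(det, truth_positions[frame], tol)
    ids = pos.index.to_numpy()
    return {int(ids[a]): int(b) for a, b in matches}


def link_identity_accuracy(tracks: TrajectorySet, truth_positions: np.ndarray,
                           tol: tuple[float, float, float] = (1.5, 1.0, 1.0)) -> float:
    """Fraction of consecutive-frame links that stay on the same true cell.

    Each track endpoint is assigned to its nearest true cell (within the
    tolerance); a link is correct when both endpoints map to the same true
    identity. Links whose endpoints cannot be assigned count as wrong.
    """
    n_frames = truth_positions.shape[0]
    maps = [_frame_mapping(tracks, truth_positions, f, tol) for f in range(n_frames)]
    correct = total = 0
    for tid in tracks.track_ids:
        sub = tracks.table[tracks.table["track_id"] == tid]
        frames = sub["frame"].to_numpy()
        for f0, f1 in zip(frames[:-1], frames[1:]):
            if f1 != f0 + 1 or f1 >= n_frames:
                continue
            total += 1
            a = maps[f0].get(int(tid))
            b = maps[f1].get(int(tid))
            if a is not None and a == b:
                correct += 1
    return correct / total if total else 0.0


def pair_r_mae(pair_table: pd.DataFrame, tracks: TrajectorySet,
               truth_positions: np.ndarray,
               tol: tuple[float, float, float] = (1.5, 1.0, 1.0)) -> float:
    """Mean absolute error of measured pair r against ground-truth pair r.

    Measured tracks are mapped to true identities per frame by nearest
    position; a row contributes when both pair members map consistently at
    the frame and its predecessor.
    """
    n_frames = truth_positions.shape[0]
    maps = [_frame_mapping(tracks, truth_positions, f, tol) for f in range(n_frames)]
    errs = []
    for row in pair_table.itertuples():
        f = int(row.frame)
        if f < 1 or f >= n_frames:
            continue
        ta = maps[f].get(int(row.id_a))
        tb = maps[f].get(int(row.id_b))
        if ta is None or tb is None:
            continue
        if maps[f - 1].get(int(row.id_a)) != ta or maps[f - 1].get(int(row.id_b)) != tb:
            continue
        va = truth_positions[f, ta] - truth_positions[f - 1, ta]
        vb = truth_positions[f, tb] - truth_positions[f - 1, tb]
        r_true = direction_correlation(va, vb, eps_motion=1e-9)
        if np.isnan(r_true):
            continue
        errs.append(abs(row.r - r_true))
    if not errs:
        raise ValueError("no pair rows could be mapped to ground truth")
    return float(np.mean(errs))
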