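"""Cell-centre tracking and the convex-hull clustering statistic.

Islet cell coalescence is quantitated as the volume of the convex 3D
polytope enclosing tracked cell centres, evaluated per frame: the
volume decreases over time as cells come into closer proximity.  For
degenerate configurations (fewer than four cells, or coplanar/collinear
centres) the 3D volume is zero; those frames are flagged and the 2D
hull area and maximum pairwise distance are exported as fallback
columns so low-n series remain informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "CellTrackSet",
    "ClusterSeries",
    "hull_volume",
    "link_detections",
    "clustering_series",
    "tracks_from_array",
]


@dataclass
class CellTrackSet:
    """Per-cell time-indexed 3D centres in µm.

    ``tracks`` maps ``cell_id -> {frame_index: (z, y, x)}``;
    ``frame_times`` gives the acquisition time of each frame in minutes
    (strictly increasing, not assumed uniform).  Gaps within a track are
    allowed and reported by :meth:`gap_cells`.
    """

    tracks: dict[int, dict[int, np.ndarray]]
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        for cid, obs in self.tracks.items():
            if len(obs) < 1:
                raise ValueError(f"track {cid} has no observations")

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    def cells_in_frame(self, frame: int) -> list[int]:
        return [cid for cid, obs in self.tracks.items() if frame in obs]

    def positions(self, frame: int, subset=None) -> tuple[np.ndarray, list[int]]:
        ids = self.cells_in_frame(frame)
        if subset is not None:
            wanted = set(subset)
            ids = [c for c in ids if c in wanted]
        pts = np.array([self.tracks[c][frame] for c in ids]).reshape(len(ids), 3)
        return pts, ids

    def gap_cells(self) -> dict[int, list[int]]:
        """Cells with missing frames between their first and last observation."""
        out = {}
        for cid, obs in self.tracks.items():
            frames = sorted(obs)
            missing = [f for f in range(frames[0], frames[-1] + 1) if f not in obs]
            if missing:
                out[cid] = missing
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid, obs in sorted(self.tracks.items()):
            for f in sorted(obs):
                z, y, x = obs[f]
                rows.append(
                    {"frame": f, "time_min": self.frame_times[f], "cell_id": cid,
                     "x": x, "y": y, "z": z}
                )
        return pd.DataFrame(rows)


@dataclass
class ClusterSeries:
    """Per-frame hull statistics of a tracked cell set."""

    time: np.ndarray  # min
    hull_volume: np.ndarray  # µm³
    n_points: np.ndarray
    degenerate_flag: np.ndarray
    hull_area_2d: np.ndarray  # µm², best-fit-plane hull area fallback
    max_pairwise_distance: np.ndarray  # µm
    incomplete_flag: np.ndarray = field(default=None)  # subset not fully present

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.time,
                "hull_volume_um3": self.hull_volume,
                "n_points": self.n_points,
                "degenerate": self.degenerate_flag,
                "hull_area_um2": self.hull_area_2d,
                "max_pairwise_distance_um": self.max_pairwise_distance,
                "incomplete_subset": self.incomplete_flag,
            }
        )


def _rank(points: np.ndarray, tol: float = 1e-9) -> int:
    centered = points - points.mean(axis=0)
    if len(points) < 2:
        return 0
    s = np.linalg.svd(centered, compute_uv=False)
    scale = max(s[0], 1.0)
    return int(np.sum(s > tol * scale))


def hull_volume(points: np.ndarray) -> tuple[float, bool]:
    """Convex-hull volume (µm³) of 3D points, with a degeneracy flag.

    Returns ``(volume, degenerate)``.  Fewer than four points, or
    affinely dependent (collinear/coplanar) points, have zero volume
    and ``degenerate=True``.  Non-finite coordinates are an error.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        pts = pts.reshape(-1, 3)
    if pts.shape[0] < 1:
        raise ValueError("need at least one point")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates")
    if pts.shape[0] < 4 or _rank(pts) < 3:
        return 0.0, True
    try:
        return float(ConvexHull(pts).volume), False
    except QhullError:
        return 0.0, True


def _hull_area_2d(points: np.ndarray) -> float:
    """Area of the 2D hull of the points projected onto their best-fit plane."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        return 0.0
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[:2].T
    if _rank_2d(proj) < 2:
        return 0.0
    try:
        return float(ConvexHull(proj).volume)  # 2D "volume" is area
    except QhullError:
        return 0.0


def _rank_2d(points: np.ndarray, tol: float = 1e-9) -> int:
    s = np.linalg.svd(points - points.mean(axis=0), compute_uv=False)
    return int(np.sum(s > tol * max(s[0], 1.0)))


def link_detections(
    detections_per_frame: list[np.ndarray],
    max_displacement: float = 10.0,
    frame_times: np.ndarray | None = None,
) -> CellTrackSet:
    """Link per-frame detections into tracks by global min-cost matching.

    For each consecutive frame pair the Euclidean distance cost matrix
    is solved with the Hungarian algorithm; assignments longer than
    ``max_displacement`` (µm) are forbidden, and unmatched detections
    start new tracks.  Tracking details of the original time-lapse
    analysis are unpublished, so this is a deliberately plain,
    reproducible scheme.
    """
    if len(detections_per_frame) < 1:
        raise ValueError("need at least one frame of detections")
    if frame_times is None:
        frame_times = np.arange(len(detections_per_frame), dtype=float)
    dets = [np.asarray(d, dtype=float).reshape(-1, 3) for d in detections_per_frame]

    tracks: dict[int, dict[int, np.ndarray]] = {}
    next_id = 0
    # active[j] = track id of detection j in the current frame
    active = []
    for j, p in enumerate(dets[0]):
        tracks[next_id] = {0: p}
        active.append(next_id)
        next_id += 1
    for f in range(1, len(dets)):
        prev, curr = dets[f - 1], dets[f]
        assigned = [-1] * len(curr)
        if len(prev) and len(curr):
            cost = cdist(prev, curr)
            big = max_displacement * 1e6 + 1.0
            cost = np.where(cost <= max_displacement, cost, big)
            ri, ci = linear_sum_assignment(cost)
            for r, c in zip(ri, ci):
                if cost[r, c] <= max_displacement:
                    assigned[c] = active[r]
        new_active = []
        for j, p in enumerate(curr):
            tid = assigned[j]
            if tid < 0:
                tid = next_id
                tracks[tid] = {}
                next_id += 1
            tracks[tid][f] = p
            new_active.append(tid)
        active = new_active
    return CellTrackSet(tracks=tracks, frame_times=np.asarray(frame_times, dtype=float))


def tracks_from_array(centers_per_frame: np.ndarray, frame_times=None) -> CellTrackSet:
    """Build a fully observed CellTrackSet from a ``(T, n, 3)`` array."""
    arr = np.asarray(centers_per_frame, dtype=float)
    T, n, _ = arr.shape
    if frame_times is None:
        frame_times = np.arange(T, dtype=float)
    tracks = {cid: {f: arr[f, cid] for f in range(T)} for cid in range(n)}
    return CellTrackSet(tracks=tracks, frame_times=frame_times)


def clustering_series(tracks: CellTrackSet, subset=None) -> ClusterSeries:
    """Hull-volume-versus-time series over the cells present in each frame.

    ``subset`` restricts the statistic to the given cell ids (e.g. the
    coloured tracked cells of one panel); frames where the subset is
    only partially observed are computed on the observed cells and
    flagged.  Raises if fewer than two frames contain any of the cells.
    """
    if subset is not None:
        subset = set(subset)
    vols, npts, degen, areas, maxd, times, incomplete = [], [], [], [], [], [], []
    n_expected = len(subset) if subset is not None else len(tracks.tracks)
    frames_with_cells = 0
    for f in range(tracks.n_frames):
        pts, ids = tracks.positions(f, subset)
        if len(ids) == 0:
            continue
        frames_with_cells += 1
        v, d = hull_volume(pts)
        vols.append(v)
        degen.append(d)
        npts.append(len(ids))
        areas.append(_hull_area_2d(pts))
        maxd.append(float(pdist(pts).max()) if len(pts) > 1 else 0.0)
        times.append(tracks.frame_times[f])
        incomplete.append(len(ids) < n_expected)
    if frames_with_cells < 2:
        raise ValueError("subset tracked in fewer than two frames")
    return ClusterSeries(
        time=np.array(times),
        hull_volume=np.array(vols),
        n_points=np.array(npts),
        degenerate_flag=np.array(degen),
        hull_area_2d=np.array(areas),
        max_pairwise_distance=np.array(maxd),
        incomplete_flag=np.array(incomplete),
    )
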