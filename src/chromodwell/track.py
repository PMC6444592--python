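"""Trajectory assembly and derived jump/dwell datasets.

Localizations in consecutive frames are considered the same molecule when
they lie within a fixed linking radius (default 6 px = 936 nm at 156 nm/px).
Ambiguities are resolved per frame pair by a global minimum-cost one-to-one
assignment: the objective minimised is

    sum of matched distances + radius * (number of unmatched localizations),

with matches restricted to pairs within the radius.  Unmatched localizations
start new trajectories; a trajectory ends on the first frame in which it
finds no partner (no gap closing).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .datasets import DwellDataset, JumpDistanceDataset

__all__ = [
    "link_localizations",
    "compute_jumps",
    "compute_dwells",
    "TRACK_COLUMNS",
]

TRACK_COLUMNS = ["trajectory_id", "frame", "x_px", "y_px"]

DEFAULT_LINK_RADIUS_PX = 6.0  # 936 nm at 156 nm per pixel


def _id_column(tracks: pd.DataFrame) -> str:
    """Accept linked tracks (trajectory_id) or simulated ground-truth
    trajectory tables (molecule_id) interchangeably."""
    for col in ("trajectory_id", "molecule_id"):
        if col in tracks.columns:
            return col
    raise ValueError("table needs a trajectory_id or molecule_id column")


def _assign(prev_xy: np.ndarray, cur_xy: np.ndarray,
            max_radius: float) -> list[tuple[int, int]]:
    """Optimal one-to-one matching between two frames.

    Minimises total matched distance plus ``max_radius`` per unmatched point,
    with matches only allowed within ``max_radius``.  Implemented by
    augmenting the cost matrix with per-point dummy partners of cost
    ``max_radius`` and solving the square assignment problem.
    """
    n_prev, n_cur = len(prev_xy), len(cur_xy)
    if n_prev == 0 or n_cur == 0:
        return []
    dist = cdist(prev_xy, cur_xy)
    big = 1e9
    size = n_prev + n_cur
    cost = np.full((size, size), 0.0)
    cost[:n_prev, :n_cur] = np.where(dist <= max_radius, dist, big)
    cost[:n_prev, n_cur:] = big
    cost[n_prev:, :n_cur] = big
    # dummy partners: leaving i unmatched costs max_radius (half of the
    # 2*max_radius both-unmatched alternative to matching a feasible pair)
    cost[np.arange(n_prev), n_cur + np.arange(n_prev)] = max_radius
    cost[n_prev + np.arange(n_cur), np.arange(n_cur)] = max_radius
    rows, cols = linear_sum_assignment(cost)
    return [(r, c) for r, c in zip(rows, cols)
            if r < n_prev and c < n_cur and dist[r, c] <= max_radius]


def link_localizations(locs: pd.DataFrame,
                       max_radius: float = DEFAULT_LINK_RADIUS_PX) -> pd.DataFrame:
    """Link a localization table into trajectories.

    Parameters
    ----------
    locs : DataFrame
        Must contain columns frame, x_px, y_px (other columns are ignored).
    max_radius : float
        Linking radius in pixels; default 6 px (936 nm).

    Returns
    -------
    DataFrame with columns trajectory_id, frame, x_px, y_px, sorted by
    (trajectory_id, frame).  Every input localization appears exactly once.
    """
    if max_radius <= 0:
        raise ValueError("max_radius must be positive")
    required = {"frame", "x_px", "y_px"}
    if not required.issubset(locs.columns):
        raise ValueError(f"localization table must have columns {sorted(required)}")
    if locs.duplicated(subset=["frame", "x_px", "y_px"]).any():
        raise ValueError("duplicate (frame, x, y) localizations")

    locs = locs.sort_values("frame", kind="stable").reset_index(drop=True)
    out_rows: list[tuple[int, int, float, float]] = []
    next_id = 0
    prev_idx: list[int] = []      # row indices of previous frame
    prev_tid: dict[int, int] = {}  # row index -> trajectory id
    prev_frame = None

    frames = locs["frame"].to_numpy()
    xy = locs[["x_px", "y_px"]].to_numpy(dtype=float)

    for frame in np.unique(frames):
        cur_idx = np.flatnonzero(frames == frame).tolist()
        assigned: dict[int, int] = {}
        if prev_idx and prev_frame is not None and frame == prev_frame + 1:
            matches = _assign(xy[prev_idx], xy[cur_idx], max_radius)
            for pi, ci in matches:
                assigned[cur_idx[ci]] = prev_tid[prev_idx[pi]]
        cur_tid: dict[int, int] = {}
        for i in cur_idx:
            tid = assigned.get(i)
            if tid is None:
                tid = next_id
                next_id += 1
            cur_tid[i] = tid
            out_rows.append((tid, int(frame), xy[i, 0], xy[i, 1]))
        prev_idx, prev_tid, prev_frame = cur_idx, cur_tid, frame

    tracks = pd.DataFrame(out_rows, columns=TRACK_COLUMNS)
    return tracks.sort_values(["trajectory_id", "frame"],
                              kind="stable").reset_index(drop=True)


def compute_jumps(tracks: pd.DataFrame, lag_frames: int = 1,
                  frame_interval: float = 0.0135,
                  pixel_size_nm: float = 156.0) -> JumpDistanceDataset:
    """Pool displacement magnitudes at a fixed frame lag over all trajectories.

    Displacements are Euclidean distances between points ``lag_frames`` apart
    within each trajectory, converted to micrometres via ``pixel_size_nm``.
    """
    if lag_frames < 1:
        raise ValueError("lag_frames must be >= 1")
    jumps: list[np.ndarray] = []
    for _, grp in tracks.groupby(_id_column(tracks), sort=True):
        grp = grp.sort_values("frame")
        xy = grp[["x_px", "y_px"]].to_numpy(dtype=float)
        if len(xy) > lag_frames:
            d = xy[lag_frames:] - xy[:-lag_frames]
            jumps.append(np.hypot(d[:, 0], d[:, 1]))
    if not jumps:
        warnings.warn("lag exceeds every trajectory length; empty jump dataset",
                      stacklevel=2)
        pooled = np.empty(0)
    else:
        pooled = np.concatenate(jumps)
    pooled_um = pooled * pixel_size_nm / 1000.0
    return JumpDistanceDataset(jumps=pooled_um, lag_s=lag_frames * frame_interval)


def compute_dwells(tracks: pd.DataFrame, frame_interval: float = 0.5,
                   last_frame: int | None = None,
                   plus_one_frame: bool = False) -> DwellDataset:
    """Residence times from trajectory lengths in the slow-exposure regime.

    The dwell of a trajectory spanning ``n`` points is ``(n - 1) *
    frame_interval`` by default (``n * frame_interval`` with
    ``plus_one_frame=True``).  Trajectories that touch the movie's final
    frame are flagged right-censored.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    if last_frame is None and len(tracks):
        last_frame = int(tracks["frame"].max())
    dwells, censored = [], []
    for _, grp in tracks.groupby(_id_column(tracks), sort=True):
        n = len(grp)
        extra = 1 if plus_one_frame else 0
        dwells.append((n - 1 + extra) * frame_interval)
        censored.append(last_frame is not None
                        and int(grp["frame"].max()) >= last_frame)
    return DwellDataset(dwells=np.asarray(dwells, dtype=float),
                        frame_interval=frame_interval,
                        censored=np.asarray(censored, dtype=bool))
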