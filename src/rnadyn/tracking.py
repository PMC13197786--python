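"""Trajectory linking for single-particle tracking.

Per-frame detections are linked into trajectories by greedy one-to-one
nearest-neighbour assignment.  A link is admissible when the lateral
displacement is below ``max_link_disp_px`` pixels per elapsed frame
(25 px by default) and the number of skipped frames is below
``max_gap_frames`` (3 by default, i.e. gaps of 1 or 2 frames may be
closed).  Closed gaps are filled by linear interpolation and the filled
points flagged, so downstream statistics can exclude them.  Only
trajectories with at least ``min_traj_frames`` (14) points are analysed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "link", "filter_trajectories", "trajectories_to_table"]


@dataclass
class Trajectory:
    """Time-ordered 2D localizations of one particle.

    Positions are in micrometres; after gap interpolation frames
    increase in steps of one and interpolated points are flagged.
    """

    traj_id: int
    frames: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    interpolated: np.ndarray
    dt_s: float
    pixel_size_um: float
    compartment: str = "none"
    cell_id: int = -1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        n = len(self.frames)
        if not (len(self.x_um) == len(self.y_um) == len(self.interpolated) == n):
            raise ValueError("trajectory arrays must have equal lengths")
        if n > 1 and np.any(np.diff(self.frames) != 1):
            raise ValueError("frames must increase in steps of 1 after interpolation")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions in micrometres."""
        return np.column_stack([self.x_um, self.y_um])

    @property
    def net_displacement_um(self) -> float:
        return float(np.hypot(self.x_um[-1] - self.x_um[0], self.y_um[-1] - self.y_um[0]))


class _Track:
    __slots__ = ("frames", "xs", "ys", "cell_id", "compartment")

    def __init__(self, frame, x, y, cell_id, compartment):
        self.frames = [frame]
        self.xs = [x]
        self.ys = [y]
        self.cell_id = cell_id
        self.compartment = compartment


def link(
    detections: pd.DataFrame,
    *,
    max_disp_px: float = 25.0,
    max_gap_frames: int = 3,
    pixel_size_um: float = 0.0433,
    dt_s: float = 0.03,
) -> list[Trajectory]:
    """Link per-frame detections into trajectories.

    ``detections`` needs columns ``frame, x_um, y_um`` and may carry
    ``cell_id``/``compartment`` (taken from the first point of a track).
    The per-frame distance gate is ``max_disp_px * pixel_size_um``; a
    link across ``g`` skipped frames is admitted when ``g <
    max_gap_frames`` with the gate scaled by ``g + 1``.  Assignment is
    greedy in ascending distance, one-to-one, with ties broken by
    (frame, y, x) so output is deterministic.
    """
    det = pd.DataFrame(detections).copy()
    required = {"frame", "x_um", "y_um"}
    if not required.issubset(det.columns):
        raise ValueError(f"detections must have columns {sorted(required)}")
    if "det_id" in det.columns and det["det_id"].duplicated().any():
        raise ValueError("duplicate detection ids")
    if "cell_id" not in det.columns:
        det["cell_id"] = -1
    if "compartment" not in det.columns:
        det["compartment"] = "none"
    det = det.sort_values(["frame", "y_um", "x_um"], kind="mergesort").reset_index(drop=True)

    gate_um = max_disp_px * pixel_size_um
    open_tracks: list[_Track] = []
    closed: list[_Track] = []

    for frame, group in det.groupby("frame", sort=True):
        frame = int(frame)
        # retire tracks whose gap can no longer be closed
        still_open = []
        for tr in open_tracks:
            gap = frame - tr.frames[-1] - 1
            if gap >= max_gap_frames:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        pts = group[["x_um", "y_um"]].to_numpy()
        # candidate (distance, track_idx, det_idx) pairs under the gate
        cands = []
        for ti, tr in enumerate(open_tracks):
            gap = frame - tr.frames[-1] - 1
            allowed = gate_um * (gap + 1)
            dx = pts[:, 0] - tr.xs[-1]
            dy = pts[:, 1] - tr.ys[-1]
            dist = np.hypot(dx, dy)
            for di in np.nonzero(dist < allowed)[0]:
                cands.append((dist[di], ti, int(di)))
        cands.sort(key=lambda c: (c[0], c[1], c[2]))
        used_t: set[int] = set()
        used_d: set[int] = set()
        for d, ti, di in cands:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            tr = open_tracks[ti]
            tr.frames.append(frame)
            tr.xs.append(pts[di, 0])
            tr.ys.append(pts[di, 1])
        for di in range(len(pts)):
            if di not in used_d:
                row = group.iloc[di]
                open_tracks.append(
                    _Track(frame, pts[di, 0], pts[di, 1], int(row["cell_id"]), str(row["compartment"]))
                )
    closed.extend(open_tracks)

    trajectories = []
    for tid, tr in enumerate(closed):
        frames, xs, ys, interp = _interpolate_gaps(tr.frames, tr.xs, tr.ys)
        trajectories.append(
            Trajectory(
                traj_id=tid,
                frames=frames,
                x_um=xs,
                y_um=ys,
                interpolated=interp,
                dt_s=dt_s,
                pixel_size_um=pixel_size_um,
                compartment=tr.compartment,
                cell_id=tr.cell_id,
            )
        )
    return trajectories


def _interpolate_gaps(frames, xs, ys):
    """Fill skipped frames by linear interpolation, flagging filled points."""
    frames = np.asarray(frames, dtype=int)
    full = np.arange(frames[0], frames[-1] + 1)
    x_full = np.interp(full, frames, xs)
    y_full = np.interp(full, frames, ys)
    interp = ~np.isin(full, frames)
    return full, x_full, y_full, interp


def filter_trajectories(
    trajectories: list[Trajectory], min_frames: int = 14
) -> tuple[list[Trajectory], int]:
    """Keep trajectories with >= ``min_frames`` points (interpolated included).

    Returns (kept, n_discarded).
    """
    kept = [t for t in trajectories if len(t) >= min_frames]
    return kept, len(trajectories) - len(kept)


def trajectories_to_table(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Long-format table with one row per localization."""
    rows = []
    for t in trajectories:
        for i in range(len(t)):
            rows.append(
                {
                    "traj_id": t.traj_id,
                    "frame": int(t.frames[i]),
                    "x_um": t.x_um[i],
                    "y_um": t.y_um[i],
                    "interpolated": bool(t.interpolated[i]),
                    "cell_id": t.cell_id,
                    "compartment": t.compartment,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["traj_id", "frame", "x_um", "y_um", "interpolated", "cell_id", "compartment"],
    )
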