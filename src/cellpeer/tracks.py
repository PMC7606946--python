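"""Trajectory data model and preprocessing.

Trajectories arrive from an external cell tracker as time-ordered (x, y)
pixel positions, one row per frame.  Before feature extraction they are:

1. length-filtered — tracks shorter than ``min_points`` frames carry too
   little statistics and are discarded (default 50 points at 1 frame/min);
2. smoothed — a penalized cubic smoothing spline fitted independently to
   x(t) and y(t) suppresses single-frame localization jumps (the tracker
   occasionally re-uses the previous position or snaps to a wrong cell);
3. screened for outlier tracks — unsupervised robust z-scores on per-track
   mean speed and on the fraction of frozen (zero-displacement) frames flag
   tracks produced by tracking failures.

Coordinates are 0-based pixel indices, x rightward, y downward; time is in
minutes.  Physical units enter only through ``pixel_size`` (default 0.66
um/px) applied at feature-extraction time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

logger = logging.getLogger(__name__)

DEFAULT_MIN_POINTS = 50
DEFAULT_SMOOTHING = 0.99
DEFAULT_PIXEL_SIZE = 0.66  # um per pixel
OUTLIER_Z_THRESHOLD = 3.5
_MIN_TRACKS_FOR_FLAGGING = 5


@dataclass(frozen=True)
class TrackPoint:
    """One sample of a trajectory: frame index, time (min) and position (px)."""

    t_index: int
    t: float
    x: float
    y: float


@dataclass
class Trajectory:
    """A single cell track in one video.

    Positions are stored as arrays for vectorized feature extraction;
    ``points`` offers the per-sample view.
    """

    video_id: str
    track_id: int
    t_index: np.ndarray  # (n,) int frame indices, strictly increasing
    x: np.ndarray  # (n,) float px
    y: np.ndarray  # (n,) float px
    dt: float = 1.0  # minutes per frame
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.t_index = np.asarray(self.t_index, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t_index.shape == self.x.shape == self.y.shape):
            raise ValueError("t_index, x, y must have equal length")
        if self.t_index.size < 2:
            raise ValueError("a trajectory needs at least 2 points")
        if np.any(np.diff(self.t_index) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("coordinates must be finite")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return int(self.t_index.size)

    @property
    def t(self) -> np.ndarray:
        """Sample times in minutes (t = t_index * dt)."""
        return self.t_index * self.dt

    @property
    def points(self) -> list[TrackPoint]:
        return [
            TrackPoint(int(i), float(i * self.dt), float(px), float(py))
            for i, px, py in zip(self.t_index, self.x, self.y)
        ]


@dataclass
class VideoInfo:
    video_id: str
    class_label: str
    treatment_tag: str = "control"


@dataclass
class ExperimentSet:
    """All videos of one experiment: metadata, trajectories and contours.

    ``contours[(video_id, track_id)]`` is a list of per-frame polygons
    (each an (m, 2) float array), parallel to the track's frames.
    """

    videos: list[VideoInfo]
    trajectories: list[Trajectory]
    contours: dict[tuple[str, int], list[np.ndarray]] = field(default_factory=dict)
    dt: float = 1.0
    pixel_size: float = DEFAULT_PIXEL_SIZE

    def __post_init__(self) -> None:
        ids = {v.video_id for v in self.videos}
        for traj in self.trajectories:
            if traj.video_id not in ids:
                raise ValueError(f"trajectory references unknown video {traj.video_id!r}")

    @property
    def class_labels(self) -> list[str]:
        return sorted({v.class_label for v in self.videos})

    def video_label(self, video_id: str) -> str:
        for v in self.videos:
            if v.video_id == video_id:
                return v.class_label
        raise KeyError(video_id)

    def tracks_of(self, video_id: str) -> list[Trajectory]:
        return [t for t in self.trajectories if t.video_id == video_id]


def filter_short_tracks(tracks: list[Trajectory], min_points: int = DEFAULT_MIN_POINTS) -> list[Trajectory]:
    """Drop tracks with fewer than ``min_points`` samples (default 50).

    Tracks of exactly ``min_points`` points are retained; input order is
    preserved.
    """
    if min_points < 2:
        raise ValueError("min_points must be >= 2")
    kept = [t for t in tracks if len(t) >= min_points]
    if len(kept) < len(tracks):
        logger.info("length filter: kept %d/%d tracks (min_points=%d)",
                    len(kept), len(tracks), min_points)
    return kept


def smooth_trajectory(traj: Trajectory, smoothing: float = DEFAULT_SMOOTHING) -> Trajectory:
    """Smooth x(t) and y(t) with a penalized cubic spline.

    ``smoothing`` is the csaps-style weight p in (0, 1]: the spline
    minimizes p * sum((y - f)^2) + (1 - p) * integral(f''^2), i.e. p = 1
    interpolates the data exactly and smaller p gives a stiffer fit.  The
    fitted spline is evaluated at the original sample times, so the number
    of points never changes.
    """
    if not 0.0 < smoothing <= 1.0:
        raise ValueError("smoothing must be in (0, 1]")
    if len(traj) < 4:
        raise ValueError("smoothing requires at least 4 points")
    t = traj.t.astype(float)
    if smoothing == 1.0:
        xs, ys = traj.x.copy(), traj.y.copy()
    else:
        lam = (1.0 - smoothing) / smoothing
        xs = make_smoothing_spline(t, traj.x, lam=lam)(t)
        ys = make_smoothing_spline(t, traj.y, lam=lam)(t)
    out = replace(traj, x=xs, y=ys)
    out.smoothed = True
    return out


def _robust_z(values: np.ndarray) -> np.ndarray:
    """Median/MAD z-scores; a zero MAD yields zeros (no discrimination)."""
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        return np.zeros_like(values, dtype=float)
    return 0.6745 * (values - med) / mad


def flag_outlier_tracks(
    tracks: list[Trajectory],
    z_threshold: float = OUTLIER_Z_THRESHOLD,
) -> np.ndarray:
    """Unsupervised outlier-track detection (per video).

    Flags tracks whose robust z-score exceeds ``z_threshold`` on either
    per-track mean speed (false localizations produce huge jumps) or the
    fraction of zero-displacement frames (a frozen position re-assigned by
    the tracker).  With fewer than 5 tracks nothing is flagged and a
    warning is logged.

    Returns a boolean array aligned with ``tracks`` (True = outlier).
    """
    n = len(tracks)
    flags = np.zeros(n, dtype=bool)
    if n < _MIN_TRACKS_FOR_FLAGGING:
        logger.warning("outlier flagging skipped: only %d tracks (< %d)",
                       n, _MIN_TRACKS_FOR_FLAGGING)
        return flags
    mean_speed = np.empty(n)
    frozen_frac = np.empty(n)
    for i, tr in enumerate(tracks):
        steps = np.hypot(np.diff(tr.x), np.diff(tr.y))
        dts = np.diff(tr.t)
        mean_speed[i] = float(np.mean(steps / dts))
        frozen_frac[i] = float(np.mean(steps == 0.0))
    z_speed = _robust_z(mean_speed)
    z_frozen = _robust_z(frozen_frac)
    flags = (np.abs(z_speed) > z_threshold) | (np.abs(z_frozen) > z_threshold)
    if flags.any():
        logger.info("outlier flagging removed %d/%d tracks", int(flags.sum()), n)
    return flags


# ---------------------------------------------------------------------------
# CSV I/O (schema shared with the synthetic writer)

TRACK_CSV_COLUMNS = ["video_id", "track_id", "frame", "x", "y"]
CONTOUR_CSV_COLUMNS = ["video_id", "track_id", "frame", "vertex_index", "x", "y"]


def read_tracks_csv(path, dt: float = 1.0) -> list[Trajectory]:
    """Read trajectories from CSV (columns video_id, track_id, frame, x, y).

    Raises ValueError naming the offending line for schema violations.
    """
    df = pd.read_csv(path)
    missing = set(TRACK_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[~np.isfinite(df["x"]) | ~np.isfinite(df["y"])]
    if len(bad):
        raise ValueError(f"{path}: non-finite coordinate at data line {bad[0] + 2}")
    out: list[Trajectory] = []
    for (vid, tid), g in df.groupby(["video_id", "track_id"], sort=True):
        g = g.sort_values("frame")
        out.append(Trajectory(str(vid), int(tid), g["frame"].to_numpy(),
                              g["x"].to_numpy(), g["y"].to_numpy(), dt=dt))
    return out


def write_tracks_csv(tracks: list[Trajectory], path) -> None:
    frames = [
        pd.DataFrame({
            "video_id": t.video_id, "track_id": t.track_id,
            "frame": t.t_index, "x": t.x, "y": t.y,
        })
        for t in tracks
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_contours_csv(path) -> dict[tuple[str, int], list[np.ndarray]]:
    """Read per-frame contour polygons keyed by (video_id, track_id)."""
    df = pd.read_csv(path)
    missing = set(CONTOUR_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[tuple[str, int], list[np.ndarray]] = {}
    for (vid, tid), g in df.groupby(["video_id", "track_id"], sort=True):
        polys = []
        for _, gf in g.groupby("frame", sort=True):
            gf = gf.sort_values("vertex_index")
            polys.append(gf[["x", "y"]].to_numpy(dtype=float))
        out[(str(vid), int(tid))] = polys
    return out


def write_contours_csv(contours: dict[tuple[str, int], list[np.ndarray]], path) -> None:
    rows = []
    for (vid, tid), polys in contours.items():
        for frame, poly in enumerate(polys):
            rows.append(pd.DataFrame({
                "video_id": vid, "track_id": tid, "frame": frame,
                "vertex_index": np.arange(len(poly)),
                "x": poly[:, 0], "y": poly[:, 1],
            }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
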