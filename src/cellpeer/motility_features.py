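"""Kinematic time series and per-track motility descriptors.

From a smoothed trajectory (x_s(t_k), y_s(t_k)) the module derives four
time series:

* tangential speed v(t_k) — norm of the forward-difference velocity;
* track curvature chi(t_k) = |x'y'' - y'x''| / (x'^2 + y'^2)^(3/2), with
  central-difference derivatives and endpoints dropped;
* turning angle theta(t_k) — four-quadrant angle of the velocity vector;
* angular velocity omega(t_k) = v(t_k) / R(t_k), where R is the distance
  from the trajectory's time-averaged center.

and two scalar descriptors:

* diffusion coefficient D = exp(y_0) / 4, with y_0 the intercept of an
  ordinary least-squares fit of ln MSD(tau) on ln tau (time-averaged MSD,
  short-lag range, see ``mean_squared_displacement``);
* directional persistence p = net displacement / path length, in [0, 1].

Summarizing each series with the 5 motility statistics and appending D
and p gives the 22-descriptor motility vector (see
``MOTILITY_DESCRIPTOR_NAMES``).

Missing values: curvature and turning angle are undefined where the speed
vanishes, and omega where R = 0; those samples are emitted as NaN and
excluded from summaries.  A series that is >50% missing yields NaN
descriptors for that block and the caller drops the track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cellpeer.series_stats import MOTILITY_STATISTICS, summarize_series
from cellpeer.tracks import Trajectory

KINEMATIC_SERIES = ("speed", "curvature", "turning_angle", "angular_velocity")

#: the motility descriptor names: 4 series x 5 statistics + D + p = 22
MOTILITY_DESCRIPTOR_NAMES = tuple(
    f"{s}_{stat}" for s in KINEMATIC_SERIES for stat in MOTILITY_STATISTICS
) + ("diffusion_coefficient", "persistence")

MSD_LAG_FRACTION = 4  # never fit beyond lag N // 4
MSD_MAX_LAGS = 20  # short-lag fit: large-lag MSD estimates are few-sample noise
_MAX_MISSING_FRACTION = 0.5

__all__ = ["KinematicSeries", "compute_kinematic_series",
           "estimate_diffusion_coefficient", "directional_persistence",
           "path_length", "motility_feature_vector",
           "MOTILITY_DESCRIPTOR_NAMES", "KINEMATIC_SERIES"]


@dataclass
class KinematicSeries:
    """Per-frame kinematics of one track (NaN marks undefined samples)."""

    speed: np.ndarray  # length/min, at t_0 .. t_{N-2} (forward differences)
    curvature: np.ndarray  # 1/length, interior points t_1 .. t_{N-2}
    turning_angle: np.ndarray  # radians, aligned with speed
    angular_velocity: np.ndarray  # rad/min, aligned with speed
    center: tuple[float, float]  # (x_c, y_c), time-average of the track

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "speed": self.speed,
            "curvature": self.curvature,
            "turning_angle": self.turning_angle,
            "angular_velocity": self.angular_velocity,
        }


def compute_kinematic_series(
    traj: Trajectory,
    pixel_size: float = 1.0,
    printed_axis_order: bool = False,
) -> KinematicSeries:
    """Speed, curvature, turning angle and angular velocity of a track.

    ``printed_axis_order=True`` swaps the arctangent arguments so the
    turning angle follows the tan^-1(v_x / v_y) axis convention instead of
    the standard atan2(v_y, v_x) math angle; both are four-quadrant.
    Requires >= 5 points.
    """
    if len(traj) < 5:
        raise ValueError("kinematic series require at least 5 points")
    x = traj.x * pixel_size
    y = traj.y * pixel_size
    t = traj.t

    # forward differences: v(t_k) for k = 0 .. N-2
    dtv = np.diff(t)
    vx = np.diff(x) / dtv
    vy = np.diff(y) / dtv
    v = np.hypot(vx, vy)

    moving = v > 0
    theta = np.full_like(v, np.nan)
    if printed_axis_order:
        theta[moving] = np.arctan2(vx[moving], vy[moving])
    else:
        theta[moving] = np.arctan2(vy[moving], vx[moving])

    # central differences on interior points k = 1 .. N-2
    dt_c = (t[2:] - t[:-2]) / 2.0
    xp = (x[2:] - x[:-2]) / (2.0 * dt_c)
    yp = (y[2:] - y[:-2]) / (2.0 * dt_c)
    xpp = (x[2:] - 2 * x[1:-1] + x[:-2]) / dt_c**2
    ypp = (y[2:] - 2 * y[1:-1] + y[:-2]) / dt_c**2
    speed_sq = xp * xp + yp * yp
    chi = np.full(len(x) - 2, np.nan)
    ok = speed_sq > 0
    chi[ok] = np.abs(xp[ok] * ypp[ok] - yp[ok] * xpp[ok]) / speed_sq[ok] ** 1.5

    xc, yc = float(x.mean()), float(y.mean())
    r = np.hypot(x[:-1] - xc, y[:-1] - yc)  # aligned with v
    omega = np.full_like(v, np.nan)
    ok_r = r > 0
    omega[ok_r] = v[ok_r] / r[ok_r]

    return KinematicSeries(speed=v, curvature=chi, turning_angle=theta,
                           angular_velocity=omega, center=(xc, yc))


def mean_squared_displacement(
    traj: Trajectory, pixel_size: float = 1.0, max_lag: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged MSD over overlapping pairs.

    The default lag range is 1 .. min(floor(N/4), 20): beyond a small
    fraction of the track length the time-averaged MSD rests on a
    handful of effectively independent segments and its scatter biases
    the log-space fit.  Returns (lags in minutes, MSD values).
    """
    n = len(traj)
    if max_lag is None:
        max_lag = max(min(n // MSD_LAG_FRACTION, MSD_MAX_LAGS), 1)
    max_lag = min(max_lag, n - 1)
    x = traj.x * pixel_size
    y = traj.y * pixel_size
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    for i, lag in enumerate(lags):
        dx = x[lag:] - x[:-lag]
        dy = y[lag:] - y[:-lag]
        msd[i] = np.mean(dx * dx + dy * dy)
    return lags * traj.dt, msd


def estimate_diffusion_coefficient(traj: Trajectory, pixel_size: float = 1.0) -> tuple[float, float]:
    """Diffusion coefficient from a log-log linear fit of the MSD.

    OLS of ln MSD(tau) on ln tau (tau in minutes) gives intercept y_0 and
    the reported D = exp(y_0) / 4 (the 2-D relation MSD = 4 D tau).
    Returns (D, y_0).  Requires >= 20 points; a zero MSD at every lag
    (immobile track) is degenerate and raises.
    """
    if len(traj) < 20:
        raise ValueError("diffusion fit requires at least 20 points")
    tau, msd = mean_squared_displacement(traj, pixel_size=pixel_size)
    positive = msd > 0
    if positive.sum() < 2:
        raise ValueError("degenerate MSD: track does not move")
    coeffs = np.polyfit(np.log(tau[positive]), np.log(msd[positive]), 1)
    y0 = float(coeffs[1])
    return float(np.exp(y0) / 4.0), y0


def msd_loglog_slope(traj: Trajectory, pixel_size: float = 1.0) -> float:
    """Slope of ln MSD vs ln tau (1 for Brownian, 2 for ballistic motion)."""
    tau, msd = mean_squared_displacement(traj, pixel_size=pixel_size)
    positive = msd > 0
    if positive.sum() < 2:
        raise ValueError("degenerate MSD: track does not move")
    return float(np.polyfit(np.log(tau[positive]), np.log(msd[positive]), 1)[0])


def path_length(traj: Trajectory, pixel_size: float = 1.0) -> float:
    """Total arc length L = sum of step lengths."""
    return float(np.hypot(np.diff(traj.x), np.diff(traj.y)).sum() * pixel_size)


def directional_persistence(traj: Trajectory) -> float:
    """Net displacement over path length, in [0, 1].

    1 for straight-line motion, 0 for a closed loop.  An immobile track
    (L = 0) has undefined persistence and returns NaN.
    """
    length = path_length(traj)
    if length == 0:
        return float("nan")
    net = float(np.hypot(traj.x[-1] - traj.x[0], traj.y[-1] - traj.y[0]))
    return net / length


def _summaries(series: np.ndarray, prefix: str) -> dict[str, float]:
    valid = series[np.isfinite(series)]
    if series.size == 0 or valid.size < 2 or valid.size < series.size * (1 - _MAX_MISSING_FRACTION):
        return {f"{prefix}_{stat}": float("nan") for stat in MOTILITY_STATISTICS}
    summary = summarize_series(valid, include_signal_entropy=False)
    return {f"{prefix}_{stat}": val
            for stat, val in summary.as_dict(include_signal_entropy=False).items()}


def motility_feature_vector(traj: Trajectory, pixel_size: float = 1.0) -> dict[str, float]:
    """The 22-descriptor motility vector of one (smoothed) track.

    Five summary statistics for each of speed, curvature, turning angle
    and angular velocity, plus the diffusion coefficient D and the
    directional persistence p.  Names and order are fixed
    (``MOTILITY_DESCRIPTOR_NAMES``); undefined entries are NaN.
    """
    kin = compute_kinematic_series(traj, pixel_size=pixel_size)
    out: dict[str, float] = {}
    for name, series in kin.as_dict().items():
        out.update(_summaries(series, name))
    try:
        d, _ = estimate_diffusion_coefficient(traj, pixel_size=pixel_size)
    except ValueError:
        d = float("nan")
    out["diffusion_coefficient"] = d
    out["persistence"] = directional_persistence(traj)
    return out
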