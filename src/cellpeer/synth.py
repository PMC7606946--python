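"""Synthetic multi-video experiments with known class and cluster structure.

The generator emulates label-free time-lapse microscopy experiments of
clustered adherent cells recorded at one frame per minute for 6-12 h:

* **Motility** — each cell follows a persistent random walk: a discrete
  Ornstein-Uhlenbeck (mean-reverting) velocity process whose relaxation
  time is the configured ``persistence_time`` and whose stationary speed
  distribution is Rayleigh with mean ``mean_speed``.  An optional
  per-class ``diffusivity`` adds uncorrelated positional jitter
  (localization noise); the velocity scale is calibrated so the empirical
  per-frame mean speed still matches ``mean_speed``.  The long-time
  effective diffusivity of the pure OU walk is sigma_v^2 * P / 2.
* **Clusters** — cluster centers sit on a jittered grid; each cell is
  tethered to its cluster center by a weak spring that engages only
  beyond a per-cell tether radius, so clusters stay compact while
  within-cluster motion is free.  A configurable fraction of "boundary"
  cells get a larger tether radius.
* **Shape** — per-frame contours are 64-vertex noisy ellipses with
  class-specific area and eccentricity; pseudopod events (one-sided
  radial bumps) occur at ``pseudopod_rate`` per frame and strictly lower
  solidity.
* **Contamination** — a configured fraction of tracks is regenerated
  from a deviant motility regime (speed x3, persistence x0.2 by default),
  emulating the noncanonical trajectories that good-teacher and
  test-sample selection must reject.

Identical config + seed gives byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cellpeer.tracks import (
    ExperimentSet,
    Trajectory,
    VideoInfo,
    write_contours_csv,
    write_tracks_csv,
)

N_CONTOUR_VERTICES = 64

__all__ = ["ShapeParams", "SimulationConfig", "SyntheticExperiment",
           "simulate_experiment", "simulate_brownian_track", "simulate_shape_series",
           "simulate_ou_track", "canonical_benchmark_config", "write_experiment"]


@dataclass(frozen=True)
class ShapeParams:
    """Per-class contour parameters (pixel units)."""

    mean_area: float  # px^2
    mean_eccentricity: float  # in [0, 1)
    pseudopod_rate: float  # events per frame, in [0, 1]
    area_noise: float = 0.08  # lognormal sigma of per-frame area
    ecc_noise: float = 0.04
    pseudopod_amplitude: float = 0.6  # bump height relative to local radius

    def validate(self) -> None:
        if not np.isfinite(self.mean_area) or self.mean_area <= 0:
            raise ValueError("mean_area must be positive and finite")
        if not 0.0 <= self.mean_eccentricity < 1.0:
            raise ValueError("mean_eccentricity must be in [0, 1)")
        if not 0.0 <= self.pseudopod_rate <= 1.0:
            raise ValueError("pseudopod_rate must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Full description of one synthetic experiment.

    Per-class parameter sequences must all have length ``n_classes``.
    Positions are in pixels; speeds in px/min; ``pixel_size`` (um/px) is
    applied downstream at feature-extraction time.
    """

    n_classes: int = 2
    videos_per_class: int = 2
    clusters_per_video: int = 4
    cells_per_cluster: int = 6
    n_frames: int = 360  # 6 h at 1 frame/min
    dt: float = 1.0  # minutes
    mean_speed: tuple[float, ...] = (0.4, 1.2)  # px/min
    persistence_time: tuple[float, ...] = (4.0, 12.0)  # min
    diffusivity: tuple[float, ...] = (0.0, 0.0)  # px^2/min positional jitter
    shape: tuple[ShapeParams, ...] = (
        ShapeParams(mean_area=300.0, mean_eccentricity=0.3, pseudopod_rate=0.05),
        ShapeParams(mean_area=600.0, mean_eccentricity=0.7, pseudopod_rate=0.2),
    )
    contamination_fraction: float = 0.0
    contaminant_speed_factor: float = 3.0
    contaminant_persistence_factor: float = 0.2
    arena_size: int = 600  # px, square field of view
    tether_radius: float = 40.0  # px, free-motion radius around cluster center
    tether_stiffness: float = 0.02  # 1/min, spring beyond the tether radius
    boundary_cell_fraction: float = 0.3  # cells with 2x tether radius
    pixel_size: float = 0.66  # um/px
    with_contours: bool = True
    class_labels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_classes": self.n_classes,
            "videos_per_class": self.videos_per_class,
            "clusters_per_video": self.clusters_per_video,
            "cells_per_cluster": self.cells_per_cluster,
            "n_frames": self.n_frames,
        }
        for name, value in counts.items():
            if int(value) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.contamination_fraction < 1.0:
            raise ValueError("contamination_fraction must be in [0, 1)")
        if self.dt <= 0 or not np.isfinite(self.dt):
            raise ValueError("dt must be positive and finite")
        for name in ("mean_speed", "persistence_time", "diffusivity", "shape"):
            if len(getattr(self, name)) != self.n_classes:
                raise ValueError(f"{name} must have length n_classes={self.n_classes}")
        for arr_name in ("mean_speed", "persistence_time", "diffusivity"):
            arr = np.asarray(getattr(self, arr_name), dtype=float)
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{arr_name} entries must be finite and non-negative")
        if np.any(np.asarray(self.persistence_time) <= 0):
            raise ValueError("persistence_time entries must be positive")
        for sp in self.shape:
            sp.validate()
        if self.class_labels is None:
            self.class_labels = tuple(f"class{i}" for i in range(self.n_classes))
        elif len(self.class_labels) != self.n_classes:
            raise ValueError("class_labels must have length n_classes")

    def labels(self) -> tuple[str, ...]:
        assert self.class_labels is not None
        return self.class_labels


@dataclass
class SyntheticExperiment:
    """Generated experiment plus its per-track ground truth.

    ``ground_truth`` has one row per track with columns video_id,
    track_id, class_label, cluster_id (1-based) and is_outlier.
    """

    experiment: ExperimentSet
    ground_truth: pd.DataFrame
    config: SimulationConfig

    @property
    def trajectories(self) -> list[Trajectory]:
        return self.experiment.trajectories


def simulate_brownian_track(
    D: float, n_frames: int, dt: float = 1.0, seed: int = 0,
    video_id: str = "sim", track_id: int = 0,
) -> Trajectory:
    """Pure 2-D Brownian track: independent Gaussian increments with
    per-axis variance 2*D*dt.  D = 0 yields an immobile track."""
    if D < 0 or not np.isfinite(D):
        raise ValueError("D must be non-negative and finite")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n_frames - 1, 2))
    pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    return Trajectory(video_id, track_id, np.arange(n_frames), pos[:, 0], pos[:, 1], dt=dt)


def _ou_sigma(mean_speed: float, diffusivity: float, dt: float) -> float:
    """Velocity scale so the empirical per-frame mean speed matches
    ``mean_speed`` after adding the diffusive jitter."""
    target_var = mean_speed**2 * 2.0 / np.pi  # Rayleigh: mean = sigma*sqrt(pi/2)
    jitter_var = 2.0 * diffusivity / dt
    if target_var < jitter_var:
        raise ValueError(
            "diffusivity too large for the requested mean_speed: "
            f"need mean_speed^2*2/pi >= 2*diffusivity/dt ({target_var:.4g} < {jitter_var:.4g})"
        )
    return float(np.sqrt(target_var - jitter_var))


def simulate_ou_track(
    mean_speed: float,
    persistence_time: float,
    n_frames: int,
    dt: float = 1.0,
    diffusivity: float = 0.0,
    start: tuple[float, float] = (0.0, 0.0),
    tether_center: tuple[float, float] | None = None,
    tether_radius: float = np.inf,
    tether_stiffness: float = 0.0,
    rng: np.random.Generator | None = None,
    video_id: str = "sim",
    track_id: int = 0,
) -> Trajectory:
    """One persistent-random-walk track (discrete OU velocity).

    The velocity follows v <- a*v + b*xi with a = exp(-dt/P) and
    b = sigma*sqrt(1 - a^2), so its stationary per-axis std is sigma and
    the speed is Rayleigh(sigma).  Beyond ``tether_radius`` from the
    tether center a spring drift -k*(r - R)*u_r confines the cell.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    sigma = _ou_sigma(mean_speed, diffusivity, dt)
    a = np.exp(-dt / persistence_time)
    b = sigma * np.sqrt(1.0 - a * a)
    jitter = np.sqrt(2.0 * diffusivity * dt)
    cx, cy = tether_center if tether_center is not None else start

    pos = np.empty((n_frames, 2))
    pos[0] = start
    v = rng.normal(0.0, sigma, size=2)
    for k in range(1, n_frames):
        step = v * dt
        if jitter > 0:
            step = step + rng.normal(0.0, jitter, size=2)
        p = pos[k - 1] + step
        rx, ry = p[0] - cx, p[1] - cy
        r = np.hypot(rx, ry)
        if r > tether_radius and tether_stiffness > 0:
            pull = tether_stiffness * (r - tether_radius) * dt / r
            p = p - pull * np.array([rx, ry])
        pos[k] = p
        v = a * v + rng.normal(0.0, b, size=2)
    return Trajectory(video_id, track_id, np.arange(n_frames), pos[:, 0], pos[:, 1], dt=dt)


def _ellipse_radius(a: float, b: float, phi: np.ndarray) -> np.ndarray:
    return a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)


def simulate_shape_series(
    params: ShapeParams,
    n_frames: int,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Per-frame contour polygons (centered at the origin) for one cell.

    Each frame is a 64-vertex ellipse with lognormal area noise, jittered
    eccentricity and a slowly drifting orientation; with probability
    ``pseudopod_rate`` a frame carries a one-sided radial Gaussian bump
    whose flanks indent the convex hull, driving solidity below 1.
    """
    params.validate()
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    phi = np.linspace(0.0, 2.0 * np.pi, N_CONTOUR_VERTICES, endpoint=False)
    orientation = rng.uniform(0, 2 * np.pi)
    polygons: list[np.ndarray] = []
    for _ in range(n_frames):
        area = params.mean_area * np.exp(rng.normal(0.0, params.area_noise))
        ecc = np.clip(
            params.mean_eccentricity + rng.normal(0.0, params.ecc_noise), 0.0, 0.97
        )
        axis_ratio = np.sqrt(1.0 - ecc * ecc)  # b/a
        a_axis = np.sqrt(area / (np.pi * axis_ratio))
        b_axis = area / (np.pi * a_axis)
        r = _ellipse_radius(a_axis, b_axis, phi)
        if rng.random() < params.pseudopod_rate:
            phi0 = rng.uniform(0, 2 * np.pi)
            width = 0.25  # rad
            dphi = np.angle(np.exp(1j * (phi - phi0)))
            r = r + params.pseudopod_amplitude * r * np.exp(-0.5 * (dphi / width) ** 2)
        theta = phi + orientation
        polygons.append(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
        orientation += rng.normal(0.0, 0.05)
    return polygons


def _cluster_centers(n_clusters: int, arena: float, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid cluster centers inside the arena."""
    g = int(np.ceil(np.sqrt(n_clusters)))
    spacing = arena / (g + 1)
    centers = []
    for i in range(g):
        for j in range(g):
            centers.append(((i + 1) * spacing, (j + 1) * spacing))
    centers = np.asarray(centers[:n_clusters], dtype=float)
    centers += rng.uniform(-0.15 * spacing, 0.15 * spacing, size=centers.shape)
    return centers


def simulate_experiment(config: SimulationConfig) -> SyntheticExperiment:
    """Generate a full synthetic experiment from a SimulationConfig.

    Videos are named ``<label>_v<i>``; tracks are numbered per video.
    Contaminated tracks use the same generator with speed and persistence
    multiplied by the configured factors; their ground-truth row carries
    ``is_outlier=True``.
    """
    root = np.random.SeedSequence(config.seed)
    videos: list[VideoInfo] = []
    trajectories: list[Trajectory] = []
    contours: dict[tuple[str, int], list[np.ndarray]] = {}
    truth_rows: list[dict] = []

    labels = config.labels()
    video_seeds = root.spawn(config.n_classes * config.videos_per_class)
    vid_idx = 0
    for c, label in enumerate(labels):
        for vrep in range(config.videos_per_class):
            video_id = f"{label}_v{vrep}"
            videos.append(VideoInfo(video_id=video_id, class_label=label))
            vrng = np.random.default_rng(video_seeds[vid_idx])
            vid_idx += 1
            centers = _cluster_centers(config.clusters_per_video, config.arena_size, vrng)
            track_id = 0
            for j, center in enumerate(centers):
                for _ in range(config.cells_per_cluster):
                    is_outlier = bool(vrng.random() < config.contamination_fraction)
                    speed = config.mean_speed[c]
                    persistence = config.persistence_time[c]
                    if is_outlier:
                        speed *= config.contaminant_speed_factor
                        persistence *= config.contaminant_persistence_factor
                    boundary = vrng.random() < config.boundary_cell_fraction
                    radius = config.tether_radius * (2.0 if boundary else 1.0)
                    start = center + vrng.normal(0.0, config.tether_radius / 2.0, size=2)
                    traj = simulate_ou_track(
                        mean_speed=speed,
                        persistence_time=persistence,
                        n_frames=config.n_frames,
                        dt=config.dt,
                        diffusivity=config.diffusivity[c],
                        start=(float(start[0]), float(start[1])),
                        tether_center=(float(center[0]), float(center[1])),
                        tether_radius=radius,
                        tether_stiffness=config.tether_stiffness,
                        rng=vrng,
                        video_id=video_id,
                        track_id=track_id,
                    )
                    trajectories.append(traj)
                    if config.with_contours:
                        polys = simulate_shape_series(config.shape[c], config.n_frames, rng=vrng)
                        contours[(video_id, track_id)] = [
                            poly + np.array([traj.x[k], traj.y[k]])
                            for k, poly in enumerate(polys)
                        ]
                    truth_rows.append({
                        "video_id": video_id,
                        "track_id": track_id,
                        "class_label": label,
                        "cluster_id": j + 1,
                        "is_outlier": is_outlier,
                    })
                    track_id += 1

    experiment = ExperimentSet(
        videos=videos,
        trajectories=trajectories,
        contours=contours,
        dt=config.dt,
        pixel_size=config.pixel_size,
    )
    return SyntheticExperiment(
        experiment=experiment,
        ground_truth=pd.DataFrame(truth_rows),
        config=config,
    )


def canonical_benchmark_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The canonical synthetic benchmark: 3 well-separated classes x 4
    videos, 4 clusters x 6 cells per video (24 tracks), 6 h at 1
    frame/min, 20% contamination.

    Used by the end-to-end evaluation; pass overrides to vary it.
    """
    base = dict(
        n_classes=3,
        videos_per_class=4,
        clusters_per_video=4,
        cells_per_cluster=6,
        n_frames=360,
        mean_speed=(0.3, 0.8, 1.6),
        persistence_time=(2.0, 6.0, 15.0),
        diffusivity=(0.0, 0.0, 0.0),
        shape=(
            ShapeParams(mean_area=300.0, mean_eccentricity=0.2, pseudopod_rate=0.02),
            ShapeParams(mean_area=500.0, mean_eccentricity=0.5, pseudopod_rate=0.1),
            ShapeParams(mean_area=800.0, mean_eccentricity=0.75, pseudopod_rate=0.25),
        ),
        contamination_fraction=0.2,
        arena_size=800,
        tether_stiffness=0.05,
        with_contours=False,
        class_labels=("lineA", "lineB", "lineC"),
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def write_experiment(synthetic: SyntheticExperiment, outdir) -> None:
    """Write tracks, contours, ground truth and config to ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_tracks_csv(synthetic.trajectories, out / "tracks.csv")
    if synthetic.experiment.contours:
        write_contours_csv(synthetic.experiment.contours, out / "contours.csv")
    synthetic.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    cfg = dataclasses.asdict(synthetic.config)
    cfg["shape"] = [dataclasses.asdict(s) for s in synthetic.config.shape]
    with open(out / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, default=float)
    meta = pd.DataFrame(
        [{"video_id": v.video_id, "class_label": v.class_label,
          "treatment_tag": v.treatment_tag} for v in synthetic.experiment.videos]
    )
    meta.to_csv(out / "videos.csv", index=False)
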