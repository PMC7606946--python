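"""Spatial cell-cluster identification from trajectories.

Cells in culture sit in clusters; the cluster is the unit over which
cooperative decisions are taken.  Clusters are recovered from the tracks
alone:

1. **Accumulation map** — every track point is stamped as a filled disk
   of the mean cell radius; summing over all frames and dividing by the
   maximum gives a [0, 1] gray-scale map whose high values mark positions
   occupied by (slow-moving) cells for many frames.
2. **Segmentation** — Otsu thresholding of the 256-level quantized map,
   then morphological closing (bridge nearby cells) followed by opening
   (remove specks) with a disk structuring element, then 8-connected
   labeling; region boundaries come out as polygons.
3. **Assignment** — each track goes to the cluster label covering the
   plurality of its points; ties break to the lower label, tracks that
   never touch a region get label 0 (unclustered) and are excluded from
   cooperative decisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label as sk_label
from skimage.morphology import closing as _closing, opening as _opening, disk as disk_selem

from cellpeer.tracks import Trajectory

DEFAULT_CELL_RADIUS = 15.0  # px, ~mean radius of the simulated cells

__all__ = ["AccumulationMap", "ClusterMap", "accumulation_map",
           "segment_clusters", "assign_tracks_to_clusters"]


@dataclass
class AccumulationMap:
    """Normalized dwell-time map: values in [0, 1], max = 1."""

    values: np.ndarray  # (H, W) float, row = y, col = x
    origin: tuple[float, float] = (0.0, 0.0)  # (x0, y0) of pixel (0, 0)
    pitch: float = 1.0  # px per grid cell

    def to_grid(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map arena coordinates to (row, col) grid indices."""
        col = np.round((np.asarray(x) - self.origin[0]) / self.pitch).astype(int)
        row = np.round((np.asarray(y) - self.origin[1]) / self.pitch).astype(int)
        return row, col


@dataclass
class ClusterMap:
    """Labeled cluster regions and the track -> cluster assignment."""

    labels: np.ndarray  # (H, W) int, 0 = background, 1..n_clusters
    n_clusters: int
    boundaries: list[np.ndarray]  # one (m, 2) row/col polygon per cluster
    accumulation: AccumulationMap
    assignment: dict[tuple[str, int], int] = field(default_factory=dict)


def accumulation_map(
    tracks: list[Trajectory],
    cell_radius: float = DEFAULT_CELL_RADIUS,
    pitch: float = 1.0,
    shape: tuple[int, int] | None = None,
    origin: tuple[float, float] | None = None,
) -> AccumulationMap:
    """Sum rasterized cell disks over every track point of every frame,
    normalized by the maximum.

    The grid covers the tracks' bounding box (plus one radius margin)
    unless ``shape``/``origin`` are given.
    """
    if not tracks:
        raise ValueError("accumulation map needs at least one track")
    if cell_radius <= 0:
        raise ValueError("cell_radius must be positive")
    xs = np.concatenate([t.x for t in tracks])
    ys = np.concatenate([t.y for t in tracks])
    margin = cell_radius + 2 * pitch
    if origin is None:
        origin = (float(xs.min() - margin), float(ys.min() - margin))
    if shape is None:
        w = int(np.ceil((xs.max() + margin - origin[0]) / pitch)) + 1
        h = int(np.ceil((ys.max() + margin - origin[1]) / pitch)) + 1
        shape = (h, w)
    acc = np.zeros(shape, dtype=float)
    r_grid = cell_radius / pitch
    for t in tracks:
        rows = (t.y - origin[1]) / pitch
        cols = (t.x - origin[0]) / pitch
        for rr, cc in zip(rows, cols):
            dr, dc = draw_disk((rr, cc), r_grid, shape=shape)
            acc[dr, dc] += 1.0
    peak = acc.max()
    if peak > 0:
        acc /= peak
    return AccumulationMap(values=acc, origin=origin, pitch=pitch)


def segment_clusters(
    amap: AccumulationMap,
    morphology_radius: float = DEFAULT_CELL_RADIUS,
) -> ClusterMap:
    """Otsu-threshold the map and extract labeled cluster regions.

    The normalized map is quantized to 256 gray levels before Otsu (so a
    brute-force threshold search over 256 levels is an exact oracle);
    closing-then-opening with a disk of ``morphology_radius`` refines the
    binary image; 8-connected components become clusters 1..N.

    Raises on a constant map (Otsu undefined).
    """
    values = amap.values
    if values.max() == values.min():
        raise ValueError("constant accumulation map: Otsu threshold undefined")
    quantized = np.round(values * 255.0).astype(np.uint8)
    thresh = threshold_otsu(quantized, nbins=256)
    binary = quantized > thresh
    selem = disk_selem(max(int(round(morphology_radius / amap.pitch)), 1))
    refined = _opening(_closing(binary, footprint=selem), footprint=selem)
    labels, n_clusters = sk_label(refined, connectivity=2, return_num=True)
    boundaries = []
    for lab in range(1, n_clusters + 1):
        contours = find_contours((labels == lab).astype(float), 0.5)
        boundaries.append(max(contours, key=len) if contours else np.empty((0, 2)))
    return ClusterMap(labels=labels, n_clusters=n_clusters,
                      boundaries=boundaries, accumulation=amap)


def assign_tracks_to_clusters(
    tracks: list[Trajectory], cluster_map: ClusterMap
) -> dict[tuple[str, int], int]:
    """Assign each track to the cluster covering the plurality of its points.

    A track with no point in any region gets label 0 (unclustered); ties
    break to the lower label.  The assignment is also stored on
    ``cluster_map``.
    """
    labels = cluster_map.labels
    h, w = labels.shape
    assignment: dict[tuple[str, int], int] = {}
    for t in tracks:
        rows, cols = cluster_map.accumulation.to_grid(t.x, t.y)
        inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        point_labels = np.zeros(len(t), dtype=int)
        point_labels[inside] = labels[rows[inside], cols[inside]]
        counts = np.bincount(point_labels, minlength=cluster_map.n_clusters + 1)
        nonzero = counts[1:]
        if nonzero.sum() == 0:
            chosen = 0
        else:
            chosen = int(np.flatnonzero(nonzero == nonzero.max())[0]) + 1
        assignment[(t.video_id, t.track_id)] = chosen
    cluster_map.assignment = assignment
    return assignment
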