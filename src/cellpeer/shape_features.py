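"""Per-frame cell shape scalars and their per-track summary vector.

Four scalars describe each contour:

* **eccentricity** — ratio of the distance between the foci to the major
  axis length of the region's equivalent (second-moment) ellipse;
* **area** — region area (pixel count in raster mode, shoelace integral
  in polygon mode);
* **perimeter** — boundary length (count of region pixels with at least
  one zero 8-neighbor in raster mode, polygon arc length otherwise);
* **solidity** — area divided by convex-hull area (1 for convex shapes,
  < 1 when pseudopodia indent the hull).

Summarizing each scalar's time series with the 6 statistics of
:mod:`cellpeer.series_stats` yields the 24-descriptor shape vector.

Polygon mode is the default: it is exact and resolution-independent.
Raster mode rasterizes the contour and applies the pixelwise definitions,
matching what a binary-mask implementation computes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon
from skimage.measure import regionprops, label as sk_label

from cellpeer.series_stats import SHAPE_STATISTICS, summarize_series

SHAPE_SCALARS = ("eccentricity", "area", "perimeter", "solidity")

__all__ = ["Contour", "ShapeScalars", "shape_scalars", "raster_scalars",
           "shape_feature_vector", "SHAPE_SCALARS", "SHAPE_DESCRIPTOR_NAMES"]

#: the 24 shape descriptor names, "<scalar>_<statistic>"
SHAPE_DESCRIPTOR_NAMES = tuple(
    f"{s}_{stat}" for s in SHAPE_SCALARS for stat in SHAPE_STATISTICS
)


@dataclass
class Contour:
    """Closed polygon contour of one cell in one frame (pixel coordinates)."""

    vertices: np.ndarray  # (m, 2)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ValueError("a contour needs >= 3 (x, y) vertices")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("contour vertices must be finite")
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise ValueError("contour polygon is self-intersecting or degenerate")
        if poly.area <= 0:
            raise ValueError("contour has zero area")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass(frozen=True)
class ShapeScalars:
    eccentricity: float  # in [0, 1)
    area: float  # px^2 (scaled by pixel_size^2 if given)
    perimeter: float  # px (scaled by pixel_size)
    solidity: float  # in (0, 1]


def _polygon_second_moments(v: np.ndarray) -> tuple[float, float, float, float]:
    """Signed area and central second moments (mu20, mu02, mu11) of a polygon."""
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * cross.sum()
    cx = ((x + x1) * cross).sum() / (6.0 * a)
    cy = ((y + y1) * cross).sum() / (6.0 * a)
    ixx = (cross * (y * y + y * y1 + y1 * y1)).sum() / 12.0  # integral of y^2
    iyy = (cross * (x * x + x * x1 + x1 * x1)).sum() / 12.0  # integral of x^2
    ixy = (cross * (x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y)).sum() / 24.0
    mu20 = iyy / a - cx * cx
    mu02 = ixx / a - cy * cy
    mu11 = ixy / a - cx * cy
    return abs(a), mu20, mu02, mu11


def _moment_eccentricity(mu20: float, mu02: float, mu11: float) -> float:
    """Eccentricity of the ellipse with the same second moments.

    Equals the foci distance over the major-axis length: for a true
    ellipse with semi-axes a >= b this is sqrt(1 - b^2/a^2).
    """
    tr = mu20 + mu02
    det_term = np.sqrt(max((mu20 - mu02) ** 2 + 4 * mu11 * mu11, 0.0))
    lam1 = (tr + det_term) / 2.0
    lam2 = (tr - det_term) / 2.0
    if lam1 <= 0:
        return 0.0
    return float(np.sqrt(max(1.0 - lam2 / lam1, 0.0)))


def shape_scalars(contour: Contour, mode: str = "polygon", pixel_size: float = 1.0) -> ShapeScalars:
    """Compute the four shape scalars for one contour.

    Parameters
    ----------
    contour : Contour
    mode : {"polygon", "raster"}
        Polygon mode uses exact geometry (shoelace area, arc-length
        perimeter, second-moment eccentricity, convex-hull solidity).
        Raster mode rasterizes the contour onto a pixel grid and applies
        the pixelwise definitions (area = pixel count, perimeter = count
        of pixels with a zero 8-neighbor).
    pixel_size : float
        Physical size of one pixel; scales perimeter linearly and area
        quadratically.  Eccentricity and solidity are dimensionless.
    """
    if mode == "polygon":
        poly = contour.polygon
        area = poly.area
        perimeter = poly.exterior.length
        _, mu20, mu02, mu11 = _polygon_second_moments(contour.vertices)
        ecc = _moment_eccentricity(mu20, mu02, mu11)
        solidity = float(area / poly.convex_hull.area)
        return ShapeScalars(ecc, float(area) * pixel_size**2,
                            float(perimeter) * pixel_size, min(solidity, 1.0))
    if mode == "raster":
        mask = rasterize_contour(contour)
        return raster_scalars(mask, pixel_size=pixel_size)
    raise ValueError(f"unknown mode {mode!r}")


def rasterize_contour(contour: Contour, pad: int = 2) -> np.ndarray:
    """Rasterize a contour to a tight boolean mask (row = y, col = x)."""
    v = contour.vertices
    x0, y0 = np.floor(v.min(axis=0)).astype(int) - pad
    shape = tuple((np.ceil(v.max(axis=0)).astype(int) - (x0, y0) + pad + 1)[::-1])
    rr, cc = draw_polygon(v[:, 1] - y0, v[:, 0] - x0, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    if not mask.any():
        raise ValueError("contour rasterized to an empty mask")
    return mask


def raster_scalars(mask: np.ndarray, pixel_size: float = 1.0) -> ShapeScalars:
    """Pixelwise shape scalars from a boolean mask.

    Area is the foreground pixel count; perimeter counts foreground
    pixels having at least one background 8-neighbor (pixels on the array
    edge count as boundary); eccentricity and solidity come from the
    region's second-moment ellipse and pixelwise convex hull.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    area = int(mask.sum())
    # interior = pixels whose full 8-neighborhood is foreground
    interior = binary_erosion(mask, structure=np.ones((3, 3), dtype=bool), border_value=0)
    perimeter = int((mask & ~interior).sum())
    props = regionprops(sk_label(mask, connectivity=2))[0]
    return ShapeScalars(
        eccentricity=float(props.eccentricity),
        area=float(area) * pixel_size**2,
        perimeter=float(perimeter) * pixel_size,
        solidity=float(props.solidity),
    )


def shape_feature_vector(scalars_series: list[ShapeScalars]) -> dict[str, float]:
    """Per-track 24-descriptor shape vector from a series of ShapeScalars.

    For each of the four scalars, the six summary statistics; names are
    ``"<scalar>_<statistic>"`` in a fixed order.
    """
    if len(scalars_series) < 2:
        raise ValueError("need at least 2 frames of shape scalars")
    out: dict[str, float] = {}
    for name in SHAPE_SCALARS:
        series = np.array([getattr(s, name) for s in scalars_series], dtype=float)
        summary = summarize_series(series, include_signal_entropy=True)
        for stat, value in summary.as_dict(include_signal_entropy=True).items():
            out[f"{name}_{stat}"] = value
    return out
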