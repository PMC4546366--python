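"""Echo-derived atrial indices: Simpson's-rule volumes, emptying fraction,
appendage length and duct fractional shortening.

Volumes use the single-plane method of disks: the traced atrial contour is
cut into strips perpendicular to the supero-inferior long axis, each strip's
chord is taken as the diameter of a circular disk, and the disk volumes are
summed.  Contours are in millimetres, volumes in microlitres (mm^3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Polygon

__all__ = [
    "AtrialTrace",
    "la_ef",
    "laa_duct_fs",
    "laa_length",
    "simpson_volume",
    "spindle_polygon",
]


@dataclass
class AtrialTrace:
    """One subject-frame's atrial tracings (mm).

    ``la_polygon_min`` / ``la_polygon_max``: closed LA contours at the
    smallest and largest frames; ``long_axis``: the supero-inferior axis
    segment; ``laa_midline``: polyline from appendage apex to duct;
    ``duct_d_min`` / ``duct_d_max``: duct diameters.
    """

    la_polygon_min: np.ndarray
    la_polygon_max: np.ndarray
    long_axis: tuple
    laa_midline: np.ndarray
    duct_d_min: float
    duct_d_max: float

    def __post_init__(self):
        if not (self.duct_d_max >= self.duct_d_min >= 0):
            raise ValueError("need duct_d_max >= duct_d_min >= 0")
        for poly in (self.la_polygon_min, self.la_polygon_max):
            if not Polygon(np.asarray(poly)).is_simple:
                raise ValueError("atrial polygon is self-intersecting")


def simpson_volume(polygon, long_axis, n_disks: int = 20) -> float:
    """Single-plane disk-summation volume (ul) of a traced contour.

    The polygon is cut into ``n_disks`` strips perpendicular to the long
    axis; the chord length at each strip's midpoint is the disk diameter d
    and each disk contributes pi (d/2)^2 h with h the strip thickness.
    """
    poly = Polygon(np.asarray(polygon, dtype=float))
    if not poly.is_valid or poly.area == 0:
        raise ValueError("polygon must be simple with nonzero area")
    (x0, y0), (x1, y1) = long_axis
    u = np.array([x1 - x0, y1 - y0], dtype=float)
    norm = np.hypot(*u)
    if norm == 0:
        raise ValueError("degenerate long axis (zero length)")
    u /= norm
    v = np.array([-u[1], u[0]])  # perpendicular
    verts = np.asarray(poly.exterior.coords)
    t = (verts - [x0, y0]) @ u
    t_min, t_max = t.min(), t.max()
    h = (t_max - t_min) / n_disks
    half_w = np.ptp((verts - [x0, y0]) @ v) + 1.0  # safely spans the polygon
    volume = 0.0
    for i in range(n_disks):
        t_mid = t_min + (i + 0.5) * h
        p = np.array([x0, y0]) + t_mid * u
        chord = LineString([p - half_w * v, p + half_w * v]).intersection(poly)
        d = chord.length
        volume += np.pi * (d / 2.0) ** 2 * h
    return float(volume)


def la_ef(vmin: float, vmax: float) -> float:
    """LA emptying fraction (%): 100 (Vmax - Vmin)/Vmax."""
    if vmax <= 0:
        raise ValueError("vmax must be positive")
    if vmin > vmax:
        raise ValueError("vmin exceeds vmax")
    return 100.0 * (vmax - vmin) / vmax


def laa_duct_fs(d_max: float, d_min: float) -> float:
    """LAA duct fractional shortening (%): 100 (max - min)/max."""
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    if d_min > d_max:
        raise ValueError("d_min exceeds d_max")
    return 100.0 * (d_max - d_min) / d_max


def laa_length(midline) -> float:
    """Appendage length (mm): arc length of the apex-to-duct midline."""
    pts = np.asarray(midline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("midline needs >= 2 vertices")
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


def spindle_polygon(volume_ul: float, aspect: float = 1.3, n_vertices: int = 96) -> tuple:
    """Ellipse contour whose solid of revolution has the given volume.

    Revolving an ellipse with semi-axes a (along the axis) and b yields a
    prolate spheroid of volume (4/3) pi a b^2; with a = aspect * b this fixes
    b from the target volume.  Returns (vertices, long_axis) in mm; useful
    for building synthetic atrial traces with known Simpson volume.
    """
    if volume_ul <= 0:
        raise ValueError("volume must be positive")
    b = (volume_ul / ((4.0 / 3.0) * np.pi * aspect)) ** (1.0 / 3.0)
    a = aspect * b
    phi = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    verts = np.column_stack([a * np.cos(phi), b * np.sin(phi)])
    return verts, ((-a, 0.0), (a, 0.0))
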