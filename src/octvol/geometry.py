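"""Planar geometry: shoelace areas and circular-ROI chord clipping.

A foveal region of interest is a circle drawn on the en-face (infrared)
image.  Each B-scan sees that circle as a chord; the traced contour on the
scan is truncated at the two vertical chord borders and only the part of
the polygon between them contributes area.  Clipping is to the vertical
strip between the borders (the on-screen procedure), not to the circular
arc, so the stack of clipped slabs reproduces the cylinder over the circle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon, box

from .annotation_io import Contour
from .errors import ContourValidityError, DegenerateContourError

__all__ = [
    "CircularROI",
    "polygon_area",
    "polygon_perimeter",
    "validate_contour",
    "chord_halfwidth",
    "clip_contour_to_strip",
    "clipped_area",
]

DEFAULT_ROI_RADIUS_MM = 0.5  # 1000-micron-diameter foveal circle


@dataclass(frozen=True)
class CircularROI:
    """Circular foveal region of interest on the en-face plane.

    ``center_x`` is the lateral position of the fovea on its B-scan,
    ``center_y`` the raster offset of that B-scan, both in mm.
    """

    center_x: float
    center_y: float
    radius: float = DEFAULT_ROI_RADIUS_MM

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError(f"ROI radius must be > 0 mm, got {self.radius}")


def validate_contour(contour: Contour) -> None:
    """Raise unless the contour is a simple (non-self-intersecting) polygon.

    A self-intersecting trace is a drawing error and is rejected rather
    than repaired.  The result is cached on the contour so repeated area
    queries (e.g. during phantom sweeps) validate only once.
    """
    if contour.validated:
        return
    if contour.n_vertices < 3:
        raise DegenerateContourError(
            f"contour '{contour.label}' on scan {contour.scan_index} has "
            f"{contour.n_vertices} vertices; >= 3 required"
        )
    ring = shapely.LinearRing(contour.closed_vertices())
    if not ring.is_simple:
        raise ContourValidityError(
            f"contour '{contour.label}' on scan {contour.scan_index} is self-intersecting"
        )
    contour.validated = True


def polygon_area(contour: Contour) -> float:
    """Absolute area (mm^2) of a simple polygon via the shoelace formula.

    Orientation-independent: clockwise and counter-clockwise traces give
    the same area.
    """
    validate_contour(contour)
    v = contour.vertices
    x, z = v[:, 0], v[:, 1]
    cross = x * np.roll(z, -1) - np.roll(x, -1) * z
    return abs(float(cross.sum())) / 2.0


def polygon_perimeter(contour: Contour) -> float:
    """Perimeter (mm) of the closed polygon."""
    if contour.n_vertices < 3:
        raise DegenerateContourError(
            f"contour '{contour.label}' has {contour.n_vertices} vertices; >= 3 required"
        )
    d = np.diff(contour.closed_vertices(), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def chord_halfwidth(roi: CircularROI, scan_offset_y: float) -> float | None:
    """Half-length (mm) of the chord the ROI circle cuts on a B-scan.

    Returns ``None`` when the scan misses the circle, including the
    tangent case ``d == radius`` (a zero-width chord contributes nothing).
    """
    d = abs(scan_offset_y - roi.center_y)
    if d >= roi.radius:
        return None
    return math.sqrt(roi.radius**2 - d**2)


def _polygons_of(geom) -> list[Polygon]:
    if geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        return [geom]
    return [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]


def clip_contour_to_strip(contour: Contour, x_min: float, x_max: float) -> list[Contour]:
    """Intersect a contour with the vertical strip ``x_min <= x <= x_max``.

    Returns a list of contour pieces (empty when the intersection has no
    area).  A simple polygon clipped by a strip can split into several
    pieces, so the result is always a list; callers that only need area
    can use :func:`clipped_area`.
    """
    if not x_min < x_max:
        raise ValueError(f"x_min must be < x_max, got [{x_min}, {x_max}]")
    validate_contour(contour)
    poly = Polygon(contour.vertices)
    lo = min(poly.bounds[1], 0.0) - 1.0
    hi = max(poly.bounds[3], 0.0) + 1.0
    clipped = poly.intersection(box(x_min, lo, x_max, hi))
    pieces = []
    for piece in _polygons_of(clipped):
        if piece.area <= 0:
            continue
        verts = np.asarray(piece.exterior.coords)[:-1]
        pieces.append(
            Contour(
                scan_index=contour.scan_index,
                vertices=verts,
                label=contour.label,
                validated=True,
            )
        )
    return pieces


def clipped_area(contour: Contour, x_min: float, x_max: float) -> float:
    """Total area (mm^2) of the contour restricted to the vertical strip."""
    return sum(polygon_area(p) for p in clip_contour_to_strip(contour, x_min, x_max))
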