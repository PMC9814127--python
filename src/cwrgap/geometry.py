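"""Planar geometric primitives shared across the pipeline.

The overlay stage assigns occurrence points to polygons with an even–odd
(ray-casting) membership test applied directly to ring coordinates.  National
protected-area and land-cover polygons are dense relative to geodesic
curvature, so the planar predicate on lon/lat (or on projected/synthetic
planar coordinates) matches standard GIS behaviour.  Points exactly on a
ring edge or vertex count as *inside*: this is deterministic and, for
protection status, conservative.

Coordinates here are plain (x, y) pairs; callers decide whether they are
degrees, metres or synthetic kilometres.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np

Ring = Sequence[tuple[float, float]]

#: tolerance (in coordinate units) for the on-boundary test
BOUNDARY_EPS = 1e-12


def _on_segment(px: float, py: float, ax: float, ay: float,
                bx: float, by: float, eps: float) -> bool:
    # collinearity + bounding-box check
    cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    if abs(cross) > eps * max(1.0, abs(bx - ax) + abs(by - ay)):
        return False
    if min(ax, bx) - eps <= px <= max(ax, bx) + eps and \
       min(ay, by) - eps <= py <= max(ay, by) + eps:
        return True
    return False


def point_on_ring_boundary(x: float, y: float, ring: Ring,
                           eps: float = BOUNDARY_EPS) -> bool:
    """True if (x, y) lies on an edge or vertex of the ring."""
    for (ax, ay), (bx, by) in zip(ring[:-1], ring[1:]):
        if _on_segment(x, y, ax, ay, bx, by, eps):
            return True
    return False


def _crossings(x: float, y: float, ring: Ring) -> int:
    """Number of ring edges crossed by the ray from (x, y) to (+inf, y)."""
    n = 0
    for (ax, ay), (bx, by) in zip(ring[:-1], ring[1:]):
        if (ay > y) != (by > y):
            # x coordinate where the edge meets the horizontal through y
            xi = ax + (y - ay) * (bx - ax) / (by - ay)
            if xi > x:
                n += 1
    return n


def point_in_rings(x: float, y: float, rings: Sequence[Ring]) -> bool:
    """Even–odd membership of (x, y) in a polygon given as closed rings.

    ``rings[0]`` is the exterior; subsequent rings are holes.  A point on
    any boundary (outer edge *or* hole edge) counts as inside.  Rings must
    be closed (first vertex equals last); an open ring is a caller error.
    """
    if not math.isfinite(x) or not math.isfinite(y):
        raise ValueError("point coordinates must be finite")
    for i, ring in enumerate(rings):
        if len(ring) < 4:
            raise ValueError(f"ring {i} has fewer than 4 vertices")
        if tuple(ring[0]) != tuple(ring[-1]):
            raise ValueError(f"ring {i} is not closed")
    for ring in rings:
        if point_on_ring_boundary(x, y, ring):
            return True
    crossings = sum(_crossings(x, y, ring) for ring in rings)
    return crossings % 2 == 1


def winding_number(x: float, y: float, ring: Ring) -> int:
    """Signed winding number of a closed ring about (x, y).

    Independent of the even–odd test above; used as a cross-check oracle.
    Undefined on the boundary.
    """
    wn = 0
    for (ax, ay), (bx, by) in zip(ring[:-1], ring[1:]):
        if ay <= y:
            if by > y and (bx - ax) * (y - ay) - (by - ay) * (x - ax) > 0:
                wn += 1
        else:
            if by <= y and (bx - ax) * (y - ay) - (by - ay) * (x - ax) < 0:
                wn -= 1
    return wn


def nearest_point_on_segments(px: float, py: float,
                              segments: np.ndarray) -> tuple[float, float, float]:
    """Closest point to (px, py) over an array of segments.

    ``segments`` has shape (n, 4): columns ax, ay, bx, by.  Returns
    (x, y, distance) of the overall nearest point.  Distances are planar;
    geodesic callers pre-transform to a local tangent plane.
    """
    seg = np.asarray(segments, dtype=float)
    ax, ay, bx, by = seg[:, 0], seg[:, 1], seg[:, 2], seg[:, 3]
    dx, dy = bx - ax, by - ay
    length2 = dx * dx + dy * dy
    with np.errstate(invalid="ignore", divide="ignore"):
        t = ((px - ax) * dx + (py - ay) * dy) / length2
    t = np.where(length2 == 0.0, 0.0, np.clip(t, 0.0, 1.0))
    qx, qy = ax + t * dx, ay + t * dy
    d2 = (qx - px) ** 2 + (qy - py) ** 2
    i = int(np.argmin(d2))
    return float(qx[i]), float(qy[i]), float(math.sqrt(d2[i]))


def rings_to_segments(rings: Sequence[Ring]) -> np.ndarray:
    """Flatten closed rings into an (n, 4) segment array."""
    segs = []
    for ring in rings:
        arr = np.asarray(ring, dtype=float)
        segs.append(np.hstack([arr[:-1], arr[1:]]))
    return np.vstack(segs)


def polygon_area(ring: Ring) -> float:
    """Unsigned shoelace area of a closed ring."""
    arr = np.asarray(ring, dtype=float)
    x, y = arr[:-1, 0], arr[:-1, 1]
    xs, ys = arr[1:, 0], arr[1:, 1]
    return abs(float(np.sum(x * ys - xs * y))) / 2.0
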