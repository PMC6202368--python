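"""Planar polyline geometry: shoelace areas and self-intersection detection.

These primitives back the pinched-point detector and the fallback lobe-area
path.  A hysteresis loop is a closed polyline in the (v, i) plane; its pinch
points are self-intersections and its lobes are the simple sub-loops obtained
by splitting the polyline at those intersections.
"""

from __future__ import annotations

import numpy as np

__all__ = ["shoelace_area", "segment_intersections", "simple_loops", "decompose_abs_area"]

_EPS = 1e-12


def shoelace_area(x: np.ndarray, y: np.ndarray) -> float:
    """Signed area of the closed polygon with vertices (x, y).

    Positive for counter-clockwise traversal. The polygon is closed
    implicitly (no repeated last vertex needed).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def segment_intersections(
    x: np.ndarray, y: np.ndarray, endpoint_tol: float = 0.0
) -> list[tuple[float, float, int, int, float, float]]:
    """All self-intersections of the closed polyline (x, y).

    The polyline is closed by a segment from the last vertex back to the
    first.  Adjacent segments (sharing a vertex) are excluded.  By default
    only strictly interior crossings count; ``endpoint_tol > 0`` widens the
    admissible fractional range to ``[-tol, 1 + tol]`` so that crossings
    located exactly at a polyline vertex (a loop pinched at a sample point)
    are found as well.

    Returns a list of ``(px, py, seg_a, seg_b, t_a, t_b)`` where ``seg_a <
    seg_b`` are segment indices and ``t`` the fractional position of the
    intersection along each segment.  Brute-force O(n^2) pair test,
    vectorized.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        return []
    # closed vertex list -> n segments
    x1 = np.append(x, x[0])
    y1 = np.append(y, y[0])
    px, py = x1[:-1], y1[:-1]
    rx, ry = np.diff(x1), np.diff(y1)

    a, b = np.triu_indices(n, k=2)
    # segments 0 and n-1 are adjacent through the closure
    keep = ~((a == 0) & (b == n - 1))
    a, b = a[keep], b[keep]

    qpx = px[b] - px[a]
    qpy = py[b] - py[a]
    denom = rx[a] * ry[b] - ry[a] * rx[b]
    ok = np.abs(denom) > _EPS
    a, b, qpx, qpy, denom = a[ok], b[ok], qpx[ok], qpy[ok], denom[ok]
    t = (qpx * ry[b] - qpy * rx[b]) / denom
    u = (qpx * ry[a] - qpy * rx[a]) / denom
    lo, hi = -endpoint_tol, 1.0 + endpoint_tol
    if endpoint_tol == 0.0:
        lo, hi = _EPS, 1.0 - _EPS
    hit = (t > lo) & (t < hi) & (u > lo) & (u < hi)
    a, b, t, u = a[hit], b[hit], t[hit], u[hit]
    ix = px[a] + t * rx[a]
    iy = py[a] + t * ry[a]
    return [
        (float(ix[k]), float(iy[k]), int(a[k]), int(b[k]), float(t[k]), float(u[k]))
        for k in range(len(a))
    ]


def simple_loops(
    x: np.ndarray, y: np.ndarray, _depth: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Decompose a closed polyline into simple (non-self-intersecting) loops.

    The polyline is split recursively at its first self-intersection into two
    closed sub-loops until every piece is simple.  For a pinched hysteresis
    loop the pieces are the individual lobes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        return []
    # endpoint-inclusive so loops pinched exactly at a sample vertex split too
    hits = segment_intersections(x, y, endpoint_tol=1e-9)
    if not hits or _depth > 200:
        return [(x, y)]
    ix, iy, a, b, _, _ = hits[0]
    # loop 1: intersection point, vertices a+1..b
    lx1 = np.concatenate(([ix], x[a + 1 : b + 1]))
    ly1 = np.concatenate(([iy], y[a + 1 : b + 1]))
    # loop 2: intersection point, vertices b+1..end, 0..a
    lx2 = np.concatenate(([ix], x[b + 1 :], x[: a + 1]))
    ly2 = np.concatenate(([iy], y[b + 1 :], y[: a + 1]))
    return simple_loops(lx1, ly1, _depth + 1) + simple_loops(lx2, ly2, _depth + 1)


def decompose_abs_area(x: np.ndarray, y: np.ndarray) -> float:
    """Total absolute area enclosed by a (possibly self-intersecting) closed
    polyline: the sum of |shoelace area| over its simple sub-loops.

    For a pinched hysteresis loop this is the total lobe area (A1 + A2),
    independent of lobe orientation.
    """
    return float(sum(abs(shoelace_area(lx, ly)) for lx, ly in simple_loops(x, y)))
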