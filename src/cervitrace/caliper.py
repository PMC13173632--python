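"""Cervical-length measurement from a binary canal mask.

The mask is reduced to an ordered centerline trace (skeletonization,
then the geodesically farthest endpoint pair and the shortest skeleton
path between them), from which three lengths are computed:

* ``single_line`` — the straight chord between the two os endpoints;
* ``two_line`` — the two chords joined at the canal's point of
  greatest curvature, operationalized as the trace point of maximum
  perpendicular deviation from the endpoint chord;
* ``ai_line`` — the polyline arc length of the traced centerline.

On a straight canal all three agree (to a pixel); on a curved canal
the ordering ai >= two >= single holds, which is exactly why a traced
arc recovers length that straight-line calipers miss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.measure import label
from skimage.morphology import skeletonize

from .images import CanalMask


class TraceError(ValueError):
    """Raised when no open centerline can be traced from a mask."""


@dataclass
class CanalTrace:
    """Ordered subpixel centerline from one os end to the other.

    ``points`` are (row, col) coordinates in pixels; the physical
    per-axis scale is ``pixel_spacing_mm`` (row_mm, col_mm).
    """

    points: np.ndarray
    pixel_spacing_mm: tuple[float, float]

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise TraceError("a trace needs at least two (row, col) points")
        if np.any(np.all(np.diff(self.points, axis=0) == 0, axis=1)):
            raise TraceError("trace contains repeated consecutive points")

    @property
    def points_mm(self) -> np.ndarray:
        return self.points * np.asarray(self.pixel_spacing_mm)

    def reversed(self) -> "CanalTrace":
        return CanalTrace(self.points[::-1].copy(), self.pixel_spacing_mm)


@dataclass
class CLMeasurement:
    """The three cervical lengths (mm) for one mask, plus quality flags."""

    single_line_mm: float
    two_line_mm: float
    ai_line_mm: float
    apex_index: int
    n_components_merged: int
    trace_point_count: int

    def __post_init__(self):
        eps = 1e-6
        if not (self.ai_line_mm >= self.two_line_mm - eps
                >= self.single_line_mm - 2 * eps):
            raise ValueError(
                "length ordering violated: expected ai >= two >= single, got "
                f"{self.ai_line_mm:.3f} / {self.two_line_mm:.3f} / "
                f"{self.single_line_mm:.3f}"
            )


def _skeleton_graph(skel: np.ndarray):
    """Sparse 8-connected graph over skeleton pixels; weights in px."""
    coords = np.column_stack(np.nonzero(skel))
    index = -np.ones(skel.shape, dtype=np.int64)
    index[tuple(coords.T)] = np.arange(len(coords))
    rows_i, cols_j, weights = [], [], []
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    h, w = skel.shape
    for dr, dc in offsets:
        rr = coords[:, 0] + dr
        cc = coords[:, 1] + dc
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        src = np.nonzero(ok)[0]
        nb = index[rr[ok], cc[ok]]
        hit = nb >= 0
        rows_i.append(src[hit])
        cols_j.append(nb[hit])
        weights.append(np.full(int(hit.sum()), np.hypot(dr, dc)))
    g = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows_i), np.concatenate(cols_j))),
        shape=(len(coords), len(coords)),
    ).tocsr()
    return coords, g


SMOOTH_SPAN_MM = 1.2  # physical span of the default moving-average window


def _resolve_window(smooth_window, spacing) -> int:
    if smooth_window != "auto":
        return int(smooth_window)
    mean_sp = float(np.mean(spacing))
    return max(3, int(round(SMOOTH_SPAN_MM / mean_sp)) | 1)


def extract_trace(mask: CanalMask, smooth_window="auto") -> CanalTrace:
    """Trace the canal centerline of the largest mask component.

    The skeleton's endpoints (pixels with exactly one skeleton
    neighbour) are candidates for the os ends; the pair at maximal
    geodesic separation is chosen — which prunes short spurs for free
    — and the shortest skeleton path between them, optionally smoothed
    by a centered moving average (endpoints pinned), is the trace.

    ``smooth_window`` is an odd point count, 1 to disable, or "auto"
    (default) for a window spanning about ``SMOOTH_SPAN_MM`` of trace
    regardless of pixel spacing.
    """
    return _extract_trace_impl(mask, smooth_window)[0]


def _extract_trace_impl(mask: CanalMask, smooth_window):
    pix = np.asarray(mask.pixels, dtype=bool)
    if not pix.any():
        raise TraceError("mask is empty; nothing to trace")

    labels, n_comp = label(pix, connectivity=2, return_num=True)
    if n_comp > 1:
        largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
        pix = labels == largest
    skel = skeletonize(pix)
    coords, graph = _skeleton_graph(skel)
    if len(coords) < 2:
        raise TraceError("skeleton degenerate (fewer than two pixels)")

    degree = (graph > 0).sum(axis=1).A1 if hasattr((graph > 0).sum(axis=1), "A1") \
        else np.asarray((graph > 0).sum(axis=1)).ravel()
    endpoints = np.nonzero(degree == 1)[0]
    if len(endpoints) < 2:
        raise TraceError(
            "skeleton has no endpoint pair (closed loop?); cannot orient a trace"
        )

    dist = dijkstra(graph, indices=endpoints, return_predecessors=False)
    sub = dist[:, endpoints]
    sub[~np.isfinite(sub)] = -1.0
    i, j = np.unravel_index(np.argmax(sub), sub.shape)
    start, goal = endpoints[i], endpoints[j]

    _, pred = dijkstra(graph, indices=start, return_predecessors=True)
    path = [goal]
    while path[-1] != start:
        p = pred[path[-1]]
        if p < 0:
            raise TraceError("skeleton endpoints are disconnected")
        path.append(p)
    pts = coords[np.asarray(path[::-1])].astype(float)

    # canonical orientation: first endpoint at the leftmost column
    if (pts[0, 1], pts[0, 0]) > (pts[-1, 1], pts[-1, 0]):
        pts = pts[::-1]

    pts = _extend_to_os(pts, pix)

    window = _resolve_window(smooth_window, mask.pixel_spacing_mm)
    if window > 1 and len(pts) > 2:
        pts = _smooth_trace(pts, window)

    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
    pts = pts[keep]

    trace = CanalTrace(pts, mask.pixel_spacing_mm)
    return trace, n_comp


def _extend_to_os(pts: np.ndarray, pix: np.ndarray) -> np.ndarray:
    """Align each trace end with the canal's os.

    The skeleton's ends are biased: on wide canals skeletonization
    erodes them short of the os, on very narrow canals they can poke
    past it into the rounded end cap.  The os is where the distance
    transform drops off the medial ridge, so each end is first
    retracted to the local ridge level and then advanced along its
    tangent while the ridge level holds (tolerance 0.6 px; the drop
    beyond the os has unit slope, so ends land within about half a
    pixel of the os).
    """
    from scipy.ndimage import distance_transform_edt

    edt = distance_transform_edt(pix)
    h, w = pix.shape

    def edt_at(p):
        r = min(max(p[0], 0.0), h - 1.001)
        c = min(max(p[1], 0.0), w - 1.001)
        r0, c0 = int(r), int(c)
        fr, fc = r - r0, c - c0
        return ((1 - fr) * (1 - fc) * edt[r0, c0]
                + (1 - fr) * fc * edt[r0, c0 + 1]
                + fr * (1 - fc) * edt[r0 + 1, c0]
                + fr * fc * edt[r0 + 1, c0 + 1])

    tol = 0.6
    step = 0.5

    def fix_end(ordered):
        """ordered[0] is the end being adjusted."""
        interior = ordered[3:13] if len(ordered) > 6 else ordered
        ridge = float(np.median([edt_at(p) for p in interior]))
        # retract while the end sits below the ridge (inside the cap)
        drop = 0
        while drop < min(6, len(ordered) - 2) and \
                edt_at(ordered[drop]) < ridge - tol:
            drop += 1
        ordered = ordered[drop:]
        end = ordered[0]
        k = min(5, len(ordered) - 1)
        tangent = end - ordered[k]
        norm = np.linalg.norm(tangent)
        if norm < 1e-9:
            return ordered
        tangent = tangent / norm
        extra = []
        pos = end.copy()
        for _ in range(2 * int(np.ceil(ridge)) + 4):
            cand = pos + step * tangent
            ri, ci = int(round(cand[0])), int(round(cand[1]))
            if not (0 <= ri < h and 0 <= ci < w) or not pix[ri, ci]:
                break
            if edt_at(cand) < ridge - tol:
                break
            extra.append(cand.copy())
            pos = cand
        if extra:
            ordered = np.vstack([np.asarray(extra[::-1]), ordered])
        return ordered

    pts = fix_end(pts)
    pts = fix_end(pts[::-1])[::-1]
    return pts


def _smooth_trace(pts: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average of interior points; endpoints pinned."""
    half = window // 2
    out = pts.copy()
    n = len(pts)
    csum = np.vstack([np.zeros((1, 2)), np.cumsum(pts, axis=0)])
    for i in range(1, n - 1):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def _seglen_mm(a: np.ndarray, b: np.ndarray, spacing) -> float:
    d = (np.asarray(b) - np.asarray(a)) * np.asarray(spacing)
    return float(np.hypot(d[0], d[1]))


def single_line(trace: CanalTrace) -> float:
    """Straight internal-to-external-os distance in mm."""
    return _seglen_mm(trace.points[0], trace.points[-1], trace.pixel_spacing_mm)


def two_line(trace: CanalTrace) -> tuple[float, int]:
    """Sum of the two chords meeting at the greatest-curvature point.

    The apex is the trace point with maximum perpendicular distance
    from the endpoint chord (ties resolved toward the internal-os
    end); returns (length_mm, apex_index).
    """
    pm = trace.points_mm
    a, b = pm[0], pm[-1]
    chord = b - a
    norm = np.linalg.norm(chord)
    if norm < 1e-12:
        apex = len(pm) // 2
    else:
        rel = pm - a
        perp = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / norm
        apex = int(np.argmax(perp))  # argmax takes the first (internal-side) tie
    length = float(np.linalg.norm(pm[apex] - a) + np.linalg.norm(b - pm[apex]))
    return length, apex


def ai_line(trace: CanalTrace) -> float:
    """Polyline arc length of the traced centerline in mm."""
    pm = trace.points_mm
    return float(np.sum(np.linalg.norm(np.diff(pm, axis=0), axis=1)))


def measure_all(mask: CanalMask, smooth_window="auto") -> CLMeasurement:
    """Run the trace once and report all three lengths with flags."""
    trace, n_comp = _extract_trace_impl(mask, smooth_window)
    two, apex = two_line(trace)
    return CLMeasurement(
        single_line_mm=single_line(trace),
        two_line_mm=two,
        ai_line_mm=ai_line(trace),
        apex_index=apex,
        n_components_merged=n_comp,
        trace_point_count=len(trace.points),
    )
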