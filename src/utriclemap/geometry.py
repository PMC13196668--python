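"""Canonical unit-circle polar frame for utricle cell maps.

Every organ's cell centroids are recentered, outlined by a concave hull,
fitted to an ellipse, and rotated so the ellipse's major axis becomes the
x-axis; each cell's radius is then normalized by the distance to the
convex-hull boundary along its ray, mapping the organ onto the unit disk.
In the canonical frame the zonal boundary runs along the 0-180 degree
line and the medial (extrastriolar) half occupies theta in (180, 360).

The fitted orientation is only defined modulo 180 degrees and reflections,
so two deterministic rules resolve the residual ambiguity: the organ is
flipped across the major axis so the majority of extrastriolar-marker-
positive cells land in the (180, 360) half, and flipped along the major
axis so the third moment of the x-coordinates is non-negative.  Together
these make the normalized frame invariant to rotation, translation,
uniform scaling and mirroring of the input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from shapely.geometry import LineString, Point, Polygon


@dataclass(frozen=True)
class EllipseFit:
    """Geometric ellipse parameters: center, semi-axes (a >= b), orientation
    of the major axis from +x in radians, phi in [0, pi)."""

    center_xy: tuple[float, float]
    semi_major: float
    semi_minor: float
    phi: float

    def __post_init__(self) -> None:
        if not self.semi_major >= self.semi_minor > 0:
            raise ValueError("require semi_major >= semi_minor > 0")
        if not 0 <= self.phi < math.pi:
            raise ValueError("phi must be in [0, pi)")


@dataclass(frozen=True)
class SectorSpec:
    """Angular sectors as half-open degree intervals [start, end).

    An interval with start > end wraps through 0/360.  ``null_fraction``
    is the arc fraction under a uniform angular null.
    """

    intervals: tuple[tuple[float, float], ...]
    name: str = ""

    @property
    def null_fraction(self) -> float:
        total = 0.0
        for lo, hi in self.intervals:
            total += (hi - lo) % 360 if lo != hi else 0.0
        return total / 360.0

    def contains(self, theta_deg) -> np.ndarray:
        t = np.asarray(theta_deg, dtype=float) % 360.0
        mask = np.zeros(t.shape, dtype=bool)
        for lo, hi in self.intervals:
            if lo <= hi:
                mask |= (t >= lo) & (t < hi)
            else:  # wraps through 0
                mask |= (t >= lo) | (t < hi)
        return mask


#: medial / extrastriolar half of the canonical plot
MEDIAL_HALF = SectorSpec(((180.0, 360.0),), name="medial_half")
#: lateral / striolar half
LATERAL_HALF = SectorSpec(((0.0, 180.0),), name="lateral_half")
#: quarter of the disk within 22.5 degrees of the 0/180 zonal-boundary axis
BOUNDARY_QUARTER = SectorSpec(((157.5, 202.5), (337.5, 22.5)), name="boundary_quarter")


def compute_center(centroids, method: str = "mean") -> np.ndarray:
    """Organ center: arithmetic mean of centroids (default) or the area
    centroid of their convex hull (``method='hull_centroid'``)."""
    pts = np.atleast_2d(np.asarray(centroids, dtype=float))
    if pts.size == 0:
        raise ValueError("no centroids")
    if method == "mean":
        return pts.mean(axis=0)
    if method == "hull_centroid":
        hull = ConvexHull(pts)
        poly = Polygon(pts[hull.vertices])
        return np.array([poly.centroid.x, poly.centroid.y])
    raise ValueError(f"unknown center method '{method}'")


# ---------------------------------------------------------------------------
# concave hull (k-nearest-neighbours gift wrapping)

def _segments_properly_intersect(p1, p2, q1, q2) -> bool:
    """True if open segments (p1,p2) and (q1,q2) cross, ignoring shared
    endpoints."""

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if abs(v) < 1e-12:
            return 0
        return 1 if v > 0 else -1

    for a, b in ((p1, p2), (p2, p1)):
        for c in (q1, q2):
            if abs(a[0] - c[0]) < 1e-12 and abs(a[1] - c[1]) < 1e-12:
                return False  # shared endpoint
    d1 = orient(q1, q2, p1)
    d2 = orient(q1, q2, p2)
    d3 = orient(p1, p2, q1)
    d4 = orient(p1, p2, q2)
    return d1 != d2 and d3 != d4 and 0 not in (d1, d2, d3, d4)


def _convex_hull_polygon(pts: np.ndarray) -> np.ndarray:
    hull = ConvexHull(pts)
    return pts[hull.vertices]


def _knn_hull_attempt(pts: np.ndarray, k: int) -> np.ndarray | None:
    """One Moreira-Santos gift-wrapping pass; None on failure.

    The start vertex (farthest point from the centroid, always on the
    convex hull) and the initial heading (perpendicular to its outward
    radial) are chosen relative to the point cloud itself so the traversal
    is equivariant under rotation, translation and uniform scaling.
    """
    n = len(pts)
    centroid = pts.mean(axis=0)
    start = int(np.argmax(np.hypot(*(pts - centroid).T)))
    hull_idx = [start]
    avail = set(range(n))
    avail.discard(start)
    current = start
    # fictitious previous point placed so the first step goes counter-
    # clockwise around the centroid
    alpha = math.atan2(pts[start][1] - centroid[1], pts[start][0] - centroid[0])
    prev_angle = (alpha - math.pi / 2.0) % (2 * math.pi)
    step = 1
    while True:
        if step == 4:
            avail.add(start)  # allow the ring to close
        if not avail:
            return None
        cand = sorted(avail, key=lambda i: np.hypot(*(pts[i] - pts[current])))[:k]
        # largest clockwise turn from the reversed incoming edge first
        def turn(i):
            a = math.atan2(pts[i][1] - pts[current][1], pts[i][0] - pts[current][0])
            return (prev_angle - a) % (2 * math.pi)

        cand.sort(key=turn, reverse=True)
        chosen = None
        for i in cand:
            closing = i == start
            new_edge = (pts[current], pts[i])
            ok = True
            last = len(hull_idx) - 1
            for m in range(last):
                if m == last - 1:
                    continue  # edge incident to current
                if closing and m == 0:
                    continue  # edge incident to the start point
                if _segments_properly_intersect(
                    new_edge[0], new_edge[1], pts[hull_idx[m]], pts[hull_idx[m + 1]]
                ):
                    ok = False
                    break
            if ok:
                chosen = i
                break
        if chosen is None:
            return None
        if chosen == start:
            break
        hull_idx.append(chosen)
        avail.discard(chosen)
        prev_angle = math.atan2(
            pts[current][1] - pts[chosen][1], pts[current][0] - pts[chosen][0]
        )
        current = chosen
        step += 1
        if step > 2 * n + 10:
            return None
    if len(hull_idx) < 3:
        return None
    return pts[np.array(hull_idx)]


def _skew_invariant(pts: np.ndarray) -> float:
    """Hu's seventh moment invariant of a point set: invariant under
    rotation, translation and uniform scaling; changes sign under
    reflection.  Used to pick a canonical chirality before hulling."""
    q = pts - pts.mean(axis=0)
    n = float(len(q))
    x, y = q[:, 0], q[:, 1]

    def eta(p_, q_):
        mu = float(np.sum(x**p_ * y**q_))
        return mu / n ** (1.0 + (p_ + q_) / 2.0)

    e30, e21, e12, e03 = eta(3, 0), eta(2, 1), eta(1, 2), eta(0, 3)
    s, t = e30 + e12, e21 + e03
    return (3 * e21 - e03) * s * (s * s - 3 * t * t) - (e30 - 3 * e12) * t * (
        3 * s * s - t * t
    )


def concave_hull(points, k_neighbors: int = 3) -> np.ndarray:
    """Concave hull of a 2D point set by KNN gift wrapping.

    k escalates automatically until a simple polygon containing every
    point is found; at k >= n-1 the convex hull is returned.  Duplicate
    points are removed first.  The point set is first reflected to a
    canonical chirality (sign of Hu's skew moment invariant) and the
    result reflected back, so mirrored inputs yield exactly mirrored
    hulls.  Returns the hull vertices in traversal order (open ring,
    Nx2).
    """
    raw = np.unique(np.asarray(points, dtype=float).reshape(-1, 2), axis=0)
    if len(raw) >= 3 and _skew_invariant(raw) < 0:
        flipped = raw.copy()
        flipped[:, 1] = -flipped[:, 1]
        ring = concave_hull(flipped, k_neighbors)
        ring = ring.copy()
        ring[:, 1] = -ring[:, 1]
        return ring
    pts = raw
    if len(pts) < 3:
        raise ValueError("need at least 3 distinct points")
    spread = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(spread, tol=1e-9 * (1 + np.abs(spread).max())) < 2:
        raise ValueError("points are collinear")
    if len(pts) == 3:
        return pts
    k = max(3, int(k_neighbors))
    while k < len(pts) - 1:
        ring = _knn_hull_attempt(pts, k)
        if ring is not None:
            poly = Polygon(ring)
            if poly.is_valid and poly.area > 0:
                eps = 1e-9 * max(poly.bounds[2] - poly.bounds[0], 1.0)
                if all(poly.buffer(eps).covers(Point(p)) for p in pts):
                    return ring
        k += 1
    return _convex_hull_polygon(pts)


# ---------------------------------------------------------------------------
# ellipse fitting and canonicalization

def fit_ellipse(vertices) -> EllipseFit:
    """Direct least-squares conic fit (ellipse-constrained) to polygon
    vertices; returns geometric parameters with a >= b and phi in [0, pi)."""
    from skimage.measure import EllipseModel

    pts = np.asarray(vertices, dtype=float).reshape(-1, 2)
    if len(pts) < 5:
        raise ValueError("ellipse fit needs at least 5 vertices")
    model = EllipseModel.from_estimate(pts)
    if not model:
        raise ValueError("degenerate conic: could not fit an ellipse")
    (xc, yc), (a, b), phi = model.center, model.axis_lengths, float(model.theta)
    xc, yc, a, b = float(xc), float(yc), float(a), float(b)
    if not (np.isfinite([xc, yc, a, b, phi]).all() and a > 0 and b > 0):
        raise ValueError("degenerate conic: could not fit an ellipse")
    if b > a:
        a, b = b, a
        phi += math.pi / 2.0
    phi %= math.pi
    return EllipseFit(center_xy=(xc, yc), semi_major=a, semi_minor=b, phi=phi)


def canonicalize(
    points,
    ellipse: EllipseFit,
    es_positive=None,
    orientation_policy: str = "marker-majority",
    flip_across_major: bool = False,
    flip_along_major: bool = False,
) -> np.ndarray:
    """Rotate/center points so the ellipse major axis is the x-axis.

    ``orientation_policy='marker-majority'`` (default) flips the organ
    across the major axis so most extrastriolar-marker-positive cells
    (boolean ``es_positive``) have theta in (180, 360), then flips along
    the major axis so the third moment of x is non-negative.  With
    ``'explicit'`` the two boolean flags are applied verbatim instead
    (needed e.g. for marker-free control images).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    q = pts - np.asarray(ellipse.center_xy)
    c, s = math.cos(-ellipse.phi), math.sin(-ellipse.phi)
    rot = np.array([[c, -s], [s, c]])
    q = q @ rot.T

    if orientation_policy == "explicit":
        if flip_across_major:
            q[:, 1] = -q[:, 1]
        if flip_along_major:
            q[:, 0] = -q[:, 0]
        return q
    if orientation_policy != "marker-majority":
        raise ValueError(f"unknown orientation policy '{orientation_policy}'")

    es = np.asarray(es_positive, dtype=bool) if es_positive is not None else None
    if es is None or es.sum() == 0:
        raise ValueError(
            "marker-majority orientation needs at least one extrastriolar-"
            "marker-positive cell; pass orientation_policy='explicit' with "
            "flip flags for marker-free images"
        )
    if np.mean(q[es, 1] < 0) < 0.5:  # medial half is y < 0 (theta 180-360)
        q[:, 1] = -q[:, 1]
    if np.sum(q[:, 0] ** 3) < 0:  # deterministic anterior-posterior chirality
        q[:, 0] = -q[:, 0]
    return q


def unit_circle_normalize(points, hull_points=None) -> tuple[np.ndarray, np.ndarray]:
    """Map canonical points onto the unit disk.

    For each point, r = (distance from origin) / (distance from origin to
    the convex-hull boundary along the same ray); theta is preserved.
    Returns (theta_deg in [0, 360), r in [0, 1]).  The hull defaults to
    the convex hull of the points themselves and must contain the origin.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if hull_points is None:
        if len(pts) < 3:
            raise ValueError("need at least 3 points to build a boundary hull")
        hull_points = _convex_hull_polygon(pts)
    hull_points = np.asarray(hull_points, dtype=float).reshape(-1, 2)
    poly = Polygon(hull_points)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("invalid hull polygon")
    if not poly.covers(Point(0.0, 0.0)):
        raise ValueError("origin lies outside the boundary hull")
    boundary = poly.exterior
    reach = 2.0 * float(np.abs(hull_points).max()) + 1.0

    theta = np.zeros(len(pts))
    r = np.zeros(len(pts))
    for i, (x, y) in enumerate(pts):
        d = math.hypot(x, y)
        if d == 0.0:
            continue
        ang = math.atan2(y, x)
        ray = LineString([(0.0, 0.0), (reach * math.cos(ang), reach * math.sin(ang))])
        inter = ray.intersection(boundary)
        if inter.is_empty:
            raise ValueError("ray missed the hull boundary (point outside hull?)")
        dists = [
            math.hypot(g.x, g.y)
            for g in (inter.geoms if hasattr(inter, "geoms") else [inter])
            if isinstance(g, Point)
        ]
        if not dists:  # ray overlaps a boundary edge
            coords = np.asarray(inter.coords)
            dists = [math.hypot(px, py) for px, py in coords]
        dmax = max(dists)
        r[i] = min(d / dmax, 1.0)
        theta[i] = math.degrees(ang) % 360.0
    return theta, r


def sector_fraction(theta_deg, sector: SectorSpec, mask=None) -> tuple[int, int]:
    """Count cells whose angle lies in the sector.

    ``mask`` restricts to a cell subset (e.g. one hair-cell type).
    Returns (k in-sector, n total in subset); (0, 0) signals an empty
    subset.
    """
    t = np.asarray(theta_deg, dtype=float)
    if mask is not None:
        t = t[np.asarray(mask, dtype=bool)]
    n = int(t.size)
    if n == 0:
        return 0, 0
    return int(sector.contains(t).sum()), n


def normalize_organ(
    table: pd.DataFrame,
    es_call_column: str = "es_call",
    orientation_policy: str = "marker-majority",
    flip_across_major: bool = False,
    flip_along_major: bool = False,
    center_method: str = "mean",
    concave_k: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Full geometric pipeline for one organ's classified cell table.

    Recenters centroids, builds the concave hull, fits the ellipse,
    canonicalizes, and unit-circle-normalizes.  Returns the table with
    added ``theta_deg``/``r`` columns plus a geometry record (center,
    ellipse, hull vertices).
    """
    pts = table[["x", "y"]].to_numpy(dtype=float)
    center = compute_center(pts, method=center_method)
    recentered = pts - center
    hull = concave_hull(recentered, k_neighbors=concave_k)
    ellipse = fit_ellipse(hull)
    es = (
        table[es_call_column].to_numpy(dtype=bool)
        if es_call_column in table.columns
        else None
    )
    canonical = canonicalize(
        recentered,
        ellipse,
        es_positive=es,
        orientation_policy=orientation_policy,
        flip_across_major=flip_across_major,
        flip_along_major=flip_along_major,
    )
    theta, r = unit_circle_normalize(canonical)
    out = table.copy()
    out["theta_deg"] = theta
    out["r"] = r
    geometry = {
        "center": center.tolist(),
        "ellipse": {
            "center_xy": list(ellipse.center_xy),
            "semi_major": ellipse.semi_major,
            "semi_minor": ellipse.semi_minor,
            "phi_rad": ellipse.phi,
        },
        "hull_vertices": hull.tolist(),
    }
    return out, geometry
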