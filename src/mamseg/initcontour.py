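"""Radial maximum-gradient initial level-set contour.

From a reference point near the centre of the innermost band contour,
uniformly spaced radial lines are cast through the dense band of iso-level
contours.  On each ray the intersection with the strongest gradient is kept;
its distance to the reference point is the radial distance r_i.  Radii that
are statistical outliers (r_i >= r_ave + n * r_std, n in {1, 2}) are pulled
back to the mean radius, which clips spurious background hits.  The ordered
hit points form the proposed initial contour for level-set evolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from shapely.geometry import LineString

from .errors import GeometryError, ParameterError
from .isolevel import SearchBand

__all__ = [
    "RadialProfile",
    "Contour",
    "radial_profile",
    "clip_profile",
    "profile_to_contour",
    "manual_contour",
]


@dataclass
class RadialProfile:
    """Radial distances and max-gradient hit points on m uniform rays."""

    ref_point: np.ndarray          # (x, y)
    angles: np.ndarray             # (m,), radians, ascending in [0, 2*pi)
    radii: np.ndarray              # (m,), pixels, > 0
    hit_points: np.ndarray         # (m, 2) (x, y)
    interpolated: np.ndarray       # (m,) bool: True where no ray intersection existed
    n_sigma: int | None = None     # clipping level applied, None if unclipped


@dataclass
class Contour:
    """A closed simple polyline (first point repeated as the last)."""

    points: np.ndarray             # (k+1, 2), points[0] == points[-1]
    source: str = "proposed"       # "proposed" or "manual"

    @property
    def vertices(self) -> np.ndarray:
        """The k distinct vertices (closure point dropped)."""
        return self.points[:-1]


def _first_self_intersection(pts: np.ndarray) -> tuple[int, int] | None:
    """Indices of the first pair of non-adjacent crossing segments, or None."""
    n = len(pts) - 1
    for i in range(n):
        a, b = pts[i], pts[i + 1]
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # closing segment shares the first vertex
            c, d = pts[j], pts[j + 1]
            e, f = b - a, d - c
            den = e[0] * f[1] - e[1] * f[0]
            if abs(den) < 1e-15:
                continue
            g = c - a
            t = (g[0] * f[1] - g[1] * f[0]) / den
            s = (g[0] * e[1] - g[1] * e[0]) / den
            if 1e-12 < t < 1 - 1e-12 and 1e-12 < s < 1 - 1e-12:
                return i, j
    return None


def _ray_segment_hits(ref, direction, p0, p1):
    """Vectorized ray / segment intersections.

    Returns distances t (> 0) along the ray for every segment the ray
    crosses, as a 1-D array (possibly empty).
    """
    e = p1 - p0                      # (K, 2)
    b = p0 - ref                     # (K, 2)
    den = e[:, 0] * direction[1] - e[:, 1] * direction[0]   # cross(e, d)
    ok = np.abs(den) > 1e-12
    t = np.empty(len(e))
    s = np.empty(len(e))
    t[ok] = (e[ok, 0] * b[ok, 1] - e[ok, 1] * b[ok, 0]) / den[ok]
    s[ok] = (direction[0] * b[ok, 1] - direction[1] * b[ok, 0]) / den[ok]
    hit = ok & (t > 1e-9) & (s >= 0.0) & (s <= 1.0)
    return t[hit]


def radial_profile(band: SearchBand, grad_mag: np.ndarray, m: int = 360) -> RadialProfile:
    """Cast m uniform rays from the band centre and keep max-gradient hits.

    The reference point is the polygon centroid of the innermost band
    contour.  Every ray/contour-segment intersection is sampled on
    ``grad_mag`` by bilinear interpolation; per ray the intersection with
    the largest gradient wins, with ties broken toward the reference point.
    Rays with no intersection get a radius linearly interpolated (circularly)
    from their angular neighbours and are flagged.

    Raises
    ------
    GeometryError
        If the reference point falls outside the image.
    """
    if m < 8:
        raise ParameterError("m must be >= 8")
    grad_mag = np.asarray(grad_mag, dtype=float)
    h, w = grad_mag.shape
    ref = np.asarray(band.innermost.polygon.centroid.coords[0], dtype=float)
    if not (0 <= ref[0] <= w - 1 and 0 <= ref[1] <= h - 1):
        raise GeometryError(f"reference point {tuple(ref)} outside image")

    p0 = np.vstack([c.vertices[:-1] for c in band.contours])
    p1 = np.vstack([c.vertices[1:] for c in band.contours])

    angles = 2 * np.pi * np.arange(m) / m
    radii = np.full(m, np.nan)
    hits = np.full((m, 2), np.nan)
    missing = np.zeros(m, dtype=bool)
    for k, th in enumerate(angles):
        d = np.array([np.cos(th), np.sin(th)])
        ts = _ray_segment_hits(ref, d, p0, p1)
        if ts.size == 0:
            missing[k] = True
            continue
        ts = np.sort(ts)
        pts = ref[None, :] + ts[:, None] * d[None, :]
        g = map_coordinates(grad_mag, [pts[:, 1], pts[:, 0]], order=1, mode="nearest")
        best = np.flatnonzero(g >= g.max() - 1e-12)[0]  # tie: nearest to ref
        radii[k] = ts[best]
        hits[k] = pts[best]

    if missing.all():
        raise GeometryError("no ray intersects the search band")
    if missing.any():
        ok = np.flatnonzero(~missing)
        radii[missing] = np.interp(
            angles[missing], angles[ok], radii[ok], period=2 * np.pi
        )
        d = np.stack([np.cos(angles[missing]), np.sin(angles[missing])], axis=1)
        hits[missing] = ref[None, :] + radii[missing, None] * d
    return RadialProfile(
        ref_point=ref, angles=angles, radii=radii, hit_points=hits,
        interpolated=missing,
    )


def clip_profile(profile: RadialProfile, n: int = 1) -> RadialProfile:
    """Statistically clip outlier radii.

    With r_ave the mean radius and r_std the sample standard deviation
    (m - 1 denominator), every radius with r_i >= r_ave + n * r_std is
    replaced by r_ave (its hit point is recomputed at that distance along
    the same ray); all other radii pass through unchanged.  ``n`` is 1 or 2.
    """
    if n not in (1, 2):
        raise ParameterError("n must be 1 or 2")
    r = np.asarray(profile.radii, dtype=float)
    if r.size < 2:
        raise ParameterError("at least 2 radii required (sample std undefined)")
    r_ave = r.mean()
    r_std = r.std(ddof=1)
    cutoff = r_ave + n * r_std
    replaced = r >= cutoff
    new_r = np.where(replaced, r_ave, r)
    d = np.stack([np.cos(profile.angles), np.sin(profile.angles)], axis=1)
    new_hits = profile.ref_point[None, :] + new_r[:, None] * d
    new_hits[~replaced] = profile.hit_points[~replaced]
    return RadialProfile(
        ref_point=profile.ref_point, angles=profile.angles, radii=new_r,
        hit_points=new_hits, interpolated=profile.interpolated, n_sigma=n,
    )


def profile_to_contour(profile: RadialProfile) -> Contour:
    """Order the hit points by angle and close them into the initial contour.

    Raises
    ------
    GeometryError
        If the closed polygon self-intersects; the angle (degrees) of the
        first offending vertex is reported.
    """
    order = np.argsort(profile.angles)
    pts = profile.hit_points[order]
    closed = np.vstack([pts, pts[:1]])
    if not LineString(closed).is_simple:
        bad = _first_self_intersection(closed)
        ang = np.degrees(profile.angles[order][bad[0]]) if bad else float("nan")
        raise GeometryError(f"initial contour self-intersects near angle {ang:.1f} deg")
    return Contour(points=closed, source="proposed")


def manual_contour(points) -> Contour:
    """Validate a user-supplied polygon and return it as a closed contour.

    Requires at least 3 distinct vertices and a simple (non-self-
    intersecting) outline; an already-closed input (first == last point)
    is accepted.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError("points must be an (k, 2) array of (x, y)")
    if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 3:
        raise ParameterError("a contour needs at least 3 distinct points")
    closed = np.vstack([pts, pts[:1]])
    if not LineString(closed).is_simple:
        raise GeometryError("manual contour self-intersects")
    return Contour(points=closed, source="manual")
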