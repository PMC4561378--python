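"""Iso-level decomposition of a smoothed mass image.

The smoothed image is read as a topological surface and thresholded with an
ordered set of equally spaced levels.  The sub-level region at threshold t is
R(t) = {(x, y) | I(x, y) <= t}; its boundaries are closed iso-level contours.
Because sub-level sets are monotone in t, the contours nest, and around a
sharp mass margin many consecutive thresholds cross the same steep intensity
ramp — their contours crowd into a dense band.  That band is the search space
in which the initial level-set contour is placed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon
from skimage import measure
from skimage.draw import polygon_perimeter
from skimage.morphology import closing, disk

from .errors import DegenerateImageError, ParameterError, SearchBandNotFoundError
from .preprocess import as_gray_image

__all__ = [
    "ThresholdSet",
    "IsoContour",
    "IsoLevelMap",
    "SearchBand",
    "compute_thresholds",
    "iso_level_map",
    "extract_search_band",
]


@dataclass
class ThresholdSet:
    """Equally spaced partition weights and the thresholds T = I_max * W."""

    weights: np.ndarray  # ascending, in (0, 1]
    values: np.ndarray   # thresholds, same length
    n_levels: int        # number of thresholds requested (before any drop)


@dataclass
class IsoContour:
    """One closed iso-level contour (sub-pixel marching-squares polyline)."""

    id: int
    level: float
    vertices: np.ndarray  # (k, 2) array of (x, y); first vertex == last
    polygon: Polygon = field(repr=False)

    @property
    def area(self) -> float:
        return self.polygon.area


@dataclass
class IsoLevelMap:
    """All closed iso-level contours plus their nesting forest.

    ``parent[cid]`` is the id of the smallest contour strictly enclosing
    contour ``cid``, or ``None`` for roots.  The forest is acyclic by
    construction (each parent has strictly larger area).
    """

    contours: list[IsoContour]
    parent: dict[int, int | None]
    shape: tuple[int, int]

    def by_id(self, cid: int) -> IsoContour:
        return next(c for c in self.contours if c.id == cid)

    def children(self, cid: int | None) -> list[int]:
        return [c.id for c in self.contours if self.parent[c.id] == cid]

    def roots(self) -> list[int]:
        return self.children(None)


@dataclass
class SearchBand:
    """A dense chain of nested iso-level contours around the mass margin."""

    contours: list[IsoContour]  # ordered outermost -> innermost
    mask: np.ndarray            # binary band mask (closing of member outlines)
    innermost: IsoContour


def compute_thresholds(img, n_levels: int = 24) -> ThresholdSet:
    """Build the threshold set T = I_max * W, W = {k/N : k = 1..N}.

    Thresholds below the image minimum select empty sub-level regions; they
    are dropped with a warning so the returned set satisfies t_1 >= I_min.

    Raises
    ------
    DegenerateImageError
        If the image is spatially constant (I_max == I_min).
    """
    if n_levels < 2:
        raise ParameterError("n_levels must be >= 2")
    a = as_gray_image(img)
    imax, imin = float(a.max()), float(a.min())
    if imax == imin:
        raise DegenerateImageError("flat image: I_max == I_min")
    weights = np.arange(1, n_levels + 1, dtype=float) / n_levels
    values = imax * weights
    keep = values >= imin
    if not np.all(keep):
        warnings.warn(
            f"dropped {int((~keep).sum())} thresholds below I_min={imin:.4g}",
            stacklevel=2,
        )
    return ThresholdSet(weights=weights[keep], values=values[keep], n_levels=n_levels)


def _closed_contours_at(a: np.ndarray, level: float, min_vertices: int):
    """Closed marching-squares contours of {I <= level}, as (x, y) polylines."""
    out = []
    for rc in measure.find_contours(a, level):
        if len(rc) < min_vertices:
            continue
        if not np.allclose(rc[0], rc[-1]):
            continue  # open contour touching the border: not a closed region boundary
        xy = rc[:, ::-1].copy()  # (row, col) -> (x, y)
        poly = Polygon(xy)
        if not poly.is_valid or poly.area <= 0:
            poly = poly.buffer(0)
            if poly.is_empty or poly.geom_type != "Polygon":
                continue
        out.append((xy, poly))
    return out


def iso_level_map(img, thresholds: ThresholdSet, min_vertices: int = 8) -> IsoLevelMap:
    """Extract closed iso-level contours at every threshold and nest them.

    Contours are traced by marching squares at each level (sub-pixel
    coordinates retained); contours with fewer than ``min_vertices`` points
    are discarded.  Nesting uses point-in-polygon containment of a
    representative interior point: the parent of a contour is the
    smallest-area contour strictly enclosing it.
    """
    a = as_gray_image(img)
    contours: list[IsoContour] = []
    cid = 0
    for level in np.asarray(thresholds.values, dtype=float):
        for xy, poly in _closed_contours_at(a, level, min_vertices):
            contours.append(IsoContour(id=cid, level=float(level), vertices=xy, polygon=poly))
            cid += 1

    parent: dict[int, int | None] = {}
    order = sorted(contours, key=lambda c: c.area)
    for i, c in enumerate(order):
        rep = c.polygon.representative_point()
        best = None
        for other in order[i + 1:]:  # strictly larger area candidates only
            if other.area <= c.area:
                continue
            if other.polygon.contains(rep):
                best = other.id
                break  # sorted by area: first hit is the smallest enclosing
        parent[c.id] = best
    return IsoLevelMap(contours=contours, parent=parent, shape=a.shape)


def _mean_radius(contour: IsoContour, ref: np.ndarray) -> float:
    v = contour.vertices[:-1]
    return float(np.mean(np.hypot(v[:, 0] - ref[0], v[:, 1] - ref[1])))


def _chains(iso: IsoLevelMap) -> list[list[int]]:
    """All root-to-leaf paths of the nesting forest (outermost first)."""
    paths = []

    def walk(cid, acc):
        acc = acc + [cid]
        kids = iso.children(cid)
        if not kids:
            paths.append(acc)
        else:
            for k in kids:
                walk(k, acc)

    for r in iso.roots():
        walk(r, [])
    return paths


def extract_search_band(
    iso: IsoLevelMap, min_run: int = 5, max_gap: float = 3.0, closing_radius: int = 3
) -> SearchBand:
    """Extract the dense nested band of iso-level contours.

    Within each maximal nesting chain, consecutive contours are "dense"
    where the gap between their mean radii (about the chain's outermost
    contour centroid) is at most ``max_gap`` pixels.  The longest dense run
    across all chains, if it has at least ``min_run`` contours, becomes the
    band.  Uniformly spaced contours (e.g. a linear intensity ramp) have no
    sub-``max_gap`` gaps at typical level counts and are rejected.

    The band mask is the morphological closing of the union of the member
    contour outlines, so it always covers the innermost member contour.

    Raises
    ------
    SearchBandNotFoundError
        If no chain contains a dense run of at least ``min_run`` contours.
    """
    if min_run < 2:
        raise ParameterError("min_run must be >= 2")
    best: list[int] | None = None
    for path in _chains(iso):
        if len(path) < min_run:
            continue
        outer = iso.by_id(path[0])
        ref = np.asarray(outer.polygon.centroid.coords[0])
        radii = [_mean_radius(iso.by_id(cid), ref) for cid in path]
        gaps = np.abs(np.diff(radii))
        dense = gaps <= max_gap
        # longest run of consecutive dense gaps -> run of (len+1) contours
        start = 0
        while start < len(dense):
            if not dense[start]:
                start += 1
                continue
            end = start
            while end < len(dense) and dense[end]:
                end += 1
            run = path[start:end + 1]
            if len(run) >= min_run and (best is None or len(run) > len(best)):
                best = run
            start = end
    if best is None:
        raise SearchBandNotFoundError(
            f"no nested chain with >= {min_run} contours at gap <= {max_gap} px"
        )

    members = [iso.by_id(cid) for cid in best]
    mask = np.zeros(iso.shape, dtype=bool)
    h, w = iso.shape
    for c in members:
        rr, cc = polygon_perimeter(
            np.clip(np.round(c.vertices[:, 1]).astype(int), 0, h - 1),
            np.clip(np.round(c.vertices[:, 0]).astype(int), 0, w - 1),
            shape=iso.shape,
        )
        mask[rr, cc] = True
    mask = closing(mask, disk(closing_radius)).astype(bool)
    return SearchBand(contours=members, mask=mask, innermost=members[-1])
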