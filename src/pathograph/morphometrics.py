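"""Morphometric parameters of pathological entities from polygon geometry.

All quantities are in pixel units.  The membrane staining measure follows
the circular-arc model: for a circular membrane with a stained arc of angle
θ, the staining extent is θ/2π; for an arbitrary polygonal membrane it is
the stained path length divided by the total perimeter, which reduces to
θ/2π in the circular case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import math

from shapely.geometry import Polygon
from shapely.validation import explain_validity

from .core_model import EntityNode, FeatureNode, Outline, Point, QuantParam
from .errors import GeometryError

#: Default five-parameter morphological feature set attached to each
#: nucleus.  The names double as feature-node names in built entity graphs.
DEFAULT_FEATURE_SET = ("area", "perimeter", "roundness", "shape factor", "solidity")


@dataclass(frozen=True)
class ShapeParams:
    """Scale-free and scale-bearing shape descriptors of a simple polygon."""

    area: float          # px²
    perimeter: float     # px
    roundness: float     # 4πA/P², 1 for a circle
    shape_factor: float  # P²/(4πA), reciprocal compactness
    solidity: float      # A / area(convex hull)


@dataclass(frozen=True)
class MembraneStainingMeasure:
    """Stained fraction of a membrane outline."""

    total_perimeter: float
    stained_length: float
    theta: float    # equivalent stained arc angle, radians
    extent: float   # stained_length / total_perimeter ∈ [0, 1]


def _polygon(outline: Sequence[Point]) -> Polygon:
    if len(outline) < 3:
        raise GeometryError(f"outline requires ≥3 vertices, got {len(outline)}")
    poly = Polygon(outline)
    if not poly.is_valid:
        raise GeometryError(f"invalid polygon: {explain_validity(poly)}")
    if poly.area == 0.0:
        raise GeometryError("degenerate polygon with zero area")
    return poly


def polygon_area(outline: Sequence[Point]) -> float:
    """Shoelace area of a simple polygon, orientation-independent."""
    return _polygon(outline).area


def shape_params(outline: Sequence[Point]) -> ShapeParams:
    """Compute the five shape descriptors of a simple polygon."""
    poly = _polygon(outline)
    a, p = poly.area, poly.length
    roundness = 4.0 * math.pi * a / (p * p)
    return ShapeParams(area=a, perimeter=p, roundness=roundness,
                       shape_factor=1.0 / roundness,
                       solidity=a / poly.convex_hull.area)


def _cumulative_lengths(outline: Sequence[Point]) -> list[float]:
    """cum[i] = path length from vertex 0 to vertex i along the closed outline."""
    cum = [0.0]
    n = len(outline)
    for i in range(n):
        x0, y0 = outline[i]
        x1, y1 = outline[(i + 1) % n]
        cum.append(cum[-1] + math.hypot(x1 - x0, y1 - y0))
    return cum


def _position(t: float, cum: list[float], n: int) -> float:
    """Arc-length position of fractional vertex index t ∈ [0, n]."""
    if t < 0 or t > n:
        raise GeometryError(f"arc endpoint {t} outside vertex index range [0, {n}]")
    i = int(math.floor(t))
    if i == n:
        return cum[n]
    frac = t - i
    return cum[i] + frac * (cum[i + 1] - cum[i])


def staining_extent(membrane_outline: Sequence[Point],
                    stained_arcs: Sequence[tuple[float, float]],
                    ) -> MembraneStainingMeasure:
    """Stained fraction of a membrane given stained sub-paths of its outline.

    ``stained_arcs`` are (start, end) fractional vertex indices traversed
    forward along the outline; an arc with end < start wraps through vertex
    0.  Arcs must be mutually non-overlapping.  For a circle discretized at
    uniform angular steps this equals θ/2π where θ is the total stained
    angle.
    """
    _polygon(membrane_outline)  # geometry sanity
    n = len(membrane_outline)
    cum = _cumulative_lengths(membrane_outline)
    perimeter = cum[n]

    intervals: list[tuple[float, float]] = []  # arc-length intervals on [0, P)
    stained = 0.0
    for (s, e) in stained_arcs:
        ps, pe = _position(s, cum, n), _position(e, cum, n)
        if ps == pe:
            continue
        if pe > ps:
            segs = [(ps, pe)]
        else:  # wraps through the start vertex
            segs = [(ps, perimeter), (0.0, pe)]
        for seg in segs:
            stained += seg[1] - seg[0]
            intervals.append(seg)
    intervals.sort()
    for (a0, a1), (b0, _b1) in zip(intervals, intervals[1:]):
        if b0 < a1 - 1e-12:
            raise GeometryError(f"overlapping stained arcs near arc length {b0:.6g}")
    if stained > perimeter + 1e-9:
        raise GeometryError("stained length exceeds membrane perimeter")
    stained = min(stained, perimeter)
    extent = stained / perimeter
    return MembraneStainingMeasure(total_perimeter=perimeter,
                                   stained_length=stained,
                                   theta=2.0 * math.pi * extent,
                                   extent=extent)


def feature_bundle(nucleus: EntityNode,
                   feature_set: Sequence[str] = DEFAULT_FEATURE_SET,
                   id_prefix: str = "",
                   ) -> tuple[list[FeatureNode], list[QuantParam]]:
    """Morphological feature nodes + parameters for one nucleus outline.

    Returns one named :class:`FeatureNode` and one :class:`QuantParam` per
    feature in ``feature_set`` (five by default), all owned by the nucleus.
    """
    if nucleus.outline is None:
        raise GeometryError(f"nucleus {nucleus.id!r} has no outline")
    sp = shape_params(nucleus.outline)
    values = {"area": sp.area, "perimeter": sp.perimeter,
              "roundness": sp.roundness, "shape factor": sp.shape_factor,
              "solidity": sp.solidity}
    units = {"area": "px^2", "perimeter": "px"}
    prefix = id_prefix or nucleus.id
    feats: list[FeatureNode] = []
    params: list[QuantParam] = []
    for name in feature_set:
        if name not in values:
            raise ValueError(f"unknown morphological feature {name!r}")
        slug = name.replace(" ", "_")
        f = FeatureNode(id=f"{prefix}-feat-{slug}", feature_name=name,
                        owner_id=nucleus.id)
        q = QuantParam(id=f"{prefix}-param-{slug}", param_name=name,
                       value=values[name], unit=units.get(name, ""),
                       feature_id=f.id)
        feats.append(f)
        params.append(q)
    return feats, params


def regular_polygon(cx: float, cy: float, r: float, n: int,
                    phase: float = 0.0) -> Outline:
    """Vertices of a regular n-gon; a convenience for circular membranes."""
    return tuple((cx + r * math.cos(phase + 2.0 * math.pi * k / n),
                  cy + r * math.sin(phase + 2.0 * math.pi * k / n))
                 for k in range(n))
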