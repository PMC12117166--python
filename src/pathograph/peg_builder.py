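"""Automated construction of pathology entity graphs from segmentation.

Input is a segmentation scene: tumor-region and nucleus polygons with
class labels, carried as a GeoJSON FeatureCollection.  Coordinates are
0-based pixels in image convention (y increases downward); GeoJSON itself
is axis-agnostic, so this reader fixes the convention.

Pipeline: ``load_scene`` → ``assign_parts`` (part–whole assignment of
neoplastic nuclei to tumors by polygon-overlap fraction) → ``build_pegs``
(one entity graph per tumor, with per-nucleus morphometric features) →
PathoML via :mod:`pathograph.pathoml_io`, or GraphML via
``export_for_ml``.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
from shapely.geometry import Polygon

from .core_model import (EntityGraph, EntityNode, PathoDocument, SlideMeta,
                         bbox_of, build_entity_graph)
from .errors import GeometryError, ResolutionError
from .morphometrics import DEFAULT_FEATURE_SET, feature_bundle

REGION_LABELS = frozenset({"tumor", "other"})
NUCLEUS_LABELS = frozenset({"neoplastic", "non_neoplastic"})

#: GeoJSON properties.class values accepted by the reader.
GEOJSON_CLASSES = {"tumor": ("region", "tumor"),
                   "other": ("region", "other"),
                   "neoplastic_nucleus": ("nucleus", "neoplastic"),
                   "non_neoplastic_nucleus": ("nucleus", "non_neoplastic")}

DEFAULT_OVERLAP_THRESHOLD = 0.5


@dataclass
class SceneRegion:
    id: str
    label: str                      # "tumor" | "other"
    outline: tuple[tuple[float, float], ...]
    bbox: tuple[float, float, float, float]


@dataclass
class SceneNucleus:
    id: str
    label: str                      # "neoplastic" | "non_neoplastic"
    outline: tuple[tuple[float, float], ...]
    bbox: tuple[float, float, float, float]
    centroid: tuple[float, float]


@dataclass
class SegScene:
    width: int
    height: int
    regions: list[SceneRegion] = field(default_factory=list)
    nuclei: list[SceneNucleus] = field(default_factory=list)

    def tumors(self) -> list[SceneRegion]:
        return [r for r in self.regions if r.label == "tumor"]


@dataclass
class PartWholeAssignment:
    """nucleus id → tumor id (or absent = unassigned), with overlap fractions."""

    assigned: dict[str, str] = field(default_factory=dict)
    overlap: dict[tuple[str, str], float] = field(default_factory=dict)


def _feature_outline(feat: dict, idx: int) -> tuple:
    geom = feat.get("geometry") or {}
    if geom.get("type") != "Polygon":
        raise GeometryError(
            f"feature #{idx} ({feat.get('id', 'unnamed')}): geometry type "
            f"{geom.get('type')!r} is not Polygon")
    rings = geom.get("coordinates") or []
    if not rings or len(rings[0]) < 3:
        raise GeometryError(f"feature #{idx}: polygon ring with <3 vertices")
    ring = [(float(x), float(y)) for x, y in rings[0]]
    if ring[0] == ring[-1]:  # GeoJSON rings are explicitly closed
        ring = ring[:-1]
    return tuple(ring)


def load_scene(geojson_text: str) -> SegScene:
    """Parse a GeoJSON FeatureCollection into a :class:`SegScene`.

    Each feature needs ``properties.class`` in {tumor, other,
    neoplastic_nucleus, non_neoplastic_nucleus} and a Polygon geometry.
    Bounding boxes and centroids are computed when absent.  Top-level
    ``width``/``height`` keys set the image extent; otherwise it is taken
    from the geometry envelope.
    """
    try:
        data = json.loads(geojson_text)
    except json.JSONDecodeError as exc:
        raise GeometryError(f"not valid JSON: {exc}") from exc
    if data.get("type") != "FeatureCollection":
        raise GeometryError("input is not a GeoJSON FeatureCollection")
    features = data.get("features", [])
    regions: list[SceneRegion] = []
    nuclei: list[SceneNucleus] = []
    max_x = max_y = 0.0
    for idx, feat in enumerate(features):
        props = feat.get("properties") or {}
        cls = props.get("class")
        if cls is None:
            raise GeometryError(f"feature #{idx}: missing properties.class")
        if cls not in GEOJSON_CLASSES:
            raise GeometryError(f"feature #{idx}: unknown class {cls!r}")
        outline = _feature_outline(feat, idx)
        fid = str(feat.get("id") or props.get("id") or f"feature-{idx}")
        bbox = bbox_of(outline)
        max_x, max_y = max(max_x, bbox[2]), max(max_y, bbox[3])
        kind, label = GEOJSON_CLASSES[cls]
        if kind == "region":
            regions.append(SceneRegion(id=fid, label=label, outline=outline,
                                       bbox=bbox))
        else:
            c = Polygon(outline).centroid
            nuclei.append(SceneNucleus(id=fid, label=label, outline=outline,
                                       bbox=bbox, centroid=(c.x, c.y)))
    width = int(data.get("width") or (max_x + 1))
    height = int(data.get("height") or (max_y + 1))
    for idx, feat_bbox in enumerate([r.bbox for r in regions] + [n.bbox for n in nuclei]):
        if feat_bbox[0] < 0 or feat_bbox[1] < 0 or feat_bbox[2] >= width + 1 \
                or feat_bbox[3] >= height + 1:
            raise GeometryError(
                f"geometry #{idx} bbox {feat_bbox} outside image "
                f"[0,{width})×[0,{height})")
    return SegScene(width=width, height=height, regions=regions, nuclei=nuclei)


def assign_parts(scene: SegScene,
                 threshold: float = DEFAULT_OVERLAP_THRESHOLD,
                 ) -> PartWholeAssignment:
    """Assign each neoplastic nucleus to the tumor of maximal overlap.

    The overlap fraction is intersection area / nucleus area.  A nucleus is
    assigned only when its best fraction is ≥ ``threshold``; ties go to the
    lexicographically smaller tumor id.  Non-neoplastic nuclei are never
    assigned.
    """
    result = PartWholeAssignment()
    tumors = [(r.id, Polygon(r.outline)) for r in scene.tumors()]
    for nuc in scene.nuclei:
        poly = Polygon(nuc.outline)
        area = poly.area
        if nuc.label != "neoplastic" or area == 0.0 or not tumors:
            continue
        best: Optional[tuple[float, str]] = None
        for tid, tpoly in tumors:
            frac = poly.intersection(tpoly).area / area
            if frac > 0.0:
                result.overlap[(nuc.id, tid)] = frac
            if frac >= threshold:
                # max fraction wins; ties broken by smaller tumor id
                if best is None or frac > best[0] + 1e-12 or \
                        (abs(frac - best[0]) <= 1e-12 and tid < best[1]):
                    best = (frac, tid)
        if best is not None:
            result.assigned[nuc.id] = best[1]
    return result


def build_pegs(scene: SegScene, assignment: PartWholeAssignment,
               feature_set=DEFAULT_FEATURE_SET) -> list[EntityGraph]:
    """One entity graph per tumor region.

    The root is a Tumor node; its components are the assigned neoplastic
    nuclei, modeled as NeoplasticCell nodes carrying their outlines and
    bounding boxes, each with the morphometric feature bundle attached.
    """
    nuclei_by_id = {n.id: n for n in scene.nuclei}
    for nid, tid in assignment.assigned.items():
        if nid not in nuclei_by_id:
            raise ResolutionError(nid, "assignment nucleus")
        if tid not in {r.id for r in scene.tumors()}:
            raise ResolutionError(tid, "assignment tumor")
    pegs: list[EntityGraph] = []
    for region in scene.tumors():
        root = EntityNode(id=region.id, entity_class="Tumor",
                          display_name=region.id, outline=region.outline,
                          bbox=region.bbox)
        components, features, params = [], [], []
        for nid in sorted(n for n, t in assignment.assigned.items()
                          if t == region.id):
            nuc = nuclei_by_id[nid]
            node = EntityNode(id=nid, entity_class="NeoplasticCell",
                              display_name=nid, outline=nuc.outline,
                              bbox=nuc.bbox)
            components.append(node)
            fs, qs = feature_bundle(node, feature_set=feature_set)
            features.extend(fs)
            params.extend(qs)
        pegs.append(build_entity_graph(root, components, features, params))
    return pegs


def pegs_to_document(scene: SegScene, pegs: list[EntityGraph],
                     provenance: str = "") -> PathoDocument:
    """Bundle all PEGs of one scene into a single document."""
    doc = PathoDocument(slide_meta=SlideMeta(modality="HE", height=scene.height,
                                             width=scene.width),
                        provenance=provenance)
    for g in pegs:
        doc.add_graph(g)
    return doc


def export_for_ml(pegs: list[EntityGraph]) -> str:
    """GraphML export of PEGs as one attributed graph (plain hook for ML).

    Entity nodes carry their class, bounding box and the five morphometric
    features; edges are typed by kind (component / attribute /
    quantification / express).
    """
    g = nx.DiGraph()
    for peg in pegs:
        for e in peg.entities().values():
            attrs = {"kind": "entity", "entity_class": e.entity_class}
            if e.bbox is not None:
                attrs["bbox"] = ",".join(f"{v:g}" for v in e.bbox)
            g.add_node(e.id, **attrs)
        feature_values = {}
        for (fid, qid) in peg.quant_links:
            feature_values[fid] = peg.params[qid].value
        for fid, f in peg.features.items():
            # fold the parameter value onto its owning entity attribute
            slug = f.feature_name.replace(" ", "_")
            if fid in feature_values:
                g.nodes[f.owner_id][slug] = float(feature_values[fid])
        for (a, b) in sorted(peg.part_whole):
            g.add_edge(a, b, kind="component")
        for (a, b) in sorted(peg.express_links):
            g.add_edge(a, b, kind="express")
    buf = io.BytesIO()
    nx.write_graphml(g, buf, named_key_ids=True)
    return buf.getvalue().decode("utf-8")
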