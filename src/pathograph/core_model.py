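"""In-memory typed graph model for pathology knowledge.

Three kinds of graphs are represented:

* **Entity graphs** — a pathological entity (cell, tumor, cellular
  component, protein ...), its part–whole component tree, its pathological
  features (e.g. "staining extent", "nuclear shape") and the quantitative
  parameters measuring those features.
* **Phenotypes** — single-cell, multi-cell (with spatial/behavioral
  relationships among entities) and quantitative phenotypic indicators.
* **Diagnosis processes** — ordered diagnostic stages, each considering a
  set of diagnostic possibilities that are established or excluded on the
  basis of supporting/contradicting phenotypic evidence.

A :class:`PathoDocument` bundles graphs together with slide metadata and is
the unit of PathoML serialization (see :mod:`pathograph.pathoml_io`).
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .errors import CycleError, ResolutionError

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

CELL_CLASSES = frozenset({"Cell", "NeoplasticCell"})
COMPONENT_CLASSES = frozenset({"Cellular_Component", "NeoplasticCellularComponent"})
PROTEIN_CLASSES = frozenset({"Protein"})
TISSUE_CLASSES = frozenset({"Tumor", "Stroma", "Parenchyma", "Substance",
                            "Anatomical_Structure"})

#: Closed controlled vocabulary for entity classes, with an "Other" escape
#: hatch carrying a free-text subtype.
ENTITY_CLASSES = CELL_CLASSES | COMPONENT_CLASSES | PROTEIN_CLASSES | TISSUE_CLASSES | {"Other"}

PHENOTYPE_KINDS = frozenset({"single_cell", "multi_cell", "quantitative_indicator"})
PHENOTYPE_CLASSES = frozenset({"Cytopathological_Phenotype", "Histopathological_Phenotype",
                               "Immunophenotype", "Quantitative_Indicators"})
DIAGNOSIS_STATUSES = frozenset({"established", "excluded"})
RELATIONSHIP_CATEGORIES = frozenset({"spatial", "behavioral"})
SLIDE_MODALITIES = frozenset({"HE", "IHC", "report"})

Point = tuple[float, float]
Outline = tuple[Point, ...]
BBox = tuple[float, float, float, float]  # xmin, ymin, xmax, ymax


def _shoelace(outline: Sequence[Point]) -> float:
    n = len(outline)
    s = 0.0
    for i in range(n):
        x0, y0 = outline[i]
        x1, y1 = outline[(i + 1) % n]
        s += x0 * y1 - x1 * y0
    return abs(s) / 2.0


def bbox_of(outline: Sequence[Point]) -> BBox:
    xs = [p[0] for p in outline]
    ys = [p[1] for p in outline]
    return (min(xs), min(ys), max(xs), max(ys))


# ---------------------------------------------------------------------------
# Node types
# ---------------------------------------------------------------------------


@dataclass
class EntityNode:
    """A pathological entity: a biological structure observable on a slide."""

    id: str
    entity_class: str
    display_name: str = ""
    subtype: str = ""          # free text, used with entity_class == "Other"
    outline: Optional[Outline] = None
    bbox: Optional[BBox] = None
    xrefs: list[tuple[str, str]] = field(default_factory=list)

    def is_cell(self) -> bool:
        return self.entity_class in CELL_CLASSES

    def is_component(self) -> bool:
        return self.entity_class in COMPONENT_CLASSES

    def is_protein(self) -> bool:
        return self.entity_class in PROTEIN_CLASSES


@dataclass
class FeatureNode:
    """A pathological feature of an entity (e.g. "staining extent")."""

    id: str
    feature_name: str
    owner_id: str


@dataclass
class QuantParam:
    """A quantitative parameter measuring a pathological feature.

    ``feature_id`` is optional: indicator parameters are free-standing,
    whereas parameters inside an entity graph must name their feature.
    """

    id: str
    param_name: str
    value: float
    unit: str = ""
    feature_id: Optional[str] = None


@dataclass
class EntityGraph:
    """A rooted entity graph: root, components, features and parameters.

    Relation sets follow the set-theoretic contract: ``part_whole`` is a set
    of (whole, part) pairs over {root} ∪ components × components;
    ``feature_links`` pairs entities with features; ``quant_links`` pairs
    features with parameters; ``express_links`` pairs cellular components
    with the proteins they express.
    """

    root: EntityNode
    components: dict[str, EntityNode] = field(default_factory=dict)
    features: dict[str, FeatureNode] = field(default_factory=dict)
    params: dict[str, QuantParam] = field(default_factory=dict)
    part_whole: set[tuple[str, str]] = field(default_factory=set)
    feature_links: set[tuple[str, str]] = field(default_factory=set)
    quant_links: set[tuple[str, str]] = field(default_factory=set)
    express_links: set[tuple[str, str]] = field(default_factory=set)

    @property
    def id(self) -> str:
        return self.root.id

    def entities(self) -> dict[str, EntityNode]:
        d = {self.root.id: self.root}
        d.update(self.components)
        return d

    def node_count(self) -> int:
        """Total node count: entities + features + parameters."""
        return 1 + len(self.components) + len(self.features) + len(self.params)


@dataclass
class RelationshipEdge:
    """A spatial-arrangement or dynamic-behavior relationship.

    ``subjects`` initiate/anchor the relationship (e.g. the invading tumor,
    or the reference follicle in a back-to-back arrangement); ``objects``
    receive it.
    """

    id: str
    predicate: str
    category: str                 # "spatial" | "behavioral"
    subjects: list[str] = field(default_factory=list)
    objects: list[str] = field(default_factory=list)


@dataclass
class Phenotype:
    """A pathological phenotype (single-cell, multi-cell or indicator-kind).

    ``entities`` lists the ids of the involved pathological entities;
    ``entity_graphs`` holds the per-entity expansion (populated by
    :func:`expand_phenotype`).  A phenotype used purely as a named
    diagnostic feature may declare no entities at all.
    """

    id: str
    label: str
    kind: str                     # member of PHENOTYPE_KINDS
    pathoml_class: str            # member of PHENOTYPE_CLASSES
    entities: list[str] = field(default_factory=list)
    relationships: list[RelationshipEdge] = field(default_factory=list)
    entity_graphs: dict[str, EntityGraph] = field(default_factory=dict)


@dataclass
class QuantIndicator:
    """A quantitative phenotypic indicator with its value and formula.

    ``formula`` is a content-MathML string; it is stored, serialized and
    roundtripped but never interpreted.
    """

    id: str
    name: str
    value: float
    formula: str = ""
    params: dict[str, QuantParam] = field(default_factory=dict)


@dataclass
class Diagnosis:
    """A diagnostic possibility, established or excluded at its stage."""

    id: str
    label: str
    status: str                   # "established" | "excluded"
    support: list[str] = field(default_factory=list)      # phenotype/indicator ids
    contradict: list[str] = field(default_factory=list)


@dataclass
class DiagnosisStage:
    id: str
    index: int
    possibilities: list[Diagnosis] = field(default_factory=list)
    phenotypes: list[str] = field(default_factory=list)   # P_i


@dataclass
class DiagnosisProcess:
    """An ordered chain of diagnostic stages for one diagnostic item."""

    id: str
    stages: list[DiagnosisStage] = field(default_factory=list)
    item: str = ""


@dataclass
class SlideMeta:
    modality: str                 # "HE" | "IHC" | "report"
    height: Optional[int] = None
    width: Optional[int] = None
    magnification: Optional[float] = None
    antigen: str = ""             # IHC only


@dataclass
class Xref:
    """A mapping of a node to a controlled-vocabulary code."""

    node_id: str
    vocabulary: str
    code: str


@dataclass
class PathoDocument:
    """Container binding graphs to slide/report metadata."""

    entity_graphs: dict[str, EntityGraph] = field(default_factory=dict)
    phenotypes: dict[str, Phenotype] = field(default_factory=dict)
    indicators: dict[str, QuantIndicator] = field(default_factory=dict)
    processes: dict[str, DiagnosisProcess] = field(default_factory=dict)
    slide_meta: Optional[SlideMeta] = None
    provenance: str = ""
    xrefs: list[Xref] = field(default_factory=list)

    # -- convenience -------------------------------------------------------
    def add_graph(self, g: EntityGraph) -> None:
        self.entity_graphs[g.id] = g

    def add_phenotype(self, p: Phenotype) -> None:
        self.phenotypes[p.id] = p

    def add_indicator(self, qi: QuantIndicator) -> None:
        self.indicators[qi.id] = qi

    def add_process(self, dp: DiagnosisProcess) -> None:
        self.processes[dp.id] = dp

    def all_entities(self) -> dict[str, EntityNode]:
        out: dict[str, EntityNode] = {}
        for g in self.entity_graphs.values():
            out.update(g.entities())
        for p in self.phenotypes.values():
            for g in p.entity_graphs.values():
                out.update(g.entities())
        return out

    def evidence_targets(self) -> set[str]:
        """Ids that diagnosis evidence links may legally reference."""
        return set(self.phenotypes) | set(self.indicators)

    def is_empty(self) -> bool:
        return not (self.entity_graphs or self.phenotypes or self.indicators
                    or self.processes or self.slide_meta or self.provenance
                    or self.xrefs)


class IdFactory:
    """Deterministic ``<class>-<counter>`` id scheme used by builders."""

    def __init__(self) -> None:
        self._counters: dict[str, int] = {}

    def new(self, kind: str) -> str:
        n = self._counters.get(kind, 0) + 1
        self._counters[kind] = n
        return f"{kind}-{n}"


# ---------------------------------------------------------------------------
# Cycle detection (kept dependency-free; cross-checked against networkx in
# the test suite)
# ---------------------------------------------------------------------------


def find_cycle(pairs: Iterable[tuple[str, str]]) -> Optional[list[str]]:
    """Return one directed cycle in the pair set, or None if acyclic."""
    adj: dict[str, list[str]] = {}
    for a, b in pairs:
        adj.setdefault(a, []).append(b)
    WHITE, GREY, BLACK = 0, 1, 2
    color: dict[str, int] = {}
    stack_path: list[str] = []

    def visit(u: str) -> Optional[list[str]]:
        color[u] = GREY
        stack_path.append(u)
        for v in adj.get(u, ()):  # deterministic insertion order
            c = color.get(v, WHITE)
            if c == GREY:
                i = stack_path.index(v)
                return stack_path[i:] + [v]
            if c == WHITE:
                found = visit(v)
                if found:
                    return found
        stack_path.pop()
        color[u] = BLACK
        return None

    for node in list(adj):
        if color.get(node, WHITE) == WHITE:
            found = visit(node)
            if found:
                return found
    return None


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def build_entity_graph(root: EntityNode,
                       components: Iterable[EntityNode] = (),
                       features: Iterable[FeatureNode] = (),
                       params: Iterable[QuantParam] = (),
                       relations: Optional[Mapping[str, Iterable[tuple[str, str]]]] = None,
                       ) -> EntityGraph:
    """Assemble and validate an :class:`EntityGraph`.

    ``relations`` may carry the keys ``part_whole``, ``feature_links``,
    ``quant_links`` and ``express_links``.  When ``part_whole`` is omitted,
    every component is attached directly to the root; ``feature_links`` and
    ``quant_links`` default to the ownership recorded on the feature/param
    objects themselves.

    Raises :class:`ResolutionError` on a dangling reference and
    :class:`CycleError` when the part–whole relation is cyclic.
    """
    relations = dict(relations or {})
    comp_map = {c.id: c for c in components}
    feat_map = {f.id: f for f in features}
    param_map = {q.id: q for q in params}

    part_whole = set(relations.get("part_whole",
                                   {(root.id, cid) for cid in comp_map}))
    feature_links = set(relations.get("feature_links",
                                      {(f.owner_id, f.id) for f in feat_map.values()}))
    quant_links = set(relations.get("quant_links",
                                    {(q.feature_id, q.id) for q in param_map.values()
                                     if q.feature_id is not None}))
    express_links = set(relations.get("express_links", ()))

    entity_ids = {root.id} | set(comp_map)
    for a, b in part_whole:
        for x in (a, b):
            if x not in entity_ids:
                raise ResolutionError(x, "part_whole endpoint")
    for e, c in feature_links:
        if e not in entity_ids:
            raise ResolutionError(e, "feature_links source")
        if c not in feat_map:
            raise ResolutionError(c, "feature_links target")
    for c, q in quant_links:
        if c not in feat_map:
            raise ResolutionError(c, "quant_links source")
        if q not in param_map:
            raise ResolutionError(q, "quant_links target")
    for c, p in express_links:
        if c not in entity_ids:
            raise ResolutionError(c, "express_links source")
        if p not in entity_ids:
            raise ResolutionError(p, "express_links target")

    cyc = find_cycle(part_whole)
    if cyc is not None:
        raise CycleError(cyc)

    return EntityGraph(root=root, components=comp_map, features=feat_map,
                       params=param_map, part_whole=part_whole,
                       feature_links=feature_links, quant_links=quant_links,
                       express_links=express_links)


def build_diagnosis_process(stages: Sequence[DiagnosisStage],
                            item: str = "",
                            proc_id: str = "Process1") -> DiagnosisProcess:
    """Assemble a :class:`DiagnosisProcess`; list order encodes stage order.

    Raises ``ValueError`` for an empty stage list or duplicate/non-increasing
    stage indices.  Multiple established outcomes at a non-terminal stage
    are permitted but produce a ``UserWarning``.
    """
    stages = list(stages)
    if not stages:
        raise ValueError("a diagnosis process requires at least one stage")
    indices = [s.index for s in stages]
    if len(set(indices)) != len(indices):
        raise ValueError(f"duplicate stage indices: {indices}")
    if indices != sorted(indices):
        raise ValueError(f"stage indices must be strictly increasing: {indices}")
    for s in stages[:-1]:
        n_est = sum(1 for d in s.possibilities if d.status == "established")
        if n_est > 1:
            warnings.warn(
                f"stage {s.id} has {n_est} established outcomes; the model "
                "permits this but typical processes establish at most one",
                UserWarning, stacklevel=2)
    return DiagnosisProcess(id=proc_id, stages=stages, item=item)


def expand_phenotype(p: Phenotype,
                     graphs: Mapping[str, EntityGraph]) -> Phenotype:
    """Return a copy of ``p`` with ``entity_graphs`` populated.

    Every entity of ``p`` must have a matching entity graph, either already
    attached to ``p`` or present in ``graphs`` keyed by the root id.  The
    original phenotype is left untouched, and expanding an already-expanded
    phenotype with the same map is a no-op.
    """
    expansion: dict[str, EntityGraph] = dict(p.entity_graphs)
    for eid in p.entities:
        if eid in expansion:
            continue
        g = graphs.get(eid)
        if g is None:
            raise ResolutionError(eid, "no entity graph for phenotype entity")
        if g.root.id != eid:
            raise ResolutionError(eid, f"graph rooted at {g.root.id!r} does not match")
        expansion[eid] = copy.deepcopy(g)
    return replace(p, entities=list(p.entities),
                   relationships=list(p.relationships),
                   entity_graphs=expansion)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    """One violated model constraint, naming the object and the clause."""

    type_name: str
    obj_id: str
    clause: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.type_name} {self.obj_id}] {self.clause}: {self.message}"


def _validate_entity_node(e: EntityNode, out: list[Violation]) -> None:
    if e.entity_class not in ENTITY_CLASSES:
        out.append(Violation("EntityNode", e.id, "entity_class",
                             f"{e.entity_class!r} is not in the controlled hierarchy"))
    if e.outline is not None:
        if len(e.outline) < 3:
            out.append(Violation("EntityNode", e.id, "outline",
                                 "outline requires at least 3 vertices"))
        elif _shoelace(e.outline) <= 0.0:
            out.append(Violation("EntityNode", e.id, "outline",
                                 "outline has zero area"))
        if e.bbox is not None:
            xmin, ymin, xmax, ymax = e.bbox
            for (x, y) in e.outline:
                if not (xmin <= x <= xmax and ymin <= y <= ymax):
                    out.append(Violation("EntityNode", e.id, "bbox",
                                         f"vertex ({x}, {y}) outside bbox"))
                    break


def _validate_entity_graph(g: EntityGraph, out: list[Violation]) -> None:
    entity_ids = {g.root.id} | set(g.components)
    for e in g.entities().values():
        _validate_entity_node(e, out)
    for fid, f in g.features.items():
        if f.owner_id not in entity_ids:
            out.append(Violation("FeatureNode", fid, "owner_id",
                                 f"owner {f.owner_id!r} not in graph"))
    for qid, q in g.params.items():
        if not math.isfinite(q.value):
            out.append(Violation("QuantParam", qid, "value",
                                 f"value {q.value!r} is not finite"))
        if q.feature_id is None:
            out.append(Violation("QuantParam", qid, "feature_id",
                                 "entity-graph parameter must name its feature"))
        elif q.feature_id not in g.features:
            out.append(Violation("QuantParam", qid, "feature_id",
                                 f"feature {q.feature_id!r} not in graph"))
    gid = g.id
    for a, b in g.part_whole:
        if a not in entity_ids or b not in entity_ids or b == g.root.id:
            out.append(Violation("EntityGraph", gid, "R_ee",
                                 f"pair ({a!r}, {b!r}) outside ({{root}} ∪ E_a) × E_a"))
    for e, c in g.feature_links:
        if e not in entity_ids or c not in g.features:
            out.append(Violation("EntityGraph", gid, "R_ec",
                                 f"pair ({e!r}, {c!r}) outside ({{root}} ∪ E_a) × C_a"))
    for c, q in g.quant_links:
        if c not in g.features or q not in g.params:
            out.append(Violation("EntityGraph", gid, "R_cq",
                                 f"pair ({c!r}, {q!r}) outside C_a × Q_a"))
    cyc = find_cycle(g.part_whole)
    if cyc is not None:
        out.append(Violation("EntityGraph", gid, "part_whole acyclicity",
                             "cycle: " + " -> ".join(cyc)))
    else:
        # proteins hang off components via express; count those edges for
        # reachability so an expressed protein is a legal graph member
        reachable = {g.root.id}
        frontier = [g.root.id]
        adj: dict[str, list[str]] = {}
        for a, b in set(g.part_whole) | set(g.express_links):
            adj.setdefault(a, []).append(b)
        while frontier:
            u = frontier.pop()
            for v in adj.get(u, ()):
                if v not in reachable:
                    reachable.add(v)
                    frontier.append(v)
        for cid in g.components:
            if cid not in reachable:
                out.append(Violation("EntityGraph", gid, "reachability",
                                     f"component {cid!r} unreachable from root"))
    entities = g.entities()
    for c, p in g.express_links:
        cn, pn = entities.get(c), entities.get(p)
        if cn is None or pn is None:
            out.append(Violation("EntityGraph", gid, "express",
                                 f"pair ({c!r}, {p!r}) references unknown entity"))
        elif not (cn.is_component() and pn.is_protein()):
            out.append(Violation("EntityGraph", gid, "express",
                                 f"({c!r}, {p!r}) must pair a cellular component "
                                 "with a protein"))


def _validate_phenotype(p: Phenotype, doc: Optional[PathoDocument],
                        out: list[Violation]) -> None:
    if p.kind not in PHENOTYPE_KINDS:
        out.append(Violation("Phenotype", p.id, "kind",
                             f"{p.kind!r} not in {sorted(PHENOTYPE_KINDS)}"))
    if p.pathoml_class not in PHENOTYPE_CLASSES:
        out.append(Violation("Phenotype", p.id, "pathoml_class",
                             f"{p.pathoml_class!r} not a Phenotype subclass"))
    declared = bool(p.entities or p.relationships)
    entity_lookup: dict[str, EntityNode] = {}
    for g in p.entity_graphs.values():
        entity_lookup.update(g.entities())
    if doc is not None:
        entity_lookup.update(doc.all_entities())
    if declared and p.kind == "single_cell":
        if len(p.entities) != 1:
            out.append(Violation("Phenotype", p.id, "single_cell cardinality",
                                 f"single-cell phenotype declares {len(p.entities)} "
                                 "entities; exactly one cell is required"))
        else:
            node = entity_lookup.get(p.entities[0])
            if node is not None and not node.is_cell():
                out.append(Violation("Phenotype", p.id, "single_cell entity class",
                                     f"entity {node.id!r} has class "
                                     f"{node.entity_class!r}, not a cell kind"))
    if declared and p.kind == "multi_cell":
        if len(p.entities) < 2 and not p.relationships:
            out.append(Violation("Phenotype", p.id, "multi_cell cardinality",
                                 "multi-cell phenotype requires ≥2 entities or "
                                 "≥1 relationship"))
    ent_set = set(p.entities)
    for rel in p.relationships:
        if rel.category not in RELATIONSHIP_CATEGORIES:
            out.append(Violation("RelationshipEdge", rel.id, "category",
                                 f"{rel.category!r} not spatial|behavioral"))
        if not rel.subjects or not rel.objects:
            out.append(Violation("RelationshipEdge", rel.id, "cardinality",
                                 "subjects and objects must be nonempty"))
        if set(rel.subjects) & set(rel.objects):
            out.append(Violation("RelationshipEdge", rel.id, "disjointness",
                                 "subjects and objects overlap"))
        for x in list(rel.subjects) + list(rel.objects):
            if x not in ent_set:
                out.append(Violation("RelationshipEdge", rel.id, "endpoint",
                                     f"endpoint {x!r} not among phenotype entities"))
    for eid, g in p.entity_graphs.items():
        if g.root.id != eid:
            out.append(Violation("Phenotype", p.id, "entity_graphs",
                                 f"expansion key {eid!r} != graph root {g.root.id!r}"))


def _validate_indicator(qi: QuantIndicator, out: list[Violation]) -> None:
    if not math.isfinite(qi.value):
        out.append(Violation("QuantIndicator", qi.id, "value",
                             f"value {qi.value!r} is not finite"))
    for q in qi.params.values():
        if not math.isfinite(q.value):
            out.append(Violation("QuantParam", q.id, "value",
                                 f"value {q.value!r} is not finite"))


def _validate_process(dp: DiagnosisProcess, doc: Optional[PathoDocument],
                      out: list[Violation]) -> None:
    if not dp.stages:
        out.append(Violation("DiagnosisProcess", dp.id, "stages",
                             "at least one stage is required"))
        return
    indices = [s.index for s in dp.stages]
    if any(i <= 0 for i in indices):
        out.append(Violation("DiagnosisProcess", dp.id, "stage index",
                             f"indices must be positive: {indices}"))
    if indices != sorted(set(indices)) or len(set(indices)) != len(indices):
        out.append(Violation("DiagnosisProcess", dp.id, "stage order",
                             f"indices must be strictly increasing: {indices}"))
    visible = doc.evidence_targets() if doc is not None else None
    for si, stage in enumerate(dp.stages):
        if not stage.possibilities:
            out.append(Violation("DiagnosisStage", stage.id, "possibilities",
                                 "a stage must consider at least one possibility"))
        terminal = si == len(dp.stages) - 1
        n_est = sum(1 for d in stage.possibilities if d.status == "established")
        if terminal and n_est > 1:
            out.append(Violation("DiagnosisStage", stage.id, "terminal outcome",
                                 f"{n_est} established outcomes at the terminal stage"))
        for d in stage.possibilities:
            if d.status not in DIAGNOSIS_STATUSES:
                out.append(Violation("Diagnosis", d.id, "status",
                                     f"{d.status!r} not established|excluded"))
            overlap = set(d.support) & set(d.contradict)
            if overlap:
                out.append(Violation("Diagnosis", d.id, "evidence disjointness",
                                     f"ids in both support and contradict: "
                                     f"{sorted(overlap)}"))
            if visible is not None:
                for pid in list(d.support) + list(d.contradict):
                    if pid not in visible:
                        out.append(Violation("Diagnosis", d.id, "evidence resolution",
                                             f"evidence {pid!r} is not a phenotype "
                                             "or indicator of the document"))
        if visible is not None:
            for pid in stage.phenotypes:
                if pid not in visible:
                    out.append(Violation("DiagnosisStage", stage.id, "phenotypes",
                                         f"phenotype {pid!r} not in document"))


def document_ids(doc: PathoDocument) -> dict[str, str]:
    """Map every node id declared in the document to its type name."""
    ids: dict[str, str] = {}
    for g in doc.entity_graphs.values():
        for eid in g.entities():
            ids.setdefault(eid, "EntityNode")
        for fid in g.features:
            ids.setdefault(fid, "FeatureNode")
        for qid in g.params:
            ids.setdefault(qid, "QuantParam")
    for p in doc.phenotypes.values():
        ids.setdefault(p.id, "Phenotype")
        for rel in p.relationships:
            ids.setdefault(rel.id, "RelationshipEdge")
        for g in p.entity_graphs.values():
            for eid in g.entities():
                ids.setdefault(eid, "EntityNode")
            for fid in g.features:
                ids.setdefault(fid, "FeatureNode")
            for qid in g.params:
                ids.setdefault(qid, "QuantParam")
    for qi in doc.indicators.values():
        ids.setdefault(qi.id, "QuantIndicator")
        for qid in qi.params:
            ids.setdefault(qid, "QuantParam")
    for dp in doc.processes.values():
        ids.setdefault(dp.id, "DiagnosisProcess")
        for s in dp.stages:
            ids.setdefault(s.id, "DiagnosisStage")
            for d in s.possibilities:
                ids.setdefault(d.id, "Diagnosis")
    return ids


def validate(doc: PathoDocument) -> list[Violation]:
    """Check every model invariant of every object in the document.

    Returns an empty list iff the document is clean; violations are
    returned, never raised.
    """
    out: list[Violation] = []
    seen: dict[str, str] = {}

    def claim(node_id: str, type_name: str) -> None:
        if node_id in seen:
            out.append(Violation(type_name, node_id, "id uniqueness",
                                 f"id also used by a {seen[node_id]}"))
        else:
            seen[node_id] = type_name

    for g in doc.entity_graphs.values():
        for eid in g.entities():
            claim(eid, "EntityNode")
        for fid in g.features:
            claim(fid, "FeatureNode")
        for qid in g.params:
            claim(qid, "QuantParam")
        _validate_entity_graph(g, out)
    for p in doc.phenotypes.values():
        claim(p.id, "Phenotype")
        _validate_phenotype(p, doc, out)
    for qi in doc.indicators.values():
        claim(qi.id, "QuantIndicator")
        _validate_indicator(qi, out)
    for dp in doc.processes.values():
        claim(dp.id, "DiagnosisProcess")
        for s in dp.stages:
            claim(s.id, "DiagnosisStage")
            for d in s.possibilities:
                claim(d.id, "Diagnosis")
        _validate_process(dp, doc, out)
    if doc.slide_meta is not None and doc.slide_meta.modality not in SLIDE_MODALITIES:
        out.append(Violation("SlideMeta", "slide", "modality",
                             f"{doc.slide_meta.modality!r} not in "
                             f"{sorted(SLIDE_MODALITIES)}"))
    known_nodes = set(document_ids(doc))
    for x in doc.xrefs:
        if x.node_id not in known_nodes:
            out.append(Violation("Xref", f"{x.vocabulary}:{x.code}", "node",
                                 f"xref target {x.node_id!r} unknown"))
    # cross-references from phenotype entity lists
    all_ents = doc.all_entities()
    for p in doc.phenotypes.values():
        for eid in p.entities:
            if eid not in all_ents:
                out.append(Violation("Phenotype", p.id, "entity resolution",
                                     f"entity {eid!r} has no node in the document"))
    return out
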