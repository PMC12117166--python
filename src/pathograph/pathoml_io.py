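"""PathoML serialization: pathology documents as OWL ontologies.

Model nodes become named individuals typed by PathoML classes
(NeoplasticCell, EntityAttribute, Quantification, Immunophenotype,
DiagnosisStage, ...), edges become object-property triples (hasComponent,
express, hasAttribute, quantification, present_Entity, stepProcess,
nextStep, ...) and scalars become data-property assertions (hasValue,
hasFormula, segmentation, ...).

Canonical Turtle output is the N-Triples-compatible subset of Turtle with
fixed prefixes and triples sorted by (subject, predicate, object); two
writes of the same document are byte-identical.  RDF/XML is offered as an
alternative dialect parsing to the same triple set.
"""

from __future__ import annotations

import re
import urllib.parse
from dataclasses import dataclass, field
from typing import Optional

from rdflib import Graph, Literal, Namespace, RDF, URIRef
from rdflib.namespace import OWL, XSD

from . import core_model as cm
from .core_model import (Diagnosis, DiagnosisProcess, DiagnosisStage, EntityGraph,
                         EntityNode, FeatureNode, PathoDocument, Phenotype,
                         QuantIndicator, QuantParam, RelationshipEdge, SlideMeta,
                         Xref, validate, document_ids)
from .errors import DocumentValidationError, PathoMLParseError, ResolutionError

SCHEMA_IRI = "https://w3id.org/pathoml/schema#"
DOC_IRI = "https://w3id.org/pathoml/document#"

PATHOML = Namespace(SCHEMA_IRI)

DIALECTS = ("turtle", "rdfxml")

# class local names ---------------------------------------------------------
ENTITY_CLASS_NAMES = frozenset(cm.ENTITY_CLASSES)
PHENOTYPE_CLASS_NAMES = frozenset(cm.PHENOTYPE_CLASSES)
_SLIDE_CLASS = {"HE": "HE_Slide", "IHC": "IHC_Slide", "report": "Pathology_Report"}
_SLIDE_MODALITY = {v: k for k, v in _SLIDE_CLASS.items()}

KNOWN_CLASSES = (ENTITY_CLASS_NAMES | PHENOTYPE_CLASS_NAMES
                 | set(_SLIDE_CLASS.values())
                 | {"EntityAttribute", "Quantification", "Relationship",
                    "DiagnosisProcess", "DiagnosisStage",
                    "Final_Diagnosis", "Differential_Diagnosis",
                    "Xref", "PathoDocument"})

OBJECT_PROPERTIES = ("hasComponent", "express", "hasAttribute", "quantification",
                     "present_Entity", "hasRelationship", "subject", "object",
                     "has_quantity", "diagnosisOrder", "nextStep", "stepProcess",
                     "usesPhenotype", "hasSupportEvidence", "hasContradictEvidence",
                     "has_Phenotype", "has_Process", "has_Entity", "hasXref")

DATA_PROPERTIES = ("hasValue", "hasFormula", "segmentation", "boundingBox",
                   "name", "displayName", "subtype", "unit", "phenotypeKind",
                   "predicate", "category", "stageIndex", "diagnosticItem",
                   "vocabulary", "code", "height", "width", "magnification",
                   "antigen", "provenance")


@dataclass
class PathoMLBinding:
    """IRI binding of model types and edge kinds to ontology terms."""

    schema_iri: str = SCHEMA_IRI
    doc_iri: str = DOC_IRI
    class_map: dict[str, URIRef] = field(default_factory=dict)
    objprop_map: dict[str, URIRef] = field(default_factory=dict)
    dataprop_map: dict[str, URIRef] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ns = Namespace(self.schema_iri)
        for name in KNOWN_CLASSES:
            self.class_map.setdefault(name, ns[name])
        for name in OBJECT_PROPERTIES:
            self.objprop_map.setdefault(name, ns[name])
        for name in DATA_PROPERTIES:
            self.dataprop_map.setdefault(name, ns[name])

    def individual(self, node_id: str) -> URIRef:
        return URIRef(self.doc_iri + urllib.parse.quote(node_id, safe="-_."))

    def local_id(self, iri: URIRef) -> str:
        s = str(iri)
        if not s.startswith(self.doc_iri):
            raise PathoMLParseError(f"individual {s} outside document namespace")
        return urllib.parse.unquote(s[len(self.doc_iri):])


DEFAULT_BINDING = PathoMLBinding()

_DOC_NODE_ID = "document"


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def _outline_str(outline: cm.Outline) -> str:
    return " ".join(f"{x:g},{y:g}" for x, y in outline)


def _parse_outline(text: str) -> cm.Outline:
    pts = []
    for tok in text.split():
        x, y = tok.split(",")
        pts.append((float(x), float(y)))
    return tuple(pts)


def _bbox_str(bbox: cm.BBox) -> str:
    return ",".join(f"{v:g}" for v in bbox)


def _doc_triples(doc: PathoDocument, b: PathoMLBinding) -> list[tuple]:
    """All triples of the document, as rdflib terms."""
    C, O, D = b.class_map, b.objprop_map, b.dataprop_map
    ind = b.individual
    triples: list[tuple] = []

    def add(s, p, o):
        triples.append((s, p, o))

    docnode = ind(_DOC_NODE_ID)
    add(docnode, RDF.type, C["PathoDocument"])
    if doc.slide_meta is not None:
        m = doc.slide_meta
        add(docnode, RDF.type, C[_SLIDE_CLASS[m.modality]])
        if m.height is not None:
            add(docnode, D["height"], Literal(int(m.height)))
        if m.width is not None:
            add(docnode, D["width"], Literal(int(m.width)))
        if m.magnification is not None:
            add(docnode, D["magnification"], Literal(float(m.magnification)))
        if m.antigen:
            add(docnode, D["antigen"], Literal(m.antigen))
    if doc.provenance:
        add(docnode, D["provenance"], Literal(doc.provenance))

    def emit_entity(e: EntityNode) -> None:
        s = ind(e.id)
        add(s, RDF.type, C[e.entity_class])
        if e.display_name:
            add(s, D["displayName"], Literal(e.display_name))
        if e.subtype:
            add(s, D["subtype"], Literal(e.subtype))
        if e.outline is not None:
            add(s, D["segmentation"], Literal(_outline_str(e.outline)))
        if e.bbox is not None:
            add(s, D["boundingBox"], Literal(_bbox_str(e.bbox)))
        for (voc, code) in e.xrefs:
            emit_xref(e.id, voc, code)

    xref_seen: set[tuple[str, str, str]] = set()

    def emit_xref(node_id: str, voc: str, code: str) -> None:
        key = (node_id, voc, code)
        if key in xref_seen:
            return
        xref_seen.add(key)
        xid = ind(f"xref-{voc}-{code}")
        add(xid, RDF.type, C["Xref"])
        add(xid, D["vocabulary"], Literal(voc))
        add(xid, D["code"], Literal(code))
        add(ind(node_id), O["hasXref"], xid)

    def emit_param(q: QuantParam) -> None:
        s = ind(q.id)
        add(s, RDF.type, C["Quantification"])
        add(s, D["name"], Literal(q.param_name))
        add(s, D["hasValue"], Literal(float(q.value)))
        if q.unit:
            add(s, D["unit"], Literal(q.unit))

    def emit_graph(g: EntityGraph) -> None:
        for e in g.entities().values():
            emit_entity(e)
        for f in g.features.values():
            s = ind(f.id)
            add(s, RDF.type, C["EntityAttribute"])
            add(s, D["name"], Literal(f.feature_name))
        for q in g.params.values():
            emit_param(q)
        for (a, c) in g.part_whole:
            add(ind(a), O["hasComponent"], ind(c))
        for (e, c) in g.feature_links:
            add(ind(e), O["hasAttribute"], ind(c))
        for (c, q) in g.quant_links:
            add(ind(c), O["quantification"], ind(q))
        for (c, p) in g.express_links:
            add(ind(c), O["express"], ind(p))

    # entity graphs: document-level plus phenotype expansions, emitted once
    emitted_roots: set[str] = set()
    for g in doc.entity_graphs.values():
        emit_graph(g)
        add(docnode, O["has_Entity"], ind(g.root.id))
        emitted_roots.add(g.root.id)
    for p in doc.phenotypes.values():
        for g in p.entity_graphs.values():
            if g.root.id in emitted_roots:
                continue
            emit_graph(g)
            add(docnode, O["has_Entity"], ind(g.root.id))
            emitted_roots.add(g.root.id)

    for p in doc.phenotypes.values():
        s = ind(p.id)
        add(s, RDF.type, C[p.pathoml_class])
        if p.label:
            add(s, D["name"], Literal(p.label))
        add(s, D["phenotypeKind"], Literal(p.kind))
        add(docnode, O["has_Phenotype"], s)
        for eid in p.entities:
            add(s, O["present_Entity"], ind(eid))
        for rel in p.relationships:
            r = ind(rel.id)
            add(r, RDF.type, C["Relationship"])
            add(r, D["predicate"], Literal(rel.predicate))
            add(r, D["category"], Literal(rel.category))
            for sid in rel.subjects:
                add(r, O["subject"], ind(sid))
            for oid in rel.objects:
                add(r, O["object"], ind(oid))
            add(s, O["hasRelationship"], r)

    for qi in doc.indicators.values():
        s = ind(qi.id)
        add(s, RDF.type, C["Quantitative_Indicators"])
        if qi.name:
            add(s, D["name"], Literal(qi.name))
        add(s, D["hasValue"], Literal(float(qi.value)))
        if qi.formula:
            add(s, D["hasFormula"], Literal(qi.formula))
        add(docnode, O["has_Phenotype"], s)
        for q in qi.params.values():
            emit_param(q)
            add(s, O["has_quantity"], ind(q.id))

    for dp in doc.processes.values():
        s = ind(dp.id)
        add(s, RDF.type, C["DiagnosisProcess"])
        if dp.item:
            add(s, D["diagnosticItem"], Literal(dp.item))
        add(docnode, O["has_Process"], s)
        prev: Optional[URIRef] = None
        for stage in dp.stages:
            t = ind(stage.id)
            add(t, RDF.type, C["DiagnosisStage"])
            add(t, D["stageIndex"], Literal(int(stage.index)))
            add(s, O["diagnosisOrder"], t)
            if prev is not None:
                add(prev, O["nextStep"], t)
            prev = t
            for pid in stage.phenotypes:
                add(t, O["usesPhenotype"], ind(pid))
            for d in stage.possibilities:
                u = ind(d.id)
                cls = "Final_Diagnosis" if d.status == "established" else "Differential_Diagnosis"
                add(u, RDF.type, C[cls])
                if d.label:
                    add(u, D["name"], Literal(d.label))
                add(t, O["stepProcess"], u)
                for pid in d.support:
                    add(u, O["hasSupportEvidence"], ind(pid))
                for pid in d.contradict:
                    add(u, O["hasContradictEvidence"], ind(pid))

    for x in doc.xrefs:
        emit_xref(x.node_id, x.vocabulary, x.code)

    return triples


_PREFIXES = (("rdf", str(RDF)), ("owl", str(OWL)), ("xsd", str(XSD)))
_XSD_RE = re.compile(r"\^\^<http://www\.w3\.org/2001/XMLSchema#(\w+)>")


def _term_str(term, b: PathoMLBinding) -> str:
    if isinstance(term, URIRef):
        s = str(term)
        if s == str(RDF.type):
            return "a"
        if s.startswith(b.schema_iri):
            return "pathoml:" + s[len(b.schema_iri):]
        if s.startswith(b.doc_iri):
            return ":" + s[len(b.doc_iri):]
        for pfx, ns in _PREFIXES:
            if s.startswith(ns):
                return f"{pfx}:{s[len(ns):]}"
        return f"<{s}>"
    return _XSD_RE.sub(r"^^xsd:\1", term.n3())


def _canonical_turtle(triples: list[tuple], b: PathoMLBinding) -> str:
    lines = [
        f"@prefix : <{b.doc_iri}> .",
        f"@prefix pathoml: <{b.schema_iri}> .",
        "@prefix owl: <http://www.w3.org/2002/07/owl#> .",
        "@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .",
        "@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .",
        "",
        f"<{b.doc_iri.rstrip('#')}> a owl:Ontology .",
    ]
    body = sorted({(_term_str(s, b), _term_str(p, b), _term_str(o, b))
                   for s, p, o in triples})
    lines.extend(f"{s} {p} {o} ." for s, p, o in body)
    return "\n".join(lines) + "\n"


def write_pathoml(doc: PathoDocument, dialect: str = "turtle",
                  binding: PathoMLBinding = DEFAULT_BINDING) -> str:
    """Serialize a validated document to PathoML text.

    Refuses an invalid document, raising
    :class:`~pathograph.errors.DocumentValidationError` with the violation
    list.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}, got {dialect!r}")
    violations = validate(doc)
    if violations:
        raise DocumentValidationError(violations)
    triples = [] if doc.is_empty() else _doc_triples(doc, binding)
    if dialect == "turtle":
        return _canonical_turtle(triples, binding)
    g = Graph()
    g.bind("pathoml", binding.schema_iri)
    g.bind("", binding.doc_iri)
    g.add((URIRef(binding.doc_iri.rstrip("#")), RDF.type, OWL.Ontology))
    for t in sorted(triples, key=lambda t: (t[0].n3(), t[1].n3(), t[2].n3())):
        g.add(t)
    return g.serialize(format="xml")


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _detect_format(text: str) -> str:
    head = text.lstrip()[:200]
    if head.startswith("<?xml") or head.startswith("<rdf:RDF") or head.startswith("<rdf"):
        return "xml"
    return "turtle"


def read_pathoml(text: str, binding: PathoMLBinding = DEFAULT_BINDING) -> PathoDocument:
    """Parse PathoML text (Turtle or RDF/XML) into a :class:`PathoDocument`.

    Raises :class:`PathoMLParseError` for unparseable input or an unknown
    class IRI, and :class:`ResolutionError` when an object property points
    at an undeclared individual.
    """
    g = Graph()
    try:
        g.parse(data=text, format=_detect_format(text))
    except Exception as exc:  # rdflib raises assorted parse exceptions
        raise PathoMLParseError(f"could not parse input: {exc}") from exc

    b = binding
    objprops = {str(v): k for k, v in b.objprop_map.items()}
    dataprops = {str(v): k for k, v in b.dataprop_map.items()}
    class_by_iri = {str(v): k for k, v in b.class_map.items()}

    types: dict[str, set[str]] = {}
    for s, _, o in g.triples((None, RDF.type, None)):
        if o == OWL.Ontology:
            continue
        cls = class_by_iri.get(str(o))
        if cls is None:
            raise PathoMLParseError(f"unknown class IRI {o}")
        types.setdefault(b.local_id(s), set()).add(cls)

    # object-property targets must be declared individuals
    for s, p, o in g:
        kind = objprops.get(str(p))
        if kind is None:
            continue
        for term, role in ((s, "subject"), (o, "target")):
            if not isinstance(term, URIRef):
                raise PathoMLParseError(f"{kind} {role} is not an IRI: {term}")
            if b.local_id(term) not in types:
                raise ResolutionError(b.local_id(term),
                                      f"{kind} {role} has no declaration")

    def dval(node_id: str, prop: str, default=None):
        for o in g.objects(b.individual(node_id), b.dataprop_map[prop]):
            return o.toPython()
        return default

    def targets(node_id: str, prop: str) -> list[str]:
        return sorted(b.local_id(o)
                      for o in g.objects(b.individual(node_id), b.objprop_map[prop]))

    def sources(node_id: str, prop: str) -> list[str]:
        return sorted(b.local_id(s)
                      for s in g.subjects(b.objprop_map[prop], b.individual(node_id)))

    doc = PathoDocument()

    by_class: dict[str, list[str]] = {}
    for nid, cls_set in types.items():
        for cls in cls_set:
            by_class.setdefault(cls, []).append(nid)

    def make_entity(nid: str) -> EntityNode:
        cls = next(c for c in types[nid] if c in ENTITY_CLASS_NAMES)
        outline = dval(nid, "segmentation")
        bbox = dval(nid, "boundingBox")
        return EntityNode(
            id=nid, entity_class=cls,
            display_name=dval(nid, "displayName", "") or "",
            subtype=dval(nid, "subtype", "") or "",
            outline=_parse_outline(outline) if outline else None,
            bbox=tuple(float(v) for v in bbox.split(",")) if bbox else None)

    def make_param(nid: str, feature_id: Optional[str] = None) -> QuantParam:
        return QuantParam(id=nid, param_name=str(dval(nid, "name", "") or ""),
                          value=float(dval(nid, "hasValue", 0.0)),
                          unit=str(dval(nid, "unit", "") or ""),
                          feature_id=feature_id)

    # --- entity graphs anchored at the document node -----------------------
    doc_ids = [nid for nid, cls in types.items() if "PathoDocument" in cls]
    doc_node = doc_ids[0] if doc_ids else None

    if doc_node is not None:
        for root_id in targets(doc_node, "has_Entity"):
            entity_ids = {root_id}
            frontier = [root_id]
            part_whole: set[tuple[str, str]] = set()
            express: set[tuple[str, str]] = set()
            while frontier:
                u = frontier.pop()
                for v in targets(u, "hasComponent"):
                    part_whole.add((u, v))
                    if v not in entity_ids:
                        entity_ids.add(v)
                        frontier.append(v)
                for v in targets(u, "express"):
                    express.add((u, v))
                    if v not in entity_ids:
                        entity_ids.add(v)
                        frontier.append(v)
            root = make_entity(root_id)
            components = {nid: make_entity(nid)
                          for nid in sorted(entity_ids - {root_id})}
            features: dict[str, FeatureNode] = {}
            feature_links: set[tuple[str, str]] = set()
            quant_links: set[tuple[str, str]] = set()
            params: dict[str, QuantParam] = {}
            for eid in sorted(entity_ids):
                for fid in targets(eid, "hasAttribute"):
                    features[fid] = FeatureNode(
                        id=fid, feature_name=str(dval(fid, "name", "") or ""),
                        owner_id=eid)
                    feature_links.add((eid, fid))
            for fid in sorted(features):
                for qid in targets(fid, "quantification"):
                    params[qid] = make_param(qid, feature_id=fid)
                    quant_links.add((fid, qid))
            doc.add_graph(EntityGraph(
                root=root, components=components, features=features,
                params=params, part_whole=part_whole,
                feature_links=feature_links, quant_links=quant_links,
                express_links=express))

    # --- phenotypes --------------------------------------------------------
    for cls in sorted(PHENOTYPE_CLASS_NAMES - {"Quantitative_Indicators"}):
        for nid in sorted(by_class.get(cls, ())):
            rels = []
            for rid in targets(nid, "hasRelationship"):
                rels.append(RelationshipEdge(
                    id=rid, predicate=str(dval(rid, "predicate", "") or ""),
                    category=str(dval(rid, "category", "") or ""),
                    subjects=targets(rid, "subject"),
                    objects=targets(rid, "object")))
            doc.add_phenotype(Phenotype(
                id=nid, label=str(dval(nid, "name", "") or ""),
                kind=str(dval(nid, "phenotypeKind", "") or ""),
                pathoml_class=cls, entities=targets(nid, "present_Entity"),
                relationships=rels))

    for nid in sorted(by_class.get("Quantitative_Indicators", ())):
        params = {qid: make_param(qid) for qid in targets(nid, "has_quantity")}
        doc.add_indicator(QuantIndicator(
            id=nid, name=str(dval(nid, "name", "") or ""),
            value=float(dval(nid, "hasValue", 0.0)),
            formula=str(dval(nid, "hasFormula", "") or ""), params=params))

    # --- diagnosis processes ----------------------------------------------
    for nid in sorted(by_class.get("DiagnosisProcess", ())):
        stage_ids = targets(nid, "diagnosisOrder")
        stages = []
        for sid in stage_ids:
            poss = []
            for did in targets(sid, "stepProcess"):
                status = ("established" if "Final_Diagnosis" in types[did]
                          else "excluded")
                poss.append(Diagnosis(
                    id=did, label=str(dval(did, "name", "") or ""),
                    status=status,
                    support=targets(did, "hasSupportEvidence"),
                    contradict=targets(did, "hasContradictEvidence")))
            stages.append(DiagnosisStage(
                id=sid, index=int(dval(sid, "stageIndex", 0)),
                possibilities=poss, phenotypes=targets(sid, "usesPhenotype")))
        stages.sort(key=lambda s: s.index)
        doc.add_process(DiagnosisProcess(
            id=nid, stages=stages,
            item=str(dval(nid, "diagnosticItem", "") or "")))

    # --- document metadata and xrefs ---------------------------------------
    if doc_node is not None:
        slide_types = types[doc_node] & set(_SLIDE_MODALITY)
        if slide_types:
            cls = sorted(slide_types)[0]
            h = dval(doc_node, "height")
            w = dval(doc_node, "width")
            mag = dval(doc_node, "magnification")
            doc.slide_meta = SlideMeta(
                modality=_SLIDE_MODALITY[cls],
                height=int(h) if h is not None else None,
                width=int(w) if w is not None else None,
                magnification=float(mag) if mag is not None else None,
                antigen=str(dval(doc_node, "antigen", "") or ""))
        doc.provenance = str(dval(doc_node, "provenance", "") or "")

    xrefs = set()
    for xid in sorted(by_class.get("Xref", ())):
        voc = str(dval(xid, "vocabulary", "") or "")
        code = str(dval(xid, "code", "") or "")
        for owner in sources(xid, "hasXref"):
            xrefs.add((owner, voc, code))
    doc.xrefs = [Xref(node_id=a, vocabulary=v, code=c)
                 for a, v, c in sorted(xrefs)]
    return doc


# ---------------------------------------------------------------------------
# Xrefs and comparisons
# ---------------------------------------------------------------------------


def attach_xref(node_id: str, vocabulary: str, code: str,
                doc: PathoDocument) -> PathoDocument:
    """Record a controlled-vocabulary mapping on a document node.

    Idempotent: attaching an identical xref twice leaves one record.
    Raises :class:`ResolutionError` for an unknown node.
    """
    if node_id not in document_ids(doc):
        raise ResolutionError(node_id, "attach_xref target")
    if not any(x.node_id == node_id and x.vocabulary == vocabulary
               and x.code == code for x in doc.xrefs):
        doc.xrefs.append(Xref(node_id=node_id, vocabulary=vocabulary, code=code))
    return doc


def triple_set(text: str) -> set[tuple[str, str, str]]:
    """The RDF triple set of a PathoML text, as plain string triples."""
    g = Graph()
    g.parse(data=text, format=_detect_format(text))
    return {(str(s), str(p), str(o)) for s, p, o in g}


def documents_isomorphic(a: PathoDocument, d: PathoDocument,
                         binding: PathoMLBinding = DEFAULT_BINDING) -> bool:
    """Graph isomorphism of two documents, treating node ids as labels.

    Since ids are labels (not blank nodes), isomorphism reduces to equality
    of the canonical serialized triple sets.
    """
    return (triple_set(write_pathoml(a, binding=binding))
            == triple_set(write_pathoml(d, binding=binding)))
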