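"""Deterministic generators for scenes, IHC cohorts and exemplar documents.

These stand in for the upstream inputs of the pipeline: segmentation
scenes (as produced by tumor/nucleus segmenters), IHC cohorts with a
prescribed staining-completeness distribution, and small hand-built
documents reproducing the package's worked examples (the HER2
immunophenotype, the back-to-back follicular pattern, the cervical
subtyping process, the lymphoma differential and the cervical slide used
for reasoning).

Every generator is seed-deterministic: the same spec and seed produce
byte-identical output.  Exemplars encode only what the worked examples
state; unstated detail (component counts, ids) is fixed minimally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .core_model import (Diagnosis, DiagnosisStage, EntityNode, FeatureNode,
                         PathoDocument, Phenotype, QuantIndicator, QuantParam,
                         RelationshipEdge, SlideMeta, Xref,
                         build_diagnosis_process, build_entity_graph)
from .errors import PathoGraphError

EXEMPLAR_NAMES = ("her2_fig4", "follicle_fig5", "cervical_fig6",
                  "lymphoma_fig7", "cervical_slide_fig11", "lymphoma_slide_fig7")


@dataclass(frozen=True)
class SceneSpec:
    """Synthetic segmentation-scene layout."""

    n_tumors: int = 2
    nuclei_per_tumor: int = 5
    n_stray_nuclei: int = 3
    width: int = 1000
    height: int = 1000
    seed: int = 0


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic IHC cohort with target staining-bin fractions."""

    complete: float = 0.75
    moderate: float = 0.15
    incomplete: float = 0.05
    unstained: float = 0.05
    n_cells: int = 20
    seed: int = 0


def _blob(rng: np.random.Generator, cx: float, cy: float, r: float,
          n_pts: int = 12) -> tuple[tuple[float, float], ...]:
    """A random convex blob: convex hull of jittered circle points."""
    angles = np.sort(rng.uniform(0.0, 2.0 * math.pi, size=n_pts))
    radii = rng.uniform(0.6 * r, r, size=n_pts)
    pts = [(cx + rad * math.cos(a), cy + rad * math.sin(a))
           for a, rad in zip(angles, radii)]
    hull = Polygon(pts).convex_hull.exterior.coords[:-1]
    return tuple((round(x, 2), round(y, 2)) for x, y in hull)


def _nucleus_poly(rng: np.random.Generator, cx: float, cy: float,
                  r: float) -> tuple[tuple[float, float], ...]:
    angles = np.linspace(0.0, 2.0 * math.pi, 8, endpoint=False)
    radii = rng.uniform(0.75 * r, r, size=8)
    return tuple((round(cx + rad * math.cos(a), 2),
                  round(cy + rad * math.sin(a), 2))
                 for a, rad in zip(angles, radii))


def make_scene(spec: SceneSpec) -> tuple[str, dict[str, str | None]]:
    """Generate a GeoJSON scene and its ground-truth assignment.

    Tumors are random convex blobs on a non-overlapping grid; each tumor
    contains ``nuclei_per_tumor`` neoplastic nuclei strictly inside its
    polygon; stray nuclei lie outside every tumor.  The ground truth maps
    each neoplastic nucleus id to its containing tumor id (strays map to
    None).
    """
    rng = np.random.default_rng(spec.seed)
    features: list[dict] = []
    truth: dict[str, str | None] = {}

    n_cells_axis = max(1, math.ceil(math.sqrt(max(spec.n_tumors, 1))))
    cell_w = spec.width / n_cells_axis
    cell_h = spec.height / n_cells_axis
    tumor_polys: list[Polygon] = []

    def add_feature(fid: str, cls: str, outline) -> None:
        ring = [[x, y] for x, y in outline] + [[outline[0][0], outline[0][1]]]
        features.append({"type": "Feature", "id": fid,
                         "properties": {"class": cls},
                         "geometry": {"type": "Polygon", "coordinates": [ring]}})

    nucleus_r = min(cell_w, cell_h) * 0.02 + 4.0
    for t in range(spec.n_tumors):
        gx, gy = t % n_cells_axis, t // n_cells_axis
        cx = (gx + 0.5) * cell_w
        cy = (gy + 0.5) * cell_h
        r = 0.30 * min(cell_w, cell_h)
        tid = f"tumor-{t + 1}"
        outline = _blob(rng, cx, cy, r)
        poly = Polygon(outline)
        tumor_polys.append(poly)
        add_feature(tid, "tumor", outline)
        for k in range(spec.nuclei_per_tumor):
            nid = f"nucleus-{t + 1}-{k + 1}"
            for _ in range(200):
                ang = rng.uniform(0.0, 2.0 * math.pi)
                rad = rng.uniform(0.0, 0.45 * r)
                npoly = _nucleus_poly(rng, cx + rad * math.cos(ang),
                                      cy + rad * math.sin(ang), nucleus_r)
                if Polygon(npoly).within(poly):
                    break
            else:
                raise PathoGraphError(f"could not place nucleus {nid} inside {tid}")
            add_feature(nid, "neoplastic_nucleus", npoly)
            truth[nid] = tid

    margin = nucleus_r * 3.0
    for k in range(spec.n_stray_nuclei):
        nid = f"stray-{k + 1}"
        for _ in range(500):
            cx = rng.uniform(margin, spec.width - margin)
            cy = rng.uniform(margin, spec.height - margin)
            npoly = _nucleus_poly(rng, cx, cy, nucleus_r)
            shp = Polygon(npoly)
            if all(shp.disjoint(tp) for tp in tumor_polys):
                break
        else:
            raise PathoGraphError(f"could not place stray nucleus {nid}")
        add_feature(nid, "neoplastic_nucleus", npoly)
        truth[nid] = None

    fc = {"type": "FeatureCollection", "width": spec.width,
          "height": spec.height, "features": features}
    return json.dumps(fc, sort_keys=True, separators=(",", ":")), truth


def _largest_remainder_counts(fractions, n: int) -> list[int]:
    raw = [f * n for f in fractions]
    counts = [int(math.floor(x)) for x in raw]
    rem = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


_BIN_RANGES = {"complete": (0.9, 1.0), "moderate": (0.7, 0.9),
               "incomplete": (0.5, 0.7), "unstained": (0.0, 0.5)}


def make_cohort(spec: CohortSpec) -> tuple[PathoDocument, list[float]]:
    """An IHC document with one immunophenotyped tumor cell per cohort member.

    Bin counts realize the target fractions by largest-remainder rounding;
    each cell's staining completeness is drawn uniformly within its bin.
    Returns the document and the generated ground-truth values (cell order).
    """
    total = spec.complete + spec.moderate + spec.incomplete + spec.unstained
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"bin fractions must sum to 1, got {total}")
    rng = np.random.default_rng(spec.seed)
    counts = _largest_remainder_counts(
        (spec.complete, spec.moderate, spec.incomplete, spec.unstained),
        spec.n_cells)
    bins = [b for b, c in zip(_BIN_RANGES, counts) for _ in range(c)]
    doc = PathoDocument(slide_meta=SlideMeta(modality="IHC", antigen="HER2"),
                        provenance=f"synthetic HER2 cohort, seed={spec.seed}")
    values: list[float] = []
    for i, bin_name in enumerate(bins, start=1):
        lo, hi = _BIN_RANGES[bin_name]
        v = float(rng.uniform(lo, hi))
        values.append(v)
        cell = EntityNode(id=f"Cell{i}", entity_class="NeoplasticCell")
        membrane = EntityNode(id=f"Membrane{i}",
                              entity_class="NeoplasticCellularComponent")
        her2 = EntityNode(id=f"HER2-{i}", entity_class="Protein",
                          display_name="HER2")
        feat = FeatureNode(id=f"StainingExtent{i}",
                           feature_name="staining extent",
                           owner_id=membrane.id)
        param = QuantParam(id=f"Quantification{i}",
                           param_name="staining extent", value=v,
                           feature_id=feat.id)
        g = build_entity_graph(
            cell, [membrane, her2], [feat], [param],
            relations={"part_whole": {(cell.id, membrane.id)},
                       "express_links": {(membrane.id, her2.id)}})
        doc.add_graph(g)
        doc.add_phenotype(Phenotype(
            id=f"Phenotype{i}", label="HER2 membrane staining",
            kind="single_cell", pathoml_class="Immunophenotype",
            entities=[cell.id]))
    return doc, values


# ---------------------------------------------------------------------------
# Exemplar documents
# ---------------------------------------------------------------------------


def _her2_fig4() -> PathoDocument:
    cell = EntityNode(id="Cell1", entity_class="NeoplasticCell")
    membrane = EntityNode(id="Membrane1",
                          entity_class="NeoplasticCellularComponent")
    nucleus = EntityNode(id="Nucleus1",
                         entity_class="NeoplasticCellularComponent")
    her2 = EntityNode(id="HER2", entity_class="Protein", display_name="HER2")
    feat = FeatureNode(id="Medium", feature_name="staining extent",
                       owner_id="Membrane1")
    param = QuantParam(id="Quantification1", param_name="staining extent",
                       value=0.75, feature_id="Medium")
    g = build_entity_graph(
        cell, [membrane, nucleus, her2], [feat], [param],
        relations={"part_whole": {("Cell1", "Membrane1"), ("Cell1", "Nucleus1")},
                   "express_links": {("Membrane1", "HER2")}})
    doc = PathoDocument(slide_meta=SlideMeta(modality="IHC", antigen="HER2"))
    doc.add_graph(g)
    doc.add_phenotype(Phenotype(
        id="Phenotype1", label="HER2 membrane staining", kind="single_cell",
        pathoml_class="Immunophenotype", entities=["Cell1"]))
    return doc


def _follicle_fig5() -> PathoDocument:
    doc = PathoDocument(slide_meta=SlideMeta(modality="HE"))
    for i in (1, 2):
        root = EntityNode(id=f"Tumor{i}", entity_class="Tumor",
                          display_name=f"follicle {i}")
        comps = [EntityNode(id=f"Stroma{i}", entity_class="Stroma"),
                 EntityNode(id=f"Parenchyma{i}", entity_class="Parenchyma"),
                 EntityNode(id=f"Substance{i}", entity_class="Substance",
                            display_name="colloid"),
                 EntityNode(id=f"NeoplasticCell{i}",
                            entity_class="NeoplasticCell")]
        doc.add_graph(build_entity_graph(root, comps))
    doc.add_phenotype(Phenotype(
        id="Phenotype2", label="follicular pattern", kind="multi_cell",
        pathoml_class="Histopathological_Phenotype",
        entities=["Tumor1", "Tumor2"],
        relationships=[RelationshipEdge(
            id="Relationship1", predicate="back-to-back arrangement",
            category="spatial", subjects=["Tumor1"], objects=["Tumor2"])]))
    return doc


_MUCIN_FORMULA = ("<apply><divide/><ci>mucin_cell_count</ci>"
                  "<ci>tumor_cell_count</ci></apply>")


def _cervical_fig6() -> PathoDocument:
    doc = PathoDocument(slide_meta=SlideMeta(modality="report"))
    doc.add_phenotype(Phenotype(
        id="GlandularPattern", label="glandular pattern", kind="multi_cell",
        pathoml_class="Histopathological_Phenotype"))
    doc.add_phenotype(Phenotype(
        id="ApoptoticBody", label="apoptotic body", kind="single_cell",
        pathoml_class="Cytopathological_Phenotype"))
    doc.add_phenotype(Phenotype(
        id="LuminalMitosis", label="luminal mitosis", kind="single_cell",
        pathoml_class="Cytopathological_Phenotype"))
    doc.add_indicator(QuantIndicator(
        id="MucinIndicator", name="intracytoplasmic mucin proportion",
        value=0.40, formula=_MUCIN_FORMULA,
        params={"MucinCellCount": QuantParam(id="MucinCellCount",
                                             param_name="mucin_cell_count",
                                             value=40.0),
                "TumorCellCount": QuantParam(id="TumorCellCount",
                                             param_name="tumor_cell_count",
                                             value=100.0)}))
    stages = [
        DiagnosisStage(id="Stage1", index=1, phenotypes=["GlandularPattern"],
                       possibilities=[Diagnosis(
                           id="Diagnosis1", label="adenocarcinoma",
                           status="established",
                           support=["GlandularPattern"])]),
        DiagnosisStage(id="Stage2", index=2,
                       phenotypes=["ApoptoticBody", "LuminalMitosis"],
                       possibilities=[Diagnosis(
                           id="Diagnosis2", label="HPVA",
                           status="established",
                           support=["ApoptoticBody", "LuminalMitosis"])]),
        DiagnosisStage(id="Stage3", index=3, phenotypes=["MucinIndicator"],
                       possibilities=[Diagnosis(
                           id="Diagnosis3", label="HPVA, usual type",
                           status="established",
                           support=["MucinIndicator"])]),
    ]
    doc.add_process(build_diagnosis_process(stages, item="histologic type"))
    return doc


def _lymphoma_fig7() -> PathoDocument:
    doc = PathoDocument(slide_meta=SlideMeta(modality="report"))
    doc.add_phenotype(Phenotype(
        id="HEPhenotype", label="diffuse proliferation of large lymphoid cells",
        kind="multi_cell", pathoml_class="Histopathological_Phenotype"))
    for marker in ("LCA", "CD20", "BOB1"):
        doc.add_phenotype(Phenotype(
            id=f"{marker}Positive", label=f"{marker} positive",
            kind="single_cell", pathoml_class="Immunophenotype"))
    stages = [
        DiagnosisStage(id="Stage1", index=1, phenotypes=["HEPhenotype"],
                       possibilities=[Diagnosis(
                           id="Diagnosis1", label="lymphoma",
                           status="established", support=["HEPhenotype"])]),
        DiagnosisStage(
            id="Stage2", index=2,
            phenotypes=["LCAPositive", "CD20Positive", "BOB1Positive"],
            possibilities=[
                Diagnosis(id="Diagnosis2",
                          label="T-cell and NK-cell lymphoma",
                          status="excluded",
                          contradict=["CD20Positive", "BOB1Positive"]),
                Diagnosis(id="Diagnosis3", label="large B-cell lymphoma",
                          status="established",
                          support=["LCAPositive", "CD20Positive",
                                   "BOB1Positive"]),
                Diagnosis(id="Diagnosis4", label="Hodgkin lymphoma",
                          status="excluded",
                          contradict=["LCAPositive", "BOB1Positive"]),
            ]),
    ]
    doc.add_process(build_diagnosis_process(stages, item="histologic type"))
    return doc


def _cervical_slide_fig11() -> PathoDocument:
    doc = PathoDocument(slide_meta=SlideMeta(modality="HE"))
    doc.add_phenotype(Phenotype(
        id="SlideGlandularPattern", label="glandular pattern",
        kind="multi_cell", pathoml_class="Histopathological_Phenotype"))
    doc.add_phenotype(Phenotype(
        id="SlideApoptoticBody", label="apoptotic body", kind="single_cell",
        pathoml_class="Cytopathological_Phenotype"))
    doc.add_phenotype(Phenotype(
        id="SlideLuminalMitosis", label="luminal mitosis", kind="single_cell",
        pathoml_class="Cytopathological_Phenotype"))
    return doc


def _lymphoma_slide_fig7() -> PathoDocument:
    doc = PathoDocument(slide_meta=SlideMeta(modality="IHC"))
    doc.add_phenotype(Phenotype(
        id="SlideHEPhenotype",
        label="diffuse proliferation of large lymphoid cells",
        kind="multi_cell", pathoml_class="Histopathological_Phenotype"))
    for marker in ("LCA", "CD20", "BOB1"):
        doc.add_phenotype(Phenotype(
            id=f"Slide{marker}Positive", label=f"{marker} positive",
            kind="single_cell", pathoml_class="Immunophenotype"))
    return doc


def random_document(seed: int) -> PathoDocument:
    """A small random-but-valid document for serialization stress tests.

    Contains a random mix of entity graphs (with features, parameters and
    express edges), phenotypes, an indicator, a diagnosis process and
    xrefs; always passes validation.
    """
    rng = np.random.default_rng(seed)
    doc = PathoDocument(provenance=f"random document seed={seed}")
    n_graphs = int(rng.integers(0, 4))
    for gi in range(n_graphs):
        root = EntityNode(id=f"g{gi}-root", entity_class="Tumor")
        comps, feats, params = [], [], []
        part_whole, express = set(), set()
        for ci in range(int(rng.integers(0, 4))):
            cell = EntityNode(id=f"g{gi}-cell{ci}", entity_class="NeoplasticCell")
            comps.append(cell)
            part_whole.add((root.id, cell.id))
            if rng.random() < 0.5:
                comp = EntityNode(id=f"g{gi}-mem{ci}",
                                  entity_class="NeoplasticCellularComponent")
                comps.append(comp)
                part_whole.add((cell.id, comp.id))
                if rng.random() < 0.5:
                    prot = EntityNode(id=f"g{gi}-prot{ci}",
                                      entity_class="Protein",
                                      display_name="HER2")
                    comps.append(prot)
                    express.add((comp.id, prot.id))
            if rng.random() < 0.7:
                f = FeatureNode(id=f"g{gi}-feat{ci}", feature_name="area",
                                owner_id=cell.id)
                feats.append(f)
                params.append(QuantParam(id=f"g{gi}-param{ci}",
                                         param_name="area",
                                         value=float(rng.uniform(10, 500)),
                                         unit="px^2", feature_id=f.id))
        doc.add_graph(build_entity_graph(
            root, comps, feats, params,
            relations={"part_whole": part_whole, "express_links": express}))
    labels = ["glandular pattern", "apoptotic body", "nuclear atypia",
              "papillary arrangement", "stromal invasion"]
    n_phen = int(rng.integers(0, 4))
    for pi in range(n_phen):
        doc.add_phenotype(Phenotype(
            id=f"phen{pi}", label=labels[int(rng.integers(0, len(labels)))],
            kind="multi_cell", pathoml_class="Histopathological_Phenotype"))
    if rng.random() < 0.5:
        doc.add_indicator(QuantIndicator(
            id="indic0", name="tumor-stroma ratio",
            value=float(rng.uniform(0, 1))))
    if n_phen > 0 and rng.random() < 0.7:
        pids = [f"phen{pi}" for pi in range(n_phen)]
        stages = []
        for si in range(int(rng.integers(1, 3))):
            n_poss = int(rng.integers(1, 3))
            poss = []
            for di in range(n_poss):
                established = di == 0
                poss.append(Diagnosis(
                    id=f"s{si}-d{di}", label=f"diagnosis {si}.{di}",
                    status="established" if established else "excluded",
                    support=[pids[int(rng.integers(0, len(pids)))]]))
            stages.append(DiagnosisStage(id=f"stage{si}", index=si + 1,
                                         possibilities=poss, phenotypes=pids))
        doc.add_process(build_diagnosis_process(stages, item="histologic type"))
    if n_phen > 0 and rng.random() < 0.5:
        doc.xrefs.append(Xref(node_id="phen0", vocabulary="NCIT",
                              code=f"C{int(rng.integers(1000, 9999))}"))
    return doc


_EXEMPLARS = {"her2_fig4": _her2_fig4, "follicle_fig5": _follicle_fig5,
              "cervical_fig6": _cervical_fig6, "lymphoma_fig7": _lymphoma_fig7,
              "cervical_slide_fig11": _cervical_slide_fig11,
              "lymphoma_slide_fig7": _lymphoma_slide_fig7}


def exemplar(name: str) -> PathoDocument:
    """A fresh copy of a named exemplar document.

    Known names: her2_fig4, follicle_fig5, cervical_fig6, lymphoma_fig7,
    cervical_slide_fig11 and lymphoma_slide_fig7 (the slide-side inputs of
    the two reasoning demonstrations).
    """
    try:
        builder = _EXEMPLARS[name]
    except KeyError:
        raise KeyError(f"unknown exemplar {name!r}; known: "
                       f"{sorted(_EXEMPLARS)}") from None
    return builder()
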