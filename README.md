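# pathograph

Graph-based representation of pathology knowledge, for computational
pathology researchers and tool builders who need slide findings and
diagnostic reasoning in a machine-readable form.

Pathology knowledge — what a diseased tissue is made of, what its cells
look like, and how a pathologist reasons from findings to a diagnosis — is
normally locked inside slide pixels and free-text reports. `pathograph`
represents it as typed graphs:

* **Pathology entity graph** — for an entity *a*, the graph
  𝒢ₐ = ({a} ∪ Eₐ ∪ Cₐ ∪ Qₐ, Rₑₑ ∪ Rₑ꜀ ∪ R꜀q): its components Eₐ
  (part–whole tree), pathological features Cₐ and quantitative parameters
  Qₐ, plus *express* links between cellular components and the proteins
  they carry.
* **Phenotypes** — single-cell, multi-cell (with spatial/behavioral
  relationships such as a back-to-back arrangement of follicles) and
  quantitative phenotypic indicators with value and formula.
* **Diagnosis processes** — ordered diagnostic stages, each considering
  diagnostic possibilities that are established or excluded via
  supporting/contradicting phenotypic evidence.

Documents are serialized as **PathoML**, an OWL-based exchange format
(Turtle or RDF/XML): nodes become named individuals, edges become object
properties (`hasComponent`, `express`, `hasAttribute`, `quantification`,
`present_Entity`, `stepProcess`, …), scalars become data properties
(`hasValue`, `segmentation`, …).

On top of the model the package implements:

* **Automated entity-graph construction** from segmentation geometry
  (GeoJSON polygons for tumor regions and nuclei): nuclei are assigned to
  tumors by polygon-overlap fraction, and each nucleus carries five
  morphometric parameters (area, perimeter, roundness 4πA/P², shape
  factor P²/4πA, solidity), with an optional GraphML export for graph ML.
* **Quantitative HER2 scoring**: membrane staining extent θ/2π per tumor
  cell is retrieved by a SPARQL graph-pattern query over the serialized
  ontology, binned into complete [0.9, 1] / moderate [0.7, 0.9) /
  incomplete [0.5, 0.7) / unstained [0, 0.5), and the HER2 status called
  as 3+ / 2+ / 1+ / 0 (strict >10% rules, >90% unstained for 0).
* **Subsumption-based subtyping**: slide phenotypes and diagnostic
  knowledge become conjunctions of existential phenotype atoms
  (∃exhibits.P), and histologic subtype is decided by structural
  subsumption — sound and complete for this conjunctive-existential
  fragment.

## Worked example

A 20-cell immunohistochemistry cohort whose membrane staining-completeness
distribution is 75% complete, 15% moderate, 5% incomplete, 5% unstained:

```python
from pathograph import fixtures as fx
from pathograph.her2_quant import assess
from pathograph.pathoml_io import read_pathoml, write_pathoml

doc, _ = fx.make_cohort(fx.CohortSpec(n_cells=20, seed=1))
report = assess(read_pathoml(write_pathoml(doc)))
```

prints (keys `query` and `per_cell` omitted):

```json
{
  "fractions": {"complete": 0.75, "incomplete": 0.05,
                "moderate": 0.15, "unstained": 0.05},
  "n_cells": 20,
  "status": "3+",
  "warnings": []
}
```

More than 10% of the tumor cells show complete membrane staining, so the
slide's HER2 status is 3+. The report also carries the generated SPARQL
query and per-cell values, making every step reviewable.

Subtyping a cervical slide (glandular pattern, apoptotic body, luminal
mitosis) against a three-stage diagnostic process:

```python
from pathograph import fixtures as fx
from pathograph.dl_reasoner import subtype_slide

result = subtype_slide(fx.exemplar("cervical_slide_fig11"),
                       fx.exemplar("cervical_fig6"))
```

yields `reported_subtype = "HPVA"`: the slide concept is subsumed by the
adenocarcinoma concept (implied) and mutually subsumes the HPVA concept
(equivalent), so human-papillomavirus-associated endocervical
adenocarcinoma is reported, with the matched atoms listed as proof.

The same pipelines are available from the shell:

```sh
pathograph fixtures fixtures/            # regenerate deterministic inputs
pathograph build-peg scene.geojson pegs.ttl
pathograph her2 fixtures/her2_cohort.ttl
pathograph subtype fixtures/cervical_slide_fig11.ttl fixtures/cervical_fig6.ttl
pathograph validate doc.ttl
pathograph convert doc.ttl doc.owl --to rdfxml
```

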