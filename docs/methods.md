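# Methods

This note documents the models and procedures implemented by
`pathograph`, the defaults that matter, and what the synthetic generators
do and do not emulate.

## The graph model

A pathology document bundles three graph kinds.

**Entity graphs.** An entity graph is rooted at one pathological entity
(a tumor, a cell, …) and contains its components Eₐ, features Cₐ and
quantitative parameters Qₐ, with relation sets Rₑₑ ⊆ ({a} ∪ Eₐ) × Eₐ
(part–whole), Rₑ꜀ ⊆ ({a} ∪ Eₐ) × Cₐ (feature ownership) and
R꜀q ⊆ Cₐ × Qₐ (quantification). Validation enforces: membership of every
entity class in a closed controlled vocabulary (Cell, NeoplasticCell,
Cellular_Component, NeoplasticCellularComponent, Protein, Tumor, Stroma,
Parenchyma, Substance, Anatomical_Structure, plus an `Other` escape hatch
with a free-text subtype); acyclicity of the part–whole relation;
reachability of every component from the root; and the constraint that
`express` edges pair a cellular component with a protein. Reachability is
computed over part–whole *and* express edges: an expressed protein is a
legal graph member even though it is not a part of anything (this is how
a membrane-bound antigen such as HER2 sits in a cell's graph).

**Phenotypes.** Single-cell phenotypes involve exactly one cell;
multi-cell phenotypes involve ≥2 entities or ≥1 relationship
(spatial-arrangement or dynamic-behavior edges with nonempty, disjoint
subject and object sets); quantitative indicators carry a numeric value,
the parameters used to compute it, and a content-MathML formula that is
stored and roundtripped but never evaluated. A deliberate relaxation:
phenotypes that declare *no* entities at all (pure named diagnostic
features, e.g. "glandular pattern" cited as evidence in a diagnostic
process) are valid; the cardinality constraints apply only once entities
or relationships are declared. Without this, every label-only diagnostic
feature would be rejected, which would make the canonical diagnostic
worked examples unrepresentable.

**Diagnosis processes.** A process is a total chain of stages with
strictly increasing indices. Each stage considers ≥1 diagnostic
possibility, split into established and excluded; evidence links point at
phenotypes or indicators declared anywhere in the document (pathologists
reuse slide findings across stages). At the terminal stage at most one
possibility may be established; multiple established outcomes at earlier
stages are permitted but produce a warning at build time.

`validate(doc)` returns violation records (type, id, violated clause)
rather than raising, so a document can be triaged in one pass. The test
suite checks validation soundness by systematic single-field corruption.

## PathoML serialization

Nodes are serialized as named individuals under a per-document namespace
(`https://w3id.org/pathoml/document#`, configurable), typed by classes in
the schema namespace (`https://w3id.org/pathoml/schema#`); edges use
object properties and scalars data properties. All nodes are
individualized — no model node is flattened into a data property — which
keeps the read direction unambiguous. Design choices worth knowing:

* **Canonical Turtle** is the N-Triples-compatible subset of Turtle with
  a fixed prefix block and triples sorted by (subject, predicate,
  object). Two writes of the same document are byte-identical, and
  write→read→write is stable. RDF/XML is available as a second dialect
  and parses to the identical triple set.
* **Entity-graph anchoring**: every entity-graph root is linked from the
  document individual via `has_Entity`. Phenotype expansions
  (per-entity entity graphs) are serialized as document-level graphs;
  reading returns all graphs at document level with phenotypes
  unexpanded. `expand_phenotype` re-expands on demand and is idempotent.
* **Stage order** is emitted redundantly as `diagnosisOrder` membership,
  `nextStep` chain and an integer `stageIndex`; reading sorts by index.
* **Geometry encoding**: outlines are stored in the `segmentation` data
  property as `"x0,y0 x1,y1 …"` with 0-based pixel coordinates, polygon
  closed implicitly; bounding boxes as `"xmin,ymin,xmax,ymax"`.
* **Identifiers** are document-unique opaque strings, percent-encoded
  into IRI local names; builders use a deterministic `<class>-<counter>`
  scheme so generated fixtures are reproducible.
* MathML formulas are stored as literal strings and never interpreted.

## Morphometrics

All quantities are in pixels (physical units would require slide
magnification metadata, which is carried but not applied). For a simple
polygon with area A and perimeter P: roundness = 4πA/P², shape factor =
P²/4πA, solidity = A / area(convex hull). Roundness and shape factor are
deliberately distinct, reciprocal parameters; "shape factor" follows the
common compactness-ratio convention. The default nucleus feature bundle
is the five parameters (area, perimeter, roundness, shape factor,
solidity); the set is configurable.

Membrane staining extent is stained path length / total perimeter, which
for a circular membrane with stained arc θ equals θ/2π. Stained arcs are
index ranges over the outline's vertex sequence; fractional endpoints are
linearly interpolated, wrap-around arcs are supported, and overlapping
arcs are rejected. Degenerate or self-intersecting polygons raise
geometry errors (shapely validity is the arbiter).

## Automated entity-graph construction

The scene reader accepts GeoJSON FeatureCollections with Polygon features
classed `tumor`, `other`, `neoplastic_nucleus` or
`non_neoplastic_nucleus`. Assignment of nuclei to tumors uses the overlap
criterion *fraction of nucleus area intersecting the tumor polygon*, with
threshold 0.5 (a config key), maximum fraction winning and ties broken by
the lexicographically smaller tumor id. Non-neoplastic nuclei and
non-tumor regions are parsed but never enter entity graphs; they remain
in the scene for future phenotype construction. Each tumor becomes a
graph rooted at a Tumor node whose components are its assigned nuclei,
modeled as NeoplasticCell nodes carrying outline and bounding box — the
nucleus polygon stands for the observable footprint of the neoplastic
cell, an interpretive choice documented here. GraphML export folds each
nucleus's five feature values onto its node as attributes and types edges
by kind; it is a plain export hook, not a training pipeline.

## HER2 quantitation

Per-cell staining completeness is retrieved by a SPARQL query over the
*serialized* ontology (pattern: NeoplasticCell → hasComponent → membrane
→ hasAttribute → staining-extent attribute → quantification → hasValue),
so the retrieval path is exactly what an external PathoML consumer would
execute; the query text is included in the report for traceability. Bins
are half-open from below — complete [0.9, 1], moderate [0.7, 0.9),
incomplete [0.5, 0.7), unstained [0, 0.5) — partitioning [0, 1]; the
moderate bin's upper bound is 0.9 (the only reading under which the four
bins partition the interval). Status is decided by strict precedence:
3+ if complete > 10%, else 2+ if moderate > 10%, else 1+ if incomplete >
10%, else 0. The four printed criteria can be simultaneously true or all
false; precedence makes the classifier total and deterministic, and when
the residual 0 branch is taken with unstained ≤ 90% a warning records
that the literal 0-criterion was not met. Thresholds are strict
comparisons exactly as stated. This is a membrane-completeness score
only; intensity-based clinical guideline scoring (ASCO/CAP) is out of
scope.

## Subsumption reasoning

The logic fragment is conjunction plus existential restriction over a
single `exhibits` role, with no nesting — the smallest fragment in which
the subtyping examples are expressible. Structural subsumption (every
atom of D matched by an atom of C, under an optional acyclic
phenotype-label hierarchy) is sound and complete here, so no external
reasoner is needed; the test suite cross-checks it against brute-force
set containment over the full 2⁸×2⁸ atom-set lattice. Atom identity is
the xref code when a phenotype carries one, else its normalized
(case-folded, whitespace-collapsed) label. Diagnosis definitions are
cumulative along the stage chain — a stage inherits the atoms of
diagnoses established earlier, implementing the narrowing-down semantics
of staged diagnosis (a per-stage mode is a config switch). Contradicting
evidence cannot be expressed in a negation-free fragment, so it acts as a
post-filter: a diagnosis with a contradicting atom present on the slide
is excluded and never reported. When the slide carries atoms beyond a
diagnosis's definition, the result is "implied, most specific wins";
only mutual subsumption is reported as equivalence, and ties are left
unresolved rather than broken arbitrarily.

## Synthetic generators

The generators produce the study conditions for tests and the acceptance
script; all are seed-deterministic with one named RNG stream per call.

* **Scenes** place convex tumor blobs on a non-overlapping grid, nuclei
  strictly inside their tumor, and stray nuclei outside every tumor, with
  the intended assignment recorded as ground truth. They emulate the
  *geometry* of segmentation output, not its failure modes: no
  touching/overlapping tumors, no partially clipped nuclei, no
  segmentation noise. Passing tests therefore demonstrate correctness of
  the assignment rule, not robustness to imperfect segmentation.
* **IHC cohorts** realize target staining-bin fractions by
  largest-remainder rounding and draw each cell's completeness uniformly
  within its bin. The default cohort (75/15/5/5, n = 20) matches the
  worked HER2 example. Real IHC shows within-slide heterogeneity and
  boundary-valued cells that the uniform-in-bin model does not.
* **Exemplars** reproduce the worked examples with minimal unstated
  detail fixed once: the HER2 cell (membrane staining 0.75), the
  back-to-back follicle pair (each follicle given four components:
  stroma, parenchyma, colloid substance, neoplastic cell), the
  three-stage cervical process (glandular pattern → apoptotic body +
  luminal mitosis → 40% intracytoplasmic-mucin indicator, outcome "HPVA,
  usual type"), the lymphoma differential (stage 2: T/NK-cell and
  Hodgkin lymphoma excluded, large B-cell lymphoma established on
  LCA/CD20/BOB1 positivity; the two excluded subtypes carry only
  contradicting evidence, so they receive no concept definition and a
  warning is emitted), and the slide-side documents for both reasoning
  demonstrations. The mitosis finding is labeled "luminal mitosis"
  consistently across the cervical process and slide so the equivalence
  demonstration is self-consistent.

## Numerical choices and problem sizes

Tolerances: overlap ties at 1e-12; stained-arc overlap detection at
1e-12 of arc length; indicator formula values and staining values are
IEEE doubles roundtripped through RDF literals. The test suite runs at
desk scale by choice: 50 seeded scenes of 2 tumors × 3 nuclei for
assignment recovery, 50 random documents for serialization stress, the
full 256×256 lattice for the reasoner oracle, and 100-cell cohorts for
the threshold scan; these sizes exercise every code path while keeping
the suite fast.

## Known limitations

* OWL axiom-level semantics (punning, property chains, reasoner-backed
  consistency) are out of scope; PathoML output is a plain individual
  graph.
* The reasoner fragment has no negation, role chains or nominals;
  exclusion is extra-logical.
* No image processing: the package consumes already-segmented geometry
  and already-classified stained arcs.
* Physical units are not derived from magnification metadata.
* Whether P_i phenotype sets may repeat across stages is not constrained.
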