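"""Quantitative HER2 expression assessment from membrane staining.

Workflow: a graph-pattern (SPARQL) query over the serialized PathoML
ontology retrieves, for every neoplastic tumor cell, the staining-extent
parameter recorded on its membrane; the cohort-level distribution of
staining completeness is computed over four bins; the HER2 status is then
called from the distribution:

==========  =================================================
status      criterion (evaluated in strict precedence order)
==========  =================================================
3+          >10% of tumor cells completely stained, completeness ∈ [0.9, 1]
2+          >10% moderately stained, completeness ∈ [0.7, 0.9)
1+          >10% incompletely stained, completeness ∈ [0.5, 0.7)
0           otherwise; a warning is attached unless >90% are
            unstained (completeness ∈ [0, 0.5))
==========  =================================================

All bin boundaries are half-open from below, so the four bins partition
[0, 1] and every completeness value falls in exactly one bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from rdflib import Graph

from .core_model import PathoDocument
from .errors import AmbiguityError, EmptyCohortError
from .pathoml_io import DEFAULT_BINDING, PathoMLBinding, write_pathoml

log = logging.getLogger(__name__)

#: Feature names recognized as the membrane staining measure.
STAINING_FEATURE_NAMES = ("staining extent", "staining completeness")

COMPLETENESS_QUERY = """\
PREFIX pathoml: <{schema}>
SELECT ?cell ?value WHERE {{
    ?cell a pathoml:NeoplasticCell ;
          pathoml:hasComponent ?membrane .
    ?membrane pathoml:hasAttribute ?attr .
    ?attr pathoml:name ?attrName ;
          pathoml:quantification ?q .
    ?q pathoml:hasValue ?value .
    FILTER(lcase(str(?attrName)) IN ({names}))
}}
"""


@dataclass(frozen=True)
class StainingDistribution:
    """Fractions of tumor cells per staining-completeness bin."""

    complete: float      # completeness ∈ [0.9, 1]
    moderate: float      # ∈ [0.7, 0.9)
    incomplete: float    # ∈ [0.5, 0.7)
    unstained: float     # ∈ [0, 0.5)
    n_cells: int

    def fractions(self) -> tuple[float, float, float, float]:
        return (self.complete, self.moderate, self.incomplete, self.unstained)


@dataclass(frozen=True)
class Her2Call:
    status: str                       # "3+" | "2+" | "1+" | "0"
    distribution: StainingDistribution
    warnings: tuple[str, ...] = ()


def build_completeness_query(binding: PathoMLBinding = DEFAULT_BINDING) -> str:
    names = ", ".join(f'"{n}"' for n in STAINING_FEATURE_NAMES)
    return COMPLETENESS_QUERY.format(schema=binding.schema_iri, names=names)


def query_completeness(doc: PathoDocument,
                       binding: PathoMLBinding = DEFAULT_BINDING,
                       ) -> list[tuple[str, float]]:
    """Per-cell membrane staining completeness, via SPARQL over PathoML.

    The document is serialized and the graph-pattern query is executed over
    the resulting ontology, so the retrieval path is exactly what an
    external consumer of the PathoML file would use.  Returns ``(cell_id,
    completeness)`` pairs sorted by cell id.  A cell carrying conflicting
    staining parameters raises :class:`AmbiguityError`.
    """
    text = write_pathoml(doc, binding=binding)
    g = Graph()
    g.parse(data=text, format="turtle")
    query = build_completeness_query(binding)
    log.info("HER2 completeness query:\n%s", query)
    per_cell: dict[str, set[float]] = {}
    for row in g.query(query):
        cell_id = binding.local_id(row.cell)
        per_cell.setdefault(cell_id, set()).add(float(row.value))
    conflicted = sorted(c for c, vals in per_cell.items() if len(vals) > 1)
    if conflicted:
        raise AmbiguityError(
            f"cells with conflicting staining parameters: {conflicted}")
    return [(c, vals.pop()) for c, vals in sorted(per_cell.items())]


def completeness_bin(value: float) -> str:
    """Bin name for one completeness value; bins partition [0, 1]."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"staining completeness {value} outside [0, 1]")
    if value >= 0.9:
        return "complete"
    if value >= 0.7:
        return "moderate"
    if value >= 0.5:
        return "incomplete"
    return "unstained"


def distribution(values: Sequence[float]) -> StainingDistribution:
    """Bin fractions of a cohort of staining-completeness values."""
    if len(values) == 0:
        raise EmptyCohortError("cannot compute a distribution over zero cells")
    counts = {"complete": 0, "moderate": 0, "incomplete": 0, "unstained": 0}
    for v in values:
        counts[completeness_bin(float(v))] += 1
    n = len(values)
    return StainingDistribution(
        complete=counts["complete"] / n, moderate=counts["moderate"] / n,
        incomplete=counts["incomplete"] / n, unstained=counts["unstained"] / n,
        n_cells=n)


def classify(dist: StainingDistribution) -> Her2Call:
    """HER2 status from a staining distribution, strict precedence 3+→2+→1+→0.

    Thresholds are strict (">10%", ">90%") as printed.  When no positive
    criterion fires and the unstained fraction does not exceed 90%, the
    status is still "0" but a warning records that the printed 0-criterion
    was not literally met.
    """
    warnings: tuple[str, ...] = ()
    if dist.complete > 0.10:
        status = "3+"
    elif dist.moderate > 0.10:
        status = "2+"
    elif dist.incomplete > 0.10:
        status = "1+"
    else:
        status = "0"
        if dist.unstained <= 0.90:
            warnings = (
                f"unstained fraction {dist.unstained:.3f} ≤ 0.90: the "
                "0-status criterion is not literally met; 0 assigned as "
                "the residual class",)
    return Her2Call(status=status, distribution=dist, warnings=warnings)


def assess(doc: PathoDocument,
           binding: PathoMLBinding = DEFAULT_BINDING) -> dict:
    """Full pipeline: query → distribution → classification, as a report."""
    pairs = query_completeness(doc, binding=binding)
    dist = distribution([v for _, v in pairs])
    call = classify(dist)
    return {
        "status": call.status,
        "fractions": {"complete": dist.complete, "moderate": dist.moderate,
                      "incomplete": dist.incomplete, "unstained": dist.unstained},
        "n_cells": dist.n_cells,
        "warnings": list(call.warnings),
        "per_cell": {c: v for c, v in pairs},
        "query": build_completeness_query(binding),
    }
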