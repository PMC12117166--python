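"""Subsumption-based histologic subtyping over phenotype concepts.

Slide phenotypes and a pathologist's diagnosis process are translated into
concept expressions of a small description-logic fragment: conjunctions of
existential restrictions over a single "exhibits" role, one atom per
phenotype label (EL without nesting).  For this fragment structural
subsumption is sound and complete: C ⊑ D iff every atom of D is matched by
an atom of C, where a match is label equality or descent in an optional
phenotype-label hierarchy.

Contradicting evidence has no counterpart in the fragment (no negation);
it is applied as a post-filter that excludes a diagnosis whenever one of
its contradicting phenotypes is present on the slide.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .core_model import DiagnosisProcess, PathoDocument
from .errors import CycleError
from .core_model import find_cycle

Hierarchy = Iterable[tuple[str, str]]  # (child, parent) pairs


def normalize_label(label: str) -> str:
    """Case-folded, whitespace-collapsed atom identity for a label."""
    return re.sub(r"\s+", " ", label.strip()).casefold()


@dataclass(frozen=True)
class ConceptExpr:
    """Conjunction of existential phenotype atoms; frozenset-deduplicated."""

    atoms: frozenset[str]
    name: Optional[str] = None

    def is_top(self) -> bool:
        return not self.atoms

    def __str__(self) -> str:  # e.g. "∃exhibits.a ⊓ ∃exhibits.b"
        if not self.atoms:
            return "⊤"
        return " ⊓ ".join(f"∃exhibits.{a}" for a in sorted(self.atoms))


@dataclass
class KnowledgeBase:
    """Diagnosis definitions and exclusions distilled from a process."""

    definitions: dict[str, ConceptExpr] = field(default_factory=dict)
    exclusions: dict[str, frozenset[str]] = field(default_factory=dict)
    hierarchy: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class InferenceResult:
    reported: Optional[str]
    implied: list[str]
    equivalent: list[str]
    excluded: list[str]
    unresolved: list[str]
    proof: dict[str, list[str]]

    def to_dict(self) -> dict:
        return {"reported_subtype": self.reported, "implied": self.implied,
                "equivalent": self.equivalent, "excluded": self.excluded,
                "unresolved": self.unresolved, "proof": self.proof}


def _atom_index(doc: PathoDocument) -> dict[str, str]:
    """Map phenotype/indicator ids to their atom identities.

    Atom identity is the xref code ("VOCAB:code") when the node carries
    one, else the normalized label.
    """
    xref_by_node: dict[str, str] = {}
    for x in doc.xrefs:
        xref_by_node.setdefault(x.node_id, f"{x.vocabulary}:{x.code}")
    atoms: dict[str, str] = {}
    for pid, p in doc.phenotypes.items():
        atoms[pid] = xref_by_node.get(pid) or normalize_label(p.label or pid)
    for qid, qi in doc.indicators.items():
        atoms[qid] = xref_by_node.get(qid) or normalize_label(qi.name or qid)
    return atoms


def slide_to_concept(doc: PathoDocument) -> ConceptExpr:
    """One existential atom per phenotype/indicator in the slide document."""
    atoms = _atom_index(doc)
    return ConceptExpr(atoms=frozenset(atoms.values()), name="slide")


def process_to_kb(dp: DiagnosisProcess, doc: PathoDocument,
                  cumulative: bool = True) -> KnowledgeBase:
    """Distill diagnosis definitions from a diagnosis process.

    With ``cumulative=True`` (the default), a diagnosis at stage *i*
    inherits the defining atoms of the diagnoses established at earlier
    stages, implementing the narrowing-down semantics of staged diagnosis.
    A diagnosis with no supporting evidence emits a warning and receives no
    definition (it can still be excluded via its contradictions).
    """
    atom_of = _atom_index(doc)
    kb = KnowledgeBase()
    inherited: frozenset[str] = frozenset()
    for stage in dp.stages:
        established_atoms: list[frozenset[str]] = []
        for d in stage.possibilities:
            own = frozenset(atom_of[pid] for pid in d.support if pid in atom_of)
            if d.contradict:
                kb.exclusions[d.label] = frozenset(
                    atom_of[pid] for pid in d.contradict if pid in atom_of)
            if not own:
                warnings.warn(
                    f"diagnosis {d.label!r} has no supporting evidence; "
                    "no concept definition generated", UserWarning,
                    stacklevel=2)
                continue
            atoms = (own | inherited) if cumulative else own
            kb.definitions[d.label] = ConceptExpr(atoms=atoms, name=d.label)
            if d.status == "established":
                established_atoms.append(atoms)
        if cumulative:
            for atoms in established_atoms:
                inherited = inherited | atoms
    return kb


def _ancestor_closure(hierarchy: Optional[Hierarchy]) -> dict[str, set[str]]:
    pairs = [(normalize_label(c), normalize_label(p))
             for c, p in (hierarchy or ())]
    cyc = find_cycle(pairs)
    if cyc is not None:
        raise CycleError(cyc)
    parents: dict[str, set[str]] = {}
    for c, p in pairs:
        parents.setdefault(c, set()).add(p)
    closure: dict[str, set[str]] = {}

    def ancestors(x: str) -> set[str]:
        if x in closure:
            return closure[x]
        acc: set[str] = set()
        for p in parents.get(x, ()):
            acc.add(p)
            acc |= ancestors(p)
        closure[x] = acc
        return acc

    for node in list(parents):
        ancestors(node)
    return closure


def subsumes(c: ConceptExpr, d: ConceptExpr,
             hierarchy: Optional[Hierarchy] = None) -> bool:
    """Decide C ⊑ D structurally.

    True iff every atom of D is matched by an atom of C — matched meaning
    an equal label, or a C-atom whose label is a descendant of the D-atom's
    label in the hierarchy.  A cyclic hierarchy raises
    :class:`~pathograph.errors.CycleError`.
    """
    if not d.atoms:
        return True  # everything is subsumed by top
    anc = _ancestor_closure(hierarchy) if hierarchy else {}
    for atom_d in d.atoms:
        if atom_d in c.atoms:
            continue
        if anc and any(atom_d in anc.get(atom_c, ()) for atom_c in c.atoms):
            continue
        return False
    return True


def infer(slide: ConceptExpr, kb: KnowledgeBase) -> InferenceResult:
    """Subtype a slide concept against a knowledge base.

    ``implied`` lists diagnoses D with slide ⊑ D; ``equivalent`` those with
    mutual subsumption; ``excluded`` those with a contradicting atom present
    on the slide.  The reported subtype is the unique non-excluded
    equivalent diagnosis if one exists, else the most specific (largest
    definition) non-excluded implied diagnosis; ties are left unresolved.
    """
    hierarchy = kb.hierarchy or None
    excluded = sorted(label for label, excl in kb.exclusions.items()
                      if excl & slide.atoms)
    implied, equivalent, proof = [], [], {}
    for label, concept in sorted(kb.definitions.items()):
        if subsumes(slide, concept, hierarchy):
            implied.append(label)
            proof[label] = sorted(concept.atoms)
            if subsumes(concept, slide, hierarchy):
                equivalent.append(label)
    candidates_eq = [d for d in equivalent if d not in excluded]
    reported: Optional[str] = None
    unresolved: list[str] = []
    if len(candidates_eq) == 1:
        reported = candidates_eq[0]
    else:
        candidates = [d for d in implied if d not in excluded]
        if candidates:
            best = max(len(kb.definitions[d].atoms) for d in candidates)
            top = [d for d in candidates if len(kb.definitions[d].atoms) == best]
            if len(top) == 1:
                reported = top[0]
            else:
                unresolved = top
    return InferenceResult(reported=reported, implied=implied,
                           equivalent=equivalent, excluded=excluded,
                           unresolved=unresolved, proof=proof)


def subtype_slide(slide_doc: PathoDocument, knowledge_doc: PathoDocument,
                  cumulative: bool = True) -> dict:
    """End-to-end subtyping of a slide document against a knowledge document.

    The knowledge document must contain at least one diagnosis process; all
    its processes contribute definitions (later processes win on label
    clashes).
    """
    slide = slide_to_concept(slide_doc)
    kb = KnowledgeBase()
    for dp in knowledge_doc.processes.values():
        part = process_to_kb(dp, knowledge_doc, cumulative=cumulative)
        kb.definitions.update(part.definitions)
        kb.exclusions.update(part.exclusions)
    result = infer(slide, kb)
    out = result.to_dict()
    out["slide_concept"] = sorted(slide.atoms)
    return out
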