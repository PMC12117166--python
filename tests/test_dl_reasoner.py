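"""Concept translation and structural subsumption reasoning."""

import itertools

import numpy as np
import pytest

from pathograph import fixtures as fx
from pathograph.core_model import PathoDocument, Phenotype
from pathograph.dl_reasoner import (ConceptExpr, KnowledgeBase, infer,
                                    normalize_label, process_to_kb,
                                    slide_to_concept, subsumes,
                                    subtype_slide)
from pathograph.errors import CycleError


def C(*atoms, name=None):
    return ConceptExpr(atoms=frozenset(atoms), name=name)


class TestSlideToConcept:
    def test_cervical_slide_has_three_atoms(self, cervical_slide_doc):
        concept = slide_to_concept(cervical_slide_doc)
        assert concept.atoms == {"glandular pattern", "apoptotic body",
                                 "luminal mitosis"}

    def test_empty_slide_is_top(self):
        assert slide_to_concept(PathoDocument()).is_top()

    def test_duplicate_labels_deduplicated(self):
        doc = PathoDocument()
        for i in range(3):
            doc.add_phenotype(Phenotype(
                id=f"p{i}", label="  Glandular   PATTERN ",
                kind="multi_cell",
                pathoml_class="Histopathological_Phenotype"))
        assert slide_to_concept(doc).atoms == {"glandular pattern"}

    def test_normalization_rules(self):
        assert normalize_label("  Apoptotic\t Body ") == "apoptotic body"


class TestProcessToKb:
    def test_cervical_definitions_are_cumulative(self, cervical_doc):
        kb = process_to_kb(cervical_doc.processes["Process1"], cervical_doc)
        assert kb.definitions["adenocarcinoma"].atoms == {"glandular pattern"}
        assert kb.definitions["HPVA"].atoms == {
            "glandular pattern", "apoptotic body", "luminal mitosis"}
        assert kb.definitions["HPVA, usual type"].atoms == {
            "glandular pattern", "apoptotic body", "luminal mitosis",
            "intracytoplasmic mucin proportion"}

    def test_per_stage_mode_does_not_inherit(self, cervical_doc):
        kb = process_to_kb(cervical_doc.processes["Process1"], cervical_doc,
                           cumulative=False)
        assert kb.definitions["HPVA"].atoms == {"apoptotic body",
                                                "luminal mitosis"}

    def test_single_stage_single_diagnosis(self):
        doc = fx.exemplar("cervical_fig6")
        dp = doc.processes["Process1"]
        dp.stages = dp.stages[:1]
        kb = process_to_kb(dp, doc)
        assert set(kb.definitions) == {"adenocarcinoma"}
        assert len(kb.definitions["adenocarcinoma"].atoms) == 1

    def test_lymphoma_supports_and_contradictions(self, lymphoma_doc):
        with pytest.warns(UserWarning, match="no supporting evidence"):
            kb = process_to_kb(lymphoma_doc.processes["Process1"],
                               lymphoma_doc)
        assert kb.definitions["large B-cell lymphoma"].atoms == {
            "diffuse proliferation of large lymphoid cells",
            "lca positive", "cd20 positive", "bob1 positive"}
        assert "T-cell and NK-cell lymphoma" not in kb.definitions
        assert kb.exclusions["T-cell and NK-cell lymphoma"] == {
            "cd20 positive", "bob1 positive"}
        assert kb.exclusions["Hodgkin lymphoma"] == {"lca positive",
                                                     "bob1 positive"}


class TestSubsumes:
    def test_slide_subsumed_by_adenocarcinoma(self, cervical_slide_doc,
                                              cervical_doc):
        slide = slide_to_concept(cervical_slide_doc)
        kb = process_to_kb(cervical_doc.processes["Process1"], cervical_doc)
        assert subsumes(slide, kb.definitions["adenocarcinoma"], None)
        assert subsumes(slide, kb.definitions["HPVA"], None)
        assert subsumes(kb.definitions["HPVA"], slide, None)  # equivalence
        assert not subsumes(slide, kb.definitions["HPVA, usual type"], None)

    def test_everything_subsumed_by_top(self):
        assert subsumes(C("a", "b"), C(), None)
        assert subsumes(C(), C(), None)

    def test_matches_set_containment_oracle_on_six_label_universe(self):
        """Structural subsumption equals superset containment over all
        subset pairs of a 6-label universe (no hierarchy)."""
        labels = [f"l{i}" for i in range(6)]
        subsets = [frozenset(s) for r in range(7)
                   for s in itertools.combinations(labels, r)]
        for a in subsets:
            ca = ConceptExpr(atoms=a)
            for b in subsets:
                assert subsumes(ca, ConceptExpr(atoms=b), None) == (b <= a)

    def test_hierarchy_descendant_matches(self):
        hierarchy = [("signet-ring mitosis", "luminal mitosis"),
                     ("luminal mitosis", "mitosis")]
        assert subsumes(C("signet-ring mitosis"), C("mitosis"), hierarchy)
        assert subsumes(C("signet-ring mitosis"), C("luminal mitosis"),
                        hierarchy)
        assert not subsumes(C("mitosis"), C("luminal mitosis"), hierarchy)

    def test_cyclic_hierarchy_rejected(self):
        with pytest.raises(CycleError):
            subsumes(C("a"), C("b"), [("a", "b"), ("b", "a")])

    def test_preorder_reflexive_transitive(self):
        """Subsumption is a preorder on 500 random concept triples."""
        rng = np.random.default_rng(31)
        labels = [f"l{i}" for i in range(6)]

        def rand_concept():
            mask = rng.random(len(labels)) < 0.45
            return ConceptExpr(atoms=frozenset(
                l for l, m in zip(labels, mask) if m))

        for _ in range(500):
            a, b, c = rand_concept(), rand_concept(), rand_concept()
            assert subsumes(a, a, None)
            if subsumes(a, b, None) and subsumes(b, c, None):
                assert subsumes(a, c, None)

    def test_equivalence_is_atom_equality_without_hierarchy(self):
        rng = np.random.default_rng(37)
        labels = [f"l{i}" for i in range(5)]
        for _ in range(100):
            a = frozenset(l for l in labels if rng.random() < 0.5)
            b = frozenset(l for l in labels if rng.random() < 0.5)
            ca, cb = ConceptExpr(atoms=a), ConceptExpr(atoms=b)
            mutual = subsumes(ca, cb, None) and subsumes(cb, ca, None)
            assert mutual == (a == b)


class TestInfer:
    def test_cervical_slide_reports_hpva(self, cervical_slide_doc,
                                         cervical_doc):
        result = subtype_slide(cervical_slide_doc, cervical_doc)
        assert result["reported_subtype"] == "HPVA"
        assert set(result["implied"]) == {"adenocarcinoma", "HPVA"}
        assert result["equivalent"] == ["HPVA"]
        assert result["excluded"] == []

    def test_lymphoma_slide_reports_large_b_cell(self, lymphoma_slide_doc,
                                                 lymphoma_doc):
        with pytest.warns(UserWarning):
            result = subtype_slide(lymphoma_slide_doc, lymphoma_doc)
        assert result["reported_subtype"] == "large B-cell lymphoma"
        assert set(result["excluded"]) == {"T-cell and NK-cell lymphoma",
                                           "Hodgkin lymphoma"}

    def test_empty_kb_yields_empty_result(self):
        result = infer(C("a"), KnowledgeBase())
        assert result.reported is None
        assert result.implied == [] and result.excluded == []

    def test_excluded_diagnosis_never_reported(self):
        """Even when the excluded diagnosis is the only implied one."""
        kb = KnowledgeBase(
            definitions={"D": C("a", name="D")},
            exclusions={"D": frozenset({"b"})})
        result = infer(C("a", "b"), kb)
        assert result.implied == ["D"]
        assert result.excluded == ["D"]
        assert result.reported is None

    def test_most_specific_implied_wins_without_equivalence(self):
        kb = KnowledgeBase(definitions={
            "broad": C("a", name="broad"),
            "narrow": C("a", "b", name="narrow")})
        result = infer(C("a", "b", "c"), kb)
        assert result.equivalent == []
        assert result.reported == "narrow"

    def test_tied_most_specific_left_unresolved(self):
        kb = KnowledgeBase(definitions={
            "x": C("a", name="x"), "y": C("b", name="y")})
        result = infer(C("a", "b", "c"), kb)
        assert result.reported is None
        assert set(result.unresolved) == {"x", "y"}

    def test_implied_set_matches_brute_force_over_random_kbs(self):
        """infer's implied set equals brute-force set containment for
        random KBs of ≤6 diagnoses over ≤8 labels."""
        rng = np.random.default_rng(41)
        labels = [f"l{i}" for i in range(8)]
        for _ in range(50):
            kb = KnowledgeBase()
            for d in range(int(rng.integers(1, 7))):
                atoms = frozenset(l for l in labels if rng.random() < 0.4)
                if atoms:
                    kb.definitions[f"d{d}"] = ConceptExpr(atoms=atoms)
            slide = ConceptExpr(atoms=frozenset(
                l for l in labels if rng.random() < 0.5))
            expected = sorted(name for name, c in kb.definitions.items()
                              if c.atoms <= slide.atoms)
            assert infer(slide, kb).implied == expected
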