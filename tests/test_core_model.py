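"""Typed-graph model: builders, invariants, validation soundness."""

import math

import networkx as nx
import numpy as np
import pytest

from pathograph import fixtures as fx
from pathograph.core_model import (Diagnosis, DiagnosisStage, EntityNode,
                                   FeatureNode, PathoDocument, Phenotype,
                                   QuantParam, build_diagnosis_process,
                                   build_entity_graph, expand_phenotype,
                                   find_cycle, validate)
from pathograph.errors import CycleError, ResolutionError


def _her2_cell_graph():
    cell = EntityNode(id="Cell1", entity_class="NeoplasticCell")
    membrane = EntityNode(id="Membrane1", entity_class="NeoplasticCellularComponent")
    nucleus = EntityNode(id="Nucleus1", entity_class="NeoplasticCellularComponent")
    her2 = EntityNode(id="HER2", entity_class="Protein")
    feat = FeatureNode(id="Medium", feature_name="staining extent",
                       owner_id="Membrane1")
    param = QuantParam(id="Q1", param_name="staining extent", value=0.75,
                       feature_id="Medium")
    return build_entity_graph(
        cell, [membrane, nucleus, her2], [feat], [param],
        relations={"part_whole": {("Cell1", "Membrane1"), ("Cell1", "Nucleus1")},
                   "express_links": {("Membrane1", "HER2")}})


class TestBuildEntityGraph:
    def test_her2_cell_counts(self):
        """A stained tumor cell yields 4 entities, 1 feature, 1 parameter,
        2 part-whole edges and 1 express edge."""
        g = _her2_cell_graph()
        assert len(g.entities()) == 4
        assert len(g.features) == 1
        assert len(g.params) == 1
        assert len(g.part_whole) == 2
        assert len(g.express_links) == 1
        assert g.params["Q1"].value == 0.75

    def test_root_only_graph_is_minimal(self):
        g = build_entity_graph(EntityNode(id="T", entity_class="Tumor"))
        assert g.components == {} and g.features == {} and g.params == {}
        assert not (g.part_whole | g.feature_links | g.quant_links
                    | g.express_links)

    def test_part_whole_cycle_raises(self):
        cell = EntityNode(id="Cell1", entity_class="Cell")
        nucleus = EntityNode(id="Nucleus1", entity_class="Cellular_Component")
        with pytest.raises(CycleError) as exc:
            build_entity_graph(cell, [nucleus],
                               relations={"part_whole": {("Nucleus1", "Cell1"),
                                                         ("Cell1", "Nucleus1")}})
        assert "Cell1" in str(exc.value) and "Nucleus1" in str(exc.value)

    def test_dangling_reference_names_the_id(self):
        cell = EntityNode(id="Cell1", entity_class="Cell")
        with pytest.raises(ResolutionError, match="Ghost"):
            build_entity_graph(cell, relations={"part_whole": {("Cell1", "Ghost")}})


class TestValidate:
    @pytest.mark.parametrize("name", fx.EXEMPLAR_NAMES)
    def test_exemplars_are_clean(self, name):
        assert validate(fx.exemplar(name)) == []

    def test_empty_document_is_clean(self):
        assert validate(PathoDocument()) == []

    def test_single_cell_with_two_entities_flagged(self, follicle_doc):
        doc = follicle_doc
        doc.add_phenotype(Phenotype(
            id="Bad", label="x", kind="single_cell",
            pathoml_class="Cytopathological_Phenotype",
            entities=["Tumor1", "Tumor2"]))
        violations = validate(doc)
        assert any(v.obj_id == "Bad" and "cardinality" in v.clause
                   for v in violations)

    # systematic single-field corruptions; each must surface ≥1 violation
    # whose clause names the broken invariant
    CORRUPTIONS = [
        ("entity_class",
         lambda d: setattr(d.entity_graphs["Cell1"].root, "entity_class",
                           "Martian")),
        ("outline",
         lambda d: setattr(d.entity_graphs["Cell1"].root, "outline",
                           ((0.0, 0.0), (1.0, 1.0)))),
        ("bbox",
         lambda d: (setattr(d.entity_graphs["Cell1"].root, "outline",
                            ((0.0, 0.0), (4.0, 0.0), (4.0, 4.0))),
                    setattr(d.entity_graphs["Cell1"].root, "bbox",
                            (0.0, 0.0, 2.0, 2.0)))),
        ("value",
         lambda d: setattr(d.entity_graphs["Cell1"].params["Quantification1"],
                           "value", math.nan)),
        ("feature_id",
         lambda d: setattr(d.entity_graphs["Cell1"].params["Quantification1"],
                           "feature_id", "NoSuchFeature")),
        ("owner_id",
         lambda d: setattr(d.entity_graphs["Cell1"].features["Medium"],
                           "owner_id", "NoSuchEntity")),
        ("part_whole acyclicity",
         lambda d: d.entity_graphs["Cell1"].part_whole.update(
             {("Membrane1", "Nucleus1"), ("Nucleus1", "Membrane1")})),
        ("express",
         lambda d: d.entity_graphs["Cell1"].express_links.add(
             ("Cell1", "Nucleus1"))),
        ("R_ee",
         lambda d: d.entity_graphs["Cell1"].part_whole.add(
             ("Membrane1", "Cell1"))),
        ("single_cell cardinality",
         lambda d: d.phenotypes["Phenotype1"].entities.append("Nucleus1")),
        ("kind",
         lambda d: setattr(d.phenotypes["Phenotype1"], "kind", "weird")),
    ]

    @pytest.mark.parametrize("clause,mutate", CORRUPTIONS,
                             ids=[c for c, _ in CORRUPTIONS])
    def test_corruption_yields_named_violation(self, clause, mutate):
        doc = fx.exemplar("her2_fig4")
        assert validate(doc) == []
        mutate(doc)
        violations = validate(doc)
        assert violations, f"corrupting {clause} produced no violation"
        assert any(clause in v.clause for v in violations), \
            [str(v) for v in violations]

    def test_terminal_stage_two_established_flagged(self, cervical_doc):
        stage = cervical_doc.processes["Process1"].stages[-1]
        stage.possibilities.append(Diagnosis(
            id="DiagnosisX", label="other", status="established",
            support=["GlandularPattern"]))
        violations = validate(cervical_doc)
        assert any("terminal outcome" in v.clause for v in violations)

    def test_unresolved_evidence_flagged(self, cervical_doc):
        diag = cervical_doc.processes["Process1"].stages[0].possibilities[0]
        diag.support.append("NoSuchPhenotype")
        violations = validate(cervical_doc)
        assert any("evidence resolution" in v.clause for v in violations)

    def test_duplicate_ids_flagged(self, her2_doc):
        her2_doc.add_phenotype(Phenotype(
            id="Cell1", label="clash", kind="multi_cell",
            pathoml_class="Histopathological_Phenotype"))
        violations = validate(her2_doc)
        assert any("id uniqueness" in v.clause for v in violations)


class TestExpandPhenotype:
    def test_expansion_pulls_in_entity_graph(self, her2_doc):
        p = her2_doc.phenotypes["Phenotype1"]
        assert p.entity_graphs == {}
        expanded = expand_phenotype(p, her2_doc.entity_graphs)
        g = expanded.entity_graphs["Cell1"]
        assert set(g.entities()) == {"Cell1", "Membrane1", "Nucleus1", "HER2"}
        assert "Medium" in g.features and "Quantification1" in g.params
        assert p.entity_graphs == {}  # original untouched

    def test_expanded_node_count_is_sum_of_parts(self, follicle_doc):
        p = follicle_doc.phenotypes["Phenotype2"]
        expanded = expand_phenotype(p, follicle_doc.entity_graphs)
        total = 1 + sum(g.node_count()
                        for g in follicle_doc.entity_graphs.values())
        assert 1 + sum(g.node_count()
                       for g in expanded.entity_graphs.values()) == total

    def test_expand_is_idempotent(self, her2_doc):
        p = her2_doc.phenotypes["Phenotype1"]
        once = expand_phenotype(p, her2_doc.entity_graphs)
        twice = expand_phenotype(once, her2_doc.entity_graphs)
        assert set(twice.entity_graphs) == set(once.entity_graphs)
        assert twice.entity_graphs["Cell1"].part_whole == \
            once.entity_graphs["Cell1"].part_whole

    def test_expand_with_empty_map_is_identity_when_already_expanded(self):
        p = Phenotype(id="p", label="x", kind="multi_cell",
                      pathoml_class="Histopathological_Phenotype")
        assert expand_phenotype(p, {}).entity_graphs == {}

    def test_missing_graph_raises(self, her2_doc):
        p = her2_doc.phenotypes["Phenotype1"]
        with pytest.raises(ResolutionError, match="Cell1"):
            expand_phenotype(p, {})


class TestCycleOracle:
    def test_matches_networkx_on_random_relation_sets(self):
        """find_cycle agrees with networkx DAG detection on 200 random
        small pair sets."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(2, 8))
            m = int(rng.integers(0, 12))
            pairs = {(f"n{int(rng.integers(0, n))}", f"n{int(rng.integers(0, n))}")
                     for _ in range(m)}
            pairs = {(a, b) for a, b in pairs if a != b} | (
                {(f"n0", f"n0")} if rng.random() < 0.05 else set())
            g = nx.DiGraph(list(pairs))
            expected_acyclic = nx.is_directed_acyclic_graph(g)
            assert (find_cycle(pairs) is None) == expected_acyclic

    def test_self_loop_is_a_cycle(self):
        assert find_cycle({("a", "a")}) == ["a", "a"]


class TestBuildDiagnosisProcess:
    def test_cervical_process_shape(self, cervical_doc):
        dp = cervical_doc.processes["Process1"]
        assert len(dp.stages) == 3
        terminal = dp.stages[-1]
        (final,) = [d for d in terminal.possibilities
                    if d.status == "established"]
        assert final.label == "HPVA, usual type"

    def test_lymphoma_stage_two_differential(self, lymphoma_doc):
        stage2 = lymphoma_doc.processes["Process1"].stages[1]
        assert len(stage2.possibilities) == 3
        statuses = sorted(d.status for d in stage2.possibilities)
        assert statuses == ["established", "excluded", "excluded"]

    def test_single_stage_process(self):
        dp = build_diagnosis_process([DiagnosisStage(
            id="s1", index=1,
            possibilities=[Diagnosis(id="d1", label="benign",
                                     status="established")])])
        assert len(dp.stages) == 1

    def test_empty_stage_list_rejected(self):
        with pytest.raises(ValueError, match="at least one stage"):
            build_diagnosis_process([])

    def test_duplicate_indices_rejected(self):
        stages = [DiagnosisStage(id=f"s{i}", index=1,
                                 possibilities=[Diagnosis(id=f"d{i}", label="x",
                                                          status="excluded")])
                  for i in range(2)]
        with pytest.raises(ValueError, match="duplicate"):
            build_diagnosis_process(stages)

    def test_multiple_established_nonterminal_warns(self):
        stages = [
            DiagnosisStage(id="s1", index=1, possibilities=[
                Diagnosis(id="d1", label="a", status="established"),
                Diagnosis(id="d2", label="b", status="established")]),
            DiagnosisStage(id="s2", index=2, possibilities=[
                Diagnosis(id="d3", label="c", status="established")]),
        ]
        with pytest.warns(UserWarning, match="established"):
            build_diagnosis_process(stages)
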