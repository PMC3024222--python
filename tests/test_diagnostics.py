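"""QA battery: disjointness, polarity conflicts, redundancy, duplicates."""

from obolog.diagnostics import (
    check_disjointness,
    check_polarity_conflicts,
    find_duplicate_relation_pairs,
    find_redundant_edges,
    validate,
)
from obolog.expand import normalize_ontology
from obolog.fixtures import build_paper_fixture
from obolog.model import DEVELOPS_FROM
from obolog.reasoner import classify

from conftest import make_onto


def run_checks(onto):
    ax = normalize_ontology(onto)
    closure = classify(ax)
    return closure, ax


class TestDisjointness:
    def test_too_general_receptor_differentia_flags_violation(self):
        onto, _ = build_paper_fixture("tcr_disjoint_pre")
        closure, ax = run_checks(onto)
        findings = check_disjointness(closure, ax)
        assert len(findings) == 1
        assert set(findings[0].subjects) == {"CL:0000798", "CL:0000789"}
        assert findings[0].severity == "error"
        assert closure.unsatisfiable == {"CL:0000798"}

    def test_narrowed_differentia_is_clean(self):
        onto, _ = build_paper_fixture("tcr_disjoint_post")
        closure, ax = run_checks(onto)
        assert check_disjointness(closure, ax) == []
        assert closure.unsatisfiable == set()

    def test_no_pairs_no_findings(self):
        onto, _ = build_paper_fixture("helper_t_inference")
        closure, ax = run_checks(onto)
        assert check_disjointness(closure, ax) == []

    def test_descendants_of_violating_class_cascade(self):
        onto, _ = build_paper_fixture("tcr_disjoint_pre")
        onto.add(make_onto({"CL:0900099": {}}).classes["CL:0900099"])
        onto.classes["CL:0900099"].is_a_parents.append("CL:0000798")
        closure, ax = run_checks(onto)
        findings = check_disjointness(closure, ax)
        assert len(findings) == 2
        cascaded = [f for f in findings if f.subjects[0] == "CL:0900099"]
        assert cascaded and "cascaded" in cascaded[0].detail


class TestPolarityConflicts:
    def test_granule_contradiction_three_levels_apart(self):
        """lacks_part tertiary granule on a myelocyte contradicts has_part
        tertiary granule inherited from the granulocyte ancestor."""
        onto, _ = build_paper_fixture("granule_conflict")
        closure, ax = run_checks(onto)
        findings = check_polarity_conflicts(closure, ax)
        assert len(findings) == 1
        assert findings[0].subjects[0] == "CL:0900043"
        assert "GO:0070820" in findings[0].subjects

    def test_membrane_part_of_subtype_conflicts_with_lacks_of_supertype(self):
        """Having the alpha-beta receptor complex on the membrane clashes
        with lacking T cell receptor complexes in general."""
        onto = make_onto({
            "GO:0042101": {"ns": "cellular_component"},
            "GO:0042105": {"ns": "cellular_component", "parent": "GO:0042101"},
            "CL:0000001": {"rels": [
                ("lacks_plasma_membrane_part", "GO:0042101"),
                ("has_plasma_membrane_part", "GO:0042105")]},
        })
        closure, ax = run_checks(onto)
        findings = check_polarity_conflicts(closure, ax)
        assert [f.subjects[0] for f in findings] == ["CL:0000001"]

    def test_membrane_part_does_not_conflict_with_plain_part_elsewhere(self):
        # lacking a *membrane* part says nothing about the part existing
        # elsewhere in the cell
        onto = make_onto({
            "GO:0000001": {"ns": "cellular_component"},
            "CL:0000001": {"rels": [
                ("lacks_plasma_membrane_part", "GO:0000001"),
                ("has_part", "GO:0000001")]},
        })
        closure, ax = run_checks(onto)
        assert check_polarity_conflicts(closure, ax) == []

    def test_membrane_part_conflicts_with_lacks_part(self):
        # ... but the converse does hold: a membrane part is a part
        onto = make_onto({
            "GO:0000001": {"ns": "cellular_component"},
            "CL:0000001": {"rels": [
                ("lacks_part", "GO:0000001"),
                ("has_plasma_membrane_part", "GO:0000001")]},
        })
        closure, ax = run_checks(onto)
        assert len(check_polarity_conflicts(closure, ax)) == 1

    def test_no_negative_facts_no_findings(self):
        onto, _ = build_paper_fixture("helper_t_inference")
        closure, ax = run_checks(onto)
        assert check_polarity_conflicts(closure, ax) == []


class TestRedundantEdges:
    def test_shortcut_over_two_chain(self):
        onto = make_onto({
            "A:1": {"parent": "A:2"}, "A:2": {"parent": "A:3"}, "A:3": {},
        })
        onto.classes["A:1"].is_a_parents.append("A:3")
        findings = find_redundant_edges(onto)
        assert [(f.subjects, f.severity) for f in findings] == \
            [(("A:1", "A:3"), "warning")]

    def test_pure_tree_has_none(self):
        onto = make_onto({
            "A:1": {"parent": "A:2"}, "A:2": {"parent": "A:3"}, "A:3": {},
        })
        assert find_redundant_edges(onto) == []

    def test_genus_restating_the_asserted_parent_is_not_redundant(self):
        # the is_a line and the definition genus are one assertion twice
        onto = make_onto({
            "GO:0000001": {"ns": "biological_process"},
            "A:1": {"parent": "A:2", "diff": [("capable_of", "GO:0000001")]},
            "A:2": {},
        })
        assert find_redundant_edges(onto) == []

    def test_treg_develops_from_shortcut_found_and_repaired(self):
        onto, _ = build_paper_fixture("treg_pre")
        findings = find_redundant_edges(onto)
        assert [f.subjects for f in findings] == [("CL:0000903", "CL:0000809")]
        repaired, _ = build_paper_fixture("treg_post")
        assert find_redundant_edges(repaired) == []

    def test_simultaneous_deletion_preserves_closure(self):
        """Deleting every redundant edge at once must leave the entailment
        closure untouched."""
        from obolog.generator import GeneratorParams, generate_random_ontology
        for onto in [build_paper_fixture("treg_pre")[0],
                     generate_random_ontology(GeneratorParams(
                         n_classes=40, p_defined=0.6,
                         n_planted_redundant_edges=3, seed=11))[0]]:
            before = classify(normalize_ontology(onto))
            for f in find_redundant_edges(onto):
                child, target = f.subjects
                node = onto.classes[child]
                if target in node.is_a_parents:
                    node.is_a_parents.remove(target)
                if (DEVELOPS_FROM, target) in node.relationships:
                    node.relationships.remove((DEVELOPS_FROM, target))
            after = classify(normalize_ontology(onto))
            assert after.entailed_isa == before.entailed_isa
            assert after.entailed_develops_from == before.entailed_develops_from


class TestDuplicateRelationPairs:
    def test_is_a_plus_develops_from_between_same_pair(self):
        onto = make_onto({
            "A:1": {"parent": "A:2", "rels": [("develops_from", "A:2")]},
            "A:2": {},
        })
        findings = find_duplicate_relation_pairs(onto)
        assert [f.subjects for f in findings] == [("A:1", "A:2")]
        assert findings[0].severity == "warning"

    def test_single_relation_is_fine(self):
        onto = make_onto({"A:1": {"parent": "A:2"}, "A:2": {}})
        assert find_duplicate_relation_pairs(onto) == []

    def test_different_pairs_are_fine(self):
        onto = make_onto({
            "A:1": {"parent": "A:2"},
            "A:3": {"rels": [("develops_from", "A:2")]},
            "A:2": {},
        })
        assert find_duplicate_relation_pairs(onto) == []


class TestValidate:
    def test_report_matches_union_of_checks(self):
        onto, _ = build_paper_fixture("tcr_disjoint_pre")
        report = validate(onto)
        assert [f.category for f in report.findings] == ["disjointness_violation"]
        assert report.has_errors

    def test_clean_scenarios_produce_no_findings(self, scenario):
        name, onto, truth = scenario
        if truth.clean:
            report = validate(onto)
            assert report.findings == [], (name, report.to_text())
            assert not report.has_errors

    def test_cycle_reported_as_finding_not_crash(self):
        onto = make_onto({"A:1": {"parent": "A:2"}, "A:2": {"parent": "A:1"}})
        report = validate(onto)
        assert [f.category for f in report.findings] == ["cycle"]
        assert report.closure is None

    def test_dangling_reference_reported(self):
        onto = make_onto({"A:1": {"parent": "A:9"}})
        report = validate(onto)
        assert any(f.category == "dangling_reference" for f in report.findings)

    def test_deterministic_ordering(self):
        onto, _ = build_paper_fixture("treg_pre")
        r1, r2 = validate(onto), validate(onto)
        assert [f.sort_key() for f in r1.findings] == \
            [f.sort_key() for f in r2.findings]
        cats = [f.category for f in r1.findings]
        assert cats == sorted(cats)

    def test_tsv_report_shape(self):
        onto, _ = build_paper_fixture("granule_conflict")
        tsv = validate(onto).to_tsv().splitlines()
        assert tsv[0].split("\t") == ["category", "severity", "subjects",
                                      "detail", "explanation_steps"]
        assert len(tsv) == 2
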