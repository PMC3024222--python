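"""Packaged scenarios and the random generator with planted ground truth."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from obolog.diagnostics import validate
from obolog.errors import InfeasibleParamsError, UnknownEntityError
from obolog.expand import normalize_ontology
from obolog.fixtures import build_paper_fixture
from obolog.generator import GeneratorParams, generate_random_ontology
from obolog.io import parse_obo, same_content, write_obo
from obolog.reasoner import classify


class TestScenarioGroundTruth:
    def test_ground_truth_reproduced(self, scenario):
        """The main contract: reasoning plus diagnostics on each packaged
        scenario reproduce exactly the outcomes it was built to show."""
        name, onto, truth = scenario
        closure = classify(normalize_ontology(onto))
        for sub, sup, rel in truth.expected_entailments:
            assert closure.is_entailed(sub, sup, rel), (name, sub, sup, rel)
        for sub, sup, rel in truth.absent_entailments:
            assert not closure.is_entailed(sub, sup, rel), (name, sub, sup, rel)
        for parent, kids in truth.direct_children.items():
            assert closure.inferred_direct_children(parent) == set(kids)
        for child, parents in truth.direct_parents.items():
            assert closure.inferred_direct_parents(child) == set(parents)
        report = validate(onto)
        if truth.clean:
            assert report.findings == [], (name, report.to_text())
        else:
            assert sorted(f.category for f in report.findings) == \
                sorted(c for c, _ in truth.expected_findings), name
            for category, subjects in truth.expected_findings:
                assert any(f.category == category
                           and set(subjects) <= set(f.subjects)
                           for f in report.findings), (name, category, subjects)

    def test_fixtures_parse_cleanly_and_are_dags(self, scenario):
        name, onto, _ = scenario
        assert onto.dangling_references() == set(), name
        assert onto.detect_cycles() == []
        assert same_content(parse_obo(write_obo(onto)), onto)

    def test_stem_cell_scenario_negative_marker_inheritance(self):
        """Species-specific stem cells inherit the full lineage-negative
        panel from the species-neutral class."""
        onto, _ = build_paper_fixture("hsc_species")
        ax = normalize_ontology(onto)
        closure = classify(ax)
        panel = {f for r, f in ax.negative_facts["CL:0000037"]}
        assert len(panel) == 12
        for subtype in ("CL:0900061", "CL:0900062"):
            inherited = set()
            for sup in {b for a, b in closure.entailed_isa if a == subtype}:
                inherited |= {f for r, f in ax.negative_facts.get(sup, set())}
            assert panel <= inherited

    def test_unknown_name_rejected(self):
        with pytest.raises(UnknownEntityError):
            build_paper_fixture("no_such_scenario")


PLANTED = GeneratorParams(
    n_classes=60, p_defined=0.7, n_planted_subsumptions=2,
    n_planted_disjoint_violations=3, n_planted_redundant_edges=2,
    n_planted_polarity_conflicts=2, df_chain_length=5, seed=42)


class TestGenerator:
    def test_byte_identical_output_per_seed(self):
        o1, t1 = generate_random_ontology(PLANTED)
        o2, t2 = generate_random_ontology(PLANTED)
        assert write_obo(o1) == write_obo(o2)
        assert t1.expected_entailments == t2.expected_entailments

    def test_different_seeds_differ(self):
        o1, _ = generate_random_ontology(PLANTED)
        o2, _ = generate_random_ontology(
            GeneratorParams(**{**PLANTED.__dict__, "seed": 43}))
        assert write_obo(o1) != write_obo(o2)

    def test_planted_findings_are_exactly_what_diagnostics_reports(self):
        onto, truth = generate_random_ontology(PLANTED)
        report = validate(onto)
        got = Counter(f.category for f in report.findings)
        want = Counter(c for c, _ in truth.expected_findings)
        assert got == want
        for category, subjects in truth.expected_findings:
            assert any(f.category == category and set(subjects) <= set(f.subjects)
                       for f in report.findings), (category, subjects)

    def test_planted_entailments_hold(self):
        onto, truth = generate_random_ontology(PLANTED)
        closure = classify(normalize_ontology(onto))
        for sub, sup, rel in truth.expected_entailments:
            assert closure.is_entailed(sub, sup, rel)

    def test_empty_request(self):
        onto, truth = generate_random_ontology(GeneratorParams(n_classes=0))
        assert onto.classes == {}
        assert truth.expected_entailments == set()

    def test_infeasible_params_rejected(self):
        with pytest.raises(InfeasibleParamsError):
            generate_random_ontology(GeneratorParams(
                n_classes=5, n_planted_disjoint_violations=4))
        with pytest.raises(InfeasibleParamsError):
            generate_random_ontology(GeneratorParams(n_classes=10, p_defined=1.5))

    def test_planted_cycle_is_detected(self):
        onto, truth = generate_random_ontology(GeneratorParams(
            n_classes=20, plant_cycle=True, seed=3))
        cycles = onto.detect_cycles()
        assert len(cycles) == 1
        assert set(cycles[0]) == set(truth.planted_cycles[0])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_output_round_trips_for_any_seed(self, seed):
        onto, _ = generate_random_ontology(GeneratorParams(
            n_classes=25, p_defined=0.5, df_chain_length=3, seed=seed))
        text = write_obo(onto)
        again = parse_obo(text)
        assert same_content(again, onto)
        assert write_obo(again) == text
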