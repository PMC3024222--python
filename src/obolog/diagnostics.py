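"""Curation QA battery.

Four checks mirror the errors a reasoner can surface during cell-type
curation:

* **disjointness violations** — a class entailed under both members of a
  ``disjoint_from`` pair is unsatisfiable;
* **polarity conflicts** — an inherited lacks-type fact contradicting an
  inherited positive fact on the same base relation (e.g. a myelocyte that
  ``lacks_part`` tertiary granule below a granulocyte ancestor that
  ``has_part`` tertiary granule);
* **redundant edges** — an asserted ``is_a``/``develops_from`` edge that the
  rest of the ontology re-derives on its own;
* **duplicate relation pairs** — two assertions with different relations
  between the same pair of classes, a common curation slip.

``validate`` aggregates everything (plus parse-level checks and stats) into
one deterministic report.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field

from .expand import (
    DEFAULT_CONFIG,
    NormalizedAxiomSet,
    ReasonerConfig,
    conflict_positive_facts,
    normalize_ontology,
)
from .io import StatsSummary, stats
from .model import CURIE, DEVELOPS_FROM, IS_A, OntologyGraph
from .reasoner import InferredClosure, classify

CATEGORIES = (
    "cycle",
    "dangling_reference",
    "disjointness_violation",
    "duplicate_relation_pair",
    "malformed_definition",
    "polarity_conflict",
    "redundant_edge",
)


@dataclass(frozen=True)
class DiagnosticFinding:
    category: str
    subjects: tuple[CURIE, ...]
    detail: str
    severity: str = "error"  # error | warning
    explanation: tuple = ()

    def sort_key(self):
        return (self.category, self.subjects, self.detail)


def _isa_chain(closure: InferredClosure, sub: CURIE, sup: CURIE) -> tuple:
    if sub == sup:
        return ()
    return tuple(tuple(sorted(s.items())) for s in closure.explain(sub, sup, IS_A))


# ---------------------------------------------------------------------------


def check_disjointness(closure: InferredClosure,
                       axioms: NormalizedAxiomSet) -> list[DiagnosticFinding]:
    """One error finding per (class, disjoint pair) with the class entailed
    under both members; the pair members themselves count."""
    findings = []
    unsat_roots: dict[frozenset, list[CURIE]] = {}
    for pair in sorted(axioms.disjointness, key=sorted):
        a, b = sorted(pair)
        offenders = [x for x in sorted(closure.known_ids)
                     if (x == a or (x, a) in closure.entailed_isa)
                     and (x == b or (x, b) in closure.entailed_isa)]
        unsat_roots[pair] = offenders
        for x in offenders:
            cascaded = any(o != x and (x, o) in closure.entailed_isa for o in offenders)
            detail = (f"{x} is entailed under both members of the disjoint "
                      f"pair ({a}, {b}) and is therefore unsatisfiable")
            if cascaded:
                detail += " (cascaded from an unsatisfiable ancestor)"
            findings.append(DiagnosticFinding(
                category="disjointness_violation",
                subjects=(x, a, b),
                detail=detail,
                severity="error",
                explanation=_isa_chain(closure, x, a) + _isa_chain(closure, x, b),
            ))
    return sorted(findings, key=DiagnosticFinding.sort_key)


def check_polarity_conflicts(closure: InferredClosure,
                             axioms: NormalizedAxiomSet) -> list[DiagnosticFinding]:
    """Classes whose inherited positive and negative facts contradict.

    A negative fact (base relation b, filler F0) clashes with an inherited
    positive fact (b, F) whenever F is_a* F0: an exactly-zero constraint on
    the broader filler forbids every narrower one.  Positive facts are
    first augmented with their structural consequences (membrane-part
    implies plain parthood; surface-amount implies membrane presence)."""
    cfg = axioms.config
    findings = []
    sup = {x: {b for (a, b) in closure.entailed_isa if a == x}
           for x in closure.known_ids}

    def inherited(fact_map, x):
        out = {}
        for owner in [x] + sorted(sup.get(x, ())):
            for f in fact_map.get(owner, ()):
                out.setdefault(f, owner)
        return out

    for x in sorted(closure.known_ids):
        neg = inherited(axioms.negative_facts, x)
        if not neg:
            continue
        pos = {}
        for fact, owner in sorted(inherited(axioms.positive_facts, x).items()):
            for g in conflict_positive_facts({fact}, cfg):
                pos.setdefault(g, owner)
        seen = set()
        for (nb, f0), nowner in sorted(neg.items()):
            for (pb, f), powner in sorted(pos.items()):
                if pb != nb:
                    continue
                if f == f0 or (f, f0) in closure.entailed_isa:
                    key = (x, nb, f, f0)
                    if key in seen:
                        continue
                    seen.add(key)
                    findings.append(DiagnosticFinding(
                        category="polarity_conflict",
                        subjects=(x, f, f0),
                        detail=(f"{x} inherits '{pb} {f}' (from {powner}) but also "
                                f"'lacks {nb} {f0}' (from {nowner}); having a "
                                f"{f} contradicts having exactly zero {f0}"),
                        severity="error",
                        explanation=_isa_chain(closure, x, powner)
                        + _isa_chain(closure, x, nowner)
                        + _isa_chain(closure, f, f0),
                    ))
    return sorted(findings, key=DiagnosticFinding.sort_key)


def find_redundant_edges(onto: OntologyGraph,
                         config: ReasonerConfig = DEFAULT_CONFIG) -> list[DiagnosticFinding]:
    """Asserted edges the ontology re-derives without them.

    Each asserted ``is_a``/``develops_from`` edge is removed in turn
    (together with the definition line restating it, which is the same
    assertion written twice) and the ontology reclassified; if the edge is
    still entailed it is redundant, and the alternate derivation is
    attached as the explanation."""
    findings = []
    edges = [(c, p, IS_A) for c, p in onto.asserted_edges(IS_A)]
    edges += [(c, t, DEVELOPS_FROM) for c, t in onto.asserted_edges(DEVELOPS_FROM)]
    for child, target, rel in sorted(edges):
        reduced = normalize_ontology(onto, config, omit_edges=frozenset({(child, target, rel)}))
        closure = classify(reduced)
        if target not in closure.known_ids or child not in closure.known_ids:
            continue
        if closure.is_entailed(child, target, rel):
            findings.append(DiagnosticFinding(
                category="redundant_edge",
                subjects=(child, target),
                detail=(f"asserted '{child} {rel} {target}' is redundant: it is "
                        "re-derived from the remaining axioms"),
                severity="warning",
                explanation=tuple(tuple(sorted(s.items()))
                                  for s in closure.explain(child, target, rel)),
            ))
    return sorted(findings, key=DiagnosticFinding.sort_key)


def find_duplicate_relation_pairs(onto: OntologyGraph) -> list[DiagnosticFinding]:
    """Unordered class pairs connected by two or more distinct asserted
    relations — usually a curation mistake even when consistent."""
    by_pair: dict[frozenset, set[str]] = {}
    for node in onto.classes.values():
        for p in node.is_a_parents:
            by_pair.setdefault(frozenset((node.id, p)), set()).add(IS_A)
        for rel, t in node.relationships:
            by_pair.setdefault(frozenset((node.id, t)), set()).add(rel)
    findings = []
    for pair, rels in by_pair.items():
        if len(rels) >= 2 and len(pair) == 2:
            a, b = sorted(pair)
            findings.append(DiagnosticFinding(
                category="duplicate_relation_pair",
                subjects=(a, b),
                detail=(f"classes {a} and {b} are connected by "
                        f"{len(rels)} distinct relations: {', '.join(sorted(rels))}"),
                severity="warning",
            ))
    return sorted(findings, key=DiagnosticFinding.sort_key)


# ---------------------------------------------------------------------------


@dataclass
class DiagnosticReport:
    findings: list[DiagnosticFinding] = field(default_factory=list)
    summary: StatsSummary = field(default_factory=StatsSummary)
    closure: InferredClosure | None = None

    @property
    def has_errors(self) -> bool:
        return any(f.severity == "error" for f in self.findings)

    def by_category(self, category: str) -> list[DiagnosticFinding]:
        return [f for f in self.findings if f.category == category]

    def to_tsv(self) -> str:
        buf = _io.StringIO()
        w = csv.writer(buf, delimiter="\t", lineterminator="\n")
        w.writerow(["category", "severity", "subjects", "detail", "explanation_steps"])
        for f in self.findings:
            w.writerow([f.category, f.severity, "|".join(f.subjects),
                        f.detail, len(f.explanation)])
        return buf.getvalue()

    def to_text(self) -> str:
        lines = [f"{len(self.findings)} finding(s); "
                 f"{'errors present' if self.has_errors else 'no errors'}"]
        for f in self.findings:
            lines.append(f"[{f.severity.upper()}] {f.category}: {f.detail}")
        return "\n".join(lines) + "\n"


def validate(onto: OntologyGraph,
             config: ReasonerConfig = DEFAULT_CONFIG) -> DiagnosticReport:
    """Run the whole battery: parse-level checks, classification, then the
    four reasoning checks, deterministically ordered by (category,
    subjects).  A cyclic hierarchy is itself reported as a finding and
    suppresses the classification-dependent checks rather than crashing."""
    findings: list[DiagnosticFinding] = []

    for ref in sorted(onto.dangling_references()):
        findings.append(DiagnosticFinding(
            category="dangling_reference", subjects=(ref,),
            detail=f"referenced class {ref} is not declared in the merged ontology",
            severity="warning"))
    for node in onto.classes.values():
        if node.definition is not None and node.definition.genus not in onto.classes:
            findings.append(DiagnosticFinding(
                category="malformed_definition", subjects=(node.id,),
                detail=f"genus {node.definition.genus} of {node.id} does not resolve",
                severity="warning"))

    cycles = onto.detect_cycles(IS_A)
    closure = None
    if cycles:
        for cyc in cycles:
            findings.append(DiagnosticFinding(
                category="cycle", subjects=tuple(sorted(cyc)),
                detail="asserted is_a cycle: " + " -> ".join(cyc + [cyc[0]]),
                severity="error"))
    else:
        axioms = normalize_ontology(onto, config)
        closure = classify(axioms)
        findings += check_disjointness(closure, axioms)
        findings += check_polarity_conflicts(closure, axioms)
        findings += find_redundant_edges(onto, config)
        findings += find_duplicate_relation_pairs(onto)

    return DiagnosticReport(
        findings=sorted(findings, key=DiagnosticFinding.sort_key),
        summary=stats(onto),
        closure=closure,
    )
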