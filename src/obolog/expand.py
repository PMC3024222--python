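"""Macro expansion of shorthand relations and whole-ontology normalization.

OBO format has no negation, so curation uses shorthand relations such as
``lacks_plasma_membrane_part`` whose real semantics is an exactly-zero
cardinality over an expanded part-of structure.  This module expands each
shorthand into its canonical structural form (``expand_relation``) and
flattens a whole ontology into the axiom shapes the saturation reasoner
consumes (``normalize_ontology``):

* asserted ``is_a`` lines and definition genera  -> subsumptions
* positive relationships / differentia           -> positive facts
* lacks-type relationships / differentia         -> negative facts, keyed by
  the positive base relation they negate
* cross-product definitions                      -> equivalences (plus their
  decomposition into the items above)
* ``disjoint_from``                              -> unordered disjoint pairs

The expansion table:

=============================  =================================================
shorthand                      expansion
=============================  =================================================
has_plasma_membrane_part Y     has_part some ('plasma membrane' and has_part some Y)
lacks_plasma_membrane_part Y   has_part exactly 0 ('plasma membrane' and has_part some Y)
lacks_part Y                   has_part exactly 0 Y
capable_of Y                   bearer_of some (realized_by only Y)
participates_in Y              (no expansion)
has_completed Y                transformation_of some (participates_in some Y)
has_not_completed Y            not (transformation_of some (participates_in some Y))
=============================  =================================================

The high/low plasma-membrane-amount relations have quantitative semantics
that this axiom language cannot express; they stay atomic, optionally
entailing plain membrane-part presence for subsumption matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import CycleError, UnknownEntityError
from .model import (
    CURIE,
    IS_A,
    Definition,
    OntologyGraph,
    RelationId,
    base_relation,
    is_negative,
)

#: Filler the membrane-part expansions are built around.
PLASMA_MEMBRANE: CURIE = "GO:0005886"


# ---------------------------------------------------------------------------
# expression language


@dataclass(frozen=True)
class NormalizedExpression:
    """A tiny class-expression tree: atomic | some | exactly_zero | and |
    not | only.  Negation (``exactly_zero`` / ``not``) appears only at the
    top level of an expansion."""

    form: str
    relation: RelationId | None = None
    curie: CURIE | None = None
    children: tuple["NormalizedExpression", ...] = ()

    def render(self) -> str:
        if self.form == "atomic":
            return self.curie
        if self.form == "some":
            return f"{self.relation} some ({self.children[0].render()})"
        if self.form == "exactly_zero":
            return f"{self.relation} exactly 0 ({self.children[0].render()})"
        if self.form == "only":
            return f"{self.relation} only ({self.children[0].render()})"
        if self.form == "and":
            return " and ".join(c.render() for c in self.children)
        if self.form == "not":
            return f"not ({self.children[0].render()})"
        raise AssertionError(self.form)


def atomic(c: CURIE) -> NormalizedExpression:
    return NormalizedExpression("atomic", curie=c)


def some(rel: RelationId, x: NormalizedExpression) -> NormalizedExpression:
    return NormalizedExpression("some", relation=rel, children=(x,))


def exactly_zero(rel: RelationId, x: NormalizedExpression) -> NormalizedExpression:
    return NormalizedExpression("exactly_zero", relation=rel, children=(x,))


def only(rel: RelationId, x: NormalizedExpression) -> NormalizedExpression:
    return NormalizedExpression("only", relation=rel, children=(x,))


def and_(*xs: NormalizedExpression) -> NormalizedExpression:
    return NormalizedExpression("and", children=tuple(xs))


def not_(x: NormalizedExpression) -> NormalizedExpression:
    return NormalizedExpression("not", children=(x,))


def _membrane_body(filler: CURIE) -> NormalizedExpression:
    return and_(atomic(PLASMA_MEMBRANE), some("has_part", atomic(filler)))


def expand_relation(relation: RelationId, filler: CURIE,
                    expand_capable_of: bool = True) -> NormalizedExpression:
    """Expand one shorthand relation-filler pair into its structural form.

    Relations outside the expansion table pass through as plain
    existentials.  Purely syntactic and total; expanding an already-expanded
    ontology changes nothing (the expansion never reintroduces a shorthand).
    """
    if relation == "has_plasma_membrane_part":
        return some("has_part", _membrane_body(filler))
    if relation == "lacks_plasma_membrane_part":
        return exactly_zero("has_part", _membrane_body(filler))
    if relation == "lacks_part":
        return exactly_zero("has_part", atomic(filler))
    if relation == "capable_of" and expand_capable_of:
        # inert for classification; required only for upper-ontology
        # compatibility of the exported axioms
        return some("bearer_of", only("realized_by", atomic(filler)))
    if relation == "has_completed":
        return some("transformation_of", some("participates_in", atomic(filler)))
    if relation == "has_not_completed":
        return not_(some("transformation_of", some("participates_in", atomic(filler))))
    if not relation or not filler:
        raise UnknownEntityError(f"cannot expand ({relation!r}, {filler!r})")
    return some(relation, atomic(filler))


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ReasonerConfig:
    """Toggles for the optional entailment conventions (all default on).

    participates_in_entails_capable_of
        actual participation in a process entails the capability for it, so
        a ``participates_in`` fact satisfies a ``capable_of`` differentia.
    amount_entails_membrane_part
        a high/low surface-amount fact entails plain membrane-part presence.
    membrane_part_entails_part_in_conflicts
        the expanded membrane-part form nests a plain ``has_part``, so a
        membrane-part fact clashes with ``lacks_part`` of the same filler
        (the converse does not hold: lacking a *membrane* part says nothing
        about the part being elsewhere in the cell).
    df_source_interplay / df_target_interplay
        whether ``develops_from`` composes with ``is_a`` on the descendant
        side (X is_a X', X' develops_from Y  =>  X develops_from Y) and/or
        the origin side (X develops_from Y, Y is_a Y'  =>  X develops_from
        Y').
    """

    participates_in_entails_capable_of: bool = True
    amount_entails_membrane_part: bool = True
    membrane_part_entails_part_in_conflicts: bool = True
    df_source_interplay: bool = True
    df_target_interplay: bool = True
    expand_capable_of: bool = True

    def sub_relations(self, relation: RelationId) -> frozenset[RelationId]:
        """Relations whose positive facts satisfy a differentia on
        ``relation`` (always includes the relation itself)."""
        subs = {relation}
        if relation == "capable_of" and self.participates_in_entails_capable_of:
            subs.add("participates_in")
        if relation == "has_plasma_membrane_part" and self.amount_entails_membrane_part:
            subs.add("has_high_plasma_membrane_amount")
            subs.add("has_low_plasma_membrane_amount")
        return frozenset(subs)


DEFAULT_CONFIG = ReasonerConfig()


# ---------------------------------------------------------------------------
# normalization

Fact = tuple[RelationId, CURIE]
Edge = tuple[CURIE, CURIE]
#: (child, target, relation) triple naming one asserted edge to omit;
#: the definition genus / differentia duplicating that edge is omitted too.
OmittedEdge = tuple[CURIE, CURIE, RelationId]


@dataclass
class NormalizedAxiomSet:
    """Post-expansion internal axioms of one (merged) ontology."""

    subsumptions: set[Edge] = field(default_factory=set)
    positive_facts: dict[CURIE, set[Fact]] = field(default_factory=dict)
    negative_facts: dict[CURIE, set[Fact]] = field(default_factory=dict)
    equivalences: dict[CURIE, Definition] = field(default_factory=dict)
    disjointness: set[frozenset] = field(default_factory=set)
    config: ReasonerConfig = DEFAULT_CONFIG
    #: expression form of every expanded fact, for export/eyeballing
    expressions: dict[CURIE, list[NormalizedExpression]] = field(default_factory=dict)

    def classes(self) -> list[CURIE]:
        ids: set[CURIE] = set()
        for a, b in self.subsumptions:
            ids.add(a)
            ids.add(b)
        for m in (self.positive_facts, self.negative_facts):
            for c, facts in m.items():
                ids.add(c)
                ids.update(f for _, f in facts)
        for c, d in self.equivalences.items():
            ids.add(c)
            ids.add(d.genus)
            ids.update(x.filler for x in d.differentia)
        for pair in self.disjointness:
            ids.update(pair)
        return sorted(ids)

    def _fact_map(self, neg: bool) -> dict[CURIE, set[Fact]]:
        return self.negative_facts if neg else self.positive_facts

    def add_fact(self, cls: CURIE, relation: RelationId, filler: CURIE) -> None:
        """File one relationship/differentia under the right polarity,
        keying negatives by their positive base relation."""
        neg = is_negative(relation)
        self._fact_map(neg).setdefault(cls, set()).add((base_relation(relation), filler))
        self.expressions.setdefault(cls, []).append(
            expand_relation(relation, filler, self.config.expand_capable_of))

    def export_functional(self) -> str:
        """Expanded axioms as human-readable functional-style text, one per
        line, deterministically ordered."""
        lines: list[str] = []
        for a, b in sorted(self.subsumptions):
            lines.append(f"SubClassOf({a} {b})")
        for c in sorted(self.expressions):
            for expr in sorted((e.render() for e in self.expressions[c])):
                lines.append(f"SubClassOf({c} {expr})")
        for c in sorted(self.equivalences):
            d = self.equivalences[c]
            parts = [d.genus] + [
                expand_relation(x.relation, x.filler, self.config.expand_capable_of).render()
                for x in sorted(d.differentia, key=lambda x: (x.relation, x.filler))]
            lines.append(f"EquivalentClasses({c} ObjectIntersectionOf({' '.join(parts)}))")
        for pair in sorted(self.disjointness, key=sorted):
            a, b = sorted(pair)
            lines.append(f"DisjointClasses({a} {b})")
        return "\n".join(lines) + "\n"


def normalize_ontology(
    onto: OntologyGraph,
    config: ReasonerConfig = DEFAULT_CONFIG,
    omit_edges: frozenset[OmittedEdge] = frozenset(),
) -> NormalizedAxiomSet:
    """Flatten an ontology into the axiom set the reasoner consumes.

    Every definition is decomposed: its genus becomes a subsumption and its
    differentia become facts, alongside the equivalence used for membership
    inference.  ``omit_edges`` supports the redundancy check: an omitted
    asserted edge is dropped *together with* the genus line or
    develops_from differentia that restates it, since in cross-product
    curation those are one assertion written twice.

    Requires the asserted ``is_a`` graph to be acyclic.
    """
    cycles = onto.detect_cycles(IS_A)
    if cycles:
        raise CycleError(cycles[0], IS_A)

    ax = NormalizedAxiomSet(config=config)
    for cid in sorted(onto.classes):
        node = onto.classes[cid]
        for p in node.is_a_parents:
            if (cid, p, IS_A) not in omit_edges:
                ax.subsumptions.add((cid, p))
        for rel, target in node.relationships:
            if (cid, target, rel) in omit_edges:
                continue
            ax.add_fact(cid, rel, target)
        d = node.definition
        if d is not None:
            ax.equivalences[cid] = d
            if (cid, d.genus, IS_A) not in omit_edges:
                ax.subsumptions.add((cid, d.genus))
            for x in d.differentia:
                if (cid, x.filler, x.relation) in omit_edges:
                    continue
                ax.add_fact(cid, x.relation, x.filler)
        for other in node.disjoint_from:
            ax.disjointness.add(frozenset((cid, other)))
    return ax


def conflict_positive_facts(facts: set[Fact], config: ReasonerConfig) -> set[Fact]:
    """Positive facts augmented with what they structurally entail for
    conflict checking: the membrane-part expansion nests a plain has_part,
    and amount facts assert membrane presence."""
    out = set(facts)
    for rel, filler in facts:
        if rel in ("has_high_plasma_membrane_amount", "has_low_plasma_membrane_amount") \
                and config.amount_entails_membrane_part:
            out.add(("has_plasma_membrane_part", filler))
    if config.membrane_part_entails_part_in_conflicts:
        for rel, filler in list(out):
            if rel == "has_plasma_membrane_part":
                out.add(("has_part", filler))
    return out
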