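"""In-memory model of an OBO ontology with genus-differentia definitions.

A cell-type class is defined by refining a single more general class (the
*genus*) with one or more differentiating relation-filler conditions (the
*differentia*), e.g. a nucleate erythrocyte is an erythrocyte that
``has_part`` a nucleus.  The model holds one :class:`OntologyGraph` per
parsed file (plus merged imports) and knows nothing about reasoning; the
saturation rules live in :mod:`obolog.reasoner`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import CycleError, UnknownEntityError

CURIE = str
RelationId = str

#: Prefixes the hematopoietic cell-type work draws on; unknown prefixes are
#: accepted but reported by :meth:`OntologyGraph.unknown_prefix_ids`.
KNOWN_PREFIXES = frozenset({"CL", "GO", "PR", "UBERON", "PATO", "CP"})

#: CURIE aliases canonicalized on input (Protein Ontology is cited under
#: both spellings in the literature).
PREFIX_ALIASES = {"PRO": "PR"}

IS_A: RelationId = "is_a"
DEVELOPS_FROM: RelationId = "develops_from"

#: Negative ("lacks"-type) shorthand relation -> its positive base relation.
#: Conflict detection and definition matching pair a negative fact with
#: positive facts on the base relation.
NEGATIVE_BASE: dict[RelationId, RelationId] = {
    "lacks_plasma_membrane_part": "has_plasma_membrane_part",
    "lacks_part": "has_part",
    "has_not_completed": "has_completed",
}

#: The differentia vocabulary available without an explicit [Typedef].
BUILTIN_RELATIONS: frozenset[RelationId] = frozenset(
    {
        "has_plasma_membrane_part",
        "lacks_plasma_membrane_part",
        "has_high_plasma_membrane_amount",
        "has_low_plasma_membrane_amount",
        "capable_of",
        "participates_in",
        "has_completed",
        "has_not_completed",
        "has_part",
        "lacks_part",
        "part_of",
        "develops_from",
        "has_quality",
    }
)

#: Builtins that are transitive by OBO convention.
BUILTIN_TRANSITIVE: frozenset[RelationId] = frozenset(
    {"part_of", "develops_from", "has_part"}
)


def is_negative(relation: RelationId) -> bool:
    return relation in NEGATIVE_BASE


def base_relation(relation: RelationId) -> RelationId:
    """The positive base of a relation (identity for positive relations)."""
    return NEGATIVE_BASE.get(relation, relation)


def curie_prefix(curie: CURIE) -> str:
    return curie.split(":", 1)[0] if ":" in curie else ""


def canonical_curie(curie: CURIE) -> CURIE:
    prefix, _, local = curie.partition(":")
    if prefix in PREFIX_ALIASES:
        return f"{PREFIX_ALIASES[prefix]}:{local}"
    return curie


@dataclass(frozen=True)
class Differentia:
    """One differentiating condition: a relation to a named filler class."""

    relation: RelationId
    filler: CURIE


@dataclass(frozen=True)
class Definition:
    """Genus-differentia (cross-product) definition of a class.

    The defined class is equivalent to the genus intersected with all
    differentia; a valid definition has exactly one genus and at least one
    differentia.
    """

    genus: CURIE
    differentia: tuple[Differentia, ...]

    def __post_init__(self):
        if not self.differentia:
            raise ValueError("a definition needs at least one differentia")


@dataclass
class RelationDef:
    """Declared properties of a relation (OBO [Typedef])."""

    id: RelationId
    name: str | None = None
    is_transitive: bool = False
    parent_relations: list[RelationId] = field(default_factory=list)
    extra_tags: list[tuple[str, str]] = field(default_factory=list)

    @property
    def polarity(self) -> str:
        return "negative" if is_negative(self.id) else "positive"

    def __post_init__(self):
        # exactly-zero semantics cannot chain: a negative relation being
        # transitive would be unsound, so it is rejected outright.
        if is_negative(self.id) and self.is_transitive:
            raise ValueError(f"negative relation {self.id} cannot be transitive")


@dataclass
class ClassNode:
    """One [Term]: a named class with its asserted links and definition."""

    id: CURIE
    name: str | None = None
    namespace: str | None = None
    is_a_parents: list[CURIE] = field(default_factory=list)
    relationships: list[tuple[RelationId, CURIE]] = field(default_factory=list)
    definition: Definition | None = None
    disjoint_from: list[CURIE] = field(default_factory=list)
    synonyms: list[str] = field(default_factory=list)
    textual_def: str | None = None
    extra_tags: list[tuple[str, str]] = field(default_factory=list)

    def referenced_ids(self) -> set[CURIE]:
        refs = set(self.is_a_parents)
        refs.update(f for _, f in self.relationships)
        refs.update(self.disjoint_from)
        if self.definition is not None:
            refs.add(self.definition.genus)
            refs.update(d.filler for d in self.definition.differentia)
        return refs

    def content_key(self):
        """Order-insensitive content fingerprint (used for merge conflicts
        and round-trip equality)."""
        defn = None
        if self.definition is not None:
            defn = (self.definition.genus, tuple(sorted(self.definition.differentia,
                                                        key=lambda d: (d.relation, d.filler))))
        return (
            self.id,
            self.name,
            self.namespace,
            tuple(sorted(self.is_a_parents)),
            tuple(sorted(self.relationships)),
            defn,
            tuple(sorted(self.disjoint_from)),
            tuple(sorted(self.synonyms)),
            self.textual_def,
            tuple(sorted(self.extra_tags)),
        )


@dataclass
class OntologyGraph:
    """Classes, relation declarations and axioms of one (merged) ontology."""

    classes: dict[CURIE, ClassNode] = field(default_factory=dict)
    typedefs: dict[RelationId, RelationDef] = field(default_factory=dict)
    header: dict[str, list[str]] = field(default_factory=dict)

    # -- lookup ---------------------------------------------------------

    def __contains__(self, curie: CURIE) -> bool:
        return curie in self.classes

    def node(self, curie: CURIE) -> ClassNode:
        try:
            return self.classes[curie]
        except KeyError:
            raise UnknownEntityError(curie) from None

    def add(self, node: ClassNode) -> None:
        if node.id in self.classes:
            raise ValueError(f"duplicate class id {node.id}")
        self.classes[node.id] = node

    @property
    def disjoint_pairs(self) -> set[frozenset]:
        """Unordered (hence symmetric) disjointness pairs."""
        pairs: set[frozenset] = set()
        for node in self.classes.values():
            for other in node.disjoint_from:
                pairs.add(frozenset((node.id, other)))
        return pairs

    def dangling_references(self) -> set[CURIE]:
        """Referenced CURIEs that resolve to no class.

        Relation ids are not classes and are checked separately via
        :meth:`undeclared_relations`.
        """
        known = set(self.classes)
        dangling: set[CURIE] = set()
        for node in self.classes.values():
            dangling.update(node.referenced_ids() - known)
        return dangling

    def undeclared_relations(self) -> set[RelationId]:
        used: set[RelationId] = set()
        for node in self.classes.values():
            used.update(r for r, _ in node.relationships)
            if node.definition is not None:
                used.update(d.relation for d in node.definition.differentia)
        return {r for r in used if r not in BUILTIN_RELATIONS and r not in self.typedefs}

    def unknown_prefix_ids(self) -> set[CURIE]:
        return {c for c in self.classes if curie_prefix(c) not in KNOWN_PREFIXES}

    def is_transitive(self, relation: RelationId) -> bool:
        if relation == IS_A:
            return True
        if relation in self.typedefs:
            return self.typedefs[relation].is_transitive
        return relation in BUILTIN_TRANSITIVE

    # -- asserted-edge queries ------------------------------------------

    def _edge_targets(self, curie: CURIE, relation: RelationId) -> list[CURIE]:
        node = self.node(curie)
        if relation == IS_A:
            return list(node.is_a_parents)
        return [f for r, f in node.relationships if r == relation]

    def asserted_edges(self, relation: RelationId) -> list[tuple[CURIE, CURIE]]:
        return [
            (c, t)
            for c in sorted(self.classes)
            for t in self._edge_targets(c, relation)
        ]

    def get_ancestors(self, curie: CURIE, relation: RelationId = IS_A) -> set[CURIE]:
        """All classes reachable from ``curie`` along asserted edges of a
        transitive relation, excluding ``curie`` itself.

        Raises :class:`UnknownEntityError` for an unknown id and
        :class:`CycleError` if traversal returns to the start class.
        """
        self.node(curie)
        if not self.is_transitive(relation):
            raise ValueError(f"{relation} is not transitive; ancestors undefined")
        seen: set[CURIE] = set()
        # dangling targets still count as reachable names (lenient parsing)
        stack = list(self._edge_targets(curie, relation))
        while stack:
            current = stack.pop()
            if current in seen:
                continue
            seen.add(current)
            if current in self.classes:
                stack.extend(self._edge_targets(current, relation))
        for cycle in self.detect_cycles(relation):
            if seen.intersection(cycle) or curie in cycle:
                raise CycleError(cycle, relation)
        return seen

    def detect_cycles(self, relation: RelationId = IS_A) -> list[list[CURIE]]:
        """Cycles in the asserted graph of one relation, each reported as
        its member classes in traversal order.  Reporting only: never raises.
        """
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.classes)
        for sub, sup in self.asserted_edges(relation):
            if sup in self.classes:
                g.add_edge(sub, sup)
        cycles = []
        for scc in nx.strongly_connected_components(g):
            if len(scc) > 1:
                sub = g.subgraph(scc)
                cycles.append(next(iter(nx.simple_cycles(sub))))
            elif len(scc) == 1:
                (n,) = scc
                if g.has_edge(n, n):
                    cycles.append([n])
        return sorted(cycles, key=lambda c: sorted(c))
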