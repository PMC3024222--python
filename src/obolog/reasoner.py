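"""Structural saturation reasoner for genus-differentia ontologies.

Classification applies monotone completion rules to a least fixpoint:

R1  is_a transitivity.
R2  fact inheritance: a class inherits the positive and negative facts of
    all its is_a ancestors (realized lazily during matching).
R3  definition introduction: for a defined class C = G and differentia set
    D, any class X (other than C) subsumed by the genus whose inherited
    facts satisfy every differentia gains X is_a C.  A positive differentia
    (r, F) is satisfied by an inherited fact (r', F') with r' a declared
    sub-relation of r and F' is_a* F; a lacks-type differentia is satisfied
    by an inherited negative fact on the same base relation whose filler is
    F or a superclass of F (lacking the broader kind entails lacking the
    narrower); a develops_from differentia is matched against the entailed
    develops_from closure.
R4  definition decomposition (performed by normalization: genus -> edge,
    differentia -> facts).
R5  develops_from closure: transitivity, plus the is_a interplay on the
    descendant-cell side and the origin-cell side (each toggleable).

All rules are monotone over finite sets, so the fixpoint exists and the
closure is order-independent; the worklist is processed in sorted CURIE
order so the recorded provenance is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .errors import CycleError, NotEntailedError, UnknownEntityError
from .expand import NormalizedAxiomSet, ReasonerConfig
from .model import CURIE, DEVELOPS_FROM, IS_A, RelationId

Edge = tuple[CURIE, CURIE]
EdgeKey = tuple[str, CURIE, CURIE]  # (relation, sub, sup)
Premise = tuple
Derivation = tuple[str, tuple[Premise, ...]]  # (rule id, premises)


@dataclass
class InferredClosure:
    """Saturated entailments with per-edge provenance.

    ``entailed_isa`` is transitively closed, contains every asserted edge,
    and excludes reflexive pairs; ``direct_isa`` is its transitive
    reduction (the curator-facing "direct parents" view).
    """

    entailed_isa: set[Edge]
    entailed_develops_from: set[Edge]
    direct_isa: set[Edge]
    unsatisfiable: set[CURIE]
    provenance: dict[EdgeKey, Derivation]
    axioms: NormalizedAxiomSet
    known_ids: frozenset[CURIE]

    # -- queries --------------------------------------------------------

    def _check_known(self, *ids: CURIE) -> None:
        for i in ids:
            if i not in self.known_ids:
                raise UnknownEntityError(i)

    def is_entailed(self, sub: CURIE, sup: CURIE, relation: RelationId = IS_A) -> bool:
        """Membership test; reflexive is_a pairs are by convention False."""
        self._check_known(sub, sup)
        if relation == IS_A:
            return (sub, sup) in self.entailed_isa
        if relation == DEVELOPS_FROM:
            return (sub, sup) in self.entailed_develops_from
        raise ValueError(f"closure holds is_a and develops_from, not {relation}")

    def inferred_direct_parents(self, curie: CURIE) -> set[CURIE]:
        self._check_known(curie)
        return {b for a, b in self.direct_isa if a == curie}

    def inferred_direct_children(self, curie: CURIE) -> set[CURIE]:
        self._check_known(curie)
        return {a for a, b in self.direct_isa if b == curie}

    # -- explanation ----------------------------------------------------

    def explain(self, sub: CURIE, sup: CURIE,
                relation: RelationId = IS_A) -> list[dict]:
        """A premise chain from asserted axioms to the entailment, ordered
        so every step's edge premises were concluded by an earlier step.
        ``replay`` re-derives the edge from the chain."""
        rel = IS_A if relation == IS_A else DEVELOPS_FROM
        if not self.is_entailed(sub, sup, rel):
            raise NotEntailedError(f"{sub} {rel} {sup} is not entailed")
        steps: list[dict] = []
        seen: set[EdgeKey] = set()

        def visit(key: EdgeKey) -> None:
            if key in seen:
                return
            seen.add(key)
            rule, premises = self.provenance[key]
            for p in premises:
                if p[0] == "edge":
                    visit((p[1], p[2], p[3]))
            steps.append({"rule": rule, "conclusion": key, "premises": list(premises)})

        visit((rel, sub, sup))
        return steps


# ---------------------------------------------------------------------------


class _Saturation:
    """Event-driven saturation: each newly derived edge is joined against
    the adjacency maps, so R1/R5 propagation is incremental rather than a
    repeated pairwise scan."""

    def __init__(self, axioms: NormalizedAxiomSet):
        self.ax = axioms
        self.cfg: ReasonerConfig = axioms.config
        self.isa: dict[Edge, Derivation] = {}
        self.df: dict[Edge, Derivation] = {}
        self.classes = axioms.classes()
        from collections import defaultdict, deque

        self.isa_out = defaultdict(set)  # a -> {b: a is_a b}
        self.isa_in = defaultdict(set)   # b -> {a: a is_a b}
        self.df_out = defaultdict(set)
        self.df_in = defaultdict(set)
        self.queue = deque()

    # -- primitive additions -------------------------------------------

    def add_isa(self, a: CURIE, b: CURIE, rule: str, premises: tuple) -> bool:
        if a == b or (a, b) in self.isa:
            return False
        self.isa[(a, b)] = (rule, premises)
        self.isa_out[a].add(b)
        self.isa_in[b].add(a)
        self.queue.append((IS_A, a, b))
        return True

    def add_df(self, a: CURIE, b: CURIE, rule: str, premises: tuple) -> bool:
        if (a, b) in self.df:
            return False
        self.df[(a, b)] = (rule, premises)
        self.df_out[a].add(b)
        self.df_in[b].add(a)
        self.queue.append((DEVELOPS_FROM, a, b))
        return True

    def sub_refl(self, a: CURIE, b: CURIE) -> bool:
        return a == b or (a, b) in self.isa

    def supers(self, a: CURIE) -> list[CURIE]:
        return sorted(self.isa_out.get(a, ()))

    # -- rules ----------------------------------------------------------

    def seed(self) -> None:
        for a, b in sorted(self.ax.subsumptions):
            self.add_isa(a, b, "asserted", (("axiom_isa", a, b),))
        for x in sorted(self.ax.positive_facts):
            for rel, f in sorted(self.ax.positive_facts[x]):
                if rel == DEVELOPS_FROM:
                    self.add_df(x, f, "asserted_df",
                                (("axiom_fact", x, rel, f, "positive"),))

    def propagate(self) -> None:
        """Drain the worklist, applying R1 and R5 joins to each new edge."""
        ie = lambda a, b: ("edge", IS_A, a, b)
        de = lambda a, b: ("edge", DEVELOPS_FROM, a, b)
        while self.queue:
            rel, a, b = self.queue.popleft()
            if rel == IS_A:
                for c in sorted(self.isa_out[b]):
                    self.add_isa(a, c, "isa_transitivity", (ie(a, b), ie(b, c)))
                for x in sorted(self.isa_in[a]):
                    self.add_isa(x, b, "isa_transitivity", (ie(x, a), ie(a, b)))
                if self.cfg.df_source_interplay:
                    for y in sorted(self.df_out[b]):
                        self.add_df(a, y, "df_isa_source", (ie(a, b), de(b, y)))
                if self.cfg.df_target_interplay:
                    for x in sorted(self.df_in[a]):
                        self.add_df(x, b, "df_isa_target", (de(x, a), ie(a, b)))
            else:
                for z in sorted(self.df_out[b]):
                    self.add_df(a, z, "df_transitivity", (de(a, b), de(b, z)))
                for w in sorted(self.df_in[a]):
                    self.add_df(w, b, "df_transitivity", (de(w, a), de(a, b)))
                if self.cfg.df_source_interplay:
                    for x in sorted(self.isa_in[a]):
                        self.add_df(x, b, "df_isa_source", (ie(x, a), de(a, b)))
                if self.cfg.df_target_interplay:
                    for z in sorted(self.isa_out[b]):
                        self.add_df(a, z, "df_isa_target", (de(a, b), ie(b, z)))

    def _match_positive(self, x: CURIE, rel: RelationId,
                        filler: CURIE) -> tuple | None:
        subrels = self.cfg.sub_relations(rel)
        for owner in [x] + self.supers(x):
            for r2, f2 in sorted(self.ax.positive_facts.get(owner, ())):
                if r2 in subrels and (f2 == filler or (f2, filler) in self.isa):
                    prem = [("axiom_fact", owner, r2, f2, "positive")]
                    if owner != x:
                        prem.append(("edge", IS_A, x, owner))
                    if f2 != filler:
                        prem.append(("edge", IS_A, f2, filler))
                    return tuple(prem)
        return None

    def _match_negative(self, x: CURIE, base: RelationId,
                        filler: CURIE) -> tuple | None:
        # lacking the broader class entails lacking the narrower one
        for owner in [x] + self.supers(x):
            for r2, f2 in sorted(self.ax.negative_facts.get(owner, ())):
                if r2 == base and (f2 == filler or (filler, f2) in self.isa):
                    prem = [("axiom_fact", owner, r2, f2, "negative")]
                    if owner != x:
                        prem.append(("edge", IS_A, x, owner))
                    if f2 != filler:
                        prem.append(("edge", IS_A, filler, f2))
                    return tuple(prem)
        return None

    def _match_df(self, x: CURIE, filler: CURIE) -> tuple | None:
        for (x2, f2) in sorted(self.df):
            if x2 == x and (f2 == filler or (f2, filler) in self.isa):
                prem = [("edge", DEVELOPS_FROM, x, f2)]
                if f2 != filler:
                    prem.append(("edge", IS_A, f2, filler))
                return tuple(prem)
        return None

    def apply_definitions(self) -> bool:
        from .model import base_relation, is_negative

        changed = False
        for c in sorted(self.ax.equivalences):
            defn = self.ax.equivalences[c]
            for x in self.classes:
                if x == c or (x, c) in self.isa:
                    continue
                if not self.sub_refl(x, defn.genus):
                    continue
                premises: list[Premise] = [("definition", c)]
                premises.append(("refl", x) if x == defn.genus
                                else ("edge", IS_A, x, defn.genus))
                ok = True
                for d in sorted(defn.differentia, key=lambda d: (d.relation, d.filler)):
                    if d.relation == DEVELOPS_FROM:
                        m = self._match_df(x, d.filler)
                    elif is_negative(d.relation):
                        m = self._match_negative(x, base_relation(d.relation), d.filler)
                    else:
                        m = self._match_positive(x, d.relation, d.filler)
                    if m is None:
                        ok = False
                        break
                    premises.extend(m)
                if ok:
                    changed |= self.add_isa(x, c, "definition_intro", tuple(premises))
        return changed

    def run(self) -> None:
        self.seed()
        self.propagate()
        while self.apply_definitions():
            self.propagate()


def _transitive_reduction(entailed: set[Edge], nodes) -> set[Edge]:
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(entailed)
    if nx.is_directed_acyclic_graph(g):
        return set(nx.transitive_reduction(g).edges())
    # inferred equivalence groups form cycles; reduce over the condensation
    # and keep one cycle per group so the closure is regenerated
    cond = nx.condensation(g)
    red = nx.transitive_reduction(cond)
    members = {n: sorted(cond.nodes[n]["members"]) for n in cond.nodes}
    direct: set[Edge] = set()
    for u, v in red.edges():
        for a in members[u]:
            for b in members[v]:
                direct.add((a, b))
    for n, ms in members.items():
        if len(ms) > 1:
            for a, b in zip(ms, ms[1:] + ms[:1]):
                direct.add((a, b))
    return direct


def classify(axioms: NormalizedAxiomSet) -> InferredClosure:
    """Saturate to a fixpoint and return the closure with provenance.

    Refuses to classify if the asserted subsumption graph is cyclic.
    """
    g = nx.DiGraph(sorted(axioms.subsumptions))
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        pass
    else:
        raise CycleError([a for a, _ in cycle], IS_A)

    sat = _Saturation(axioms)
    sat.run()
    entailed_isa = set(sat.isa)
    entailed_df = set(sat.df)

    unsat: set[CURIE] = set()
    for pair in axioms.disjointness:
        a, b = sorted(pair)
        for x in sat.classes:
            if sat.sub_refl(x, a) and sat.sub_refl(x, b):
                unsat.add(x)

    provenance: dict[EdgeKey, Derivation] = {}
    for (x, y), deriv in sat.isa.items():
        provenance[(IS_A, x, y)] = deriv
    for (x, y), deriv in sat.df.items():
        provenance[(DEVELOPS_FROM, x, y)] = deriv

    return InferredClosure(
        entailed_isa=entailed_isa,
        entailed_develops_from=entailed_df,
        direct_isa=_transitive_reduction(entailed_isa, sat.classes),
        unsatisfiable=unsat,
        provenance=provenance,
        axioms=axioms,
        known_ids=frozenset(sat.classes),
    )


# ---------------------------------------------------------------------------
# replay of explanation chains


def _facts_from(premises: list) -> dict[tuple, bool]:
    return {p: True for p in premises if p and p[0] == "axiom_fact"}


def replay(axioms: NormalizedAxiomSet, steps: list[dict], target: EdgeKey) -> bool:
    """Re-derive ``target`` by applying each step after checking it locally.

    Every premise must be an asserted axiom of ``axioms`` or the conclusion
    of an earlier step; every rule application must actually license its
    conclusion.  Returns True iff the chain is valid and ends by
    establishing the target edge.
    """
    from .model import base_relation, is_negative

    established: set[EdgeKey] = set()

    def axiom_ok(p) -> bool:
        kind = p[0]
        if kind == "axiom_isa":
            return (p[1], p[2]) in axioms.subsumptions
        if kind == "axiom_fact":
            _, cls, rel, filler, pol = p
            fmap = axioms.negative_facts if pol == "negative" else axioms.positive_facts
            return (rel, filler) in fmap.get(cls, ())
        if kind == "definition":
            return p[1] in axioms.equivalences
        if kind == "refl":
            return True
        if kind == "edge":
            return (p[1], p[2], p[3]) in established
        return False

    def edges(premises, rel):
        return [(p[2], p[3]) for p in premises if p[0] == "edge" and p[1] == rel]

    for step in steps:
        rule, concl, premises = step["rule"], step["conclusion"], step["premises"]
        if not all(axiom_ok(tuple(p)) for p in premises):
            return False
        rel, a, b = concl
        isa_edges = edges(premises, IS_A)
        df_edges = edges(premises, DEVELOPS_FROM)
        ok = False
        if rule == "asserted":
            ok = rel == IS_A and ("axiom_isa", a, b) in [tuple(p) for p in premises]
        elif rule == "asserted_df":
            ok = rel == DEVELOPS_FROM and any(
                p[0] == "axiom_fact" and p[1] == a and p[2] == DEVELOPS_FROM and p[3] == b
                for p in map(tuple, premises))
        elif rule == "isa_transitivity":
            ok = rel == IS_A and any(
                (a, m) in isa_edges and (m, b) in isa_edges
                for m in {e[1] for e in isa_edges})
        elif rule == "df_transitivity":
            ok = rel == DEVELOPS_FROM and any(
                (a, m) in df_edges and (m, b) in df_edges
                for m in {e[1] for e in df_edges})
        elif rule == "df_isa_source":
            ok = rel == DEVELOPS_FROM and any(
                (a, m) in isa_edges and (m, b) in df_edges
                for m in {e[1] for e in isa_edges})
        elif rule == "df_isa_target":
            ok = rel == DEVELOPS_FROM and any(
                (a, m) in df_edges and (m, b) in isa_edges
                for m in {e[1] for e in df_edges})
        elif rule == "definition_intro":
            ok = _check_definition_step(axioms, a, b, premises, established)
        if not ok:
            return False
        established.add((rel, a, b))
    return target in established


def _check_definition_step(axioms, x, c, premises, established) -> bool:
    from .model import base_relation, is_negative

    defn = axioms.equivalences.get(c)
    if defn is None:
        return False
    premises = [tuple(p) for p in premises]
    isa = {(p[2], p[3]) for p in premises
           if p[0] == "edge" and p[1] == IS_A}
    df = {(p[2], p[3]) for p in premises
          if p[0] == "edge" and p[1] == DEVELOPS_FROM}
    facts = [p for p in premises if p[0] == "axiom_fact"]

    def sub_refl(a, b):
        return a == b or (a, b) in isa

    if not sub_refl(x, defn.genus):
        return False
    cfg = axioms.config
    for d in defn.differentia:
        satisfied = False
        if d.relation == DEVELOPS_FROM:
            satisfied = any((x, f) in df and sub_refl(f, d.filler)
                            for f in {e[1] for e in df if e[0] == x})
        elif is_negative(d.relation):
            base = base_relation(d.relation)
            for _, owner, rel, filler, pol in facts:
                if pol == "negative" and rel == base and sub_refl(x, owner) \
                        and sub_refl(d.filler, filler):
                    satisfied = True
                    break
        else:
            subrels = cfg.sub_relations(d.relation)
            for _, owner, rel, filler, pol in facts:
                if pol == "positive" and rel in subrels and sub_refl(x, owner) \
                        and sub_refl(filler, d.filler):
                    satisfied = True
                    break
        if not satisfied:
            return False
    return True
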