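"""Deliberately naive entailment engine used as ground truth in tests.

Every rule is re-stated here from first principles and applied by
exhaustive enumeration over all class/axiom tuples, round after round,
until nothing changes.  No worklists, no adjacency indexes, no provenance,
and no code shared with :mod:`obolog.reasoner` beyond the axiom container
— that independence is the point.  Cubic behaviour is acceptable: the size
guard rejects inputs above ~200 classes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .expand import NormalizedAxiomSet
from .model import CURIE, DEVELOPS_FROM, base_relation, is_negative

Edge = tuple[CURIE, CURIE]

SIZE_GUARD = 200


@dataclass
class OracleClosure:
    """Same observable content as the reasoner's closure, sans provenance."""

    entailed_isa: frozenset[Edge]
    entailed_develops_from: frozenset[Edge]
    unsatisfiable: frozenset[CURIE]

    def sorted_isa(self) -> list[Edge]:
        return sorted(self.entailed_isa)

    def sorted_develops_from(self) -> list[Edge]:
        return sorted(self.entailed_develops_from)


def naive_closure(axioms: NormalizedAxiomSet) -> OracleClosure:
    classes = axioms.classes()
    if len(classes) > SIZE_GUARD:
        raise ValueError(
            f"oracle is for small instances only ({len(classes)} > {SIZE_GUARD} classes)")
    cfg = axioms.config

    isa: set[Edge] = {(a, b) for (a, b) in axioms.subsumptions if a != b}
    df: set[Edge] = set()
    for cls, facts in axioms.positive_facts.items():
        for rel, filler in facts:
            if rel == DEVELOPS_FROM:
                df.add((cls, filler))

    def sub_eq(a: CURIE, b: CURIE) -> bool:
        return a == b or (a, b) in isa

    def all_facts(x: CURIE, fact_map) -> set:
        # inherited = own plus everything on any is_a ancestor
        out = set(fact_map.get(x, ()))
        for y in classes:
            if (x, y) in isa:
                out |= fact_map.get(y, set())
        return out

    inherited_pos: dict[CURIE, set] = {}
    inherited_neg: dict[CURIE, set] = {}

    def refresh_inherited() -> None:
        for x in classes:
            inherited_pos[x] = all_facts(x, axioms.positive_facts)
            inherited_neg[x] = all_facts(x, axioms.negative_facts)

    def satisfies(x: CURIE, c: CURIE) -> bool:
        defn = axioms.equivalences[c]
        if x == c or not sub_eq(x, defn.genus):
            return False
        pos = inherited_pos[x]
        neg = inherited_neg[x]
        for d in defn.differentia:
            if d.relation == DEVELOPS_FROM:
                if not any((x, f) in df and sub_eq(f, d.filler) for f in classes):
                    return False
            elif is_negative(d.relation):
                b = base_relation(d.relation)
                if not any(r == b and sub_eq(d.filler, f) for r, f in neg):
                    return False
            else:
                subrels = cfg.sub_relations(d.relation)
                if not any(r in subrels and sub_eq(f, d.filler) for r, f in pos):
                    return False
        return True

    changed = True
    while changed:
        changed = False
        # is_a transitivity
        for a in classes:
            for b in classes:
                for c in classes:
                    if (a, b) in isa and (b, c) in isa and a != c and (a, c) not in isa:
                        isa.add((a, c))
                        changed = True
        # develops_from: transitivity and is_a interplay
        for x in classes:
            for y in classes:
                for z in classes:
                    if (x, y) in df and (y, z) in df and (x, z) not in df:
                        df.add((x, z))
                        changed = True
                    if cfg.df_source_interplay and (x, y) in isa and (y, z) in df \
                            and (x, z) not in df:
                        df.add((x, z))
                        changed = True
                    if cfg.df_target_interplay and (x, y) in df and (y, z) in isa \
                            and (x, z) not in df:
                        df.add((x, z))
                        changed = True
        # definition introduction
        refresh_inherited()
        for c in axioms.equivalences:
            for x in classes:
                if (x, c) not in isa and x != c and satisfies(x, c):
                    isa.add((x, c))
                    changed = True

    unsat = set()
    for pair in axioms.disjointness:
        a, b = sorted(pair)
        for x in classes:
            if sub_eq(x, a) and sub_eq(x, b):
                unsat.add(x)

    return OracleClosure(frozenset(isa), frozenset(df), frozenset(unsat))
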