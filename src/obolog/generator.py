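"""Seeded random ontology generator with planted ground truth.

The generator emulates the shape of a curated cell-type ontology: a
single-inheritance class tree, a parallel mini process ontology supplying
differentia fillers, cross-product definitions on a random subset of
classes, and a develops_from chain.  Each definition carries a filler
unique to its class, so no subsumption, violation or conflict arises by
accident — everything the reasoner may add beyond the assertions is
*planted*, recorded in the returned :class:`GroundTruth`, and re-verified
with the naive oracle before the ontology is handed out.

What it does not emulate: realistic marker panels, multiple-axis
definitions mixing ontologies, or dangling imports; its purpose is
differential testing of the reasoner and diagnostics, not biological
plausibility.

Identical parameters and seed yield byte-identical OBO text.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .errors import InfeasibleParamsError
from .expand import normalize_ontology
from .fixtures import GroundTruth
from .model import ClassNode, Definition, Differentia, OntologyGraph, RelationDef
from .oracle import naive_closure


@dataclass(frozen=True)
class GeneratorParams:
    n_classes: int = 40
    max_depth: int = 5
    p_defined: float = 0.6
    #: weights over 1..4 differentia per definition
    n_differentia_weights: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)
    n_planted_subsumptions: int = 0
    n_planted_disjoint_violations: int = 0
    n_planted_redundant_edges: int = 0
    n_planted_polarity_conflicts: int = 0
    plant_cycle: bool = False
    df_chain_length: int = 0
    seed: int = 0


def _cl(i: int) -> str:
    return f"CL:{8000000 + i:07d}"


def _go(i: int) -> str:
    return f"GO:{9000000 + i:07d}"


def generate_random_ontology(params: GeneratorParams) -> tuple[OntologyGraph, GroundTruth]:
    """Build a random ontology; planted structures are recorded in the
    returned GroundTruth and oracle-verified (unless a cycle is planted,
    which makes the ontology unclassifiable by design)."""
    p = params
    n_planted = (p.n_planted_subsumptions + p.n_planted_disjoint_violations
                 + p.n_planted_redundant_edges + p.n_planted_polarity_conflicts)
    if p.n_classes < 0 or p.p_defined < 0 or p.p_defined > 1:
        raise InfeasibleParamsError("negative sizes or probability out of [0, 1]")
    # every plant consumes fresh leaf classes; require headroom
    if p.n_classes and p.n_classes < 3 + 2 * n_planted + p.df_chain_length:
        raise InfeasibleParamsError(
            f"{p.n_classes} classes cannot host {n_planted} planted structures "
            f"and a develops_from chain of {p.df_chain_length}")
    rng = random.Random(p.seed)

    onto = OntologyGraph(header={
        "format-version": ["1.2"],
        "default-namespace": ["cell"],
        "remark": [f"obolog random ontology (seed={p.seed})"],
    })
    truth = GroundTruth()
    if p.n_classes == 0:
        return onto, truth
    onto.typedefs["develops_from"] = RelationDef(
        "develops_from", name="develops_from", is_transitive=True)

    # process mini-ontology: shallow tree of filler classes
    go_root = _go(0)
    onto.add(ClassNode(id=go_root, name="process 0", namespace="biological_process"))
    go_ids = [go_root]

    def new_filler(parent: str | None = None) -> str:
        gid = _go(len(go_ids))
        onto.add(ClassNode(
            id=gid, name=f"process {len(go_ids)}", namespace="biological_process",
            is_a_parents=[parent if parent is not None
                          else rng.choice(go_ids[: max(1, len(go_ids) // 3)])]))
        go_ids.append(gid)
        return gid

    # class tree (asserted single inheritance)
    depth: dict[str, int] = {}
    cl_ids: list[str] = []
    unique_filler: dict[str, str] = {}

    def new_class(parent: str | None, define: bool) -> str:
        cid = _cl(len(cl_ids))
        node = ClassNode(id=cid, name=f"cell type {len(cl_ids)}", namespace="cell")
        if parent is not None:
            node.is_a_parents.append(parent)
            if define:
                f = new_filler()
                unique_filler[cid] = f
                diffs = [Differentia("capable_of", f)]
                extra = rng.choices(range(4), weights=p.n_differentia_weights)[0]
                for _ in range(extra):
                    diffs.append(Differentia("participates_in", new_filler()))
                node.definition = Definition(parent, tuple(dict.fromkeys(diffs)))
        onto.add(node)
        depth[cid] = 0 if parent is None else depth[parent] + 1
        cl_ids.append(cid)
        return cid

    root = new_class(None, define=False)
    n_tree = p.n_classes - 2 * n_planted - p.df_chain_length - (3 if p.plant_cycle else 0)
    for _ in range(max(0, n_tree - 1)):
        candidates = [c for c in cl_ids if depth[c] < p.max_depth]
        parent = rng.choice(candidates)
        new_class(parent, define=rng.random() < p.p_defined)

    defined = [c for c in cl_ids if onto.classes[c].definition is not None]

    def pick_defined(pool: set[str]) -> str:
        avail = [c for c in defined if c not in pool]
        if not avail:
            raise InfeasibleParamsError("not enough defined classes to plant into")
        c = rng.choice(avail)
        pool.add(c)
        return c

    used: set[str] = set()

    # planted inferred subsumptions: a fresh sibling whose facts satisfy an
    # existing definition through a narrower filler
    for _ in range(p.n_planted_subsumptions):
        c = pick_defined(used)
        genus = onto.classes[c].definition.genus
        x = new_class(genus, define=False)
        used.add(x)
        for d in onto.classes[c].definition.differentia:
            filler = d.filler
            if filler == unique_filler.get(c) and rng.random() < 0.5:
                filler = new_filler(parent=d.filler)  # exercise filler subsumption
            onto.classes[x].relationships.append((d.relation, filler))
        truth.expected_entailments.add((x, c, "is_a"))

    # planted disjointness violations
    for _ in range(p.n_planted_disjoint_violations):
        bdef = pick_defined(used)
        genus = onto.classes[bdef].definition.genus
        a = new_class(genus, define=False)
        onto.classes[a].disjoint_from.append(bdef)
        x = new_class(a, define=False)
        used.update((a, x))
        for d in onto.classes[bdef].definition.differentia:
            onto.classes[x].relationships.append((d.relation, d.filler))
        truth.expected_entailments.add((x, bdef, "is_a"))
        truth.expected_findings.append(("disjointness_violation", (x,)))

    # planted redundant is_a shortcuts across an existing 2-chain
    grandchildren = [c for c in cl_ids
                     if c not in used and depth[c] >= 2
                     and onto.classes[c].definition is None]
    rng.shuffle(grandchildren)
    if p.n_planted_redundant_edges > len(grandchildren):
        raise InfeasibleParamsError("not enough deep classes for redundant edges")
    for i in range(p.n_planted_redundant_edges):
        a = grandchildren[i]
        b = onto.classes[a].is_a_parents[0]
        c = onto.classes[b].is_a_parents[0]
        onto.classes[a].is_a_parents.append(c)
        truth.expected_findings.append(("redundant_edge", (a, c)))

    # planted polarity conflicts: ancestor has_part F, fresh leaf lacks_part F
    for _ in range(p.n_planted_polarity_conflicts):
        anchor = rng.choice([c for c in cl_ids if c not in used])
        used.add(anchor)
        g = new_filler()
        onto.classes[anchor].relationships.append(("has_part", g))
        leaf = new_class(anchor, define=False)
        onto.classes[leaf].relationships.append(("lacks_part", g))
        used.add(leaf)
        truth.expected_findings.append(("polarity_conflict", (leaf,)))

    # develops_from chain over fresh leaves
    chain = [new_class(root, define=False) for _ in range(p.df_chain_length)]
    for a, b in zip(chain, chain[1:]):
        onto.classes[a].relationships.append(("develops_from", b))
    if len(chain) >= 3:
        truth.expected_entailments.add((chain[0], chain[-1], "develops_from"))

    if p.plant_cycle:
        trio = [new_class(None, define=False) for _ in range(3)]
        for a, b in zip(trio, trio[1:] + trio[:1]):
            onto.classes[a].is_a_parents.append(b)
        truth.planted_cycles.append(trio)
        return onto, truth  # unclassifiable by construction; skip verification

    closure = naive_closure(normalize_ontology(onto))
    for sub, sup, rel in truth.expected_entailments:
        entailed = closure.entailed_isa if rel == "is_a" else closure.entailed_develops_from
        if (sub, sup) not in entailed:
            raise AssertionError(
                f"generator bookkeeping broken: {sub} {rel} {sup} not entailed")
    return onto, truth
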