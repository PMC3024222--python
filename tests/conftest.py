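import pytest

from obolog.fixtures import all_fixture_names, build_paper_fixture
from obolog.model import ClassNode, Definition, Differentia, OntologyGraph, RelationDef


@pytest.fixture(params=all_fixture_names())
def scenario(request):
    """Each packaged worked scenario with its ground truth."""
    onto, truth = build_paper_fixture(request.param)
    return request.param, onto, truth


def make_onto(spec: dict, disjoint=(), header=None) -> OntologyGraph:
    """Tiny ontology builder for hand-rolled test graphs.

    ``spec`` maps a CURIE to a dict with optional keys ``parent``, ``genus``,
    ``diff`` (list of (relation, filler)), ``rels``, ``name``, ``ns``.
    """
    onto = OntologyGraph(header=header or {"format-version": ["1.2"]})
    onto.typedefs["develops_from"] = RelationDef(
        "develops_from", is_transitive=True)
    for cid, cfg in spec.items():
        node = ClassNode(id=cid, name=cfg.get("name", cid),
                         namespace=cfg.get("ns", "cell"))
        if cfg.get("parent"):
            node.is_a_parents.append(cfg["parent"])
        if cfg.get("diff"):
            node.definition = Definition(
                cfg.get("genus", cfg.get("parent")),
                tuple(Differentia(r, f) for r, f in cfg["diff"]))
        node.relationships.extend(cfg.get("rels", []))
        onto.add(node)
    for a, b in disjoint:
        onto.classes[a].disjoint_from.append(b)
    return onto
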