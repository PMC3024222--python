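"""Reading and writing the OBO 1.2 flat-file dialect.

The dialect is the one used by hematopoietic Cell Ontology curation:
``[Term]`` stanzas carrying ``is_a``, ``relationship``, ``disjoint_from``
and cross-product ``intersection_of`` lines (one bare CURIE for the genus,
``relation CURIE`` lines for the differentia), and ``[Typedef]`` stanzas
declaring relations.  Unrecognized tag lines are preserved verbatim and
round-tripped.  Output is deterministic: stanzas sorted by CURIE, tags in
canonical order, so two writes of the same model are byte-identical.

Also here: MIREOT-style ``is_a``-closure subsetting of external ontologies,
merging of imports, and file-level statistics.
"""

from __future__ import annotations

import copy
import io as _io
import re
from collections import Counter
from dataclasses import dataclass, field

from .errors import MalformedDefinitionError, MergeConflictError, OboParseError, UnknownEntityError
from .model import (
    CURIE,
    IS_A,
    ClassNode,
    Definition,
    Differentia,
    OntologyGraph,
    RelationDef,
    canonical_curie,
)

_CURIE_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*:\S+$")


def _strip_comment(value: str) -> str:
    # trailing " ! label" comments; quoted tags (def/synonym) never reach here
    idx = value.find(" ! ")
    if idx >= 0:
        return value[:idx].rstrip()
    if value.endswith(" !"):
        return value[:-2].rstrip()
    return value


def _parse_tag_line(line: str, lineno: int) -> tuple[str, str]:
    tag, sep, value = line.partition(":")
    if not sep:
        raise OboParseError(f"expected 'tag: value', got {line!r}", lineno)
    return tag.strip(), value.strip()


RECOGNIZED_TERM_TAGS = {
    "id", "name", "namespace", "is_a", "relationship", "intersection_of",
    "disjoint_from", "synonym", "def",
}
RECOGNIZED_TYPEDEF_TAGS = {"id", "name", "is_transitive", "is_a"}


def parse_obo(stream, mode: str = "lenient") -> OntologyGraph:
    """Parse OBO 1.2 text into an :class:`OntologyGraph`.

    ``stream`` may be a string or a text file object.  In ``lenient`` mode
    (default) unresolvable references are recorded and reported through
    :meth:`OntologyGraph.dangling_references`; ``strict`` mode raises.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be strict or lenient, not {mode!r}")
    text = stream.read() if hasattr(stream, "read") else stream
    lines = text.replace("\r\n", "\n").replace("\r", "\n").split("\n")

    onto = OntologyGraph()
    stanza_type: str | None = None  # None = header
    stanza: list[tuple[str, str, int]] = []

    def flush():
        if stanza_type == "Term":
            _add_term(onto, stanza)
        elif stanza_type == "Typedef":
            _add_typedef(onto, stanza)
        elif stanza_type is not None:
            pass  # unknown stanza types (e.g. [Instance]) are skipped
        stanza.clear()

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            flush()
            stanza_type = line[1:-1]
            continue
        tag, value = _parse_tag_line(line, lineno)
        if stanza_type is None:
            onto.header.setdefault(tag, []).append(value)
        else:
            stanza.append((tag, value, lineno))
    flush()

    if mode == "strict":
        problems = sorted(onto.dangling_references() | onto.undeclared_relations())
        if problems:
            raise UnknownEntityError(
                "unresolvable references in strict mode: " + ", ".join(problems)
            )
    return onto


def _take_curie(value: str, lineno: int) -> CURIE:
    value = _strip_comment(value)
    if not _CURIE_RE.match(value):
        raise OboParseError(f"expected a CURIE, got {value!r}", lineno)
    return canonical_curie(value)


def _add_term(onto: OntologyGraph, stanza: list[tuple[str, str, int]]) -> None:
    node = ClassNode(id="")
    genus: list[CURIE] = []
    differentia: list[Differentia] = []
    n_intersection = 0
    first_line = stanza[0][2] if stanza else 0
    for tag, value, lineno in stanza:
        if tag == "id":
            node.id = _take_curie(value, lineno)
        elif tag == "name":
            node.name = _strip_comment(value)
        elif tag == "namespace":
            node.namespace = _strip_comment(value)
        elif tag == "is_a":
            node.is_a_parents.append(_take_curie(value, lineno))
        elif tag == "relationship":
            parts = _strip_comment(value).split()
            if len(parts) != 2:
                raise OboParseError(f"expected 'relationship: REL CURIE', got {value!r}", lineno)
            node.relationships.append((parts[0], canonical_curie(parts[1])))
        elif tag == "intersection_of":
            n_intersection += 1
            parts = _strip_comment(value).split()
            if len(parts) == 1:
                genus.append(_take_curie(parts[0], lineno))
            elif len(parts) == 2:
                differentia.append(Differentia(parts[0], canonical_curie(parts[1])))
            else:
                raise OboParseError(f"bad intersection_of line {value!r}", lineno)
        elif tag == "disjoint_from":
            node.disjoint_from.append(_take_curie(value, lineno))
        elif tag == "synonym":
            node.synonyms.append(value)
        elif tag == "def":
            node.textual_def = value
        else:
            node.extra_tags.append((tag, value))
    if not node.id:
        raise OboParseError("[Term] stanza without an id", first_line)
    if n_intersection == 1:
        raise MalformedDefinitionError(
            f"{node.id}: a cross-product needs a genus and at least one "
            "differentia (single intersection_of line)", first_line)
    if n_intersection:
        if len(genus) != 1 or not differentia:
            raise MalformedDefinitionError(
                f"{node.id}: a cross-product needs exactly one genus and "
                f">=1 differentia (got {len(genus)} genus, "
                f"{len(differentia)} differentia)", first_line)
        node.definition = Definition(genus[0], tuple(differentia))
    if node.id in onto.classes:
        raise OboParseError(f"duplicate term id {node.id}", first_line)
    onto.classes[node.id] = node


def _add_typedef(onto: OntologyGraph, stanza: list[tuple[str, str, int]]) -> None:
    rid = None
    name = None
    transitive = False
    parents: list[str] = []
    extra: list[tuple[str, str]] = []
    first_line = stanza[0][2] if stanza else 0
    for tag, value, lineno in stanza:
        if tag == "id":
            rid = _strip_comment(value)
        elif tag == "name":
            name = _strip_comment(value)
        elif tag == "is_transitive":
            transitive = _strip_comment(value).lower() == "true"
        elif tag == "is_a":
            parents.append(_strip_comment(value))
        else:
            extra.append((tag, value))
    if rid is None:
        raise OboParseError("[Typedef] stanza without an id", first_line)
    if rid in onto.typedefs:
        raise OboParseError(f"duplicate typedef id {rid}", first_line)
    onto.typedefs[rid] = RelationDef(
        id=rid, name=name, is_transitive=transitive,
        parent_relations=parents, extra_tags=extra,
    )


# ---------------------------------------------------------------------------
# writing


def _comment_for(onto: OntologyGraph, curie: CURIE) -> str:
    node = onto.classes.get(curie)
    if node is not None and node.name:
        return f" ! {node.name}"
    return ""


def write_obo(onto: OntologyGraph) -> str:
    """Serialize deterministically; ``parse_obo(write_obo(x))`` reproduces
    ``x`` up to ordering of list-valued tags."""
    out = _io.StringIO()
    header = dict(onto.header)
    fv = header.pop("format-version", ["1.2"])
    for v in fv:
        out.write(f"format-version: {v}\n")
    for tag in sorted(header):
        for v in header[tag]:
            out.write(f"{tag}: {v}\n")

    for cid in sorted(onto.classes):
        node = onto.classes[cid]
        out.write(f"\n[Term]\nid: {node.id}\n")
        if node.name is not None:
            out.write(f"name: {node.name}\n")
        if node.namespace is not None:
            out.write(f"namespace: {node.namespace}\n")
        if node.textual_def is not None:
            out.write(f"def: {node.textual_def}\n")
        for syn in sorted(node.synonyms):
            out.write(f"synonym: {syn}\n")
        for p in sorted(node.is_a_parents):
            out.write(f"is_a: {p}{_comment_for(onto, p)}\n")
        if node.definition is not None:
            g = node.definition.genus
            out.write(f"intersection_of: {g}{_comment_for(onto, g)}\n")
            for d in sorted(node.definition.differentia,
                            key=lambda d: (d.relation, d.filler)):
                out.write(f"intersection_of: {d.relation} {d.filler}"
                          f"{_comment_for(onto, d.filler)}\n")
        for rel, target in sorted(node.relationships):
            out.write(f"relationship: {rel} {target}{_comment_for(onto, target)}\n")
        for dj in sorted(node.disjoint_from):
            out.write(f"disjoint_from: {dj}{_comment_for(onto, dj)}\n")
        for tag, value in node.extra_tags:
            out.write(f"{tag}: {value}\n")

    for rid in sorted(onto.typedefs):
        td = onto.typedefs[rid]
        out.write(f"\n[Typedef]\nid: {td.id}\n")
        if td.name is not None:
            out.write(f"name: {td.name}\n")
        for p in sorted(td.parent_relations):
            out.write(f"is_a: {p}\n")
        if td.is_transitive:
            out.write("is_transitive: true\n")
        for tag, value in td.extra_tags:
            out.write(f"{tag}: {value}\n")
    return out.getvalue()


def load(path, mode: str = "lenient") -> OntologyGraph:
    with open(path, encoding="utf-8") as fh:
        return parse_obo(fh, mode=mode)


def dump(onto: OntologyGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_obo(onto))


def same_content(a: OntologyGraph, b: OntologyGraph) -> bool:
    """Model equality up to ordering of list-valued tags."""
    if set(a.classes) != set(b.classes) or set(a.typedefs) != set(b.typedefs):
        return False
    if any(a.classes[c].content_key() != b.classes[c].content_key() for c in a.classes):
        return False
    for r in a.typedefs:
        ta, tb = a.typedefs[r], b.typedefs[r]
        if (ta.name, ta.is_transitive, sorted(ta.parent_relations), sorted(ta.extra_tags)) != \
           (tb.name, tb.is_transitive, sorted(tb.parent_relations), sorted(tb.extra_tags)):
            return False
    return {t: sorted(v) for t, v in a.header.items()} == \
           {t: sorted(v) for t, v in b.header.items()}


# ---------------------------------------------------------------------------
# subsetting, merging, statistics


def extract_isa_closure_subset(external: OntologyGraph, seeds: set[CURIE]) -> OntologyGraph:
    """MIREOT-style subset: the seed classes plus their full ``is_a``
    ancestry, keeping only ``is_a`` edges among retained classes.

    Relationships, definitions and disjointness axioms of the external
    ontology are not carried over; the subset serves purely as a filler
    hierarchy for definition matching.
    """
    for s in seeds:
        external.node(s)  # raises UnknownEntityError
    retained: set[CURIE] = set()
    for s in seeds:
        retained.add(s)
        retained.update(a for a in external.get_ancestors(s, IS_A) if a in external.classes)
    sub = OntologyGraph(header=copy.deepcopy(external.header))
    for cid in sorted(retained):
        node = external.classes[cid]
        sub.classes[cid] = ClassNode(
            id=cid, name=node.name, namespace=node.namespace,
            is_a_parents=[p for p in node.is_a_parents if p in retained],
            synonyms=list(node.synonyms), textual_def=node.textual_def,
        )
    return sub


def merge(main: OntologyGraph, imports: list[OntologyGraph]) -> OntologyGraph:
    """Union of classes and typedefs.  A shared id must carry identical
    content in every source, otherwise :class:`MergeConflictError`."""
    result = OntologyGraph(
        classes={c: copy.deepcopy(n) for c, n in main.classes.items()},
        typedefs={r: copy.deepcopy(t) for r, t in main.typedefs.items()},
        header=copy.deepcopy(main.header),
    )
    for imp in imports:
        for cid, node in imp.classes.items():
            if cid in result.classes:
                if result.classes[cid].content_key() != node.content_key():
                    raise MergeConflictError(f"conflicting content for {cid}")
            else:
                result.classes[cid] = copy.deepcopy(node)
        for rid, td in imp.typedefs.items():
            if rid in result.typedefs:
                existing = result.typedefs[rid]
                if (existing.is_transitive, sorted(existing.parent_relations)) != \
                   (td.is_transitive, sorted(td.parent_relations)):
                    raise MergeConflictError(f"conflicting typedef {rid}")
            else:
                result.typedefs[rid] = copy.deepcopy(td)
    return result


@dataclass
class StatsSummary:
    """File-level counts (terms, definitions, disjointness, relation usage)."""

    n_terms: int = 0
    n_with_definition: int = 0
    n_disjoint_from: int = 0
    n_by_relation: dict[str, int] = field(default_factory=dict)
    n_dangling: int = 0

    def to_tsv(self) -> str:
        rows = [("metric", "value"),
                ("n_terms", self.n_terms),
                ("n_with_definition", self.n_with_definition),
                ("n_disjoint_from", self.n_disjoint_from)]
        rows += [(f"n_differentia[{r}]", n) for r, n in sorted(self.n_by_relation.items())]
        rows.append(("n_dangling", self.n_dangling))
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def stats(onto: OntologyGraph) -> StatsSummary:
    by_rel: Counter = Counter()
    n_def = 0
    n_dj = 0
    for node in onto.classes.values():
        n_dj += len(node.disjoint_from)
        if node.definition is not None:
            n_def += 1
            by_rel.update(d.relation for d in node.definition.differentia)
    return StatsSummary(
        n_terms=len(onto.classes),
        n_with_definition=n_def,
        n_disjoint_from=n_dj,
        n_by_relation=dict(by_rel),
        n_dangling=len(onto.dangling_references()),
    )
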