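# obolog

Genus–differentia logical definitions for OBO cell-type ontologies:
parsing, macro expansion, structural saturation reasoning, and curation
diagnostics.

## What this is for

Cell-type ontologies are curated as single-inheritance `is_a` trees, but
cell biology is poly-hierarchical: the same cell type belongs to groupings
by surface phenotype, function and developmental origin at once.  The
curation strategy this package supports gives each class a *computable
definition* — a genus plus differentiating relation–filler conditions over
classes from other OBO ontologies:

    "CD4-positive, alpha-beta T cell"  ≡
        "mature alpha-beta T cell"  ⊓  has_plasma_membrane_part CD4

A reasoner then infers the full polyhierarchy from the definitions,
checks `disjoint_from` constraints, and flags curation slips.  `obolog`
implements that loop for curators and ontology engineers:

* **`obolog.io`** — OBO 1.2 parsing/writing (cross-product
  `intersection_of` stanzas, deterministic round-tripping), MIREOT-style
  `is_a`-closure subsetting of external ontologies, merging, statistics;
* **`obolog.expand`** — macro expansion of the shorthand relations
  (`lacks_plasma_membrane_part`, `has_completed`, …) into their structural
  forms, and normalization into reasoner-ready axioms;
* **`obolog.reasoner`** — saturation to a fixpoint: `is_a` transitivity,
  fact inheritance, definition introduction (with sub-relations and filler
  subsumption over merged external hierarchies), the transitive
  `develops_from` closure with `is_a` interplay, transitive reduction,
  and per-edge provenance whose explanation chains replay;
* **`obolog.diagnostics`** — disjointness violations, positive/negative
  polarity conflicts, redundant edges, duplicate relation pairs;
* **`obolog.fixtures` / `obolog.generator`** — packaged worked curation
  scenarios with ground truth, and a seeded random-ontology generator
  with planted structure;
* **`obolog.oracle`** — an independent brute-force entailment engine used
  for differential testing;
* a **CLI** (`obolog parse|stats|classify|validate|fixture|random`).

## Worked example

The classic inference scenario: "helper T cell" is defined as an effector
T cell capable of cytokine production and has no asserted children; four
effector subtypes defined by specific cytokine-production capabilities
classify under it because those processes sit below cytokine production
in the process ontology.

```python
from obolog import build_paper_fixture, normalize_ontology
from obolog.reasoner import classify

onto, _ = build_paper_fixture("helper_t_inference")
closure = classify(normalize_ontology(onto))

helper = "CL:0000912"
asserted = [c for c, n in onto.classes.items() if helper in n.is_a_parents]
print("asserted children:", len(asserted))
for child in sorted(closure.inferred_direct_children(helper)):
    print(" inferred child:", child, onto.classes[child].name)
```

prints

```
asserted children: 0
 inferred child: CL:0000545 T-helper 1 cell
 inferred child: CL:0000546 T-helper 2 cell
 inferred child: CL:0000899 T-helper 17 cell
 inferred child: CL:0900001 IL-17-secreting gamma-delta T cell
```

The asserted tree is single-inheritance; the inferred hierarchy is not —
the gamma-delta subtype now sits under both "gamma-delta T cell" and
"helper T cell", and `closure.explain(...)` produces the premise chain
(including the process-ontology edge `GO:0032620 is_a GO:0001816` that
drove the inference).

The same machinery powers QA from the shell:

```sh
obolog fixture tcr_disjoint_pre -o pre.obo
obolog validate pre.obo        # exit 1; reports the disjointness violation
```

which reports that "gamma-delta T cell" is inferred under "alpha-beta
T cell" (a too-general receptor-complex differentia) in violation of
their disjointness constraint.

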