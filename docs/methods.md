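# Methods

## The problem

Cell-type ontologies such as the hematopoietic branch of the Cell Ontology
are curated as single-inheritance `is_a` trees, but the biology is
poly-hierarchical: a cell type belongs simultaneously to groupings by
surface phenotype, by function, by developmental origin.  The curation
strategy this package supports resolves the tension by *computable
definitions*: each class C is defined by a genus G (its single asserted
parent) and a set of differentia D — relation–filler conditions over
classes from other OBO ontologies (Protein Ontology surface markers, GO
biological processes and cellular components, PATO qualities, UBERON
anatomy).  A definition is an equivalence

    C  ≡  G  ⊓  r₁ some F₁  ⊓ … ⊓  rₖ some Fₖ

and a reasoner then *infers* the full polyhierarchy, checks disjointness
constraints, and flags curation slips.  This package implements the whole
loop — OBO parsing, macro expansion, saturation reasoning, diagnostics —
for the specific relation vocabulary that cell-type curation uses.

## Relation vocabulary and macro expansion

OBO format has no negation, so curation uses shorthand relations.  The
expansion table (see `obolog/expand.py`) rewrites each shorthand into its
structural form:

| shorthand | expansion |
|---|---|
| `has_plasma_membrane_part` Y | `has_part some ('plasma membrane' and has_part some Y)` |
| `lacks_plasma_membrane_part` Y | `has_part exactly 0 ('plasma membrane' and has_part some Y)` |
| `lacks_part` Y | `has_part exactly 0 Y` |
| `capable_of` Y | `bearer_of some (realized_by only Y)` |
| `participates_in` Y | (no expansion) |
| `has_completed` Y | `transformation_of some (participates_in some Y)` |
| `has_not_completed` Y | `not (transformation_of some (participates_in some Y))` |

Consequences the code draws from the expanded forms:

* Each *lacks*-type relation is the exactly-zero counterpart of its
  positive base (`lacks_part` ↔ `has_part`,
  `lacks_plasma_membrane_part` ↔ `has_plasma_membrane_part`,
  `has_not_completed` ↔ `has_completed`).  Normalization stores negative
  facts keyed by the base relation.
* Because the membrane-part expansion nests a plain `has_part`, a
  `has_plasma_membrane_part P` fact clashes with `lacks_part P`.  The
  converse does **not** hold: `lacks_plasma_membrane_part P` is compatible
  with `has_part P` — the part may sit elsewhere than the membrane.
* The `capable_of` expansion is inert for classification (it introduces
  fresh relations nothing else mentions); a test asserts closures are
  identical with it expanded or atomic.
* `has_high/low_plasma_membrane_amount` have quantitative semantics this
  axiom language cannot express; they stay atomic.  By default each is
  taken to entail plain membrane-part *presence* for subsumption matching
  (configurable off via `ReasonerConfig.amount_entails_membrane_part`).

## Saturation rules

`classify` computes the least fixpoint of:

* **R1** `is_a` transitivity.
* **R2** fact inheritance down `is_a`.
* **R3** definition introduction: X ⊑ C when X ⊑* G and every differentium
  (r, F) is matched by an inherited fact.  Positive match: a fact (r′, F′)
  with r′ a sub-relation of r and F′ ⊑* F — the filler subsumption is what
  lets an external ontology's internal hierarchy (e.g. interleukin-17
  production under cytokine production) drive inferences in the cell
  ontology.  Negative match: a negative fact on the same base relation
  with filler F′ ⊒* F, since lacking the broader kind entails lacking the
  narrower.  `develops_from` differentia are matched against the entailed
  develops_from closure.
* **R4** definition decomposition (done during normalization: genus →
  subsumption, differentia → facts).
* **R5** `develops_from` closure: transitivity plus the `is_a` interplay
  on both sides (X ⊑ X′ ∧ X′ df Y ⇒ X df Y; X df Y ∧ Y ⊑ Y′ ⇒ X df Y′),
  each side separately toggleable because OBO practice varies.

All rules are monotone over finite sets, so the fixpoint exists, is
reached in finitely many steps, and is independent of application order.
The worklist is drained in sorted-CURIE order so the recorded provenance
(one derivation per edge: rule id plus premises) is reproducible run to
run.  Reflexive `is_a` pairs are excluded from the closure by convention.
Equivalence is used only in the introduction direction; equivalent named
classes are never merged.  `direct_isa` is the transitive reduction of the
entailed DAG (with a condensation fallback should inferred equivalences
create two-cycles).

Unsatisfiability is reported for classes entailed under both members of a
disjoint pair.  Polarity contradictions are surfaced by the diagnostics
battery rather than folded into unsatisfiability, which keeps the closure
a pure description of the subsumption/lineage structure.

### Sub-relation conventions

Two defaults, both configurable: `participates_in` counts as a
sub-relation of `capable_of` (all instances actively engaged in a process
certainly have the capability), and the amount relations count as
membrane-part presence (above).  Negative-polarity relations are never
transitive; the model layer rejects such a declaration outright.

## Diagnostics

* **Disjointness**: one finding per (class, disjoint pair); a finding is
  marked *cascaded* when a proper ancestor is unsatisfiable for the same
  pair, so curators can fix the root cause first.  All findings are still
  reported.
* **Polarity conflicts**: inherited positive vs inherited negative facts
  on the same base relation with positive filler ⊑* negative filler,
  after the structural augmentation described above.
* **Redundant edges**: an asserted `is_a`/`develops_from` edge is
  redundant iff the closure computed *without that single edge* still
  entails it.  In cross-product curation the definition's genus restates
  the asserted parent; the two are treated as one assertion, removed
  together — otherwise every defined class's parent link would be
  trivially "redundant" through its own genus, which is noise, not
  signal.  The same pairing applies to an asserted `develops_from`
  relationship duplicated as a `develops_from` differentium.  A property
  test asserts that deleting all redundant edges simultaneously leaves the
  closure unchanged.
* **Duplicate relation pairs**: two or more distinct relations asserted
  between one unordered class pair.

`validate` orders findings by (category, subjects) and reports an `is_a`
cycle as a finding instead of crashing; classification-dependent checks
are skipped in that case.

## Worked scenarios

The ten packaged fixtures reconstruct the canonical curation episodes
(helper-T-cell inference, granulocyte lineage closure, the
receptor-complex disjointness error and its repair, the regulatory-T-cell
collapse/redundancy and its repair, the innate-effector regrouping, the
tertiary-granule contradiction, the lineage-negative stem cell, the
nucleate erythrocyte).  Where the episode pins down an outcome — *four*
inferred helper-T children, *seven* intermediate cell types, *twelve*
lineage-negative markers, exactly one granule conflict — the fixture's
`GroundTruth` encodes it; the surrounding class structure is this
package's reconstruction of standard curation practice and is not itself
asserted as ground truth.  Real CURIEs are used where the episodes name
them (CL:0000912, GO:0042105/6, GO:0070820, PR:000001004, …), synthetic
`CL:09…`/`PR:09…` ids elsewhere.

Two reconstruction choices worth knowing about:

* `develops_from` differentia are matched against the *entailed*
  develops_from closure (the relation is transitive, so "develops from X"
  includes indirect origin).  In the repaired regulatory-T-cell fixture
  the two Treg definitions therefore stay separate through the extra
  neuropilin-1 marker on the natural Treg, not through a "direct
  development only" reading of the relation.
* The lineage-negative panel is fixed at 12 markers usable in both mouse
  and human; published panels range from 3 to 19 and the exact membership
  of a 12-marker panel is a reconstruction.

## The random generator

`generate_random_ontology` emulates the *shape* of a curated ontology: a
single-inheritance class tree (default depth ≤ 5), a parallel process
ontology supplying fillers, definitions on a random subset of classes
(default p = 0.6, 1–4 differentia with weights 0.4/0.3/0.2/0.1), and an
optional develops_from chain.  Every definition carries a filler unique to
its class, so nothing is entailed or flagged *by accident*: planted
subsumptions, disjointness violations, redundant shortcuts and polarity
conflicts are the only non-asserted structure, each recorded in the
returned `GroundTruth` and re-verified with the oracle before the
ontology is handed out.  `n_classes` is a budget (plants consume classes
from it), and identical parameters plus seed give byte-identical OBO
text.

What the generator does **not** emulate: realistic marker panels,
definitions mixing many external ontologies, dangling MIREOT truncations,
annotation noise.  Passing the differential battery therefore shows the
two engines agree on the rule semantics over this structural envelope; it
is not evidence about parsing robustness on arbitrary real-world files.

## The oracle

`naive_closure` restates the same rule semantics by exhaustive
enumeration over all class/axiom tuples per round, with no worklist, no
indexes and no shared code with the reasoner.  A size guard (~200 classes)
keeps its cubic behaviour harmless.  The equivalence suite compares
sorted edge lists exactly on every fixture and on seeded random instances
of up to 80 classes.

## Numerical / engineering choices

* Determinism everywhere: sorted stanza and tag order on write, sorted
  worklists in the reasoner, sorted finding order in reports.  Two runs on
  the same input are byte-identical.
* Degenerate inputs: empty ontologies parse and classify to empty
  closures; a definition with a genus but no differentia (or vice versa)
  is rejected at parse time as malformed; cycles refuse classification
  but are reported, not raised, by `validate`.
* Lenient parsing records dangling references (MIREOT subsets routinely
  truncate ancestry); strict mode raises.  `PRO:` is canonicalized to the
  `PR:` prefix on input.
* Problem sizes: the packaged scenarios have 6–24 classes each; the
  differential battery uses 100 instances of 20–80 classes in the test
  suite and 50 in the acceptance script.

## Known limitations

* The axiom language is deliberately small: named fillers only, no nested
  class expressions beyond the fixed expansion templates, no cardinality
  other than exactly-zero, no property chains beyond the
  develops_from/is_a interplay.  It is a structural subsumption engine,
  not a tableau OWL-DL reasoner.
* High/low-amount semantics are not reasoned over (only the presence
  entailment is used).
* Duplicate-relation checking considers asserted edges only; whether
  inferred edges should count is a matter of curator taste and is out of
  scope.
* The full historical hematopoietic ontology (406 classes, 377
  definitions, 28 disjointness axioms) is not bundled; file-level counts
  on it are reproducible only against that file, which `stats` will
  happily compute given the download.
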