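"""Packaged worked scenarios from hematopoietic cell-type curation.

Each fixture is a small ontology built programmatically (the ``fixture``
CLI command writes it out as OBO text) together with a :class:`GroundTruth`
recording the outcomes the scenario is known for: which non-asserted edges
reasoning must add, which it must *not* add, and which QA findings the
diagnostics battery must raise.  Only outcomes the scenarios actually
establish are encoded; the surrounding class structure is a plausible
reconstruction of hematopoietic curation practice.

Scenarios
---------
helper_t_inference
    "helper T cell" has no asserted children, but four effector subtypes
    with specific cytokine-production capabilities are inferred under it —
    the asserted single-inheritance tree becomes an inferred polyhierarchy.
granulocyte_lineage
    mature basophil and eosinophil reach the granulocyte-monocyte
    progenitor through seven intermediate cell types; the transitive
    develops_from closure states the shared origin directly.
tcr_disjoint_pre / tcr_disjoint_post
    a too-general T-cell-receptor-complex differentia makes gamma-delta
    T cell subsume under alpha-beta T cell, violating their disjointness;
    narrowing the filler to the alpha-beta receptor complex repairs it.
treg_pre / treg_post
    natural Tregs are inferred to be induced Tregs and their asserted
    develops_from link to the double-positive thymocyte is redundant;
    moving develops_from into the definitions separates the two.
innate_t_grouping
    NK T cells and MAIT cells regroup under a new "innate effector T cell"
    class via capable_of innate immune response.
granule_conflict
    a myelocyte lacking tertiary granules three is_a levels below a
    granulocyte ancestor that has them — a polarity contradiction.
hsc_species
    the species-neutral lineage-negative stem cell with 12 lacks-marker
    differentia and species-specific subtypes linked by develops_from.
nucleate_erythrocyte
    the classic genus-differentia example: nucleate erythrocyte is
    inferred under nucleate cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import UnknownEntityError
from .model import (
    ClassNode,
    Definition,
    Differentia,
    OntologyGraph,
    RelationDef,
)

Entailment = tuple[str, str, str]  # (sub, sup, relation)


@dataclass
class GroundTruth:
    """Expected outcomes for a fixture or generated ontology."""

    expected_entailments: set[Entailment] = field(default_factory=set)
    absent_entailments: set[Entailment] = field(default_factory=set)
    #: (category, subjects that the finding's subject tuple must contain)
    expected_findings: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    #: exact inferred direct children where the scenario pins them down
    direct_children: dict[str, frozenset] = field(default_factory=dict)
    direct_parents: dict[str, frozenset] = field(default_factory=dict)
    #: True if validate() must produce no findings at all
    clean: bool = False
    planted_cycles: list[list[str]] = field(default_factory=list)


class _Builder:
    """Small convenience layer over OntologyGraph for fixture assembly."""

    def __init__(self, name: str):
        self.onto = OntologyGraph(header={
            "format-version": ["1.2"],
            "default-namespace": ["cell"],
            "remark": [f"obolog packaged fixture: {name}"],
        })
        self.onto.typedefs["develops_from"] = RelationDef(
            "develops_from", name="develops_from", is_transitive=True)
        self.onto.typedefs["part_of"] = RelationDef(
            "part_of", name="part of", is_transitive=True)

    def term(self, cid, name, ns="cell", parent=None, genus=None, diff=(),
             rels=(), disjoint=()):
        node = ClassNode(id=cid, name=name, namespace=ns)
        if parent:
            node.is_a_parents.append(parent)
        if diff:
            node.definition = Definition(
                genus if genus is not None else parent,
                tuple(Differentia(r, f) for r, f in diff))
        node.relationships.extend(rels)
        node.disjoint_from.extend(disjoint)
        self.onto.add(node)
        return cid


# ---------------------------------------------------------------------------
# shared mini-ontology pieces

_BP_ROOT = "GO:0008150"       # biological_process
_CC_ROOT = "GO:0005575"       # cellular_component
_CYTOKINE_PROD = "GO:0001816"
_IL17_PROD = "GO:0032620"
_IFNG_PROD = "GO:0032609"
_IL4_PROD = "GO:0032633"
_TCELL_SELECTION = "GO:0045058"
_TCELL_CHEMOTAXIS = "GO:0072678"
_CYTOTOXICITY = "GO:0001913"
_INNATE_IMMUNE = "GO:0045087"
_TCR_COMPLEX = "GO:0042101"
_AB_TCR = "GO:0042105"
_GD_TCR = "GO:0042106"
_TERTIARY_GRANULE = "GO:0070820"
_NUCLEUS = "GO:0005634"
_RENIFORM = "PATO:0001871"
_CD4 = "PR:000001004"

_T_CELL = "CL:0000084"
_EFFECTOR_T = "CL:0000911"
_HELPER_T = "CL:0000912"
_GAMMA_DELTA_T = "CL:0000798"
_ALPHA_BETA_T = "CL:0000789"


def _effector_t_block(b: _Builder) -> None:
    """T cell / effector T cell backbone with its mini process ontology."""
    b.term(_BP_ROOT, "biological_process", "biological_process")
    b.term(_TCELL_SELECTION, "T cell selection", "biological_process", _BP_ROOT)
    b.term(_TCELL_CHEMOTAXIS, "T cell chemotaxis", "biological_process", _BP_ROOT)
    b.term(_T_CELL, "T cell")
    b.term(_EFFECTOR_T, "effector T cell", parent=_T_CELL,
           diff=[("has_completed", _TCELL_SELECTION),
                 ("capable_of", _TCELL_CHEMOTAXIS)])


def _helper_t_inference():
    b = _Builder("helper_t_inference")
    _effector_t_block(b)
    b.term(_CYTOKINE_PROD, "cytokine production", "biological_process", _BP_ROOT)
    for cid, label in [(_IFNG_PROD, "interferon-gamma production"),
                       (_IL4_PROD, "interleukin-4 production"),
                       (_IL17_PROD, "interleukin-17 production")]:
        b.term(cid, label, "biological_process", _CYTOKINE_PROD)
    b.term(_CYTOTOXICITY, "T cell mediated cytotoxicity",
           "biological_process", _BP_ROOT)
    b.term(_CC_ROOT, "cellular_component", "cellular_component")
    b.term(_TCR_COMPLEX, "T cell receptor complex", "cellular_component", _CC_ROOT)
    b.term(_GD_TCR, "gamma-delta T cell receptor complex",
           "cellular_component", _TCR_COMPLEX)
    b.term(_CD4, "CD4 molecule", "protein")

    b.term(_GAMMA_DELTA_T, "gamma-delta T cell", parent=_T_CELL,
           diff=[("has_plasma_membrane_part", _GD_TCR)])
    b.term(_HELPER_T, "helper T cell", parent=_EFFECTOR_T,
           diff=[("capable_of", _CYTOKINE_PROD)])
    th1 = b.term("CL:0000545", "T-helper 1 cell", parent=_EFFECTOR_T,
                 diff=[("capable_of", _IFNG_PROD)])
    th2 = b.term("CL:0000546", "T-helper 2 cell", parent=_EFFECTOR_T,
                 diff=[("capable_of", _IL4_PROD)])
    th17 = b.term("CL:0000899", "T-helper 17 cell", parent=_EFFECTOR_T,
                  diff=[("capable_of", _IL17_PROD),
                        ("has_plasma_membrane_part", _CD4)])
    gd17 = b.term("CL:0900001", "IL-17-secreting gamma-delta T cell",
                  parent=_GAMMA_DELTA_T,
                  diff=[("has_completed", _TCELL_SELECTION),
                        ("capable_of", _TCELL_CHEMOTAXIS),
                        ("capable_of", _IL17_PROD)])
    b.term("CL:0000910", "cytotoxic T cell", parent=_EFFECTOR_T,
           diff=[("capable_of", _CYTOTOXICITY)])

    truth = GroundTruth(
        expected_entailments={(c, _HELPER_T, "is_a") for c in (th1, th2, th17, gd17)}
        | {(gd17, _EFFECTOR_T, "is_a")},
        absent_entailments={("CL:0000910", _HELPER_T, "is_a")},
        direct_children={_HELPER_T: frozenset({th1, th2, th17, gd17})},
        direct_parents={gd17: frozenset({_GAMMA_DELTA_T, _HELPER_T})},
        clean=True,
    )
    return b.onto, truth


def _granulocyte_lineage():
    b = _Builder("granulocyte_lineage")
    myeloid = b.term("CL:0000766", "myeloid leukocyte")
    gmp = b.term("CL:0000557", "granulocyte monocyte progenitor", parent=myeloid)
    myeloblast = b.term("CL:0000835", "myeloblast", parent=myeloid,
                        rels=[("develops_from", gmp)])

    def chain(adj, noun, start_num, mature_id):
        stages = [f"{adj} promyelocyte", f"{adj} myelocyte",
                  f"{adj} metamyelocyte", f"{noun} band form",
                  f"immature {noun}", noun]
        prev = myeloblast
        for i, label in enumerate(stages):
            prev = b.term(f"CL:09000{start_num + i:02d}", label, parent=myeloid,
                          rels=[("develops_from", prev)])
        b.term(mature_id, f"mature {noun}", parent=myeloid,
               rels=[("develops_from", prev)])

    chain("basophilic", "basophil", 10, "CL:0000767")
    chain("eosinophilic", "eosinophil", 20, "CL:0000771")

    truth = GroundTruth(
        expected_entailments={
            ("CL:0000767", gmp, "develops_from"),
            ("CL:0000771", gmp, "develops_from"),
            ("CL:0000767", myeloblast, "develops_from"),
            ("CL:0000771", myeloblast, "develops_from"),
        },
        absent_entailments={("CL:0000767", "CL:0000771", "develops_from")},
        clean=True,
    )
    return b.onto, truth


def _tcr_fixture(narrowed: bool):
    b = _Builder("tcr_disjoint_post" if narrowed else "tcr_disjoint_pre")
    b.term(_CC_ROOT, "cellular_component", "cellular_component")
    b.term(_TCR_COMPLEX, "T cell receptor complex", "cellular_component", _CC_ROOT)
    b.term(_AB_TCR, "alpha-beta T cell receptor complex",
           "cellular_component", _TCR_COMPLEX)
    b.term(_GD_TCR, "gamma-delta T cell receptor complex",
           "cellular_component", _TCR_COMPLEX)
    b.term(_T_CELL, "T cell")
    b.term(_ALPHA_BETA_T, "alpha-beta T cell", parent=_T_CELL,
           diff=[("has_plasma_membrane_part", _AB_TCR if narrowed else _TCR_COMPLEX)],
           disjoint=[_GAMMA_DELTA_T])
    b.term(_GAMMA_DELTA_T, "gamma-delta T cell", parent=_T_CELL,
           diff=[("has_plasma_membrane_part", _GD_TCR)])
    if narrowed:
        truth = GroundTruth(
            absent_entailments={(_GAMMA_DELTA_T, _ALPHA_BETA_T, "is_a"),
                                (_ALPHA_BETA_T, _GAMMA_DELTA_T, "is_a")},
            clean=True)
    else:
        truth = GroundTruth(
            expected_entailments={(_GAMMA_DELTA_T, _ALPHA_BETA_T, "is_a")},
            expected_findings=[("disjointness_violation",
                                (_GAMMA_DELTA_T, _ALPHA_BETA_T))])
    return b.onto, truth


_DP_THYMOCYTE = "CL:0000809"
_CD4_T = "CL:0000624"
_TREG = "CL:0000815"
_NTREG = "CL:0000903"
_ITREG = "CL:0000902"
_ACT_CD4 = "CL:0900050"
_CD25, _GITR, _NRP1 = "PR:0900021", "PR:0900022", "PR:0900023"


def _treg_backbone(b: _Builder) -> None:
    b.term(_T_CELL, "T cell")
    dp = b.term(_DP_THYMOCYTE, "double-positive, alpha-beta thymocyte",
                parent=_T_CELL)
    sp = b.term("CL:0900051", "CD4-positive, single-positive thymocyte",
                parent=_T_CELL, rels=[("develops_from", dp)])
    b.term(_CD4_T, "CD4-positive, alpha-beta T cell", parent=_T_CELL,
           rels=[("develops_from", sp)])
    naive = b.term("CL:0900052", "naive CD4-positive, alpha-beta T cell",
                   parent=_CD4_T)
    b.term(_ACT_CD4, "activated CD4-positive, alpha-beta T cell",
           parent=_CD4_T, rels=[("develops_from", naive)])
    b.term(_TREG, "regulatory T cell", parent=_CD4_T)
    for cid, label in [(_CD25, "CD25 (interleukin-2 receptor alpha)"),
                       (_GITR, "GITR (TNF receptor superfamily member 18)"),
                       (_NRP1, "neuropilin-1")]:
        b.term(cid, label, "protein")


def _treg_fixture(repaired: bool):
    b = _Builder("treg_post" if repaired else "treg_pre")
    _treg_backbone(b)
    shared = [("has_plasma_membrane_part", _CD25),
              ("has_plasma_membrane_part", _GITR)]
    if repaired:
        b.term(_ITREG, "induced regulatory T cell", parent=_TREG,
               diff=[("develops_from", _ACT_CD4)] + shared)
        b.term(_NTREG, "natural regulatory T cell", parent=_TREG,
               diff=[("develops_from", _DP_THYMOCYTE)] + shared
               + [("has_plasma_membrane_part", _NRP1)],
               disjoint=[_ITREG])
        truth = GroundTruth(
            absent_entailments={(_NTREG, _ITREG, "is_a"),
                                (_ITREG, _NTREG, "is_a")},
            expected_entailments={(_NTREG, _DP_THYMOCYTE, "develops_from"),
                                  (_ITREG, _DP_THYMOCYTE, "develops_from")},
            clean=True)
    else:
        b.term(_ITREG, "induced regulatory T cell", parent=_TREG,
               diff=shared, rels=[("develops_from", _ACT_CD4)])
        b.term(_NTREG, "natural regulatory T cell", parent=_TREG,
               diff=shared + [("has_plasma_membrane_part", _NRP1)],
               rels=[("develops_from", _DP_THYMOCYTE)],
               disjoint=[_ITREG])
        truth = GroundTruth(
            expected_entailments={(_NTREG, _ITREG, "is_a"),
                                  (_NTREG, _DP_THYMOCYTE, "develops_from")},
            expected_findings=[("disjointness_violation", (_NTREG, _ITREG)),
                               ("redundant_edge", (_NTREG, _DP_THYMOCYTE))])
    return b.onto, truth


def _innate_t_grouping():
    b = _Builder("innate_t_grouping")
    _effector_t_block(b)
    b.term(_INNATE_IMMUNE, "innate immune response", "biological_process", _BP_ROOT)
    nk11 = b.term("PR:0900031", "NK1.1 (killer cell lectin-like receptor B1)",
                  "protein")
    mr1 = b.term("PR:0900032", "MR1-restricted invariant T cell receptor",
                 "protein")
    innate = b.term("CL:0900030", "innate effector T cell", parent=_EFFECTOR_T,
                    diff=[("capable_of", _INNATE_IMMUNE)])
    nkt = b.term("CL:0000814", "mature NK T cell", parent=_EFFECTOR_T,
                 diff=[("capable_of", _INNATE_IMMUNE),
                       ("has_plasma_membrane_part", nk11)])
    mait = b.term("CL:0000940", "mucosal associated invariant T cell",
                  parent=_EFFECTOR_T,
                  diff=[("capable_of", _INNATE_IMMUNE),
                        ("has_plasma_membrane_part", mr1)])
    truth = GroundTruth(
        expected_entailments={(nkt, innate, "is_a"), (mait, innate, "is_a")},
        absent_entailments={(nkt, mait, "is_a"), (mait, nkt, "is_a")},
        direct_parents={nkt: frozenset({innate}), mait: frozenset({innate})},
        clean=True)
    return b.onto, truth


def _granule_conflict():
    b = _Builder("granule_conflict")
    b.term(_CC_ROOT, "cellular_component", "cellular_component")
    b.term(_TERTIARY_GRANULE, "tertiary granule", "cellular_component", _CC_ROOT)
    b.term(_NUCLEUS, "nucleus", "cellular_component", _CC_ROOT)
    b.term(_RENIFORM, "reniform", "quality")
    myeloid = b.term("CL:0000766", "myeloid leukocyte")
    gran = b.term("CL:0000094", "granulocyte", parent=myeloid,
                  diff=[("has_part", _TERTIARY_GRANULE)])
    imm = b.term("CL:0900041", "immature granulocyte", parent=gran)
    myelo = b.term("CL:0900042", "myelocyte", parent=imm)
    nmyelo = b.term("CL:0900043", "neutrophilic myelocyte", parent=myelo,
                    rels=[("lacks_part", _TERTIARY_GRANULE)])
    # cellular-phenotype composite: a quality-bearing component class used
    # as a differentia filler
    cp = b.term("CP:0000001", "reniform nucleus", "cellular_phenotype",
                genus=_NUCLEUS, diff=[("has_quality", _RENIFORM)])
    imm_baso = b.term("CL:0900045", "immature basophil", parent=imm)
    b.term("CL:0900044", "basophilic metamyelocyte", parent=imm_baso,
           diff=[("has_part", cp)])
    truth = GroundTruth(
        expected_entailments={(nmyelo, gran, "is_a")},
        expected_findings=[("polarity_conflict", (nmyelo,))])
    return b.onto, truth


def _hsc_species():
    b = _Builder("hsc_species")
    lin_markers = [
        ("PR:0900101", "CD2"), ("PR:0900102", "CD3 epsilon"),
        ("PR:0900103", "CD11b"), ("PR:0900104", "CD14"),
        ("PR:0900105", "CD15"), ("PR:0900106", "CD16"),
        ("PR:0900107", "CD19"), ("PR:0900108", "CD20"),
        ("PR:0900109", "CD56 (neural cell adhesion molecule 1)"),
        ("PR:0900110", "CD123 (interleukin-3 receptor alpha)"),
        ("PR:0900111", "CD235a (glycophorin A)"),
        ("PR:0900112", "Ter-119 (lymphocyte antigen 76)"),
    ]
    for cid, label in lin_markers:
        b.term(cid, label, "protein")
    for cid, label in [("PR:0900113", "CD34"), ("PR:0900114", "CD38"),
                       ("PR:0900115", "Kit (mast/stem cell growth factor receptor)"),
                       ("PR:0900116", "Spa-1 (signal-induced proliferation-associated protein 1)")]:
        b.term(cid, label, "protein")
    marrow = b.term("UBERON:0002371", "bone marrow", "anatomy")

    hemo = b.term("CL:0000988", "hematopoietic cell")
    hsc = b.term("CL:0000037", "hematopoietic stem cell", parent=hemo,
                 diff=[("lacks_plasma_membrane_part", cid)
                       for cid, _ in lin_markers],
                 rels=[("part_of", marrow)])
    human = b.term("CL:0900061", "CD34-positive, CD38-negative hematopoietic stem cell",
                   parent=hsc,
                   diff=[("has_plasma_membrane_part", "PR:0900113"),
                         ("lacks_plasma_membrane_part", "PR:0900114")])
    mouse = b.term("CL:0900062", "Kit-positive, Spa-1-positive hematopoietic stem cell",
                   parent=hsc,
                   diff=[("has_plasma_membrane_part", "PR:0900115"),
                         ("has_plasma_membrane_part", "PR:0900116")])
    mpp = b.term("CL:0900063", "multipotent progenitor", parent=hemo)
    b.term("CL:0900064", "CD34-positive multipotent progenitor", parent=mpp,
           rels=[("develops_from", human)])
    b.term("CL:0900065", "Kit-positive multipotent progenitor", parent=mpp,
           rels=[("develops_from", mouse)])
    truth = GroundTruth(
        expected_entailments={("CL:0900064", hsc, "develops_from"),
                              ("CL:0900065", hsc, "develops_from")},
        absent_entailments={(human, mouse, "is_a"), (mouse, human, "is_a")},
        clean=True)
    return b.onto, truth


def _nucleate_erythrocyte():
    b = _Builder("nucleate_erythrocyte")
    b.term(_CC_ROOT, "cellular_component", "cellular_component")
    b.term(_NUCLEUS, "nucleus", "cellular_component", _CC_ROOT)
    cell = b.term("CL:0000000", "cell")
    ery = b.term("CL:0000232", "erythrocyte", parent=cell)
    nuc_cell = b.term("CL:0002242", "nucleate cell", parent=cell,
                      diff=[("has_part", _NUCLEUS)])
    nuc_ery = b.term("CL:0000562", "nucleate erythrocyte", parent=ery,
                     diff=[("has_part", _NUCLEUS)])
    truth = GroundTruth(
        expected_entailments={(nuc_ery, nuc_cell, "is_a")},
        direct_parents={nuc_ery: frozenset({ery, nuc_cell})},
        clean=True)
    return b.onto, truth


FIXTURES = {
    "helper_t_inference": _helper_t_inference,
    "granulocyte_lineage": _granulocyte_lineage,
    "tcr_disjoint_pre": lambda: _tcr_fixture(narrowed=False),
    "tcr_disjoint_post": lambda: _tcr_fixture(narrowed=True),
    "treg_pre": lambda: _treg_fixture(repaired=False),
    "treg_post": lambda: _treg_fixture(repaired=True),
    "innate_t_grouping": _innate_t_grouping,
    "granule_conflict": _granule_conflict,
    "hsc_species": _hsc_species,
    "nucleate_erythrocyte": _nucleate_erythrocyte,
}


def all_fixture_names() -> list[str]:
    return sorted(FIXTURES)


def build_paper_fixture(name: str) -> tuple[OntologyGraph, GroundTruth]:
    """Construct one packaged scenario and its expected outcomes."""
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise UnknownEntityError(
            f"unknown fixture {name!r}; available: {', '.join(all_fixture_names())}"
        ) from None
    return builder()
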