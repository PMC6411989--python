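"""Compound-ontology construction from (anatomy, pathology) class pairs.

Four design patterns are supported.  Each creates one compound class per
distinct (anatomy, pathology) pair observed in a dataset:

* **MAP** — an anatomical entity bearing a lesion; the anatomy taxonomy is
  the backbone, and one compound class subsumes another when both its
  anatomy and its pathology class subsume the other's.
* **MAPT** — like MAP, but the anatomy side is closed over transitive
  ``part_of``: a lesion observed in an organ also counts as observed in
  any structure the organ is part of.
* **PAM** — a lesion affecting an anatomical site; the pathology taxonomy
  is the backbone, subsumption as in MAP.
* **PAMT** — like PAM with the ``part_of`` closure on the anatomy side.

The subsumption rules below are the structural equivalent of running a DL
reasoner over the corresponding axiom templates (a named class conjoined
with a single existential restriction, plus top-level contextualization
axioms): for that fragment the component-wise ancestor test is sound and
complete, so the classified hierarchy can be computed directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .ontology import (
    IS_A,
    PART_OF,
    OntologyGraph,
    UnknownClassError,
    ancestors,
)

__all__ = [
    "PatternKind",
    "PatternClass",
    "CombinedOntology",
    "enumerate_pairs",
    "pattern_subsumes",
    "build_pattern_ontology",
    "TOP_ID",
]

TOP_ID = "ROOT:thing"  # owl:Thing stand-in topping every combined ontology


class PatternKind(str, Enum):
    MAP = "MAP"
    MAPT = "MAPT"
    PAM = "PAM"
    PAMT = "PAMT"

    @property
    def anatomy_backbone(self) -> bool:
        return self in (PatternKind.MAP, PatternKind.MAPT)

    @property
    def uses_part_of(self) -> bool:
        return self in (PatternKind.MAPT, PatternKind.PAMT)

    @property
    def anatomy_relations(self) -> tuple[str, ...]:
        return (IS_A, PART_OF) if self.uses_part_of else (IS_A,)


def _local(class_id: str) -> str:
    return class_id.split(":", 1)[-1]


@dataclass(frozen=True)
class PatternClass:
    """A compound class keyed by its anatomy and pathology components."""

    anatomy_id: str
    pathology_id: str
    kind: PatternKind

    @property
    def compound_id(self) -> str:
        return f"{self.kind.value}:{_local(self.anatomy_id)}-{_local(self.pathology_id)}"


@dataclass
class CombinedOntology:
    """A classified compound ontology (pattern classes + both sources).

    ``backbone`` is the full union graph: all anatomy classes, all
    pathology classes and all pattern classes under a fresh top node, with
    the inferred is_a edges reduced to their transitive reduction.
    ``class_for_pair`` maps each observed pair to the graph node carrying
    it — normally the compound ID, but pairs whose contextual side is a
    source root collapse onto the backbone class they are equivalent to.
    """

    kind: PatternKind
    pattern_classes: set[PatternClass]
    backbone: OntologyGraph
    provenance: tuple[str, str]
    class_for_pair: dict[tuple[str, str], str] = field(default_factory=dict)
    pair_for_class: dict[str, tuple[str, str]] = field(default_factory=dict)
    equivalences: dict[str, str] = field(default_factory=dict)

    @property
    def n_pattern_classes(self) -> int:
        return len(self.pattern_classes)

    def new_class_ids(self) -> set[str]:
        """IDs of compound classes materialised as new graph nodes."""
        return set(self.pair_for_class)


def enumerate_pairs(
    records: Sequence,
    anatomy: OntologyGraph,
    pathology: OntologyGraph,
) -> set[tuple[str, str]]:
    """Distinct (anatomy ID, pathology ID) pairs observed in the records.

    Records may be any objects with ``anatomy_id``/``pathology_id``
    attributes, or plain ``(anatomy_id, pathology_id)`` tuples.
    """
    pairs: set[tuple[str, str]] = set()
    for rec in records:
        if hasattr(rec, "anatomy_id"):
            a, p = rec.anatomy_id, rec.pathology_id
        else:
            a, p = rec
        if a not in anatomy.classes:
            raise UnknownClassError(f"unknown anatomy class {a!r} in record {rec!r}")
        if p not in pathology.classes:
            raise UnknownClassError(f"unknown pathology class {p!r} in record {rec!r}")
        pairs.add((a, p))
    return pairs


def pattern_subsumes(
    kind: PatternKind,
    anatomy: OntologyGraph,
    pathology: OntologyGraph,
    c1: PatternClass,
    c2: PatternClass,
) -> bool:
    """True iff ``c2`` subsumes ``c1`` under the pattern's semantics."""
    if c1.kind != kind or c2.kind != kind:
        raise ValueError(
            f"pattern kind mismatch: expected {kind.value}, "
            f"got {c1.kind.value} and {c2.kind.value}"
        )
    anat_ok = c2.anatomy_id in ancestors(
        anatomy, c1.anatomy_id, kind.anatomy_relations, reflexive=True
    )
    path_ok = c2.pathology_id in ancestors(
        pathology, c1.pathology_id, (IS_A,), reflexive=True
    )
    return anat_ok and path_ok


def build_pattern_ontology(
    anatomy: OntologyGraph,
    pathology: OntologyGraph,
    pairs: Iterable[tuple[str, str]],
    kind: PatternKind | str,
    classify: bool = True,
) -> CombinedOntology:
    """Create and classify the compound ontology for one pattern kind.

    With ``classify=True`` (the default) the pattern classes carry the
    full inferred subsumption hierarchy, transitively reduced; with
    ``classify=False`` only the asserted attachment of each compound
    class to its backbone class is kept (the pre-reasoning view, useful
    for comparing asserted vs. classified structure).

    A pair whose contextual-side class is that source's root is
    equivalent to its backbone class (everything bears a lesion /
    affects something, by the contextualization axioms) and is merged
    onto it rather than materialised as a separate node.
    """
    kind = PatternKind(kind)
    pairs = set(pairs)
    if not pairs:
        raise ValueError("pairs must be non-empty")
    for a, p in pairs:
        if a not in anatomy.classes:
            raise UnknownClassError(f"unknown anatomy class {a!r}")
        if p not in pathology.classes:
            raise UnknownClassError(f"unknown pathology class {p!r}")

    # split off pairs equivalent to a backbone class
    context_root = pathology.root if kind.anatomy_backbone else anatomy.root
    merged: dict[tuple[str, str], str] = {}
    kept: list[PatternClass] = []
    for a, p in sorted(pairs):
        ctx = p if kind.anatomy_backbone else a
        if ctx == context_root:
            merged[(a, p)] = a if kind.anatomy_backbone else p
        else:
            kept.append(PatternClass(a, p, kind))

    classes = set(anatomy.classes) | set(pathology.classes) | {TOP_ID}
    labels = dict(anatomy.labels)
    labels.update(pathology.labels)
    labels[TOP_ID] = "owl:Thing"
    edges: set[tuple[str, str]] = set(anatomy.is_a_edges) | set(pathology.is_a_edges)
    edges.add((anatomy.root, TOP_ID))
    edges.add((pathology.root, TOP_ID))

    synonyms: dict[str, set[str]] = {}
    for pair, target in merged.items():
        synonyms.setdefault(target, set()).add(
            PatternClass(pair[0], pair[1], kind).compound_id
        )

    pair_for_class: dict[str, tuple[str, str]] = {}
    for pc in kept:
        cid = pc.compound_id
        classes.add(cid)
        labels[cid] = _compound_label(pc, anatomy, pathology)
        pair_for_class[cid] = (pc.anatomy_id, pc.pathology_id)
        backbone_parent = pc.anatomy_id if kind.anatomy_backbone else pc.pathology_id
        edges.add((cid, backbone_parent))

    if classify and kept:
        # precompute ancestor sets once; O(n^2) pairwise test
        anat_anc = {
            pc.anatomy_id: ancestors(
                anatomy, pc.anatomy_id, kind.anatomy_relations, reflexive=True
            )
            for pc in kept
        }
        path_anc = {
            pc.pathology_id: ancestors(
                pathology, pc.pathology_id, (IS_A,), reflexive=True
            )
            for pc in kept
        }
        for c1 in kept:
            for c2 in kept:
                if c1 is c2:
                    continue
                if (
                    c2.anatomy_id in anat_anc[c1.anatomy_id]
                    and c2.pathology_id in path_anc[c1.pathology_id]
                ):
                    edges.add((c1.compound_id, c2.compound_id))
        # a compound class is also subsumed by any merged (root-context)
        # class, i.e. by the corresponding backbone ancestor — already
        # covered by the backbone attachment plus source is_a edges.

    g = nx.DiGraph()
    g.add_nodes_from(classes)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("combined ontology is not acyclic")
    reduced = nx.transitive_reduction(g)

    backbone = OntologyGraph(
        classes=classes,
        labels=labels,
        is_a_edges=set(reduced.edges()),
        part_of_edges=set(anatomy.part_of_edges),
        root=TOP_ID,
        synonyms=synonyms,
    )
    class_for_pair = {pair: merged.get(pair) or PatternClass(*pair, kind).compound_id
                      for pair in pairs}
    return CombinedOntology(
        kind=kind,
        pattern_classes=set(kept),
        backbone=backbone,
        provenance=(anatomy.root, pathology.root),
        class_for_pair=class_for_pair,
        pair_for_class=pair_for_class,
        equivalences={
            PatternClass(a, p, kind).compound_id: tgt for (a, p), tgt in merged.items()
        },
    )


def _compound_label(
    pc: PatternClass, anatomy: OntologyGraph, pathology: OntologyGraph
) -> str:
    a = anatomy.labels.get(pc.anatomy_id, pc.anatomy_id)
    p = pathology.labels.get(pc.pathology_id, pc.pathology_id)
    if pc.kind.anatomy_backbone:
        return f"{a} with {p}"
    return f"{p} affecting {a}"


def write_pairs_tsv(pairs: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("anatomy_id\tpathology_id\n")
        for a, p in sorted(set(pairs)):
            fh.write(f"{a}\t{p}\n")


def read_pairs_tsv(path) -> set[tuple[str, str]]:
    pairs = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("anatomy_id"):
            raise ValueError("pairs TSV must have an anatomy_id/pathology_id header")
        for line in fh:
            a, p = line.rstrip("\n").split("\t")
            pairs.add((a, p))
    return pairs


def write_edges_tsv(combined: CombinedOntology, path) -> None:
    with open(path, "w") as fh:
        fh.write("child\tparent\n")
        for child, parent in sorted(combined.backbone.is_a_edges):
            fh.write(f"{child}\t{parent}\n")
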