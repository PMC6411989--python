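"""Rooted DAG ontologies with ``is_a`` and ``part_of`` edges.

The ontologies handled here are simple taxonomies in the OBO style: named
classes identified by CURIEs (``MA:0000001``), a subsumption hierarchy of
``is_a`` edges, and an optional mereology of ``part_of`` edges.  Everything
downstream — compound pattern construction, structural metrics, information
content — only needs this fragment, so richer OWL axioms are deliberately
out of scope.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Collection, Iterable

import networkx as nx
import obonet

__all__ = [
    "OntologyGraph",
    "CyclicHierarchyError",
    "UnknownClassError",
    "load_ontology",
    "ancestors",
    "descendants",
    "subsumes",
    "write_obo",
]

IS_A = "is_a"
PART_OF = "part_of"


class CyclicHierarchyError(ValueError):
    """The is_a relation contains a cycle (names one member)."""


class UnknownClassError(KeyError):
    """A class ID was referenced that is not defined in the ontology."""


@dataclass
class OntologyGraph:
    """A rooted DAG of named classes with typed edges.

    Edges are stored child-first: ``(child, parent)`` for is_a and
    ``(part, whole)`` for part_of.  Every class except ``root`` has at
    least one is_a path to the root.
    """

    classes: set[str]
    labels: dict[str, str]
    is_a_edges: set[tuple[str, str]]
    part_of_edges: set[tuple[str, str]]
    root: str
    synonyms: dict[str, set[str]] = field(default_factory=dict)

    # parent adjacency caches, built lazily
    _up: dict[str, dict[str, tuple[str, ...]]] = field(
        default_factory=dict, repr=False, compare=False
    )
    _down: dict[str, dict[str, tuple[str, ...]]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if self.root not in self.classes:
            raise UnknownClassError(f"root {self.root!r} not among classes")
        for child, parent in self.is_a_edges | self.part_of_edges:
            for cid in (child, parent):
                if cid not in self.classes:
                    raise UnknownClassError(f"unknown class {cid!r} in edge")
        cycle = _find_cycle(self.classes, self.is_a_edges)
        if cycle is not None:
            raise CyclicHierarchyError(
                f"cyclic hierarchy: class {cycle!r} lies on an is_a cycle"
            )
        # rootedness: every class reaches root through is_a
        reach = _reachable_up(self.is_a_edges, self.root)
        missing = self.classes - reach
        if missing:
            raise ValueError(
                f"{len(missing)} classes have no is_a path to root "
                f"(e.g. {sorted(missing)[0]!r})"
            )

    # -- adjacency -----------------------------------------------------
    def parents(self, class_id: str, relations: Collection[str] = (IS_A,)) -> tuple[str, ...]:
        key = _relkey(relations)
        cache = self._up.setdefault(key, {})
        if not cache:
            for rel in key:
                edges = self.is_a_edges if rel == IS_A else self.part_of_edges
                for child, parent in edges:
                    cache.setdefault(child, [])
                    cache[child].append(parent)  # type: ignore[attr-defined]
            for k, v in cache.items():
                cache[k] = tuple(sorted(set(v)))
            for cid in self.classes:
                cache.setdefault(cid, ())
        if class_id not in cache:
            raise UnknownClassError(f"unknown class {class_id!r}")
        return cache[class_id]

    def children(self, class_id: str, relations: Collection[str] = (IS_A,)) -> tuple[str, ...]:
        key = _relkey(relations)
        cache = self._down.setdefault(key, {})
        if not cache:
            for rel in key:
                edges = self.is_a_edges if rel == IS_A else self.part_of_edges
                for child, parent in edges:
                    cache.setdefault(parent, [])
                    cache[parent].append(child)  # type: ignore[attr-defined]
            for k, v in cache.items():
                cache[k] = tuple(sorted(set(v)))
            for cid in self.classes:
                cache.setdefault(cid, ())
        if class_id not in cache:
            raise UnknownClassError(f"unknown class {class_id!r}")
        return cache[class_id]

    def leaves(self) -> set[str]:
        """Classes with no is_a children."""
        return {c for c in self.classes if not self.children(c)}

    def __contains__(self, class_id: str) -> bool:
        return class_id in self.classes


def _relkey(relations: Collection[str]) -> tuple[str, ...]:
    key = tuple(sorted(set(relations)))
    bad = set(key) - {IS_A, PART_OF}
    if bad:
        raise ValueError(f"unknown relation(s): {sorted(bad)}")
    if not key:
        raise ValueError("at least one relation required")
    return key


def _find_cycle(classes: Iterable[str], edges: set[tuple[str, str]]) -> str | None:
    g = nx.DiGraph()
    g.add_nodes_from(classes)
    g.add_edges_from(edges)
    try:
        cyc = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return None
    return cyc[0][0]


def _reachable_up(edges: set[tuple[str, str]], root: str) -> set[str]:
    down: dict[str, list[str]] = {}
    for child, parent in edges:
        down.setdefault(parent, []).append(child)
    seen = {root}
    stack = [root]
    while stack:
        for c in down.get(stack.pop(), ()):
            if c not in seen:
                seen.add(c)
                stack.append(c)
    return seen


def _slug(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "-", label.strip()).strip("-").lower() or "root"


def load_ontology(path, root_label: str = "root") -> OntologyGraph:
    """Load an OBO file into an :class:`OntologyGraph`.

    Only ``[Term]`` stanzas and the ``id``, ``name``, ``is_a``,
    ``relationship: part_of`` and ``is_obsolete`` tags are interpreted;
    obsolete terms are dropped.  If the file has several top-level classes
    a fresh root with ID ``ROOT:<slug of root_label>`` is inserted and all
    of them are attached beneath it, mirroring the usual preprocessing
    step of forcing a single common root before computing taxonomic
    statistics.
    """
    multigraph = obonet.read_obo(path, ignore_obsolete=True)
    classes: set[str] = set()
    labels: dict[str, str] = {}
    for node, data in multigraph.nodes(data=True):
        if not data:
            # appears only as an edge target, never defined
            raise UnknownClassError(f"unknown class {node!r} referenced by an edge")
        classes.add(node)
        labels[node] = data.get("name", node)
    is_a_edges: set[tuple[str, str]] = set()
    part_of_edges: set[tuple[str, str]] = set()
    for child, parent, rel in multigraph.edges(keys=True):
        if rel == IS_A:
            is_a_edges.add((child, parent))
        elif rel == PART_OF:
            part_of_edges.add((child, parent))
        # any other relationship type is ignored

    cycle = _find_cycle(classes, is_a_edges)
    if cycle is not None:
        raise CyclicHierarchyError(
            f"cyclic hierarchy: class {cycle!r} lies on an is_a cycle"
        )

    has_parent = {c for c, _ in is_a_edges}
    tops = sorted(classes - has_parent)
    if len(tops) == 1:
        root = tops[0]
    else:
        root = f"ROOT:{_slug(root_label)}"
        classes.add(root)
        labels[root] = root_label
        is_a_edges |= {(t, root) for t in tops}

    part_cycle = _find_cycle(classes, part_of_edges)
    if part_cycle is not None:
        warnings.warn(
            f"part_of relation contains a cycle through {part_cycle!r}; "
            "kept as-is (only is_a acyclicity is required)",
            stacklevel=2,
        )
    return OntologyGraph(
        classes=classes,
        labels=labels,
        is_a_edges=is_a_edges,
        part_of_edges=part_of_edges,
        root=root,
    )


def ancestors(
    graph: OntologyGraph,
    class_id: str,
    relations: Collection[str] = (IS_A,),
    reflexive: bool = False,
) -> set[str]:
    """Classes reachable child→parent from ``class_id`` over ``relations``."""
    if class_id not in graph.classes:
        raise UnknownClassError(f"unknown class {class_id!r}")
    out: set[str] = set()
    stack = [class_id]
    while stack:
        for p in graph.parents(stack.pop(), relations):
            if p not in out:
                out.add(p)
                stack.append(p)
    if reflexive:
        out.add(class_id)
    else:
        out.discard(class_id)  # part_of cycles could re-reach the start
    return out


def descendants(
    graph: OntologyGraph,
    class_id: str,
    relations: Collection[str] = (IS_A,),
    reflexive: bool = False,
) -> set[str]:
    """Classes reachable parent→child from ``class_id`` over ``relations``."""
    if class_id not in graph.classes:
        raise UnknownClassError(f"unknown class {class_id!r}")
    out: set[str] = set()
    stack = [class_id]
    while stack:
        for c in graph.children(stack.pop(), relations):
            if c not in out:
                out.add(c)
                stack.append(c)
    if reflexive:
        out.add(class_id)
    else:
        out.discard(class_id)
    return out


def subsumes(graph: OntologyGraph, a: str, b: str) -> bool:
    """True iff ``a`` is an is_a ancestor-or-self of ``b``."""
    if a not in graph.classes:
        raise UnknownClassError(f"unknown class {a!r}")
    return a in ancestors(graph, b, (IS_A,), reflexive=True)


def write_obo(graph: OntologyGraph, path) -> None:
    """Serialize as a minimal OBO 1.2 flat file (is_a and part_of only)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"ontology: {_slug(graph.labels.get(graph.root, graph.root))}\n")
        for cid in sorted(graph.classes):
            fh.write("\n[Term]\n")
            fh.write(f"id: {cid}\n")
            fh.write(f"name: {graph.labels.get(cid, cid)}\n")
            for syn in sorted(graph.synonyms.get(cid, ())):
                fh.write(f'synonym: "{syn}" EXACT []\n')
            for child, parent in sorted(graph.is_a_edges):
                if child == cid:
                    fh.write(f"is_a: {parent}\n")
            for part, whole in sorted(graph.part_of_edges):
                if part == cid:
                    fh.write(f"relationship: part_of {whole}\n")
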