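"""Structural ontology-quality metrics (OQuaRE subset).

Three taxonomy-level measures:

* tangledness ``TMOnto`` — fraction of classes with more than one direct
  is_a parent;
* weighted method count ``WMCOnto`` — mean depth of the leaf classes;
* depth of inheritance ``DITOnto`` — maximum leaf depth.

Depth is the number of is_a edges from the root to a class.  Because an
ontology is a DAG, a class can have several root paths; the longest one
is used by default (configurable to shortest), and the root has depth 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Literal

from .ontology import IS_A, OntologyGraph, UnknownClassError

__all__ = ["OQuaREMetrics", "class_depth", "compute_oquare"]

DepthConvention = Literal["longest", "shortest"]


@dataclass(frozen=True)
class OQuaREMetrics:
    tangledness: float
    weighted_method_count: float
    depth_of_hierarchy: int
    n_classes: int
    n_leaves: int


def _depth_table(graph: OntologyGraph, convention: DepthConvention) -> dict[str, int]:
    pick = max if convention == "longest" else min
    depth: dict[str, int] = {graph.root: 0}
    # iterative DFS with memoisation (graphs can be deep)
    def compute(cid: str) -> int:
        stack = [cid]
        while stack:
            c = stack[-1]
            if c in depth:
                stack.pop()
                continue
            parents = graph.parents(c, (IS_A,))
            pending = [p for p in parents if p not in depth]
            if pending:
                stack.extend(pending)
            else:
                depth[c] = pick(depth[p] for p in parents) + 1
                stack.pop()
        return depth[cid]

    for c in graph.classes:
        compute(c)
    return depth


def class_depth(
    graph: OntologyGraph, class_id: str, convention: DepthConvention = "longest"
) -> int:
    """is_a distance from the root (longest path by default, root = 0)."""
    if class_id not in graph.classes:
        raise UnknownClassError(f"unknown class {class_id!r}")
    return _depth_table(graph, convention)[class_id]


def compute_oquare(
    graph: OntologyGraph,
    restrict_to: Collection[str] | None = None,
    convention: DepthConvention = "longest",
) -> OQuaREMetrics:
    """Compute TMOnto, WMCOnto and DITOnto on a rooted DAG.

    ``restrict_to`` intersects the class and leaf sets with the given
    subset (depths are still measured in the full graph) — used to score
    only the newly created compound classes of a combined ontology.
    """
    universe = set(graph.classes)
    if restrict_to is not None:
        unknown = set(restrict_to) - universe
        if unknown:
            raise UnknownClassError(f"unknown classes in restrict_to: {sorted(unknown)[:3]}")
        universe &= set(restrict_to)
    if not universe:
        raise ValueError("empty class set")

    multi = sum(1 for c in universe if len(graph.parents(c, (IS_A,))) > 1)
    tangledness = multi / len(universe)

    leaves = graph.leaves() & universe
    depths = _depth_table(graph, convention)
    if leaves:
        leaf_depths = [depths[c] for c in sorted(leaves)]
        wmc = sum(leaf_depths) / len(leaf_depths)
        dit = max(leaf_depths)
    else:  # restricted set with no leaves: fall back to the set itself
        sub = [depths[c] for c in sorted(universe)]
        wmc = sum(sub) / len(sub)
        dit = max(sub)
    return OQuaREMetrics(
        tangledness=tangledness,
        weighted_method_count=wmc,
        depth_of_hierarchy=dit,
        n_classes=len(universe),
        n_leaves=len(leaves),
    )
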