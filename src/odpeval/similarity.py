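"""Information content, Resnik similarity and best-match-average.

The information content (IC) of a class is the negative natural log of
its annotation probability in a corpus, where a class's probability
accumulates the counts of all its is_a descendants, so the root always
has probability 1 and IC 0.  Resnik similarity of two classes is the IC
of their most informative common ancestor (MICA).  Mouse-to-mouse
similarity is the best-match average (BMA): every annotation in either
set is matched to its best counterpart in the other set and the matches
are averaged over both directions,

    sim(m1, m2) = ( Σ_i max_j s(p1i, p2j) + Σ_i max_j s(p2i, p1j) ) / (m1 + m2).

Counting convention: the corpus counts each distinct class once per
mouse (annotation sets are deduplicated), so repeated necropsy line
items for one animal do not inflate a class's probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import AnnotationView
from .ontology import IS_A, OntologyGraph, UnknownClassError, ancestors

__all__ = [
    "ICTable",
    "SimilarityMatrix",
    "compute_ic",
    "resnik",
    "most_informative_common_ancestor",
    "bma",
    "similarity_matrix",
]


@dataclass
class ICTable:
    graph: OntologyGraph
    count: dict[str, int]          # direct annotation counts
    cumulative: dict[str, int]     # summed over is_a descendants-or-self
    total: int                     # corpus size N
    ic: dict[str, float]           # nats
    smoothed: set[str] = field(default_factory=set)

    def __getitem__(self, class_id: str) -> float:
        return self.ic[class_id]


@dataclass
class SimilarityMatrix:
    mouse_ids: list[str]
    values: np.ndarray
    view: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.mouse_ids), len(self.mouse_ids)):
            raise ValueError("matrix shape does not match the mouse list")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if (v < 0).any():
            raise ValueError("similarities must be non-negative")
        self.values = v

    def reorder(self, mouse_ids: Sequence[str]) -> "SimilarityMatrix":
        idx = [self.mouse_ids.index(m) for m in mouse_ids]
        return SimilarityMatrix(
            list(mouse_ids), self.values[np.ix_(idx, idx)], self.view
        )


def compute_ic(view: AnnotationView, log_base: float | None = None) -> ICTable:
    """Build the information-content table for one annotation view.

    Classes never annotated (zero cumulative count) get the floor
    probability 1/N, are flagged in ``smoothed`` and are skipped when
    searching for a MICA.
    """
    if not view.annotations:
        raise ValueError("empty corpus: no annotated mice")
    graph = view.graph
    count: dict[str, int] = {c: 0 for c in graph.classes}
    total = 0
    for classes in view.annotations.values():
        for c in classes:
            count[c] += 1
            total += 1
    cumulative = {c: 0 for c in graph.classes}
    for c, n in count.items():
        if n:
            for a in ancestors(graph, c, (IS_A,), reflexive=True):
                cumulative[a] += n
    log = math.log if log_base is None else (lambda x: math.log(x, log_base))
    ic: dict[str, float] = {}
    smoothed: set[str] = set()
    for c in graph.classes:
        n = cumulative[c]
        if n == 0:
            smoothed.add(c)
            n = 1
        ic[c] = max(0.0, -log(n / total))
    return ICTable(
        graph=graph, count=count, cumulative=cumulative, total=total,
        ic=ic, smoothed=smoothed,
    )


def most_informative_common_ancestor(
    ic: ICTable, x1: str, x2: str
) -> tuple[str, float]:
    """The common is_a ancestor (reflexive) with maximal IC, and its IC.

    Ties break lexicographically on the class ID; smoothed (never
    annotated) classes are not eligible unless no informative common
    ancestor exists, in which case the root is returned with IC 0.
    """
    g = ic.graph
    common = ancestors(g, x1, (IS_A,), reflexive=True) & ancestors(
        g, x2, (IS_A,), reflexive=True
    )
    eligible = common - ic.smoothed
    if not eligible:
        return g.root, 0.0
    best = min(eligible, key=lambda c: (-ic.ic[c], c))
    return best, ic.ic[best]


def resnik(ic: ICTable, x1: str, x2: str) -> float:
    """IC of the most informative common ancestor of the two classes."""
    for x in (x1, x2):
        if x not in ic.graph.classes:
            raise UnknownClassError(f"unknown class {x!r}")
    return most_informative_common_ancestor(ic, x1, x2)[1]


def bma(ic: ICTable, set1, set2) -> float:
    """Best-match-average similarity between two annotation sets."""
    s1, s2 = sorted(set1), sorted(set2)
    if not s1 or not s2:
        raise ValueError("annotation sets must be non-empty")
    fwd = sum(max(resnik(ic, a, b) for b in s2) for a in s1)
    bwd = sum(max(resnik(ic, b, a) for a in s1) for b in s2)
    return (fwd + bwd) / (len(s1) + len(s2))


def _class_sim_matrix(ic: ICTable, used: list[str]) -> np.ndarray:
    """Pairwise Resnik similarity for the classes actually annotated."""
    g = ic.graph
    anc = [
        frozenset(ancestors(g, c, (IS_A,), reflexive=True)) - ic.smoothed
        for c in used
    ]
    n = len(used)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            common = anc[i] & anc[j]
            val = max((ic.ic[c] for c in common), default=0.0)
            out[i, j] = out[j, i] = val
    return out


def similarity_matrix(
    view: AnnotationView, mice: Sequence[str], ic: ICTable | None = None
) -> SimilarityMatrix:
    """Pairwise BMA similarity over the given mice (symmetric, ordered)."""
    if ic is None:
        ic = compute_ic(view)
    missing = [m for m in mice if m not in view.annotations]
    if missing:
        raise KeyError(f"mice missing from view: {missing[:3]}")
    used = sorted({c for m in mice for c in view.annotations[m]})
    index = {c: k for k, c in enumerate(used)}
    csim = _class_sim_matrix(ic, used)
    idx_sets = [np.array([index[c] for c in sorted(view.annotations[m])]) for m in mice]
    n = len(mice)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            block = csim[np.ix_(idx_sets[i], idx_sets[j])]
            s = block.max(axis=1).sum() + block.max(axis=0).sum()
            values[i, j] = values[j, i] = s / (len(idx_sets[i]) + len(idx_sets[j]))
    return SimilarityMatrix(list(mice), values, view.view)


def write_matrix_tsv(matrix: SimilarityMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("mouse_id\t" + "\t".join(matrix.mouse_ids) + "\n")
        for m, row in zip(matrix.mouse_ids, matrix.values):
            fh.write(m + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
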