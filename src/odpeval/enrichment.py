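"""Strain over-representation analysis and cross-view rank comparison.

For each ontology class, a one-sided hypergeometric test asks whether
mice of one strain carry the (ancestor-propagated) annotation more often
than the rest of the cohort.  Family-wise error rates are estimated by
the random-set procedure: the case/control labels are permuted many
times, the minimum p-value over all classes is recorded for each
permutation, and a class's FWER is the fraction of permutations whose
minimum p-value is at least as small as that class's observed p-value.
Rank lists produced under different ontology views are compared with
Kendall's tau-b.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AnnotationView, Cohort
from .ontology import IS_A, ancestors
from .patterns import TOP_ID

__all__ = [
    "EnrichmentResult",
    "propagate",
    "hypergeometric_pvalue",
    "enrich_strain",
    "kendall_tau_b",
    "paired_class_ranks",
]


@dataclass
class EnrichmentResult:
    strain: str
    view: str
    classes: list[str]
    raw_p: dict[str, float]
    fwer: dict[str, float]
    rank: dict[str, int]  # 1 = most significant; ties broken by class ID
    n_random_sets: int
    n_case: int
    n_total: int

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.classes, key=lambda c: self.rank[c])
        return pd.DataFrame(
            {
                "class_id": rows,
                "raw_p": [self.raw_p[c] for c in rows],
                "fwer": [self.fwer[c] for c in rows],
                "rank": [self.rank[c] for c in rows],
            }
        )


def propagate(view: AnnotationView) -> AnnotationView:
    """Close every mouse's annotations under is_a ancestors (reflexive).

    A shared top node (an ``owl:Thing`` stand-in) is added above every
    view's root so that all six views hang from the same top; the
    operation is idempotent.
    """
    graph = view.graph
    cache: dict[str, frozenset[str]] = {}

    def closure(c: str) -> frozenset[str]:
        if c not in cache:
            if c == TOP_ID:
                cache[c] = frozenset({TOP_ID})
            else:
                cache[c] = frozenset(
                    ancestors(graph, c, (IS_A,), reflexive=True) | {TOP_ID}
                )
        return cache[c]

    annotations = {
        m: frozenset().union(*(closure(c) for c in classes))
        for m, classes in view.annotations.items()
    }
    out = AnnotationView(view=view.view, graph=graph, annotations=annotations)
    return out


def hypergeometric_pvalue(K: int, n: int, k: int, M: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(M, K, n).

    ``M`` mice in total, ``K`` of them annotated with the class, ``n``
    in the strain, ``k`` of the strain annotated.
    """
    if not (0 <= k <= min(K, n) <= M) or n > M or K > M:
        raise ValueError(
            f"inconsistent counts: M={M}, K={K}, n={n}, k={k}"
        )
    return float(stats.hypergeom.sf(k - 1, M, K, n))


def _annotation_matrix(
    view: AnnotationView, mice: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    classes = sorted({c for m in mice for c in view.annotations[m]})
    index = {c: j for j, c in enumerate(classes)}
    mat = np.zeros((len(mice), len(classes)), dtype=bool)
    for i, m in enumerate(mice):
        for c in view.annotations[m]:
            mat[i, index[c]] = True
    return mat, classes


def _pvalues(mat: np.ndarray, case: np.ndarray, M: int, n: int) -> np.ndarray:
    K = mat.sum(axis=0)
    k = mat[case].sum(axis=0)
    return stats.hypergeom.sf(k - 1, M, K, n)


def enrich_strain(
    view: AnnotationView,
    cohort: Cohort,
    strain: str,
    n_random: int = 1000,
    seed: int = 0,
    already_propagated: bool = False,
) -> EnrichmentResult:
    """Per-class over-representation of one strain versus the rest."""
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    pview = view if already_propagated else propagate(view)
    mice = sorted(pview.annotations)
    case = np.array([cohort.strain_of(m) == strain for m in mice])
    n, M = int(case.sum()), len(mice)
    if n == 0:
        raise ValueError(f"strain {strain!r} has no mice in the view")
    if n == M:
        raise ValueError("control group is empty")

    mat, classes = _annotation_matrix(pview, mice)
    raw = _pvalues(mat, case, M, n)

    rng = np.random.default_rng(seed)
    min_ps = np.empty(n_random)
    idx = np.arange(M)
    for r in range(n_random):
        perm = rng.permutation(idx)[:n]
        pcase = np.zeros(M, dtype=bool)
        pcase[perm] = True
        min_ps[r] = _pvalues(mat, pcase, M, n).min()
    fwer = {
        c: float((min_ps <= raw[j]).mean()) for j, c in enumerate(classes)
    }

    order = sorted(range(len(classes)), key=lambda j: (raw[j], classes[j]))
    rank = {classes[j]: r + 1 for r, j in enumerate(order)}
    return EnrichmentResult(
        strain=strain,
        view=view.view,
        classes=list(classes),
        raw_p={c: float(raw[j]) for j, c in enumerate(classes)},
        fwer=fwer,
        rank=rank,
        n_random_sets=n_random,
        n_case=n,
        n_total=M,
    )


def kendall_tau_b(ranks1: Mapping, ranks2: Mapping) -> float:
    """Kendall's tau-b between two rankings of the same key set."""
    if set(ranks1) != set(ranks2):
        raise KeyError("rankings must cover the same key set")
    keys = sorted(ranks1)
    if len(keys) < 2:
        raise ValueError("need at least two ranked items")
    a = [ranks1[k] for k in keys]
    b = [ranks2[k] for k in keys]
    tau, _ = stats.kendalltau(a, b, variant="b")
    return float(tau)


def paired_class_ranks(
    results1: Sequence[EnrichmentResult],
    results2: Sequence[EnrichmentResult],
    decompose1: Mapping[str, tuple[str, str]],
    decompose2: Mapping[str, tuple[str, str]],
    per_strain: bool = False,
):
    """Pool enrichment ranks from two views onto shared keys.

    Keys are (strain, anatomy ID, pathology ID) triples; classes that do
    not decompose to a pair in both views (e.g. backbone classes pulled
    in by propagation) are dropped.  Returns the two keyed rank dicts,
    or a per-strain mapping of them when ``per_strain`` is set.
    """
    def keyed(results, decompose):
        out: dict[tuple, int] = {}
        for res in results:
            for c, r in res.rank.items():
                pair = decompose.get(c)
                if pair is not None:
                    out[(res.strain, *pair)] = r
        return out

    r1, r2 = keyed(results1, decompose1), keyed(results2, decompose2)
    shared = set(r1) & set(r2)
    r1 = {k: v for k, v in r1.items() if k in shared}
    r2 = {k: v for k, v in r2.items() if k in shared}
    if not per_strain:
        return r1, r2
    strains = {k[0] for k in shared}
    return {
        s: (
            {k: v for k, v in r1.items() if k[0] == s},
            {k: v for k, v in r2.items() if k[0] == s},
        )
        for s in strains
    }
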