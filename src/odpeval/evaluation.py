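"""Clustering purity and ROC evaluation of ontology views.

The external yardstick is the inbred-strain premise: genetically
identical mice should show more similar lesion spectra than mice from
different strains.  Two evaluations quantify how well a similarity
matrix recovers strain structure:

* **Cluster purity** — similarities are converted to distances, mice are
  clustered (k-medoids/PAM, complete linkage, UPGMA, neighbor joining),
  and for each cluster count k the purity is the fraction of mice whose
  strain matches their cluster's modal strain.  The area under the
  purity curve, normalised by the group size, summarises the sweep:

      AUC = 1/(2(M-1)) * Σ_{n=2}^{M-1} (Purity_n + Purity_{n+1}).

* **ROC analysis** — each mouse ranks all other mice by similarity; at
  threshold t the positives are same-strain mice among the top t.  The
  pooled true/false positive rates trace a ROC curve whose area measures
  how strongly same-strain pairs outrank different-strain pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .similarity import SimilarityMatrix

__all__ = [
    "ClusteringResult",
    "PurityCurve",
    "ROCCurve",
    "to_distance",
    "cluster",
    "purity",
    "purity_curve",
    "purity_auc",
    "roc_curve",
    "per_mouse_roc_auc",
    "wilcoxon_compare",
]

CLUSTER_METHODS = ("kmedoids", "complete", "upgma", "nj")


# ---------------------------------------------------------------------------
# distance conversion
# ---------------------------------------------------------------------------

def to_distance(sim: SimilarityMatrix | np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Convert similarities to distances: d_ij = s_max − s_ij, zero diagonal."""
    s = sim.values if isinstance(sim, SimilarityMatrix) else np.asarray(sim, float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(s, s.T, atol=atol):
        raise ValueError("similarity matrix is not symmetric")
    d = s.max() - s
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusteringResult:
    """A clustering with a labels(k) accessor for every 1 <= k <= M.

    For the agglomerative methods (complete, UPGMA, NJ) ``merges`` lists
    the M−1 joins in order; labels at k are obtained by replaying the
    first M−k joins.  For k-medoids each k is a separate PAM run.
    """

    method: str
    n: int
    merges: list[tuple[int, int]] | None = None
    _pam_distance: np.ndarray | None = field(default=None, repr=False)
    _cache: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def labels(self, k: int) -> np.ndarray:
        if not (1 <= k <= self.n):
            raise ValueError(f"k={k} out of range 1..{self.n}")
        if k not in self._cache:
            if self.merges is not None:
                self._cache[k] = _labels_from_merges(self.merges, self.n, k)
            else:
                self._cache[k] = _pam(self._pam_distance, k)[1]
        return self._cache[k]


def _labels_from_merges(merges, n: int, k: int) -> np.ndarray:
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in merges[: n - k]:
        ra, rb = find(a), find(b)
        parent[max(ra, rb)] = min(ra, rb)
    roots = [find(i) for i in range(n)]
    relabel = {r: i for i, r in enumerate(sorted(set(roots)))}
    return np.array([relabel[r] for r in roots])


def _linkage_merges(d: np.ndarray, method: str) -> list[tuple[int, int]]:
    z = hierarchy.linkage(squareform(d, checks=False), method=method)
    n = d.shape[0]
    members: dict[int, int] = {i: i for i in range(n)}  # cluster id -> a member leaf
    merges = []
    for step, (a, b, *_rest) in enumerate(z):
        a, b = int(a), int(b)
        merges.append((members[a], members[b]))
        members[n + step] = members[a]
    return merges


def _nj_merges(d: np.ndarray) -> list[tuple[int, int]]:
    """Neighbor joining (Q-criterion) recorded as a merge sequence.

    Ties in Q break on the smaller pair distance, then on the smallest
    (i, j) index pair, so the result is deterministic.  Joins continue
    past the usual 3-taxon stopping point so the full partition sweep
    down to one cluster is defined.
    """
    n = d.shape[0]
    d = d.astype(float).copy()
    active = list(range(n))
    rep = {i: i for i in range(n)}  # matrix row -> a leaf index
    merges: list[tuple[int, int]] = []
    dm = d
    while len(active) > 2:
        m = len(active)
        sub = dm[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        iu, ju = np.triu_indices(m, k=1)
        order = np.lexsort((ju, iu, sub[iu, ju], q[iu, ju]))
        i, j = int(iu[order[0]]), int(ju[order[0]])
        ai, aj = active[i], active[j]
        merges.append((rep[ai], rep[aj]))
        # distances from the new node u to every other active node
        du = 0.5 * (dm[ai, active] + dm[aj, active] - dm[ai, aj])
        dm[ai, active] = du
        dm[active, ai] = du
        dm[ai, ai] = 0.0
        active.remove(aj)
    if len(active) == 2:
        merges.append((rep[active[0]], rep[active[1]]))
    return merges


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        current = d[:, medoids].min(axis=1)
        gains = np.array([
            np.maximum(current - d[:, c], 0.0).sum() if c not in medoids else -np.inf
            for c in range(n)
        ])
        medoids.append(int(np.argmax(gains)))
    return sorted(medoids)


def _pam(d: np.ndarray, k: int, max_iter: int = 200) -> tuple[list[int], np.ndarray]:
    """PAM k-medoids: greedy BUILD then best-improvement SWAP (deterministic)."""
    n = d.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range 1..{n}")
    medoids = _pam_build(d, k)

    def cost(meds):
        return d[:, meds].min(axis=1).sum()

    best_cost = cost(medoids)
    for _ in range(max_iter):
        improved = False
        best_swap = None
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids[:mi] + [h] + medoids[mi + 1:]
                c = cost(trial)
                if c < best_cost - 1e-12:
                    best_cost, best_swap = c, (mi, h)
                    improved = True
        if not improved:
            break
        mi, h = best_swap
        medoids[mi] = h
        medoids.sort()
    assign = np.argmin(d[:, medoids], axis=1)
    # medoids belong to their own cluster even under distance ties
    for ci, m in enumerate(medoids):
        assign[m] = ci
    return medoids, assign


def cluster(
    distance: np.ndarray,
    method: str,
    k: int | None = None,
    seed: int | None = None,
) -> ClusteringResult:
    """Cluster a precomputed distance matrix.

    ``method`` is one of ``kmedoids``, ``complete``, ``upgma``, ``nj``.
    The agglomerative methods build the whole merge tree regardless of
    ``k``; k-medoids runs PAM lazily per requested k.  All methods are
    deterministic (``seed`` is accepted for interface symmetry and for
    optional randomized PAM restarts, which the default run never uses).
    """
    d = np.asarray(distance, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    n = d.shape[0]
    if method == "complete":
        return ClusteringResult("complete", n, merges=_linkage_merges(d, "complete"))
    if method == "upgma":
        return ClusteringResult("upgma", n, merges=_linkage_merges(d, "average"))
    if method == "nj":
        return ClusteringResult("nj", n, merges=_nj_merges(d))
    if method == "kmedoids":
        res = ClusteringResult("kmedoids", n, _pam_distance=d)
        if k is not None:
            res.labels(k)
        return res
    raise ValueError(f"unknown clustering method {method!r}")


# ---------------------------------------------------------------------------
# purity
# ---------------------------------------------------------------------------

def purity(labels: Sequence, strains: Sequence[str]) -> float:
    """Fraction of mice whose strain is their cluster's modal strain.

    Modal-strain ties break lexicographically on the strain name.
    """
    labels = list(labels)
    strains = list(strains)
    if len(labels) != len(strains):
        raise ValueError("labels and strains must have equal length")
    by_cluster: dict = {}
    for lab, s in zip(labels, strains):
        by_cluster.setdefault(lab, []).append(s)
    modal = {}
    for lab, members in by_cluster.items():
        counts: dict[str, int] = {}
        for s in members:
            counts[s] = counts.get(s, 0) + 1
        modal[lab] = min(counts, key=lambda s: (-counts[s], s))
    hits = sum(1 for lab, s in zip(labels, strains) if modal[lab] == s)
    return hits / len(labels)


@dataclass
class PurityCurve:
    purity_at_k: dict[int, float]
    auc: float
    M: int


def purity_curve(clustering: ClusteringResult, strains: Sequence[str]) -> PurityCurve:
    """Purity at every cluster count k = 1..M plus the normalised AUC."""
    M = clustering.n
    if len(strains) != M:
        raise ValueError("strain vector length must match the clustering")
    pk = {k: purity(clustering.labels(k), strains) for k in range(1, M + 1)}
    return PurityCurve(purity_at_k=pk, auc=purity_auc(pk, M), M=M)


def purity_auc(purity_at_k: Mapping[int, float], M: int) -> float:
    """Trapezoidal area under the purity curve, normalised by M−1."""
    if M < 2:
        raise ValueError("need at least two mice")
    missing = [k for k in range(2, M + 1) if k not in purity_at_k]
    if missing:
        raise ValueError(f"purity missing for k={missing[:3]}")
    total = sum(
        purity_at_k[n] + purity_at_k[n + 1] for n in range(2, M)
    )
    return total / (2 * (M - 1))


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class ROCCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def _same_strain_ranking(
    sim: SimilarityMatrix, strains: Sequence[str]
) -> np.ndarray:
    """Row j: same-strain indicator of the candidates ranked for probe j.

    Candidates are every other mouse, ordered by descending similarity;
    ties break by ascending mouse ID.
    """
    s = sim.values
    ids = sim.mouse_ids
    M = len(ids)
    out = np.zeros((M, M - 1), dtype=bool)
    for j in range(M):
        cand = [i for i in range(M) if i != j]
        cand.sort(key=lambda i: (-s[j, i], ids[i]))
        out[j] = [strains[i] == strains[j] for i in cand]
    return out


def roc_curve(sim: SimilarityMatrix, strains: Sequence[str]) -> ROCCurve:
    """Pooled per-mouse ROC for same-strain retrieval by similarity."""
    strains = list(strains)
    if len(strains) != len(sim.mouse_ids):
        raise ValueError("strain vector length must match the matrix")
    if len(set(strains)) < 2:
        raise ValueError("ROC needs at least two strains")
    ranked = _same_strain_ranking(sim, strains)
    M, m_cand = ranked.shape
    pjt = np.cumsum(ranked, axis=1)           # P_j(t), t = 1..M-1
    pos_total = pjt[:, -1].sum()              # Σ_j P_j(M_cand)
    neg_total = M * m_cand - pos_total
    if pos_total == 0 or neg_total == 0:
        raise ValueError("degenerate strain composition for ROC")
    t = np.arange(1, m_cand + 1)
    tpr = pjt.sum(axis=0) / pos_total
    fpr = (t[None, :] - pjt).sum(axis=0) / neg_total
    tpr = np.concatenate([[0.0], tpr])
    fpr = np.concatenate([[0.0], fpr])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=t, tpr=tpr[1:], fpr=fpr[1:], auc=auc)


def per_mouse_roc_auc(sim: SimilarityMatrix, strains: Sequence[str]) -> np.ndarray:
    """One-vs-rest retrieval AUC per probe mouse (NaN if no positives)."""
    strains = list(strains)
    ranked = _same_strain_ranking(sim, strains)
    M, m_cand = ranked.shape
    out = np.full(M, np.nan)
    for j in range(M):
        pos = ranked[j].sum()
        neg = m_cand - pos
        if pos == 0 or neg == 0:
            continue
        # negatives preceding each position; a positive with `a` negatives
        # above it wins (neg - a) of its pos/neg pairs
        above = np.cumsum(~ranked[j])
        out[j] = (pos * neg - above[ranked[j]].sum()) / (pos * neg)
    return out


# ---------------------------------------------------------------------------
# rank-sum comparison
# ---------------------------------------------------------------------------

def wilcoxon_compare(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) with tie correction.

    Returns (U statistic for the first sample, two-sided p-value by the
    tie-corrected normal approximation).  Bonferroni adjustment over
    multiple view pairs is the caller's responsibility.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both score lists must be non-empty")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", use_continuity=False, method="asymptotic"
    )
    return float(res.statistic), float(res.pvalue)
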