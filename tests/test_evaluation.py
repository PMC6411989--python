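import itertools

import numpy as np
import pytest

from odpeval import (
    SimilarityMatrix,
    cluster,
    per_mouse_roc_auc,
    purity,
    purity_auc,
    purity_curve,
    roc_curve,
    to_distance,
    wilcoxon_compare,
)


def simmat(values, ids=None):
    values = np.asarray(values, float)
    ids = ids or [f"m{i}" for i in range(len(values))]
    return SimilarityMatrix(ids, values, "MA")


class TestToDistance:
    def test_constant_matrix_gives_zero(self):
        d = to_distance(simmat(np.full((3, 3), 2.0)))
        assert np.all(d == 0)

    def test_two_by_two(self):
        d = to_distance(simmat([[2, 1], [1, 2]]))
        assert np.allclose(d, [[0, 1], [1, 0]])

    def test_nonnegative_on_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            v = rng.random((6, 6))
            d = to_distance(simmat((v + v.T) / 2))
            assert (d >= 0).all()
            assert np.allclose(np.diag(d), 0)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            to_distance(np.array([[0.0, 1.0], [2.0, 0.0]]))


def blob_distance():
    """Two well-separated triples: within 0, between 1."""
    d = np.ones((6, 6))
    d[:3, :3] = 0
    d[3:, 3:] = 0
    np.fill_diagonal(d, 0)
    return d


class TestCluster:
    @pytest.mark.parametrize("method", ["kmedoids", "complete", "upgma", "nj"])
    def test_two_blobs_recovered(self, method):
        labels = cluster(blob_distance(), method).labels(2)
        assert len(set(labels)) == 2
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_complete_linkage_first_merge_is_minimum_pair(self):
        d = np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0]], float)
        res = cluster(d, "complete")
        assert set(res.merges[0]) == {0, 1}

    def test_upgma_recovers_ultrametric_topology(self):
        # tree: ((a,b),(c,d)) with heights 1 and 2, root height 4
        d = np.array(
            [[0, 2, 8, 8],
             [2, 0, 8, 8],
             [8, 8, 0, 4],
             [8, 8, 4, 0]], float,
        )
        res = cluster(d, "upgma")
        assert set(res.merges[0]) == {0, 1}
        assert set(res.merges[1]) == {2, 3}

    def test_labels_counts_full_sweep(self):
        rng = np.random.default_rng(1)
        v = rng.random((7, 7))
        d = to_distance(simmat((v + v.T) / 2))
        for method in ("complete", "upgma", "nj"):
            res = cluster(d, method)
            for k in range(1, 8):
                assert len(set(res.labels(k))) == k
        res = cluster(d, "kmedoids")
        for k in range(1, 8):
            assert len(set(res.labels(k))) == k

    def test_nj_matches_reference_tree_grouping(self):
        # additive tree ((a:1,b:2):1,(c:3,d:4):1) -> NJ must pair (a,b), (c,d)
        d = np.array(
            [[0, 3, 5, 6],
             [3, 0, 6, 7],
             [5, 6, 0, 7],
             [6, 7, 7, 0]], float,
        )
        res = cluster(d, "nj")
        first = set(res.merges[0])
        assert first in ({0, 1}, {2, 3})
        assert set(res.labels(2)[:2]) != set(res.labels(2)[2:])

    def test_k_out_of_range(self):
        res = cluster(blob_distance(), "complete")
        with pytest.raises(ValueError):
            res.labels(0)
        with pytest.raises(ValueError):
            res.labels(7)


class TestPurity:
    def test_direct_example(self):
        labels = [1, 1, 1, 2, 2]
        strains = ["a", "a", "b", "b", "b"]
        assert purity(labels, strains) == pytest.approx(0.8)

    def test_singletons_are_pure(self):
        assert purity(range(5), list("abcab")) == 1.0

    def test_single_cluster_max_fraction(self):
        assert purity([0, 0, 0, 0], ["a", "a", "a", "b"]) == pytest.approx(0.75)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            purity([0, 1], ["a"])

    def test_modal_tie_breaks_lexicographically(self):
        assert purity([0, 0], ["b", "a"]) == pytest.approx(0.5)
        # the "a" mouse is the one counted correct
        assert purity([0, 0, 1], ["b", "a", "b"]) == pytest.approx(2 / 3)


class TestPurityAUC:
    def test_worked_example(self):
        assert purity_auc({2: 0.5, 3: 0.75, 4: 1.0}, 4) == pytest.approx(0.5)

    def test_constant_curve_closed_form(self):
        for M, c in ((5, 0.6), (10, 0.3), (25, 1.0)):
            pk = {k: c for k in range(2, M + 1)}
            assert purity_auc(pk, M) == pytest.approx(c * (M - 2) / (M - 1))

    def test_matches_trapezoid_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            M = int(rng.integers(3, 30))
            pk = {k: float(rng.random()) for k in range(2, M + 1)}
            ks = np.arange(2, M + 1)
            ys = np.array([pk[k] for k in ks])
            expected = np.trapezoid(ys, ks) / (M - 1)
            assert purity_auc(pk, M) == pytest.approx(expected, abs=1e-12)

    def test_missing_k_rejected(self):
        with pytest.raises(ValueError):
            purity_auc({2: 0.5, 4: 1.0}, 4)

    def test_perfect_purity_approaches_one(self):
        M = 200
        pk = {k: 1.0 for k in range(2, M + 1)}
        assert 0.99 < purity_auc(pk, M) < 1.0

    def test_monotone_along_hierarchical_sweep(self):
        rng = np.random.default_rng(5)
        v = rng.random((12, 12))
        d = to_distance(simmat((v + v.T) / 2))
        strains = list("aaabbbcccddd")
        for method in ("complete", "upgma"):
            res = cluster(d, method)
            pc = purity_curve(res, strains)
            ks = sorted(pc.purity_at_k)
            diffs = np.diff([pc.purity_at_k[k] for k in ks])
            assert (diffs >= -1e-12).all()


def oracle_roc_auc(sim, strains):
    """Pooled pair-ordering probability (ties at equal rank count half)."""
    s, ids = sim.values, sim.mouse_ids
    M = len(ids)
    ranked = []
    for j in range(M):
        cand = sorted((i for i in range(M) if i != j),
                      key=lambda i: (-s[j, i], ids[i]))
        ranked.append([strains[i] == strains[j] for i in cand])
    num = den = 0.0
    for r1, r2 in itertools.product(range(M - 1), repeat=2):
        P = sum(row[r1] for row in ranked)
        N = sum(not row[r2] for row in ranked)
        if r1 < r2:
            num += P * N
        elif r1 == r2:
            num += 0.5 * P * N
        den += P * N
    return num / den


class TestROC:
    def perfect(self):
        # strain-mates strictly more similar than everyone else
        v = np.array(
            [[1.0, 0.9, 0.1, 0.2],
             [0.9, 1.0, 0.2, 0.1],
             [0.1, 0.2, 1.0, 0.9],
             [0.2, 0.1, 0.9, 1.0]]
        )
        return simmat(v), ["s1", "s1", "s2", "s2"]

    def test_perfect_separation(self):
        sim, strains = self.perfect()
        assert roc_curve(sim, strains).auc == pytest.approx(1.0)

    def test_first_threshold_rates(self):
        sim, strains = self.perfect()
        curve = roc_curve(sim, strains)
        assert curve.tpr[0] == pytest.approx(1.0)
        assert curve.fpr[0] == pytest.approx(0.0)

    def test_terminal_rates_are_one(self):
        rng = np.random.default_rng(0)
        v = rng.random((8, 8))
        sim = simmat((v + v.T) / 2)
        curve = roc_curve(sim, list("aabbccdd"))
        assert curve.tpr[-1] == pytest.approx(1.0)
        assert curve.fpr[-1] == pytest.approx(1.0)
        assert (np.diff(curve.tpr) >= -1e-12).all()
        assert (np.diff(curve.fpr) >= -1e-12).all()

    def test_matches_pair_ordering_oracle_exhaustively(self):
        rng = np.random.default_rng(42)
        done = 0
        while done < 15:
            v = rng.random((6, 6))
            strains = [str(x) for x in rng.integers(0, 3, size=6)]
            if len(set(strains)) < 2:
                continue
            counts = {s: strains.count(s) for s in strains}
            if all(c == 1 for c in counts.values()):
                continue
            sim = simmat((v + v.T) / 2)
            assert roc_curve(sim, strains).auc == pytest.approx(
                oracle_roc_auc(sim, strains), abs=1e-12
            )
            done += 1

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(7)
        aucs = []
        for _ in range(20):
            v = rng.random((20, 20))
            sim = simmat((v + v.T) / 2)
            strains = rng.permutation(list("aaaaabbbbbcccccddddd")).tolist()
            aucs.append(roc_curve(sim, strains).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_single_strain_rejected(self):
        sim = simmat(np.eye(3))
        with pytest.raises(ValueError):
            roc_curve(sim, ["a", "a", "a"])


class TestPerMouseAUC:
    def test_perfect_probe(self):
        v = np.array(
            [[1.0, 0.9, 0.1, 0.2],
             [0.9, 1.0, 0.2, 0.1],
             [0.1, 0.2, 1.0, 0.9],
             [0.2, 0.1, 0.9, 1.0]]
        )
        aucs = per_mouse_roc_auc(simmat(v), ["s1", "s1", "s2", "s2"])
        assert np.allclose(aucs, 1.0)

    def test_no_strainmates_gives_nan(self):
        v = np.eye(3) + 0.1
        aucs = per_mouse_roc_auc(simmat((v + v.T) / 2), ["a", "b", "c"])
        assert np.isnan(aucs).all()


class TestWilcoxon:
    def test_identical_samples(self):
        a = list(range(10))
        u, p = wilcoxon_compare(a, a)
        assert u == pytest.approx(50.0)  # n1*n2/2
        assert p == pytest.approx(1.0)

    def test_separated_samples(self):
        a = np.arange(20) + 100.0
        b = np.arange(20.0)
        _, p = wilcoxon_compare(a, b)
        assert p < 1e-3

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.random(15), rng.random(12) + 0.2
        ua, pa = wilcoxon_compare(a, b)
        ub, pb = wilcoxon_compare(b, a)
        assert pa == pytest.approx(pb)
        assert ua + ub == pytest.approx(len(a) * len(b))
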