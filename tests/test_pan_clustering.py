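"""Distances, agglomeration against an exact rational oracle, and cuts."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from flabkit import (
    PresenceMatrix,
    ValidationError,
    binary_distance,
    evaluate_focal_cluster,
    hierarchical_cluster,
    sweep_focal_cluster,
)
from flabkit.pan_clustering import Dendrogram

from conftest import random_presence


class TestBinaryDistance:
    def test_identical_profiles_distance_zero(self, toy_presence):
        df = toy_presence.values.copy()
        df["F"] = df["A"]
        d = binary_distance(PresenceMatrix(df), "jaccard")
        assert d.loc["A", "F"] == 0.0

    def test_disjoint_profiles_jaccard_one(self):
        df = pd.DataFrame({"A": [1, 1, 0, 0], "B": [0, 0, 1, 1]},
                          index=["K1", "K2", "K3", "K4"])
        d = binary_distance(PresenceMatrix(df), "jaccard")
        assert d.loc["A", "B"] == 1.0

    def test_hand_enumerated_pair(self):
        # profiles 110 vs 011: intersection 1, union 3, mismatches 2
        df = pd.DataFrame({"A": [1, 1, 0], "B": [0, 1, 1]}, index=["K1", "K2", "K3"])
        pm = PresenceMatrix(df)
        assert binary_distance(pm, "jaccard").loc["A", "B"] == pytest.approx(2 / 3)
        assert binary_distance(pm, "hamming").loc["A", "B"] == pytest.approx(2 / 3)

    def test_empty_profiles_jaccard_zero(self):
        df = pd.DataFrame({"A": [0, 0], "B": [0, 0], "C": [1, 0]}, index=["K1", "K2"])
        d = binary_distance(PresenceMatrix(df), "jaccard")
        assert d.loc["A", "B"] == 0.0

    def test_single_strain_rejected(self):
        df = pd.DataFrame({"A": [1, 0]}, index=["K1", "K2"])
        with pytest.raises(ValidationError):
            binary_distance(PresenceMatrix(df))

    def test_symmetry_and_zero_diagonal(self, small_bundle):
        d = binary_distance(small_bundle.presence)
        assert np.allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)


# ---------------------------------------------------------------------------
# exact rational-arithmetic agglomeration oracle (O(n^3), recomputes every
# cluster pair distance from the original matrix instead of using the
# Lance-Williams update)
# ---------------------------------------------------------------------------


def _fraction_jaccard(mat: np.ndarray) -> dict:
    n = mat.shape[1]
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            inter = int(np.sum(mat[:, i] & mat[:, j]))
            union = int(np.sum(mat[:, i] | mat[:, j]))
            d[(i, j)] = Fraction(union - inter, union) if union else Fraction(0)
    return d


def _oracle_agglomerate(mat: np.ndarray, labels, linkage="average"):
    """Exact agglomeration; returns the cophenetic matrix as Fractions."""
    d0 = _fraction_jaccard(mat)
    n = mat.shape[1]
    clusters = {i: [i] for i in range(n)}
    minlab = {i: labels[i] for i in range(n)}
    coph = {}
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                pairs = [
                    d0[tuple(sorted((i, j)))]
                    for i in clusters[a]
                    for j in clusters[b]
                ]
                if linkage == "average":
                    dist = sum(pairs) / len(pairs)
                else:
                    dist = max(pairs)
                key = (dist, *sorted((minlab[a], minlab[b])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (dist, *_), a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[tuple(sorted((i, j)))] = dist
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        minlab[next_id] = min(minlab[a], minlab[b])
        next_id += 1
    return coph


@pytest.mark.parametrize("linkage", ["average", "complete"])
def test_cophenetic_matches_exact_oracle(linkage):
    """50 random instances, n <= 8: implementation vs rational oracle."""
    rng = np.random.default_rng(1234)
    for _ in range(50):
        n = int(rng.integers(3, 9))
        nf = int(rng.integers(5, 30))
        pm = random_presence(rng, n, nf)
        d = binary_distance(pm, "jaccard")
        dendro = hierarchical_cluster(d, linkage)
        coph = dendro.cophenetic_matrix()
        oracle = _oracle_agglomerate(
            pm.values.to_numpy().astype(bool), pm.strains, linkage
        )
        for (i, j), val in oracle.items():
            a, b = pm.strains[i], pm.strains[j]
            assert coph.loc[a, b] == pytest.approx(float(val), abs=1e-12)


class TestHierarchicalCluster:
    def test_forced_first_merge(self):
        d = pd.DataFrame(
            [[0, 1, 10], [1, 0, 10], [10, 10, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        dendro = hierarchical_cluster(d, "average")
        left, right, h = dendro.merges[0]
        assert {dendro.leaves[left], dendro.leaves[right]} == {"A", "B"}
        assert h == 1.0

    def test_equal_distances_tie_rule(self):
        d = pd.DataFrame(np.ones((4, 4)) - np.eye(4),
                         index=list("DCBA"), columns=list("DCBA"))
        dendro = hierarchical_cluster(d, "average")
        # first merge must pick the lexicographically smallest pair (A, B)
        l, r, h = dendro.merges[0]
        assert sorted((dendro.leaves[l], dendro.leaves[r])) == ["A", "B"]
        assert len(dendro.merges) == 3
        assert all(m[2] == 1.0 for m in dendro.merges)

    def test_non_symmetric_rejected(self):
        d = pd.DataFrame([[0, 1], [2, 0]], index=list("AB"), columns=list("AB"),
                         dtype=float)
        with pytest.raises(ValidationError, match="symmetric"):
            hierarchical_cluster(d)

    @pytest.mark.parametrize("linkage", ["average", "complete", "ward"])
    def test_merge_heights_non_decreasing(self, small_bundle, linkage):
        d = binary_distance(small_bundle.presence)
        dendro = hierarchical_cluster(d, linkage)
        hs = [h for _, _, h in dendro.merges]
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(hs, hs[1:]))

    def test_cophenetic_invariant_under_relabeling(self):
        rng = np.random.default_rng(5)
        pm = random_presence(rng, 7, 40)
        d = binary_distance(pm)
        coph = hierarchical_cluster(d).cophenetic_matrix()
        perm = rng.permutation(7)
        d2 = d.iloc[perm, perm]
        coph2 = hierarchical_cluster(d2).cophenetic_matrix()
        strains = pm.strains
        for a in strains:
            for b in strains:
                assert coph2.loc[a, b] == pytest.approx(coph.loc[a, b], abs=1e-12)

    def test_scipy_cross_check_on_tie_free_instance(self):
        from scipy.cluster.hierarchy import cophenet, linkage as scipy_linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(99)
        pm = random_presence(rng, 10, 200)  # many families: ties improbable
        d = binary_distance(pm)
        ours = hierarchical_cluster(d, "average").cophenetic_matrix()
        z = scipy_linkage(squareform(d.values, checks=False), method="average")
        ref = squareform(cophenet(z))
        assert np.allclose(ours.values, ref, atol=1e-10)


class TestCutsAndReports:
    def test_k1_always_single(self, small_bundle):
        d = binary_distance(small_bundle.presence)
        dendro = hierarchical_cluster(d)
        focal = [r.strain_id for r in small_bundle.metadata if r.is_focal]
        rep = evaluate_focal_cluster(dendro, focal, k=1)
        assert rep.focal_single_cluster and rep.focal_purity == 1.0

    def test_k_equals_n_single_iff_one_focal(self, small_bundle):
        d = binary_distance(small_bundle.presence)
        dendro = hierarchical_cluster(d)
        n = len(dendro.leaves)
        focal = [r.strain_id for r in small_bundle.metadata if r.is_focal]
        rep = evaluate_focal_cluster(dendro, focal, k=n)
        assert not rep.focal_single_cluster
        rep1 = evaluate_focal_cluster(dendro, focal[:1], k=n)
        assert rep1.focal_single_cluster

    def test_cut_partition_sizes(self, small_bundle):
        d = binary_distance(small_bundle.presence)
        dendro = hierarchical_cluster(d)
        for k in (1, 3, 8, 20):
            assign = dendro.cut(k=k)
            assert len(set(assign.values())) == k
            assert set(assign) == set(dendro.leaves)

    def test_cut_by_height_matches_cut_by_k(self, small_bundle):
        d = binary_distance(small_bundle.presence)
        dendro = hierarchical_cluster(d)
        h = dendro.merges[-5][2]  # height of the 5th-from-last merge
        by_height = dendro.cut(height=h + 1e-12)
        k = len(set(by_height.values()))
        assert by_height == dendro.cut(k=k)

    def test_out_of_range_k_rejected(self, small_bundle):
        d = binary_distance(small_bundle.presence)
        dendro = hierarchical_cluster(d)
        with pytest.raises(ValidationError):
            dendro.cut(k=0)
        with pytest.raises(ValidationError):
            dendro.cut(k=len(dendro.leaves) + 1)

    def test_sweep_table(self, small_bundle):
        d = binary_distance(small_bundle.presence)
        dendro = hierarchical_cluster(d)
        focal = [r.strain_id for r in small_bundle.metadata if r.is_focal]
        sweep = sweep_focal_cluster(dendro, focal, [1, 2, 4, 8])
        assert list(sweep["k"]) == [1, 2, 4, 8]
        assert bool(sweep.loc[0, "focal_single_cluster"]) is True
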