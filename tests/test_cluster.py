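"""Correlation distance, UPGMA linkage (vs a naive reference), tree cuts."""

import numpy as np
import pandas as pd
import pytest

import ifndiv as iv
from ifndiv.cluster import ClusterError


def naive_upgma(d):
    """Brute-force O(n^3) UPGMA: returns [(frozenset_of_leaves, height), ...].

    Inter-cluster distance is the unweighted mean over all cross pairs,
    maintained by size-weighted averaging at each merge. Ties broken by the
    smallest pair of current cluster indices.
    """
    d = np.array(d, dtype=float)
    n = d.shape[0]
    members = {i: frozenset([i]) for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(members) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        new = members[i] | members[j]
        merges.append((new, h))
        ni, nj = len(members[i]), len(members[j])
        del members[i], members[j]
        for k in list(members):
            a, b = (min(i, k), max(i, k)), (min(j, k), max(j, k))
            dist[(k, next_id)] = (ni * dist.pop(a) + nj * dist.pop(b)) / (ni + nj)
        dist.pop((i, j))
        members[next_id] = new
        next_id += 1
    return merges


def merge_sets(dendro):
    """scipy-format linkage -> [(frozenset_of_leaves, height), ...]."""
    n = len(dendro.leaf_ids)
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, (left, right, h, _) in enumerate(dendro.merges):
        new = members[int(left)] | members[int(right)]
        members[n + k] = new
        out.append((new, h))
    return out


def random_distance_matrix(rng, n):
    m = rng.random((n, n))
    d = (m + m.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


class TestCorrelationDistance:
    def _mat(self, rows, genes, samples):
        return iv.ExpressionMatrix(
            pd.DataFrame(rows, index=genes, columns=samples),
            stage="hc_relative_log2",
        )

    def test_one_minus_pearson(self):
        mat = self._mat(
            [[1, 2, 3], [2, 4, 6], [3, 2, 1]], list("abc"), ["s1", "s2", "s3"]
        )
        dist = iv.correlation_distance(mat)
        assert dist.d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert dist.d[0, 2] == pytest.approx(2.0, abs=1e-12)
        assert np.diag(dist.d).tolist() == [0.0, 0.0, 0.0]

    def test_zero_variance_item_named(self):
        mat = self._mat([[1, 2, 3], [7, 7, 7]], ["a", "flat"], ["s1", "s2", "s3"])
        with pytest.raises(ClusterError, match="flat"):
            iv.correlation_distance(mat)

    def test_sample_axis_transposes(self):
        rng = np.random.default_rng(0)
        mat = self._mat(
            rng.normal(size=(4, 5)), list("abcd"), [f"s{i}" for i in range(5)]
        )
        dist = iv.correlation_distance(mat, axis="samples")
        assert dist.ids == [f"s{i}" for i in range(5)]
        assert dist.d.shape == (5, 5)


class TestAverageLinkage:
    def test_hand_computed_three_leaf_merges(self):
        d = np.array([[0, 0.1, 0.9], [0.1, 0, 0.7], [0.9, 0.7, 0]])
        dendro = iv.average_linkage(iv.DistanceMatrix(list("xyz"), d))
        heights = dendro.merges[:, 2]
        assert heights[0] == pytest.approx(0.1)
        assert heights[1] == pytest.approx(0.8)  # (0.9 + 0.7) / 2
        first = merge_sets(dendro)[0][0]
        assert first == frozenset({0, 1})

    def test_two_leaves_base_case(self):
        d = np.array([[0, 0.5], [0.5, 0]])
        dendro = iv.average_linkage(iv.DistanceMatrix(["a", "b"], d))
        assert dendro.merges.shape == (1, 4)
        assert dendro.merges[0, 2] == pytest.approx(0.5)

    def test_matches_naive_reference_on_random_instances(self):
        """1,000 random instances, n <= 8: merges identical to brute force."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(2, 9))
            d = random_distance_matrix(rng, n)
            dendro = iv.average_linkage(
                iv.DistanceMatrix([str(i) for i in range(n)], d)
            )
            got = merge_sets(dendro)
            expected = naive_upgma(d)
            assert {m for m, _ in got} == {m for m, _ in expected}
            eh = dict(expected)
            for m, h in got:
                assert h == pytest.approx(eh[m], abs=1e-9)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(7)
        d = random_distance_matrix(rng, 10)
        dendro = iv.average_linkage(iv.DistanceMatrix([str(i) for i in range(10)], d))
        assert (np.diff(dendro.merges[:, 2]) >= -1e-12).all()

    def test_inverted_merge_heights_rejected(self):
        merges = np.array([[0, 1, 0.5, 2], [2, 3, 0.2, 3]])
        with pytest.raises(ClusterError, match="invert"):
            iv.Dendrogram(merges=merges, leaf_ids=["a", "b", "c"])

    def test_asymmetric_distances_rejected(self):
        d = np.array([[0, 1.0], [0.5, 0]])
        with pytest.raises(ClusterError, match="symmetric"):
            iv.DistanceMatrix(["a", "b"], d)

    def test_nan_distances_rejected(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ClusterError, match="finite"):
            iv.DistanceMatrix(["a", "b"], d)


class TestCutKClusters:
    def _dendro(self):
        d = np.array([[0, 0.1, 0.9], [0.1, 0, 0.7], [0.9, 0.7, 0]])
        return iv.average_linkage(iv.DistanceMatrix(list("xyz"), d))

    def test_k2_splits_at_highest_merge(self):
        part = iv.cut_k_clusters(self._dendro(), k=2)
        groups = {frozenset(part.members(lab)) for lab in part.labels.unique()}
        assert groups == {frozenset({"x", "y"}), frozenset({"z"})}

    def test_k1_single_cluster(self):
        part = iv.cut_k_clusters(self._dendro(), k=1)
        assert part.labels.nunique() == 1

    def test_k_equals_n_singletons(self):
        part = iv.cut_k_clusters(self._dendro(), k=3)
        assert part.labels.nunique() == 3

    @pytest.mark.parametrize("k", [0, 4])
    def test_k_out_of_range(self, k):
        with pytest.raises(ClusterError, match="out of range"):
            iv.cut_k_clusters(self._dendro(), k=k)

    def test_upper_label_follows_reference_group_expression(self):
        mat = iv.ExpressionMatrix(
            pd.DataFrame(
                [[5.0, 5.0], [5.5, 5.5], [0.0, 0.0]],
                index=list("xyz"),
                columns=["s1", "s2"],
            ),
            stage="hc_relative_log2",
        )
        part = iv.cut_k_clusters(
            self._dendro(), k=2, matrix=mat, reference_samples=["s1", "s2"]
        )
        assert set(part.members("upper")) == {"x", "y"}
        assert part.members("lower") == ["z"]

    def test_partition_invariant_to_input_order(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(6, 20)) + np.outer(
            [1, 1, 1, -1, -1, -1], rng.normal(size=20)
        )
        genes = list("abcdef")
        mat = iv.ExpressionMatrix(
            pd.DataFrame(vals, index=genes, columns=[f"s{i}" for i in range(20)]),
            stage="hc_relative_log2",
        )
        perm = ["d", "a", "f", "b", "e", "c"]
        p1 = iv.cut_k_clusters(
            iv.average_linkage(iv.correlation_distance(mat)), k=2
        )
        p2 = iv.cut_k_clusters(
            iv.average_linkage(iv.correlation_distance(mat.subset_genes(perm))), k=2
        )
        sets1 = {frozenset(p1.members(lab)) for lab in p1.labels.unique()}
        sets2 = {frozenset(p2.members(lab)) for lab in p2.labels.unique()}
        assert sets1 == sets2

    def test_planted_two_program_recovery(self, default_cohort_normalized):
        from sklearn.metrics import adjusted_rand_score

        norm, truth = default_cohort_normalized
        resp = truth.program_labels(responsive_only=True)
        sub = norm.subset_genes(list(resp.index)).subset_samples(
            norm.samples_in_group("SLE") + norm.samples_in_group("MS_IFNB")
        )
        part = iv.cut_k_clusters(
            iv.average_linkage(iv.correlation_distance(sub)), k=2
        )
        assert adjusted_rand_score(list(resp.values), list(part.labels.values)) == 1.0


class TestNewick:
    def test_export_parses_with_dendropy(self):
        import dendropy

        rng = np.random.default_rng(5)
        d = random_distance_matrix(rng, 6)
        ids = [f"g{i}" for i in range(6)]
        dendro = iv.average_linkage(iv.DistanceMatrix(ids, d))
        tree = dendropy.Tree.get(data=dendro.to_newick(), schema="newick")
        assert sorted(t.label for t in tree.taxon_namespace) == ids
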