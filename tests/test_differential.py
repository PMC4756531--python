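"""Unpaired t-tests, Benjamini-Hochberg, and GC-A/GC-B refinement."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ifndiv as iv
from ifndiv.cluster import GeneClusterPartition
from ifndiv.differential import DiffError


def _mat(rows, genes, samples):
    return iv.ExpressionMatrix(
        pd.DataFrame(rows, index=genes, columns=samples),
        stage="hc_relative_log2",
    )


def pooled_t(x, y):
    """Closed-form Student t with pooled variance; two-sided p."""
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (
        n1 + n2 - 2
    )
    t = (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df=n1 + n2 - 2)
    return t, p


def bh_reference(p):
    """Direct step-up definition with explicit running minimum."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestPerGeneTTest:
    G1, G2 = ["a1", "a2", "a3"], ["b1", "b2", "b3"]

    def _de(self, rows):
        mat = _mat(rows, [f"g{i}" for i in range(len(rows))], self.G1 + self.G2)
        return iv.per_gene_ttest(mat, self.G1, self.G2)

    def test_worked_example(self):
        de = self._de([[1, 2, 3, 4, 5, 6]])
        assert de.loc["g0", "t"] == pytest.approx(-3.6742, abs=1e-4)
        assert de.loc["g0", "df"] == 4
        assert de.loc["g0", "p"] == pytest.approx(0.0213, abs=2e-4)
        assert de.loc["g0", "direction"] == "up_in_2"

    def test_identical_groups_null(self):
        de = self._de([[1, 2, 3, 1, 2, 3]])
        assert de.loc["g0", "t"] == 0
        assert de.loc["g0", "p"] == 1
        assert de.loc["g0", "direction"] == "none"

    def test_label_swap_flips_sign_keeps_p(self):
        mat = _mat([[1, 2, 3, 4, 5, 7]], ["g0"], self.G1 + self.G2)
        fwd = iv.per_gene_ttest(mat, self.G1, self.G2)
        rev = iv.per_gene_ttest(mat, self.G2, self.G1)
        assert rev.loc["g0", "t"] == pytest.approx(-fwd.loc["g0", "t"])
        assert rev.loc["g0", "p"] == pytest.approx(fwd.loc["g0", "p"])
        assert rev.loc["g0", "mean_diff"] == pytest.approx(
            -fwd.loc["g0", "mean_diff"]
        )

    def test_matches_closed_form_on_random_groups(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            n1, n2 = rng.integers(2, 7, size=2)
            x, y = rng.normal(size=n1), rng.normal(1.0, 2.0, size=n2)
            mat = _mat(
                [np.concatenate([x, y])],
                ["g"],
                [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)],
            )
            de = iv.per_gene_ttest(
                mat, [f"a{i}" for i in range(n1)], [f"b{i}" for i in range(n2)]
            )
            t_ref, p_ref = pooled_t(x, y)
            assert de.loc["g", "t"] == pytest.approx(t_ref, abs=1e-12)
            assert de.loc["g", "p"] == pytest.approx(p_ref, abs=1e-12)

    def test_degenerate_zero_variance(self):
        de = self._de([[2, 2, 2, 2, 2, 2], [2, 2, 2, 5, 5, 5]])
        assert de.loc["g0", "p"] == 1  # zero variance, equal means
        assert de.loc["g1", "p"] == 0  # zero variance, unequal means
        assert bool(de.loc["g1", "degenerate"])

    def test_small_group_rejected(self):
        mat = _mat([[1, 2, 3]], ["g"], ["a1", "b1", "b2"])
        with pytest.raises(DiffError, match="2 samples"):
            iv.per_gene_ttest(mat, ["a1"], ["b1", "b2"])

    def test_welch_differs_under_unequal_variance(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(0, 0.1, 4), rng.normal(0, 5.0, 4)])
        mat = _mat([x], ["g"], [f"s{i}" for i in range(8)])
        g1, g2 = [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)]
        student = iv.per_gene_ttest(mat, g1, g2)
        welch = iv.per_gene_ttest(mat, g1, g2, welch=True)
        assert welch.loc["g", "df"] < student.loc["g", "df"]


class TestBenjaminiHochberg:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.05], [0.05]),
            ([0.04, 0.01], [0.04, 0.02]),
        ],
    )
    def test_worked_examples(self, p, expected):
        assert iv.benjamini_hochberg(p) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_reference(self):
        """1,000 random p-vectors of length <= 20, max abs diff <= 1e-12."""
        rng = np.random.default_rng(12)
        for _ in range(1000):
            m = int(rng.integers(1, 21))
            p = rng.random(m)
            got = iv.benjamini_hochberg(p)
            assert np.abs(got - bh_reference(p)).max() <= 1e-12

    def test_adjusted_at_least_raw_and_in_unit_interval(self):
        rng = np.random.default_rng(13)
        p = rng.random(50)
        adj = iv.benjamini_hochberg(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()

    @pytest.mark.parametrize("bad", [[-0.1], [1.5], [np.nan]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(DiffError):
            iv.benjamini_hochberg(bad)


class TestDefineGCSets:
    def _partition(self, upper, lower):
        labels = pd.Series(
            ["upper"] * len(upper) + ["lower"] * len(lower), index=upper + lower
        )
        return GeneClusterPartition(labels=labels, k=2)

    def test_significance_and_direction_filter(self):
        part = self._partition(["g1", "g2", "g3"], ["g4"])
        de = pd.DataFrame(
            {
                "p_adj": [0.01, 0.20, 0.03, 0.001],
                "direction": ["up_in_1", "up_in_1", "up_in_1", "up_in_2"],
            },
            index=["g1", "g2", "g3", "g4"],
        )
        gc = iv.define_gc_sets(part, de)
        assert set(gc.gc_a) == {"g1", "g3"}
        assert gc.gc_b == ("g4",)

    def test_wrong_direction_excluded_even_if_significant(self):
        part = self._partition(["g1"], ["g2", "g3"])
        de = pd.DataFrame(
            {
                "p_adj": [0.001, 0.001, 0.001],
                "direction": ["up_in_1", "up_in_1", "up_in_2"],
            },
            index=["g1", "g2", "g3"],
        )
        gc = iv.define_gc_sets(part, de)
        assert gc.gc_b == ("g3",)  # g2 significant but up in group 1

    def test_empty_set_is_hard_error(self):
        part = self._partition(["g1"], ["g2"])
        de = pd.DataFrame(
            {"p_adj": [0.5, 0.5], "direction": ["up_in_1", "up_in_2"]},
            index=["g1", "g2"],
        )
        with pytest.raises(DiffError, match="nonempty"):
            iv.define_gc_sets(part, de)

    def test_missing_de_rows_rejected(self):
        part = self._partition(["g1"], ["g2"])
        de = pd.DataFrame(
            {"p_adj": [0.01], "direction": ["up_in_1"]}, index=["g1"]
        )
        with pytest.raises(DiffError, match="g2"):
            iv.define_gc_sets(part, de)

    def test_raw_p_option(self):
        part = self._partition(["g1"], ["g2"])
        de = pd.DataFrame(
            {
                "p": [0.01, 0.02],
                "p_adj": [0.2, 0.2],
                "direction": ["up_in_1", "up_in_2"],
            },
            index=["g1", "g2"],
        )
        gc = iv.define_gc_sets(part, de, use_adjusted=False)
        assert gc.gc_a == ("g1",) and gc.gc_b == ("g2",)

    def test_stable_under_sample_permutation(self, default_cohort_normalized):
        norm, _ = default_cohort_normalized
        g1 = norm.samples_in_group("SLE")
        g2 = norm.samples_in_group("MS_IFNB")
        sub = norm.subset_samples(g1 + g2)
        part = iv.cut_k_clusters(
            iv.average_linkage(iv.correlation_distance(sub)),
            k=2, matrix=sub, reference_samples=g1,
        )
        rng = np.random.default_rng(4)
        perm = list(rng.permutation(g1 + g2))
        de1 = iv.adjust_pvalues(iv.per_gene_ttest(sub, g1, g2))
        de2 = iv.adjust_pvalues(
            iv.per_gene_ttest(sub.subset_samples(perm), g1, g2)
        )
        gc1, gc2 = iv.define_gc_sets(part, de1), iv.define_gc_sets(part, de2)
        assert gc1.gc_a == gc2.gc_a and gc1.gc_b == gc2.gc_b
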