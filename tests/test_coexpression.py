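"""Co-expression set comparisons: Pearson samples, Cohen's d, Wilcoxon."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from motiforient.catalog import Motif
from motiforient.coexpression import (
    ExpressionMatrix,
    build_orientation_sets,
    build_presence_absence_sets,
    cohens_d,
    compare_sets,
    pairwise_correlations,
    read_expression_tsv,
)
from motiforient.mapping import map_catalog
from motiforient.upstream import IntervalSpec, UpstreamRegion


def matrix(values, genes=None):
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    return ExpressionMatrix(
        pd.DataFrame(arr, index=genes, columns=[f"s{j}" for j in range(arr.shape[1])])
    )


class TestExpressionMatrix:
    def test_missing_values_rejected(self):
        df = pd.DataFrame([[1.0, np.nan, 2.0]], index=["g"], columns=list("abc"))
        with pytest.raises(ValueError, match="missing"):
            ExpressionMatrix(df)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            matrix([[1.0, 2.0]])

    def test_tsv_round_trip(self, tmp_path):
        expr = matrix(np.arange(12.0).reshape(3, 4))
        path = tmp_path / "expr.tsv"
        expr.write_tsv(path)
        back = read_expression_tsv(path)
        assert back.values.equals(expr.values)

    def test_non_numeric_rejected(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text("gene_id\ta\tb\tc\ng1\t1\tx\t2\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_expression_tsv(path)


class TestPairwiseCorrelations:
    def test_identical_profiles(self):
        expr = matrix([[1, 2, 3, 4], [1, 2, 3, 4]])
        assert pairwise_correlations(["g0", "g1"], expr) == pytest.approx([1.0])

    def test_negated_profiles(self):
        expr = matrix([[1, 2, 3, 4], [-1, -2, -3, -4]])
        assert pairwise_correlations(["g0", "g1"], expr) == pytest.approx([-1.0])

    def test_matches_hand_computed_pearson(self):
        X = np.array(
            [
                [0.1, 1.2, -0.3, 2.0, 0.5],
                [1.0, -0.2, 0.8, 1.5, -1.1],
                [2.2, 0.0, 0.4, -0.6, 1.3],
                [-0.5, 0.9, 1.1, 0.2, 0.7],
            ]
        )
        expr = matrix(X)
        rs = sorted(pairwise_correlations([f"g{i}" for i in range(4)], expr))

        def pearson(a, b):
            am, bm = a - a.mean(), b - b.mean()
            return float((am * bm).sum() / math.sqrt((am**2).sum() * (bm**2).sum()))

        expected = sorted(
            pearson(X[i], X[j]) for i, j in itertools.combinations(range(4), 2)
        )
        assert rs == pytest.approx(expected)

    def test_absent_genes_dropped(self):
        expr = matrix([[1, 2, 3, 4], [4, 3, 2, 1]])
        rs = pairwise_correlations(["g0", "g1", "missing"], expr)
        assert rs.size == 1

    def test_fewer_than_two_genes_rejected(self):
        expr = matrix([[1, 2, 3, 4]])
        with pytest.raises(ValueError, match=">= 2"):
            pairwise_correlations(["g0"], expr)

    def test_subsample_unbiased(self):
        """Capped sampling estimates the full mean r within 3 SE."""
        rng = np.random.default_rng(12)
        z = rng.standard_normal(100)
        X = 0.4 * z + rng.standard_normal((60, 100))
        expr = matrix(X)
        genes = [f"g{i}" for i in range(60)]
        full = pairwise_correlations(genes, expr, pair_cap=10**9)
        sub = pairwise_correlations(genes, expr, pair_cap=400, seed=5)
        assert sub.size == 400
        se = full.std(ddof=1) / math.sqrt(400)
        assert abs(sub.mean() - full.mean()) < 3 * se

    def test_subsampled_pairs_are_valid_correlations(self):
        rng = np.random.default_rng(2)
        expr = matrix(rng.standard_normal((30, 20)))
        genes = [f"g{i}" for i in range(30)]
        full = set(np.round(pairwise_correlations(genes, expr, pair_cap=10**9), 12))
        sub = pairwise_correlations(genes, expr, pair_cap=100, seed=3)
        assert all(round(r, 12) in full for r in sub)


class TestCohensD:
    def test_identical_samples_zero(self):
        a = np.array([0.1, 0.2, 0.3])
        assert cohens_d(a, a) == 0.0

    def test_arithmetic(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.3, 0.2, 40000)
        b = rng.normal(0.1, 0.2, 40000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.02)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=30), rng.normal(1, 2, size=40)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="zero pooled"):
            cohens_d(np.array([1.0, 1.0]), np.array([2.0, 2.0]))


def rank_sum_exact_oracle(a, b):
    """Two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    obs = stats.rankdata(pooled)[:n].sum()
    stats_all = []
    for idx in itertools.combinations(range(n + m), n):
        r = stats.rankdata(pooled)
        stats_all.append(r[list(idx)].sum())
    stats_all = np.array(stats_all)
    mean = stats_all.mean()
    p = np.mean(np.abs(stats_all - mean) >= abs(obs - mean) - 1e-12)
    return float(p)


class TestCompareSets:
    def test_identical_sets_null(self):
        rng = np.random.default_rng(5)
        expr = matrix(rng.standard_normal((10, 30)))
        genes = [f"g{i}" for i in range(10)]
        cmp = compare_sets(genes, genes, expr)
        assert cmp.cohens_d == 0.0
        assert cmp.p_r_diff == pytest.approx(1.0, abs=0.05)

    def test_latent_factor_module_detected(self):
        rng = np.random.default_rng(8)
        n_s = 200
        z = rng.standard_normal(n_s)
        module = 0.5 * z + rng.standard_normal((60, n_s))
        noise = rng.standard_normal((60, n_s))
        expr = matrix(np.vstack([module, noise]))
        set_a = [f"g{i}" for i in range(60)]
        set_b = [f"g{i}" for i in range(60, 120)]
        cmp = compare_sets(set_a, set_b, expr)
        assert cmp.p_r_diff < 1e-6
        assert cmp.cohens_d > 0.1
        assert cmp.mean_r_a > cmp.mean_r_b

    def test_swapping_sets_negates_d_and_keeps_p(self):
        rng = np.random.default_rng(9)
        expr = matrix(rng.standard_normal((20, 50)))
        a = [f"g{i}" for i in range(10)]
        b = [f"g{i}" for i in range(10, 20)]
        ab = compare_sets(a, b, expr)
        ba = compare_sets(b, a, expr)
        assert ab.cohens_d == pytest.approx(-ba.cohens_d)
        assert ab.p_r_diff == pytest.approx(ba.p_r_diff)

    def test_p_matches_exact_enumeration_at_tiny_n(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            a = rng.normal(size=3)
            b = rng.normal(size=4)
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                         method="exact").pvalue)
            assert p == pytest.approx(rank_sum_exact_oracle(a, b), abs=1e-9)

    def test_label_permutation_null_is_uniform(self):
        """Shuffling genes between two sets yields approximately uniform
        p-values (KS over 200 shuffles)."""
        rng = np.random.default_rng(33)
        expr = matrix(rng.standard_normal((60, 60)))
        genes = np.array([f"g{i}" for i in range(60)])
        ps = []
        for _ in range(200):
            perm = rng.permutation(genes)
            cmp = compare_sets(perm[:30], perm[30:], expr)
            ps.append(cmp.p_r_diff)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_effect_size_monotone_in_factor_loading(self):
        """Estimated d increases with the latent-factor loading."""
        rng = np.random.default_rng(77)
        n_s, n_g = 150, 40
        noise_set = [f"b{i}" for i in range(n_g)]
        ds = []
        for lam in (0.0, 0.25, 0.5):
            z = rng.standard_normal(n_s)
            module = lam * z + rng.standard_normal((n_g, n_s))
            noise = rng.standard_normal((n_g, n_s))
            genes = [f"a{i}" for i in range(n_g)] + noise_set
            expr = ExpressionMatrix(
                pd.DataFrame(np.vstack([module, noise]), index=genes,
                             columns=[f"s{j}" for j in range(n_s)])
            )
            ds.append(compare_sets(genes[:n_g], noise_set, expr).cohens_d)
        assert ds[0] < ds[1] < ds[2]


def _mapping_fixture():
    regions = [
        UpstreamRegion("fw1", "TTGACCGA" + "A" * 12),
        UpstreamRegion("fw2", "A" * 12 + "TTGACCGA"),
        UpstreamRegion("rc1", "TCGGTCAA" + "A" * 12),
        UpstreamRegion("both", "TTGACCGA" + "AAAA" + "TCGGTCAA"),
        UpstreamRegion("none1", "C" * 20),
        UpstreamRegion("none2", "G" * 20),
        UpstreamRegion("none3", "GC" * 10),
        UpstreamRegion("none4", "CG" * 10),
    ]
    iv = IntervalSpec(-20, -1)
    table = map_catalog([Motif("m", "TTGACCGA")], regions, [iv])
    return table, iv, [r.gene_id for r in regions]


class TestSetConstruction:
    def test_orientation_sets_exclusive(self):
        table, iv, _ = _mapping_fixture()
        fw_only, rc_only = build_orientation_sets("m", iv, table)
        assert fw_only == {"fw1", "fw2"}
        assert rc_only == {"rc1"}
        assert "both" not in fw_only | rc_only
        assert fw_only & rc_only == set()

    def test_presence_absence_min_size_rule(self):
        table, iv, genes = _mapping_fixture()
        pos, neg = build_presence_absence_sets(
            "m", iv, table, genes, min_neg=3, seed=1
        )
        assert pos == {"fw1", "fw2", "rc1", "both"}
        assert len(neg) == 4  # max(|pos|, 3)
        assert neg == {"none1", "none2", "none3", "none4"}

    def test_negative_floor_applies_when_positive_small(self):
        table, iv, genes = _mapping_fixture()
        with pytest.raises(ValueError, match="motif-free"):
            # only 3 motif-free genes but floor demands 100
            build_presence_absence_sets("m", iv, table, genes, min_neg=100, seed=1)

    def test_motif_in_all_genes_is_an_error(self):
        regions = [UpstreamRegion(f"g{i}", "TTGACCGA" + "A" * 12) for i in range(5)]
        iv = IntervalSpec(-20, -1)
        table = map_catalog([Motif("m", "TTGACCGA")], regions, [iv])
        with pytest.raises(ValueError, match="motif-free"):
            build_presence_absence_sets(
                "m", iv, table, [r.gene_id for r in regions], min_neg=2, seed=0
            )

    def test_negative_sampling_is_seeded(self):
        rng = np.random.default_rng(0)
        regions = [UpstreamRegion("hit", "TTGACCGA" + "A" * 12)] + [
            UpstreamRegion(f"g{i}", "".join(rng.choice(list("CG"), 20)))
            for i in range(200)
        ]
        iv = IntervalSpec(-20, -1)
        table = map_catalog([Motif("m", "TTGACCGA")], regions, [iv])
        genes = [r.gene_id for r in regions]
        _, neg1 = build_presence_absence_sets("m", iv, table, genes, seed=7)
        _, neg2 = build_presence_absence_sets("m", iv, table, genes, seed=7)
        _, neg3 = build_presence_absence_sets("m", iv, table, genes, seed=8)
        assert neg1 == neg2
        assert len(neg1) == 100
        assert neg1 != neg3
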