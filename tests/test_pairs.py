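"""Motif-pair instances, enrichment, order and arrangement statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from motiforient.catalog import Motif
from motiforient.coexpression import ExpressionMatrix
from motiforient.mapping import MappingHit, MappingTable, map_catalog
from motiforient.pairs import (
    ORIENTATION_COMBOS,
    PairArrangementCounts,
    arrangement_entropy_test,
    cooccurrence_enrichment,
    count_arrangements,
    find_pair_instances,
    order_test,
    pair_coexpression,
    secondary_order_conditional_tests,
)
from motiforient.upstream import IntervalSpec, UpstreamRegion

IV = IntervalSpec(-500, -51)


def _table(hits_by_motif):
    """MappingTable from {motif_id: [(gene, ori, start, end), ...]}."""
    t = MappingTable(intervals=[IV])
    for mid, hits in hits_by_motif.items():
        for ori in ("fw", "rc"):
            sel = [
                MappingHit(g, mid, o, s, e) for (g, o, s, e) in hits if o == ori
            ]
            t.hits_by[(mid, IV, ori)] = sel
            t.counts[(mid, IV, ori)] = len(sel)
            t.gene_sets[(mid, IV, ori)] = {h.gene_id for h in sel}
    return t


class TestFindPairInstances:
    def test_single_instance_with_order_and_orientations(self):
        t = _table({
            "A": [("g", "fw", -300, -295)],
            "B": [("g", "rc", -100, -95)],
        })
        (inst,) = find_pair_instances(t, "A", "B", IV)
        assert inst.order == "1_then_2"
        assert inst.orientations == ("fw", "rc")

    def test_reverse_positional_order(self):
        t = _table({
            "A": [("g", "fw", -100, -95)],
            "B": [("g", "rc", -300, -295)],
        })
        (inst,) = find_pair_instances(t, "A", "B", IV)
        assert inst.order == "2_then_1"
        assert inst.orientations == ("rc", "fw")  # upstream hit (B) first

    def test_overlapping_hits_yield_no_instance(self):
        t = _table({
            "A": [("g", "fw", -300, -295)],
            "B": [("g", "fw", -297, -292)],
        })
        assert find_pair_instances(t, "A", "B", IV) == []

    def test_same_motif_unordered_distinct_pairs(self):
        t = _table({"A": [("g", "fw", -300, -295), ("g", "fw", -100, -95)]})
        instances = find_pair_instances(t, "A", "A", IV)
        assert len(instances) == 1  # C(2,2) unordered

    def test_all_combinations_counted(self):
        t = _table({
            "A": [("g", "fw", -400, -395), ("g", "fw", -200, -195)],
            "B": [("g", "rc", -300, -295), ("g", "rc", -100, -95)],
        })
        instances = find_pair_instances(t, "A", "B", IV)
        assert len(instances) == 4

    def test_max_gap_filters_distant_pairs(self):
        t = _table({
            "A": [("g", "fw", -400, -395)],
            "B": [("g", "fw", -100, -95)],   # gap = 294
        })
        assert find_pair_instances(t, "A", "B", IV, max_gap=100) == []
        assert len(find_pair_instances(t, "A", "B", IV, max_gap=300)) == 1

    def test_excluded_motif_refused(self):
        t = _table({"A": [("g", "fw", -300, -295)]})
        with pytest.raises(ValueError, match="excluded"):
            find_pair_instances(t, "A", "B", IV, excluded_motifs={"B"})


class TestArrangementCounts:
    def test_eight_cells_for_different_motifs(self):
        t = _table({
            "A": [("g", "fw", -300, -295)],
            "B": [("g", "rc", -100, -95)],
        })
        counts = count_arrangements(find_pair_instances(t, "A", "B", IV), "A", "B")
        assert len(counts.cells) == 8
        assert counts.counts == {("1_then_2", "fw", "rc"): 1}

    def test_four_cells_for_same_motif(self):
        t = _table({"A": [("g", "fw", -300, -295), ("g", "rc", -100, -95)]})
        counts = count_arrangements(find_pair_instances(t, "A", "A", IV), "A", "A")
        assert len(counts.cells) == 4
        assert counts.counts == {("1_then_2", "fw", "rc"): 1}

    def test_relabeling_permutes_counts_but_not_statistics(self):
        rng = np.random.default_rng(4)
        t = _table({
            "A": [(f"g{i}", rng.choice(["fw", "rc"]), -400 + 20 * i, -395 + 20 * i)
                  for i in range(5)],
            "B": [(f"g{i}", rng.choice(["fw", "rc"]), -300 + 20 * i, -295 + 20 * i)
                  for i in range(5)],
        })
        c_ab = count_arrangements(find_pair_instances(t, "A", "B", IV), "A", "B")
        c_ba = count_arrangements(find_pair_instances(t, "B", "A", IV), "B", "A")
        assert sorted(c_ab.vector()) == sorted(c_ba.vector())
        h_ab, p_ab = arrangement_entropy_test(c_ab, n_shuffles=2000, seed=1)
        h_ba, p_ba = arrangement_entropy_test(c_ba, n_shuffles=2000, seed=1)
        assert h_ab == pytest.approx(h_ba)
        assert p_ab == pytest.approx(p_ba, abs=0.03)


def hypergeom_enumeration_oracle(k, M, n, N):
    """Upper-tail P(X >= k) by direct summation of the hypergeometric pmf."""
    return float(
        sum(
            math.comb(n, x) * math.comb(M - n, N - x) / math.comb(M, N)
            for x in range(k, min(n, N) + 1)
        )
    )


class TestCooccurrenceEnrichment:
    def test_full_overlap_of_universe_sets(self):
        assert cooccurrence_enrichment(20, 20, 20, 20) == pytest.approx(1.0)

    def test_minimal_overlap_closed_form(self):
        p = cooccurrence_enrichment(5, 5, 5, 20)
        assert p == pytest.approx(1 / math.comb(20, 5), rel=1e-9)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            M = int(rng.integers(5, 31))
            n = int(rng.integers(1, M + 1))
            N = int(rng.integers(1, M + 1))
            k = int(rng.integers(max(0, n + N - M), min(n, N) + 1))
            assert cooccurrence_enrichment(n, N, k, M) == pytest.approx(
                hypergeom_enumeration_oracle(k, M, n, N), rel=1e-9
            )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            cooccurrence_enrichment(25, 5, 5, 20)
        with pytest.raises(ValueError):
            cooccurrence_enrichment(5, 5, 6, 20)


def _counts(vec, same=False, m1="A", m2="B"):
    c = PairArrangementCounts(m1, m2 if not same else m1, same_motif=same)
    for cell, v in zip(c.cells, vec):
        if v:
            c.counts[cell] = int(v)
    return c


class TestOrderTest:
    def test_balanced_orders_null(self):
        p = order_test(_counts([10, 5, 5, 5, 10, 5, 5, 5]))
        assert p == pytest.approx(1.0)

    def test_fully_ordered_pair(self):
        p = order_test(_counts([20, 10, 10, 10, 0, 0, 0, 0]))
        assert p == pytest.approx(2 * 0.5**50, rel=1e-9)

    def test_label_swap_symmetry(self):
        v = [30, 5, 3, 2, 10, 4, 4, 2]
        swapped = v[4:] + v[:4]
        assert order_test(_counts(v)) == pytest.approx(order_test(_counts(swapped)))

    def test_same_motif_refused(self):
        with pytest.raises(ValueError, match="same-motif"):
            order_test(_counts([30, 10, 5, 5], same=True))

    def test_minimum_occurrences_enforced(self):
        with pytest.raises(ValueError, match="minimum"):
            order_test(_counts([5, 5, 5, 5, 5, 5, 5, 5]))


class TestArrangementEntropy:
    def test_uniform_cells_are_null(self):
        h, p = arrangement_entropy_test(_counts([10] * 8), n_shuffles=5000, seed=0)
        assert h == pytest.approx(math.log(8), abs=1e-9)
        assert p > 0.5

    def test_concentrated_cell_is_extreme(self):
        h, p = arrangement_entropy_test(
            _counts([80, 0, 0, 0, 0, 0, 0, 0]), n_shuffles=100_000, seed=1
        )
        assert p < 1e-4

    def test_pseudocount_keeps_entropy_finite(self):
        h, _ = arrangement_entropy_test(_counts([0] * 8), n_shuffles=100, seed=0)
        assert h == pytest.approx(math.log(8))

    def test_reproducible_and_stable_across_seeds(self):
        c = _counts([30, 10, 10, 10, 5, 5, 5, 5])
        _, p1 = arrangement_entropy_test(c, n_shuffles=20_000, seed=3)
        _, p2 = arrangement_entropy_test(c, n_shuffles=20_000, seed=3)
        assert p1 == p2
        _, p3 = arrangement_entropy_test(c, n_shuffles=20_000, seed=4)
        se = math.sqrt(p1 * (1 - p1) / 20_000)
        assert abs(p3 - p1) <= 5 * se + 1e-9

    def test_empirical_p_uniform_under_multinomial_null(self):
        """Data drawn from the null itself produce ~uniform empirical p."""
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(500):
            vec = rng.multinomial(60, np.full(8, 1 / 8))
            _, p = arrangement_entropy_test(
                vec, n_shuffles=2000, seed=int(rng.integers(2**31))
            )
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestSecondaryOrderTests:
    def test_pure_order_imbalance_not_arrangement_preferring(self):
        # order 1-2 dominates, but orientations uniform within each order
        c = _counts([25, 25, 25, 25, 2, 2, 2, 2])
        _, p8 = arrangement_entropy_test(c, n_shuffles=20_000, seed=0)
        p1, p2 = secondary_order_conditional_tests(c, n_shuffles=20_000, seed=0)
        assert p8 < 0.05          # eight-cell test sees the order imbalance
        assert p1 > 0.05 and p2 > 0.05

    def test_dominant_cell_flags_all_three_tests(self):
        c = _counts([90, 2, 2, 2, 30, 1, 1, 1])
        _, p8 = arrangement_entropy_test(c, n_shuffles=20_000, seed=1)
        p1, p2 = secondary_order_conditional_tests(c, n_shuffles=20_000, seed=1)
        assert p8 < 0.01 and p1 < 0.01 and p2 < 0.01

    def test_same_motif_pair_has_single_four_cell_test(self):
        c = _counts([50, 2, 2, 2], same=True)
        with pytest.raises(ValueError):
            secondary_order_conditional_tests(c)
        _, p = arrangement_entropy_test(c, n_shuffles=20_000, seed=2)
        assert p < 0.01


class TestPairCoexpression:
    @staticmethod
    def _world():
        rng = np.random.default_rng(15)
        # genes 0-19 carry both motifs (co-expressed module), 20-39 only A,
        # 40-59 only B, 60-79 neither
        regions = []
        for i in range(80):
            seq = list("".join(rng.choice(list("ACGT"), 500)))
            if i < 40:
                seq[50:58] = list("TTGACCGA")          # motif A fw
            if i < 20 or 40 <= i < 60:
                seq[150:158] = list("CCGTTAGG")        # motif B fw
            regions.append(UpstreamRegion(f"g{i:02d}", "".join(seq)))
        z = rng.standard_normal(120)
        X = rng.standard_normal((80, 120))
        X[:20] += 0.6 * z
        expr = ExpressionMatrix(
            pd.DataFrame(X, index=[r.gene_id for r in regions],
                         columns=[f"s{j}" for j in range(120)])
        )
        table = map_catalog(
            [Motif("A", "TTGACCGA"), Motif("B", "CCGTTAGG")], regions,
            [IntervalSpec(-500, -1)],
        )
        return table, expr

    def test_cooccurring_module_detected(self):
        table, expr = self._world()
        iv = IntervalSpec(-500, -1)
        instances = find_pair_instances(table, "A", "B", iv)
        counts = count_arrangements(instances, "A", "B")
        cmp = pair_coexpression(
            instances, counts, "both_vs_one", expr, mapping=table, interval=iv
        )
        assert cmp.cohens_d > 0
        assert cmp.p_r_diff < 1e-6

    def test_order_mode_excludes_mixed_genes(self):
        t = _table({
            "A": [("g1", "fw", -300, -295), ("g2", "fw", -100, -95),
                  ("g3", "fw", -300, -295), ("g3", "fw", -100, -95)],
            "B": [("g1", "fw", -100, -95), ("g2", "fw", -300, -295),
                  ("g3", "fw", -200, -195)],
        })
        instances = find_pair_instances(t, "A", "B", IV)
        orders_g3 = {i.order for i in instances if i.gene_id == "g3"}
        assert orders_g3 == {"1_then_2", "2_then_1"}  # g3 carries both orders
        rng = np.random.default_rng(0)
        expr = ExpressionMatrix(
            pd.DataFrame(rng.standard_normal((3, 10)),
                         index=["g1", "g2", "g3"],
                         columns=[f"s{j}" for j in range(10)])
        )
        counts = count_arrangements(instances, "A", "B")
        with pytest.raises(ValueError):
            # after excluding g3 each arm has one gene -> not assessable
            pair_coexpression(instances, counts, "order_1_vs_order_2", expr)

    def test_identical_arms_give_zero_effect(self):
        rng = np.random.default_rng(3)
        expr = ExpressionMatrix(
            pd.DataFrame(rng.standard_normal((6, 12)),
                         index=[f"g{i}" for i in range(6)],
                         columns=[f"s{j}" for j in range(12)])
        )
        from motiforient.coexpression import compare_sets
        cmp = compare_sets([f"g{i}" for i in range(6)], [f"g{i}" for i in range(6)], expr)
        assert cmp.cohens_d == 0.0
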