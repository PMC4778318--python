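"""Motif-pair co-occurrence, order and order-x-orientation arrangements.

Two motifs co-occurring in one upstream region define an *arrangement*: the
positional order of the two hits (which motif sits more upstream) combined
with each hit's orientation.  For two different motifs there are 8
arrangements (2 orders x 4 orientation combinations, labelled ++, +-, --,
-+ reading the upstream hit first); for same-motif pairs order is
meaningless and only the 4 orientation combinations in positional order
remain.  Only non-overlapping hit combinations count.

Statistics:

* co-occurrence enrichment — upper-tail hypergeometric on gene counts;
* order preference — exact two-sided binomial at p0 = 0.5 on the two order
  totals (different-motif pairs only);
* arrangement preference — Shannon entropy of the arrangement counts after
  adding a pseudocount of 1 to every cell, compared against an empirical
  null of the same total thrown uniformly over the cells; the empirical p
  is the fraction of null entropies *below* the observed one (concentration
  lowers entropy).  A pair is arrangement-preferring when the 8-cell test
  and both per-order 4-cell tests are significant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .coexpression import CoexpressionComparison, ExpressionMatrix, compare_sets
from .mapping import MappingHit, MappingTable
from .upstream import IntervalSpec

__all__ = [
    "PairInstance",
    "PairArrangementCounts",
    "ORIENTATION_COMBOS",
    "find_pair_instances",
    "count_arrangements",
    "cooccurrence_enrichment",
    "order_test",
    "arrangement_entropy_test",
    "secondary_order_conditional_tests",
    "pair_coexpression",
]

#: Orientation combinations in export order: ++, +-, --, -+ (upstream hit first).
ORIENTATION_COMBOS = (("fw", "fw"), ("fw", "rc"), ("rc", "rc"), ("rc", "fw"))
ORDERS = ("1_then_2", "2_then_1")


@dataclass(frozen=True)
class PairInstance:
    gene_id: str
    motif_1: str
    motif_2: str
    hit_1: MappingHit  # hit of motif_1
    hit_2: MappingHit  # hit of motif_2
    order: str         # which motif sits more upstream
    orientations: tuple[str, str]  # (upstream hit, downstream hit)

    def __post_init__(self) -> None:
        if self.hit_1.overlaps(self.hit_2):
            raise ValueError("pair instance with overlapping hits")


def find_pair_instances(
    mapping: MappingTable,
    motif_1: str,
    motif_2: str,
    interval: IntervalSpec,
    max_gap: int | None = None,
    excluded_motifs: set[str] | None = None,
) -> list[PairInstance]:
    """All valid co-occurrence instances of a motif pair in one interval.

    For different motifs, every combination of one hit of each; for a
    same-motif pair, every unordered combination of two distinct hits.
    Overlapping hit combinations are discarded; with ``max_gap`` set, only
    instances whose inter-hit gap is strictly below it are kept.
    """
    if excluded_motifs and (motif_1 in excluded_motifs or motif_2 in excluded_motifs):
        raise ValueError(
            f"pair ({motif_1}, {motif_2}) includes a motif excluded from pair analyses"
        )
    same = motif_1 == motif_2
    hits_1 = mapping.hits_for(motif_1, interval)
    by_gene_1: dict[str, list[MappingHit]] = {}
    for h in hits_1:
        by_gene_1.setdefault(h.gene_id, []).append(h)
    if same:
        combos_by_gene = {
            g: list(itertools.combinations(sorted(hs, key=lambda h: (h.start, h.orientation)), 2))
            for g, hs in by_gene_1.items()
        }
    else:
        hits_2 = mapping.hits_for(motif_2, interval)
        by_gene_2: dict[str, list[MappingHit]] = {}
        for h in hits_2:
            by_gene_2.setdefault(h.gene_id, []).append(h)
        combos_by_gene = {
            g: [(h1, h2) for h1 in by_gene_1[g] for h2 in by_gene_2[g]]
            for g in by_gene_1.keys() & by_gene_2.keys()
        }

    instances: list[PairInstance] = []
    for gene, combos in combos_by_gene.items():
        for h1, h2 in combos:
            if h1.overlaps(h2):
                continue
            first, second = (h1, h2) if h1.start < h2.start else (h2, h1)
            gap = second.start - first.end - 1
            if max_gap is not None and gap >= max_gap:
                continue
            order = "1_then_2" if (same or first is h1) else "2_then_1"
            instances.append(
                PairInstance(
                    gene_id=gene,
                    motif_1=motif_1,
                    motif_2=motif_2,
                    hit_1=h1,
                    hit_2=h2,
                    order=order,
                    orientations=(first.orientation, second.orientation),
                )
            )
    return instances


@dataclass
class PairArrangementCounts:
    motif_1: str
    motif_2: str
    counts: dict[tuple[str, str, str], int] = field(default_factory=dict)
    # keys: (order, upstream orientation, downstream orientation)
    same_motif: bool = False

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    @property
    def cells(self) -> list[tuple[str, str, str]]:
        orders = ("1_then_2",) if self.same_motif else ORDERS
        return [(o, a, b) for o in orders for a, b in ORIENTATION_COMBOS]

    def vector(self) -> np.ndarray:
        return np.array([self.counts.get(c, 0) for c in self.cells])

    def order_totals(self) -> tuple[int, int]:
        v = self.vector()
        if self.same_motif:
            raise ValueError("order totals undefined for same-motif pairs")
        return int(v[:4].sum()), int(v[4:].sum())


def count_arrangements(
    instances: Sequence[PairInstance], motif_1: str, motif_2: str
) -> PairArrangementCounts:
    """Tally instances into the 8 (or 4, same-motif) arrangement cells."""
    same = motif_1 == motif_2
    counts = PairArrangementCounts(motif_1, motif_2, same_motif=same)
    for inst in instances:
        key = ("1_then_2" if same else inst.order, *inst.orientations)
        counts.counts[key] = counts.counts.get(key, 0) + 1
    return counts


def cooccurrence_enrichment(
    n_genes_with_1: int, n_genes_with_2: int, n_genes_with_both: int, universe_n: int
) -> float:
    """Upper-tail hypergeometric p of >= the observed co-occurrence overlap."""
    if max(n_genes_with_1, n_genes_with_2) > universe_n:
        raise ValueError("set larger than universe")
    if n_genes_with_both > min(n_genes_with_1, n_genes_with_2):
        raise ValueError("overlap exceeds set sizes")
    return float(
        stats.hypergeom.sf(
            n_genes_with_both - 1, universe_n, n_genes_with_1, n_genes_with_2
        )
    )


def order_test(
    counts: PairArrangementCounts, min_pair_occurrences: int = 50
) -> float:
    """Exact two-sided binomial p for motif-order preference at p0 = 0.5."""
    if counts.same_motif:
        raise ValueError("order test has no meaning for same-motif pairs")
    n = counts.n_total
    if n < min_pair_occurrences:
        raise ValueError(
            f"only {n} pair occurrences, below the minimum of {min_pair_occurrences}"
        )
    k1, _ = counts.order_totals()
    return float(stats.binomtest(k1, n, 0.5, alternative="two-sided").pvalue)


def _entropy_with_pseudocount(cells: np.ndarray) -> float | np.ndarray:
    """Shannon entropy (nats) of cell counts + 1, renormalized; vectorized
    over the leading axis when given a 2-D array."""
    c = np.asarray(cells, dtype=float) + 1.0
    q = c / c.sum(axis=-1, keepdims=True)
    h = -(q * np.log(q)).sum(axis=-1)
    return h if h.ndim else float(h)


def arrangement_entropy_test(
    counts: PairArrangementCounts | np.ndarray,
    n_shuffles: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """(entropy_H, empirical p) for arrangement concentration.

    The null throws the same total uniformly over the cells (multinomial)
    and applies the identical pseudocount; p is the fraction of null
    entropies strictly below the observed entropy, so p = 0 means no random
    arrangement was as concentrated (reported as 0, resolution 1/n_shuffles).
    """
    vec = counts.vector() if isinstance(counts, PairArrangementCounts) else np.asarray(counts)
    k = vec.size
    n = int(vec.sum())
    h_obs = _entropy_with_pseudocount(vec)
    rng = np.random.default_rng(seed)
    null = rng.multinomial(n, np.full(k, 1.0 / k), size=n_shuffles)
    h_null = _entropy_with_pseudocount(null)
    p = float((h_null < h_obs).sum() / n_shuffles)
    return float(h_obs), p


def secondary_order_conditional_tests(
    counts: PairArrangementCounts,
    n_shuffles: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Per-order 4-cell entropy p-values (order 1-2 first).

    Separates genuine orientation-arrangement preference from pure order
    imbalance: a pair driven by order alone looks uniform within each order.
    """
    if counts.same_motif:
        raise ValueError("same-motif pairs have a single 4-cell test")
    v = counts.vector()
    _, p1 = arrangement_entropy_test(v[:4], n_shuffles=n_shuffles, seed=seed)
    _, p2 = arrangement_entropy_test(v[4:], n_shuffles=n_shuffles, seed=seed + 1)
    return p1, p2


def _top_and_rest_cells(
    counts: PairArrangementCounts,
) -> tuple[tuple[str, str, str], list[tuple[str, str, str]]]:
    """Most frequent cell (ties broken by lexicographically first label) and
    the three least frequent cells."""
    cells = counts.cells
    vec = counts.vector()
    order = sorted(range(len(cells)), key=lambda i: (-vec[i], cells[i]))
    top = cells[order[0]]
    rest = [cells[i] for i in order[-3:]]
    return top, rest


def pair_coexpression(
    instances: Sequence[PairInstance],
    counts: PairArrangementCounts,
    mode: str,
    expr: ExpressionMatrix,
    mapping: MappingTable | None = None,
    interval: IntervalSpec | None = None,
    pair_cap: int = 500_000,
    seed: int = 0,
) -> CoexpressionComparison:
    """Co-expression comparison for one motif pair.

    Modes:

    * ``both_vs_one`` — genes with a valid co-occurrence vs genes carrying
      exactly one of the two motifs (same-motif pairs: genes with the motif
      repeatedly vs exactly once); requires ``mapping`` and ``interval``.
    * ``order_1_vs_order_2`` — genes whose instances all have order 1-2 vs
      all order 2-1; genes showing both orders are excluded.
    * ``top_arrangement_vs_rest`` — genes harboring the most frequent
      arrangement vs genes harboring the three least frequent ones; genes
      in both arms are excluded.
    """
    m1, m2 = counts.motif_1, counts.motif_2
    genes_with_instance = {i.gene_id for i in instances}
    if mode == "both_vs_one":
        if mapping is None or interval is None:
            raise ValueError("both_vs_one mode needs mapping and interval")
        if counts.same_motif:
            hit_counts = {
                g: len(mapping.gene_hits(g, m1, interval))
                for g in mapping.genes_with(m1, interval)
            }
            set_a = genes_with_instance
            set_b = {g for g, n in hit_counts.items() if n == 1}
        else:
            g1 = mapping.genes_with(m1, interval)
            g2 = mapping.genes_with(m2, interval)
            set_a = genes_with_instance
            set_b = (g1 ^ g2)  # exactly one of the motifs
    elif mode == "order_1_vs_order_2":
        if counts.same_motif:
            raise ValueError("order mode undefined for same-motif pairs")
        g_order1 = {i.gene_id for i in instances if i.order == "1_then_2"}
        g_order2 = {i.gene_id for i in instances if i.order == "2_then_1"}
        set_a = g_order1 - g_order2
        set_b = g_order2 - g_order1
    elif mode == "top_arrangement_vs_rest":
        top, rest = _top_and_rest_cells(counts)
        rest_set = set(rest)

        def cell_of(inst: PairInstance) -> tuple[str, str, str]:
            order = "1_then_2" if counts.same_motif else inst.order
            return (order, *inst.orientations)

        g_top = {i.gene_id for i in instances if cell_of(i) == top}
        g_rest = {i.gene_id for i in instances if cell_of(i) in rest_set}
        set_a = g_top - g_rest
        set_b = g_rest - g_top
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return compare_sets(set_a, set_b, expr, pair_cap=pair_cap, seed=seed)
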