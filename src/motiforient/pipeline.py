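"""End-to-end orchestration: curate -> map -> test -> classify -> report.

Library counterpart of the analysis drivers and the CLI.  Every step
delegates to the topic modules; this module only wires them together,
keeps the statistics on a common motif universe, and renders the summary
tables.  All randomness flows from explicit seeds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import MotifSet
from .coexpression import (
    ExpressionMatrix,
    build_orientation_sets,
    build_presence_absence_sets,
    compare_sets,
)
from .mapping import MappingTable, map_catalog
from .orientation import (
    CoexprStat,
    MotifVerdict,
    OrientationTestResult,
    bh_adjust,
    classify_motifs,
    expected_forward_fraction,
    orientation_test,
    positional_entropy,
)
from .pairs import (
    arrangement_entropy_test,
    cooccurrence_enrichment,
    count_arrangements,
    find_pair_instances,
    order_test,
    pair_coexpression,
    secondary_order_conditional_tests,
)
from .upstream import IntervalSpec, UpstreamRegion, base_composition

__all__ = ["Thresholds", "RunConfig", "run_single_motif_analysis",
           "run_pair_analysis", "verdicts_frame", "summary_frame"]

DEFAULT_INTERVALS = (
    IntervalSpec(-500, -1),
    IntervalSpec(-250, -1),
    IntervalSpec(-100, -1),
    IntervalSpec(-500, -51),
)
CORE_PROMOTER_INTERVAL = IntervalSpec(-50, -1)
HUNDRED_NT_WINDOWS = tuple(
    IntervalSpec(start, start + 99) for start in range(-500, 0, 100)
)


@dataclass
class Thresholds:
    p: float = 0.05
    cohens_d: float = 0.01
    min_hits: int = 10
    min_pair_occurrences: int = 50
    min_pair_cooccurrences: int = 5   # strictly more than this are reported
    pair_cap: int = 500_000
    n_shuffles: int = 100_000


@dataclass
class RunConfig:
    motifs_path: str = ""
    fasta_path: str = ""
    expression_path: str = ""
    out_dir: str = "results"
    intervals: Sequence[IntervalSpec] = DEFAULT_INTERVALS
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    pair_max_gap: int | None = None


@dataclass
class SingleMotifAnalysis:
    """Per-interval verdicts plus the shared mapping/PE context."""

    verdicts: dict[IntervalSpec, list[MotifVerdict]]
    mapping: MappingTable
    pe_results: dict[str, dict]


def _coexpr_stat(set_a, set_b, expr, pair_cap, seed) -> CoexprStat:
    measurable_a = expr.measurable(set_a)
    measurable_b = expr.measurable(set_b)
    if len(measurable_a) < 2 or len(measurable_b) < 2:
        return CoexprStat(p=float("nan"), d=float("nan"),
                          mean_a=float("nan"), mean_b=float("nan"),
                          assessable=False)
    cmp = compare_sets(set_a, set_b, expr, pair_cap=pair_cap, seed=seed)
    return CoexprStat(p=cmp.p_r_diff, d=cmp.cohens_d,
                      mean_a=cmp.mean_r_a, mean_b=cmp.mean_r_b)


def run_single_motif_analysis(
    motifs: MotifSet,
    regions: Sequence[UpstreamRegion],
    expr: ExpressionMatrix,
    intervals: Sequence[IntervalSpec] = DEFAULT_INTERVALS,
    thresholds: Thresholds | None = None,
    seed: int = 0,
    region_length: int | None = None,
) -> SingleMotifAnalysis:
    """Run the full single-motif cascade for each interval.

    Positional entropies are always computed on the full-length scan (the
    one interval spanning the whole region), regardless of which interval's
    cascade they feed.
    """
    th = thresholds or Thresholds()
    L = region_length or regions[0].length
    full = IntervalSpec(-L, -1)
    analyzed = motifs.analyzable()
    scan_intervals = list(dict.fromkeys([*intervals, full]))
    mapping = map_catalog(analyzed, regions, scan_intervals)
    universe = set(expr.genes) & {r.gene_id for r in regions}

    # 500-bp positional entropies, per motif and orientation
    pe_results: dict[str, dict] = {}
    for m in analyzed:
        per_ori = {}
        for ori in ("fw", "rc"):
            hits = mapping.hits_for(m.id, full, ori)
            if hits:
                per_ori[ori] = positional_entropy(
                    hits, m.id, ori, region_length=L
                )
        pe_results[m.id] = per_ori

    verdicts: dict[IntervalSpec, list[MotifVerdict]] = {}
    for iv in intervals:
        comp = base_composition(regions, iv)
        orient: dict[str, OrientationTestResult] = {}
        presence: dict[str, CoexprStat] = {}
        orientation_cx: dict[str, CoexprStat] = {}
        pe_complete: dict[str, dict] = {}
        for k, m in enumerate(analyzed):
            n_fw = mapping.n_hits(m.id, iv, "fw")
            n_rc = mapping.n_hits(m.id, iv, "rc")
            F, p_fw, p_rc = expected_forward_fraction(m, comp)
            res = OrientationTestResult(
                motif_id=m.id, interval=iv, n_fw=n_fw, n_rc=n_rc,
                F_expected=F, P_fw=p_fw, P_rc=p_rc,
            )
            if n_fw + n_rc >= th.min_hits:
                res.p_orient, res.preferred = orientation_test(n_fw, n_rc, F)
            else:
                res.assessable = False
                res.p_orient = float("nan")
            orient[m.id] = res

            try:
                pos, neg = build_presence_absence_sets(
                    m.id, iv, mapping, universe, seed=seed * 100_003 + k
                )
                presence[m.id] = _coexpr_stat(
                    pos, neg, expr, th.pair_cap, seed * 100_003 + k
                )
            except ValueError:
                presence[m.id] = CoexprStat(
                    p=float("nan"), d=float("nan"), mean_a=float("nan"),
                    mean_b=float("nan"), assessable=False,
                )
            fw_only, rc_only = build_orientation_sets(m.id, iv, mapping)
            orientation_cx[m.id] = _coexpr_stat(
                fw_only & universe, rc_only & universe, expr,
                th.pair_cap, seed * 100_003 + k + 1,
            )
            # motifs with no full-length hits in an orientation keep an
            # empty PE dict entry; the cascade treats D3/F as failed there
            pe_complete[m.id] = pe_results[m.id]
        verdicts[iv] = classify_motifs(
            orient, presence, orientation_cx, pe_complete,
            p_threshold=th.p, d_threshold=th.cohens_d,
        )
    return SingleMotifAnalysis(verdicts=verdicts, mapping=mapping, pe_results=pe_results)


def verdicts_frame(verdicts: Sequence[MotifVerdict]) -> pd.DataFrame:
    rows = []
    for v in verdicts:
        row = {"motif_id": v.motif_id, "interval": str(v.interval)}
        row.update(v.flags)
        row.update(v.stats)
        rows.append(row)
    return pd.DataFrame(rows)


def summary_frame(
    verdicts_by_interval: dict[IntervalSpec, list[MotifVerdict]],
    filters: Sequence[str] = ("C", "D1", "D2", "D3", "E", "F"),
) -> pd.DataFrame:
    """Counts and percentages of motifs passing each filter per interval."""
    rows = []
    for iv, vs in verdicts_by_interval.items():
        n = len(vs)
        row: dict[str, object] = {"interval": str(iv), "n_motifs": n}
        for f in filters:
            k = sum(1 for v in vs if v.flags.get(f, False))
            row[f"{f}_n"] = k
            row[f"{f}_pct"] = 100.0 * k / n if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_pair_analysis(
    motifs: MotifSet,
    regions: Sequence[UpstreamRegion],
    expr: ExpressionMatrix,
    interval: IntervalSpec = IntervalSpec(-500, -51),
    thresholds: Thresholds | None = None,
    seed: int = 0,
    max_gap: int | None = None,
    mapping: MappingTable | None = None,
) -> dict[str, pd.DataFrame]:
    """Pair co-occurrence, order and arrangement analyses.

    Returns three tables: ``cooccurrence`` (hypergeometric enrichment of
    pairs with more than ``min_pair_cooccurrences`` co-occurring genes),
    ``order`` (binomial order preference for well-populated different-motif
    pairs) and ``arrangement`` (8-cell + per-order entropy tests with the
    arrangement-preferring verdict).
    """
    th = thresholds or Thresholds()
    subset = motifs.pair_subset()
    if mapping is None:
        mapping = map_catalog(subset, regions, [interval])
    universe_n = len(regions)
    universe_genes = set(expr.genes)

    pair_rows = []
    order_rows = []
    arr_rows = []
    pairs = list(itertools.combinations_with_replacement([m.id for m in subset], 2))
    for pair_index, (m1, m2) in enumerate(pairs):
        instances = find_pair_instances(mapping, m1, m2, interval, max_gap=max_gap)
        if not instances:
            continue
        counts = count_arrangements(instances, m1, m2)
        genes_both = {i.gene_id for i in instances}
        g1 = mapping.genes_with(m1, interval)
        g2 = mapping.genes_with(m2, interval)
        pseed = seed * 999_983 + pair_index

        if len(genes_both) > th.min_pair_cooccurrences:
            p_hyper = cooccurrence_enrichment(
                len(g1), len(g2), len(genes_both), universe_n
            )
            cx = _coexpr_stat_pair(
                instances, counts, "both_vs_one", expr, mapping, interval, th, pseed
            )
            pair_rows.append({
                "motif_1": m1, "motif_2": m2,
                "n_genes_1": len(g1), "n_genes_2": len(g2),
                "n_genes_both": len(genes_both),
                "p_hypergeom": p_hyper,
                "p_expr": cx[0], "cohens_d": cx[1],
            })

        if counts.n_total >= th.min_pair_occurrences:
            cells = counts.vector().tolist()
            if not counts.same_motif:
                p_order = order_test(counts, th.min_pair_occurrences)
                cx = _coexpr_stat_pair(
                    instances, counts, "order_1_vs_order_2", expr, mapping,
                    interval, th, pseed + 1,
                )
                k1, k2 = counts.order_totals()
                order_rows.append({
                    "motif_1": m1, "motif_2": m2,
                    "n_order_12": k1, "n_order_21": k2,
                    "cells": cells,
                    "p_binom": p_order,
                    "p_expr": cx[0], "cohens_d": cx[1],
                })
            h, p_emp = arrangement_entropy_test(
                counts, n_shuffles=th.n_shuffles, seed=pseed + 2
            )
            if counts.same_motif:
                p_sub1 = p_sub2 = float("nan")
            else:
                p_sub1, p_sub2 = secondary_order_conditional_tests(
                    counts, n_shuffles=th.n_shuffles, seed=pseed + 3
                )
            cx = _coexpr_stat_pair(
                instances, counts, "top_arrangement_vs_rest", expr, mapping,
                interval, th, pseed + 4,
            )
            arr_rows.append({
                "motif_1": m1, "motif_2": m2,
                "same_motif": counts.same_motif,
                "n_total": counts.n_total,
                "cells": cells,
                "entropy_H": h,
                "p_entropy": p_emp,
                "p_entropy_order12": p_sub1,
                "p_entropy_order21": p_sub2,
                "p_expr": cx[0], "cohens_d": cx[1],
            })

    cooc = pd.DataFrame(pair_rows)
    if not cooc.empty:
        cooc["q_hypergeom"] = bh_adjust(cooc["p_hypergeom"].to_numpy())
        cooc = cooc.sort_values("p_hypergeom").reset_index(drop=True)
    order = pd.DataFrame(order_rows)
    if not order.empty:
        order["q_binom"] = bh_adjust(order["p_binom"].to_numpy())
        order = order.sort_values("p_binom").reset_index(drop=True)
    arr = pd.DataFrame(arr_rows)
    if not arr.empty:
        arr["q_entropy"] = bh_adjust(arr["p_entropy"].to_numpy())
        sub_q1 = np.full(len(arr), np.nan)
        sub_q2 = np.full(len(arr), np.nan)
        diff = ~arr["same_motif"].to_numpy()
        if diff.any():
            sub_q1[diff] = bh_adjust(arr.loc[diff, "p_entropy_order12"].to_numpy())
            sub_q2[diff] = bh_adjust(arr.loc[diff, "p_entropy_order21"].to_numpy())
        arr["q_entropy_order12"] = sub_q1
        arr["q_entropy_order21"] = sub_q2
        alpha = th.p
        arr["arrangement_preferring"] = (
            (arr["q_entropy"] < alpha)
            & (arr["same_motif"]
               | ((arr["q_entropy_order12"] < alpha) & (arr["q_entropy_order21"] < alpha)))
        )
        arr = arr.sort_values("p_entropy").reset_index(drop=True)
    return {"cooccurrence": cooc, "order": order, "arrangement": arr}


def _coexpr_stat_pair(instances, counts, mode, expr, mapping, interval, th, seed):
    """(p, d) for one pair-co-expression mode; NaNs when not assessable."""
    try:
        cmp = pair_coexpression(
            instances, counts, mode, expr, mapping=mapping, interval=interval,
            pair_cap=th.pair_cap, seed=seed,
        )
        return cmp.p_r_diff, cmp.cohens_d
    except ValueError:
        return float("nan"), float("nan")


def write_tables(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                 prefix: str = "") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{prefix}{name}.tsv", sep="\t", index=False)
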