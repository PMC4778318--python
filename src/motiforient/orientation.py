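"""Orientation-preference and positional statistics for mapped motifs.

The central correction: on a strand with asymmetric base composition, a
non-palindromic motif is *expected* to match one orientation more often even
under a null of no biology.  The expected forward fraction is

    F = P_fw / (P_fw + P_rc),    P_fw/rc = prod_i sum_{b in variants(i)} p(b)

with p(b) the base frequencies of the scanned interval; an exact two-sided
binomial test then compares observed forward counts against F.  Orientation
preference is the sign of log((n_fw/n_rc) / (F/(1-F))).

Positional entropy (PE) summarises where a motif's hits fall along the
500-bp region: hits are binned into 10 equal windows by their 5'-most base
and PE = -sum p_i ln p_i, so ln 10 means uniform spread and 0 means complete
confinement to one window.

The per-motif filter cascade mirrors the single-motif analysis table:

    C  — motif presence (either orientation) associates with elevated
         co-expression (p_r_diff < 0.05 and Cohen's d > 0.01);
    D1 — significant orientation preference (BH-adjusted binomial q < 0.05);
    D2 — D1 and higher intra-set correlation among genes carrying the
         preferred orientation exclusively;
    D3 — D2 and strictly lower positional entropy in the preferred
         orientation;
    E  — the D2 criteria applied only to the C-passing subset, with the
         BH family re-formed over that subset;
    F  — E and lower positional entropy in the preferred orientation.

Nesting holds by construction: D3 => D2 => D1, F => E => C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import IUPAC_SETS, Motif, reverse_complement
from .mapping import MappingHit
from .upstream import CompositionProfile

__all__ = [
    "OrientationTestResult",
    "PositionalEntropyResult",
    "MotifVerdict",
    "expected_forward_fraction",
    "orientation_test",
    "positional_entropy",
    "bh_adjust",
    "classify_motifs",
]


@dataclass
class OrientationTestResult:
    motif_id: str
    interval: object
    n_fw: int
    n_rc: int
    F_expected: float
    P_fw: float
    P_rc: float
    p_orient: float = float("nan")
    q_orient: float = float("nan")
    preferred: str = "none"  # fw | rc | none
    assessable: bool = True


@dataclass
class PositionalEntropyResult:
    motif_id: str
    orientation: str
    bin_probs: np.ndarray
    PE: float


def expected_forward_fraction(
    motif: Motif | str, comp: CompositionProfile
) -> tuple[float, float, float]:
    """(F, P_fw, P_rc) under the interval's base composition.

    An ambiguous motif position contributes the summed frequencies of its
    allowed bases.  Requires strictly positive frequencies for all four
    bases so that neither product can vanish.
    """
    consensus = motif if isinstance(motif, str) else motif.consensus
    for b in "ACGT":
        if comp.freq[b] <= 0:
            raise ValueError(f"zero-probability base {b} in composition")

    def product(seq: str) -> float:
        p = 1.0
        for ch in seq:
            p *= sum(comp.freq[b] for b in IUPAC_SETS[ch])
        return p

    p_fw = product(consensus)
    p_rc = product(reverse_complement(consensus))
    return p_fw / (p_fw + p_rc), p_fw, p_rc


def orientation_test(
    n_fw: int, n_rc: int, F_expected: float
) -> tuple[float, str]:
    """Exact two-sided binomial test of the forward-mapping count.

    Returns (p, preferred) with preferred the sign of the log odds ratio of
    observed vs expected orientation: 'fw', 'rc', or 'none' when the
    observed ratio equals the expected one (or both counts are zero).
    """
    n = n_fw + n_rc
    if n == 0:
        return 1.0, "none"
    p = stats.binomtest(n_fw, n, F_expected, alternative="two-sided").pvalue
    # sign of log((n_fw/n_rc) / (F/(1-F))), with the 0-count limits
    expected_odds = F_expected / (1.0 - F_expected)
    if n_rc == 0:
        preferred = "fw" if n_fw > 0 else "none"
    elif n_fw == 0:
        preferred = "rc"
    else:
        ratio = (n_fw / n_rc) / expected_odds
        preferred = "fw" if ratio > 1 else ("rc" if ratio < 1 else "none")
    return float(p), preferred


def positional_entropy(
    hits: Sequence[MappingHit],
    motif_id: str = "",
    orientation: str = "",
    n_bins: int = 10,
    region_length: int = 500,
) -> PositionalEntropyResult:
    """Shannon entropy (nats) of hit start positions over equal bins.

    Hits are assigned to bins by their 5'-most base; bin 0 is the 5'-most
    (most upstream) window.  0*ln(0) is taken as 0, so PE ranges from 0
    (single-bin confinement) to ln(n_bins) (uniform).
    """
    if region_length % n_bins:
        raise ValueError("region_length must be divisible by n_bins")
    if not hits:
        raise ValueError("positional entropy undefined for zero hits")
    width = region_length // n_bins
    counts = np.zeros(n_bins)
    for h in hits:
        b = (h.start + region_length) // width
        if not 0 <= b < n_bins:
            raise ValueError(f"hit start {h.start} outside region of length {region_length}")
        counts[b] += 1
    probs = counts / counts.sum()
    nz = probs[probs > 0]
    pe = float(-(nz * np.log(nz)).sum())
    return PositionalEntropyResult(motif_id, orientation, probs, pe)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class MotifVerdict:
    motif_id: str
    interval: object
    flags: dict[str, bool] = field(default_factory=dict)
    stats: dict[str, float] = field(default_factory=dict)


@dataclass
class CoexprStat:
    """Minimal co-expression comparison summary used by the cascade."""

    p: float
    d: float
    mean_a: float
    mean_b: float
    assessable: bool = True


def classify_motifs(
    orientation_results: Mapping[str, OrientationTestResult],
    presence_coexpr: Mapping[str, CoexprStat],
    orientation_coexpr: Mapping[str, CoexprStat],
    pe_results: Mapping[str, Mapping[str, PositionalEntropyResult]],
    p_threshold: float = 0.05,
    d_threshold: float = 0.01,
    use_adjusted_orientation_p: bool = True,
) -> list[MotifVerdict]:
    """Evaluate the C/D1/D2/D3/E/F cascade over one motif universe.

    ``orientation_coexpr`` compares fw-only vs rc-only gene sets (set a =
    forward).  ``pe_results[motif]['fw'|'rc']`` hold 500-bp positional
    entropies.  Motifs missing any component statistic are excluded.

    Filter E re-runs the orientation test's BH correction restricted to the
    motifs passing C, per the analysis design of adjusting the multiple-
    testing family to the conditioned subset.
    """
    universe = [
        mid for mid in orientation_results
        if mid in presence_coexpr and mid in orientation_coexpr and mid in pe_results
    ]

    # family-wide BH over assessable orientation tests
    assessable = [m for m in universe if orientation_results[m].assessable]
    if assessable:
        q = bh_adjust([orientation_results[m].p_orient for m in assessable])
        for m, qv in zip(assessable, q):
            orientation_results[m].q_orient = float(qv)

    def d2_condition(mid: str) -> bool:
        o = orientation_results[mid]
        cx = orientation_coexpr[mid]
        if not cx.assessable or o.preferred == "none":
            return False
        # set a is the forward-only set: preferred orientation must be the
        # more co-expressed one, significantly and non-trivially so
        favoured = cx.mean_a > cx.mean_b if o.preferred == "fw" else cx.mean_b > cx.mean_a
        return favoured and cx.p < p_threshold and abs(cx.d) > d_threshold

    def d3_condition(mid: str) -> bool:
        o = orientation_results[mid]
        pes = pe_results[mid]
        if o.preferred not in pes or ("fw" not in pes or "rc" not in pes):
            return False
        other = "rc" if o.preferred == "fw" else "fw"
        return pes[o.preferred].PE < pes[other].PE

    verdicts: list[MotifVerdict] = []
    c_pass: set[str] = set()
    for mid in universe:
        cx = presence_coexpr[mid]
        if cx.assessable and cx.p < p_threshold and cx.d > d_threshold:
            c_pass.add(mid)

    # filter-E family: orientation BH re-formed over the C-passing subset
    e_q: dict[str, float] = {}
    e_family = [m for m in c_pass if orientation_results[m].assessable]
    if e_family:
        qs = bh_adjust([orientation_results[m].p_orient for m in e_family])
        e_q = {m: float(v) for m, v in zip(e_family, qs)}

    for mid in universe:
        o = orientation_results[mid]
        p_used = o.q_orient if use_adjusted_orientation_p else o.p_orient
        d1 = o.assessable and p_used < p_threshold
        d2 = d1 and d2_condition(mid)
        d3 = d2 and d3_condition(mid)
        c = mid in c_pass
        e = (
            c
            and o.assessable
            and (e_q.get(mid, math.inf) if use_adjusted_orientation_p else o.p_orient)
            < p_threshold
            and d2_condition(mid)
        )
        f = e and d3_condition(mid)
        pes = pe_results[mid]
        verdicts.append(
            MotifVerdict(
                motif_id=mid,
                interval=o.interval,
                flags={"C": c, "D1": d1, "D2": d2, "D3": d3, "E": e, "F": f},
                stats={
                    "n_fw": o.n_fw,
                    "n_rc": o.n_rc,
                    "F_expected": o.F_expected,
                    "p_orient": o.p_orient,
                    "q_orient": o.q_orient,
                    "p_r_diff": presence_coexpr[mid].p,
                    "cohens_d": presence_coexpr[mid].d,
                    "p_r_diff_orient": orientation_coexpr[mid].p,
                    "cohens_d_orient": orientation_coexpr[mid].d,
                    "PE_fw": pes["fw"].PE if "fw" in pes else math.nan,
                    "PE_rc": pes["rc"].PE if "rc" in pes else math.nan,
                },
            )
        )
    return verdicts
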