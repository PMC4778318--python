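"""First-order orientational sequence asymmetry via dinucleotide ratios.

Zero-order composition cannot make a strand directional by itself; the
first signal of directionality lives in dinucleotides.  For each of the 16
dinucleotides B1B2 we compute the occurrence ratio

    R_B1B2 = f_B1B2 / (p_B1 * p_B2)

(observed overlapping-dinucleotide frequency over its expectation under
positional independence, with p taken from the same interval), and the
dinucleotide orientation ratio

    DOR_B1B2 = R_B1B2 / R_rc(B1B2)

comparing a dinucleotide with its reverse complement.  log2(DOR) away from
zero means the succession B1->B2 is more (or less) likely than its mirrored
reading on the opposite strand — intrinsic strand directionality.  For the
four palindromic dinucleotides (AT, TA, CG, GC) DOR is identically 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Sequence

import pandas as pd

from .catalog import reverse_complement
from .upstream import (
    BASES,
    CompositionProfile,
    IntervalSpec,
    UpstreamRegion,
    base_composition,
    excise,
)

__all__ = [
    "DINUCLEOTIDES",
    "PALINDROMIC_DINUCLEOTIDES",
    "DinucleotideStats",
    "dinucleotide_frequencies",
    "occurrence_ratio",
    "dor_profile",
    "stats_frame",
]

DINUCLEOTIDES = tuple(a + b for a, b in product(BASES, BASES))
PALINDROMIC_DINUCLEOTIDES = ("AT", "TA", "CG", "GC")


@dataclass
class DinucleotideStats:
    interval: IntervalSpec
    f: dict[str, float]
    R: dict[str, float]
    DOR: dict[str, float]
    log2_DOR: dict[str, float]
    n_dinucleotides: int = 0


def dinucleotide_frequencies(
    regions: Sequence[UpstreamRegion], spec: IntervalSpec
) -> tuple[dict[str, float], int]:
    """Relative frequencies of overlapping dinucleotides within one interval.

    Dinucleotides are counted with step 1 inside each excised subsequence,
    never across gene boundaries; any position pair containing an ambiguity
    code is skipped.  Returns (frequencies, total counted).
    """
    if spec.width < 2:
        raise ValueError(f"interval {spec} too narrow for dinucleotides")
    counts = dict.fromkeys(DINUCLEOTIDES, 0)
    total = 0
    concrete = set(BASES)
    for region in regions:
        s = excise(region, spec)
        for i in range(len(s) - 1):
            a, b = s[i], s[i + 1]
            if a in concrete and b in concrete:
                counts[a + b] += 1
                total += 1
    if total == 0:
        raise ValueError(f"no countable dinucleotides in interval {spec}")
    return {d: c / total for d, c in counts.items()}, total


def occurrence_ratio(
    f: dict[str, float], comp: CompositionProfile
) -> dict[str, float]:
    """R = f_B1B2 / (p_B1 * p_B2) for each dinucleotide.

    A dinucleotide involving a base of zero frequency cannot occur (its f is
    necessarily 0 on the same interval); its ratio is undefined and reported
    as NaN.  An observed dinucleotide with a zero-probability base indicates
    inconsistent inputs and is rejected.
    """
    out: dict[str, float] = {}
    for d in DINUCLEOTIDES:
        denom = comp.freq[d[0]] * comp.freq[d[1]]
        if denom == 0:
            if f[d] > 0:
                raise ValueError(
                    f"dinucleotide {d} observed but a component base has zero probability"
                )
            out[d] = math.nan
        else:
            out[d] = f[d] / denom
    return out


def dor_profile(
    regions: Sequence[UpstreamRegion], windows: Sequence[IntervalSpec]
) -> list[DinucleotideStats]:
    """Per-window dinucleotide stats: f, R, DOR and log2(DOR).

    Palindromic dinucleotides are reported as exactly 1 (their R cancels).
    A dinucleotide whose reverse complement never occurs yields DOR = inf
    (log2 = inf); DOR(d) * DOR(rc(d)) = 1 holds for every defined pair.
    """
    for i, w in enumerate(windows):
        for v in windows[i + 1:]:
            if w.from_pos <= v.to_pos and v.from_pos <= w.to_pos:
                raise ValueError(f"windows {w} and {v} overlap")
    out = []
    for w in windows:
        f, total = dinucleotide_frequencies(regions, w)
        comp = base_composition(regions, w)
        R = occurrence_ratio(f, comp)
        dor: dict[str, float] = {}
        log2dor: dict[str, float] = {}
        for d in DINUCLEOTIDES:
            if d in PALINDROMIC_DINUCLEOTIDES:
                dor[d] = 1.0
                log2dor[d] = 0.0
                continue
            r_rc = R[reverse_complement(d)]
            if math.isnan(R[d]) or math.isnan(r_rc):
                dor[d] = math.nan
                log2dor[d] = math.nan
                continue
            if r_rc == 0:
                dor[d] = math.inf
                log2dor[d] = math.inf
                continue
            dor[d] = R[d] / r_rc
            log2dor[d] = math.log2(dor[d]) if dor[d] > 0 else -math.inf
        out.append(DinucleotideStats(w, f, R, dor, log2dor, total))
    return out


def stats_frame(stats: Sequence[DinucleotideStats]) -> pd.DataFrame:
    """Long-format table: window, dinucleotide, f, R, DOR, log2_DOR."""
    rows = [
        {
            "window": str(s.interval),
            "dinucleotide": d,
            "f": s.f[d],
            "R": s.R[d],
            "DOR": s.DOR[d],
            "log2_DOR": s.log2_DOR[d],
        }
        for s in stats
        for d in DINUCLEOTIDES
    ]
    return pd.DataFrame(rows)


def write_stats(stats: Sequence[DinucleotideStats], path: str | Path) -> None:
    stats_frame(stats).to_csv(path, sep="\t", index=False)
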