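"""Randomized motif controls and true-vs-random pass-rate comparisons.

Every true motif is replaced by ``multiplier`` random motifs of identical
length, with positions filled i.i.d. from one of two background character
distributions:

    R1 — canonical bases A/C/G/T at the frequencies of the scanned upstream
         interval (no ambiguity codes);
    R2 — the characters observed in the true motif set, ambiguity codes
         included, each treated as an atomic symbol at its observed
         frequency.

Filter pass-rates of true vs random motifs are compared per filter and
interval with two-sided Fisher exact tests, BH-corrected across the family.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import Motif, MotifSet, MotifSource
from .orientation import MotifVerdict, bh_adjust
from .upstream import BASES, CompositionProfile

__all__ = [
    "RandomizationConfig",
    "generate_random_motifs",
    "compare_pass_rates",
    "palindrome_enrichment_test",
    "run_control_battery",
]


@dataclass
class RandomizationConfig:
    background: str = "R1_upstream"  # or "R2_motif"
    multiplier: int = 5
    seed: int = 0
    composition: CompositionProfile | None = None  # required for R1

    def __post_init__(self) -> None:
        if self.background not in ("R1_upstream", "R2_motif"):
            raise ValueError(f"unknown background {self.background!r}")
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")
        if self.background == "R1_upstream" and self.composition is None:
            raise ValueError("R1 background requires an upstream composition")


def _character_distribution(true_set: Sequence[Motif]) -> tuple[list[str], np.ndarray]:
    counts: Counter[str] = Counter()
    for m in true_set:
        counts.update(m.consensus)
    chars = sorted(counts)
    total = sum(counts.values())
    return chars, np.array([counts[c] / total for c in chars])


def generate_random_motifs(
    true_set: MotifSet | Sequence[Motif], config: RandomizationConfig
) -> MotifSet:
    """Per-motif length-matched random replacements, i.i.d. per position."""
    motifs = list(true_set)
    if not motifs:
        raise ValueError("empty true motif set")
    rng = np.random.default_rng(config.seed)
    if config.background == "R1_upstream":
        chars = list(BASES)
        probs = np.array([config.composition.freq[b] for b in BASES])
        source = MotifSource.random_R1
        tag = "R1"
    else:
        chars, probs = _character_distribution(motifs)
        source = MotifSource.random_R2
        tag = "R2"
    out: list[Motif] = []
    for m in motifs:
        for k in range(config.multiplier):
            seq = "".join(rng.choice(chars, size=len(m.consensus), p=probs))
            out.append(Motif(f"{m.id}__{tag}_{k}", seq, source))
    return MotifSet(out, provenance=f"randomized:{tag} x{config.multiplier}")


def compare_pass_rates(k_true: int, n_true: int, k_rand: int, n_rand: int) -> float:
    """Two-sided Fisher exact p for a pass/fail x true/random 2x2 table."""
    if min(n_true, n_rand) == 0:
        raise ValueError("empty group")
    if not (0 <= k_true <= n_true and 0 <= k_rand <= n_rand):
        raise ValueError("inconsistent counts")
    table = [[k_true, n_true - k_true], [k_rand, n_rand - k_rand]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def palindrome_enrichment_test(
    k_true: int, n_true: int, k_random: int, n_random: int
) -> float:
    """Upper-tail binomial p for palindrome enrichment among true motifs.

    The background palindrome rate is estimated from a large randomized
    motif set (k_random / n_random); the p-value is the probability of
    observing at least ``k_true`` palindromes among ``n_true`` motifs at
    that rate.  Palindromy is a structural property evolution can select
    for; enrichment over the compositional background supports selection
    for orientation-invariant sites.
    """
    if not (0 <= k_true <= n_true) or not (0 < k_random <= n_random):
        raise ValueError("inconsistent palindrome counts")
    rate = k_random / n_random
    return float(stats.binom.sf(k_true - 1, n_true, rate))


def _pass_counts(verdicts: Sequence[MotifVerdict], filters: Sequence[str]) -> dict[str, int]:
    return {f: sum(1 for v in verdicts if v.flags.get(f, False)) for f in filters}


def run_control_battery(
    true_verdicts: Mapping[str, Sequence[MotifVerdict]],
    random_verdicts: Mapping[str, Mapping[str, Sequence[MotifVerdict]]],
    filters: Sequence[str] = ("C", "D1", "D2", "E"),
) -> pd.DataFrame:
    """Compare per-filter pass fractions of true vs random motif runs.

    ``true_verdicts`` maps interval label -> verdict list; ``random_verdicts``
    maps background label (R1/R2) -> interval label -> verdict list.  Fisher
    p-values are BH-corrected across all (filter, interval, background)
    comparisons.
    """
    rows = []
    for background, per_interval in random_verdicts.items():
        for interval, rand_v in per_interval.items():
            if interval not in true_verdicts:
                raise ValueError(f"missing true run for interval {interval}")
            true_v = true_verdicts[interval]
            n_t, n_r = len(true_v), len(rand_v)
            tc = _pass_counts(true_v, filters)
            rc = _pass_counts(rand_v, filters)
            for f in filters:
                rows.append(
                    {
                        "filter": f,
                        "interval": interval,
                        "background": background,
                        "n_true": n_t,
                        "k_true": tc[f],
                        "frac_true": tc[f] / n_t if n_t else np.nan,
                        "n_random": n_r,
                        "k_random": rc[f],
                        "frac_random": rc[f] / n_r if n_r else np.nan,
                        "fisher_p": compare_pass_rates(tc[f], n_t, rc[f], n_r),
                    }
                )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["fisher_q"] = bh_adjust(df["fisher_p"].to_numpy())
    return df
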