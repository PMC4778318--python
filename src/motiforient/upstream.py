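"""Gene-upstream promoter sequences and their base composition.

Sequences are coding-strand, 5'->3', anchored at the transcription start
site: the last base of each record sits at upstream position -1, the first
at -L for a region of length L.  All public coordinates are 1-based-negative
closed intervals (e.g. ``(-500, -1)`` is the full default region); 0-based
offsets never leave this module.

Composition counts ambiguity codes fractionally: an R contributes 1/2 to A
and 1/2 to G, an N a quarter to each base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import IUPAC_SETS

__all__ = [
    "UpstreamRegion",
    "IntervalSpec",
    "CompositionProfile",
    "read_upstream_fasta",
    "write_upstream_fasta",
    "excise",
    "base_composition",
    "cg_skew_profile",
    "composition_table",
]

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class UpstreamRegion:
    gene_id: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq.upper()) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"{self.gene_id}: non-IUPAC characters {sorted(bad)}")
        object.__setattr__(self, "seq", self.seq.upper())

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class IntervalSpec:
    """Closed upstream interval, both bounds negative, -1 adjacent to the TSS."""

    from_pos: int
    to_pos: int

    def __post_init__(self) -> None:
        if not (self.from_pos <= self.to_pos <= -1):
            raise ValueError(
                f"invalid interval ({self.from_pos}, {self.to_pos}): "
                "need from_pos <= to_pos <= -1"
            )

    @property
    def width(self) -> int:
        return self.to_pos - self.from_pos + 1

    def __str__(self) -> str:
        return f"{self.from_pos}..{self.to_pos}"


@dataclass
class CompositionProfile:
    interval: IntervalSpec
    freq: dict[str, float]
    n_positions: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.freq.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"frequencies sum to {total}, not 1")


def read_upstream_fasta(
    path: str | Path, strict: bool = True
) -> list[UpstreamRegion]:
    """Load one upstream region per gene from FASTA.

    In strict mode all records must share one length; otherwise longer
    records are truncated on the 5' side to the shortest length.
    """
    regions: list[UpstreamRegion] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate gene id {rec.id!r} in {path}")
        seen.add(rec.id)
        regions.append(UpstreamRegion(rec.id, str(rec.seq)))
    if not regions:
        raise ValueError(f"no FASTA records in {path}")
    lengths = {r.length for r in regions}
    if len(lengths) > 1:
        if strict:
            ref = regions[0].length
            offender = next(r for r in regions if r.length != ref)
            raise ValueError(
                f"mixed record lengths in {path}: {offender.gene_id} has "
                f"{offender.length}, expected {ref}"
            )
        target = min(lengths)
        regions = [
            UpstreamRegion(r.gene_id, r.seq[-target:]) for r in regions
        ]
    return regions


def write_upstream_fasta(regions: Iterable[UpstreamRegion], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(r.seq), id=r.gene_id, description="") for r in regions
    ]
    SeqIO.write(records, str(path), "fasta")


def excise(region: UpstreamRegion, spec: IntervalSpec) -> str:
    """Subsequence occupying upstream positions ``from_pos..to_pos``."""
    L = region.length
    if -spec.from_pos > L:
        raise ValueError(
            f"interval {spec} exceeds region length {L} for {region.gene_id}"
        )
    start = L + spec.from_pos
    stop = L + spec.to_pos + 1
    return region.seq[start:stop]


def base_composition(
    regions: Sequence[UpstreamRegion], spec: IntervalSpec
) -> CompositionProfile:
    """Pooled fractional base composition over one interval of every region."""
    counts = dict.fromkeys(BASES, 0.0)
    total = 0.0
    for region in regions:
        for ch in excise(region, spec):
            allowed = IUPAC_SETS[ch]
            w = 1.0 / len(allowed)
            for b in allowed:
                counts[b] += w
            total += 1.0
    if total == 0:
        raise ValueError(f"no positions in interval {spec}")
    return CompositionProfile(
        spec, {b: counts[b] / total for b in BASES}, n_positions=total
    )


def cg_skew_profile(
    regions: Sequence[UpstreamRegion], window: int
) -> list[tuple[IntervalSpec, float]]:
    """Per-window C/G frequency ratio, 5'-most window first.

    Windows partition the region; a window with zero G frequency yields
    ``math.inf``.
    """
    L = regions[0].length
    if L % window:
        raise ValueError(f"window {window} does not divide region length {L}")
    out: list[tuple[IntervalSpec, float]] = []
    for start in range(-L, 0, window):
        spec = IntervalSpec(start, start + window - 1)
        comp = base_composition(regions, spec)
        g = comp.freq["G"]
        ratio = math.inf if g == 0 else comp.freq["C"] / g
        out.append((spec, ratio))
    return out


def composition_table(
    regions: Sequence[UpstreamRegion], intervals: Iterable[IntervalSpec]
) -> "list[dict[str, object]]":
    """Rows of interval + percent composition, one per interval."""
    rows = []
    for spec in intervals:
        comp = base_composition(regions, spec)
        row: dict[str, object] = {"interval": str(spec)}
        row.update({b: 100.0 * comp.freq[b] for b in BASES})
        rows.append(row)
    return rows
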