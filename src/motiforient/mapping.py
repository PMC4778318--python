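"""Scan upstream intervals with consensus motifs in both orientations.

Matching mirrors global regular-expression semantics: each IUPAC position
becomes a character class over its allowed canonical bases, and successive
matches are leftmost-greedy and non-overlapping (the scan resumes after the
last matched base).  A genomic ambiguity character never satisfies a motif
position — only concrete A/C/G/T bases in the position's variant set match —
so masked sequence cannot inflate hit counts.

Forward and reverse-complement scans are independent passes over the same
coding strand; the reverse scan matches the reverse-complemented consensus.
Interval scans run on the excised subsequence, so a match can never straddle
an interval boundary; each scan's hits are stored under its own
(motif, interval, orientation) key.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .catalog import IUPAC_SETS, Motif, MotifSet, reverse_complement
from .upstream import IntervalSpec, UpstreamRegion, excise

__all__ = ["MappingHit", "MappingTable", "compile_pattern", "scan", "map_catalog"]

Orientation = Literal["fw", "rc"]


def compile_pattern(consensus: str) -> re.Pattern[str]:
    """IUPAC consensus -> compiled regex over concrete bases only."""
    parts = []
    for ch in consensus:
        bases = sorted(IUPAC_SETS[ch])
        parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    return re.compile("".join(parts))


@dataclass(frozen=True)
class MappingHit:
    gene_id: str
    motif_id: str
    orientation: Orientation
    start: int  # upstream position of the 5'-most matched base (negative)
    end: int    # upstream position of the 3'-most matched base

    def __post_init__(self) -> None:
        if not (self.start <= self.end <= -1):
            raise ValueError(f"bad hit coordinates {self.start}..{self.end}")

    def overlaps(self, other: "MappingHit") -> bool:
        return self.start <= other.end and other.start <= self.end


def scan(
    motif: Motif,
    seq: str,
    orientation: Orientation,
    gene_id: str = "",
    offset: int | None = None,
) -> list[MappingHit]:
    """Leftmost-greedy non-overlapping matches of a motif on one sequence.

    ``offset`` is the upstream position of ``seq[0]``; defaults to
    ``-len(seq)`` (the sequence ends at position -1).
    """
    if offset is None:
        offset = -len(seq)
    pattern = motif.consensus
    if orientation == "rc":
        pattern = reverse_complement(pattern)
    rx = compile_pattern(pattern)
    return [
        MappingHit(
            gene_id=gene_id,
            motif_id=motif.id,
            orientation=orientation,
            start=offset + m.start(),
            end=offset + m.end() - 1,
        )
        for m in rx.finditer(seq.upper())
    ]


Key = tuple[str, IntervalSpec, str]


@dataclass
class MappingTable:
    """Per-(motif, interval, orientation) hits, counts and gene sets."""

    hits_by: dict[Key, list[MappingHit]] = field(default_factory=dict)
    counts: dict[Key, int] = field(default_factory=dict)
    gene_sets: dict[Key, set[str]] = field(default_factory=dict)
    intervals: list[IntervalSpec] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def n_hits(self, motif_id: str, interval: IntervalSpec, orientation: str) -> int:
        return self.counts.get((motif_id, interval, orientation), 0)

    def genes_with(self, motif_id: str, interval: IntervalSpec,
                   orientation: str | None = None) -> set[str]:
        if orientation is not None:
            return set(self.gene_sets.get((motif_id, interval, orientation), set()))
        return self.genes_with(motif_id, interval, "fw") | self.genes_with(
            motif_id, interval, "rc"
        )

    def exclusive_sets(
        self, motif_id: str, interval: IntervalSpec
    ) -> tuple[set[str], set[str], set[str]]:
        """(fw-only, rc-only, both) gene sets for one motif and interval."""
        fw = self.genes_with(motif_id, interval, "fw")
        rc = self.genes_with(motif_id, interval, "rc")
        return fw - rc, rc - fw, fw & rc

    def hits_for(self, motif_id: str, interval: IntervalSpec,
                 orientation: str | None = None) -> list[MappingHit]:
        oris = ("fw", "rc") if orientation is None else (orientation,)
        out: list[MappingHit] = []
        for ori in oris:
            out.extend(self.hits_by.get((motif_id, interval, ori), []))
        return out

    def gene_hits(self, gene_id: str, motif_id: str, interval: IntervalSpec,
                  orientation: str | None = None) -> list[MappingHit]:
        return [h for h in self.hits_for(motif_id, interval, orientation)
                if h.gene_id == gene_id]

    def counts_frame(self) -> pd.DataFrame:
        rows = [
            {
                "motif_id": mid,
                "interval": str(iv),
                "orientation": ori,
                "n_hits": n,
                "n_genes": len(self.gene_sets.get((mid, iv, ori), set())),
            }
            for (mid, iv, ori), n in sorted(
                self.counts.items(), key=lambda kv: (kv[0][0], str(kv[0][1]), kv[0][2])
            )
        ]
        return pd.DataFrame(
            rows, columns=["motif_id", "interval", "orientation", "n_hits", "n_genes"]
        )

    def write_hits_bed(self, path: str | Path, region_length: int) -> None:
        """BED-like 6-column TSV; offsets are 0-based within the region."""
        lines = [
            "# columns: gene_id, start0, end_halfopen, motif_id, score, strand; "
            f"start0 = upstream_position + {region_length}"
        ]
        flat = [h for hits in self.hits_by.values() for h in hits]
        for h in sorted(flat, key=lambda h: (h.gene_id, h.start, h.motif_id)):
            s0 = h.start + region_length
            e0 = h.end + region_length + 1
            strand = "+" if h.orientation == "fw" else "-"
            lines.append(f"{h.gene_id}\t{s0}\t{e0}\t{h.motif_id}\t.\t{strand}")
        Path(path).write_text("\n".join(lines) + "\n")


def map_catalog(
    motifs: MotifSet | Sequence[Motif],
    regions: Sequence[UpstreamRegion],
    intervals: Iterable[IntervalSpec],
) -> MappingTable:
    """Scan every motif x interval x orientation over all regions."""
    motif_list = list(motifs)
    table = MappingTable(
        intervals=list(intervals), gene_ids=[r.gene_id for r in regions]
    )
    patterns: dict[tuple[str, str], re.Pattern[str]] = {}
    for m in motif_list:
        patterns[(m.id, "fw")] = compile_pattern(m.consensus)
        patterns[(m.id, "rc")] = compile_pattern(reverse_complement(m.consensus))

    for iv in table.intervals:
        sub = [(r.gene_id, excise(r, iv)) for r in regions]
        for m in motif_list:
            for ori in ("fw", "rc"):
                rx = patterns[(m.id, ori)]
                key: Key = (m.id, iv, ori)
                hits: list[MappingHit] = []
                genes: set[str] = set()
                for gene_id, s in sub:
                    for match in rx.finditer(s):
                        hits.append(
                            MappingHit(
                                gene_id=gene_id,
                                motif_id=m.id,
                                orientation=ori,  # type: ignore[arg-type]
                                start=iv.from_pos + match.start(),
                                end=iv.from_pos + match.end() - 1,
                            )
                        )
                        genes.add(gene_id)
                table.hits_by[key] = hits
                table.counts[key] = len(hits)
                table.gene_sets[key] = genes
    return table
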