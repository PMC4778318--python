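"""IUPAC consensus motif catalogs: parsing, sequence algebra and curation.

A motif is a short cis-regulatory consensus written in the IUPAC nucleotide
alphabet (A, C, G, T plus the ambiguity codes R, Y, S, W, K, M, B, D, H, V,
N).  Because transcription-factor binding sites sit on double-stranded DNA,
every motif has a reverse-complement twin presenting the identical molecular
interaction surface; palindromic motifs are their own twin and are therefore
orientation-invariant by construction.

Curation follows a fixed cascade: terminal-N trimming, a minimum number of
unambiguous bases, removal of long N runs, exact-duplicate removal,
palindrome flagging, and containment flagging (a shorter motif whose match
set is swallowed by a longer one).  Contained motifs stay in the catalog but
are marked; pair analyses use only the fully uncontained subset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "IUPAC_SETS",
    "IUPAC_COMPLEMENT",
    "Motif",
    "MotifSet",
    "MotifSource",
    "reverse_complement",
    "is_palindromic",
    "expand_variants",
    "degeneracy",
    "curate_catalog",
    "read_catalog",
    "write_catalog",
]

#: Per-code sets of allowed canonical bases.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Inverse lookup: base set -> code.
_SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_BASE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Complement of each code: the code whose variant set is the base-wise
#: complement of the original set (R<->Y, K<->M, B<->V, D<->H; S, W, N fixed).
IUPAC_COMPLEMENT: dict[str, str] = {
    code: _SET_TO_CODE[frozenset(_BASE_COMPLEMENT[b] for b in bases)]
    for code, bases in IUPAC_SETS.items()
}


class MotifSource(str, Enum):
    literature = "literature"
    pbm = "pbm"
    core_promoter = "core_promoter"
    random_R1 = "random_R1"
    random_R2 = "random_R2"


def _validate(seq: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in IUPAC_SETS:
            raise ValueError(
                f"invalid IUPAC character {ch!r} at position {i} in {seq!r}"
            )


def reverse_complement(seq: str) -> str:
    """Reverse-complement an IUPAC string (e.g. ``TATAAA`` -> ``TTTATA``)."""
    _validate(seq)
    return "".join(IUPAC_COMPLEMENT[ch] for ch in reversed(seq))


def is_palindromic(seq: str) -> bool:
    """True iff the sequence equals its own reverse complement."""
    return reverse_complement(seq) == seq


def degeneracy(seq: str) -> int:
    """Number of unambiguous sequence variants the consensus denotes."""
    _validate(seq)
    n = 1
    for ch in seq:
        n *= len(IUPAC_SETS[ch])
    return n


def expand_variants(seq: str, cap: int = 4096) -> set[str]:
    """All unambiguous A/C/G/T strings matching the consensus.

    Refuses consensi whose degeneracy product exceeds ``cap`` so that a
    pathological all-N motif cannot blow up memory.
    """
    d = degeneracy(seq)
    if d > cap:
        raise ValueError(
            f"motif {seq!r} denotes {d} variants, exceeding the cap of {cap}"
        )
    pools = [sorted(IUPAC_SETS[ch]) for ch in seq]
    return {"".join(p) for p in itertools.product(*pools)}


@dataclass
class Motif:
    """One consensus motif with its provenance and curation flags."""

    id: str
    consensus: str
    source: MotifSource = MotifSource.literature
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        _validate(self.consensus)

    def __len__(self) -> int:
        return len(self.consensus)

    @property
    def n_unambiguous(self) -> int:
        return sum(1 for ch in self.consensus if ch in "ACGT")

    @property
    def dropped(self) -> bool:
        return any(f.startswith("dropped") for f in self.flags) or "duplicate" in self.flags

    @property
    def contained(self) -> bool:
        return bool(self.flags & {"contained_explicit", "contained_variant"})


@dataclass
class MotifSet:
    """Ordered motif collection with unique ids."""

    motifs: list[Motif] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [m.id for m in self.motifs]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate motif id {dup!r}")

    def __iter__(self) -> Iterator[Motif]:
        return iter(self.motifs)

    def __len__(self) -> int:
        return len(self.motifs)

    def __getitem__(self, motif_id: str) -> Motif:
        for m in self.motifs:
            if m.id == motif_id:
                return m
        raise KeyError(motif_id)

    def analyzable(self) -> list[Motif]:
        """Motifs entering single-motif analyses: not dropped, not palindromic.

        Contained motifs are kept (flagged only).
        """
        return [
            m for m in self.motifs
            if not m.dropped and "palindromic" not in m.flags
        ]

    def pair_subset(self) -> list[Motif]:
        """Motifs entering pair analyses: analyzable and fully uncontained."""
        return [m for m in self.analyzable() if not m.contained]


def _variant_contained(short: str, long: str) -> bool:
    """Per-position variant-set subset containment at any offset (forward)."""
    ls, ll = len(short), len(long)
    if ls > ll:
        return False
    sets_s = [IUPAC_SETS[c] for c in short]
    sets_l = [IUPAC_SETS[c] for c in long]
    for off in range(ll - ls + 1):
        if all(sets_s[i] <= sets_l[off + i] for i in range(ls)):
            return True
    return False


def curate_catalog(
    raw: MotifSet,
    min_unambiguous: int = 4,
    n_run_limit: int = 4,
    variant_containment: bool = True,
    rc_containment: bool = False,
) -> MotifSet:
    """Apply the curation cascade and return a new, flagged MotifSet.

    Steps, in order: trim terminal Ns; drop motifs with fewer than
    ``min_unambiguous`` unambiguous bases; drop motifs containing a run of
    ``n_run_limit`` or more consecutive Ns; drop exact duplicate consensi
    (first occurrence kept); flag palindromes; flag containment, explicitly
    (plain substring) and, when ``variant_containment``, by per-position
    variant-set subsets at any offset.  Containment is checked in the forward
    orientation only unless ``rc_containment`` is set.

    Idempotent: curating an already-curated set changes nothing.
    """
    curated: list[Motif] = []
    for m in raw:
        seq = m.consensus.strip("N")
        flags = set(m.flags)
        if not seq:
            flags.add("dropped_short")
            curated.append(replace(m, consensus=m.consensus, flags=flags))
            continue
        nm = replace(m, consensus=seq, flags=flags)
        if nm.n_unambiguous < min_unambiguous:
            flags.add("dropped_short")
        if "N" * n_run_limit in seq:
            flags.add("dropped_n_run")
        curated.append(replace(nm, flags=flags))

    seen: dict[str, str] = {}
    for m in curated:
        if m.dropped:
            continue
        if m.consensus in seen:
            m.flags.add("duplicate")
        else:
            seen[m.consensus] = m.id

    survivors = [m for m in curated if not m.dropped]
    for m in survivors:
        if is_palindromic(m.consensus):
            m.flags.add("palindromic")

    for m in survivors:
        targets = [m.consensus]
        if rc_containment:
            targets.append(reverse_complement(m.consensus))
        for other in survivors:
            if other.id == m.id or len(other.consensus) < len(m.consensus):
                continue
            if len(other.consensus) == len(m.consensus) and other.consensus == m.consensus:
                continue
            for t in targets:
                if t in other.consensus:
                    m.flags.add("contained_explicit")
                if variant_containment and _variant_contained(t, other.consensus):
                    m.flags.add("contained_variant")

    result = MotifSet(curated, provenance=raw.provenance or "curated")
    if not result.analyzable():
        raise ValueError("curation left no analyzable motifs")
    return result


def read_catalog(path: str | Path, provenance: str = "") -> MotifSet:
    """Read a tab-separated motif catalog: motif_id, consensus, source.

    Lines starting with ``#`` are comments.  An optional fourth column holds
    comma-joined flags (as written by :func:`write_catalog`).
    """
    motifs: list[Motif] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
        mid, consensus, source = parts[0], parts[1].upper(), parts[2]
        flags = set(parts[3].split(",")) - {""} if len(parts) > 3 else set()
        motifs.append(Motif(mid, consensus, MotifSource(source), flags))
    return MotifSet(motifs, provenance=provenance or str(path))


def write_catalog(motifs: MotifSet | Iterable[Motif], path: str | Path) -> None:
    """Write a catalog TSV with a flags column (comma-joined, may be empty)."""
    lines = ["#motif_id\tconsensus\tsource\tflags"]
    for m in motifs:
        lines.append(
            f"{m.id}\t{m.consensus}\t{m.source.value}\t{','.join(sorted(m.flags))}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
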