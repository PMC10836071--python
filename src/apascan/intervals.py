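"""Genomic interval primitives.

Internal convention throughout the package: 0-based half-open coordinates
``[start, end)`` with explicit strand.  GTF input/output converts from/to the
1-based closed convention; junction tables convert on ingest.  All
strand-aware notions (5'/3' end, proximal/distal, upstream/downstream) are
derived from the strand here, once, so downstream modules never reimplement
the arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

STRANDS = ("+", "-")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    ``strand`` may be ``"."`` for strand-less features (e.g. merged binding
    peaks); transcript-derived intervals always carry ``+`` or ``-``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    # -- strand-aware anchors -------------------------------------------------
    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5'-most nucleotide (0-based)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        """Genomic coordinate of the 3'-most nucleotide (0-based)."""
        return self.end - 1 if self.strand == "+" else self.start

    def same_strand(self, other: "GenomicInterval") -> bool:
        return self.strand == other.strand or "." in (self.strand, other.strand)

    def overlaps(self, other: "GenomicInterval", stranded: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and not self.same_strand(other):
            return False
        return self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval", stranded: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and not self.same_strand(other):
            return False
        return self.start <= other.start and other.end <= self.end

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def with_strand(self, strand: str) -> "GenomicInterval":
        return replace(self, strand=strand)

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)

    # -- strand-aware edits ---------------------------------------------------
    def with_three_prime(self, pos: int) -> "GenomicInterval":
        """Return a copy whose 3'-terminal nucleotide is ``pos``."""
        if self.strand == "+":
            if pos < self.start:
                raise ValueError("3'end before interval start")
            return replace(self, end=pos + 1)
        if self.strand == "-":
            if pos >= self.end:
                raise ValueError("3'end beyond interval end")
            return replace(self, start=pos)
        raise ValueError("with_three_prime requires a stranded interval")

    def extension_beyond(self, other: "GenomicInterval") -> int:
        """Distance (nt) by which this interval's 3'end extends past *other*'s.

        Positive when this interval ends strictly 3' of *other*, strand-aware.
        """
        if self.strand == "+":
            return self.end - other.end
        return other.start - self.start


def merge_intervals(ivs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping-or-touching intervals per (chrom, strand)."""
    out: list[GenomicInterval] = []
    by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in ivs:
        by_key.setdefault((iv.chrom, iv.strand), []).append(iv)
    for (chrom, strand), group in sorted(by_key.items()):
        group.sort(key=lambda iv: iv.start)
        cur_start, cur_end = group[0].start, group[0].end
        for iv in group[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end, strand))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end, strand))
    return out


def subtract_intervals(
    iv: GenomicInterval, others: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Parts of *iv* not covered by any interval in *others* (strand ignored)."""
    cuts = sorted(
        (max(iv.start, o.start), min(iv.end, o.end))
        for o in others
        if o.chrom == iv.chrom and o.start < iv.end and iv.start < o.end
    )
    out: list[GenomicInterval] = []
    cursor = iv.start
    for s, e in cuts:
        if s > cursor:
            out.append(GenomicInterval(iv.chrom, cursor, s, iv.strand))
        cursor = max(cursor, e)
    if cursor < iv.end:
        out.append(GenomicInterval(iv.chrom, cursor, iv.end, iv.strand))
    return out
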