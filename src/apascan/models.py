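"""Transcript and annotation containers with strand-aware derived indices."""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .config import PipelineConfig
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


@dataclass
class TranscriptModel:
    """An exon-chain transcript model.

    Exons are sorted by genomic start and must be non-overlapping, on a
    single chromosome and strand.  Introns are the gaps between consecutive
    exons.  First/internal/last exon roles are strand-aware: on the minus
    strand the genomically-last exon is the *first* exon.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id}: no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"transcript {self.transcript_id}: exons on mixed "
                f"chrom/strand ({chroms}, {strands})"
            )
        if self.exons[0].strand not in ("+", "-"):
            raise ValidationError(
                f"transcript {self.transcript_id}: exons must be stranded"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, in genomic order."""
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]

    # -- strand-aware roles ---------------------------------------------------
    @property
    def first_exon(self) -> GenomicInterval:
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    @property
    def last_exon(self) -> GenomicInterval:
        return self.exons[-1] if self.strand == "+" else self.exons[0]

    @property
    def internal_exons(self) -> list[GenomicInterval]:
        return self.exons[1:-1]

    @property
    def last_intron(self) -> Optional[GenomicInterval]:
        """The intron adjacent to the last exon; None for mono-exonic models."""
        introns = self.introns
        if not introns:
            return None
        return introns[-1] if self.strand == "+" else introns[0]

    @property
    def three_prime_end(self) -> int:
        return self.last_exon.three_prime

    def intron_chain(self) -> tuple:
        """Hashable identity key: identical intron chains = same transcript."""
        return (
            self.chrom,
            self.strand,
            tuple((iv.start, iv.end) for iv in self.introns),
        )


def intron_five_prime_ss(intron: GenomicInterval) -> int:
    """Donor (5' splice site) boundary of an intron, half-open convention.

    For ``+`` the donor is the intron start; for ``-`` the intron end.  The
    same convention is applied to assembled and annotated introns, so exact
    matching is well-defined.
    """
    return intron.start if intron.strand == "+" else intron.end


@dataclass
class AnnotationSet:
    """A set of transcript models plus deterministically derived indices."""

    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        self._by_gene: dict[str, list[TranscriptModel]] = {}
        for tx in self.transcripts:
            self._by_gene.setdefault(tx.gene_id, []).append(tx)
        self._by_id = {tx.transcript_id: tx for tx in self.transcripts}

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts)

    def __len__(self) -> int:
        return len(self.transcripts)

    @property
    def gene_ids(self) -> list[str]:
        return list(self._by_gene)

    def gene_transcripts(self, gene_id: str) -> list[TranscriptModel]:
        return self._by_gene.get(gene_id, [])

    def get(self, transcript_id: str) -> Optional[TranscriptModel]:
        return self._by_id.get(transcript_id)

    # -- derived indices ------------------------------------------------------
    def exons_with_roles(self, gene_id: str) -> list[tuple[GenomicInterval, str, str]]:
        """(exon, role in {first, internal, last}, transcript_id) per gene."""
        out = []
        for tx in self.gene_transcripts(gene_id):
            if len(tx.exons) == 1:
                out.append((tx.exons[0], "last", tx.transcript_id))
                continue
            out.append((tx.first_exon, "first", tx.transcript_id))
            out.append((tx.last_exon, "last", tx.transcript_id))
            for e in tx.exons:
                if e is not tx.first_exon and e is not tx.last_exon:
                    out.append((e, "internal", tx.transcript_id))
        return out

    def gene_introns(self, gene_id: str) -> list[GenomicInterval]:
        seen = set()
        out = []
        for tx in self.gene_transcripts(gene_id):
            for iv in tx.introns:
                key = (iv.start, iv.end)
                if key not in seen:
                    seen.add(key)
                    out.append(iv)
        return out

    def gene_five_prime_splice_sites(self, gene_id: str) -> set[int]:
        return {
            intron_five_prime_ss(iv) for iv in self.gene_introns(gene_id)
        }

    def most_distal_last_exon(self, gene_id: str) -> Optional[GenomicInterval]:
        """Per-gene most distal annotated last exon, by strand-aware 3'end."""
        last = [tx.last_exon for tx in self.gene_transcripts(gene_id)]
        if not last:
            return None
        if last[0].strand == "+":
            return max(last, key=lambda e: e.three_prime)
        return min(last, key=lambda e: e.three_prime)

    def overlapping_genes(self, iv: GenomicInterval, stranded: bool = True) -> list[str]:
        hits = []
        for gene_id, txs in self._by_gene.items():
            for tx in txs:
                if tx.span.overlaps(iv, stranded=stranded):
                    hits.append(gene_id)
                    break
        return hits

    def all_exons(self) -> list[GenomicInterval]:
        return [e for tx in self.transcripts for e in tx.exons]


_TSL_RE = re.compile(r"^\s*(\d+)")


def parse_tsl(value: str) -> Optional[int]:
    """Parse a transcript_support_level attribute; None for NA/unparsable."""
    m = _TSL_RE.match(value or "")
    return int(m.group(1)) if m else None


def filter_reference(ann: AnnotationSet, cfg: PipelineConfig) -> AnnotationSet:
    """Restrict a reference annotation to well-supported mRNA-like models.

    Keeps transcripts with transcript_support_level in ``cfg.tsl_keep``
    (default {1,2,3}), gene biotype protein_coding or lncRNA, and without the
    mRNA_end_NF tag (unsupported 3'ends).  Transcripts lacking a TSL
    attribute are dropped with a logged count rather than an error.
    """
    kept: list[TranscriptModel] = []
    n_missing_tsl = 0
    for tx in ann:
        biotype = tx.attributes.get("gene_type") or tx.attributes.get("gene_biotype")
        if biotype not in ("protein_coding", "lncRNA"):
            continue
        tags = tx.attributes.get("tag", "")
        if "mRNA_end_NF" in tags.split(","):
            continue
        tsl_raw = tx.attributes.get("transcript_support_level")
        tsl = parse_tsl(tsl_raw) if tsl_raw is not None else None
        if tsl is None:
            n_missing_tsl += 1
            continue
        if tsl not in cfg.tsl_keep:
            continue
        kept.append(tx)
    if n_missing_tsl:
        logger.info(
            "filter_reference: dropped %d transcripts with missing/NA "
            "transcript_support_level", n_missing_tsl,
        )
    return AnnotationSet(kept)


@dataclass(frozen=True)
class PolyASiteRecord:
    """One polyA-site atlas cluster with its representative coordinate."""

    chrom: str
    cluster: GenomicInterval
    representative_coord: int
    strand: str
    site_id: str = ""

    def __post_init__(self) -> None:
        if not (
            self.cluster.start <= self.representative_coord < self.cluster.end
        ):
            raise ValidationError(
                f"atlas record {self.site_id or self.chrom}: representative "
                f"coordinate {self.representative_coord} outside cluster "
                f"[{self.cluster.start},{self.cluster.end})"
            )


@dataclass
class PolyASiteAtlas:
    records: list[PolyASiteRecord]

    def __post_init__(self) -> None:
        self._index: dict[tuple[str, str], list[PolyASiteRecord]] = {}
        for rec in self.records:
            self._index.setdefault((rec.chrom, rec.strand), []).append(rec)
        for group in self._index.values():
            group.sort(key=lambda r: r.representative_coord)

    def __len__(self) -> int:
        return len(self.records)

    def same_strand_records(self, chrom: str, strand: str) -> list[PolyASiteRecord]:
        return self._index.get((chrom, strand), [])

    def nearest(self, chrom: str, strand: str, pos: int) -> Optional[PolyASiteRecord]:
        """Nearest record by representative coordinate, either direction.

        Equidistant ties resolve to the more proximal site: the smaller
        coordinate on ``+``, the larger on ``-`` (closer to the gene 5' end).
        """
        recs = self.same_strand_records(chrom, strand)
        if not recs:
            return None

        def key(r: PolyASiteRecord):
            d = abs(r.representative_coord - pos)
            proximal = (
                r.representative_coord if strand == "+" else -r.representative_coord
            )
            return (d, proximal)

        return min(recs, key=key)
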