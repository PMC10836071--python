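"""Merged last-exon isoform reference, decoy transcripts and ALE junctions.

The quantification reference combines annotated last exons of every retained
reference transcript with the validated novel events.  Within a gene, last
exons sharing any overlapping sequence receive a common *last-exon isoform
identifier*; 3'UTR extensions are the exception — each gets its own
identifier while the annotated last exon(s) it extends share a single
grouped identifier, so extension usage is compared against all other
annotated last exons of the gene.  To prevent misattribution of reads,
regions overlapping annotated first/internal exons are subtracted (only
"unique" last-exon regions are retained) and last exons whose 3'end sits
inside a first/internal exon are removed entirely.

For quantification of nuclear RNA (which mixes nascent and processed
transcripts), decoy transcript models absorb intron-retaining reads: IPA
events receive a spliced and an intron-retention decoy per annotated
transcript context, ALEs a retained-intron decoy consuming the entire host
intron, 3'UTR extensions none.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .intervals import GenomicInterval, subtract_intervals
from .discovery import LastExonEvent
from .models import AnnotationSet

logger = logging.getLogger(__name__)


@dataclass
class LastExonIsoform:
    isoform_id: str
    gene_id: str
    category: str  # "annotated" or the novel category of its member event
    members: list[str]  # transcript ids and/or event ids
    last_exons: list[GenomicInterval]
    unique_regions: list[GenomicInterval]


@dataclass
class LastExonReference:
    isoforms: list[LastExonIsoform]
    tx2iso: dict[str, str]  # transcript/event id -> isoform id
    events: dict[str, LastExonEvent] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_gene: dict[str, list[LastExonIsoform]] = {}
        for iso in self.isoforms:
            self._by_gene.setdefault(iso.gene_id, []).append(iso)
        self.iso2gene = {iso.isoform_id: iso.gene_id for iso in self.isoforms}

    def gene_isoforms(self, gene_id: str) -> list[LastExonIsoform]:
        return self._by_gene.get(gene_id, [])


@dataclass
class DecoyTranscript:
    decoy_id: str
    kind: str  # IPA_spliced | IPA_intron_retention | ALE_retained_intron
    exons: list[GenomicInterval]
    parent_event_id: str

    def __post_init__(self) -> None:
        if self.kind not in (
            "IPA_spliced",
            "IPA_intron_retention",
            "ALE_retained_intron",
        ):
            raise ValueError(f"unknown decoy kind {self.kind!r}")


@dataclass(frozen=True)
class InferredJunction:
    event_id: str
    junction: GenomicInterval  # intron coordinates, half-open
    rule: str  # intronic | distal | annotated

    def __post_init__(self) -> None:
        if self.rule not in ("intronic", "distal", "annotated"):
            raise ValueError(f"unknown junction rule {self.rule!r}")


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def build_isoform_reference(
    novel_events: Sequence[LastExonEvent], ref: AnnotationSet
) -> LastExonReference:
    """Assign last-exon isoform identifiers and unique regions per gene."""
    isoforms: list[LastExonIsoform] = []
    tx2iso: dict[str, str] = {}
    events_by_id = {ev.event_id: ev for ev in novel_events}
    novel_by_gene: dict[str, list[LastExonEvent]] = {}
    for ev in novel_events:
        novel_by_gene.setdefault(ev.gene_id, []).append(ev)

    for gene_id in sorted(set(ref.gene_ids) | set(novel_by_gene)):
        blockers = [
            e
            for e, role, _tx in ref.exons_with_roles(gene_id)
            if role in ("first", "internal")
        ]

        # members: (member_id, interval, category, is_extension)
        members: list[tuple[str, GenomicInterval, str, bool]] = []
        for tx in ref.gene_transcripts(gene_id):
            members.append((tx.transcript_id, tx.last_exon, "annotated", False))
        for ev in sorted(novel_by_gene.get(gene_id, []), key=lambda e: e.key()):
            members.append(
                (ev.event_id, ev.last_exon, ev.category, ev.category == "UTR_extension")
            )

        # drop members whose 3'end sits inside a first/internal exon
        surviving = []
        for mid, le, cat, is_ext in members:
            end_pt = le.three_prime
            if any(b.contains_point(end_pt) for b in blockers):
                logger.info(
                    "gene %s: member %s removed (3'end inside first/internal exon)",
                    gene_id,
                    mid,
                )
                continue
            surviving.append((mid, le, cat, is_ext))
        if not surviving:
            logger.info("gene %s: zero surviving last-exon isoforms; gene dropped", gene_id)
            continue

        # overlap-based grouping; 3'UTR extensions stay singleton groups
        base_idx = [i for i, m in enumerate(surviving) if not m[3]]
        uf = _UnionFind(len(surviving))
        for ai in range(len(base_idx)):
            for bi in range(ai + 1, len(base_idx)):
                i, j = base_idx[ai], base_idx[bi]
                if surviving[i][1].overlaps(surviving[j][1]):
                    uf.union(i, j)

        groups: dict[int, list[int]] = {}
        for i in range(len(surviving)):
            if surviving[i][3]:
                groups.setdefault(-(i + 1), []).append(i)  # singleton per 3'Ext
            else:
                groups.setdefault(uf.find(i), []).append(i)

        # deterministic numbering: proximal -> distal by member 5' position
        def group_sort_key(idxs: list[int]):
            ivs = [surviving[i][1] for i in idxs]
            strand = ivs[0].strand
            pos = min(iv.start for iv in ivs) if strand == "+" else -max(
                iv.end for iv in ivs
            )
            return (pos, min(surviving[i][0] for i in idxs))

        ordered = sorted(groups.values(), key=group_sort_key)
        n_iso = 0
        for idxs in ordered:
            cats = {surviving[i][2] for i in idxs}
            novel_cats = cats - {"annotated"}
            category = sorted(novel_cats)[0] if novel_cats else "annotated"
            n_iso += 1
            iso_id = f"{gene_id}_iso{n_iso}"
            member_ids = [surviving[i][0] for i in idxs]
            last_exons = [surviving[i][1] for i in idxs]
            unique_regions = [
                part
                for le in last_exons
                for part in subtract_intervals(le, blockers)
            ]
            isoforms.append(
                LastExonIsoform(
                    isoform_id=iso_id,
                    gene_id=gene_id,
                    category=category,
                    members=member_ids,
                    last_exons=last_exons,
                    unique_regions=unique_regions,
                )
            )
            for mid in member_ids:
                tx2iso[mid] = iso_id
                ev = events_by_id.get(mid)
                if ev is not None and ev.source_transcript:
                    # quantifiers see the assembled transcript's id
                    tx2iso.setdefault(ev.source_transcript, iso_id)

    return LastExonReference(isoforms=isoforms, tx2iso=tx2iso, events=events_by_id)


DECOY_SUFFIXES = {
    "IPA_spliced": "_decoy_spliced",
    "IPA_intron_retention": "_decoy_ir",
    "ALE_retained_intron": "_decoy_alir",
}


def build_decoys(
    events: Sequence[LastExonEvent],
    ref: AnnotationSet,
    suffixes: Optional[dict[str, str]] = None,
) -> list[DecoyTranscript]:
    """Construct nascent-RNA decoy transcript models for cryptic events."""
    suffixes = suffixes or DECOY_SUFFIXES
    decoys: list[DecoyTranscript] = []
    for ev in events:
        if ev.category == "UTR_extension":
            continue  # no decoys for 3'Ext events
        if ev.category == "IPA_extension":
            decoys.extend(_ipa_decoys(ev, ref, suffixes))
        elif ev.category in ("ALE_spliced", "ALE_distal"):
            decoys.extend(_ale_decoys(ev, ref, suffixes))
    return decoys


def _next_exon_3prime(tx, exon: GenomicInterval) -> Optional[GenomicInterval]:
    """The transcript exon immediately 3' (downstream) of *exon*."""
    idx = next(
        (i for i, e in enumerate(tx.exons) if (e.start, e.end) == (exon.start, exon.end)),
        None,
    )
    if idx is None:
        return None
    if tx.strand == "+":
        return tx.exons[idx + 1] if idx + 1 < len(tx.exons) else None
    return tx.exons[idx - 1] if idx - 1 >= 0 else None


def _ipa_decoys(ev: LastExonEvent, ref: AnnotationSet, suffixes) -> list[DecoyTranscript]:
    host = ev.extended_exon
    if host is None:
        # recover the host internal exon by 5'end identity
        for exon, role, _tx in ref.exons_with_roles(ev.gene_id):
            if role in ("internal", "first") and exon.five_prime == ev.last_exon.five_prime:
                host = exon
                break
    if host is None:
        logger.info("IPA event %s: no host internal exon found; no decoys", ev.event_id)
        return []
    out: list[DecoyTranscript] = []
    seen: set[tuple] = set()
    n = 0
    for tx in ref.gene_transcripts(ev.gene_id):
        if not any((e.start, e.end) == (host.start, host.end) for e in tx.exons):
            continue
        if (tx.last_exon.start, tx.last_exon.end) == (host.start, host.end):
            logger.info(
                "IPA event %s: host exon is last exon of %s; no decoy",
                ev.event_id,
                tx.transcript_id,
            )
            continue
        down = _next_exon_3prime(tx, host)
        if down is None:
            continue
        pair_key = (host.start, host.end, down.start, down.end)
        if pair_key in seen:
            continue
        seen.add(pair_key)
        n += 1
        tag = f"_{n}" if n > 1 else ""
        out.append(
            DecoyTranscript(
                decoy_id=ev.event_id + suffixes["IPA_spliced"] + tag,
                kind="IPA_spliced",
                exons=sorted([host, down], key=lambda e: e.start),
                parent_event_id=ev.event_id,
            )
        )
        lo = min(host.start, down.start)
        hi = max(host.end, down.end)
        out.append(
            DecoyTranscript(
                decoy_id=ev.event_id + suffixes["IPA_intron_retention"] + tag,
                kind="IPA_intron_retention",
                exons=[GenomicInterval(host.chrom, lo, hi, host.strand)],
                parent_event_id=ev.event_id,
            )
        )
    return out


def _ale_decoys(ev: LastExonEvent, ref: AnnotationSet, suffixes) -> list[DecoyTranscript]:
    out: list[DecoyTranscript] = []
    seen: set[tuple] = set()
    n = 0
    for tx in ref.gene_transcripts(ev.gene_id):
        for i, intron in enumerate(tx.introns):
            if not intron.contains(ev.last_exon):
                continue
            up, down = tx.exons[i], tx.exons[i + 1]
            key = (up.start, down.end)
            if key in seen:
                continue
            seen.add(key)
            n += 1
            tag = f"_{n}" if n > 1 else ""
            out.append(
                DecoyTranscript(
                    decoy_id=ev.event_id + suffixes["ALE_retained_intron"] + tag,
                    kind="ALE_retained_intron",
                    exons=[GenomicInterval(up.chrom, up.start, down.end, up.strand)],
                    parent_event_id=ev.event_id,
                )
            )
    if not out:
        logger.info(
            "ALE event %s: no annotated host intron; no retained-intron decoy",
            ev.event_id,
        )
    return out


def infer_ale_junctions(
    events: Sequence[LastExonEvent], ref: AnnotationSet
) -> list[InferredJunction]:
    """Infer the terminal splice junction of each ALE event.

    * intronic — ALE fully contained within an annotated intron: junction
      runs from the intron's 5' start to the ALE's 5' start;
    * distal — ALE beyond the gene 3'end: junction from the closest upstream
      annotated intron's 5' start to the ALE 5' start;
    * annotated — all annotated introns terminating at the ALE.

    "start" and "upstream" are transcript-orientation notions: on the minus
    strand the junction's genomic interval is mirrored accordingly.
    """
    out: list[InferredJunction] = []
    for ev in events:
        le = ev.last_exon
        strand = le.strand
        if ev.category == "annotated":
            hits = set()
            for intron in ref.gene_introns(ev.gene_id):
                terminates = (
                    intron.end == le.start if strand == "+" else intron.start == le.end
                )
                if terminates:
                    hits.add((intron.start, intron.end))
            for s, e in sorted(hits):
                out.append(
                    InferredJunction(
                        ev.event_id, GenomicInterval(le.chrom, s, e, strand), "annotated"
                    )
                )
            continue

        host = next(
            (i for i in ref.gene_introns(ev.gene_id) if i.contains(le)), None
        )
        if host is not None:
            junction = (
                GenomicInterval(le.chrom, host.start, le.start, strand)
                if strand == "+"
                else GenomicInterval(le.chrom, le.end, host.end, strand)
            )
            out.append(InferredJunction(ev.event_id, junction, "intronic"))
            continue

        # distal: closest upstream annotated intron
        introns = ref.gene_introns(ev.gene_id)
        if strand == "+":
            ups = [i for i in introns if i.start < le.start]
            host = max(ups, key=lambda i: i.start) if ups else None
        else:
            ups = [i for i in introns if i.end > le.end]
            host = min(ups, key=lambda i: i.end) if ups else None
        if host is None:
            raise ValueError(
                f"ALE event {ev.event_id}: no upstream annotated intron"
            )
        junction = (
            GenomicInterval(le.chrom, host.start, le.start, strand)
            if strand == "+"
            else GenomicInterval(le.chrom, le.end, host.end, strand)
        )
        out.append(InferredJunction(ev.event_id, junction, "distal"))
    return out
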