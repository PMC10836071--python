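"""Novel last-exon discovery from assembled transcriptomes.

Assembled transcripts are expression-filtered per condition (mean TPM across
all samples of the condition, counting 0 for samples where the transcript was
not assembled, strictly > 1 TPM by default), their last exons extracted and
classified against the filtered reference annotation into the three novelty
classes:

* ``ALE_spliced``  — alternative last exon joined by a novel terminal intron
  that is contained within an annotated intron and whose donor (5' splice
  site) exactly matches an annotated donor;
* ``ALE_distal``   — alternative last exon downstream of the annotated gene
  3'end, spliced from an annotated donor;
* ``IPA_extension`` — intronic polyadenylation via extension of an annotated
  internal exon into the downstream intron (first-exon matches get a 100 nt
  5'end slack);
* ``UTR_extension`` — extension of the gene's most distal annotated last
  exon (3'UTR extension).

An event satisfying both the ALE and the IPA structural criteria against
different reference transcripts is labelled ``complex``.  All predicted
3'ends must fall outside every annotated exon, and extension-type events
must extend the known exon by at least ``min_extension`` (default 100 nt).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .config import PipelineConfig
from .intervals import GenomicInterval
from .models import AnnotationSet, TranscriptModel, intron_five_prime_ss

logger = logging.getLogger(__name__)

CATEGORIES = (
    "ALE_spliced",
    "ALE_distal",
    "IPA_extension",
    "UTR_extension",
    "annotated",
    "complex",
)


@dataclass
class LastExonEvent:
    """A candidate or validated last-exon isoform."""

    event_id: str
    gene_id: str
    last_exon: GenomicInterval
    category: str
    last_intron: Optional[GenomicInterval] = None
    source_condition: str = ""
    source_dataset: str = ""
    source_transcript: str = ""
    provenance: set = field(default_factory=set)
    validation: Optional[object] = None  # ThreeEndValidation, set downstream
    #: annotated exon the event extends (IPA / 3'Ext), when applicable
    extended_exon: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown event category {self.category!r}")
        if self.category in ("ALE_spliced", "ALE_distal") and self.last_intron is None:
            raise ValueError(f"{self.event_id}: ALE events must carry a last intron")

    @property
    def chrom(self) -> str:
        return self.last_exon.chrom

    @property
    def strand(self) -> str:
        return self.last_exon.strand

    @property
    def three_end(self) -> int:
        return self.last_exon.three_prime

    @property
    def is_extension(self) -> bool:
        return self.category in ("IPA_extension", "UTR_extension")

    def key(self) -> tuple:
        return (
            self.chrom,
            self.strand,
            self.last_exon.start,
            self.last_exon.end,
        )


@dataclass
class ConditionAssembly:
    """Expression-filtered merged assembly for one experimental condition."""

    condition: str
    transcripts: AnnotationSet
    mean_tpm: dict[str, float]


def _cluster_transcripts(
    assemblies: Sequence[AnnotationSet],
) -> list[list[tuple[int, TranscriptModel]]]:
    """Group per-sample transcripts into identity clusters.

    Multi-exonic transcripts are identical iff their intron chains are
    identical; mono-exonic transcripts cluster by >= 50% reciprocal exon
    overlap (greedy, in coordinate order).
    """
    clusters: dict[tuple, list[tuple[int, TranscriptModel]]] = {}
    mono: list[tuple[int, TranscriptModel]] = []
    for si, ann in enumerate(assemblies):
        for tx in ann:
            if len(tx.exons) > 1:
                clusters.setdefault(tx.intron_chain(), []).append((si, tx))
            else:
                mono.append((si, tx))
    out = list(clusters.values())

    mono.sort(key=lambda p: (p[1].chrom, p[1].strand, p[1].exons[0].start))
    mono_clusters: list[list[tuple[int, TranscriptModel]]] = []
    for si, tx in mono:
        exon = tx.exons[0]
        placed = False
        for cl in mono_clusters:
            rep = cl[0][1].exons[0]
            ov = rep.overlap_length(exon) if rep.same_strand(exon) else 0
            if ov >= 0.5 * len(rep) and ov >= 0.5 * len(exon):
                cl.append((si, tx))
                placed = True
                break
        if not placed:
            mono_clusters.append([(si, tx)])
    out.extend(mono_clusters)
    return out


def condition_mean_tpm(
    assemblies: Sequence[AnnotationSet],
    quants: Sequence[pd.DataFrame],
    condition: str,
    cfg: PipelineConfig,
) -> ConditionAssembly:
    """Merge per-sample assemblies of one condition and expression-filter.

    The mean TPM of each transcript is computed over *all* samples of the
    condition, assigning 0 TPM to samples where the transcript was not
    assembled; transcripts with mean <= ``min_mean_tpm`` are removed
    (strict ">").
    """
    if not assemblies:
        raise ValueError(f"condition {condition!r} has zero samples")
    if len(assemblies) != len(quants):
        raise ValueError("assemblies and quant tables must align per sample")
    n = len(assemblies)
    tpm_maps = [dict(zip(q["Name"], q["TPM"])) for q in quants]

    kept: list[TranscriptModel] = []
    mean_tpm: dict[str, float] = {}
    for cluster in _cluster_transcripts(assemblies):
        total = 0.0
        for si, tx in cluster:
            total += float(tpm_maps[si].get(tx.transcript_id, 0.0))
        mean = total / n
        if mean > cfg.min_mean_tpm:
            # merge semantics keep the most distal 3'end among members
            strand = cluster[0][1].strand
            rep = max(
                (tx for _, tx in cluster),
                key=lambda t: t.three_prime_end if strand == "+" else -t.three_prime_end,
            )
            kept.append(rep)
            mean_tpm[rep.transcript_id] = mean
    return ConditionAssembly(condition, AnnotationSet(kept), mean_tpm)


def _classify_last_exon(
    tx: TranscriptModel, gene_id: str, ref: AnnotationSet, cfg: PipelineConfig
) -> Optional[tuple[str, Optional[GenomicInterval]]]:
    """Classify one assembled transcript's last exon against one gene.

    Returns (category, extended annotated exon or None), or None when no
    novelty criterion is satisfied.
    """
    last_exon = tx.last_exon
    last_intron = tx.last_intron
    strand = tx.strand

    ale_spliced_txs: set[str] = set()
    ale_distal_txs: set[str] = set()
    ipa_txs: set[str] = set()
    ipa_exon: Optional[GenomicInterval] = None
    utr_hit: Optional[GenomicInterval] = None

    donors = ref.gene_five_prime_splice_sites(gene_id)
    gene_txs = ref.gene_transcripts(gene_id)

    if last_intron is not None and intron_five_prime_ss(last_intron) in donors:
        # ALE, spliced: terminal intron within an annotated intron, with the
        # acceptor strictly inside it (an acceptor on the intron boundary
        # means the last exon starts at an annotated exon: the IPA shape)
        for rtx in gene_txs:
            for intron in rtx.introns:
                acceptor_inside = (
                    last_intron.end < intron.end
                    if strand == "+"
                    else last_intron.start > intron.start
                )
                if intron.contains(last_intron) and acceptor_inside:
                    ale_spliced_txs.add(rtx.transcript_id)
        # ALE, distal: last exon wholly beyond the gene's annotated 3'end
        distal_le = ref.most_distal_last_exon(gene_id)
        if distal_le is not None and not ale_spliced_txs:
            beyond = (
                last_exon.start >= distal_le.end
                if strand == "+"
                else last_exon.end <= distal_le.start
            )
            if beyond:
                ale_distal_txs.add("*distal*")

    # IPA: 5'end matches the 5'end of an overlapping internal exon
    # (first-exon matches allowed a slack); must extend that exon >= min ext.
    for exon, role, rtx_id in ref.exons_with_roles(gene_id):
        if role == "last" or not exon.overlaps(last_exon):
            continue
        if role == "internal":
            match = last_exon.five_prime == exon.five_prime
        else:  # first exon: slack permitted
            match = abs(last_exon.five_prime - exon.five_prime) <= cfg.first_exon_slack
        if match and last_exon.extension_beyond(exon) >= cfg.min_extension:
            ipa_txs.add(rtx_id)
            ipa_exon = exon

    # 3'UTR extension of the most distal annotated last exon
    distal_le = ref.most_distal_last_exon(gene_id)
    if (
        distal_le is not None
        and last_exon.overlaps(distal_le)
        and last_exon.five_prime == distal_le.five_prime
        and last_exon.extension_beyond(distal_le) >= cfg.min_extension
    ):
        utr_hit = distal_le

    if ale_spliced_txs and ipa_txs:
        return ("complex", None)
    hits = []
    if ale_spliced_txs:
        hits.append(("ALE_spliced", None))
    if ale_distal_txs:
        hits.append(("ALE_distal", None))
    if ipa_txs:
        hits.append(("IPA_extension", ipa_exon))
    if utr_hit is not None:
        hits.append(("UTR_extension", utr_hit))
    if not hits:
        return None
    if len(hits) > 1:
        logger.info(
            "transcript %s: multiple structural categories %s -> complex",
            tx.transcript_id,
            [h[0] for h in hits],
        )
        return ("complex", None)
    return hits[0]


def extract_novel_last_exons(
    cond: ConditionAssembly,
    ref: AnnotationSet,
    cfg: PipelineConfig,
    dataset: str = "",
) -> list[LastExonEvent]:
    """Extract and classify novel last exons from a condition assembly.

    Criteria, applied in order per assembled transcript: (a) the predicted
    3'end must not overlap any annotated exon of the gene's strand; then
    exactly one of the structural criteria (ALE / IPA / 3'UTR-extension)
    must hold.  Transcripts spanning two reference genes, or antisense to
    every overlapping gene, are dropped and logged.
    """
    ref_exons = ref.all_exons()
    events: list[LastExonEvent] = []
    for tx in cond.transcripts:
        span = tx.span
        sense_genes = ref.overlapping_genes(span, stranded=True)
        if not sense_genes:
            if ref.overlapping_genes(span, stranded=False):
                logger.info(
                    "transcript %s antisense to all overlapping genes; dropped",
                    tx.transcript_id,
                )
            continue
        if len(sense_genes) > 1:
            logger.info(
                "transcript %s spans reference genes %s; dropped (ambiguous)",
                tx.transcript_id,
                sense_genes,
            )
            continue
        gene_id = sense_genes[0]

        # (a) predicted 3'end must not overlap any annotated exon
        three_end = tx.three_prime_end
        end_point = GenomicInterval(tx.chrom, three_end, three_end + 1, tx.strand)
        if any(e.overlaps(end_point) for e in ref_exons):
            continue

        result = _classify_last_exon(tx, gene_id, ref, cfg)
        if result is None:
            continue
        category, extended = result
        le = tx.last_exon
        event_id = f"{gene_id}|{le.chrom}:{le.start}-{le.end}:{le.strand}"
        events.append(
            LastExonEvent(
                event_id=event_id,
                gene_id=gene_id,
                last_exon=le,
                category=category,
                last_intron=tx.last_intron
                if category in ("ALE_spliced", "ALE_distal")
                else None,
                source_condition=cond.condition,
                source_dataset=dataset,
                source_transcript=tx.transcript_id,
                provenance={(cond.condition, dataset)},
                extended_exon=extended,
            )
        )
    return events


def merge_condition_events(
    per_condition: Sequence[Sequence[LastExonEvent]],
) -> list[LastExonEvent]:
    """Merge per-condition event lists, deduplicating identical coordinates.

    Events with identical (chrom, strand, 5'end, 3'end) collapse to one
    record whose provenance is the union of (condition, dataset) pairs;
    overlapping-but-distinct events stay separate for the downstream
    per-condition representative selection.
    """
    merged: dict[tuple, LastExonEvent] = {}
    for events in per_condition:
        for ev in events:
            key = ev.key()
            if key in merged:
                merged[key].provenance |= ev.provenance
            else:
                merged[key] = LastExonEvent(
                    event_id=ev.event_id,
                    gene_id=ev.gene_id,
                    last_exon=ev.last_exon,
                    category=ev.category,
                    last_intron=ev.last_intron,
                    source_condition=ev.source_condition,
                    source_dataset=ev.source_dataset,
                    source_transcript=ev.source_transcript,
                    provenance=set(ev.provenance),
                    extended_exon=ev.extended_exon,
                )
    return list(merged.values())
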