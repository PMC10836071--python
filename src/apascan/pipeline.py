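"""End-to-end orchestration of the last-exon discovery pipeline.

Chains the per-module operations in their canonical order: per-condition
expression filtering and merging of assemblies, novel last-exon extraction
and classification, 3'end validation (atlas first, hexamer rescue second),
per-locus per-condition representative selection, isoform-reference
construction, quantification aggregation and differential-usage testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .config import PipelineConfig
from .cryptic import classify_cryptic, differential_usage
from .discovery import (
    ConditionAssembly,
    LastExonEvent,
    condition_mean_tpm,
    extract_novel_last_exons,
    merge_condition_events,
)
from .models import AnnotationSet, PolyASiteAtlas, filter_reference
from .reference import LastExonReference, build_isoform_reference
from .usage import IsoformUsageMatrix, aggregate_quant, polya_usage
from .validation import select_condition_representative, validate_events


def discover_events(
    assemblies_by_condition: dict[str, list[AnnotationSet]],
    quants_by_condition: dict[str, list[pd.DataFrame]],
    reference: AnnotationSet,
    cfg: PipelineConfig,
    dataset: str = "",
) -> list[LastExonEvent]:
    """Expression-filter, extract and merge novel last exons per condition."""
    per_condition = []
    for condition, anns in assemblies_by_condition.items():
        cond = condition_mean_tpm(anns, quants_by_condition[condition], condition, cfg)
        per_condition.append(extract_novel_last_exons(cond, reference, cfg, dataset))
    return merge_condition_events(per_condition)


def select_representatives(
    events: Sequence[LastExonEvent], cfg: PipelineConfig
) -> list[LastExonEvent]:
    """One validated event per locus.

    Atlas-matched events at distinct atlas sites are distinct loci (one
    event per updated end); overlapping motif-rescued candidates collapse
    to the one whose signal offset is closest to the expected 21 nt.
    """
    out: list[LastExonEvent] = []
    atlas_seen: set[tuple] = set()
    motif_groups: dict[str, list[LastExonEvent]] = {}
    for ev in events:
        if ev.validation is None:
            continue
        if ev.validation.mode == "atlas":
            key = (ev.gene_id, ev.category, ev.strand, ev.validation.updated_end)
            if key not in atlas_seen:
                atlas_seen.add(key)
                out.append(ev)
        else:
            motif_groups.setdefault(f"{ev.gene_id}|{ev.category}", []).append(ev)
    for group in motif_groups.values():
        # overlap clusters within the gene/category group
        group.sort(key=lambda e: e.last_exon.start)
        cluster: list[LastExonEvent] = []
        for ev in group:
            if cluster and any(ev.last_exon.overlaps(c.last_exon) for c in cluster):
                cluster.append(ev)
            else:
                if cluster:
                    out.append(select_condition_representative(cluster, cfg))
                cluster = [ev]
        if cluster:
            out.append(select_condition_representative(cluster, cfg))
    return out


@dataclass
class PipelineResult:
    reference_filtered: AnnotationSet
    events: list[LastExonEvent]
    isoform_reference: LastExonReference
    usage: IsoformUsageMatrix
    results: pd.DataFrame
    calls: pd.DataFrame


def run_differential_pipeline(
    reference: AnnotationSet,
    assemblies: dict[str, AnnotationSet],
    quants: dict[str, pd.DataFrame],
    samples: pd.DataFrame,
    atlas: PolyASiteAtlas,
    genome,
    cfg: PipelineConfig,
    control: str,
    dataset: str = "",
    covariates: Sequence[str] = (),
    prefiltered: bool = False,
) -> PipelineResult:
    """Full single-dataset run: discovery through cryptic classification.

    *samples* is indexed by sample name with a ``condition`` column;
    *control* names the control condition.  *genome* is any mapping of
    contig name to sequence (a pyfaidx Fasta or a plain dict).
    """
    ref = reference if prefiltered else filter_reference(reference, cfg)
    by_cond_ann: dict[str, list[AnnotationSet]] = {}
    by_cond_quant: dict[str, list[pd.DataFrame]] = {}
    for sample, row in samples.iterrows():
        by_cond_ann.setdefault(row["condition"], []).append(assemblies[sample])
        by_cond_quant.setdefault(row["condition"], []).append(quants[sample])

    merged = discover_events(by_cond_ann, by_cond_quant, ref, cfg, dataset)
    validated = validate_events(merged, atlas, genome, cfg)
    events = select_representatives(validated, cfg)

    iso_ref = build_isoform_reference(events, ref)
    usage = polya_usage(aggregate_quant(quants, iso_ref))
    usage.samples = samples
    results = differential_usage(
        usage, samples, control=control, covariates=covariates, dataset=dataset
    )
    calls = classify_cryptic([results], cfg)
    return PipelineResult(
        reference_filtered=ref,
        events=events,
        isoform_reference=iso_ref,
        usage=usage,
        results=results,
        calls=calls,
    )
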