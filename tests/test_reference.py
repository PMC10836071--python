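"""Isoform reference construction, decoy transcripts and junction inference."""

import pytest

from apascan import (
    AnnotationSet,
    GenomicInterval,
    build_decoys,
    build_isoform_reference,
    infer_ale_junctions,
)
from apascan.discovery import LastExonEvent

from conftest import make_tx


def event(gene, start, end, category, strand="+", last_intron=None, extended=None):
    return LastExonEvent(
        event_id=f"{gene}|{start}-{end}",
        gene_id=gene,
        last_exon=GenomicInterval("chr1", start, end, strand),
        category=category,
        last_intron=(
            GenomicInterval("chr1", *last_intron, strand) if last_intron else None
        ),
        extended_exon=(
            GenomicInterval("chr1", *extended, strand) if extended else None
        ),
        source_transcript=f"src_{gene}_{start}",
    )


class TestIsoformGrouping:
    def test_overlapping_annotated_pair_merges_novel_ale_separate(self, cfg):
        """2 overlapping annotated last exons + 1 novel ALE -> 2 isoform IDs."""
        ref = AnnotationSet(
            [
                make_tx("t1", "g", "chr1", "+", [(100, 300), (5000, 5400)]),
                make_tx("t2", "g", "chr1", "+", [(100, 300), (5200, 5600)]),
            ]
        )
        ale = event("g", 1000, 1200, "ALE_spliced", last_intron=(300, 1000))
        iso_ref = build_isoform_reference([ale], ref)
        isoforms = iso_ref.gene_isoforms("g")
        assert len(isoforms) == 2
        by_members = {frozenset(i.members) for i in isoforms}
        assert frozenset({"t1", "t2"}) in by_members
        assert frozenset({ale.event_id}) in by_members
        # both quantifier names resolve to the same isoform
        assert iso_ref.tx2iso[ale.event_id] == iso_ref.tx2iso["src_g_1000"]

    def test_utr_extension_gets_distinct_id(self, cfg):
        """A 3'Ext overlapping the single annotated last exon -> 2 IDs."""
        ref = AnnotationSet(
            [make_tx("t1", "g", "chr1", "+", [(100, 300), (5000, 5400)])]
        )
        ext = event("g", 5000, 5700, "UTR_extension")
        iso_ref = build_isoform_reference([ext], ref)
        isoforms = iso_ref.gene_isoforms("g")
        assert len(isoforms) == 2
        assert iso_ref.tx2iso["t1"] != iso_ref.tx2iso[ext.event_id]

    def test_ipa_overlap_subtracted_and_inside_removed(self, cfg):
        """Overlap with internal exons is subtracted; 3'end inside -> removed."""
        ref = AnnotationSet(
            [
                make_tx(
                    "t1", "g", "chr1", "+",
                    [(100, 300), (1000, 1200), (5000, 5400)],
                ),
                # second transcript whose internal exon overlaps the IPA tail
                make_tx(
                    "t2", "g", "chr1", "+",
                    [(100, 300), (1300, 1400), (5000, 5400)],
                ),
            ]
        )
        ipa = event("g", 1000, 1450, "IPA_extension", extended=(1000, 1200))
        iso_ref = build_isoform_reference([ipa], ref)
        iso = next(
            i for i in iso_ref.gene_isoforms("g") if ipa.event_id in i.members
        )
        # [1000,1200) and [1300,1400) subtracted
        assert [(r.start, r.end) for r in iso.unique_regions] == [
            (1200, 1300),
            (1400, 1450),
        ]

        # 3'end (1379) inside t2's internal exon [1300,1400) -> removed
        inside = event("g", 1000, 1380, "IPA_extension", extended=(1000, 1200))
        iso_ref2 = build_isoform_reference([inside], ref)
        assert inside.event_id not in iso_ref2.tx2iso

    def test_unique_regions_never_overlap_first_internal_exons(self, cfg):
        ref = AnnotationSet(
            [
                make_tx(
                    "t1", "g", "chr1", "+",
                    [(100, 300), (1000, 1200), (5000, 5400)],
                )
            ]
        )
        ipa = event("g", 1000, 1450, "IPA_extension", extended=(1000, 1200))
        iso_ref = build_isoform_reference([ipa], ref)
        blockers = [
            GenomicInterval("chr1", 100, 300, "+"),
            GenomicInterval("chr1", 1000, 1200, "+"),
        ]
        for iso in iso_ref.isoforms:
            for region in iso.unique_regions:
                assert all(not region.overlaps(b) for b in blockers)


class TestDecoys:
    def _ref(self):
        # internal exons A=[100,200), B=[500,600), last [900,1100)
        return AnnotationSet(
            [
                make_tx(
                    "t1", "g", "chr1", "+",
                    [(10, 50), (100, 200), (500, 600), (900, 1100)],
                )
            ]
        )

    def test_ipa_decoy_pair_exact_coordinates(self, cfg):
        ipa = event("g", 100, 350, "IPA_extension", extended=(100, 200))
        decoys = build_decoys([ipa], self._ref())
        by_kind = {d.kind: d for d in decoys}
        assert set(by_kind) == {"IPA_spliced", "IPA_intron_retention"}
        spliced = by_kind["IPA_spliced"]
        assert [(e.start, e.end) for e in spliced.exons] == [(100, 200), (500, 600)]
        retention = by_kind["IPA_intron_retention"]
        assert [(e.start, e.end) for e in retention.exons] == [(100, 600)]

    def test_no_decoys_for_utr_extension(self, cfg):
        ext = event("g", 900, 1300, "UTR_extension")
        assert build_decoys([ext], self._ref()) == []

    def test_ale_retained_intron_decoy(self, cfg):
        """ALE inside intron [1000,2000) flanked by [900,1000) and [2000,2100)."""
        ref = AnnotationSet(
            [make_tx("t1", "g", "chr1", "+", [(900, 1000), (2000, 2100)])]
        )
        ale = event("g", 1300, 1500, "ALE_spliced", last_intron=(1000, 1300))
        decoys = build_decoys([ale], ref)
        assert len(decoys) == 1
        assert decoys[0].kind == "ALE_retained_intron"
        assert [(e.start, e.end) for e in decoys[0].exons] == [(900, 2100)]

    def test_decoy_construction_deterministic_and_ids_distinct(self, cfg):
        ipa = event("g", 100, 350, "IPA_extension", extended=(100, 200))
        d1 = build_decoys([ipa], self._ref())
        d2 = build_decoys([ipa], self._ref())
        assert [d.decoy_id for d in d1] == [d.decoy_id for d in d2]
        assert len({d.decoy_id for d in d1}) == len(d1)
        iso_ref = build_isoform_reference([ipa], self._ref())
        assert not ({d.decoy_id for d in d1} & set(iso_ref.tx2iso.values()))

    def test_ipa_in_last_exon_context_no_decoy(self, cfg):
        ref = AnnotationSet(
            [make_tx("t1", "g", "chr1", "+", [(10, 50), (100, 200)])]
        )
        ipa = event("g", 100, 350, "IPA_extension", extended=(100, 200))
        assert build_decoys([ipa], ref) == []


class TestJunctionInference:
    def _ref(self, strand="+"):
        if strand == "+":
            exons = [(100, 300), (1000, 1200), (2000, 2200), (3000, 3400)]
        else:
            exons = [(100, 500), (1300, 1500), (2300, 2500), (3200, 3400)]
        return AnnotationSet([make_tx("t1", "g", "chr1", strand, exons)])

    def test_intronic_rule_plus_strand(self, cfg):
        """ALE at 1500 inside intron [1000,2000)... junction [intron start, ALE start)."""
        ref = AnnotationSet(
            [make_tx("t1", "g", "chr1", "+", [(500, 1000), (2000, 2200)])]
        )
        ale = event("g", 1500, 1800, "ALE_spliced", last_intron=(1000, 1500))
        (j,) = infer_ale_junctions([ale], ref)
        assert j.rule == "intronic"
        assert (j.junction.start, j.junction.end) == (1000, 1500)
        assert j.junction.end == ale.last_exon.start

    def test_intronic_rule_minus_strand_mirrored(self, cfg):
        ref = AnnotationSet(
            [make_tx("t1", "g", "chr1", "-", [(500, 1000), (2000, 2200)])]
        )
        ale = event("g", 1200, 1500, "ALE_spliced", strand="-", last_intron=(1500, 2000))
        (j,) = infer_ale_junctions([ale], ref)
        assert j.rule == "intronic"
        assert (j.junction.start, j.junction.end) == (1500, 2000)
        assert j.junction.start == ale.last_exon.end

    def test_distal_rule_uses_closest_upstream_intron(self, cfg):
        ref = self._ref("+")
        ale = event("g", 4000, 4200, "ALE_distal", last_intron=(2200, 4000))
        (j,) = infer_ale_junctions([ale], ref)
        assert j.rule == "distal"
        # closest upstream annotated intron starts at 2200
        assert (j.junction.start, j.junction.end) == (2200, 4000)

    def test_annotated_rule_reports_all_terminating_introns(self, cfg):
        ref = AnnotationSet(
            [
                make_tx("t1", "g", "chr1", "+", [(100, 300), (3000, 3400)]),
                make_tx("t2", "g", "chr1", "+", [(100, 300), (1000, 1200), (3000, 3400)]),
            ]
        )
        annotated = event("g", 3000, 3400, "annotated")
        js = infer_ale_junctions([annotated], ref)
        assert {j.rule for j in js} == {"annotated"}
        assert {(j.junction.start, j.junction.end) for j in js} == {
            (300, 3000),
            (1200, 3000),
        }

    def test_no_upstream_intron_is_error(self, cfg):
        ref = AnnotationSet([make_tx("t1", "g", "chr1", "+", [(100, 400)])])
        orphan = event("g", 4000, 4200, "ALE_distal", last_intron=(400, 4000))
        with pytest.raises(ValueError, match=orphan.event_id.replace("|", r"\|")):
            infer_ale_junctions([orphan], ref)

    def test_junction_acceptor_equals_event_five_prime_start(self, cfg):
        for strand in "+-":
            ref = AnnotationSet(
                [
                    make_tx(
                        "t1", "g", "chr1", strand, [(500, 1000), (4000, 4200)]
                    )
                ]
            )
            if strand == "+":
                ale = event("g", 2000, 2300, "ALE_spliced", last_intron=(1000, 2000))
            else:
                ale = event(
                    "g", 2000, 2300, "ALE_spliced", strand="-", last_intron=(2300, 4000)
                )
            (j,) = infer_ale_junctions([ale], ref)
            if strand == "+":
                assert j.junction.end == ale.last_exon.start
            else:
                assert j.junction.start == ale.last_exon.end
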