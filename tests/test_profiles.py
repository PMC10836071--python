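"""Representative collapsing, landmark extraction and coverage metaprofiles."""

import numpy as np
import pytest

from apascan import (
    AnnotationSet,
    EventPrediction,
    GenomicInterval,
    Landmark,
    collapse_representative,
    coverage_profile,
    extract_landmarks,
    loess_smooth,
)
from apascan.discovery import LastExonEvent

from conftest import make_tx
from oracles import coverage_fraction_oracle


def pred(start, end, strand="+", site=None, rep=None, n_datasets=1, offset=None,
         category="ALE_spliced"):
    return EventPrediction(
        interval=GenomicInterval("chr1", start, end, strand),
        category=category,
        atlas_site_id=site,
        atlas_rep_coord=rep,
        n_datasets=n_datasets,
        motif_offset=offset,
    )


class TestCollapsingLadder:
    """Each tie-break rule has a dedicated fixture and fires in order."""

    def test_rule1_atlas_beats_motif(self, cfg):
        atlas = pred(100, 300, site="s1", rep=299)
        motif = pred(100, 340, offset=21)
        iv, fired = collapse_representative([atlas, motif], cfg)
        assert iv == atlas.interval
        assert fired[0] == "atlas_filter"

    def test_rule2_most_datasets_wins(self, cfg):
        a = pred(100, 300, site="s1", rep=299, n_datasets=3)
        b = pred(100, 400, site="s2", rep=399, n_datasets=1)
        iv, fired = collapse_representative([a, b], cfg)
        assert iv == a.interval
        assert "most_datasets" in fired

    def test_rule3_site_tie_more_proximal(self, cfg):
        a = pred(100, 300, site="s1", rep=299, n_datasets=2)
        b = pred(100, 400, site="s2", rep=399, n_datasets=2)
        iv, fired = collapse_representative([a, b], cfg)
        assert iv == a.interval
        assert "site_tie_more_proximal" in fired
        # minus strand: proximal is the larger coordinate
        am = pred(300, 500, strand="-", site="s1", rep=300, n_datasets=2)
        bm = pred(200, 500, strand="-", site="s2", rep=200, n_datasets=2)
        iv_m, fired_m = collapse_representative([am, bm], cfg)
        assert iv_m == am.interval
        assert "site_tie_more_proximal" in fired_m

    def test_rule4_closest_to_representative(self, cfg):
        # same cluster (site id), distinct predicted ends
        a = pred(100, 305, site="s1", rep=299)   # end 304, distance 5
        b = pred(100, 301, site="s1", rep=299)   # end 300, distance 1
        iv, fired = collapse_representative([a, b], cfg)
        assert iv == b.interval
        assert "closest_to_representative" in fired

    def test_rule5_equidistant_most_distal(self, cfg):
        a = pred(100, 298, site="s1", rep=299)   # end 297, distance 2
        b = pred(100, 302, site="s1", rep=299)   # end 301, distance 2
        iv, fired = collapse_representative([a, b], cfg)
        assert iv == b.interval
        assert "end_tie_most_distal" in fired

    def test_rule6_motif_min_deviance(self, cfg):
        a = pred(100, 300, offset=21)
        b = pred(100, 340, offset=30)
        iv, fired = collapse_representative([a, b], cfg)
        assert iv == a.interval
        assert "motif_min_deviance" in fired

    def test_rule7_motif_tie_most_proximal(self, cfg):
        a = pred(100, 340, offset=18)  # deviance 3, end 339
        b = pred(100, 300, offset=24)  # deviance 3, end 299 (proximal)
        iv, fired = collapse_representative([a, b], cfg)
        assert iv == b.interval
        assert "motif_tie_most_proximal" in fired

    def test_rule8_ipa_most_distal_end(self, cfg):
        a = pred(100, 300, offset=21, category="IPA_extension")
        b = pred(100, 360, offset=21, category="IPA_extension")
        iv, fired = collapse_representative([a, b], cfg)
        assert iv == b.interval
        assert "ipa_most_distal_3end" in fired

    def test_rule9_ale_shortest_exon(self, cfg):
        # same atlas-updated 3'end, distinct 5'ends
        a = pred(100, 300, site="s1", rep=299)
        b = pred(150, 300, site="s1", rep=299)
        iv, fired = collapse_representative([a, b], cfg)
        assert iv == b.interval
        assert "ale_shortest_exon" in fired

    def test_ladder_order_is_documented_order(self, cfg):
        """A fixture exercising rules 1, 2 and 9 fires them in order."""
        preds = [
            pred(100, 300, site="s1", rep=299, n_datasets=3),
            pred(150, 300, site="s1", rep=299, n_datasets=2),
            pred(100, 400, site="s2", rep=399, n_datasets=1),
            pred(100, 340, offset=21),
        ]
        iv, fired = collapse_representative(preds, cfg)
        assert fired == ["atlas_filter", "most_datasets", "ale_shortest_exon"]
        assert iv == preds[1].interval

    def test_single_prediction_fires_nothing(self, cfg):
        iv, fired = collapse_representative([pred(100, 300)], cfg)
        assert fired == []


def ale_event(start, end, strand="+", gene="g"):
    return LastExonEvent(
        event_id=f"{gene}|{start}",
        gene_id=gene,
        last_exon=GenomicInterval("chr1", start, end, strand),
        category="ALE_spliced",
        last_intron=GenomicInterval(
            "chr1", start - 500, start, strand
        ) if strand == "+" else GenomicInterval("chr1", end, end + 500, strand),
    )


class TestLandmarks:
    def test_ale_landmarks_plus_strand(self, cfg):
        """ALE [1500,1800)+ -> exon start 1500, PAS 1799."""
        ref = AnnotationSet([make_tx("t", "g", "chr1", "+", [(100, 300), (3000, 3200)])])
        ev = ale_event(1500, 1800)
        lms = extract_landmarks([ev], ref, {ev.event_id: "cryptic"})
        by_kind = {lm.kind: lm for lm in lms}
        assert by_kind["ALE_exon_start"].point.start == 1500
        assert by_kind["ALE_pas"].point.start == 1799

    def test_ale_landmarks_minus_strand_mirrored(self, cfg):
        ref = AnnotationSet([make_tx("t", "g", "chr1", "-", [(100, 300), (3000, 3200)])])
        ev = ale_event(1500, 1800, strand="-")
        lms = extract_landmarks([ev], ref, {ev.event_id: "cryptic"})
        by_kind = {lm.kind: lm for lm in lms}
        assert by_kind["ALE_exon_start"].point.start == 1799
        assert by_kind["ALE_pas"].point.start == 1500

    def test_ext_landmarks_use_annotated_distal_site(self, cfg):
        """3'Ext over a last exon ending 5500 -> proximal 5499, distal = ext end."""
        ref = AnnotationSet([make_tx("t", "g", "chr1", "+", [(100, 300), (5000, 5500)])])
        ev = LastExonEvent(
            event_id="g|ext",
            gene_id="g",
            last_exon=GenomicInterval("chr1", 5000, 5900, "+"),
            category="UTR_extension",
        )
        lms = extract_landmarks([ev], ref, {"g|ext": "cryptic"})
        by_kind = {lm.kind: lm for lm in lms}
        assert by_kind["Ext_proximal_pas"].point.start == 5499
        assert by_kind["Ext_distal_pas"].point.start == 5899

    def test_ext_without_annotated_site_is_error(self, cfg):
        ref = AnnotationSet([make_tx("t", "other", "chr1", "+", [(0, 100), (300, 400)])])
        ev = LastExonEvent(
            event_id="g|ext",
            gene_id="g",
            last_exon=GenomicInterval("chr1", 5000, 5900, "+"),
            category="UTR_extension",
        )
        with pytest.raises(ValueError):
            extract_landmarks([ev], ref, {"g|ext": "cryptic"})


def lm(pos, group="cryptic", strand="+", kind="ALE_pas", event="e"):
    return Landmark(event, kind, GenomicInterval("chr1", pos, pos + 1, strand), group)


class TestCoverageProfile:
    def test_all_events_covered_at_position(self, cfg):
        """A peak at +10 of every event: mean 1.0, SE 0 there."""
        landmarks = [lm(5000, event="e1"), lm(9000, event="e2")]
        peaks = [
            GenomicInterval("chr1", 5008, 5013, "+"),
            GenomicInterval("chr1", 9008, 9013, "+"),
        ]
        prof = coverage_profile(landmarks, peaks, cfg, smooth=False)[("ALE_pas", "cryptic")]
        at10 = np.where(prof.positions == 10)[0][0]
        assert prof.mean[at10] == 1.0
        assert prof.se[at10] == 0.0
        at100 = np.where(prof.positions == 100)[0][0]
        assert prof.mean[at100] == 0.0

    def test_no_peaks_flat_zero(self, cfg):
        prof = coverage_profile([lm(5000)], [], cfg, smooth=False)[("ALE_pas", "cryptic")]
        assert np.nansum(prof.mean) == 0.0

    def test_half_covered_se(self, cfg):
        """2 of 4 events covered -> mean 0.5, SE = sd/sqrt(n) = 0.289."""
        landmarks = [lm(p, event=f"e{i}") for i, p in enumerate([5000, 9000, 13000, 17000])]
        peaks = [
            GenomicInterval("chr1", 5010, 5011, "+"),
            GenomicInterval("chr1", 9010, 9011, "+"),
        ]
        prof = coverage_profile(landmarks, peaks, cfg, smooth=False)[("ALE_pas", "cryptic")]
        at10 = np.where(prof.positions == 10)[0][0]
        assert prof.mean[at10] == pytest.approx(0.5)
        assert prof.se[at10] == pytest.approx(0.289, abs=1e-3)

    def test_mean_equals_brute_force_fraction(self, cfg):
        rng = np.random.default_rng(17)
        landmarks = []
        peaks = []
        for i in range(12):
            pos = 2000 + i * 3000
            strand = "+" if i % 2 == 0 else "-"
            landmarks.append(lm(pos, strand=strand, event=f"e{i}"))
            for _ in range(int(rng.integers(0, 4))):
                s = pos + int(rng.integers(-480, 450))
                peaks.append(GenomicInterval("chr1", s, s + int(rng.integers(5, 60)), strand))
        prof = coverage_profile(landmarks, peaks, cfg, smooth=False)[("ALE_pas", "cryptic")]
        pts = [(l.point.chrom, l.point.start, l.point.strand) for l in landmarks]
        pks = [(p.chrom, p.start, p.end, p.strand) for p in peaks]
        for rel in (-500, -123, -1, 0, 1, 57, 499, 500):
            idx = np.where(prof.positions == rel)[0][0]
            assert prof.mean[idx] == pytest.approx(
                coverage_fraction_oracle(pts, pks, rel)
            )

    def test_strand_mirror_leaves_profile_identical(self, cfg):
        span = 200_000
        landmarks = [lm(5000, event="e1"), lm(11000, event="e2")]
        peaks = [
            GenomicInterval("chr1", 4970, 5030, "+"),
            GenomicInterval("chr1", 11100, 11180, "+"),
        ]
        mirrored_lms = [
            lm(span - 1 - l.point.start, strand="-", event=l.event_id)
            for l in landmarks
        ]
        mirrored_peaks = [
            GenomicInterval("chr1", span - p.end, span - p.start, "-") for p in peaks
        ]
        p1 = coverage_profile(landmarks, peaks, cfg, smooth=False)[("ALE_pas", "cryptic")]
        p2 = coverage_profile(mirrored_lms, mirrored_peaks, cfg, smooth=False)[
            ("ALE_pas", "cryptic")
        ]
        assert np.array_equal(p1.mean, p2.mean)

    def test_contig_edge_positions_missing(self, cfg):
        prof = coverage_profile(
            [lm(200)], [], cfg, contig_lengths={"chr1": 500}, smooth=False
        )[("ALE_pas", "cryptic")]
        at_minus_300 = np.where(prof.positions == -300)[0][0]
        at_400 = np.where(prof.positions == 400)[0][0]
        assert np.isnan(prof.mean[at_minus_300])
        assert np.isnan(prof.mean[at_400])


class TestLoess:
    def test_constant_profile_returns_constant(self):
        x = np.arange(-500, 501, dtype=float)
        y = np.full_like(x, 0.37)
        out = loess_smooth(x, y, span=0.1)
        assert np.allclose(out, 0.37, atol=1e-8)

    def test_linear_trend_preserved(self):
        x = np.arange(100, dtype=float)
        y = 2.0 * x + 1.0
        out = loess_smooth(x, y, span=0.3)
        assert np.allclose(out, y, atol=1e-6)

    def test_smooths_noise(self):
        rng = np.random.default_rng(8)
        x = np.arange(-500, 501, dtype=float)
        signal = np.exp(-(x**2) / (2 * 150**2))
        y = signal + rng.normal(0, 0.15, size=x.size)
        out = loess_smooth(x, y, span=0.1)
        assert np.mean((out - signal) ** 2) < 0.25 * np.mean((y - signal) ** 2)

    def test_nan_positions_stay_nan(self):
        x = np.arange(50, dtype=float)
        y = np.ones(50)
        y[10] = np.nan
        out = loess_smooth(x, y, span=0.3)
        assert np.isnan(out[10])
        assert np.allclose(np.delete(out, 10), 1.0, atol=1e-8)
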