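"""3'end validation: polyA-atlas matching and hexamer rescue.

A predicted last-exon 3'end is credible if it lies strictly within 100 nt
of a polyA-site atlas record (the end is then snapped to the atlas
coordinate), or if one of the 18 polyA-signal hexamers occurs in the final
100 nt of the exon — signals concentrate ~21 nt upstream of cleavage sites.
"""

from apascan import (
    GenomicInterval,
    PipelineConfig,
    PolyASiteAtlas,
    PolyASiteRecord,
    hexamer_rescue,
    match_atlas,
)
from apascan.discovery import LastExonEvent
from apascan.validation import apply_validation

cfg = PipelineConfig()

atlas = PolyASiteAtlas([
    PolyASiteRecord(
        chrom="chr1",
        cluster=GenomicInterval("chr1", 10_010, 10_031, "+"),
        representative_coord=10_020,
        strand="+",
        site_id="chr1:10020:+",
    )
])

predicted = LastExonEvent(
    event_id="demo|9500-10051",
    gene_id="demo",
    last_exon=GenomicInterval("chr1", 9_500, 10_051, "+"),  # 3'end at 10,050
    category="ALE_spliced",
    last_intron=GenomicInterval("chr1", 9_000, 9_500, "+"),
)

val = match_atlas(predicted, atlas, cfg)
updated = apply_validation(predicted, val)
print(f"predicted 3'end {predicted.three_end} -> atlas site {updated.three_end} "
      f"(distance {val.distance_to_atlas} nt < {cfg.atlas_max_dist})")

# an end far from any atlas site falls back to the hexamer scan
exon_seq = "C" * 179 + "AATAAA" + "C" * 15   # AATAAA 21 nt upstream of the end
genome = {"chr2": exon_seq}
orphan = LastExonEvent(
    event_id="demo2|0-200",
    gene_id="demo2",
    last_exon=GenomicInterval("chr2", 0, 200, "+"),
    category="IPA_extension",
)
rescue = hexamer_rescue(orphan, genome, cfg)
print(f"hexamer rescue: motif {rescue.motif} at offset {rescue.motif_offset} nt "
      f"(expected ~{cfg.expected_pas_offset} nt upstream)")
print("An event matching neither the atlas nor a polyA signal is dropped.")
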