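"""End-to-end discovery of cryptic last exons on a synthetic dataset.

Simulates 20 genes where five carry a planted last-exon isoform whose usage
rises from 5% of gene output in control samples to 30% after knockdown,
then runs the full pipeline: assembly merging, novel last-exon extraction,
3'end validation, isoform quantification and differential-usage testing.
"""

import apascan as ap

spec = ap.FixtureSpec(
    n_genes=20,
    planted=[
        ap.PlantedEvent(kind)
        for kind in ("ALE_spliced", "ALE_distal", "IPA_extension",
                     "UTR_extension", "proximal_Ext")
    ],
    seed=42,
)
fixture = ap.make_genome_annotation(spec)
data = ap.make_assemblies_and_quant(spec, fixture)

cfg = ap.PipelineConfig()
result = ap.run_differential_pipeline(
    fixture.reference, data.assemblies, data.quants, data.samples,
    fixture.atlas, fixture.genome, cfg, control="CTRL", dataset="demo",
)

print(f"novel last exons discovered: {len(result.events)}")
for ev in result.events:
    print(f"  {ev.event_id:<32} {ev.category:<14} 3'end via {ev.validation.mode}")

cryptic = result.calls[result.calls.is_cryptic]
print(f"\ncryptic isoforms called: {len(cryptic)}")
print(
    cryptic[["isoform_id", "median_ctrl_usage", "median_delta",
             "cross_dataset_category"]].to_string(index=False)
)
print(
    "\nEach cryptic isoform has <10% usage in controls and gains >10% usage "
    "after knockdown at BH-adjusted p < 0.05; median_ctrl_usage and "
    "median_delta should sit near the planted 0.05 and 0.25."
)
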