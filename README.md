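# apascan

Detection, validation and quantification of novel last exons from
assembled transcriptomes, and classification of *cryptic*
alternative-polyadenylation (APA) events — isoforms that are near-silent
in normal cells but strongly induced when an RNA-binding protein such as
TDP-43 is lost.  TDP-43 depletion, the hallmark of ALS and frontotemporal
dementia pathology, de-represses three kinds of last-exon isoform which
this package discovers from short-read assemblies:

* **ALE** — alternative last exons joined by a novel terminal splice
  junction whose donor matches an annotated 5' splice site;
* **IPA** — intronic polyadenylation via extension of an annotated
  internal exon into its downstream intron;
* **3'Ext** — usage of a distal polyA site extending an annotated 3'UTR.

Candidate 3'ends are validated against a polyA-site atlas (match within
100 nt, end snapped to the atlas coordinate) or rescued by the presence of
one of the 18 polyA-signal hexamers in the final 100 nt of the exon
(signals sit ~21 nt upstream of cleavage sites).  Validated events join
annotated last exons in a quantification reference with last-exon isoform
identifiers and, for nuclear RNA, intron-retention decoy transcripts.

The central statistic is fractional polyA usage

    usage_is = TPM_is / Σ_{i' ∈ gene(i)} TPM_{i's}

tested between conditions with a per-isoform quasi-binomial GLM of isoform
counts against gene-total counts.  An isoform is called **cryptic** when,
in at least one dataset,

    padj < 0.05,  mean usage_ctrl < 10%,  Δusage (KD − CTRL) > 10%.

Around each event the package computes binding-peak metaprofiles
(fraction of events covered per position, ±1 SE, LOESS-smoothed),
positional 6-mer enrichment at cryptic vs background landmarks with
one-sided GSEA of the TDP-43-preferred UG-rich hexamer groups, and a
cohort screen that calls a cryptic splice junction *selective* when
expressed (≥2 spliced reads) in ≥1% of samples with expected TDP-43
pathology and ≤0.5% of the rest.

A deterministic synthetic-fixture generator (toy genomes with planted
events, Dirichlet usage, negative-binomial counts, Poisson junction reads)
makes every stage testable without downloads.

## Worked example

`examples/01_discover_cryptic_events.py` simulates 20 genes, five with a
planted isoform whose usage rises from 5% (control) to 30% (knockdown),
and runs the full pipeline:

```
novel last exons discovered: 4
  g001|chrS:2402-2602:+            ALE_spliced    3'end via atlas
  g002|chrS:6992-7192:-            ALE_distal     3'end via atlas
  g003|chrS:14031-14474:+          IPA_extension  3'end via atlas
  g004|chrS:19614-20106:-          UTR_extension  3'end via atlas

cryptic isoforms called: 5
isoform_id  median_ctrl_usage  median_delta cross_dataset_category
 g001_iso1           0.062362      0.231988     cryptic_consistent
 g002_iso3           0.037862      0.255703     cryptic_consistent
 g003_iso1           0.051769      0.271640     cryptic_consistent
 g004_iso3           0.056080      0.244959     cryptic_consistent
 g005_iso1           0.039268      0.250450     cryptic_consistent
```

All four novel-event classes are recovered (the fifth cryptic call,
`g005_iso1`, is the planted proximal shift on an annotated isoform), with
median control usage near the planted 5% and usage gains near the planted
25 points.  The other examples cover 3'end validation, reference/decoy
construction, binding metaprofiles, motif GSEA and the cohort screen; each
prints its numbers with a line on what they mean.

A thin CLI wraps the same functions for shell use:

```
apascan simulate --out fixtures --seed 42
apascan discover --assemblies fixtures/sample_sheet.tsv \
    --reference fixtures/reference.gtf --atlas fixtures/atlas.bed \
    --genome fixtures/genome.fa --out run1
apascan build-ref --events run1/novel_last_exons.gtf \
    --reference fixtures/reference.gtf --out ref
apascan screen --sj-dir sj/ --junctions ref/inferred_junctions.bed \
    --metadata cohort.tsv --out selectivity.tsv
```

## Layout

- `src/apascan/` — the library: `intervals`, `models`, `io` (genomic core),
  `discovery`, `validation`, `reference`, `usage`, `cryptic`, `profiles`,
  `motifs`, `cohort`, `simulate`, `pipeline`, `cli`.
- `examples/` — one narrative script per capability.
- `tests/` — pytest suite, including brute-force oracles
  (`tests/oracles.py`) independent of the implementation.
- `docs/methods.md` — the model, parameters, numerical choices and
  limitations.
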