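# Methods

`apascan` detects and quantifies alternative-polyadenylation (APA) isoforms
— novel last exons — from short-read transcriptome assemblies, and screens
them for *cryptic* behaviour: near-silent under normal conditions, strongly
induced when an RNA-binding protein such as TDP-43 is depleted.  This note
documents the model behind each stage, the parameters that matter, the
numerical choices, and what the synthetic fixtures do and do not establish.

## Event model and discovery

A transcript model is an ordered chain of exons on one strand; introns are
the gaps between consecutive exons, and the last exon / last intron are
strand-aware notions (on the minus strand the genomically first exon is the
transcript's last).  Internally all coordinates are 0-based half-open; GTF
I/O converts from the 1-based closed convention and splice-junction tables
convert on ingest, so no other module performs coordinate arithmetic of its
own.

The reference annotation is first restricted to well-supported mRNA-like
models: transcript support level (TSL) in {1, 2, 3}, gene biotype
protein-coding or lncRNA, and no `mRNA_end_NF` tag (3'end unsupported).
TSL "NA" transcripts are dropped with a logged count.  The TSL rule is
configurable (`tsl_keep`); the default reads the support-level filter in
its quality-increasing direction, i.e. keeping the three best-supported
tiers.

Per-sample assemblies are grouped by experimental condition.  Transcript
identity across samples is established by identical intron chains
(mono-exonic models: >= 50% reciprocal exon overlap); within an identity
cluster the representative is the member with the most distal 3'end, which
mirrors assembler-merge semantics (a redundant merge keeps the longest
3'end) and is what allows a 3'UTR-extension transcript to survive merging
with its unextended parent.  The condition mean TPM counts a transcript as
0 in samples where it was not assembled; transcripts at or below 1 TPM mean
are removed (strict `>`).

Each surviving transcript's last exon is classified against the filtered
reference.  The predicted 3'end must fall outside every annotated exon;
then exactly one structural criterion must hold:

* **ALE (spliced)** — the terminal intron is contained within an annotated
  intron, its donor exactly matches an annotated 5' splice site, and the
  acceptor lies strictly inside the annotated intron.  The strictness is
  what separates ALEs from IPAs: an acceptor on the intron boundary means
  the last exon begins exactly at an annotated exon, which is the IPA
  shape.
* **ALE (distal)** — the donor matches an annotated 5' splice site and the
  exon lies wholly beyond the gene's most distal annotated 3'end.
* **IPA (exon extension)** — the last exon's 5'end equals the 5'end of an
  overlapping annotated internal exon (first-exon matches tolerate a
  100 nt slack, `first_exon_slack`, because assembled transcript 5'ends
  are imprecise) and extends that exon by at least `min_extension`
  (100 nt).
* **3'UTR extension** — the last exon overlaps the gene's most distal
  annotated last exon, matches its 5'end exactly, and extends its 3'end by
  at least `min_extension`.

Events satisfying both the ALE and IPA criteria are labelled `complex` and
excluded from category-specific downstream steps.  Transcripts spanning
two same-strand reference genes, or antisense to every overlapping gene,
are dropped and logged.  Proximal 3'UTR *shortening* has no extraction
rule of its own; it surfaces downstream as increased usage of an annotated
proximal isoform.

## 3'end validation

A predicted 3'end is credible when the nearest same-strand polyA-site
atlas record (distance to the representative coordinate, either direction)
is strictly below `atlas_max_dist` = 100 nt; the end is then snapped to the
atlas coordinate, since 3'end-sequencing-derived atlases are
nucleotide-resolved.  Ends with no atlas support are rescued when one of
the 18 polyA-signal hexamer variants (AATAAA and its weaker relatives; the
set is configurable because different compilations circulate) occurs in
the 3'-terminal `motif_search_window` = 100 nt of the exon's sense
sequence; exons shorter than the window are scanned whole.  The motif
offset is measured from motif start to the cleavage position; signals
concentrate ~21 nt upstream, so when several motif-rescued candidates
overlap at a locus the one minimising |offset − 21| represents the
condition, ties breaking to the more proximal 3'end.  Equidistant atlas
sites also resolve to the more proximal site.  Atlas matches always take
precedence over motif rescue.

## Isoform reference, decoys and junctions

Annotated last exons of every retained reference transcript are combined
with the validated novel events.  Within a gene, last exons sharing any
overlapping sequence receive one last-exon isoform identifier — except
3'UTR extensions, which keep their own identifier while the annotated last
exon(s) they extend share a single grouped one, so extension usage is
measured against the rest of the gene's output.  To prevent read
misattribution, sequence overlapping annotated first/internal exons is
subtracted from every last exon (only "unique" regions are retained), and
a last exon whose 3'end lies inside a first/internal exon is removed
outright.

For nuclear RNA, where nascent transcripts retain introns, decoy models
absorb reads that would otherwise inflate cryptic isoforms: an IPA event
begets, per annotated exon-pair context, a spliced decoy (host internal
exon + downstream exon) and an intron-retention decoy (one exon spanning
both plus the intervening intron); an intronic ALE begets a retained-intron
decoy consuming the entire host intron with its flanking exons; 3'UTR
extensions need none, as they contain no intron to retain.  Decoys carry
suffixed identifiers (`_decoy_spliced`, `_decoy_ir`, `_decoy_alir`), never
receive isoform identifiers, and are excluded from isoform sums.  Decoys
are built against transcripts of the event's own gene only.

ALE splice junctions are inferred from annotation: intronic ALEs take the
host intron's donor to the ALE start; ALEs beyond the gene take the
closest upstream annotated donor; annotated ALEs report every annotated
intron terminating at them.  All three rules are transcript-orientation
aware.

## Usage quantification and differential testing

Member-transcript TPMs are summed per isoform.  Count estimates follow the
length-scaled-TPM contract: isoform TPM times the across-sample mean
isoform effective length (TPM-weighted over members), each sample's column
rescaled to its total read count.  Fractional polyA usage divides isoform
TPM by the gene's summed TPM; genes with zero total in a sample are
undefined there (NaN, never 0) and propagate as missing.

Differential usage between two conditions is tested per isoform with a
quasi-binomial GLM of isoform counts against gene-total counts: the full
model adds the condition to an intercept (plus optional categorical
covariates, e.g. differentiation batch); the F statistic is the deviance
difference scaled by the full model's Pearson dispersion, with p from
F(1, n − p).  This is a deliberate stand-in for a dedicated exon-usage GLM
engine — the scientific contribution here is the thresholds and plumbing,
not the dispersion estimator — and `results_from_table` ingests externally
computed per-isoform p-value tables in its place.  On simulated null data
(negative-binomial counts, Dirichlet usage, n = 3 vs 3) the empirical
type-I error at nominal 0.05 is ~0.05 (the acceptance script recomputes
this).  Benjamini–Hochberg adjustment is applied within dataset.

A **cryptic** isoform satisfies, in at least one dataset: BH-adjusted
p < `alpha` (0.05), mean control usage < `cryptic_max_ctrl_usage` (10%),
and usage gain > `cryptic_min_delta` (10%) — all strict inequalities.
Across datasets, isoforms are categorised from medians over the datasets
where they were tested: consistent cryptics (median control < 10%, median
gain > 10%), low-basal non-responders, responders with high basal usage
(significant increase in >= 1 dataset — configurable to *all* — but median
control usage > 10%), and background (tested everywhere, never
significant).  The background set used for binding analyses requires
padj > alpha in every dataset of the chosen group.

For paired FACS-sorted populations, sample-wise usage differences subtract
the depleted-population usage from the intact one per pair; an isoform is
enrichment-flagged when the median difference exceeds
`facs_enrichment_min_median_delta` (5%).

## Landmark metaprofiles

Predictions of the same isoform from several datasets collapse to one
representative interval via a fixed ladder: atlas-matched predictions win;
among distinct atlas sites, most supporting datasets, then the more
proximal site; among distinct cluster-overlapping ends, closest to the
representative coordinate, then most distal; among motif-only candidates,
minimal |offset − 21|, then most proximal.  Residual distinct IPA 3'ends
take the most distal (the generic end tie-breaks defer to this category
rule for IPAs); residual distinct ALE 5'ends take the shortest exon
(`ale_collapse_shortest_exon`; the alternative reading, most proximal
5'end, is available behind the switch).  Every firing rule is logged.

Landmarks are single nucleotides: ALE exon start and polyA site; for 3'UTR
extensions, the proximal landmark is the gene's most distal *annotated*
polyA site and the distal one the extension end.  Windows of
`map_flank` = 500 nt on each side are scored 0/1 per position against
merged, non-redundant binding peaks in transcript orientation (negative =
upstream).  The per-position mean is exactly the fraction of events with
an overlapping peak; the band is ±1 standard error (sample SD / √n).
Positions falling off the contig are missing, not zero.  Curves are
smoothed by LOESS — degree-2 local regression with tricube weights, span
`loess_span` = 0.1 interpreted as a fraction of points — implemented
in-package so the contract is exact: a constant series is returned
unchanged to ~1e-15.

## Positional k-mer enrichment and GSEA

For motif analysis, windows of ±`peka_distal` (500 nt) around cryptic and
background landmarks are extracted in transcript orientation and handled
as RNA (T→U).  For each 6-mer (`kmer_k`), the per-landmark relative
occurrence is (count in the ±`peka_proximal` = 250 nt window of interest
+ 0.5) / (count in the surrounding context — the distal window excluding
the window of interest — + 0.5); the enrichment score is the z-statistic
contrasting group means, with a 1e-9 floor on the standard error so exact
contrasts stay finite.  All proximal positions contribute and no
expression thresholding of background landmarks is applied.  Rankings are
total, ties resolved lexicographically.  At least 10 landmarks per group
are required; below that the contrast is too unstable to report.

Predefined TDP-43-preferred hexamer groups (YG-, YA- and AA-containing
[UG]n 6-mers: 6, 6 and 8 members, pairwise disjoint, plus their union) are
tested by one-sided GSEA on the score ranking: a weighted running sum
(weight exponent 1, hits weighted by |score|, misses by 1/(N − m)), ES its
maximum, permutation p from random same-size member sets (default 10,000,
seeded; floor 1/(N+1)), NES = ES / mean |ES| of the permuted sets, and BH
adjustment jointly across all landmark × set tests.  Set-level coverage
maps mark, per position, the fraction of events whose window places any
member 6-mer over that position (union across members, so the mean stays
in [0, 1] even for overlapping members such as UGUGUG/GUGUGU in a UG
repeat), smoothed like the peak maps.

## Cohort junction screen

Per-sample splice-junction tables (9-column spliced-aligner dialect,
1-based closed intron coordinates, unique-read counts) are queried for
target junctions; absent junctions count 0, duplicate rows within a sample
are an error, and undetermined-strand rows match either strand by default
(`strand_agnostic_undetermined`).  A junction is *expressed* in a sample
at >= `min_junction_reads` = 2 unique spliced reads, and *selective* when
expressed in at most 0.5% of samples where TDP-43 pathology is not
expected and at least 1% of samples where it is (both inclusive).  The
pathology-expected flag is data-driven from a (disease subtype, tissue)
mapping; the shipped template lists ALS-TDP motor cortex, frontal/temporal
cortex and cervical/lumbar/thoracic spinal cord, and FTLD-TDP
frontal/temporal cortex.

## Synthetic fixtures

The generator emulates the statistical structure the pipeline assumes, on
a scale chosen for complete desk-side runs: 50 genes by default, each with
four exons and two annotated isoforms (a full-length model and a variant
ending at an annotated intronic ALE), with ten planted events — two of
each class (spliced ALE, distal ALE, IPA, 3'UTR extension, and a proximal
shift realised as a usage change on the annotated variant).  Planted
events carry 5% usage in control and 30% after knockdown; per-sample usage
is Dirichlet-distributed (concentration 300, a mild overdispersion about
the planted fractions), isoform counts are negative-binomial with variance
μ + αμ² at α = 0.05 and 500 reads per gene, TPMs are exact usage fractions
of an equal per-gene expression budget, and AATAAA is planted 21 nt
upstream of every true 3'end.  Annotated ends always enter the polyA
atlas; novel ends enter with probability `atlas_fraction` = 0.7, the rest
exercising the motif-rescue path.  Binding peaks appear at cryptic
landmarks with probability 0.8 and background landmarks 0.1; cohort
junction reads are Poisson on top of the 2-read detection floor at
group-specific expression rates.  Every output is a pure function of the
seed, with independent substreams per stage.

What passing on fixtures does *not* show: real assemblies carry fragmented
and truncated models, expression-correlated assembly dropout, alignment
and GC biases in quantification, atlas clusters wider than the planted
±10 nt, and sequence composition far from uniform — so recovery rates here
bound behaviour under the generative model only, not on real tissue data.

## Known limitations

* The differential-usage stand-in shares the quasi-binomial mean-variance
  assumption but not the dispersion-sharing machinery of dedicated
  exon-usage engines; borderline calls near the thresholds can differ.
* Intron-retention artefacts that mimic IPA (coverage wells inside
  introns) are not detected; the original screen curated those manually.
* The k-mer enrichment score is a documented z-contrast, not a bit-exact
  reimplementation of any published k-mer tool; external score tables can
  be substituted.
* Complex events (ALE and IPA structure simultaneously) are reported but
  not resolved further.
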