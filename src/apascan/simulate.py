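"""Deterministic synthetic fixtures with planted APA events.

The generator emulates the statistical structure the pipeline assumes: toy
multi-exon genes on both strands, a knockdown-induced gain in usage of a
planted novel last exon (ALE / IPA / 3'UTR extension), polyA-signal
hexamers planted 21 nt upstream of every true 3'end, a polyA-site atlas
covering a configurable subset of true sites (the rest must be rescued by
motif), Dirichlet-distributed per-sample usage fractions, negative-binomial
isoform counts (variance mu + alpha*mu^2), and Poisson junction reads with
group-specific detection rates.

Every output is a pure function of the seed.  Independent random streams
are derived per generator stage so the stages may be called in any order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .discovery import LastExonEvent
from .intervals import GenomicInterval, reverse_complement
from .models import AnnotationSet, PolyASiteAtlas, PolyASiteRecord, TranscriptModel
from .profiles import Landmark

PLANTABLE_KINDS = (
    "ALE_spliced",
    "ALE_distal",
    "IPA_extension",
    "UTR_extension",
    "proximal_Ext",
)


@dataclass(frozen=True)
class PlantedEvent:
    kind: str
    ctrl_usage: float = 0.05
    kd_usage: float = 0.30

    def __post_init__(self) -> None:
        if self.kind not in PLANTABLE_KINDS:
            raise ValueError(f"unknown planted event kind {self.kind!r}")
        for u in (self.ctrl_usage, self.kd_usage):
            if not (0 <= u <= 1):
                raise ValueError("usage fractions must lie in [0, 1]")


def _default_planted() -> list[PlantedEvent]:
    return [PlantedEvent(kind) for _ in range(2) for kind in PLANTABLE_KINDS]


@dataclass
class FixtureSpec:
    n_genes: int = 50
    planted: list[PlantedEvent] = field(default_factory=_default_planted)
    n_replicates: int = 3
    conditions: tuple[str, str] = ("CTRL", "KD")  # (control, knockdown)
    nb_dispersion: float = 0.05
    mean_gene_depth: float = 500.0
    dirichlet_concentration: float = 300.0
    atlas_fraction: float = 0.7
    p_peak_cryptic: float = 0.8
    p_peak_background: float = 0.1
    exon_length_range: tuple[int, int] = (150, 300)
    intron_length_range: tuple[int, int] = (800, 1200)
    n_low_support_genes: int = 0  # extra TSL=4 genes, removed by the filter
    chrom: str = "chrS"
    seed: int = 42

    def __post_init__(self) -> None:
        if len(self.planted) > self.n_genes:
            raise ValueError("more planted events than genes")


@dataclass
class GeneFixture:
    gene_id: str
    strand: str
    window: GenomicInterval
    main_tx: TranscriptModel       # e1..e4
    variant_tx: TranscriptModel    # e1..e3 + annotated variant ALE
    planted: Optional[PlantedEvent]
    novel_tx: Optional[TranscriptModel]
    #: member name -> (transcript id, base usage ctrl, base usage kd)
    members: dict[str, tuple[str, float, float]]


@dataclass
class FixtureGenome:
    genome: dict[str, str]
    reference: AnnotationSet
    genes: list[GeneFixture]
    atlas: PolyASiteAtlas

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")


def _mirror(iv: tuple[int, int], length: int) -> tuple[int, int]:
    a, b = iv
    return (length - b, length - a)


def _plant(seq: list[str], pos: int, motif: str) -> None:
    seq[pos : pos + len(motif)] = list(motif)


def make_genome_annotation(spec: FixtureSpec) -> FixtureGenome:
    """Build the toy genome, reference annotation and polyA-site atlas.

    Each gene has four exons (e1..e4, plus introns i1..i3), two annotated
    transcripts — the full model and a variant ending at an annotated ALE
    inside i3 — and, for genes carrying a planted event, one novel
    transcript realising that event.  AATAAA is planted 21 nt upstream of
    every true 3'end; annotated ends always enter the atlas, novel ends
    with probability ``atlas_fraction``.
    """
    rng = np.random.default_rng([spec.seed, 0])
    margin = 700
    genes: list[GeneFixture] = []
    transcripts: list[TranscriptModel] = []
    atlas_records: list[PolyASiteRecord] = []
    chrom_seq: list[str] = []
    offset = 0
    n_total = spec.n_genes + spec.n_low_support_genes

    for gi in range(n_total):
        gene_id = f"g{gi + 1:03d}"
        strand = "+" if gi % 2 == 0 else "-"
        low_support = gi >= spec.n_genes
        planted = (
            spec.planted[gi] if (not low_support and gi < len(spec.planted)) else None
        )

        elens = rng.integers(*spec.exon_length_range, size=4)
        ilens = rng.integers(*spec.intron_length_range, size=3)
        # layout space: gene built 5'->3' on the + strand, mirrored later
        pos = margin
        exons_l: list[tuple[int, int]] = []
        for k in range(4):
            exons_l.append((pos, pos + int(elens[k])))
            pos += int(elens[k])
            if k < 3:
                pos += int(ilens[k])
        e1, e2, e3, e4 = exons_l
        variant_l = (e3[1] + 300, e3[1] + 500)  # annotated ALE inside i3

        novel_l: Optional[list[tuple[int, int]]] = None
        kind = planted.kind if planted else None
        if kind == "ALE_spliced":
            s = e2[1] + 300
            novel_l = [e1, e2, (s, s + 200)]
        elif kind == "ALE_distal":
            s = e4[1] + 250
            novel_l = [e1, e2, e3, (s, s + 200)]
        elif kind == "IPA_extension":
            novel_l = [e1, (e2[0], e2[1] + 250)]
        elif kind == "UTR_extension":
            novel_l = [e1, e2, e3, (e4[0], e4[1] + 300)]
        # proximal_Ext: no novel transcript, a usage shift on the variant

        length = max(
            e4[1] + 600,
            novel_l[-1][1] + 100 if novel_l else 0,
        ) + margin

        seq = list("".join(rng.choice(list("ACGT"), size=length)))
        three_end_exons = [e4, variant_l] + ([novel_l[-1]] if novel_l else [])
        for _, exon_end in three_end_exons:
            _plant(seq, exon_end - 21, "AATAAA")
        layout_seq = "".join(seq)

        def to_genomic(iv: tuple[int, int]) -> GenomicInterval:
            a, b = iv if strand == "+" else _mirror(iv, length)
            return GenomicInterval(spec.chrom, offset + a, offset + b, strand)

        genome_seq = layout_seq if strand == "+" else reverse_complement(layout_seq)
        chrom_seq.append(genome_seq + "".join(rng.choice(list("ACGT"), size=300)))

        attrs = {
            "gene_id": gene_id,
            "gene_type": "protein_coding",
            "transcript_support_level": "4" if low_support else "1",
        }
        main_tx = TranscriptModel(
            f"{gene_id}_t1", gene_id, [to_genomic(e) for e in exons_l], dict(attrs)
        )
        variant_tx = TranscriptModel(
            f"{gene_id}_t2",
            gene_id,
            [to_genomic(e) for e in (e1, e2, e3, variant_l)],
            dict(attrs),
        )
        transcripts += [main_tx, variant_tx]

        novel_tx = None
        if novel_l is not None:
            novel_tx = TranscriptModel(
                f"{gene_id}_novel",
                gene_id,
                [to_genomic(e) for e in novel_l],
                {"gene_id": gene_id},
            )

        # atlas records for true 3'ends
        ends = [(main_tx.last_exon, True), (variant_tx.last_exon, True)]
        if novel_tx is not None:
            ends.append((novel_tx.last_exon, rng.random() < spec.atlas_fraction))
        for exon, in_atlas in ends:
            if not in_atlas:
                continue
            rep = exon.three_prime
            atlas_records.append(
                PolyASiteRecord(
                    chrom=spec.chrom,
                    cluster=GenomicInterval(spec.chrom, rep - 10, rep + 11, strand),
                    representative_coord=rep,
                    strand=strand,
                    site_id=f"{spec.chrom}:{rep}:{strand}",
                )
            )

        # base usage fractions per member
        if planted is None or low_support:
            members = {
                "main": (main_tx.transcript_id, 0.7, 0.7),
                "variant": (variant_tx.transcript_id, 0.3, 0.3),
            }
        elif kind == "proximal_Ext":
            members = {
                "main": (main_tx.transcript_id, 1 - planted.ctrl_usage, 1 - planted.kd_usage),
                "variant": (variant_tx.transcript_id, planted.ctrl_usage, planted.kd_usage),
            }
        else:
            u0, u1 = planted.ctrl_usage, planted.kd_usage
            members = {
                "main": (main_tx.transcript_id, (1 - u0) * 0.75, (1 - u1) * 0.75),
                "variant": (variant_tx.transcript_id, (1 - u0) * 0.25, (1 - u1) * 0.25),
                "novel": (novel_tx.transcript_id, u0, u1),
            }

        genes.append(
            GeneFixture(
                gene_id=gene_id,
                strand=strand,
                window=GenomicInterval(spec.chrom, offset, offset + length, strand),
                main_tx=main_tx,
                variant_tx=variant_tx,
                planted=None if low_support else planted,
                novel_tx=novel_tx,
                members=members,
            )
        )
        offset += length + 300

    return FixtureGenome(
        genome={spec.chrom: "".join(chrom_seq)},
        reference=AnnotationSet(transcripts),
        genes=genes,
        atlas=PolyASiteAtlas(atlas_records),
    )


@dataclass
class FixtureData:
    """Per-sample assemblies, quantifications and sample metadata."""

    samples: pd.DataFrame  # index: sample name; columns: condition
    assemblies: dict[str, AnnotationSet]
    quants: dict[str, pd.DataFrame]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with variance mu + alpha*mu^2 (gamma-Poisson)."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
    return rng.poisson(lam).astype(float)


def make_assemblies_and_quant(
    spec: FixtureSpec, fg: FixtureGenome
) -> FixtureData:
    """Simulate per-sample transcript assemblies and quantification tables.

    Knockdown samples assemble the planted novel transcripts; control
    samples do not (the novel isoform is still *quantified* everywhere, as
    all samples are quantified against the combined reference).  Usage
    fractions are Dirichlet-distributed around the planted values and
    isoform counts negative-binomial at the configured dispersion.
    """
    rng = np.random.default_rng([spec.seed, 1])
    ctrl, kd = spec.conditions
    sample_names = [
        f"{cond}_{i + 1}" for cond in (ctrl, kd) for i in range(spec.n_replicates)
    ]
    samples = pd.DataFrame(
        {"condition": [s.rsplit("_", 1)[0] for s in sample_names]}, index=sample_names
    )

    assemblies: dict[str, AnnotationSet] = {}
    quant_rows: dict[str, list[dict]] = {s: [] for s in sample_names}
    for sample in sample_names:
        is_kd = samples.loc[sample, "condition"] == kd
        txs: list[TranscriptModel] = []
        for g in fg.genes:
            txs += [g.main_tx, g.variant_tx]
            if is_kd and g.novel_tx is not None:
                txs.append(g.novel_tx)
        assemblies[sample] = AnnotationSet(txs)

    for g in fg.genes:
        member_names = list(g.members)
        base = {
            False: np.array([g.members[m][1] for m in member_names]),
            True: np.array([g.members[m][2] for m in member_names]),
        }
        tx_ids = [g.members[m][0] for m in member_names]
        lengths = np.array(
            [
                sum(len(e) for e in (fg.reference.get(t) or g.novel_tx).exons)
                for t in tx_ids
            ],
            dtype=float,
        )
        eff_lens = np.maximum(lengths - 200.0, 25.0)
        gene_tpm_total = 1e6 / len(fg.genes)  # genes equally expressed
        for sample in sample_names:
            is_kd = samples.loc[sample, "condition"] == kd
            # usage is a TPM fraction; reads are proportional to TPM x length
            frac_tpm = rng.dirichlet(base[is_kd] * spec.dirichlet_concentration)
            read_frac = frac_tpm * eff_lens
            read_frac = read_frac / read_frac.sum()
            counts = _nb_draw(
                rng, spec.mean_gene_depth * read_frac, spec.nb_dispersion
            )
            for t, L, eL, f, c in zip(tx_ids, lengths, eff_lens, frac_tpm, counts):
                quant_rows[sample].append(
                    {
                        "Name": t,
                        "Length": L,
                        "EffectiveLength": eL,
                        "TPM": gene_tpm_total * f,
                        "NumReads": c,
                    }
                )

    quants = {s: pd.DataFrame(rows) for s, rows in quant_rows.items()}
    return FixtureData(samples=samples, assemblies=assemblies, quants=quants)


def planted_event_ids(fg: FixtureGenome) -> dict[str, str]:
    """gene_id -> planted kind, for genes carrying a cryptic event."""
    return {g.gene_id: g.planted.kind for g in fg.genes if g.planted is not None}


# ---------------------------------------------------------------------------
# peaks and junction cohort
# ---------------------------------------------------------------------------

def make_peaks(
    spec: FixtureSpec, landmarks: Sequence[Landmark]
) -> list[GenomicInterval]:
    """Plant binding peaks at landmarks with group-specific probabilities."""
    rng = np.random.default_rng([spec.seed, 2])
    peaks = []
    for lm in landmarks:
        p = spec.p_peak_cryptic if lm.group == "cryptic" else spec.p_peak_background
        if rng.random() < p:
            pos = lm.point.start
            peaks.append(
                GenomicInterval(lm.point.chrom, max(0, pos - 25), pos + 15, lm.point.strand)
            )
    return peaks


@dataclass
class CohortSpec:
    n_pathology: int = 100
    n_nonpathology: int = 200
    #: junction key -> (detection rate in pathology, in non-pathology)
    rates: dict[str, tuple[float, float]] = field(default_factory=dict)
    expressed_extra_reads: float = 3.0  # Poisson mean on top of 2 reads
    seed: int = 42


def make_junction_cohort(
    cohort: CohortSpec,
    junctions: Sequence[GenomicInterval],
    out_dir,
    default_rates: tuple[float, float] = (0.02, 0.0),
) -> tuple[dict[str, Path], pd.DataFrame]:
    """Write per-sample splice-junction tables and the cohort metadata.

    A sample expresses a junction with its group's detection rate; when
    expressed, the unique-read count is 2 + Poisson(extra), otherwise 0
    (absent from the table).  Pathology-expected samples are ALS-TDP motor
    cortex; the rest are controls (cerebellum).
    """
    from .cohort import junction_key

    rng = np.random.default_rng([cohort.seed, 3])
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    paths: dict[str, Path] = {}
    strand_code = {"+": 1, "-": 2, ".": 0}
    for i in range(cohort.n_pathology + cohort.n_nonpathology):
        pathology = i < cohort.n_pathology
        sample = f"{'path' if pathology else 'ctrl'}_{i + 1:04d}"
        meta_rows.append(
            {
                "sample": sample,
                "tissue": "motor_cortex" if pathology else "cerebellum",
                "disease_subtype": "ALS-TDP" if pathology else "Control",
            }
        )
        lines = []
        for j in junctions:
            key = junction_key(j)
            rate_p, rate_n = cohort.rates.get(key, default_rates)
            rate = rate_p if pathology else rate_n
            if rng.random() < rate:
                count = 2 + rng.poisson(cohort.expressed_extra_reads)
                lines.append(
                    f"{j.chrom}\t{j.start + 1}\t{j.end}\t{strand_code[j.strand]}"
                    f"\t1\t0\t{count}\t0\t30\n"
                )
        path = out_dir / f"{sample}.SJ.out.tab"
        path.write_text("".join(lines))
        paths[sample] = path
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    return paths, metadata


# ---------------------------------------------------------------------------
# stand-alone null-usage simulation (for test calibration)
# ---------------------------------------------------------------------------

def simulate_null_usage(
    n_genes: int,
    n_per_condition: int,
    depth: float = 500.0,
    dispersion: float = 0.05,
    concentration: float = 300.0,
    n_isoforms: int = 2,
    base_usage: Optional[Sequence[float]] = None,
    seed: int = 0,
):
    """Isoform usage matrix with no condition effect (null model).

    Returns an :class:`~apascan.usage.IsoformUsageMatrix` (usage filled) and
    the matching design table; used to calibrate the differential-usage
    test's type-I error.
    """
    from .usage import IsoformUsageMatrix, polya_usage

    rng = np.random.default_rng([seed, 4])
    if base_usage is None:
        base_usage = np.ones(n_isoforms) / n_isoforms
    base = np.asarray(base_usage, dtype=float)
    sample_names = [
        f"{cond}_{i + 1}" for cond in ("CTRL", "KD") for i in range(n_per_condition)
    ]
    design = pd.DataFrame(
        {"condition": [s.rsplit("_", 1)[0] for s in sample_names]}, index=sample_names
    )
    iso_ids, gene_ids, rows = [], [], []
    for gi in range(n_genes):
        gene = f"ng{gi + 1:04d}"
        for k in range(n_isoforms):
            iso_ids.append(f"{gene}_iso{k + 1}")
            gene_ids.append(gene)
        mat = np.empty((n_isoforms, len(sample_names)))
        for si in range(len(sample_names)):
            frac = rng.dirichlet(base * concentration)
            mat[:, si] = _nb_draw(rng, depth * frac, dispersion)
        rows.append(mat)
    counts = pd.DataFrame(
        np.vstack(rows), index=iso_ids, columns=sample_names
    )
    m = IsoformUsageMatrix(
        tpm=counts.copy(),
        counts=counts,
        iso2gene=pd.Series(gene_ids, index=iso_ids, name="gene_id"),
        samples=design,
    )
    return polya_usage(m), design
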