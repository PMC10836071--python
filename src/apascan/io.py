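"""Readers and writers for the pipeline's interchange formats.

GTF (GENCODE attribute dialect), PolyASite-style extended BED for the polyA
atlas, FASTA sequence extraction, and the Name/Length/EffectiveLength/TPM/
NumReads quantification tables produced by transcript quantifiers.

GTF coordinates are 1-based closed on disk and converted to the internal
0-based half-open convention on read (and back on write).  Attribute strings
are preserved verbatim, so a read-write-read round trip is lossless for
everything the pipeline consumes.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
from pyfaidx import Fasta

from .intervals import GenomicInterval, reverse_complement
from .models import (
    AnnotationSet,
    PolyASiteAtlas,
    PolyASiteRecord,
    TranscriptModel,
    ValidationError,
)

PathLike = Union[str, Path]


class GtfParseError(ValueError):
    """Malformed GTF content; message names the offending line."""


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"\s*;?')


def _parse_attributes(attr_string: str, path: PathLike, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    stripped = attr_string.strip()
    if not stripped:
        return attrs
    consumed = 0
    for m in _ATTR_RE.finditer(stripped):
        key, value = m.group(1), m.group(2)
        # GENCODE repeats the "tag" key; collect repeats comma-separated
        if key in attrs:
            attrs[key] = attrs[key] + "," + value
        else:
            attrs[key] = value
        consumed = m.end()
    if consumed < len(stripped.rstrip(";").rstrip()):
        raise GtfParseError(
            f"{path}: malformed attribute string at line {lineno}: "
            f"{attr_string!r}"
        )
    return attrs


def read_gtf(path: PathLike, dialect: str = "reference") -> AnnotationSet:
    """Read exon rows of a GTF file into an :class:`AnnotationSet`.

    ``dialect`` is ``"reference"`` for a curated annotation or ``"assembly"``
    for assembler output; both share the parser, the flag is recorded per
    transcript under the ``source_dialect`` attribute.  Transcripts without
    exon rows are rejected implicitly (only exon rows are consumed); exon
    rows lacking transcript_id or gene_id raise with the offending
    transcript/line named.
    """
    if dialect not in ("reference", "assembly"):
        raise ValueError(f"unknown GTF dialect {dialect!r}")
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, dict[str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(
                    f"{path}: expected 9 tab-separated columns at line "
                    f"{lineno}, got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame = fields[:8]
            if feature != "exon":
                continue
            attrs = _parse_attributes(fields[8], path, lineno)
            tx_id = attrs.get("transcript_id")
            if not tx_id:
                raise GtfParseError(
                    f"{path}: exon row without transcript_id at line {lineno}"
                )
            if not attrs.get("gene_id"):
                raise GtfParseError(
                    f"{path}: transcript {tx_id!r} lacks gene_id "
                    f"(line {lineno})"
                )
            try:
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            except ValueError as exc:
                raise GtfParseError(f"{path}: line {lineno}: {exc}") from exc
            if tx_id not in exons:
                exons[tx_id] = []
                order.append(tx_id)
                attrs["source_dialect"] = dialect
                meta[tx_id] = attrs
            exons[tx_id].append(iv)
    transcripts = []
    for tx_id in order:
        attrs = meta[tx_id]
        transcripts.append(
            TranscriptModel(
                transcript_id=tx_id,
                gene_id=attrs["gene_id"],
                exons=exons[tx_id],
                attributes=attrs,
            )
        )
    return AnnotationSet(transcripts)


_INTERNAL_ATTRS = ("source_dialect",)


def write_gtf(ann: AnnotationSet, path: PathLike, source: str = "apascan") -> None:
    """Write an AnnotationSet as exon rows (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for tx in ann:
            attrs = {
                "gene_id": tx.gene_id,
                "transcript_id": tx.transcript_id,
            }
            for k, v in tx.attributes.items():
                if k not in attrs and k not in _INTERNAL_ATTRS:
                    attrs[k] = v
            parts = []
            for k, v in attrs.items():
                if k == "tag":
                    parts.extend(f'tag "{t}"' for t in v.split(","))
                else:
                    parts.append(f'{k} "{v}"')
            attr_str = "; ".join(parts) + ";"
            for exon in tx.exons:
                fh.write(
                    "\t".join(
                        [
                            exon.chrom,
                            source,
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            exon.strand,
                            ".",
                            attr_str,
                        ]
                    )
                    + "\n"
                )


def _normalise_chrom(chrom: str, style: Optional[str]) -> str:
    if style is None:
        return chrom
    if style == "chr":
        return chrom if chrom.startswith("chr") else "chr" + chrom
    if style == "bare":
        return chrom[3:] if chrom.startswith("chr") else chrom
    raise ValueError(f"unknown chromosome-name style {style!r}")


def read_polyasite_atlas(
    path: PathLike, chrom_style: Optional[str] = None
) -> PolyASiteAtlas:
    """Read a PolyASite-style extended BED atlas.

    Expected columns (tab-separated): chrom, cluster start (0-based), cluster
    end, site id, score, strand, representative coordinate (0-based).  A site
    id of the PolyASite form ``chrom:rep:strand`` is used as fallback when
    the seventh column is absent.  Chromosome naming is normalised to
    ``chrom_style`` ("chr", "bare" or None for as-is).
    """
    records: list[PolyASiteRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValidationError(
                    f"{path}: atlas line {lineno}: expected >= 6 columns"
                )
            chrom = _normalise_chrom(fields[0], chrom_style)
            start, end = int(fields[1]), int(fields[2])
            site_id, strand = fields[3], fields[5]
            if len(fields) >= 7:
                rep = int(fields[6])
            else:
                parts = site_id.split(":")
                if len(parts) != 3:
                    raise ValidationError(
                        f"{path}: atlas line {lineno}: no representative "
                        "coordinate column and site id is not chrom:rep:strand"
                    )
                rep = int(parts[1])
            try:
                records.append(
                    PolyASiteRecord(
                        chrom=chrom,
                        cluster=GenomicInterval(chrom, start, end, strand),
                        representative_coord=rep,
                        strand=strand,
                        site_id=site_id,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return PolyASiteAtlas(records)


def write_polyasite_atlas(atlas: PolyASiteAtlas, path: PathLike) -> None:
    with open(path, "w") as fh:
        for rec in atlas.records:
            fh.write(
                "\t".join(
                    [
                        rec.chrom,
                        str(rec.cluster.start),
                        str(rec.cluster.end),
                        rec.site_id or f"{rec.chrom}:{rec.representative_coord}:{rec.strand}",
                        "0",
                        rec.strand,
                        str(rec.representative_coord),
                    ]
                )
                + "\n"
            )


def extract_sequence(genome: Fasta, iv: GenomicInterval) -> str:
    """Extract the sense-strand sequence of *iv*, uppercase.

    Minus-strand intervals are reverse-complemented so position 0 of the
    returned string is the biological 5' end.
    """
    if iv.chrom not in genome:
        raise KeyError(f"contig {iv.chrom!r} not in genome")
    contig = genome[iv.chrom]
    if iv.end > len(contig):
        raise ValueError(
            f"interval {iv.chrom}:{iv.start}-{iv.end} beyond contig end "
            f"({len(contig)})"
        )
    seq = str(contig[iv.start : iv.end]).upper()
    if iv.strand == "-":
        seq = reverse_complement(seq)
    return seq


QUANT_COLUMNS = ["Name", "Length", "EffectiveLength", "TPM", "NumReads"]


def read_quant_table(path: PathLike) -> pd.DataFrame:
    """Read a transcript quantification table (quant.sf dialect)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: quant table missing columns {missing}")
    if df.empty:
        raise ValidationError(f"{path}: quant table is empty")
    return df[QUANT_COLUMNS].copy()


def read_bed_peaks(path: PathLike) -> list[GenomicInterval]:
    """Read a BED file of binding peaks (strand optional)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}: BED line {lineno}: < 3 columns")
            strand = fields[5] if len(fields) >= 6 else "."
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike, names=None) -> None:
    names = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"iv{i}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )
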