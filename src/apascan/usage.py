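"""Last-exon isoform usage quantification.

Transcript-level TPMs are summed according to their assigned last-exon
isoform identifier (decoys excluded), converted to length-scaled count
estimates, and turned into fractional polyA-site usage by dividing each
isoform's TPM by the summed TPM of all isoforms of its gene.  Genes with
zero total expression in a sample have undefined usage there (NaN, never 0),
and undefined values propagate as missing into all downstream means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .reference import DECOY_SUFFIXES, LastExonReference

logger = logging.getLogger(__name__)


@dataclass
class IsoformUsageMatrix:
    """Isoform x sample matrices of TPM, scaled counts and usage."""

    tpm: pd.DataFrame
    counts: pd.DataFrame
    iso2gene: pd.Series
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)
    usage: Optional[pd.DataFrame] = None

    @property
    def sample_names(self) -> list[str]:
        return list(self.tpm.columns)

    def gene_isoforms(self, gene_id: str) -> list[str]:
        return list(self.iso2gene.index[self.iso2gene == gene_id])


def _is_decoy(name: str) -> bool:
    return any(suffix in name for suffix in DECOY_SUFFIXES.values())


def aggregate_quant(
    quants: dict[str, pd.DataFrame],
    reference: LastExonReference,
    total_reads: Optional[dict[str, float]] = None,
) -> IsoformUsageMatrix:
    """Aggregate per-sample transcript quantifications to isoforms.

    Isoform TPM is the sum of member-transcript TPMs; decoy rows are
    excluded from every isoform sum.  Scaled counts follow the
    length-scaled-TPM contract: ``counts = TPM x mean-across-samples of the
    isoform effective length``, with each sample's column then rescaled so
    it sums to that sample's total read count (taken from NumReads when not
    given).  Transcripts absent from the isoform mapping are counted,
    reported, and excluded.
    """
    if not quants:
        raise ValueError("no quantification tables supplied")
    sample_names = sorted(quants)
    iso_ids = [iso.isoform_id for iso in reference.isoforms]
    tpm = pd.DataFrame(0.0, index=iso_ids, columns=sample_names)
    efflen = pd.DataFrame(np.nan, index=iso_ids, columns=sample_names)
    totals: dict[str, float] = {}

    n_unmapped = 0
    unmapped_examples: set[str] = set()
    for sample in sample_names:
        q = quants[sample]
        if q.empty:
            raise ValueError(f"sample {sample}: empty quant table")
        iso_tpm: dict[str, float] = {}
        iso_efflen_num: dict[str, float] = {}
        iso_efflen_any: dict[str, list[float]] = {}
        totals[sample] = (
            float(total_reads[sample]) if total_reads else float(q["NumReads"].sum())
        )
        for name, eff, t in zip(q["Name"], q["EffectiveLength"], q["TPM"]):
            if _is_decoy(name):
                continue
            iso = reference.tx2iso.get(name)
            if iso is None:
                n_unmapped += 1
                if len(unmapped_examples) < 5:
                    unmapped_examples.add(name)
                continue
            iso_tpm[iso] = iso_tpm.get(iso, 0.0) + float(t)
            iso_efflen_num[iso] = iso_efflen_num.get(iso, 0.0) + float(t) * float(eff)
            iso_efflen_any.setdefault(iso, []).append(float(eff))
        for iso, value in iso_tpm.items():
            tpm.loc[iso, sample] = value
            if value > 0:
                efflen.loc[iso, sample] = iso_efflen_num[iso] / value
            else:
                efflen.loc[iso, sample] = float(np.mean(iso_efflen_any[iso]))
    if n_unmapped:
        logger.warning(
            "aggregate_quant: %d quant rows had no isoform mapping and were "
            "excluded (e.g. %s)",
            n_unmapped,
            sorted(unmapped_examples),
        )

    # length-scaled counts
    mean_efflen = efflen.mean(axis=1)
    counts = tpm.mul(mean_efflen.fillna(1.0), axis=0)
    col_sums = counts.sum(axis=0)
    for sample in sample_names:
        if col_sums[sample] > 0:
            counts[sample] *= totals[sample] / col_sums[sample]

    iso2gene = pd.Series(
        {iso.isoform_id: iso.gene_id for iso in reference.isoforms}, name="gene_id"
    ).loc[iso_ids]
    return IsoformUsageMatrix(tpm=tpm, counts=counts, iso2gene=iso2gene)


def polya_usage(m: IsoformUsageMatrix) -> IsoformUsageMatrix:
    """Fill fractional polyA-site usage: isoform TPM / gene-summed TPM.

    Genes with zero total TPM in a sample are flagged undefined (NaN) for
    that sample and excluded from downstream means.
    """
    gene_tot = m.tpm.groupby(m.iso2gene).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        usage = m.tpm / gene_tot
    usage = usage.where(gene_tot > 0)
    m.usage = usage
    return m


def paired_usage_difference(
    m: IsoformUsageMatrix,
    pairs: Sequence[tuple[str, str]],
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """Sample-wise usage differences over (negative, positive) sample pairs.

    delta = usage(negative) - usage(positive); a positive delta means higher
    relative usage in the depleted (negative) population.  Returns one row
    per isoform with per-pair deltas, the median delta, and the enrichment
    flag (median > ``facs_enrichment_min_median_delta``).
    """
    if m.usage is None:
        raise ValueError("usage not computed; call polya_usage first")
    available = set(m.usage.columns)
    missing = [s for pair in pairs for s in pair if s not in available]
    if missing:
        raise ValueError(f"unpaired/unknown samples: {sorted(set(missing))}")
    deltas = {}
    for neg, pos in pairs:
        deltas[f"{neg}-{pos}"] = m.usage[neg] - m.usage[pos]
    out = pd.DataFrame(deltas)
    out["median_delta"] = out.median(axis=1, skipna=True)
    out["enriched"] = out["median_delta"] > cfg.facs_enrichment_min_median_delta
    out.insert(0, "gene_id", m.iso2gene)
    return out
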