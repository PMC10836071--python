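"""Shared fixtures: configuration, toy annotations and random loci."""

from __future__ import annotations

import numpy as np
import pytest

from apascan import AnnotationSet, PipelineConfig, TranscriptModel
from apascan.intervals import GenomicInterval


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


def make_tx(tx_id, gene_id, chrom, strand, exons, **attrs):
    attrs.setdefault("gene_id", gene_id)
    return TranscriptModel(
        tx_id,
        gene_id,
        [GenomicInterval(chrom, s, e, strand) for s, e in exons],
        attrs,
    )


@pytest.fixture()
def simple_gene():
    """One + strand gene: exons [100,300) [1000,1200) [2000,2200) [3000,3400)."""
    tx = make_tx(
        "t1", "gA", "chr1", "+", [(100, 300), (1000, 1200), (2000, 2200), (3000, 3400)]
    )
    return AnnotationSet([tx])


def mirror_exons(exons, span=100_000):
    """Mirror (start, end) pairs to the opposite strand within a window."""
    return sorted((span - e, span - s) for s, e in exons)


# ---------------------------------------------------------------------------
# random toy loci for the classification oracle
# ---------------------------------------------------------------------------

def random_locus(rng: np.random.Generator):
    """A random reference gene plus one assembled transcript.

    Plants, uniformly, one of: a valid event of each class, a boundary case
    (extension exactly at / one below the minimum, first-exon slack at /
    one beyond the limit), or a deliberately invalid transcript.  Returns
    (ref exon lists, assembled exons, strand).
    """
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(3, 6))
    pos = int(rng.integers(100, 400))
    exons = []
    for _ in range(n_exons):
        elen = int(rng.integers(120, 320))
        exons.append((pos, pos + elen))
        pos += elen + int(rng.integers(700, 1300))
    gene = [tuple(e) for e in exons]

    kind = rng.choice(
        [
            "ale_valid",
            "ale_bad_donor",
            "ale_acceptor_on_boundary",
            "ipa_valid",
            "ipa_ext_99",
            "ipa_ext_100",
            "ipa_first_slack_ok",
            "ipa_first_slack_over",
            "utr_valid",
            "utr_ext_99",
            "utr_ext_100",
            "end_in_exon",
            "distal_ale",
            "junk",
        ]
    )
    # build in + orientation ("left" = 5') then mirror if needed
    first, last = gene[0], gene[-1]
    internal = gene[1:-1]
    introns = [(a[1], b[0]) for a, b in zip(gene, gene[1:])]

    def pick_intron(min_len=500):
        ok = [i for i in introns if i[1] - i[0] >= min_len]
        return ok[int(rng.integers(len(ok)))] if ok else introns[0]

    if kind == "ale_valid":
        intron = pick_intron()
        upstream = [e for e in gene if e[1] <= intron[0]]
        s = intron[0] + int(rng.integers(200, (intron[1] - intron[0]) - 250))
        assembled = upstream + [(s, s + 180)]
    elif kind == "ale_bad_donor":
        intron = pick_intron()
        upstream = [e for e in gene if e[1] <= intron[0]]
        if upstream:
            # shrink the terminal exon so the donor no longer matches
            a, b = upstream[-1]
            upstream = upstream[:-1] + [(a, b - int(rng.integers(5, 30)))]
        s = intron[0] + int(rng.integers(200, (intron[1] - intron[0]) - 250))
        assembled = upstream + [(s, s + 180)]
    elif kind == "ale_acceptor_on_boundary":
        i = int(rng.integers(len(introns)))
        intron = introns[i]
        upstream = [e for e in gene if e[1] <= intron[0]]
        down = gene[i + 1]
        assembled = upstream + [(intron[1], down[1] + int(rng.integers(120, 200)))]
    elif kind.startswith("ipa_first"):
        slack = 100 if kind.endswith("ok") else 101
        shift = int(rng.integers(1, slack + 1)) if kind.endswith("ok") else slack
        assembled = [(first[0] + shift, first[1] + int(rng.integers(150, 400)))]
    elif kind.startswith("ipa"):
        if not internal:
            internal = [gene[0]]
        exon = internal[int(rng.integers(len(internal)))]
        ext = {"ipa_valid": int(rng.integers(100, 400)), "ipa_ext_99": 99, "ipa_ext_100": 100}[kind]
        upstream = [e for e in gene if e[1] <= exon[0]]
        assembled = upstream + [(exon[0], exon[1] + ext)]
    elif kind.startswith("utr"):
        ext = {"utr_valid": int(rng.integers(100, 400)), "utr_ext_99": 99, "utr_ext_100": 100}[kind]
        assembled = gene[:-1] + [(last[0], last[1] + ext)]
    elif kind == "end_in_exon":
        exon = gene[int(rng.integers(1, len(gene)))]
        upstream = [e for e in gene if e[1] <= exon[0]]
        mid = (exon[0] + exon[1]) // 2
        assembled = upstream[:-1] + [(upstream[-1][0] if upstream else 10, mid)]
        assembled = [iv for iv in assembled if iv[0] < iv[1]]
    elif kind == "distal_ale":
        s = last[1] + int(rng.integers(200, 500))
        assembled = gene[:-1] + [(s, s + 180)]
    else:  # junk: random exon far inside an intron, no matching donor
        intron = pick_intron()
        s = intron[0] + int(rng.integers(150, (intron[1] - intron[0]) - 200))
        assembled = [(s, s + 150)]

    if strand == "-":
        span = pos + 1000
        gene = mirror_exons(gene, span)
        assembled = mirror_exons(assembled, span)
    return [gene], sorted(assembled), strand
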