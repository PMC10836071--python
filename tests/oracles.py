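"""Independent brute-force oracles.

Each function re-derives its quantity literally from the written criteria
with plain loops, sharing no code with the package implementation it
checks.
"""

from __future__ import annotations

from typing import Optional, Sequence


# ---------------------------------------------------------------------------
# last-exon classification (five novelty criteria, enumerated literally)
# ---------------------------------------------------------------------------

def classify_last_exon_oracle(
    tx_exons: Sequence[tuple[int, int]],
    strand: str,
    ref_tx_exons: Sequence[Sequence[tuple[int, int]]],
    min_extension: int = 100,
    first_exon_slack: int = 100,
) -> Optional[str]:
    """Literal enumeration of the novelty criteria for one assembled tx.

    Exons are (start, end) tuples, 0-based half-open, genomic order.
    Returns the category or None.
    """
    tx_exons = sorted(tx_exons)

    def five_prime(exon):
        return exon[0] if strand == "+" else exon[1] - 1

    def three_prime(exon):
        return exon[1] - 1 if strand == "+" else exon[0]

    last_exon = tx_exons[-1] if strand == "+" else tx_exons[0]
    introns = [
        (a[1], b[0]) for a, b in zip(tx_exons, tx_exons[1:])
    ]
    last_intron = (introns[-1] if strand == "+" else introns[0]) if introns else None

    # annotated structures
    all_exons = []
    all_introns = []
    donors = set()
    roles = []  # (exon, role)
    last_exon_3ends = []
    annotated_last_exons = []
    for exons in ref_tx_exons:
        exons = sorted(exons)
        for a, b in zip(exons, exons[1:]):
            intron = (a[1], b[0])
            all_introns.append(intron)
            donors.add(intron[0] if strand == "+" else intron[1])
        first = exons[0] if strand == "+" else exons[-1]
        last = exons[-1] if strand == "+" else exons[0]
        for e in exons:
            all_exons.append(e)
            if len(exons) == 1:
                roles.append((e, "last"))
            elif e == first:
                roles.append((e, "first"))
            elif e == last:
                roles.append((e, "last"))
            else:
                roles.append((e, "internal"))
        annotated_last_exons.append(last)
        last_exon_3ends.append(three_prime(last))

    # criterion: predicted 3'end must not overlap any annotated exon
    end_nt = three_prime(last_exon)
    for s, e in all_exons:
        if s <= end_nt < e:
            return None

    # ALE (spliced): last intron within an annotated intron, donor matches,
    # acceptor strictly inside
    ale = False
    if last_intron is not None:
        donor = last_intron[0] if strand == "+" else last_intron[1]
        if donor in donors:
            for intron in all_introns:
                contained = intron[0] <= last_intron[0] and last_intron[1] <= intron[1]
                strictly_inside = (
                    last_intron[1] < intron[1]
                    if strand == "+"
                    else last_intron[0] > intron[0]
                )
                if contained and strictly_inside:
                    ale = True

    # ALE (distal): donor matches, exon wholly beyond the gene 3'end
    ale_distal = False
    if last_intron is not None and not ale:
        donor = last_intron[0] if strand == "+" else last_intron[1]
        if donor in donors:
            if strand == "+":
                gene_end_exon = max(annotated_last_exons, key=lambda e: e[1] - 1)
                ale_distal = last_exon[0] >= gene_end_exon[1]
            else:
                gene_end_exon = min(annotated_last_exons, key=lambda e: e[0])
                ale_distal = last_exon[1] <= gene_end_exon[0]

    def overlaps(a, b):
        return a[0] < b[1] and b[0] < a[1]

    def extension_beyond(a, b):
        return a[1] - b[1] if strand == "+" else b[0] - a[0]

    # IPA: 5'end matches the 5'end of an overlapping internal (or, with
    # slack, first) exon, and extends it by >= min_extension
    ipa = False
    for exon, role in roles:
        if role == "last" or not overlaps(last_exon, exon):
            continue
        if role == "internal":
            match = five_prime(last_exon) == five_prime(exon)
        else:
            match = abs(five_prime(last_exon) - five_prime(exon)) <= first_exon_slack
        if match and extension_beyond(last_exon, exon) >= min_extension:
            ipa = True

    # 3'UTR extension of the most distal annotated last exon
    utr = False
    if strand == "+":
        distal = max(annotated_last_exons, key=lambda e: e[1] - 1)
    else:
        distal = min(annotated_last_exons, key=lambda e: e[0])
    if (
        overlaps(last_exon, distal)
        and five_prime(last_exon) == five_prime(distal)
        and extension_beyond(last_exon, distal) >= min_extension
    ):
        utr = True

    if ale and ipa:
        return "complex"
    hits = [
        name
        for name, hit in [
            ("ALE_spliced", ale),
            ("ALE_distal", ale_distal),
            ("IPA_extension", ipa),
            ("UTR_extension", utr),
        ]
        if hit
    ]
    if not hits:
        return None
    if len(hits) > 1:
        return "complex"
    return hits[0]


# ---------------------------------------------------------------------------
# hexamer scan
# ---------------------------------------------------------------------------

def hexamer_scan_oracle(seq: str, hexamers) -> list[tuple[int, str]]:
    """Naive substring search; offsets measured from motif start to seq end."""
    seq = seq.upper()
    out = []
    for motif in sorted(hexamers):
        start = 0
        while True:
            i = seq.find(motif, start)
            if i < 0:
                break
            out.append((len(seq) - i, motif))
            start = i + 1
    return sorted(out, reverse=True)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up
# ---------------------------------------------------------------------------

def bh_oracle(pvalues: Sequence[float]) -> list[float]:
    """Textbook step-up: p_(i) * m / i, cumulative minimum from the top."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, pvalues[i] * m / rank_from_top)
        running_min = min(running_min, value)
        adj[i] = running_min
    return adj


# ---------------------------------------------------------------------------
# GSEA running sum
# ---------------------------------------------------------------------------

def gsea_es_oracle(
    ranked: Sequence[str], scores: Sequence[float], members
) -> float:
    """Hand-enumerated weighted running sum (weight exponent 1)."""
    n = len(ranked)
    member_weight = sum(abs(s) for k, s in zip(ranked, scores) if k in members)
    n_members = sum(1 for k in ranked if k in members)
    if n_members == 0 or n_members == n:
        return 0.0
    best = 0.0
    running = 0.0
    for k, s in zip(ranked, scores):
        if k in members:
            if member_weight > 0:
                running += abs(s) / member_weight
            else:
                running += 1.0 / n_members
        else:
            running -= 1.0 / (n - n_members)
        best = max(best, running)
    return best


# ---------------------------------------------------------------------------
# coverage fraction
# ---------------------------------------------------------------------------

def coverage_fraction_oracle(
    points: Sequence[tuple[str, int, str]],
    peaks: Sequence[tuple[str, int, int, str]],
    rel_pos: int,
) -> float:
    """Fraction of landmarks with a peak overlapping the given position."""
    covered = 0
    for chrom, pos0, strand in points:
        g = pos0 + rel_pos if strand == "+" else pos0 - rel_pos
        hit = any(
            c == chrom
            and s <= g < e
            and (st == "." or strand == "." or st == strand)
            for c, s, e, st in peaks
        )
        covered += hit
    return covered / len(points)
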