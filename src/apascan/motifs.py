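"""Positional k-mer enrichment at cryptic vs background landmarks.

For each k-mer, per-landmark occurrence in a proximal window of interest
(+/- 250 nt by default) is normalised by occurrence in the surrounding
distal context (+/- 500 nt) and contrasted between cryptic and background
landmark groups as a z-statistic; all proximal positions contribute and no
landmark thresholding is applied.  Ranked k-mers feed a one-sided gene-set
enrichment analysis of predefined hexamer groups (the UG-rich 6-mer sets
preferred by TDP-43) with permutation p-values, and set-level positional
coverage maps are produced in the same shape as the peak metaprofiles.

Sequences are handled in the RNA alphabet (T -> U) so hexamer-set members
match verbatim; windows are extracted in transcript orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .config import PipelineConfig
from .cryptic import benjamini_hochberg
from .intervals import GenomicInterval, reverse_complement
from .profiles import Landmark, LandmarkProfile, loess_smooth

MIN_LANDMARKS = 10
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class HexamerGroups:
    """The three preferred TDP-43 binding 6-mer groups (RNA alphabet)."""

    YG: frozenset[str] = frozenset(
        {"UGUGUG", "GUGUGU", "UGUGCG", "UGCGUG", "CGUGUG", "GUGUGC"}
    )
    YA: frozenset[str] = frozenset(
        {"AUGUGU", "GUAUGU", "GUGUAU", "UGUGUA", "UGUAUG", "UGCAUG"}
    )
    AA: frozenset[str] = frozenset(
        {"GUGUGA", "AAUGAA", "GAAUGA", "UGAAUG", "AUGAAU", "GUGAAU", "GAAUGU", "UUGAAU"}
    )

    def __post_init__(self) -> None:
        if len(self.YG) + len(self.YA) + len(self.AA) != len(self.union):
            raise ValueError("hexamer groups must be pairwise disjoint")

    @property
    def union(self) -> frozenset[str]:
        return self.YG | self.YA | self.AA

    def named_sets(self) -> dict[str, frozenset[str]]:
        return {"YG": self.YG, "YA": self.YA, "AA": self.AA, "union": self.union}


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def landmark_window_sequence(
    genome: Fasta, landmark: Landmark, flank: int
) -> str:
    """Sense-orientation sequence of the window +/- flank around a landmark.

    Off-contig positions are padded with 'N' so the returned string always
    has length 2*flank + 1 and index ``flank`` is the landmark nucleotide.
    """
    pos0 = landmark.point.start
    chrom = landmark.point.chrom
    contig = genome[chrom]
    lo, hi = pos0 - flank, pos0 + flank + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(contig))
    seq = str(contig[max(lo, 0) : min(hi, len(contig))]).upper()
    seq = "N" * left_pad + seq + "N" * right_pad
    if landmark.point.strand == "-":
        seq = reverse_complement(seq)
    return to_rna(seq)


def count_kmers(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def kmer_enrichment_from_sequences(
    cryptic_seqs: Sequence[str],
    background_seqs: Sequence[str],
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """Positional k-mer enrichment table from pre-extracted window sequences.

    Each sequence must be a full distal window (length 2*peka_distal + 1,
    landmark at the centre).  For each k-mer the per-landmark relative
    occurrence is (proximal count + 0.5) / (distal count + 0.5); the score
    is the z-statistic contrasting group means.  Returns a table with one
    row per k-mer present in either group, ranked (ties lexicographic).
    """
    if len(cryptic_seqs) < MIN_LANDMARKS or len(background_seqs) < MIN_LANDMARKS:
        raise ValueError(
            f"need >= {MIN_LANDMARKS} landmarks per group, got "
            f"{len(cryptic_seqs)} cryptic / {len(background_seqs)} background"
        )
    k = cfg.kmer_k
    distal, prox = cfg.peka_distal, cfg.peka_proximal

    def group_ratios(seqs: Sequence[str]) -> dict[str, np.ndarray]:
        # per-landmark relative occurrence: proximal-window count normalised
        # by the occurrence in the surrounding context (the distal window
        # excluding the window of interest), pseudocount 0.5 on both
        per_kmer: dict[str, np.ndarray] = {}
        for si, seq in enumerate(seqs):
            centre = len(seq) // 2
            lo = max(0, centre - prox)
            hi = min(len(seq), centre + prox + 1)
            prox_counts = count_kmers(seq[lo:hi], k)
            dist_counts = count_kmers(seq, k)
            for kmer, dcount in dist_counts.items():
                if kmer not in per_kmer:
                    per_kmer[kmer] = np.zeros(len(seqs))
                context = max(dcount - prox_counts.get(kmer, 0), 0)
                per_kmer[kmer][si] = (prox_counts.get(kmer, 0) + PSEUDOCOUNT) / (
                    context + PSEUDOCOUNT
                )
        return per_kmer

    ratios_c = group_ratios(cryptic_seqs)
    ratios_b = group_ratios(background_seqs)
    all_kmers = sorted(set(ratios_c) | set(ratios_b))
    absent_ratio = PSEUDOCOUNT / PSEUDOCOUNT  # (0+0.5)/(0+0.5) = 1.0

    rows = []
    nc, nb = len(cryptic_seqs), len(background_seqs)
    for kmer in all_kmers:
        rc = ratios_c.get(kmer)
        rb = ratios_b.get(kmer)
        vc = np.full(nc, absent_ratio) if rc is None else np.where(rc == 0, absent_ratio, rc)
        vb = np.full(nb, absent_ratio) if rb is None else np.where(rb == 0, absent_ratio, rb)
        mc, mb = vc.mean(), vb.mean()
        var = vc.var(ddof=1) / nc + vb.var(ddof=1) / nb
        se = max(np.sqrt(var), 1e-9)  # floor so exact contrasts stay finite
        score = (mc - mb) / se
        rows.append({"kmer": kmer, "score": float(score)})
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["score", "kmer"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def positional_kmer_enrichment(
    cryptic_landmarks: Sequence[Landmark],
    background_landmarks: Sequence[Landmark],
    genome: Fasta,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """K-mer enrichment at cryptic vs background landmarks of one kind."""
    cseqs = [
        landmark_window_sequence(genome, lm, cfg.peka_distal)
        for lm in cryptic_landmarks
    ]
    bseqs = [
        landmark_window_sequence(genome, lm, cfg.peka_distal)
        for lm in background_landmarks
    ]
    return kmer_enrichment_from_sequences(cseqs, bseqs, cfg)


# ---------------------------------------------------------------------------
# one-sided GSEA of hexamer groups
# ---------------------------------------------------------------------------

@dataclass
class GseaResult:
    set_name: str
    landmark_kind: str
    es: float
    nes: float
    p_value: float
    n_perm: int
    absent: bool = False
    padj: Optional[float] = None


def enrichment_score(
    ranked_kmers: Sequence[str],
    scores: Sequence[float],
    members: frozenset[str],
    weight: float = 1.0,
) -> float:
    """One-sided weighted Kolmogorov-Smirnov running-sum statistic.

    Hits advance the running sum by |score|^weight (normalised over member
    hits), misses retreat by 1/(N - n_members); the statistic is the maximum
    of the running sum (positive enrichment only), bounded by 1.
    """
    scores = np.asarray(scores, dtype=float)
    is_member = np.array([kmer in members for kmer in ranked_kmers])
    n = len(ranked_kmers)
    n_hit = int(is_member.sum())
    if n_hit == 0 or n_hit == n:
        return 0.0
    w = np.abs(scores) ** weight
    hit_total = w[is_member].sum()
    if hit_total == 0:
        w = np.ones(n)
        hit_total = float(n_hit)
    steps = np.where(is_member, w / hit_total, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    return float(max(running.max(), 0.0))


def gsea_kmers(
    table: pd.DataFrame,
    groups: HexamerGroups,
    landmark_kind: str = "",
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[GseaResult]:
    """One-sided GSEA of the hexamer groups over a complete k-mer ranking.

    Permutation p-values draw random same-size member sets from the ranking;
    the reported floor is 1/(n_perm + 1).  NES is ES divided by the mean
    |ES| of the permuted sets.  Benjamini-Hochberg adjustment across all
    landmark x set tests is applied separately via :func:`adjust_gsea`.
    """
    rng = np.random.default_rng(seed)
    ranked = list(table["kmer"])
    scores = table["score"].to_numpy()
    results = []
    for set_name, members in groups.named_sets().items():
        present = frozenset(m for m in members if m in set(ranked))
        if not present:
            results.append(
                GseaResult(set_name, landmark_kind, np.nan, np.nan, np.nan, n_perm, absent=True)
            )
            continue
        es = enrichment_score(ranked, scores, present)
        size = len(present)
        perm_es = np.empty(n_perm)
        idx = np.arange(len(ranked))
        for i in range(n_perm):
            chosen = rng.choice(idx, size=size, replace=False)
            perm_set = frozenset(ranked[j] for j in chosen)
            perm_es[i] = enrichment_score(ranked, scores, perm_set)
        p = (1 + np.sum(perm_es >= es)) / (n_perm + 1)
        mean_abs = np.mean(np.abs(perm_es))
        nes = es / mean_abs if mean_abs > 0 else np.nan
        results.append(GseaResult(set_name, landmark_kind, es, float(nes), float(p), n_perm))
    return results


def adjust_gsea(results: Sequence[GseaResult]) -> list[GseaResult]:
    """BH adjustment jointly across all landmark x set tests."""
    testable = [r for r in results if not r.absent]
    if testable:
        padj = benjamini_hochberg(np.array([r.p_value for r in testable]))
        for r, a in zip(testable, padj):
            r.padj = float(a)
    return list(results)


# ---------------------------------------------------------------------------
# k-mer coverage maps
# ---------------------------------------------------------------------------

def kmer_coverage_map(
    kmer_set: frozenset[str],
    landmarks: Sequence[Landmark],
    genome: Fasta,
    cfg: PipelineConfig,
    smooth: bool = True,
) -> LandmarkProfile:
    """Positional coverage of a k-mer set around landmarks.

    Per relative position, the fraction of events whose window places any
    set k-mer covering that position; smoothed as for the peak metaprofiles.
    """
    if not kmer_set:
        raise ValueError("empty k-mer set")
    flank = cfg.map_flank
    k = len(next(iter(kmer_set)))
    vecs = []
    for lm in landmarks:
        seq = landmark_window_sequence(genome, lm, flank)
        vec = np.zeros(2 * flank + 1)
        for i in range(len(seq) - k + 1):
            if seq[i : i + k] in kmer_set:
                vec[i : i + k] = 1.0
        vec[np.array([c == "N" for c in seq])] = np.nan
        vecs.append(vec)
    mat = np.vstack(vecs)
    n_at = np.sum(~np.isnan(mat), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
    se = np.where(n_at > 1, sd / np.sqrt(np.maximum(n_at, 1)), 0.0)
    prof = LandmarkProfile(
        positions=np.arange(-flank, flank + 1), mean=mean, se=se, n=mat.shape[0]
    )
    if smooth:
        prof.smoothed_mean = loess_smooth(prof.positions, mean, cfg.loess_span)
        prof.smoothed_lo = loess_smooth(prof.positions, mean - se, cfg.loess_span)
        prof.smoothed_hi = loess_smooth(prof.positions, mean + se, cfg.loess_span)
    return prof
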