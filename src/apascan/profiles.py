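"""Landmark metaprofiles of binding-peak coverage.

Events predicted independently in several datasets may carry distinct
intervals for the same last-exon isoform; a deterministic collapsing ladder
reduces them to a single representative interval.  Single-nucleotide
landmarks (ALE exon start / polyA site, 3'UTR-extension proximal / distal
polyA site) are then extended by ``map_flank`` nt in both directions and
per-position peak coverage is computed in transcript orientation: position 0
is the landmark, negative positions are upstream.  The per-position mean
equals the fraction of events overlapped by a peak there; confidence bands
are +/- 1 standard error, and both are LOESS-smoothed (degree-2 local
regression, tricube weights, span as a fraction of points).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import PipelineConfig
from .discovery import LastExonEvent
from .intervals import GenomicInterval, merge_intervals
from .models import AnnotationSet

logger = logging.getLogger(__name__)

LANDMARK_KINDS = ("ALE_exon_start", "ALE_pas", "Ext_proximal_pas", "Ext_distal_pas")


@dataclass(frozen=True)
class Landmark:
    event_id: str
    kind: str
    point: GenomicInterval  # length-1 interval
    group: str  # "cryptic" | "background"

    def __post_init__(self) -> None:
        if self.kind not in LANDMARK_KINDS:
            raise ValueError(f"unknown landmark kind {self.kind!r}")
        if len(self.point) != 1:
            raise ValueError("landmark point must have length 1")


@dataclass
class LandmarkProfile:
    positions: np.ndarray  # -flank .. +flank
    mean: np.ndarray
    se: np.ndarray
    n: int
    smoothed_mean: Optional[np.ndarray] = None
    smoothed_lo: Optional[np.ndarray] = None
    smoothed_hi: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# collapsing ladder
# ---------------------------------------------------------------------------

@dataclass
class EventPrediction:
    """One dataset's predicted interval for a last-exon isoform."""

    interval: GenomicInterval
    category: str = "ALE_spliced"
    atlas_site_id: Optional[str] = None
    atlas_rep_coord: Optional[int] = None
    n_datasets: int = 1
    motif_offset: Optional[int] = None

    @property
    def three_end(self) -> int:
        return self.interval.three_prime

    @property
    def five_end(self) -> int:
        return self.interval.five_prime


def _proximal_end_key(p: EventPrediction) -> int:
    return p.three_end if p.interval.strand == "+" else -p.three_end


def collapse_representative(
    predictions: Sequence[EventPrediction], cfg: PipelineConfig
) -> tuple[GenomicInterval, list[str]]:
    """Collapse multi-dataset predictions to one representative interval.

    The ladder, applied in order (each firing rule is logged and reported):

    1. ``atlas_filter`` — predictions matching a polyA-atlas site win over
       motif-only ones;
    2. ``most_datasets`` — among distinct atlas sites, the site predicted in
       the most independent datasets;
    3. ``site_tie_more_proximal`` — equally supported sites: the more
       proximal one;
    4. ``closest_to_representative`` — distinct cluster-overlapping 3'ends:
       the one closest to the atlas representative coordinate;
    5. ``end_tie_most_distal`` — equidistant ends: the most distal;
    6. ``motif_min_deviance`` — motif-only: minimise |offset - 21 nt|;
    7. ``motif_tie_most_proximal`` — equally deviant: the most proximal;
    8. ``ipa_most_distal_3end`` — IPA intervals still distinct: most distal
       3'end (for IPA events the arbitrary end tie-breaks 5 and 7 defer to
       this category rule);
    9. ``ale_shortest_exon`` — ALE 5'ends still distinct: shortest exon
       (or most proximal 5'end when ``ale_collapse_shortest_exon`` is off).
    """
    if not predictions:
        raise ValueError("collapse_representative: no predictions")
    preds = list(predictions)
    fired: list[str] = []

    def fire(rule: str, survivors: list[EventPrediction]) -> list[EventPrediction]:
        if len(survivors) < len(preds):
            fired.append(rule)
            logger.debug("collapse: rule %s -> %d candidates", rule, len(survivors))
        return survivors

    atlas = [p for p in preds if p.atlas_site_id is not None]
    if atlas:
        preds = fire("atlas_filter", atlas)
        sites: dict[str, list[EventPrediction]] = {}
        for p in preds:
            sites.setdefault(p.atlas_site_id, []).append(p)
        if len(sites) > 1:
            support = {
                sid: sum(p.n_datasets for p in ps) for sid, ps in sites.items()
            }
            best = max(support.values())
            top = [sid for sid, s in support.items() if s == best]
            survivors = [p for p in preds if p.atlas_site_id in top]
            preds = fire("most_datasets", survivors)
            if len(top) > 1:
                strand = preds[0].interval.strand
                rep_of = {
                    sid: sites[sid][0].atlas_rep_coord
                    if sites[sid][0].atlas_rep_coord is not None
                    else sites[sid][0].three_end
                    for sid in top
                }
                proximal_site = min(
                    top, key=lambda s: rep_of[s] if strand == "+" else -rep_of[s]
                )
                preds = fire(
                    "site_tie_more_proximal",
                    [p for p in preds if p.atlas_site_id == proximal_site],
                )
        if len({p.three_end for p in preds}) > 1:
            rep = preds[0].atlas_rep_coord
            if rep is not None:
                dmin = min(abs(p.three_end - rep) for p in preds)
                preds = fire(
                    "closest_to_representative",
                    [p for p in preds if abs(p.three_end - rep) == dmin],
                )
            if (
                len({p.three_end for p in preds}) > 1
                and preds[0].category != "IPA_extension"
            ):
                distal = max(preds, key=_proximal_end_key).three_end
                preds = fire(
                    "end_tie_most_distal",
                    [p for p in preds if p.three_end == distal],
                )
    else:
        if len({p.three_end for p in preds}) > 1:
            dev = {
                id(p): abs((p.motif_offset or 10**9) - cfg.expected_pas_offset)
                for p in preds
            }
            dmin = min(dev.values())
            preds = fire(
                "motif_min_deviance", [p for p in preds if dev[id(p)] == dmin]
            )
            if (
                len({p.three_end for p in preds}) > 1
                and preds[0].category != "IPA_extension"
            ):
                proximal = min(preds, key=_proximal_end_key).three_end
                preds = fire(
                    "motif_tie_most_proximal",
                    [p for p in preds if p.three_end == proximal],
                )

    # category-specific final arbitration
    category = preds[0].category
    if category == "IPA_extension" and len({p.three_end for p in preds}) > 1:
        distal = max(preds, key=_proximal_end_key).three_end
        preds = fire(
            "ipa_most_distal_3end", [p for p in preds if p.three_end == distal]
        )
    if category.startswith("ALE") and len({p.five_end for p in preds}) > 1:
        if cfg.ale_collapse_shortest_exon:
            shortest = min(len(p.interval) for p in preds)
            preds = fire(
                "ale_shortest_exon",
                [p for p in preds if len(p.interval) == shortest],
            )
        else:
            strand = preds[0].interval.strand
            proximal = min(
                (p.five_end if strand == "+" else -p.five_end) for p in preds
            )
            preds = fire(
                "ale_shortest_exon",
                [
                    p
                    for p in preds
                    if (p.five_end if strand == "+" else -p.five_end) == proximal
                ],
            )

    preds.sort(key=lambda p: (p.interval.start, p.interval.end))
    return preds[0].interval, fired


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def _point(chrom: str, pos: int, strand: str) -> GenomicInterval:
    return GenomicInterval(chrom, pos, pos + 1, strand)


def extract_landmarks(
    events: Sequence[LastExonEvent],
    ref: AnnotationSet,
    groups: dict[str, str],
) -> list[Landmark]:
    """Derive single-nucleotide landmarks from collapsed events.

    ALE events yield an exon-start and a PAS landmark; 3'UTR extensions
    yield a proximal landmark (the most distal *annotated* polyA site of
    the gene) and a distal landmark (the extension 3'end).  *groups* maps
    event_id -> "cryptic" | "background"; unlisted events are skipped.
    """
    out: list[Landmark] = []
    for ev in events:
        group = groups.get(ev.event_id)
        if group is None:
            continue
        le = ev.last_exon
        if ev.category in ("ALE_spliced", "ALE_distal", "annotated"):
            out.append(
                Landmark(ev.event_id, "ALE_exon_start", _point(le.chrom, le.five_prime, le.strand), group)
            )
            out.append(
                Landmark(ev.event_id, "ALE_pas", _point(le.chrom, le.three_prime, le.strand), group)
            )
        elif ev.category == "UTR_extension":
            annotated_distal = ref.most_distal_last_exon(ev.gene_id)
            if annotated_distal is None:
                raise ValueError(
                    f"3'Ext event {ev.event_id}: gene {ev.gene_id} has no "
                    "annotated polyA site"
                )
            out.append(
                Landmark(
                    ev.event_id,
                    "Ext_proximal_pas",
                    _point(le.chrom, annotated_distal.three_prime, le.strand),
                    group,
                )
            )
            out.append(
                Landmark(ev.event_id, "Ext_distal_pas", _point(le.chrom, le.three_prime, le.strand), group)
            )
    return out


# ---------------------------------------------------------------------------
# coverage profiles
# ---------------------------------------------------------------------------

def landmark_coverage_vector(
    landmark: Landmark,
    peaks: Sequence[GenomicInterval],
    flank: int,
    contig_length: Optional[int] = None,
) -> np.ndarray:
    """0/1 coverage over relative positions -flank..+flank, NaN off-contig."""
    pos0 = landmark.point.start
    strand = landmark.point.strand
    vec = np.zeros(2 * flank + 1)
    lo, hi = pos0 - flank, pos0 + flank  # genomic bounds of the window
    for pk in peaks:
        if pk.chrom != landmark.point.chrom:
            continue
        if pk.strand in "+-" and strand in "+-" and pk.strand != strand:
            continue
        g0, g1 = max(pk.start, lo), min(pk.end - 1, hi)
        if g0 > g1:
            continue
        if strand == "+":
            vec[g0 - pos0 + flank : g1 - pos0 + flank + 1] = 1.0
        else:
            vec[pos0 - g1 + flank : pos0 - g0 + flank + 1] = 1.0
    # off-contig positions are missing, not zero
    genomic = pos0 + np.arange(-flank, flank + 1) * (1 if strand == "+" else -1)
    invalid = genomic < 0
    if contig_length is not None:
        invalid |= genomic >= contig_length
    vec[invalid] = np.nan
    return vec


def loess_smooth(
    x: np.ndarray, y: np.ndarray, span: float, degree: int = 2
) -> np.ndarray:
    """Local polynomial regression with tricube weights.

    ``span`` is the fraction of points in each local window.  Positions with
    missing *y* are excluded from fitting and returned as NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(y)
    xs, ys = x[ok], y[ok]
    n = len(xs)
    out = np.full_like(y, np.nan)
    if n == 0:
        return out
    k = max(degree + 2, int(math.ceil(span * n)))
    k = min(k, n)
    for i in np.nonzero(ok)[0]:
        xi = x[i]
        d = np.abs(xs - xi)
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = ys[idx].mean()
            continue
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 1e-12, None)
        coeffs = np.polyfit(xs[idx] - xi, ys[idx], deg=min(degree, len(idx) - 1), w=np.sqrt(w))
        out[i] = coeffs[-1]  # polynomial evaluated at 0
    return out


def coverage_profile(
    landmarks: Sequence[Landmark],
    peaks: Sequence[GenomicInterval],
    cfg: PipelineConfig,
    contig_lengths: Optional[dict[str, int]] = None,
    smooth: bool = True,
) -> dict[tuple[str, str], LandmarkProfile]:
    """Mean/SE peak-coverage metaprofile per (landmark kind, group).

    Peaks are merged into non-redundant intervals first.  The mean at each
    relative position is the fraction of events with an overlapping peak
    there; SE is the sample standard deviation / sqrt(n).
    """
    merged = merge_intervals(peaks)
    flank = cfg.map_flank
    grouped: dict[tuple[str, str], list[np.ndarray]] = {}
    for lm in landmarks:
        clen = (contig_lengths or {}).get(lm.point.chrom)
        vec = landmark_coverage_vector(lm, merged, flank, clen)
        grouped.setdefault((lm.kind, lm.group), []).append(vec)

    out: dict[tuple[str, str], LandmarkProfile] = {}
    positions = np.arange(-flank, flank + 1)
    for key, vecs in grouped.items():
        mat = np.vstack(vecs)
        n_at = np.sum(~np.isnan(mat), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(mat, axis=0)
            sd = np.nanstd(mat, axis=0, ddof=1)
        se = np.where(n_at > 1, sd / np.sqrt(np.maximum(n_at, 1)), 0.0)
        prof = LandmarkProfile(positions=positions, mean=mean, se=se, n=mat.shape[0])
        if smooth:
            prof.smoothed_mean = loess_smooth(positions, mean, cfg.loess_span)
            prof.smoothed_lo = loess_smooth(positions, mean - se, cfg.loess_span)
            prof.smoothed_hi = loess_smooth(positions, mean + se, cfg.loess_span)
        out[key] = prof
    return out
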