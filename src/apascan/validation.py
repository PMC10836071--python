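"""3'end validation: polyA-atlas matching and polyA-signal hexamer rescue.

A candidate last exon survives if its predicted 3'end lies strictly within
``atlas_max_dist`` (default 100 nt, either direction) of a polyA-site atlas
record — in which case the 3'end is updated to the atlas representative
coordinate — or, failing that, if one of the 18 polyA-signal hexamers occurs
within the 3'-terminal ``motif_search_window`` nt (default 100) of the exon's
sense sequence.  Signals concentrate ~21 nt upstream of cleavage sites, so
when several candidates survive at one locus the one whose best motif offset
is closest to 21 nt is selected per condition.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

from pyfaidx import Fasta

from .config import PipelineConfig
from .discovery import LastExonEvent
from .intervals import GenomicInterval
from .io import extract_sequence
from .models import PolyASiteAtlas, PolyASiteRecord


@dataclass
class ThreeEndValidation:
    """Evidence that a predicted 3'end is a credible cleavage site."""

    mode: str  # "atlas" | "motif"
    updated_end: int
    matched_atlas_record: Optional[PolyASiteRecord] = None
    distance_to_atlas: Optional[int] = None
    motif: Optional[str] = None
    motif_offset: Optional[int] = None  # nt from motif start to the 3'end
    all_motif_offsets: tuple = ()

    def __post_init__(self) -> None:
        if self.mode not in ("atlas", "motif"):
            raise ValueError(f"unknown validation mode {self.mode!r}")


def match_atlas(
    event: LastExonEvent, atlas: PolyASiteAtlas, cfg: PipelineConfig
) -> Optional[ThreeEndValidation]:
    """Match a predicted 3'end to the nearest same-strand atlas site.

    Distance is measured to the representative coordinate in either
    direction; a match requires distance strictly below ``atlas_max_dist``.
    On match the event 3'end is updated to the atlas coordinate.
    """
    rec = atlas.nearest(event.chrom, event.strand, event.three_end)
    if rec is None:
        return None
    dist = abs(rec.representative_coord - event.three_end)
    if dist >= cfg.atlas_max_dist:
        return None
    return ThreeEndValidation(
        mode="atlas",
        updated_end=rec.representative_coord,
        matched_atlas_record=rec,
        distance_to_atlas=dist,
    )


def scan_pas_hexamers(seq: str, hexamers: frozenset[str]) -> list[tuple[int, str]]:
    """All (offset, hexamer) exact matches in *seq*.

    *seq* is the sense-strand 3'-terminal window; the offset is the distance
    from the motif start to the 3'end of the window (i.e. ``len(seq) - i``
    for a match starting at index ``i``), matching the convention that the
    canonical signal sits ~21 nt upstream of the cleavage site.
    """
    seq = seq.upper()
    n = len(seq)
    hits = []
    for i in range(n - 5):
        if seq[i : i + 6] in hexamers:
            hits.append((n - i, seq[i : i + 6]))
    return hits


def hexamer_rescue(
    event: LastExonEvent, genome: Fasta, cfg: PipelineConfig
) -> Optional[ThreeEndValidation]:
    """Rescue an atlas-unmatched 3'end by polyA-signal hexamer presence.

    Scans the final ``motif_search_window`` nt of the last exon (the whole
    exon when shorter) for exact matches to the configured hexamers.  The
    best motif minimises |offset - expected_pas_offset|; absent any match
    the event is dropped (None returned).
    """
    le = event.last_exon
    if len(le) < 6:
        return None
    window = min(cfg.motif_search_window, len(le))
    if le.strand == "+":
        iv = GenomicInterval(le.chrom, le.end - window, le.end, "+")
    else:
        iv = GenomicInterval(le.chrom, le.start, le.start + window, "-")
    seq = extract_sequence(genome, iv)
    hits = scan_pas_hexamers(seq, cfg.pas_hexamers)
    if not hits:
        return None
    best_offset, best_motif = min(
        hits, key=lambda h: (abs(h[0] - cfg.expected_pas_offset), h[0])
    )
    return ThreeEndValidation(
        mode="motif",
        updated_end=event.three_end,
        motif=best_motif,
        motif_offset=best_offset,
        all_motif_offsets=tuple(h[0] for h in hits),
    )


def apply_validation(event: LastExonEvent, val: ThreeEndValidation) -> LastExonEvent:
    """Return a copy of *event* carrying *val*, with its 3'end updated."""
    new_exon = event.last_exon.with_three_prime(val.updated_end)
    return dataclasses.replace(event, last_exon=new_exon, validation=val)


def validate_events(
    events: Sequence[LastExonEvent],
    atlas: PolyASiteAtlas,
    genome: Fasta,
    cfg: PipelineConfig,
) -> list[LastExonEvent]:
    """Atlas-match first, hexamer-rescue second; drop events failing both."""
    out = []
    for ev in events:
        val = match_atlas(ev, atlas, cfg)
        if val is None:
            val = hexamer_rescue(ev, genome, cfg)
        if val is not None:
            out.append(apply_validation(ev, val))
    return out


def _proximal_key(event: LastExonEvent) -> int:
    """Sort key placing more proximal 3'ends (closer to gene 5') first."""
    return event.three_end if event.strand == "+" else -event.three_end


def select_condition_representative(
    events: Sequence[LastExonEvent], cfg: PipelineConfig
) -> LastExonEvent:
    """Pick one representative among overlapping motif-rescued candidates.

    The candidate whose polyA-signal motif offset is closest to the expected
    21 nt upstream distance wins; ties break to the more proximal 3'end.
    Atlas-matched events are assumed already resolved (distinct atlas sites
    are distinct loci).
    """
    if not events:
        raise ValueError("select_condition_representative: empty input")
    if len(events) == 1:
        return events[0]

    def key(ev: LastExonEvent):
        val = ev.validation
        if val is None or val.motif_offset is None:
            deviance = float("inf")
        else:
            deviance = abs(val.motif_offset - cfg.expected_pas_offset)
        return (deviance, _proximal_key(ev))

    return min(events, key=key)
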