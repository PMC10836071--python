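"""Cohort splice-junction specificity screen.

Cryptic junctions are quantified across a cohort of per-sample splice
junction count tables (the 9-column spliced-aligner dialect, 1-based closed
intron coordinates) and screened with the detection/selectivity criteria: a
junction is *expressed* in a sample when at least ``min_junction_reads``
(default 2) uniquely-mapped spliced reads support it, and *selective* when
expressed in at most 0.5% of samples where TDP-43 pathology is not expected
and at least 1% of samples where it is (both boundaries inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .config import DEFAULT_PATHOLOGY_MAP, PipelineConfig
from .intervals import GenomicInterval

PathLike = Union[str, Path]

_STRAND_CODE = {0: ".", 1: "+", 2: "-"}


@dataclass
class JunctionCountMatrix:
    """Junction x sample matrix of uniquely-mapped spliced-read counts.

    Junctions are stored internally 0-based half-open; sample metadata must
    carry a boolean ``pathology_expected`` column.
    """

    counts: pd.DataFrame  # index: junction key "chrom:start-end:strand"
    junctions: dict[str, GenomicInterval]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if "pathology_expected" not in self.metadata.columns:
            raise ValueError("metadata must carry a pathology_expected column")
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("junction counts must be non-negative")


def junction_key(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}:{iv.strand}"


def assign_pathology_expected(
    metadata: pd.DataFrame,
    pathology_map: Union[frozenset, set, None] = None,
    subtype_col: str = "disease_subtype",
    tissue_col: str = "tissue",
) -> pd.DataFrame:
    """Fill the pathology_expected flag from a (subtype, tissue) mapping.

    The default template lists the ALS-TDP motor/spinal/cortical and
    FTLD-TDP cortical combinations; supply any set of (subtype, tissue)
    pairs to override.
    """
    mapping = pathology_map if pathology_map is not None else DEFAULT_PATHOLOGY_MAP
    out = metadata.copy()
    out["pathology_expected"] = [
        (s, t) in mapping for s, t in zip(out[subtype_col], out[tissue_col])
    ]
    return out


def read_junction_tables(
    paths: dict[str, PathLike],
    targets: Sequence[GenomicInterval],
    metadata: pd.DataFrame,
    cfg: PipelineConfig,
) -> JunctionCountMatrix:
    """Extract unique-read counts for target junctions from SJ tables.

    Each table has 9 tab-separated columns: chrom, intron start (1-based),
    intron end (1-based, inclusive), strand code (0 undetermined / 1 + /
    2 -), motif, annotated flag, unique reads, multimapped reads, max
    overhang.  Absent target junctions count 0; duplicate rows for one
    junction within a sample are an error.  Strand-code-0 rows match
    targets on either strand when ``strand_agnostic_undetermined`` is set.
    """
    target_map = {junction_key(t): t for t in targets}
    sample_names = sorted(paths)
    counts = pd.DataFrame(0, index=list(target_map), columns=sample_names, dtype=int)

    for sample in sample_names:
        path = paths[sample]
        seen: set[tuple] = set()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 9:
                    raise ValueError(
                        f"{path}: line {lineno}: expected 9 columns, got "
                        f"{len(fields)}"
                    )
                try:
                    chrom = fields[0]
                    start1, end1 = int(fields[1]), int(fields[2])
                    strand = _STRAND_CODE[int(fields[3])]
                    unique = int(fields[6])
                except (ValueError, KeyError) as exc:
                    raise ValueError(
                        f"{path}: line {lineno}: malformed row ({exc})"
                    ) from exc
                key0 = (chrom, start1, end1, strand)
                if key0 in seen:
                    raise ValueError(
                        f"{path}: line {lineno}: duplicate junction row "
                        f"{chrom}:{start1}-{end1}"
                    )
                seen.add(key0)
                # 1-based closed -> 0-based half-open
                start, end = start1 - 1, end1
                if strand == "." and cfg.strand_agnostic_undetermined:
                    candidates = [
                        f"{chrom}:{start}-{end}:+",
                        f"{chrom}:{start}-{end}:-",
                    ]
                else:
                    candidates = [f"{chrom}:{start}-{end}:{strand}"]
                for cand in candidates:
                    if cand in target_map:
                        counts.loc[cand, sample] += unique
    return JunctionCountMatrix(counts=counts, junctions=target_map, metadata=metadata)


def detect(m: JunctionCountMatrix, cfg: PipelineConfig) -> pd.DataFrame:
    """Boolean detection matrix: count >= min_junction_reads."""
    return m.counts >= cfg.min_junction_reads


@dataclass(frozen=True)
class SelectivityCall:
    junction: str
    detected_fraction_pathology: float
    detected_fraction_nonpathology: float
    n_pathology: int
    n_nonpathology: int
    selective: bool


def selectivity(
    detected: pd.DataFrame,
    metadata: pd.DataFrame,
    cfg: PipelineConfig,
) -> list[SelectivityCall]:
    """Selectivity calls over the pathology-expected / not-expected groups.

    selective <=> detected fraction among non-pathology samples <=
    ``max_nonpathology_fraction`` AND among pathology-expected samples >=
    ``min_pathology_fraction`` (both inclusive).
    """
    flags = metadata.loc[detected.columns, "pathology_expected"].astype(bool)
    path_samples = list(flags.index[flags])
    nonpath_samples = list(flags.index[~flags])
    if not path_samples or not nonpath_samples:
        raise ValueError(
            "both pathology-expected and not-expected groups must be nonempty"
        )
    out = []
    for junction in detected.index:
        f_path = float(detected.loc[junction, path_samples].mean())
        f_non = float(detected.loc[junction, nonpath_samples].mean())
        out.append(
            SelectivityCall(
                junction=junction,
                detected_fraction_pathology=f_path,
                detected_fraction_nonpathology=f_non,
                n_pathology=len(path_samples),
                n_nonpathology=len(nonpath_samples),
                selective=(
                    f_non <= cfg.max_nonpathology_fraction
                    and f_path >= cfg.min_pathology_fraction
                ),
            )
        )
    return out


def selectivity_table(calls: Sequence[SelectivityCall]) -> pd.DataFrame:
    return pd.DataFrame([call.__dict__ for call in calls])
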