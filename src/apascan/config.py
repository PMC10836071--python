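"""Pipeline configuration.

Every numeric threshold used anywhere in the pipeline lives here, with the
field defaults being the published operating point of the method: a last exon
must come from a transcript with mean expression > 1 TPM within its condition;
its predicted 3'end either lies strictly within 100 nt of a polyA-site atlas
record or carries one of the 18 polyA-signal hexamers within its final
100 nt (signals sit ~21 nt upstream of cleavage sites); extension-type events
must extend a known exon by >= 100 nt; a cryptic isoform has < 10% usage in
controls and gains > 10% usage upon knockdown at BH-adjusted p < 0.05; cohort
junctions need >= 2 spliced reads per sample and selectivity of <= 0.5% of
non-pathology vs >= 1% of pathology-expected samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

#: The 18 polyA-signal hexamer variants (DNA alphabet) of the
#: Gruber/PolyASite compilation, most prominent first (AATAAA).
PAS_HEXAMERS: frozenset[str] = frozenset(
    {
        "AATAAA", "ATTAAA", "AGTAAA", "TATAAA", "CATAAA", "GATAAA",
        "AATATA", "AATACA", "AATAGA", "AAAAAG", "ACTAAA", "AATGAA",
        "TTTAAA", "AAGAAA", "AATAAT", "ATTACA", "AACAAA", "ATTATA",
    }
)


@dataclass
class PipelineConfig:
    # expression / discovery
    min_mean_tpm: float = 1.0          # strict ">", TPM units
    min_extension: int = 100           # nt, extension-type events
    first_exon_slack: int = 100        # nt, 5'end slack over first exons

    # 3'end validation
    atlas_max_dist: int = 100          # nt, strict "below"
    motif_search_window: int = 100     # nt, 3'-terminal scan window
    expected_pas_offset: int = 21      # nt, motif start to cleavage site
    pas_hexamers: frozenset[str] = field(default_factory=lambda: PAS_HEXAMERS)

    # cryptic calling
    cryptic_max_ctrl_usage: float = 0.10
    cryptic_min_delta: float = 0.10
    alpha: float = 0.05
    tsl_keep: frozenset[int] = field(default_factory=lambda: frozenset({1, 2, 3}))
    require_all_datasets_significant: bool = False

    # landmark maps / motifs
    map_flank: int = 500               # nt either side of a landmark
    peka_proximal: int = 250           # nt, window of interest
    peka_distal: int = 500             # nt, context window
    loess_span: float = 0.1
    kmer_k: int = 6
    ale_collapse_shortest_exon: bool = True

    # cohort screen
    min_junction_reads: int = 2
    max_nonpathology_fraction: float = 0.005
    min_pathology_fraction: float = 0.01
    strand_agnostic_undetermined: bool = True

    # FACS-seq enrichment
    facs_enrichment_min_median_delta: float = 0.05

    def __post_init__(self) -> None:
        self.pas_hexamers = frozenset(h.upper() for h in self.pas_hexamers)
        if len(self.pas_hexamers) != 18:
            raise ValueError(
                f"pas_hexamers must have 18 members, got {len(self.pas_hexamers)}"
            )
        for h in self.pas_hexamers:
            if len(h) != 6 or set(h) - set("ACGT"):
                raise ValueError(f"invalid polyA-signal hexamer {h!r}")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v <= 0:
                raise ValueError(f"config field {f.name} must be positive, got {v}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "pas_hexamers" in data:
            data["pas_hexamers"] = frozenset(data["pas_hexamers"])
        if "tsl_keep" in data:
            data["tsl_keep"] = frozenset(int(x) for x in data["tsl_keep"])
        return cls(**data)


#: (disease subtype, tissue) pairs where TDP-43 pathology — and hence specific
#: cryptic junction expression — is expected.  Used as the default template
#: for the cohort screen; any mapping of the same shape may be supplied.
DEFAULT_PATHOLOGY_MAP: frozenset[tuple[str, str]] = frozenset(
    {
        ("ALS-TDP", "motor_cortex"),
        ("ALS-TDP", "frontal_cortex"),
        ("ALS-TDP", "temporal_cortex"),
        ("ALS-TDP", "cervical_spinal_cord"),
        ("ALS-TDP", "lumbar_spinal_cord"),
        ("ALS-TDP", "thoracic_spinal_cord"),
        ("FTLD-TDP", "frontal_cortex"),
        ("FTLD-TDP", "temporal_cortex"),
    }
)
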