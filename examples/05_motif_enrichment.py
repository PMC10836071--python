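"""Positional k-mer enrichment and hexamer-group GSEA.

Plants a UG-rich 6-mer near cryptic landmarks only, scores all 6-mers by
their proximal-vs-context occurrence contrast between cryptic and
background windows, and tests the predefined TDP-43-preferred hexamer
groups for enrichment at the top of the ranking.
"""

import numpy as np

from apascan import HexamerGroups, PipelineConfig, adjust_gsea, gsea_kmers
from apascan.motifs import kmer_enrichment_from_sequences

cfg = PipelineConfig()
rng = np.random.default_rng(11)
width = 2 * cfg.peka_distal + 1

def window():
    return "".join(rng.choice(list("ACGU"), size=width))

def plant(seq, offset, motif):
    pos = cfg.peka_distal + offset
    return seq[:pos] + motif + seq[pos + len(motif):]

cryptic = [plant(plant(window(), -30, "UGUGUG"), -60, "GUGUGU") for _ in range(30)]
background = [window() for _ in range(30)]

table = kmer_enrichment_from_sequences(cryptic, background, cfg)
print("top 5 enriched 6-mers at cryptic landmarks:")
print(table.head(5).to_string(index=False))

results = adjust_gsea(gsea_kmers(table, HexamerGroups(), landmark_kind="ALE_pas",
                                 n_perm=2000, seed=1))
print("\nhexamer-group GSEA (one-sided):")
for r in results:
    if r.absent:
        print(f"  {r.set_name:>6}: no member in the ranking")
    else:
        print(f"  {r.set_name:>6}: ES={r.es:.3f} NES={r.nes:.2f} "
              f"p={r.p_value:.4g} padj={r.padj:.4g}")
print(
    "\nThe planted UGUGUG/GUGUGU drive the YG set (and the union) to the "
    "top of the ranking: ES near 1 and p at the permutation floor, while "
    "unplanted sets stay unenriched."
)
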