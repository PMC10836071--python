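"""Binding-peak metaprofiles around event landmarks.

Plants binding peaks upstream of cryptic polyA sites with high probability
(and rarely at background sites), then computes the positional coverage
profile: at each position relative to the landmark, the fraction of events
overlapped by a peak, with +/- 1 SE bands and LOESS smoothing.
"""

import numpy as np

from apascan import (
    FixtureSpec,
    GenomicInterval,
    Landmark,
    PipelineConfig,
    coverage_profile,
    make_peaks,
)

cfg = PipelineConfig()
spec = FixtureSpec(seed=7, p_peak_cryptic=0.9, p_peak_background=0.1)

landmarks = [
    Landmark(f"c{i}", "ALE_pas", GenomicInterval("chrS", 10_000 + 4_000 * i, 10_001 + 4_000 * i, "+"), "cryptic")
    for i in range(40)
] + [
    Landmark(f"b{i}", "ALE_pas", GenomicInterval("chrS", 200_000 + 4_000 * i, 200_001 + 4_000 * i, "+"), "background")
    for i in range(40)
]
peaks = make_peaks(spec, landmarks)

profiles = coverage_profile(landmarks, peaks, cfg)
for group in ("cryptic", "background"):
    prof = profiles[("ALE_pas", group)]
    centre = np.where(prof.positions == -10)[0][0]
    far = np.where(prof.positions == 400)[0][0]
    print(
        f"{group:>10}: coverage at -10 nt = {prof.mean[centre]:.2f} "
        f"(+/- {prof.se[centre]:.2f}), at +400 nt = {prof.mean[far]:.2f}, "
        f"n = {prof.n}"
    )
print(
    "\nPeaks were planted just upstream of cryptic polyA sites, so cryptic "
    "coverage near the landmark approaches the planting probability (0.9) "
    "while background stays near 0.1; far from the landmark both fall to 0."
)
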