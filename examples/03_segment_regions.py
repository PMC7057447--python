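"""Segment called CpGs into UMR/MMR/FMR genomic regions.

Adjacent same-state CpGs merge while their genomic gap stays below a
density-aware threshold (300 bp for island pairs, 11,300 bp in the open
sea on HM450K); regions with fewer than 3 CpGs are dropped and their
same-state neighbours re-merged; finally the region mean betas are
re-classified with the same two-layer HMM.
"""

from collections import Counter

from methylstates import (
    Platform,
    SegmentationConfig,
    annotate_islands,
    call_site_states,
    segment,
    simulate,
    SimulationConfig,
    width_summary,
    write_region_bed,
)

truth = simulate(SimulationConfig(seed=1))
profile = annotate_islands(truth.profile, truth.islands, flank=300)
calls = call_site_states(profile).frame["final_state"].to_numpy()

config = SegmentationConfig().resolve(Platform.HM450K)
regions = segment(profile, calls, config)

print(f"{len(regions)} regions:", dict(Counter(r.state for r in regions)))
print("width summary (bp):")
print(width_summary(regions).round(0).to_string())

write_region_bed(regions, "regions.bed", header="example segmentation")
print("wrote regions.bed (BED6 + n_cpg, mean_beta columns)")
# Region counts track the planted state runs; widths reflect the probe
# layout (island regions are narrow, open-sea regions span tens of kb).
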