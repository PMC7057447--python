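"""Gap- and state-aware segmentation of CpG sites into genomic regions.

Array probes are sparse and unevenly spaced: dense inside CpG islands,
sparse in the open sea.  Segmentation therefore proceeds in four steps:

1. merge adjacent CpGs into a candidate region while the genomic gap is
   at or below a density-dependent threshold (island pairs: 300 bp;
   open-sea pairs: 11,300 bp on HM450K, 4800 bp on EPIC) AND the two
   sites carry the same final site-state;
2. drop candidate regions with fewer than three CpGs (too few sites to
   support a regional state);
3. re-merge surviving same-state neighbours under the same gap
   thresholds, so that a dropped one-or-two-CpG state flicker does not
   fragment a region; dropped CpGs inside a merged span are
   re-absorbed;
4. classify each region from its mean beta-value with the same
   two-layer two-state HMM used at site level, yielding UMR/MMR/FMR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .profiles import MethylationProfile, Platform
from .sites import CallerConfig, two_layer_labels

logger = logging.getLogger(__name__)

UMR, MMR, FMR = "UMR", "MMR", "FMR"
REGION_LABELS = (UMR, MMR, FMR)
UNSET = "UNSET"

#: platform defaults for the open-sea gap threshold (bp)
OPENSEA_GAP = {Platform.HM450K: 11300, Platform.EPIC: 4800}


@dataclass(frozen=True)
class SegmentationConfig:
    """All thresholds of the segmentation pipeline.

    island_gap / opensea_gap
        Maximum genomic gap (bp) for two adjacent CpGs to share a
        region, depending on whether both are island-associated.  The
        open-sea gap is platform-dependent; ``resolve`` fills it from
        the platform when left unset (GENERIC platforms must set it
        explicitly).
    min_cpgs
        Minimum CpG count for a region to survive filtering.
    remerge_same_state_only
        If True (default), step 3 re-merges only regions whose (uniform)
        member site-state agrees: that rescues a region fragmented by a
        dropped one-or-two-CpG state flicker without welding genuinely
        different-state neighbours together.  The permissive False
        variant merges regardless of state; on dense probe grids where
        most gaps are under threshold it collapses adjacent state runs
        into one region and is offered only for comparison.
    min_regions_for_hmm
        Below this many regions the HMM classification is replaced by a
        fixed-threshold fallback (mean < 0.25 -> UMR, > 0.75 -> FMR).
    """

    island_gap: int = 300
    opensea_gap: int | None = None
    min_cpgs: int = 3
    remerge_same_state_only: bool = True
    min_regions_for_hmm: int = 10
    caller: CallerConfig = field(default_factory=CallerConfig)

    def __post_init__(self) -> None:
        if self.island_gap <= 0 or (self.opensea_gap is not None and self.opensea_gap <= 0):
            raise ValidationError("gap thresholds must be positive")
        if self.min_cpgs < 1:
            raise ValidationError("min_cpgs must be >= 1")

    def resolve(self, platform: Platform) -> "SegmentationConfig":
        """Fill the open-sea gap from the platform preset if unset."""
        if self.opensea_gap is not None:
            return self
        platform = Platform(platform)
        if platform not in OPENSEA_GAP:
            raise ValidationError(
                "platform GENERIC requires an explicit opensea_gap"
            )
        return replace(self, opensea_gap=OPENSEA_GAP[platform])


@dataclass(eq=False)
class Region:
    """A genomic interval of CpGs sharing one methylation state.

    ``start``/``end`` are the 1-based positions of the first and last
    member CpG (the region claims nothing about unprobed flanks);
    ``cpg_indices`` index rows of the profile the region was built from.
    ``site_state`` is the uniform final site label of the members where
    one exists (None after a cross-state re-merge); ``state`` is the
    regional label set by classification.
    """

    chrom: str
    start: int
    end: int
    cpg_indices: np.ndarray
    mean_beta: float
    state: str = UNSET
    site_state: str | None = None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Region):
            return NotImplemented
        return (
            (self.chrom, self.start, self.end, self.state, self.site_state)
            == (other.chrom, other.start, other.end, other.state, other.site_state)
            and np.array_equal(self.cpg_indices, other.cpg_indices)
            and self.mean_beta == other.mean_beta
        )

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_indices)

    @property
    def width(self) -> int:
        return self.end - self.start + 1


def gap_threshold(site_a, site_b, config: SegmentationConfig) -> int:
    """Gap threshold (bp) applying between two island-annotated sites.

    Returns the island gap iff BOTH sites are island-associated, the
    open-sea gap otherwise (mixed pairs take the permissive open-sea
    threshold).  Sites must share a chromosome.
    """
    if site_a["chrom"] != site_b["chrom"]:
        raise ValidationError("gap_threshold: sites on different chromosomes")
    if config.opensea_gap is None:
        raise ValidationError("opensea_gap unset; call SegmentationConfig.resolve first")
    if bool(site_a["island_member"]) and bool(site_b["island_member"]):
        return config.island_gap
    return config.opensea_gap


def _pair_thresholds(island: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    return np.where(island[:-1] & island[1:], config.island_gap, config.opensea_gap)


def build_primary_regions(
    profile: MethylationProfile,
    site_calls: Sequence[str],
    config: SegmentationConfig,
) -> list[Region]:
    """Step 1: scan each chromosome, joining adjacent CpGs into a region
    iff the gap is within threshold AND the final site-state matches."""
    if config.opensea_gap is None:
        raise ValidationError("opensea_gap unset; call SegmentationConfig.resolve first")
    calls = np.asarray(site_calls, dtype=object)
    if calls.size != len(profile):
        raise ValidationError("site_calls not aligned to profile")
    regions: list[Region] = []
    df = profile.records
    for chrom in profile.chroms:
        idx = np.flatnonzero((df["chrom"] == chrom).to_numpy())
        pos = df["pos"].to_numpy()[idx]
        island = df["island_member"].to_numpy()[idx]
        beta = df["beta"].to_numpy()[idx]
        st = calls[idx]
        if idx.size == 0:
            continue
        thr = _pair_thresholds(island, config)
        brk = np.flatnonzero((np.diff(pos) > thr) | (st[:-1] != st[1:])) + 1
        for seg in np.split(np.arange(idx.size), brk):
            members = idx[seg]
            regions.append(
                Region(
                    chrom=chrom,
                    start=int(pos[seg[0]]),
                    end=int(pos[seg[-1]]),
                    cpg_indices=members,
                    mean_beta=float(beta[seg].mean()),
                    site_state=str(st[seg[0]]),
                )
            )
    return regions


def filter_small_regions(
    regions: Sequence[Region], config: SegmentationConfig
) -> list[Region]:
    """Step 2: drop regions with fewer than ``min_cpgs`` member CpGs."""
    kept = [r for r in regions if r.n_cpg >= config.min_cpgs]
    n_dropped = len(regions) - len(kept)
    if n_dropped:
        logger.info("filter_small_regions: dropped %d region(s)", n_dropped)
    return kept


def _merge_pair(a: Region, b: Region, profile: MethylationProfile) -> Region:
    """Merge two neighbouring regions, re-absorbing every profile CpG
    inside the merged span (this recovers previously dropped CpGs)."""
    df = profile.records
    on_chrom = np.flatnonzero((df["chrom"] == a.chrom).to_numpy())
    pos = df["pos"].to_numpy()[on_chrom]
    inside = on_chrom[(pos >= a.start) & (pos <= b.end)]
    beta = df["beta"].to_numpy()[inside]
    return Region(
        chrom=a.chrom,
        start=a.start,
        end=b.end,
        cpg_indices=inside,
        mean_beta=float(beta.mean()),
        site_state=a.site_state if a.site_state == b.site_state else None,
    )


def remerge_regions(
    regions: Sequence[Region],
    profile: MethylationProfile,
    config: SegmentationConfig,
) -> list[Region]:
    """Step 3: re-merge surviving neighbours under the gap thresholds.

    The gap is measured between the last CpG of one region and the
    first CpG of the next, with the threshold decided by that site
    pair's island flags; dropped CpGs inside a merged span are
    re-absorbed.  Iterates to a fixpoint (idempotent on its output).
    """
    df = profile.records
    out: list[Region] = []
    for r in sorted(regions, key=lambda r: (profile.chroms.index(r.chrom), r.start)):
        while out and out[-1].chrom == r.chrom:
            last = out[-1]
            a = df.iloc[last.cpg_indices[-1]]
            b = df.iloc[r.cpg_indices[0]]
            if int(b["pos"]) - int(a["pos"]) > gap_threshold(a, b, config):
                break
            if config.remerge_same_state_only and last.site_state != r.site_state:
                break
            r = _merge_pair(last, r, profile)
            out.pop()
        out.append(r)
    return out


def classify_regions(
    regions: Sequence[Region], config: SegmentationConfig
) -> list[Region]:
    """Step 4: label each region UMR/MMR/FMR from its mean beta.

    The per-chromosome sequences of region mean betas are fed to the
    same two-layer two-state HMM procedure used at site level.  With
    fewer regions than ``min_regions_for_hmm`` the HMM has nothing to
    learn from and a fixed-threshold fallback is applied instead
    (mean < 0.25 -> UMR, > 0.75 -> FMR, else MMR), with a warning.
    """
    regions = list(regions)
    if not regions:
        return []
    if len(regions) < config.min_regions_for_hmm:
        logger.warning(
            "classify_regions: only %d regions; using fixed thresholds "
            "(0.25 / 0.75) instead of the HMM", len(regions),
        )
        for r in regions:
            r.state = UMR if r.mean_beta < 0.25 else (FMR if r.mean_beta > 0.75 else MMR)
        return regions
    chains = []
    chrom_order = list(dict.fromkeys(r.chrom for r in regions))
    for chrom in chrom_order:
        chains.append(np.array([r.mean_beta for r in regions if r.chrom == chrom]))
    res = two_layer_labels(chains, config.caller, labels=REGION_LABELS)
    i = 0
    for chrom in chrom_order:
        for r in regions:
            if r.chrom == chrom:
                r.state = str(res.labels[i])
                i += 1
    return regions


def segment(
    profile: MethylationProfile,
    site_calls: Sequence[str],
    config: SegmentationConfig | None = None,
) -> list[Region]:
    """Full pipeline: build -> filter -> re-merge -> classify.

    ``config.opensea_gap`` is resolved from the profile's platform when
    unset.  Returns regions sorted by (chrom, start), pairwise disjoint,
    each with at least ``min_cpgs`` CpGs and a UMR/MMR/FMR state.
    """
    config = (config or SegmentationConfig()).resolve(profile.platform)
    if len(profile) == 0:
        return []
    primary = build_primary_regions(profile, site_calls, config)
    kept = filter_small_regions(primary, config)
    merged = remerge_regions(kept, profile, config)
    return classify_regions(merged, config)
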