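"""Region building, filtering, re-merging and classification."""

import numpy as np
import pytest

from methylstates import (
    Platform,
    SegmentationConfig,
    ValidationError,
    build_primary_regions,
    classify_regions,
    filter_small_regions,
    gap_threshold,
    remerge_regions,
    segment,
    simulate,
    SimulationConfig,
)

from conftest import make_profile

HM = SegmentationConfig().resolve(Platform.HM450K)
EPIC = SegmentationConfig().resolve(Platform.EPIC)


def _site(chrom="chr1", island=True):
    return {"chrom": chrom, "island_member": island}


class TestGapThreshold:
    def test_island_pair(self):
        assert gap_threshold(_site(), _site(), HM) == 300

    def test_opensea_pair_by_platform(self):
        a, b = _site(island=False), _site(island=False)
        assert gap_threshold(a, b, HM) == 11300
        assert gap_threshold(a, b, EPIC) == 4800

    def test_mixed_pair_uses_opensea(self):
        assert gap_threshold(_site(island=True), _site(island=False), HM) == 11300

    def test_cross_chromosome_raises(self):
        with pytest.raises(ValidationError):
            gap_threshold(_site("chr1"), _site("chr2"), HM)

    def test_generic_platform_requires_gap(self):
        with pytest.raises(ValidationError, match="GENERIC"):
            SegmentationConfig().resolve(Platform.GENERIC)


class TestBuildPrimaryRegions:
    def test_island_gap_split_hand_trace(self):
        # gaps 100 and 800; island threshold 300 -> split before 1900
        prof = make_profile([1000, 1100, 1900], [0.1] * 3, island=[True] * 3)
        regions = build_primary_regions(prof, ["UMS"] * 3, HM)
        assert [(r.start, r.end, r.n_cpg) for r in regions] == [(1000, 1100, 2), (1900, 1900, 1)]

    def test_state_change_splits_despite_small_gap(self):
        prof = make_profile([1000, 1100], [0.1, 0.9], island=[True, True])
        regions = build_primary_regions(prof, ["UMS", "FMS"], HM)
        assert len(regions) == 2

    def test_single_site_region_and_states_uniform(self):
        prof = make_profile([5000], [0.5], island=[False])
        [r] = build_primary_regions(prof, ["MMS"], HM)
        assert (r.start, r.end, r.n_cpg, r.site_state) == (5000, 5000, 1, "MMS")

    def test_intra_region_gaps_respect_threshold(self):
        truth = simulate(SimulationConfig(seed=9, n_islands=15))
        from methylstates import annotate_islands

        prof = annotate_islands(truth.profile, truth.islands, flank=300)
        calls = [("UMS", "MMS", "FMS")[s] for s in truth.true_site_state]
        df = prof.records
        for r in build_primary_regions(prof, calls, HM):
            pos = df["pos"].to_numpy()[r.cpg_indices]
            isl = df["island_member"].to_numpy()[r.cpg_indices]
            gaps = np.diff(pos)
            thr = np.where(isl[:-1] & isl[1:], HM.island_gap, HM.opensea_gap)
            assert (gaps <= thr).all()


class TestFilterSmallRegions:
    @pytest.fixture
    def regions(self):
        prof = make_profile(
            [1000, 1100, 1200, 5000, 5100, 9000, 9050, 9100, 9150],
            [0.1] * 9,
            island=[True] * 9,
        )
        calls = ["UMS"] * 3 + ["FMS"] * 2 + ["UMS"] * 4
        return build_primary_regions(prof, calls, HM)

    def test_below_min_dropped_boundary_kept(self, regions):
        kept = filter_small_regions(regions, HM)
        assert [r.n_cpg for r in kept] == [3, 4]  # the 2-CpG region dropped

    def test_empty_input(self):
        assert filter_small_regions([], HM) == []

    def test_count_monotone(self, regions):
        assert len(filter_small_regions(regions, HM)) <= len(regions)


def flicker_profile():
    """Two 3-CpG UMS runs flanking a 2-CpG FMS flicker, all island."""
    pos = [1000, 1050, 1100, 1150, 1160, 1300, 1350, 1400]
    beta = [0.05, 0.06, 0.05, 0.9, 0.92, 0.05, 0.04, 0.06]
    calls = ["UMS"] * 3 + ["FMS"] * 2 + ["UMS"] * 3
    return make_profile(pos, beta, island=[True] * 8), calls


class TestRemergeRegions:
    def test_flicker_absorbed_hand_trace(self):
        prof, calls = flicker_profile()
        primary = build_primary_regions(prof, calls, HM)
        assert [r.n_cpg for r in primary] == [3, 2, 3]
        kept = filter_small_regions(primary, HM)
        merged = remerge_regions(kept, prof, HM)
        # 1300 - 1100 = 200 <= 300: regions merge, flicker re-absorbed
        assert len(merged) == 1
        assert merged[0].n_cpg == 8
        assert (merged[0].start, merged[0].end) == (1000, 1400)
        assert merged[0].mean_beta == pytest.approx(np.mean(flicker_profile()[0].records["beta"]))

    def test_far_apart_regions_unchanged(self):
        prof = make_profile(
            [1000, 1100, 1200, 60_000, 60_100, 60_200],
            [0.1] * 6,
            island=[False] * 6,
        )
        regions = build_primary_regions(prof, ["UMS"] * 6, HM)
        assert len(regions) == 2  # 58,800 bp > 11,300
        assert remerge_regions(regions, prof, HM) == regions

    def test_idempotent_fixpoint(self):
        prof, calls = flicker_profile()
        kept = filter_small_regions(build_primary_regions(prof, calls, HM), HM)
        once = remerge_regions(kept, prof, HM)
        twice = remerge_regions(once, prof, HM)
        assert [(r.start, r.end, r.n_cpg) for r in twice] == [
            (r.start, r.end, r.n_cpg) for r in once
        ]

    def test_permissive_variant_merges_across_states(self):
        prof = make_profile(
            [1000, 1050, 1100, 1200, 1250, 1300],
            [0.05, 0.05, 0.05, 0.9, 0.9, 0.9],
            island=[True] * 6,
        )
        calls = ["UMS"] * 3 + ["FMS"] * 3
        kept = filter_small_regions(build_primary_regions(prof, calls, HM), HM)
        assert len(remerge_regions(kept, prof, HM)) == 2  # default keeps states apart
        from dataclasses import replace

        permissive = replace(HM, remerge_same_state_only=False)
        assert len(remerge_regions(kept, prof, permissive)) == 1

    def test_count_monotone(self):
        prof, calls = flicker_profile()
        kept = filter_small_regions(build_primary_regions(prof, calls, HM), HM)
        assert len(remerge_regions(kept, prof, HM)) <= len(kept)


def block_fixture(n_blocks=90, cpgs_per_block=5, rng=None):
    """Open-sea blocks 20 kb apart, cycling through the three strata."""
    rng = rng or np.random.default_rng(123)
    means = [0.05, 0.5, 0.95]
    labels = ["UMS", "MMS", "FMS"]
    pos, beta, calls, strata = [], [], [], []
    p = 10_000
    for b in range(n_blocks):
        s = b % 3
        for _ in range(cpgs_per_block):
            pos.append(p)
            beta.append(float(np.clip(rng.normal(means[s], 0.03), 0, 1)))
            calls.append(labels[s])
            strata.append(s)
        p += 20_000
        pos[-cpgs_per_block:] = [q + i * 100 for i, q in enumerate(pos[-cpgs_per_block:])]
    prof = make_profile(pos, beta, island=[False] * len(pos))
    return prof, calls, strata


class TestClassifyRegions:
    def test_planted_blocks_recovered(self):
        prof, calls, strata = block_fixture()
        regions = segment(prof, calls, HM)
        assert len(regions) == 90
        label_of = {0: "UMR", 1: "MMR", 2: "FMR"}
        correct = sum(
            r.state == label_of[strata[r.cpg_indices[0]]] for r in regions
        )
        assert correct / len(regions) >= 0.90

    def test_label_mean_ordering(self):
        prof, calls, _ = block_fixture()
        regions = segment(prof, calls, HM)
        by = {}
        for r in regions:
            by.setdefault(r.state, []).append(r.mean_beta)
        assert set(by) == {"UMR", "MMR", "FMR"}
        assert np.mean(by["UMR"]) < np.mean(by["MMR"]) < np.mean(by["FMR"])

    def test_all_low_means_all_umr(self):
        prof, calls, _ = block_fixture(n_blocks=12)
        # force all means low
        rec = prof.records.copy()
        rec["beta"] = np.random.default_rng(0).uniform(0.0, 0.18, len(rec))
        prof = prof.replace_records(rec)
        regions = segment(prof, ["UMS"] * len(rec), HM)
        assert len(regions) == 12
        assert all(r.state == "UMR" for r in regions)

    def test_threshold_fallback_below_min_regions(self):
        prof, calls, strata = block_fixture(n_blocks=6)
        regions = segment(prof, calls, HM)
        assert len(regions) == 6
        label_of = {0: "UMR", 1: "MMR", 2: "FMR"}
        assert [r.state for r in regions] == [label_of[s % 3] for s in range(6)]


class TestSegmentPipeline:
    def test_empty_profile(self):
        prof = make_profile([100], [0.5])
        prof.records = prof.records.iloc[:0]
        assert segment(prof, [], HM) == []

    def test_output_disjoint_sorted_min_cpgs(self):
        prof, calls, _ = block_fixture()
        regions = segment(prof, calls, HM)
        assert all(r.n_cpg >= HM.min_cpgs for r in regions)
        for a, b in zip(regions, regions[1:]):
            if a.chrom == b.chrom:
                assert a.end < b.start

    def test_deterministic(self):
        prof, calls, _ = block_fixture()
        a = segment(prof, calls, HM)
        b = segment(prof, calls, HM)
        assert [(r.start, r.end, r.state) for r in a] == [
            (r.start, r.end, r.state) for r in b
        ]

    def test_boundary_recovery_on_synthetic_truth(self):
        """>= 80% of planted state-change boundaries fall within one
        inter-CpG step of a called region boundary."""
        from methylstates import annotate_islands, call_site_states

        truth = simulate(SimulationConfig(seed=21))
        prof = annotate_islands(truth.profile, truth.islands, flank=300)
        calls = call_site_states(prof).frame["final_state"].to_numpy()
        regions = segment(prof, calls, HM)
        bounds = set()
        for r in regions:
            bounds.add(r.cpg_indices[0] - 0.5)
            bounds.add(r.cpg_indices[-1] + 0.5)
        st = truth.true_site_state
        df = prof.records
        hits = total = 0
        for chrom in prof.chroms:
            idx = np.flatnonzero((df["chrom"] == chrom).to_numpy())
            for local in np.flatnonzero(st[idx][:-1] != st[idx][1:]):
                planted = idx[local] + 0.5
                total += 1
                hits += any(abs(b - planted) <= 1.0 for b in bounds)
        assert total >= 30
        assert hits / total >= 0.80
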