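"""Minimum-tiling-path selection, gap augmentation and coverage statistics."""

from __future__ import annotations

import itertools
import random

import pytest

from bacmap.anchoring import BESHit, place_clone
from bacmap.fpc import FPCContig, FPCMap
from bacmap.mtp import (
    CoverageIsland,
    MTPParams,
    MTPResult,
    augment_with_unpaired,
    build_islands,
    build_mtp,
    count_spanned_sequence_gaps,
    coverage_table,
    mtp_stats,
    pick_mtp,
    select_pool,
)
from bacmap.simulate import GapRecord, ReferenceGenome

PARAMS = MTPParams()


def paired(cid, start, end, chrom="chr1"):
    hits = [
        BESHit(f"{cid}.F", chrom, start, start + 600, "+"),
        BESHit(f"{cid}.R", chrom, end - 600, end, "-"),
    ]
    return place_clone(cid, hits, 2)


def one_end(cid, start, strand, chrom="chr1"):
    return place_clone(cid, [BESHit(f"{cid}.F", chrom, start, start + 600, strand)], 1)


def brute_force_mtp(island, spans):
    """Oracle: enumerate all covering paths, return min (count, overlap)."""
    nodes = sorted({spans[c]: c for c in sorted(island.members)}.values())
    best = None
    sources = [c for c in nodes if spans[c][0] <= island.start < spans[c][1]]

    def extend(path, covered_to, overlap):
        nonlocal best
        if covered_to >= island.end:
            key = (len(path), overlap)
            if best is None or key < best:
                best = key
            return
        if best is not None and len(path) >= best[0]:
            return
        u = path[-1]
        us, ue = spans[u]
        for v in nodes:
            vs, ve = spans[v]
            if us < vs < ue and ve > ue:
                extend(path + [v], ve, overlap + (ue - vs))

    for s in sources:
        extend([s], spans[s][1], 0)
    return best


class TestSelectPool:
    fmap = FPCMap([FPCContig("ctg1", ["a", "b"], [0, 0], 30)], ["s1"])

    def test_span_outside_window_excluded(self):
        p = paired("a", 0, 300_000)
        assert select_pool([p], self.fmap, "B", True, PARAMS) == []

    def test_pool_a_requires_map_membership(self):
        inside = paired("a", 0, 150_000)
        outside = paired("z", 0, 150_000)
        got = select_pool([inside, outside], self.fmap, "A", True, PARAMS)
        assert [p.clone_id for p in got] == ["a"]
        got_b = select_pool([inside, outside], self.fmap, "B", True, PARAMS)
        assert sorted(p.clone_id for p in got_b) == ["a", "z"]

    def test_singletons_count_as_map_members(self):
        p = paired("s1", 0, 150_000)
        assert select_pool([p], self.fmap, "A", True, PARAMS) == [p]

    def test_paired_only_drops_one_end(self):
        p = one_end("a", 1000, "+")
        assert select_pool([p], self.fmap, "B", True, PARAMS) == []
        assert select_pool([p], self.fmap, "B", False, PARAMS) == [p]


class TestBuildIslands:
    def test_overlapping_spans_fuse(self):
        isl = build_islands([paired("a", 0, 100_000), paired("b", 90_000, 200_000)], "chr1")
        assert len(isl) == 1
        assert (isl[0].start, isl[0].end) == (0, 200_000)

    def test_disjoint_spans_split(self):
        isl = build_islands([paired("a", 0, 100_000), paired("b", 150_000, 250_000)], "chr1")
        assert len(isl) == 2

    def test_abutting_spans_split(self):
        isl = build_islands([paired("a", 0, 100_000), paired("b", 100_000, 200_000)], "chr1")
        assert len(isl) == 2


class TestPickMTP:
    def test_three_clone_chain(self):
        spans = {"A": (0, 150_000), "B": (50_000, 200_000), "C": (100_000, 250_000)}
        island = CoverageIsland("chr1", 0, 250_000, list(spans))
        path = pick_mtp(island, spans, PARAMS)
        assert path == ["A", "C"]

    def test_single_clone_island(self):
        spans = {"A": (0, 150_000)}
        island = CoverageIsland("chr1", 0, 150_000, ["A"])
        assert pick_mtp(island, spans, PARAMS) == ["A"]

    def test_smaller_overlap_preferred_at_equal_count(self):
        spans = {
            "A": (0, 150_000),
            "B1": (90_000, 250_000),   # overlap 60k with A
            "B2": (110_000, 250_000),  # overlap 40k with A
        }
        island = CoverageIsland("chr1", 0, 250_000, list(spans))
        assert pick_mtp(island, spans, PARAMS) == ["A", "B2"]

    def test_matches_brute_force_on_random_islands(self):
        rng = random.Random(77)
        for _ in range(40):
            spans = {}
            start, end = 0, 0
            for i in range(rng.randrange(2, 10)):
                cid = f"c{i:02d}"
                s = rng.randrange(0, max(end - 1, 1))
                e = s + rng.randrange(50_000, 200_000)
                if s >= end and i > 0:
                    s = max(end - rng.randrange(1, 40_000), 0)
                    e = s + rng.randrange(50_000, 200_000)
                spans[cid] = (s, e)
                end = max(end, e)
            islands = build_islands(
                [paired(c, s, e) for c, (s, e) in spans.items()], "chr1"
            )
            for island in islands:
                sub = {c: spans[c] for c in island.members}
                path = pick_mtp(island, sub, PARAMS)
                got_overlap = sum(
                    sub[u][1] - sub[v][0] for u, v in zip(path, path[1:])
                )
                assert brute_force_mtp(island, sub) == (len(path), got_overlap)


class TestAugment:
    def make_mtp(self):
        placements = [paired("a", 350_000, 500_000)]
        return build_mtp(placements, PARAMS)

    def test_clone_pointing_into_gap_added(self):
        mtp = self.make_mtp()
        gap = [GapRecord("chr1", 500_000, 501_000, "scaffold_join")]
        hit = one_end("u1", 495_000, "+")
        out, stats = augment_with_unpaired(mtp, [hit], gap, PARAMS)
        added = [c for v in out.clones.values() for c in v if c.augmented]
        assert len(added) == 1
        assert (added[0].credited_start, added[0].credited_end) == (495_000, 501_000)
        assert stats["gaps_touched"] == 1

    def test_clone_pointing_away_not_added(self):
        mtp = self.make_mtp()
        gap = [GapRecord("chr1", 500_000, 501_000, "scaffold_join")]
        hit = one_end("u1", 495_000, "-")
        out, stats = augment_with_unpaired(mtp, [hit], gap, PARAMS)
        assert stats["gaps_touched"] == 0
        assert out.n_clones == mtp.n_clones

    def test_clone_far_from_edge_not_added(self):
        mtp = self.make_mtp()
        gap = [GapRecord("chr1", 900_000, 901_000, "scaffold_join")]
        hit = one_end("u1", 495_000, "+")  # 400 kb from the gap edge
        _, stats = augment_with_unpaired(mtp, [hit], gap, PARAMS)
        assert stats["gaps_touched"] == 0

    def test_best_extension_per_side_kept(self):
        mtp = self.make_mtp()
        gap = [GapRecord("chr1", 500_000, 501_000, "scaffold_join")]
        hits = [one_end("u1", 495_000, "+"), one_end("u2", 480_000, "+")]
        out, _ = augment_with_unpaired(mtp, hits, gap, PARAMS)
        added = [c for v in out.clones.values() for c in v if c.augmented]
        assert [c.clone_id for c in added] == ["u1"]  # longer reach into the gap


class TestStatsAndCoverage:
    def test_mean_overlap_single_pair(self):
        spans = {"A": (0, 150_000), "B": (50_000, 200_000), "C": (100_000, 250_000)}
        mtp = build_mtp([paired(c, s, e) for c, (s, e) in spans.items()], PARAMS)
        stats = mtp_stats(mtp)
        assert stats["Total"] == 2
        assert stats["Avg. of overlap"] == 50_000.0
        assert stats["Gaps"] == 0

    def test_empty_mtp_zeros(self):
        stats = mtp_stats(MTPResult())
        assert stats["Total"] == 0 and stats["Avg. of overlap"] == 0.0

    def test_augmentation_increases_clone_count(self):
        placements = [paired("a", 350_000, 500_000)]
        mtp = build_mtp(placements, PARAMS)
        gap = [GapRecord("chr1", 500_000, 501_000, "scaffold_join")]
        out, _ = augment_with_unpaired(mtp, [one_end("u1", 495_000, "+")], gap, PARAMS)
        assert out.n_clones == mtp.n_clones + 1

    def test_coverage_union_semantics(self):
        genome = ReferenceGenome({"chr1": "A" * 1_000_000})
        mtp = build_mtp(
            [paired("a", 0, 150_000), paired("b", 100_000, 250_000)], PARAMS
        )
        table = coverage_table(mtp, genome)
        assert table["chr1"] == 250_000
        assert table["Total"] == 250_000

    def test_single_clone_coverage(self):
        genome = ReferenceGenome({"chr1": "A" * 1_000_000})
        mtp = build_mtp([paired("a", 0, 150_000)], PARAMS)
        assert coverage_table(mtp, genome)["chr1"] == 150_000

    def test_gap_complement_identity(self):
        genome = ReferenceGenome({"chr1": "A" * 1_000_000})
        mtp = build_mtp(
            [paired("a", 0, 150_000), paired("b", 300_000, 450_000)], PARAMS
        )
        covered = coverage_table(mtp, genome)["chr1"]
        inter_island = sum(e - s for _, s, e in mtp.gap_intervals())
        flanks = 0 + (1_000_000 - 450_000)
        assert covered + inter_island + flanks == 1_000_000


class TestSequenceGaps:
    def test_spanned_gap(self):
        mtp = build_mtp([paired("a", 990_000, 1_140_000)], PARAMS)
        gaps = [GapRecord("chr1", 1_000_000, 1_001_000, "scaffold_join")]
        assert count_spanned_sequence_gaps(mtp, gaps) == {"spanned": 1, "partially_filled": 0}

    def test_clone_ending_at_gap_start_not_counted(self):
        mtp = build_mtp([paired("a", 850_000, 1_000_000)], PARAMS)
        gaps = [GapRecord("chr1", 1_000_000, 1_001_000, "scaffold_join")]
        assert count_spanned_sequence_gaps(mtp, gaps) == {"spanned": 0, "partially_filled": 0}

    def test_partial_fill_by_credited_extension(self):
        base = build_mtp([paired("a", 700_000, 850_000)], PARAMS)
        gaps = [GapRecord("chr1", 1_000_000, 1_003_000, "sized")]
        # augment against a scaffold-type gap at the same spot to get a credit
        sgaps = [GapRecord("chr1", 1_000_000, 1_001_000, "scaffold_join")]
        hit = one_end("u1", 850_300, "+")  # credit reaches 300 bp into the gap
        out, _ = augment_with_unpaired(base, [hit], sgaps, PARAMS)
        counts = count_spanned_sequence_gaps(out, sgaps)
        assert counts == {"spanned": 0, "partially_filled": 1}
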