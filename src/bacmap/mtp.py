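"""Minimum tiling path (MTP) selection over BES-anchored clones.

Clones placed on the reference are grouped into coverage islands (maximal
unions of overlapping spans). Within each island a tiling path is chosen by
Dijkstra's algorithm on the overlap graph, minimizing clone count first and
total pairwise overlap second (a lexicographic objective encoded as
edge weight = clone_count_weight + overlap). Clones with a single usable
end read ("unpaired BES") can afterwards be credited with an assumed-length
extension into assembly or coverage gaps they point into.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable

from bacmap.anchoring import ClonePlacement
from bacmap.fpc import FPCMap
from bacmap.simulate import GapRecord, ReferenceGenome


@dataclass(frozen=True)
class MTPParams:
    insert_min: int = 75_000
    insert_max: int = 225_000
    #: large constant making clone count lexicographically dominant over overlap
    clone_count_weight: int = 10_000_000
    edge_window: int = 150_000
    assumed_insert: int = 150_000

    def __post_init__(self) -> None:
        if self.clone_count_weight <= self.insert_max:
            raise ValueError("clone_count_weight must exceed insert_max")


@dataclass
class CoverageIsland:
    chrom: str
    start: int
    end: int
    members: list[str]


@dataclass
class MTPClone:
    clone_id: str
    chrom: str
    start: int
    end: int
    library: str = ""
    augmented: bool = False
    credited_start: int | None = None
    credited_end: int | None = None

    @property
    def covered(self) -> tuple[int, int]:
        """Interval this clone contributes to coverage (span plus credit)."""
        lo = self.start if self.credited_start is None else min(self.start, self.credited_start)
        hi = self.end if self.credited_end is None else max(self.end, self.credited_end)
        return lo, hi


@dataclass
class MTPResult:
    clones: dict[str, list[MTPClone]] = field(default_factory=dict)  # per chrom, ordered
    islands: dict[str, list[CoverageIsland]] = field(default_factory=dict)
    overlaps: dict[str, list[int]] = field(default_factory=dict)  # adjacent same-island pairs

    @property
    def n_clones(self) -> int:
        return sum(len(v) for v in self.clones.values())

    @property
    def n_gaps(self) -> int:
        """Breaks between covered blocks within chromosomes.

        Counted on the union of member spans plus credited extensions, so a
        credited extension that bridges two islands closes the break.
        Uncovered chromosome ends are not counted as gaps.
        """
        total = 0
        for clones in self.clones.values():
            blocks = _merge_intervals([c.covered for c in clones])
            total += max(len(blocks) - 1, 0)
        return total

    def gap_intervals(self) -> list[tuple[str, int, int]]:
        """Inter-island breaks (pre-augmentation structure)."""
        out = []
        for chrom, isls in self.islands.items():
            for a, b in zip(isls, isls[1:]):
                out.append((chrom, a.end, b.start))
        return out


def select_pool(
    placements: Iterable[ClonePlacement],
    fpc_map: FPCMap | None,
    pool: str,
    paired_only: bool,
    params: MTPParams,
) -> list[ClonePlacement]:
    """Restrict placements to one clone pool.

    Pool A keeps only clones present in the fingerprint map (contig members
    or singletons); pool B keeps every clone with BES. Same-chromosome
    placements must have spans within the insert window; with
    ``paired_only`` false, one-end placements are also kept so they can be
    used to extend coverage into gaps.
    """
    if pool not in ("A", "B"):
        raise ValueError("pool must be 'A' or 'B'")
    if pool == "A":
        if fpc_map is None:
            raise ValueError("pool A requires the fingerprint map")
        members = fpc_map.clone_ids
    out = []
    for p in placements:
        if pool == "A" and p.clone_id not in members:
            continue
        if p.status == "both_same_chrom":
            if params.insert_min <= p.span_len <= params.insert_max:
                out.append(p)
        elif p.status == "one_end" and not paired_only:
            out.append(p)
    return out


def build_islands(placements: Iterable[ClonePlacement], chrom: str) -> list[CoverageIsland]:
    """Maximal unions of overlapping same-chromosome spans (>=1 bp overlap).

    Abutting spans (overlap exactly 0 under half-open coordinates) start a
    new island: a tiling path requires genuine overlap between neighbors.
    """
    spans = sorted(
        (p.span_start, p.span_end, p.clone_id)
        for p in placements
        if p.status == "both_same_chrom" and p.chrom == chrom
    )
    islands: list[CoverageIsland] = []
    for start, end, cid in spans:
        if islands and start < islands[-1].end:
            isl = islands[-1]
            isl.end = max(isl.end, end)
            isl.members.append(cid)
        else:
            islands.append(CoverageIsland(chrom, start, end, [cid]))
    return islands


def pick_mtp(
    island: CoverageIsland,
    spans: dict[str, tuple[int, int]],
    params: MTPParams,
) -> list[str]:
    """Tiling path through one island minimizing (clone count, total overlap).

    Nodes are the island's clones (identical spans deduplicated to the
    lexicographically smallest id); an edge u->v exists when v starts
    strictly inside u and extends it, with weight clone_count_weight +
    overlap(u, v). Dijkstra from a virtual source (clones containing the
    island start) to a virtual sink (clones containing the last island base)
    yields the lexicographic optimum.
    """
    if not island.members:
        raise ValueError("empty island")
    # deduplicate identical spans, keep lexicographically smallest id
    by_span: dict[tuple[int, int], str] = {}
    for cid in sorted(island.members):
        by_span.setdefault(spans[cid], cid)
    nodes = sorted(by_span.values())
    span = {cid: spans[cid] for cid in nodes}

    W = params.clone_count_weight
    adj: dict[str, list[tuple[str, int]]] = {cid: [] for cid in nodes}
    starts = sorted(nodes, key=lambda c: span[c][0])
    for u in nodes:
        us, ue = span[u]
        for v in starts:
            vs, ve = span[v]
            if vs >= ue:
                break
            if us < vs < ue and ve > ue:
                adj[u].append((v, W + (ue - vs)))

    SOURCE, SINK = "\x00src", "\x00snk"
    adj[SOURCE] = [
        (c, W) for c in nodes if span[c][0] <= island.start < span[c][1]
    ]
    for c in nodes:
        if span[c][0] <= island.end - 1 < span[c][1]:
            adj[c].append((SINK, 0))

    dist: dict[str, int] = {SOURCE: 0}
    pred: dict[str, str] = {}
    heap: list[tuple[int, str]] = [(0, SOURCE)]
    settled: set[str] = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in settled:
            continue
        settled.add(u)
        if u == SINK:
            break
        for v, w in adj.get(u, ()):
            nd = d + w
            if v not in dist or nd < dist[v] or (nd == dist[v] and u < pred.get(v, "\x7f")):
                dist[v] = nd
                pred[v] = u
                if v not in settled:
                    heapq.heappush(heap, (nd, v))
    if SINK not in pred:
        raise AssertionError("island not coverable by its own members")
    path: list[str] = []
    node = pred[SINK]
    while node != SOURCE:
        path.append(node)
        node = pred[node]
    path.reverse()
    assert span[path[0]][0] <= island.start and span[path[-1]][1] >= island.end
    return path


def build_mtp(
    eligible: Iterable[ClonePlacement],
    params: MTPParams,
    libraries: dict[str, str] | None = None,
) -> MTPResult:
    """Islands plus per-island tiling paths over all chromosomes."""
    eligible = [p for p in eligible if p.status == "both_same_chrom"]
    libraries = libraries or {}
    spans = {p.clone_id: (p.span_start, p.span_end) for p in eligible}
    chroms = sorted({p.chrom for p in eligible})
    result = MTPResult()
    for chrom in chroms:
        islands = build_islands(eligible, chrom)
        clones: list[MTPClone] = []
        overlaps: list[int] = []
        for island in islands:
            path = pick_mtp(island, spans, params)
            for u, v in zip(path, path[1:]):
                overlaps.append(spans[u][1] - spans[v][0])
            for cid in path:
                s, e = spans[cid]
                clones.append(MTPClone(cid, chrom, s, e, libraries.get(cid, "")))
        result.clones[chrom] = clones
        result.islands[chrom] = islands
        result.overlaps[chrom] = overlaps
    return result


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _interval_union_length(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in _merge_intervals(intervals))


def augment_with_unpaired(
    mtp: MTPResult,
    one_end: Iterable[ClonePlacement],
    gap_track: list[GapRecord],
    params: MTPParams,
    libraries: dict[str, str] | None = None,
) -> tuple[MTPResult, dict[str, int]]:
    """Add one-end clones that point into gaps, crediting assumed extensions.

    Gaps considered are the reference assembly's scaffold-join gaps plus the
    MTP's own inter-island breaks. A one-end clone qualifies when its single
    hit lies within ``edge_window`` of a gap edge on the covered side with
    its strand pointing into the gap; it is credited with an extension of
    ``assumed_insert`` bp from the hit's inner edge, truncated at the gap's
    far side. Per gap edge, only the clone with the longest credited
    extension into the gap is kept.
    """
    libraries = libraries or {}
    gaps: list[tuple[str, int, int]] = [
        (g.chrom, g.start, g.end) for g in gap_track if g.gap_class == "scaffold_join"
    ]
    gaps.extend(mtp.gap_intervals())
    hits = [(p, p.hits[0]) for p in one_end if p.status == "one_end" and p.hits]

    out = MTPResult(
        clones={c: list(v) for c, v in mtp.clones.items()},
        islands={c: list(v) for c, v in mtp.islands.items()},
        overlaps={c: list(v) for c, v in mtp.overlaps.items()},
    )
    used: set[str] = set()
    gaps_touched = 0
    added_bp = 0
    for chrom, gstart, gend in sorted(gaps):
        best_per_side: dict[str, tuple[int, str, MTPClone]] = {}
        for p, h in hits:
            if h.chrom != chrom or p.clone_id in used:
                continue
            if h.strand == "+" and h.end <= gstart and gstart - h.end <= params.edge_window:
                ext_start, ext_end = h.start, min(h.start + params.assumed_insert, gend)
                side = "left"
            elif h.strand == "-" and h.start >= gend and h.start - gend <= params.edge_window:
                ext_start, ext_end = max(h.end - params.assumed_insert, gstart), h.end
                side = "right"
            else:
                continue
            into_gap = min(ext_end, gend) - max(ext_start, gstart)
            if into_gap <= 0:
                continue
            clone = MTPClone(
                p.clone_id, chrom, h.start, h.end, libraries.get(p.clone_id, ""),
                augmented=True, credited_start=ext_start, credited_end=ext_end,
            )
            cur = best_per_side.get(side)
            # longest extension into the gap wins; ties broken by clone_id
            if cur is None or into_gap > cur[0] or (into_gap == cur[0] and p.clone_id < cur[1]):
                best_per_side[side] = (into_gap, p.clone_id, clone)
        if best_per_side:
            gaps_touched += 1
        for into_gap, cid, clone in best_per_side.values():
            used.add(cid)
            out.clones.setdefault(chrom, []).append(clone)
            added_bp += into_gap
    for chrom in out.clones:
        out.clones[chrom].sort(key=lambda c: (c.covered[0], c.clone_id))
    return out, {"gaps_touched": gaps_touched, "added_bp": added_bp}


def mtp_stats(mtp: MTPResult, libraries: list[str] | None = None) -> dict[str, float]:
    """Per-library clone counts, gap count, and mean adjacent overlap."""
    all_clones = [c for v in mtp.clones.values() for c in v]
    lib_names = libraries or sorted({c.library for c in all_clones})
    stats: dict[str, float] = {lib: 0 for lib in lib_names}
    for c in all_clones:
        if c.library in stats:
            stats[c.library] += 1
    overlaps = [o for v in mtp.overlaps.values() for o in v]
    stats["Total"] = len(all_clones)
    stats["Gaps"] = mtp.n_gaps
    stats["Avg. of overlap"] = float(sum(overlaps) / len(overlaps)) if overlaps else 0.0
    stats["Augmented clones"] = sum(c.augmented for c in all_clones)
    return stats


def coverage_table(mtp: MTPResult, genome: ReferenceGenome) -> dict[str, int]:
    """Union of MTP spans plus credited extensions, per chromosome and total."""
    table: dict[str, int] = {}
    for chrom in genome.names:
        intervals = [c.covered for c in mtp.clones.get(chrom, [])]
        covered = _interval_union_length(intervals)
        if covered > genome.length(chrom):
            raise AssertionError("coverage exceeds chromosome length")
        table[chrom] = covered
    table["Total"] = sum(v for k, v in table.items() if k != "Total")
    return table


def count_spanned_sequence_gaps(
    mtp: MTPResult, gap_track: list[GapRecord]
) -> dict[str, int]:
    """Scaffold-join gaps spanned or merely entered by MTP clones.

    A gap is spanned when some clone's covered interval strictly contains
    both gap edges; partially filled when an interval reaches into the gap
    without containing both edges.
    """
    spanned = partial = 0
    for g in gap_track:
        if g.gap_class != "scaffold_join":
            continue
        intervals = [c.covered for c in mtp.clones.get(g.chrom, [])]
        if any(s < g.start and e > g.end for s, e in intervals):
            spanned += 1
        elif any(e > g.start and s < g.end for s, e in intervals):
            partial += 1
    return {"spanned": spanned, "partially_filled": partial}
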