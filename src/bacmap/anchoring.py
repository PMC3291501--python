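"""BES-to-reference alignment and clone/contig anchoring.

Reads are placed by exact full-length match (forward or reverse complement)
against a sorted k-mer index of the reference; reads matching zero or more
than one locus are discarded, keeping placements deterministic and
conservative. A clone with both ends on one chromosome gets a span and an
orientation class: a correctly placed pair points toward each other, so
``same_direction`` and ``opposite`` pairs flag potential inversions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.stats import spearmanr

from bacmap.fpc import FPCContig, FPCMap
from bacmap.simulate import BESRead, ReferenceGenome

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass(frozen=True)
class BESHit:
    read_id: str
    chrom: str
    start: int
    end: int
    strand: str  # + | -


@dataclass(frozen=True)
class ClonePlacement:
    """A clone's BES-derived location on the reference.

    ``status`` is one of no_end / one_end / both_diff_chrom /
    both_same_chrom; span fields are set only for both_same_chrom, where the
    span runs between the outermost hit coordinates.
    """

    clone_id: str
    status: str
    chrom: str | None = None
    span_start: int | None = None
    span_end: int | None = None
    orientation_class: str = "not_applicable"
    hits: tuple[BESHit, ...] = ()

    @property
    def span_len(self) -> int | None:
        if self.status != "both_same_chrom":
            return None
        return self.span_end - self.span_start


class _KmerIndex:
    """Sorted 2-bit k-mer codes of one chromosome for exact-seed lookup."""

    def __init__(self, seq: str, k: int):
        self.k = k
        self.seq = seq
        b = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        code = np.full(len(b), -1, dtype=np.int64)
        for base, val in zip(b"ACGT", range(4)):
            code[b == base] = val
        n = len(b) - k + 1
        if n <= 0:
            self.codes = np.empty(0, dtype=np.int64)
            self.positions = np.empty(0, dtype=np.int64)
            return
        kmers = np.zeros(n, dtype=np.int64)
        valid = np.ones(n, dtype=bool)
        for j in range(k):
            window = code[j : j + n]
            kmers = (kmers << 2) | np.maximum(window, 0)
            valid &= window >= 0
        order = np.argsort(kmers[valid], kind="stable")
        self.positions = np.flatnonzero(valid)[order]
        self.codes = kmers[valid][order]

    def lookup(self, query: str) -> np.ndarray:
        """Start positions whose k-mer equals the first k bases of ``query``."""
        code = 0
        for ch in query[: self.k]:
            v = "ACGT".find(ch)
            if v < 0:
                return np.empty(0, dtype=np.int64)
            code = (code << 2) | v
        lo = np.searchsorted(self.codes, code, side="left")
        hi = np.searchsorted(self.codes, code, side="right")
        return self.positions[lo:hi]


def align_bes(
    reads: Iterable[BESRead], genome: ReferenceGenome, seed_len: int = 24
) -> list[BESHit]:
    """Exact-unique full-length alignment of BES reads.

    A read aligns where it (plus strand) or its reverse complement (minus
    strand) matches the reference exactly, located through a ``seed_len``-mer
    index and verified over the full read. Reads with zero or multiple
    distinct matching loci yield no hit.
    """
    reads = list(reads)
    if not reads:
        raise ValueError("no reads to align")
    indexes = {name: _KmerIndex(seq, seed_len) for name, seq in genome.chromosomes.items()}
    hits: list[BESHit] = []
    for read in reads:
        loci: set[tuple[str, int, str]] = set()
        for strand, query in (("+", read.sequence), ("-", _revcomp(read.sequence))):
            for chrom, idx in indexes.items():
                for pos in idx.lookup(query):
                    p = int(pos)
                    if idx.seq[p : p + len(query)] == query:
                        loci.add((chrom, p, strand))
                if len(loci) > 1:
                    break
            if len(loci) > 1:
                break
        if len(loci) == 1:
            chrom, p, strand = next(iter(loci))
            hits.append(BESHit(read.read_id, chrom, p, p + len(read.sequence), strand))
    return hits


def place_clone(clone_id: str, hits: list[BESHit], n_reads_emitted: int) -> ClonePlacement:
    """Classify one clone from its (0-2) retained BES hits."""
    if n_reads_emitted not in (1, 2):
        raise ValueError("a clone emits one or two end reads")
    if len(hits) > 2:
        raise ValueError(f"clone {clone_id}: more than two hits")
    if len(hits) == 0:
        return ClonePlacement(clone_id, "no_end")
    if len(hits) == 1:
        return ClonePlacement(clone_id, "one_end", hits=tuple(hits))
    a, b = hits
    if a.chrom != b.chrom:
        return ClonePlacement(clone_id, "both_diff_chrom", hits=tuple(hits))
    left, right = sorted(hits, key=lambda h: h.start)
    if left.strand == "+" and right.strand == "-":
        orient = "toward"
    elif left.strand == right.strand:
        orient = "same_direction"
    else:
        orient = "opposite"
    span_start = min(a.start, b.start)
    span_end = max(a.end, b.end)
    return ClonePlacement(
        clone_id,
        "both_same_chrom",
        chrom=a.chrom,
        span_start=span_start,
        span_end=span_end,
        orientation_class=orient,
        hits=tuple(hits),
    )


def place_all_clones(
    bes: Iterable[BESRead], hits: Iterable[BESHit]
) -> list[ClonePlacement]:
    """Group hits by clone and place every clone that emitted at least one read."""
    emitted: dict[str, int] = {}
    for read in bes:
        emitted[read.clone_id] = emitted.get(read.clone_id, 0) + 1
    by_clone: dict[str, list[BESHit]] = {cid: [] for cid in emitted}
    for hit in hits:
        cid = hit.read_id.rsplit(".", 1)[0]
        by_clone[cid].append(hit)
    return [
        place_clone(cid, by_clone[cid], emitted[cid]) for cid in sorted(emitted)
    ]


def summarize_placements(
    placements: Iterable[ClonePlacement],
    span_min: int = 75_000,
    span_max: int = 225_000,
    artifact_span: int = 1_500_000,
) -> dict[str, float]:
    """Tallies of placement statuses, span classes and orientation classes.

    Row labels follow the conventional paired-BES alignment summary; the
    orientation classes partition the same-chromosome clones, as do the span
    classes (in-window / short / long, with spans beyond ``artifact_span``
    excluded as artifacts).
    """
    placements = list(placements)
    same = [p for p in placements if p.status == "both_same_chrom"]
    spans = np.array([p.span_len for p in same], dtype=float)
    in_range = ((spans >= span_min) & (spans <= span_max)).sum() if len(spans) else 0
    too_short = (spans < span_min).sum() if len(spans) else 0
    too_long = ((spans > span_max) & (spans <= artifact_span)).sum() if len(spans) else 0
    artifact = (spans > artifact_span).sum() if len(spans) else 0
    summary = {
        "Clones placed": len(placements),
        "Clones where no end aligned": sum(p.status == "no_end" for p in placements),
        "Clones where only one end aligned": sum(p.status == "one_end" for p in placements),
        "Clones where BES aligned to different chromosomes": sum(
            p.status == "both_diff_chrom" for p in placements
        ),
        "Clones where BES aligned to same chromosome": len(same),
        f"{span_min // 1000} kbp < clones < {span_max // 1000} kbp": int(in_range),
        f"Clones < {span_min // 1000} kbp": int(too_short),
        f"Clones > {span_max // 1000} kbp": int(too_long),
        "Clones excluded as artifacts": int(artifact),
        "Clones with BES with expected orientation": sum(
            p.orientation_class == "toward" for p in same
        ),
        "Clones with BES in opposite direction": sum(
            p.orientation_class == "opposite" for p in same
        ),
        "Clones with BES same direction": sum(
            p.orientation_class == "same_direction" for p in same
        ),
        "Mean span, in-window clones": float(
            spans[(spans >= span_min) & (spans <= span_max)].mean()
        )
        if in_range
        else 0.0,
        "Mean span, clones below window": float(spans[spans < span_min].mean())
        if too_short
        else 0.0,
        "Mean span, clones above window": float(
            spans[(spans > span_max) & (spans <= artifact_span)].mean()
        )
        if too_long
        else 0.0,
    }
    # partition checks: every same-chrom clone is in exactly one class per axis
    assert in_range + too_short + too_long + artifact == len(same)
    assert (
        summary["Clones with BES with expected orientation"]
        + summary["Clones with BES in opposite direction"]
        + summary["Clones with BES same direction"]
        == len(same)
    )
    return summary


@dataclass(frozen=True)
class ContigAnchor:
    contig_id: str
    anchored: bool
    chrom: str | None = None
    position: float | None = None
    orientation: int = 1  # +1 / -1


def anchor_contigs(
    fpc_map: FPCMap,
    placements: Iterable[ClonePlacement],
    min_placed: int = 2,
    agreement: float = 0.8,
) -> dict[str, ContigAnchor]:
    """Anchor each contig to the chromosome most of its placed clones agree on.

    A contig anchors when at least ``min_placed`` members have same-chromosome
    placements and at least ``agreement`` of those agree on one chromosome.
    Position is the median member span midpoint; orientation is the sign of
    the Spearman correlation between contig order index and reference
    midpoint (ties and undefined correlations count as +).
    """
    placed = {
        p.clone_id: p for p in placements if p.status == "both_same_chrom"
    }
    anchors: dict[str, ContigAnchor] = {}
    for contig in fpc_map.contigs:
        members = [(i, placed[cid]) for i, cid in enumerate(contig.clones) if cid in placed]
        if len(members) < min_placed:
            anchors[contig.contig_id] = ContigAnchor(contig.contig_id, False)
            continue
        chrom_votes: dict[str, int] = {}
        for _, p in members:
            chrom_votes[p.chrom] = chrom_votes.get(p.chrom, 0) + 1
        chrom, votes = sorted(chrom_votes.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        if votes < agreement * len(members) or votes < min_placed:
            anchors[contig.contig_id] = ContigAnchor(contig.contig_id, False)
            continue
        on_chrom = [(i, p) for i, p in members if p.chrom == chrom]
        mids = [(p.span_start + p.span_end) / 2 for _, p in on_chrom]
        position = float(np.median(mids))
        orientation = 1
        if len(on_chrom) >= 2 and len(set(mids)) > 1:
            rho = spearmanr([i for i, _ in on_chrom], mids).statistic
            if np.isfinite(rho) and rho < 0:
                orientation = -1
        anchors[contig.contig_id] = ContigAnchor(
            contig.contig_id, True, chrom, position, orientation
        )
    return anchors


def merge_contigs_by_reference(
    anchors: dict[str, ContigAnchor],
    fpc_map: FPCMap,
    placements: Iterable[ClonePlacement],
    max_join_gap: int = 150_000,
) -> tuple[FPCMap, int]:
    """Merge reference-adjacent anchored contigs separated by a small gap.

    Two contigs merge when they anchor to the same chromosome, no third
    anchored contig lies between them, and the distance between their nearest
    member-clone span ends is at most ``max_join_gap``. Merging concatenates
    clone orders respecting each contig's orientation; repeated pairwise
    merging closes chains transitively.
    """
    placed = {p.clone_id: p for p in placements if p.status == "both_same_chrom"}

    def ref_extent(contig: FPCContig, chrom: str) -> tuple[int, int] | None:
        spans = [
            (placed[cid].span_start, placed[cid].span_end)
            for cid in contig.clones
            if cid in placed and placed[cid].chrom == chrom
        ]
        if not spans:
            return None
        return min(s for s, _ in spans), max(e for _, e in spans)

    contigs = {c.contig_id: c for c in fpc_map.contigs}
    oriented: dict[str, list[str]] = {}
    for cid, contig in contigs.items():
        anchor = anchors.get(cid)
        clones = list(contig.clones)
        if anchor and anchor.anchored and anchor.orientation < 0:
            clones = clones[::-1]
        oriented[cid] = clones

    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for cid, contig in contigs.items():
        anchor = anchors.get(cid)
        if not anchor or not anchor.anchored:
            continue
        extent = ref_extent(contig, anchor.chrom)
        if extent is None:
            continue
        by_chrom.setdefault(anchor.chrom, []).append((extent[0], extent[1], cid))

    merge_count = 0
    merged_away: set[str] = set()
    chains: dict[str, list[str]] = {cid: [cid] for cid in contigs}
    for chrom, recs in by_chrom.items():
        recs.sort()
        chain_head = recs[0][2]
        chain_end = recs[0][1]
        for start, end, cid in recs[1:]:
            if start - chain_end <= max_join_gap:
                chains[chain_head].append(cid)
                merged_away.add(cid)
                merge_count += 1
            else:
                chain_head = cid
            chain_end = max(chain_end, end)

    def orient_offsets(contig: FPCContig, flipped: bool) -> list[int]:
        if not flipped:
            return list(contig.offsets)
        top = max(contig.offsets)
        return [top - o for o in reversed(contig.offsets)]

    new_contigs: list[FPCContig] = []
    for cid, contig in contigs.items():
        if cid in merged_away:
            continue
        if chains[cid] == [cid]:
            new_contigs.append(contig)
            continue
        clones: list[str] = []
        offsets: list[int] = []
        shift = 0
        for block_id in chains[cid]:
            block = contigs[block_id]
            anchor = anchors.get(block_id)
            flipped = bool(anchor and anchor.anchored and anchor.orientation < 0)
            block_offsets = orient_offsets(block, flipped)
            clones.extend(oriented[block_id])
            offsets.extend(o + shift for o in block_offsets)
            shift += block.cb_length
        new_contigs.append(
            FPCContig(contig_id=cid, clones=clones, offsets=offsets,
                      cb_length=shift)
        )
    return FPCMap(contigs=new_contigs, singletons=list(fpc_map.singletons)), merge_count
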