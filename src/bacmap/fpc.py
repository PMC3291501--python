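"""Fingerprint contig (FPC-style) assembly.

Clones are clustered into contigs by the probability-of-coincidence
(Sulston) score: the binomial tail probability that two fingerprints share
at least the observed number of matching bands by chance. Two clones whose
score falls at or below a cutoff are joined; single-linkage over these
joins defines the contigs. Within a contig, clones are ordered by a greedy
seriation on shared-band counts and given consensus-band (CB) offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import networkx as nx
from scipy.stats import binom

from bacmap.simulate import Fingerprint


@dataclass(frozen=True)
class AssemblyParams:
    """Band-match tolerance, gel resolution and the join cutoff.

    ``gel_space`` is the number of distinguishable band positions G; the
    chance that one band of clone B lands within ``tolerance`` of a given
    band of clone A is approximately 2*tolerance/G per band.
    """

    tolerance: int = 7
    gel_space: int = 3600
    cutoff: float = 1e-12

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.gel_space <= 2 * self.tolerance:
            raise ValueError("gel_space must exceed 2 * tolerance")
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError("cutoff must lie in (0, 1)")


@dataclass
class FPCContig:
    contig_id: str
    clones: list[str]  # ordered left to right
    offsets: list[int]  # CB offset per clone, same order, starting at 0
    cb_length: int

    def __post_init__(self) -> None:
        if len(self.clones) < 2:
            raise ValueError("a contig holds at least two clones")
        if any(o < 0 for o in self.offsets):
            raise ValueError("CB offsets must be non-negative")
        if any(b < a for a, b in zip(self.offsets, self.offsets[1:])):
            raise ValueError("CB offsets must be non-decreasing in clone order")


@dataclass
class FPCMap:
    contigs: list[FPCContig]
    singletons: list[str]

    @property
    def total_cb(self) -> int:
        return sum(c.cb_length for c in self.contigs)

    @property
    def clone_ids(self) -> set[str]:
        ids = set(self.singletons)
        for c in self.contigs:
            ids.update(c.clones)
        return ids

    def clone_to_contig(self) -> dict[str, str | None]:
        """Map every clone to its contig id (None for singletons)."""
        out: dict[str, str | None] = {cid: None for cid in self.singletons}
        for c in self.contigs:
            for cid in c.clones:
                out[cid] = c.contig_id
        return out


def match_bands(a: Fingerprint, b: Fingerprint, tolerance: int) -> int:
    """Greedy one-to-one matching of sorted band lists within ``tolerance``.

    Two-pointer sweep over the sorted lists; a pair matches when the sizes
    differ by at most ``tolerance`` and each band is used at most once. The
    count is symmetric and bounded by the smaller band count.
    """
    xs, ys = sorted(a.bands), sorted(b.bands)
    i = j = m = 0
    while i < len(xs) and j < len(ys):
        d = xs[i] - ys[j]
        if abs(d) <= tolerance:
            m += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return m


def sulston_score(a: Fingerprint, b: Fingerprint, params: AssemblyParams) -> float:
    """Probability of observing >= m matching bands by chance.

    With nL = min(|a|,|b|), nH = max(|a|,|b|) and per-band chance-match
    probability q = 1 - (1 - 2*tolerance/G)^nH, the score is the binomial
    tail P(X >= m) for X ~ Binomial(nL, q). Low scores indicate true overlap.
    """
    m = match_bands(a, b, params.tolerance)
    n_lo = min(len(a.bands), len(b.bands))
    n_hi = max(len(a.bands), len(b.bands))
    q = 1.0 - (1.0 - 2.0 * params.tolerance / params.gel_space) ** n_hi
    return float(binom.sf(m - 1, n_lo, q))


def order_contig(
    clones: list[str], fingerprints: dict[str, Fingerprint], m: dict[tuple[str, str], int]
) -> tuple[list[str], list[int]]:
    """Greedy seriation of one contig by shared-band counts.

    Seed with the pair of largest m (ties: lexicographic ids); repeatedly
    append the unplaced clone with the largest m to either end of the layout.
    A clone appended on the right gets offset(neighbor) + (|neighbor| - m);
    on the left, offset(neighbor) - (|clone| - m). Offsets are then shifted
    to start at 0.
    """
    if len(clones) < 2:
        raise ValueError("order_contig needs at least two clones")

    def mm(x: str, y: str) -> int:
        return m[(x, y)] if (x, y) in m else m[(y, x)]

    pairs = sorted(
        ((mm(x, y), x, y) for i, x in enumerate(clones) for y in clones[i + 1 :]),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    _, left, right = pairs[0]
    order = [left, right]
    offsets = {left: 0, right: len(fingerprints[left].bands) - pairs[0][0]}
    unplaced = sorted(set(clones) - {left, right})
    while unplaced:
        candidates = [
            (mm(cid, endpoint), cid, side)
            for cid in unplaced
            for endpoint, side in ((order[0], "L"), (order[-1], "R"))
        ]
        # largest m wins; ties broken by clone_id, then left end
        m_best, cid, side = sorted(candidates, key=lambda t: (-t[0], t[1], t[2]))[0]
        unplaced.remove(cid)
        if side == "R":
            nb = order[-1]
            offsets[cid] = offsets[nb] + len(fingerprints[nb].bands) - m_best
            order.append(cid)
        else:
            nb = order[0]
            offsets[cid] = offsets[nb] - (len(fingerprints[cid].bands) - m_best)
            order.insert(0, cid)
    shift = -min(offsets.values())
    ordered_offsets = [offsets[c] + shift for c in order]
    # enforce monotone offsets (seriation can locally misplace at zero overlap)
    for i in range(1, len(ordered_offsets)):
        ordered_offsets[i] = max(ordered_offsets[i], ordered_offsets[i - 1])
    return order, ordered_offsets


def cluster_contigs(fingerprints: list[Fingerprint], params: AssemblyParams) -> FPCMap:
    """Single-linkage clustering at the Sulston-score cutoff.

    Every pair scoring at or below ``params.cutoff`` is an edge; connected
    components of two or more clones become contigs (ordered by seriation),
    size-one components become singletons. Deterministic: contigs are
    numbered by their lexicographically smallest member.
    """
    if not fingerprints:
        raise ValueError("need at least one fingerprint")
    fps = {fp.clone_id: fp for fp in fingerprints}
    if len(fps) != len(fingerprints):
        raise ValueError("duplicate clone_id among fingerprints")
    ids = sorted(fps)
    g = nx.Graph()
    g.add_nodes_from(ids)
    m_cache: dict[tuple[str, str], int] = {}
    pairs: list[tuple[str, str]] = []
    m_list: list[int] = []
    for i, x in enumerate(ids):
        for y in ids[i + 1 :]:
            mv = match_bands(fps[x], fps[y], params.tolerance)
            m_cache[(x, y)] = mv
            if mv > 0:
                pairs.append((x, y))
                m_list.append(mv)
    if pairs:
        counts = {cid: len(fp.bands) for cid, fp in fps.items()}
        n_lo = np.array([min(counts[x], counts[y]) for x, y in pairs])
        n_hi = np.array([max(counts[x], counts[y]) for x, y in pairs])
        q = 1.0 - (1.0 - 2.0 * params.tolerance / params.gel_space) ** n_hi
        scores = binom.sf(np.array(m_list) - 1, n_lo, q)
        for (x, y), score in zip(pairs, scores):
            if score <= params.cutoff:
                g.add_edge(x, y)

    contigs: list[FPCContig] = []
    singletons: list[str] = []
    components = sorted((sorted(comp) for comp in nx.connected_components(g)), key=lambda c: c[0])
    for comp in components:
        if len(comp) == 1:
            singletons.append(comp[0])
            continue
        order, offsets = order_contig(comp, fps, m_cache)
        cb_length = max(
            off + len(fps[cid].bands) for cid, off in zip(order, offsets)
        )
        contigs.append(
            FPCContig(
                contig_id=f"ctg_{len(contigs) + 1:04d}",
                clones=order,
                offsets=offsets,
                cb_length=cb_length,
            )
        )
    return FPCMap(contigs=contigs, singletons=sorted(singletons))


#: Contig-size bins, largest first, as (label, lo, hi) with hi inclusive.
HISTOGRAM_BINS: list[tuple[str, int, float]] = [
    (">1000 clones", 1001, float("inf")),
    ("999-800 clones", 800, 999),
    ("799-600 clones", 600, 799),
    ("599-400 clones", 400, 599),
    ("399-200 clones", 200, 399),
    ("199-100 clones", 100, 199),
    ("99-50 clones", 50, 99),
    ("49-25 clones", 25, 49),
    ("24-10 clones", 10, 24),
    ("9-3 clones", 3, 9),
    ("2 clones", 2, 2),
]


def contig_histogram(fpc_map: FPCMap) -> dict[str, int]:
    """Contig counts per size bin, plus the singleton count."""
    counts = {label: 0 for label, _, _ in HISTOGRAM_BINS}
    for contig in fpc_map.contigs:
        n = len(contig.clones)
        for label, lo, hi in HISTOGRAM_BINS:
            if lo <= n <= hi:
                counts[label] += 1
                break
    counts["singletons"] = len(fpc_map.singletons)
    return counts
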