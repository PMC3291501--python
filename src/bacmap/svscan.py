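"""Structural-difference classification from paired-BES clone placements.

A clone library from a query genome, end-sequenced and aligned to a
reference, reveals structural differences through discordant pairs: ends on
different chromosomes suggest translocations; same-chromosome spans longer
than the insert window suggest deletions in the query (extra reference
sequence between the ends), shorter spans suggest insertions; pairs that do
not point toward each other suggest inversions. Spans far beyond the window
are treated as alignment artifacts and excluded from indel tallies.

Indel sizes are estimated against the library's expected insert length:
size = |span - expected_insert|, the only estimator available when each
clone's true insert length is unknown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from bacmap.anchoring import ClonePlacement
from bacmap.simulate import SVEvent

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisParams:
    span_min: int = 75_000
    span_max: int = 225_000
    artifact_span: int = 1_500_000
    expected_insert: int = 150_000

    def __post_init__(self) -> None:
        if not self.span_min < self.span_max < self.artifact_span:
            raise ValueError("require span_min < span_max < artifact_span")


@dataclass(frozen=True)
class SVCall:
    clone_id: str
    span_class: str  # in_range | too_short | too_long | artifact | not_applicable
    orientation_class: str
    interchrom: bool
    candidate_type: str  # none | insertion | deletion | inversion | translocation | artifact
    size_estimate: int | None = None
    chrom: str | None = None
    locus_start: int | None = None
    locus_end: int | None = None
    # second end, populated for interchromosomal (translocation) calls only
    chrom2: str | None = None
    locus2_start: int | None = None
    locus2_end: int | None = None


def classify_sv(placement: ClonePlacement, params: AnalysisParams) -> SVCall:
    """Classify one placement along the span and orientation axes.

    Artifact spans trump everything; otherwise an abnormal orientation is
    called an inversion (whatever the span), and a normal-orientation span
    outside the insert window becomes an indel candidate. The two axes stay
    independently recorded in ``span_class`` and ``orientation_class``.
    """
    if placement.status in ("no_end", "one_end"):
        return SVCall(placement.clone_id, "not_applicable", "not_applicable", False, "none")
    if placement.status == "both_diff_chrom":
        h1, h2 = placement.hits
        return SVCall(
            placement.clone_id, "not_applicable", "not_applicable", True, "translocation",
            chrom=h1.chrom, locus_start=h1.start, locus_end=h1.end,
            chrom2=h2.chrom, locus2_start=h2.start, locus2_end=h2.end,
        )
    span = placement.span_len
    if span > params.artifact_span:
        span_class, ctype, size = "artifact", "artifact", None
    elif span > params.span_max:
        span_class, ctype, size = "too_long", "deletion", span - params.expected_insert
    elif span < params.span_min:
        span_class, ctype, size = "too_short", "insertion", params.expected_insert - span
    else:
        span_class, ctype, size = "in_range", "none", None
    if span_class != "artifact" and placement.orientation_class in ("same_direction", "opposite"):
        # a pair not pointing toward each other is an inversion signature even
        # when its span is also abnormal: clones straddling an inversion edge
        # show exactly this joint pattern, and calling them indels would
        # misattribute the span anomaly
        ctype = "inversion"
        size = None
    return SVCall(
        placement.clone_id,
        span_class,
        placement.orientation_class,
        False,
        ctype,
        size_estimate=size,
        chrom=placement.chrom,
        locus_start=placement.span_start,
        locus_end=placement.span_end,
    )


def sv_summary(calls: Iterable[SVCall]) -> dict[str, float]:
    """Category counts and per-span-class means, with partition checks."""
    calls = list(calls)
    same = [c for c in calls if not c.interchrom and c.span_class != "not_applicable"]
    by_span: dict[str, list[SVCall]] = {}
    for c in same:
        by_span.setdefault(c.span_class, []).append(c)
    spans = {
        c.clone_id: (c.locus_end - c.locus_start)
        for c in same
        if c.locus_start is not None
    }
    summary: dict[str, float] = {
        "Clones where BES aligned to different chromosomes": sum(c.interchrom for c in calls),
        "Clones where BES aligned to same chromosome": len(same),
        "Clones in expected span range": len(by_span.get("in_range", [])),
        "Clones below expected span range": len(by_span.get("too_short", [])),
        "Clones above expected span range": len(by_span.get("too_long", [])),
        "Clones excluded as artifacts": len(by_span.get("artifact", [])),
        "Clones with BES with expected orientation": sum(
            c.orientation_class == "toward" for c in same
        ),
        "Clones with BES in opposite direction": sum(
            c.orientation_class == "opposite" for c in same
        ),
        "Clones with BES same direction": sum(
            c.orientation_class == "same_direction" for c in same
        ),
    }
    for cls, label in (
        ("in_range", "Mean span, expected range"),
        ("too_short", "Mean span, below range"),
        ("too_long", "Mean span, above range"),
    ):
        group = by_span.get(cls, [])
        summary[label] = (
            float(sum(spans[c.clone_id] for c in group) / len(group)) if group else 0.0
        )
    assert (
        summary["Clones in expected span range"]
        + summary["Clones below expected span range"]
        + summary["Clones above expected span range"]
        + summary["Clones excluded as artifacts"]
        == summary["Clones where BES aligned to same chromosome"]
    )
    assert (
        summary["Clones with BES with expected orientation"]
        + summary["Clones with BES in opposite direction"]
        + summary["Clones with BES same direction"]
        == summary["Clones where BES aligned to same chromosome"]
    )
    return summary


def _merge_loci(calls: list[SVCall]) -> list[tuple[int, int, int]]:
    """Union overlapping call loci; each locus gets its mean size estimate.

    The mean over member clones is an (approximately) unbiased event-size
    estimator because individual estimates err by each clone's deviation
    from the expected insert length, which averages out.
    """
    groups: list[tuple[int, int, list[int]]] = []
    for c in sorted(calls, key=lambda c: (c.locus_start, c.locus_end)):
        if groups and c.locus_start < groups[-1][1]:
            s, e, sizes = groups[-1]
            groups[-1] = (s, max(e, c.locus_end), sizes + [c.size_estimate])
        else:
            groups.append((c.locus_start, c.locus_end, [c.size_estimate]))
    return [(s, e, round(sum(sz) / len(sz))) for s, e, sz in groups]


def estimate_flux(calls: Iterable[SVCall]) -> dict[str, int]:
    """Total bp inferred to differ by insertion/deletion between the genomes.

    Overlapping candidate clones over one chromosome are collapsed into loci
    (interval union) so redundant clone coverage of a single event counts
    once; each locus contributes the mean size estimate of its clones.
    """
    per_type: dict[str, int] = {"insertion": 0, "deletion": 0}
    n_loci: dict[str, int] = {"insertion": 0, "deletion": 0}
    for sv_type in per_type:
        group: dict[str, list[SVCall]] = {}
        for c in calls:
            if c.candidate_type == sv_type and c.chrom is not None:
                group.setdefault(c.chrom, []).append(c)
        for chrom_calls in group.values():
            loci = _merge_loci(chrom_calls)
            n_loci[sv_type] += len(loci)
            per_type[sv_type] += sum(sz for _, _, sz in loci)
    return {
        "insertion_bp": per_type["insertion"],
        "deletion_bp": per_type["deletion"],
        "total_flux_bp": per_type["insertion"] + per_type["deletion"],
        "insertion_loci": n_loci["insertion"],
        "deletion_loci": n_loci["deletion"],
    }


def evaluate_against_truth(
    calls: Iterable[SVCall], truth: Iterable[SVEvent]
) -> dict[str, dict[str, float]]:
    """Per-type precision and recall of candidate calls against planted events.

    A call is a true positive when its locus overlaps a truth interval of
    the same type (insertions are points in reference coordinates; their
    truth interval is a 1 bp point at the breakpoint). Translocation calls
    match on either partner chromosome. Empty-versus-empty comparisons score
    1.0 by convention.
    """
    calls = list(calls)
    truth = list(truth)
    #: slack around a truth interval for the clone-resolution of breakpoints
    pad = 225_000
    out: dict[str, dict[str, float]] = {}
    for sv_type in ("insertion", "deletion", "inversion", "translocation"):
        events = [e for e in truth if e.sv_type == sv_type]
        type_calls = [c for c in calls if c.candidate_type == sv_type]
        intervals: list[tuple[str, int, int]] = []
        for e in events:
            size = 1 if sv_type == "insertion" else e.size
            intervals.append((e.ref_chrom, e.ref_start, e.ref_start + size))
            if sv_type == "translocation":
                intervals.append((e.partner_chrom, e.partner_start, e.partner_start + e.size))

        def ends(c: SVCall) -> list[tuple[str, int, int]]:
            res = [(c.chrom, c.locus_start, c.locus_end)]
            if c.chrom2 is not None:
                res.append((c.chrom2, c.locus2_start, c.locus2_end))
            return res

        def overlaps(c: SVCall, iv: tuple[str, int, int]) -> bool:
            chrom, s, e = iv
            lo, hi = s - pad, e + pad
            return any(
                cc == chrom and ce > lo and cs < hi for cc, cs, ce in ends(c)
            )

        def event_intervals(e: SVEvent) -> list[tuple[str, int, int]]:
            size = 1 if e.sv_type == "insertion" else e.size
            res = [(e.ref_chrom, e.ref_start, e.ref_start + size)]
            if e.sv_type == "translocation":
                res.append((e.partner_chrom, e.partner_start, e.partner_start + e.size))
            return res

        tp = sum(1 for c in type_calls if any(overlaps(c, iv) for iv in intervals))
        hit_events = sum(
            1
            for e in events
            if any(overlaps(c, iv) for c in type_calls for iv in event_intervals(e))
        )
        if not events and not type_calls:
            logger.info(
                "no %s events and no %s calls; precision/recall vacuously 1", sv_type, sv_type
            )
            out[sv_type] = {"precision": 1.0, "recall": 1.0}
            continue
        precision = tp / len(type_calls) if type_calls else 1.0
        recall = hit_events / len(events) if events else 1.0
        out[sv_type] = {"precision": precision, "recall": recall}
    return out
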