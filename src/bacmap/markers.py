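"""Genetic-marker tallies against the fingerprint contig map.

Markers (SSR or RFLP probes) screened against BAC libraries hit sets of
clones; hits are summarized per marker into the number of distinct contigs
and clones reached, and multiple-hit markers (MHM, markers anchored to two
or more clones) are classified into three groups: hitting two or more
contigs, hitting multiple clones on a single contig, or hitting only
singleton clones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from bacmap.fpc import FPCMap

MARKER_TYPES = ("SSR", "RFLP")

#: clone-count bins as printed in marker summary tables: 1, 2-4, 5-9, >=10
CLONE_BINS = (("1", 1, 1), ("<5", 2, 4), ("<10", 5, 9), (">=10", 10, float("inf")))


@dataclass(frozen=True)
class MarkerHit:
    marker_id: str
    marker_type: str  # SSR | RFLP
    clone_id: str

    def __post_init__(self) -> None:
        if self.marker_type not in MARKER_TYPES:
            raise ValueError(f"unknown marker type {self.marker_type!r}")


def tally_marker(
    hits: Iterable[MarkerHit], clone_to_contig: Mapping[str, str | None]
) -> dict[str, object]:
    """Summarize one marker's hits: clone count, contig count, MHM class.

    ``clone_to_contig`` maps each mapped clone to its contig id, or None for
    singletons. Singleton hits contribute to the clone count but not to the
    contig count. A marker hitting two or more clones is an MHM:
    ``multi_contig`` when the hit clones lie on two or more contigs,
    ``single_contig_multi_clone`` when they share exactly one contig (even
    if singletons are also hit), ``multi_singleton`` when all hit clones are
    singletons.
    """
    hits = list(hits)
    if not hits:
        raise ValueError("marker has no hits")
    marker_ids = {h.marker_id for h in hits}
    if len(marker_ids) != 1:
        raise ValueError("tally_marker expects hits of a single marker")
    seen = set()
    clones = []
    for h in hits:
        if h.clone_id not in clone_to_contig:
            raise KeyError(f"clone {h.clone_id} unknown to the map")
        if (h.marker_id, h.clone_id) in seen:
            raise ValueError(f"duplicate hit {h.marker_id}/{h.clone_id}")
        seen.add((h.marker_id, h.clone_id))
        clones.append(h.clone_id)
    contigs = {clone_to_contig[c] for c in clones} - {None}
    n_clones, n_contigs = len(clones), len(contigs)
    if n_clones < 2:
        mhm = "none"
    elif n_contigs >= 2:
        mhm = "multi_contig"
    elif n_contigs == 1:
        mhm = "single_contig_multi_clone"
    else:
        mhm = "multi_singleton"
    return {
        "marker_id": hits[0].marker_id,
        "marker_type": hits[0].marker_type,
        "n_clones": n_clones,
        "n_contigs": n_contigs,
        "mhm_class": mhm,
    }


def tally_all_markers(
    hits: Iterable[MarkerHit], fpc_map_or_mapping: FPCMap | Mapping[str, str | None]
) -> pd.DataFrame:
    """Per-marker summaries for a full hit table."""
    mapping = (
        fpc_map_or_mapping.clone_to_contig()
        if isinstance(fpc_map_or_mapping, FPCMap)
        else fpc_map_or_mapping
    )
    by_marker: dict[str, list[MarkerHit]] = {}
    for h in hits:
        by_marker.setdefault(h.marker_id, []).append(h)
    rows = [tally_marker(v, mapping) for _, v in sorted(by_marker.items())]
    return pd.DataFrame(rows)


def marker_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Marker-anchoring summary table with contig and clone-count bins.

    Per marker type: counts of markers hitting 0, 1, 2, or >2 contigs (">2"
    read as "two or more" only for the MHM classification, the contig bins
    here are literal), clone-count bins 1 / 2-4 / 5-9 / >=10, the average
    numbers of contigs and clones hit, and the MHM class totals.
    """
    rows = []
    for mtype in MARKER_TYPES:
        sub = summaries[summaries["marker_type"] == mtype]
        n = len(sub)
        row: dict[str, float] = {"marker_type": mtype, "n_markers": n}
        row["avg_contigs"] = round(float(sub["n_contigs"].mean()), 1) if n else 0.0
        row["avg_clones"] = round(float(sub["n_clones"].mean()), 1) if n else 0.0
        row["contigs_0"] = int((sub["n_contigs"] == 0).sum())
        row["contigs_1"] = int((sub["n_contigs"] == 1).sum())
        row["contigs_2"] = int((sub["n_contigs"] == 2).sum())
        row["contigs_gt2"] = int((sub["n_contigs"] > 2).sum())
        for label, lo, hi in CLONE_BINS:
            row[f"clones_{label}"] = int(sub["n_clones"].between(lo, hi).sum())
        rows.append(row)
    table = pd.DataFrame(rows).set_index("marker_type")
    mhm = summaries["mhm_class"].value_counts()
    for cls in ("multi_singleton", "single_contig_multi_clone", "multi_contig"):
        table.attrs[f"mhm_{cls}"] = int(mhm.get(cls, 0))
    table.attrs["mhm_total"] = sum(
        table.attrs[f"mhm_{c}"]
        for c in ("multi_singleton", "single_contig_multi_clone", "multi_contig")
    )
    # bin partitions must sum to the marker count per type
    for mtype in MARKER_TYPES:
        r = table.loc[mtype]
        assert r["contigs_0"] + r["contigs_1"] + r["contigs_2"] + r["contigs_gt2"] == r["n_markers"]
    return table
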