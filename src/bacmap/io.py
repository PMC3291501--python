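"""Readers and writers for the pipeline's on-disk formats.

Genomes go out as FASTA, gap structure as AGP v2.0, clones / fingerprints /
placements / calls as TSV, and BES hits as BED6. Printed coordinates follow
each format's convention (AGP is 1-based inclusive; BED and internal tables
are 0-based half-open).
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from bacmap.anchoring import BESHit, ClonePlacement
from bacmap.simulate import (
    BESRead,
    CloneRecord,
    Fingerprint,
    GapRecord,
    ReferenceGenome,
    SVEvent,
)


def write_fasta(genome: ReferenceGenome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.chromosomes.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> ReferenceGenome:
    chroms = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return ReferenceGenome(chroms)


_AGP_GAP_TYPE = {"scaffold_join": "scaffold", "unknown_size": "contig", "sized": "contig"}


def write_agp(genome: ReferenceGenome, gaps: list[GapRecord], path: str | Path) -> None:
    """AGP v2.0: component (W) lines between gap (N/U) lines, 1-based inclusive."""
    lines = ["##agp-version\t2.0"]
    by_chrom: dict[str, list[GapRecord]] = {}
    for g in gaps:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in genome.names:
        recs = sorted(by_chrom.get(chrom, []), key=lambda g: g.start)
        pos = 0
        part = 1
        length = genome.length(chrom)
        for g in recs + [None]:
            seg_end = length if g is None else g.start
            if seg_end > pos:
                lines.append(
                    "\t".join(
                        [
                            chrom, str(pos + 1), str(seg_end), str(part), "W",
                            f"{chrom}_part{part}", "1", str(seg_end - pos), "+",
                        ]
                    )
                )
                part += 1
            if g is not None:
                kind = "N" if g.gap_class != "unknown_size" else "U"
                lines.append(
                    "\t".join(
                        [
                            chrom, str(g.start + 1), str(g.end), str(part), kind,
                            str(g.end - g.start), _AGP_GAP_TYPE[g.gap_class], "yes", "paired-ends",
                        ]
                    )
                )
                part += 1
                pos = g.end
        # trailing handled by the sentinel above
    Path(path).write_text("\n".join(lines) + "\n")


def write_clones_tsv(clones: Iterable[CloneRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "clone_id": c.clone_id, "library": c.library, "enzyme": c.enzyme,
                "truth_chrom": c.truth_chrom, "truth_start": c.truth_start,
                "truth_end": c.truth_end,
            }
            for c in clones
        ]
    ).to_csv(path, sep="\t", index=False)


def read_clones_tsv(path: str | Path) -> list[CloneRecord]:
    df = pd.read_csv(path, sep="\t")
    return [CloneRecord(**row) for row in df.to_dict("records")]


def write_bes_fasta(reads: Iterable[BESRead], path: str | Path) -> None:
    records = [SeqRecord(Seq(r.sequence), id=r.read_id, description="") for r in reads]
    SeqIO.write(records, str(path), "fasta")


def write_fingerprints_tsv(fps: Iterable[Fingerprint], path: str | Path) -> None:
    pd.DataFrame(
        [{"clone_id": fp.clone_id, "bands": ",".join(map(str, sorted(fp.bands)))} for fp in fps]
    ).to_csv(path, sep="\t", index=False)


def read_fingerprints_tsv(path: str | Path) -> list[Fingerprint]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        Fingerprint(row["clone_id"], tuple(int(b) for b in row["bands"].split(",")))
        for row in df.to_dict("records")
    ]


def write_sv_truth_tsv(events: Iterable[SVEvent], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sv_id": e.sv_id, "sv_type": e.sv_type, "ref_chrom": e.ref_chrom,
                "ref_start": e.ref_start, "size": e.size,
                "partner_chrom": e.partner_chrom or "", "partner_start": e.partner_start,
            }
            for e in events
        ]
    ).to_csv(path, sep="\t", index=False)


def write_hits_bed(hits: Iterable[BESHit], path: str | Path) -> None:
    rows = [f"{h.chrom}\t{h.start}\t{h.end}\t{h.read_id}\t0\t{h.strand}" for h in hits]
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


def write_placements_tsv(placements: Iterable[ClonePlacement], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "clone_id": p.clone_id, "status": p.status, "chrom": p.chrom or "",
                "span_start": p.span_start, "span_end": p.span_end,
                "span_len": p.span_len, "orientation_class": p.orientation_class,
            }
            for p in placements
        ]
    ).to_csv(path, sep="\t", index=False)


def params_digest(*objects: object) -> str:
    """Stable short hash of parameter objects, for provenance headers."""
    text = "|".join(repr(o) for o in objects)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
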