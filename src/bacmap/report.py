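"""Pipeline driver and printed-report arithmetic.

``run_pipeline`` executes the full chain — simulation, fingerprint contig
assembly, BES anchoring, the four tiling-path variants (clone pool A =
fingerprint-map clones, pool B = all clones with BES; each with and without
unpaired-BES gap augmentation), the paired-BES structural-difference scan
against the planted truth, and marker tallies — and renders every summary
table with a provenance header (seed and parameter hash), so that two runs
with the same configuration are byte-identical.

``percent_of`` centralizes percentage formatting: round half-up at a stated
number of decimals, matching the conventions of printed map reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from bacmap import io as bio
from bacmap.anchoring import (
    align_bes,
    anchor_contigs,
    merge_contigs_by_reference,
    place_all_clones,
    summarize_placements,
)
from bacmap.fpc import AssemblyParams, cluster_contigs, contig_histogram
from bacmap.markers import MarkerHit, marker_table, tally_all_markers
from bacmap.mtp import (
    MTPParams,
    augment_with_unpaired,
    build_mtp,
    count_spanned_sequence_gaps,
    coverage_table,
    mtp_stats,
    select_pool,
)
from bacmap.simulate import (
    GapRecord,
    SimParams,
    SVEvent,
    derive_variant_genome,
    inject_gaps,
    make_reference,
    simulate_library,
)
from bacmap.svscan import (
    AnalysisParams,
    classify_sv,
    estimate_flux,
    evaluate_against_truth,
    sv_summary,
)

logger = logging.getLogger(__name__)


def percent_of(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ``decimals`` places."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    value = Decimal(100 * numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def default_gap_track(n_chrom: int, chrom_length: int) -> list[GapRecord]:
    """Per chromosome: two scaffold-join gaps, an unknown-size gap, and one
    large sized gap (300 kb) that no clone insert can span, so that coverage
    breaks there and only unpaired-BES credit can reach into it."""
    gaps = []
    for i in range(n_chrom):
        chrom = f"chr{i + 1}"
        at = lambda frac: int(chrom_length * frac)
        gaps += [
            GapRecord(chrom, at(0.27), at(0.27) + 1000, "scaffold_join"),
            GapRecord(chrom, at(0.50), at(0.50) + 100, "unknown_size"),
            GapRecord(chrom, at(0.71), at(0.71) + 1000, "scaffold_join"),
            GapRecord(chrom, at(0.90), at(0.90) + 300_000, "sized"),
        ]
    return gaps


def default_sv_events(chrom_length: int) -> list[SVEvent]:
    """Planted structural differences for a two-chromosome simulation.

    Indels of 120-200 kb are comfortably above the ~75 kb detectability
    threshold of a 150 kb insert library; the translocation swaps equal
    blocks between the two chromosomes.
    """
    L = chrom_length
    at = lambda frac: int(L * frac)
    return [
        SVEvent("del1", "deletion", "chr1", at(0.14), 150_000),
        SVEvent("ins1", "insertion", "chr1", at(0.36), 120_000),
        SVEvent("inv1", "inversion", "chr1", at(0.58), 100_000),
        SVEvent(
            "tra1", "translocation", "chr1", at(0.80), 100_000,
            partner_chrom="chr2", partner_start=at(0.80),
        ),
        SVEvent("del2", "deletion", "chr2", at(0.16), 200_000),
        SVEvent("ins2", "insertion", "chr2", at(0.40), 130_000),
        SVEvent("inv2", "inversion", "chr2", at(0.62), 100_000),
    ]


@dataclass
class PipelineConfig:
    """Everything one run needs: scale, libraries, events, parameters, seed."""

    seed: int = 1
    outdir: str | None = None
    n_chrom: int = 2
    chrom_length: int = 5_000_000
    gc: float = 0.35
    #: (library name, cloning enzyme, genome-equivalent coverage)
    libraries: tuple[tuple[str, str, float], ...] = (
        ("LIB_Ha", "HindIII", 4.0),
        ("LIB_Bb", "BstYI", 3.0),
        ("LIB_Ec", "EcoRI", 3.0),
    )
    query_library: tuple[str, str, float] = ("QRY_Ha", "HindIII", 10.0)
    with_markers: bool = True
    n_ssr: int = 60
    n_rflp: int = 20
    sim: SimParams = field(default_factory=SimParams)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    mtp: MTPParams = field(default_factory=MTPParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    gaps: list[GapRecord] | None = None
    sv_events: list[SVEvent] | None = None


def _simulate_marker_hits(
    clones, n_ssr: int, n_rflp: int, genome, rng: np.random.Generator
) -> list[MarkerHit]:
    """Markers as random genomic points hitting every clone that contains them."""
    hits: list[MarkerHit] = []
    names = genome.names
    lengths = np.array([genome.length(c) for c in names], dtype=float)
    probs = lengths / lengths.sum()
    specs = [("SSR", i, f"ssr_{i:04d}") for i in range(n_ssr)] + [
        ("RFLP", i, f"rflp_{i:04d}") for i in range(n_rflp)
    ]
    for mtype, _, marker_id in specs:
        chrom = names[rng.choice(len(names), p=probs)]
        pos = int(rng.integers(0, genome.length(chrom)))
        for c in clones:
            if c.truth_chrom == chrom and c.truth_start <= pos < c.truth_end:
                hits.append(MarkerHit(marker_id, mtype, c.clone_id))
    return hits


def _frame(summary: dict) -> pd.DataFrame:
    return pd.DataFrame({"quantity": list(summary), "value": list(summary.values())})


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Execute every stage and return (and optionally write) the report bundle."""
    seed = config.seed
    rng = np.random.default_rng(seed)
    logger.info("stage: simulate")
    try:
        plain = make_reference(config.n_chrom, config.chrom_length, config.gc, seed)
        gaps = config.gaps if config.gaps is not None else default_gap_track(
            config.n_chrom, config.chrom_length
        )
        reference = inject_gaps(plain, gaps)
        events = (
            config.sv_events
            if config.sv_events is not None
            else default_sv_events(config.chrom_length)
        )
        variant, truth = derive_variant_genome(
            reference, events, seed=(seed + 101) % 2**31, params=config.sim
        )
        # clone DNA comes from the underlying (ungapped) genome; the gapped
        # assembly is only the alignment target, so BES falling inside an
        # assembly gap go unaligned and their clones become unpaired evidence
        ref_libs = []
        for i, (name, enzyme, coverage) in enumerate(config.libraries):
            n_clones = int(
                coverage * plain.total_length / config.sim.insert_mean
            )
            ref_libs.append(
                simulate_library(
                    plain, name, enzyme, n_clones, config.sim,
                    seed=(seed + 7 * i + 11) % 2**31,
                )
            )
        qname, qenzyme, qcov = config.query_library
        n_query = int(qcov * variant.total_length / config.sim.insert_mean)
        query_lib = simulate_library(
            variant, qname, qenzyme, n_query, config.sim, seed=(seed + 503) % 2**31
        )
    except Exception as exc:
        raise PipelineError("simulate", exc) from exc

    logger.info("stage: fpc_assembly")
    try:
        fingerprints = [fp for lib in ref_libs for fp in lib.fingerprints]
        fpc_map = cluster_contigs(fingerprints, config.assembly)
        histogram = contig_histogram(fpc_map)
    except Exception as exc:
        raise PipelineError("fpc_assembly", exc) from exc

    logger.info("stage: anchoring")
    try:
        ref_bes = [r for lib in ref_libs for r in lib.bes]
        ref_hits = align_bes(ref_bes, reference)
        placements = place_all_clones(ref_bes, ref_hits)
        placement_summary = summarize_placements(
            placements,
            span_min=config.analysis.span_min,
            span_max=config.analysis.span_max,
            artifact_span=config.analysis.artifact_span,
        )
        anchors = anchor_contigs(fpc_map, placements)
        merged_map, merge_count = merge_contigs_by_reference(
            anchors, fpc_map, placements, max_join_gap=config.mtp.assumed_insert
        )
    except Exception as exc:
        raise PipelineError("anchoring", exc) from exc

    logger.info("stage: mtp")
    try:
        clone_library = {
            c.clone_id: c.library for lib in ref_libs for c in lib.clones
        }
        lib_names = [name for name, _, _ in config.libraries]
        variants: dict[str, object] = {}
        mtp_tables: dict[str, dict] = {}
        for pool in ("A", "B"):
            paired = select_pool(placements, fpc_map, pool, True, config.mtp)
            base = build_mtp(paired, config.mtp, clone_library)
            unpaired = [
                p
                for p in select_pool(placements, fpc_map, pool, False, config.mtp)
                if p.status == "one_end"
            ]
            augmented, aug_stats = augment_with_unpaired(
                base, unpaired, gaps, config.mtp, clone_library
            )
            for label, result in ((f"pool{pool}_paired", base), (f"pool{pool}_unpaired", augmented)):
                variants[label] = result
                mtp_tables[label] = {
                    "stats": mtp_stats(result, lib_names),
                    "coverage": coverage_table(result, reference),
                    "sequence_gaps": count_spanned_sequence_gaps(result, gaps),
                }
            mtp_tables[f"pool{pool}_unpaired"]["augmentation"] = aug_stats
    except Exception as exc:
        raise PipelineError("mtp", exc) from exc

    logger.info("stage: svscan")
    try:
        query_hits = align_bes(query_lib.bes, reference)
        query_placements = place_all_clones(query_lib.bes, query_hits)
        calls = [classify_sv(p, config.analysis) for p in query_placements]
        call_summary = sv_summary(calls)
        flux = estimate_flux(calls)
        accuracy = evaluate_against_truth(calls, truth)
    except Exception as exc:
        raise PipelineError("svscan", exc) from exc

    marker_bundle = None
    if config.with_markers:
        logger.info("stage: markers")
        try:
            ref_clones = [c for lib in ref_libs for c in lib.clones]
            marker_hits = _simulate_marker_hits(
                ref_clones, config.n_ssr, config.n_rflp, reference, rng
            )
            in_map = fpc_map.clone_ids
            marker_hits = [h for h in marker_hits if h.clone_id in in_map]
            summaries = tally_all_markers(marker_hits, fpc_map)
            marker_bundle = {
                "summaries": summaries,
                "table": marker_table(summaries) if len(summaries) else None,
            }
        except Exception as exc:
            raise PipelineError("markers", exc) from exc

    bundle: dict[str, object] = {
        "reference": reference,
        "variant": variant,
        "gaps": gaps,
        "truth": truth,
        "libraries": ref_libs,
        "query_library": query_lib,
        "fpc_map": fpc_map,
        "merged_map": merged_map,
        "merge_count": merge_count,
        "histogram": histogram,
        "placements": placements,
        "placement_summary": placement_summary,
        "anchors": anchors,
        "mtp_variants": variants,
        "mtp_tables": mtp_tables,
        "sv_calls": calls,
        "sv_summary": call_summary,
        "flux": flux,
        "sv_accuracy": accuracy,
        "markers": marker_bundle,
    }
    if config.outdir:
        _write_bundle(bundle, config)
    return bundle


class PipelineError(RuntimeError):
    """A stage failure with a machine-readable stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.code = f"E_{stage.upper()}"


def _write_bundle(bundle: dict[str, object], config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = bio.params_digest(config.sim, config.assembly, config.mtp, config.analysis)
    header = f"# seed={config.seed} params={digest}\n"

    def write_tsv(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)

    bio.write_fasta(bundle["reference"], outdir / "reference.fa")
    bio.write_fasta(bundle["variant"], outdir / "variant.fa")
    bio.write_agp(bundle["reference"], bundle["gaps"], outdir / "reference.agp")
    bio.write_sv_truth_tsv(bundle["truth"], outdir / "sv_truth.tsv")
    all_clones = [c for lib in bundle["libraries"] for c in lib.clones]
    bio.write_clones_tsv(all_clones, outdir / "clones.tsv")
    bio.write_fingerprints_tsv(
        [fp for lib in bundle["libraries"] for fp in lib.fingerprints],
        outdir / "fingerprints.tsv",
    )
    bio.write_bes_fasta(
        [r for lib in bundle["libraries"] for r in lib.bes], outdir / "bes.fa"
    )
    bio.write_placements_tsv(bundle["placements"], outdir / "placements.tsv")

    fpc_map = bundle["fpc_map"]
    rows = [
        {"contig_id": c.contig_id, "clone_id": cid, "order": i, "cb_offset": off}
        for c in fpc_map.contigs
        for i, (cid, off) in enumerate(zip(c.clones, c.offsets))
    ]
    write_tsv(pd.DataFrame(rows), "fpc_map.tsv")
    write_tsv(
        pd.DataFrame({"clone_id": fpc_map.singletons}), "fpc_singletons.tsv"
    )
    write_tsv(_frame(bundle["histogram"]), "contig_histogram.tsv")
    write_tsv(_frame(bundle["placement_summary"]), "placement_summary.tsv")
    for label, tables in bundle["mtp_tables"].items():
        write_tsv(_frame(tables["stats"]), f"mtp_{label}_stats.tsv")
        write_tsv(_frame(tables["coverage"]), f"mtp_{label}_coverage.tsv")
    for label, result in bundle["mtp_variants"].items():
        rows = [
            {
                "chrom": chrom, "order": i, "clone_id": c.clone_id,
                "span_start": c.start, "span_end": c.end, "library": c.library,
                "augmented": int(c.augmented),
                "credited_start": c.credited_start, "credited_end": c.credited_end,
            }
            for chrom, clones in result.clones.items()
            for i, c in enumerate(clones)
        ]
        write_tsv(pd.DataFrame(rows), f"mtp_{label}.tsv")
    write_tsv(_frame(bundle["sv_summary"]), "sv_summary.tsv")
    write_tsv(_frame(bundle["flux"]), "flux.tsv")
    sv_rows = pd.DataFrame(
        [
            {
                "clone_id": c.clone_id, "chrom": c.chrom or "", "chrom2": c.chrom2 or "",
                "locus_start": c.locus_start, "locus_end": c.locus_end,
                "span_class": c.span_class, "orientation_class": c.orientation_class,
                "candidate_type": c.candidate_type, "size_estimate": c.size_estimate,
            }
            for c in bundle["sv_calls"]
        ]
    )
    write_tsv(sv_rows, "sv_calls.tsv")
    if bundle["markers"]:
        write_tsv(bundle["markers"]["summaries"], "marker_summaries.tsv")
        if bundle["markers"]["table"] is not None:
            table = bundle["markers"]["table"].reset_index()
            write_tsv(table, "marker_table.tsv")
    accuracy = {
        f"{svt}_{k}": v for svt, d in bundle["sv_accuracy"].items() for k, v in d.items()
    }
    (outdir / "sv_accuracy.json").write_text(json.dumps(accuracy, indent=2) + "\n")
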