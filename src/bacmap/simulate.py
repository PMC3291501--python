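"""Synthetic genomes, clone libraries, BES reads and restriction fingerprints.

This module generates the inputs the physical-mapping pipeline consumes:

* a reference genome of random i.i.d. bases with assembly gaps written as
  runs of ``N`` (1000 N = scaffold-join gap, 100 N = unknown-size gap, any
  other run length = sized gap);
* a "sister" genome derived from the reference by planting insertions,
  deletions, inversions and translocations with a recorded truth set;
* BAC clone libraries drawn as partial-digest restriction fragments with
  insert lengths restricted to 75-225 kb (mean ~150 kb);
* paired BAC-end sequences (BES) with occasional single-end failure; and
* restriction fingerprints (complete-digest band-size multisets) with
  multiplicative sizing noise and a small-band detection cutoff.

All operations are pure functions of their inputs plus an explicit seed.
Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: Standard recognition sites for the three library enzymes.
DEFAULT_ENZYMES: dict[str, str] = {
    "HindIII": "AAGCTT",
    "BstYI": "RGATCY",
    "EcoRI": "GAATTC",
}

GAP_RUN_LENGTHS = {"scaffold_join": 1000, "unknown_size": 100}


@dataclass(frozen=True)
class SimParams:
    """Tunable parameters of the clone-library simulation.

    Insert-length limits follow the 75-225 kb acceptance window applied when
    tiling paths are picked; ``artifact_span`` is the span beyond which a
    paired-end placement is treated as an alignment artifact downstream.
    """

    enzymes: tuple[tuple[str, str], ...] = tuple(DEFAULT_ENZYMES.items())
    insert_min: int = 75_000
    insert_max: int = 225_000
    insert_mean: int = 150_000
    #: spread of the gel size-selection around insert_mean; candidate
    #: fragments are kept with probability exp(-(L-mean)^2 / 2 sd^2), so the
    #: library is concentrated near the target insert as real size-selected
    #: BAC libraries are
    insert_sd: int = 15_000
    artifact_span: int = 1_500_000
    bes_len: int = 600
    bes_single_end_prob: float = 0.024
    #: per-site retention of the partial digest; None calibrates it per
    #: enzyme/genome so the mean partial-digest fragment equals insert_mean,
    #: mimicking how digestion time is tuned to the target insert size
    partial_digest_prob: float | None = None
    band_detect_min: int = 600
    #: multiplicative band-sizing error; default keeps the drift of typical
    #: (<= ~10 kb) bands within the assembly band-match tolerance
    sizing_cv: float = 2e-4
    #: fraction of clones whose fingerprinting fails outright (clone keeps
    #: its BES but never enters the fingerprint map) — real libraries lose
    #: 13-59% of clones here, which is why an all-clones pool exists
    fingerprint_fail_prob: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.insert_min < self.insert_mean < self.insert_max < self.artifact_span):
            raise ValueError("require insert_min < insert_mean < insert_max < artifact_span")
        for p in (self.bes_single_end_prob, self.partial_digest_prob):
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def enzyme_pattern(self, name: str) -> str:
        for enz, pat in self.enzymes:
            if enz == name:
                return pat
        raise KeyError(f"unknown enzyme {name!r}")


@dataclass
class ReferenceGenome:
    """A set of named chromosomes; the coordinate frame for everything."""

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome needs at least one chromosome")
        for name, seq in self.chromosomes.items():
            if len(seq) == 0:
                raise ValueError(f"chromosome {name} is empty")

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.chromosomes[chrom]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(f"interval {chrom}:{start}-{end} out of bounds")
        return seq[start:end]


@dataclass(frozen=True)
class GapRecord:
    chrom: str
    start: int
    end: int
    gap_class: str  # scaffold_join | unknown_size | sized

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("gap end must exceed start")
        run = self.end - self.start
        expected = GAP_RUN_LENGTHS.get(self.gap_class)
        if expected is not None and run != expected:
            raise ValueError(f"{self.gap_class} gap must span {expected} bp, got {run}")
        if self.gap_class == "sized" and run in GAP_RUN_LENGTHS.values():
            raise ValueError("sized gap may not use a reserved run length (1000 or 100)")
        if self.gap_class not in ("scaffold_join", "unknown_size", "sized"):
            raise ValueError(f"unknown gap class {self.gap_class!r}")


def validate_gap_track(gaps: list[GapRecord], genome: ReferenceGenome) -> None:
    """Check gap intervals are in bounds and mutually disjoint."""
    by_chrom: dict[str, list[GapRecord]] = {}
    for g in gaps:
        if g.chrom not in genome.chromosomes:
            raise ValueError(f"gap on unknown chromosome {g.chrom}")
        if g.end > genome.length(g.chrom) or g.start < 0:
            raise ValueError(f"gap {g} exceeds chromosome bounds")
        by_chrom.setdefault(g.chrom, []).append(g)
    for recs in by_chrom.values():
        recs.sort(key=lambda g: g.start)
        for a, b in zip(recs, recs[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping gaps {a} and {b}")


@dataclass(frozen=True)
class SVEvent:
    """A planted structural difference, in reference coordinates."""

    sv_id: str
    sv_type: str  # insertion | deletion | inversion | translocation
    ref_chrom: str
    ref_start: int
    size: int
    partner_chrom: str | None = None
    partner_start: int | None = None

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("event size must be positive")
        if self.sv_type not in ("insertion", "deletion", "inversion", "translocation"):
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.sv_type == "translocation" and (
            self.partner_chrom is None or self.partner_start is None
        ):
            raise ValueError("translocation needs partner_chrom and partner_start")


@dataclass(frozen=True)
class CloneRecord:
    clone_id: str
    library: str
    enzyme: str
    truth_chrom: str
    truth_start: int
    truth_end: int

    @property
    def insert_length(self) -> int:
        return self.truth_end - self.truth_start


@dataclass(frozen=True)
class BESRead:
    """One end read of a clone.

    The F read is taken from the left insert end on the plus strand; the R
    read from the right end on the minus strand, so that a correctly placed
    pair points toward each other ("inverted relative to each other").
    Truth fields are simulation bookkeeping only; analysis code never reads
    them.
    """

    clone_id: str
    end_label: str  # F | R
    sequence: str
    truth_chrom: str
    truth_start: int
    truth_strand: str

    @property
    def read_id(self) -> str:
        return f"{self.clone_id}.{self.end_label}"


@dataclass(frozen=True)
class Fingerprint:
    clone_id: str
    bands: tuple[int, ...]  # measured fragment sizes, unordered multiset

    def __post_init__(self) -> None:
        if len(self.bands) == 0:
            raise ValueError("fingerprint must retain at least one band")


class ZeroBandFingerprint(ValueError):
    """Raised when a clone's digest retains no band above the detection cutoff."""


# ---------------------------------------------------------------------------
# reference construction

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def make_reference(
    n_chrom: int, chrom_length: int, gc: float, seed: int, min_length: int | None = None
) -> ReferenceGenome:
    """Generate ``n_chrom`` chromosomes of i.i.d. bases at the given GC fraction.

    ``min_length`` defaults to ten times the largest allowed insert so that
    the genome can host clones at all; shorter requests are rejected.
    """
    if n_chrom < 1:
        raise ValueError("need at least one chromosome")
    floor = 10 * SimParams().insert_max if min_length is None else min_length
    if chrom_length < floor:
        raise ValueError(
            f"chrom_length {chrom_length} too small to host clones (minimum {floor})"
        )
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chroms: dict[str, str] = {}
    for i in range(n_chrom):
        arr = rng.choice(_BASES, size=chrom_length, p=p)
        chroms[f"chr{i + 1}"] = arr.tobytes().decode("ascii")
    return ReferenceGenome(chroms)


def inject_gaps(genome: ReferenceGenome, gaps: list[GapRecord]) -> ReferenceGenome:
    """Return a copy of the genome with ``N`` written over each gap interval."""
    validate_gap_track(gaps, genome)
    chroms = dict(genome.chromosomes)
    for chrom in {g.chrom for g in gaps}:
        seq = bytearray(chroms[chrom], "ascii")
        for g in gaps:
            if g.chrom == chrom:
                seq[g.start : g.end] = b"N" * (g.end - g.start)
        chroms[chrom] = seq.decode("ascii")
    return ReferenceGenome(chroms)


# ---------------------------------------------------------------------------
# structural variants

def _check_event_spacing(events: list[SVEvent], params: SimParams) -> None:
    min_sep = 2 * params.insert_max
    spans: dict[str, list[tuple[int, int, str]]] = {}
    for ev in events:
        spans.setdefault(ev.ref_chrom, []).append((ev.ref_start, ev.ref_start + ev.size, ev.sv_id))
        if ev.sv_type == "translocation":
            spans.setdefault(ev.partner_chrom, []).append(
                (ev.partner_start, ev.partner_start + ev.size, ev.sv_id)
            )
    for recs in spans.values():
        recs.sort()
        for (s1, e1, i1), (s2, e2, i2) in zip(recs, recs[1:]):
            if s2 - e1 < min_sep:
                raise ValueError(
                    f"events {i1} and {i2} closer than {min_sep} bp; "
                    "truth intervals would be ambiguous"
                )


def derive_variant_genome(
    ref: ReferenceGenome, events: list[SVEvent], seed: int, params: SimParams | None = None
) -> tuple[ReferenceGenome, list[SVEvent]]:
    """Apply planted events to a copy of ``ref`` and return the realized truth.

    Events are expressed in reference coordinates and must be separated by at
    least twice the maximum insert length on each chromosome so every clone
    overlaps at most one event. Deletions/insertions on the same chromosome
    are applied right-to-left so recorded reference coordinates stay valid.
    """
    params = params or SimParams()
    _check_event_spacing(events, params)
    rng = np.random.default_rng(seed)
    chroms = dict(ref.chromosomes)

    for ev in events:
        end = ev.ref_start + (0 if ev.sv_type == "insertion" else ev.size)
        if not (0 <= ev.ref_start and end <= len(chroms[ev.ref_chrom])):
            raise ValueError(f"event {ev.sv_id} out of bounds")
        if ev.sv_type == "translocation":
            if ev.partner_start + ev.size > len(chroms[ev.partner_chrom]):
                raise ValueError(f"event {ev.sv_id} partner block out of bounds")

    # Translocations and inversions do not shift coordinates; apply them first.
    for ev in events:
        if ev.sv_type == "inversion":
            seq = chroms[ev.ref_chrom]
            s, e = ev.ref_start, ev.ref_start + ev.size
            chroms[ev.ref_chrom] = (
                seq[:s] + str(Seq(seq[s:e]).reverse_complement()) + seq[e:]
            )
        elif ev.sv_type == "translocation":
            a = chroms[ev.ref_chrom]
            b = chroms[ev.partner_chrom]
            s1, e1 = ev.ref_start, ev.ref_start + ev.size
            s2, e2 = ev.partner_start, ev.partner_start + ev.size
            block1, block2 = a[s1:e1], b[s2:e2]
            if ev.ref_chrom == ev.partner_chrom:
                if s2 < e1:
                    raise ValueError(f"translocation {ev.sv_id} blocks overlap")
                seq = a[:s1] + block2 + a[e1:s2] + block1 + a[e2:]
                chroms[ev.ref_chrom] = seq
            else:
                chroms[ev.ref_chrom] = a[:s1] + block2 + a[e1:]
                chroms[ev.partner_chrom] = b[:s2] + block1 + b[e2:]

    # Indels shift downstream coordinates: apply per chromosome right-to-left.
    indels = [ev for ev in events if ev.sv_type in ("insertion", "deletion")]
    for ev in sorted(indels, key=lambda e: (e.ref_chrom, -e.ref_start)):
        seq = chroms[ev.ref_chrom]
        if ev.sv_type == "deletion":
            chroms[ev.ref_chrom] = seq[: ev.ref_start] + seq[ev.ref_start + ev.size :]
        else:
            ins = rng.choice(_BASES, size=ev.size).tobytes().decode("ascii")
            chroms[ev.ref_chrom] = seq[: ev.ref_start] + ins + seq[ev.ref_start :]

    return ReferenceGenome(chroms), list(events)


# ---------------------------------------------------------------------------
# restriction digestion

def _iupac_regex(pattern: str) -> re.Pattern[str]:
    if not pattern:
        raise ValueError("empty recognition pattern")
    parts = []
    for ch in pattern.upper():
        try:
            bases = ambiguous_dna_values[ch]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {ch!r}") from None
        parts.append(ch if len(bases) == 1 else f"[{bases}]")
    # lookahead so overlapping sites are all reported
    return re.compile("(?=" + "".join(parts) + ")")


def digest_sites(sequence: str, pattern: str) -> list[int]:
    """Sorted 0-based start positions of every IUPAC-pattern match."""
    rx = _iupac_regex(pattern)
    return [m.start() for m in rx.finditer(sequence.upper())]


# ---------------------------------------------------------------------------
# clone sampling

def _chromosome_boundaries(genome: ReferenceGenome, pattern: str) -> dict[str, np.ndarray]:
    """Complete-digest fragment boundaries per chromosome (cut sites + ends)."""
    out = {}
    for chrom, seq in genome.chromosomes.items():
        cuts = digest_sites(seq, pattern)
        bounds = np.unique(np.concatenate([[0], cuts, [len(seq)]]).astype(np.int64))
        out[chrom] = bounds
    return out


def acceptable_fragment_count(bounds: np.ndarray, params: SimParams) -> int:
    """Number of boundary pairs whose distance lies in the insert window."""
    lo = np.searchsorted(bounds, bounds + params.insert_min, side="left")
    hi = np.searchsorted(bounds, bounds + params.insert_max, side="right")
    return int(np.sum(np.maximum(hi - lo, 0)))


def sample_clones(
    genome: ReferenceGenome,
    library: str,
    enzyme: str,
    n_clones: int,
    params: SimParams,
    seed: int | None = None,
    max_attempts_factor: int = 2000,
) -> list[CloneRecord]:
    """Draw ``n_clones`` partial-digest clones with inserts in the size window.

    Each clone starts at a uniformly chosen cut site; subsequent sites are
    retained independently with ``partial_digest_prob`` and the clone ends at
    the first retained site. Draws outside [insert_min, insert_max] are
    rejected outright, and in-window draws pass a Gaussian size-selection
    filter centered on ``insert_mean`` (width ``insert_sd``), emulating the
    gel cut of a size-selected library. Chromosomes are chosen with
    replacement in proportion to their number of acceptable digest fragments.
    """
    if n_clones == 0:
        return []
    seed = params.seed if seed is None else seed
    pattern = params.enzyme_pattern(enzyme)
    bounds = _chromosome_boundaries(genome, pattern)
    chrom_names = list(bounds)
    weights = np.array([acceptable_fragment_count(b, params) for b in bounds.values()], float)
    if weights.sum() == 0:
        raise ValueError(f"no acceptable {enzyme} fragment in any chromosome")
    weights /= weights.sum()

    rng = np.random.default_rng(seed)
    p = params.partial_digest_prob
    if p is None:
        # calibrate retention so the mean partial-digest fragment matches
        # the target insert length: mean fragment = site spacing / retention
        total_len = sum(int(b[-1]) for b in bounds.values())
        total_sites = sum(len(b) - 2 for b in bounds.values())
        spacing = total_len / max(total_sites, 1)
        p = min(1.0, spacing / params.insert_mean)
    clones: list[CloneRecord] = []
    attempts = 0
    max_attempts = max_attempts_factor * n_clones
    while len(clones) < n_clones:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not draw {n_clones} acceptable clones in {max_attempts} attempts"
            )
        chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
        b = bounds[chrom]
        i = int(rng.integers(0, len(b) - 1))
        # geometric number of skipped (unretained) sites; p=1 keeps every site
        skip = 0 if p >= 1.0 else int(rng.geometric(p)) - 1
        j = i + 1 + skip
        if j >= len(b):
            continue
        length = int(b[j] - b[i])
        if not params.insert_min <= length <= params.insert_max:
            continue
        # gel size selection: acceptance peaked at the target insert length
        keep = np.exp(-0.5 * ((length - params.insert_mean) / params.insert_sd) ** 2)
        if rng.random() > keep:
            continue
        clones.append(
            CloneRecord(
                clone_id=f"{library}_{len(clones):06d}",
                library=library,
                enzyme=enzyme,
                truth_chrom=chrom,
                truth_start=int(b[i]),
                truth_end=int(b[j]),
            )
        )
    return clones


# ---------------------------------------------------------------------------
# BES extraction and fingerprinting

def extract_bes(
    clone: CloneRecord,
    genome: ReferenceGenome,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> list[BESRead]:
    """Sequence both insert ends; with ``bes_single_end_prob`` keep only one."""
    if params.bes_len > clone.insert_length:
        raise ValueError("bes_len exceeds insert length")
    rng = rng or np.random.default_rng(params.seed)
    f_seq = genome.fetch(clone.truth_chrom, clone.truth_start, clone.truth_start + params.bes_len)
    r_src = genome.fetch(clone.truth_chrom, clone.truth_end - params.bes_len, clone.truth_end)
    reads = [
        BESRead(clone.clone_id, "F", f_seq, clone.truth_chrom, clone.truth_start, "+"),
        BESRead(
            clone.clone_id,
            "R",
            str(Seq(r_src).reverse_complement()),
            clone.truth_chrom,
            clone.truth_end - params.bes_len,
            "-",
        ),
    ]
    if rng.random() < params.bes_single_end_prob:
        return [reads[int(rng.integers(0, 2))]]
    return reads


def fingerprint_clone(
    clone: CloneRecord,
    genome: ReferenceGenome,
    enzyme: str,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> Fingerprint:
    """Complete-digest fingerprint of the insert with multiplicative sizing noise.

    Fragment sizes are perturbed by independent Normal(1, sizing_cv) factors;
    fragments below ``band_detect_min`` fall off the gel and are dropped.
    Raises :class:`ZeroBandFingerprint` if nothing remains.
    """
    rng = rng or np.random.default_rng(params.seed)
    insert = genome.fetch(clone.truth_chrom, clone.truth_start, clone.truth_end)
    pattern = params.enzyme_pattern(enzyme)
    cuts = digest_sites(insert, pattern)
    bounds = np.unique(np.concatenate([[0], cuts, [len(insert)]]).astype(np.int64))
    sizes = np.diff(bounds).astype(float)
    if params.sizing_cv > 0:
        sizes = sizes * rng.normal(1.0, params.sizing_cv, size=len(sizes))
    measured = np.rint(sizes).astype(int)
    bands = tuple(int(x) for x in measured if x >= params.band_detect_min)
    if not bands:
        raise ZeroBandFingerprint(f"clone {clone.clone_id}: no band >= {params.band_detect_min}")
    return Fingerprint(clone.clone_id, bands)


# ---------------------------------------------------------------------------
# library-scale convenience

@dataclass
class SimulatedLibrary:
    """A clone library with its end reads and fingerprints."""

    library: str
    enzyme: str
    clones: list[CloneRecord]
    bes: list[BESRead]
    fingerprints: list[Fingerprint]


def simulate_library(
    genome: ReferenceGenome,
    library: str,
    enzyme: str,
    n_clones: int,
    params: SimParams,
    seed: int,
    fingerprint_enzyme: str | None = None,
) -> SimulatedLibrary:
    """Sample a library and derive BES and fingerprints for every clone.

    Fingerprinting uses ``fingerprint_enzyme`` (default HindIII) regardless of
    the cloning enzyme, mirroring a single fingerprinting protocol applied to
    all libraries. Clones whose digest retains no band are kept as clones but
    have no fingerprint (they model fingerprinting failures).
    """
    clones = sample_clones(genome, library, enzyme, n_clones, params, seed=seed)
    rng = np.random.default_rng((seed + 1) % 2**31)
    fp_enzyme = fingerprint_enzyme or "HindIII"
    bes: list[BESRead] = []
    fps: list[Fingerprint] = []
    for clone in clones:
        bes.extend(extract_bes(clone, genome, params, rng=rng))
        if rng.random() < params.fingerprint_fail_prob:
            continue
        try:
            fps.append(fingerprint_clone(clone, genome, fp_enzyme, params, rng=rng))
        except ZeroBandFingerprint as exc:
            logger.warning("skipping fingerprint: %s", exc)
    return SimulatedLibrary(library, enzyme, clones, bes, fps)
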