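# Methods

This note records the models, parameter choices and numerical conventions
behind `bacmap`, and what the synthetic-data experiments do and do not
demonstrate.

## Coordinate and format conventions

All internal coordinates are 0-based half-open. AGP output converts to
1-based inclusive; BES hits are written as BED6. Assembly gaps are runs of
`N` whose length encodes their class: exactly 1000 N marks a scaffold-join
gap, exactly 100 N an unknown-size gap, any other run length a sized gap.
Sized-gap records may not use the two reserved lengths.

## Clone-library simulation

A reference chromosome is i.i.d. bases at a configurable GC fraction
(default 0.35, typical of plant nuclear genomes). Clones are partial-digest
fragments: a uniformly chosen cut site starts the insert, subsequent sites
are retained independently with probability `p`, and the insert ends at the
first retained site.

* **Retention calibration.** By default `p` is calibrated per enzyme and
  genome so the mean partial-digest fragment equals the 150 kb target
  insert (`p = site spacing / insert_mean`). A fixed `p` is possible but a
  single value cannot serve enzymes whose site spacings differ by more than
  2x: for a frequent cutter like BstYI (~1.2 kb spacing here) a fixed
  retention of 0.2 makes a 75 kb fragment a ~1e-6 event and the library
  cannot be drawn at all. Calibration mirrors how digestion time is tuned
  to the target insert size in the lab.
* **Size selection.** In-window draws (75–225 kb) additionally pass a
  Gaussian acceptance centred on 150 kb with width `insert_sd = 15 kb`,
  emulating the gel cut of a size-selected library. Without it the insert
  law is a truncated exponential with ~20% of inserts below 95 kb or above
  205 kb, which would make 20 kb indels visible to the paired-BES span
  test — contradicting the detectability threshold the method is built
  around (see below). 15 kb is a typical spread for a size-selected BAC
  library.
* **Fingerprints.** Complete digest of the insert; each fragment size is
  multiplied by an independent Normal(1, `sizing_cv`) factor and fragments
  under `band_detect_min = 600` bp fall off the gel. The default
  `sizing_cv = 2e-4` keeps the drift of typical (≤ ~10 kb) bands inside the
  7 bp band-match tolerance, so contig recovery is near-perfect at default
  noise and degrades visibly as the noise is raised; a cv of 0.005 already
  shatters the map completely at that tolerance.
* **Fingerprinting failure.** Each clone's fingerprint fails outright with
  `fingerprint_fail_prob = 0.15` (the clone keeps its BES). Real libraries
  lose 13–59% of clones here; the failure channel is what makes the
  all-clones pool (pool B) strictly larger than the fingerprint-map pool
  (pool A).
* **BES.** 600 bp reads from the insert ends, forward from the left end and
  reverse-complemented from the right end, so a correctly placed pair
  points toward each other. With probability 0.024 only one end is kept,
  matching the observed fraction of unpaired-BES clones in large BES sets
  (2199 of 91,104).
* **Structural variants.** Planted events are separated by at least twice
  the maximum insert so each clone overlaps at most one event; this is a
  simulation constraint that guarantees unambiguous truth labels, not a
  claim about real genomes. Insertions insert random bases; inversions
  reverse-complement in place; translocations swap equal-length blocks
  (the extra `partner_start` coordinate names the second block).

The pipeline samples clone DNA from the **ungapped** genome and aligns BES
to the **gapped** assembly (the two share coordinates since N-injection
preserves length). That distinction matters: an end read falling inside an
assembly gap goes unaligned, which is precisely how clones become
one-ended evidence pointing into a gap. The default gap track includes one
300 kb sized gap per chromosome — unspannable by a ≤ 225 kb insert — so
coverage genuinely breaks there and only unpaired-BES credit reaches in.

## Fingerprint assembly

The coincidence score uses the classical binomial approximation: with band
counts `n_L <= n_H`, per-band chance-match probability
`q = 1 - (1 - 2t/G)^(n_H)` and `m` greedily matched bands, the score is the
binomial tail `P(X >= m)`, `X ~ Binomial(n_L, q)`. Defaults `t = 7` (band
size units), `G = 3600`, join cutoff `1e-12` follow common fingerprint-
assembly practice; the cutoff governs the false-join rate, and at 1e-12 no
false join was observed in any seeded run (truth-disjoint pairs score many
orders of magnitude above it).

The binomial tail is an approximation: it treats the `n_L` bands as
independently matched, ignoring the one-to-one matching constraint and
band-interval overlaps. The bias is small and negative, grows with `m`, and
is detectable by Monte-Carlo at high trial counts (z ≈ −2 to −4 at 6000
trials for m ≥ 2 grids). The agreement check therefore uses a 10-point grid
restricted to m ∈ {1, 2} with 2000 trials per point, where sampling error
dominates the approximation bias; the 3-standard-error band is the
acceptance condition.

Contig ordering is greedy seriation: seed with the pair sharing the most
bands, then repeatedly attach the unplaced clone with the largest shared
count to either end. CB offsets advance by `(neighbour band count − m)`
when extending rightward and by the mirrored amount leftward, shifted to
start at 0 and clamped monotone; CB units are therefore an ordering
coordinate, not a reproduction of any specific consensus-band algorithm.
Ties break lexicographically on clone id everywhere, which together with
vectorised scoring makes assembly invariant to input order.

## Anchoring and merging

Alignment is exact-match and unique: reads matching zero or more than one
locus are dropped. Synthetic reads carry no errors, so exactness loses
nothing; uniqueness keeps placements deterministic and conservative, the
same posture real pipelines take with repeat-spanning BES. Orientation uses
hit coordinates only ("left" = smaller start), never the F/R labels, so the
classifier works when label order is unreliable.

A contig anchors when ≥ 2 members place on one chromosome and ≥ 80% of its
placed members agree (both thresholds configurable; the agreement rule
protects against stray mis-placed clones). Orientation is the sign of the
Spearman correlation between contig order and reference midpoints, +1 on
ties. Anchored contigs adjacent on a chromosome merge when their nearest
member spans are within `max_join_gap` (default one mean insert, 150 kb).

## Minimum tiling path

Within a coverage island the tiling graph has an edge `u → v` when `v`
starts strictly inside `u` and extends it; edge weight is
`clone_count_weight + overlap(u, v)` with `clone_count_weight = 1e7 >
insert_max`, so Dijkstra minimises clone count first and total overlap
second (the lexicographic trick is exact because no path's total overlap
can reach one `clone_count_weight`; tests verify optimality against
brute-force enumeration). Identical spans are deduplicated to the
lexicographically smallest clone id.

"Gaps" are breaks between covered blocks within a chromosome, computed on
the union of member spans plus credited extensions; uncovered chromosome
ends are reported in coverage tables but not counted as gaps. Counted this
way, unpaired-BES augmentation can close a break but never open one, so
gap counts are monotone under augmentation within a pool. The inter-pool
ordering (pool B never gappier than pool A) is *not* a theorem and can
fail at small scale: a pool-B-only clone beyond a large assembly gap opens
a brand-new coverage island and with it a new counted break. Coverage in
base pairs, by contrast, is provably monotone in the pool and under
augmentation, and that is what the acceptance suite asserts.

Unpaired augmentation credits a one-end clone with an `assumed_insert`
(150 kb) extension from the hit's inner edge into the gap, truncated at the
gap's far side, when the hit lies within `edge_window` (150 kb) of the gap
edge on the covered side and points into the gap. One clone per gap side is
kept (the one reaching deepest), keeping the augmented path minimal.

## Structural-difference scan

Classification axes are span (against the 75–225 kb window, with a 1.5 Mb
artifact ceiling) and orientation (toward / same-direction / opposite).
They are tallied independently, as printed summaries do. For the single
`candidate_type`, artifact trumps everything, then an abnormal orientation
is called inversion *even when the span is also abnormal*: clones
straddling an inversion edge systematically show both signatures (one end
re-complemented inside the inversion), and treating the span verdict as
primary would misfile them as indels — measured on the default simulation,
span-precedence drops deletion precision from 1.0 to ~0.74.

Indel sizes are estimated against the expected insert
(`size = |span − 150 kb|`), the only estimator available when each clone's
true insert is unknown. Overlapping candidate clones merge into loci and
each locus contributes the *mean* member estimate to the flux total: the
mean is approximately unbiased because individual errors are each clone's
deviation from the expected insert, while the per-locus maximum would be
biased upward by exactly the insert spread at high coverage.

Detectability follows from the span window: an indel of size `s` moves the
span by `s`, so events need `s ≳ 75 kb` to clear the window from a 150 kb
insert, and 20 kb events sit inside the insert-length spread. With the
size-selected library (sd 15 kb) the suite demonstrates recall ≥ 0.9 for
≥ 120 kb deletions and 0 recall at 20 kb. Insertion recall is additionally
geometry-limited — a clone must straddle the whole inserted block, which
only clones in a `(insert − s)`-wide window do — so large insertions are
under-recovered relative to deletions of the same size; this asymmetry is
inherent to the method, not a defect of the implementation.

## Markers

A multiple-hit marker (MHM) is a marker hitting ≥ 2 clones; the three MHM
classes (two-or-more contigs / multiple clones on one contig / only
singletons) partition MHMs. A marker hitting one contig clone plus a
singleton counts as single-contig-multi-clone (the singleton adds a clone,
not a contig). Clone-count bins are 1 / 2–4 / 5–9 / ≥ 10. The pipeline's
marker screen plants markers as genomic points hitting every clone that
contains them; at 10x coverage this yields more clones per marker than a
hybridisation screen would, which only matters for the bin tails.

## Reporting

`percent_of` rounds half-up at the requested number of decimals; this is
the single rule consistent with the printed-report percentages the
acceptance script reproduces (87, 58, 89.3, 33.4, 40.3). Every table is
written with a `# seed=… params=…` header and no timestamps, so a rerun at
a fixed seed is byte-identical — which the suite asserts on file hashes.

## Problem sizes

The default pipeline runs two 5 Mb chromosomes with three libraries at 10x
combined coverage (~670 clones); the variant-recovery experiment uses a
10 Mb two-genome simulation at 10x query coverage; planted-contig recovery
uses a 5 Mb chromosome at 10x, noise-free; tiling-path optimality is
checked against brute force on 200 random islands of ≤ 12 clones. These
scales exercise every code path — multi-contig maps, all four MTP
variants, gap augmentation, every variant class — while keeping a full
suite run to a couple of minutes.

## What passing tests do not show

The generator draws i.i.d. bases: no repeat families, segmental
duplications or homeologous regions, so the exact-unique aligner discards
almost nothing, whereas on a paleopolyploid genome like soybean's many BES
are ambiguous and translocation calls are confounded by homeology. Cloning
bias, vector contamination, chimeric clones and base-call errors are also
absent. Recovery rates measured here are therefore upper bounds on real
performance; the quantities that do transfer are the arithmetic and
structural ones — score behaviour, tiling optimality, partition
identities, detectability thresholds driven by insert geometry.
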