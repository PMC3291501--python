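"""Unit and property tests for the synthetic-data generator."""

from __future__ import annotations

import itertools
import re

import numpy as np
import pytest

from bacmap.simulate import (
    GapRecord,
    SimParams,
    SVEvent,
    ZeroBandFingerprint,
    acceptable_fragment_count,
    derive_variant_genome,
    digest_sites,
    extract_bes,
    fingerprint_clone,
    inject_gaps,
    make_reference,
    sample_clones,
)

REVCOMP = str.maketrans("ACGT", "TGCA")


class TestMakeReference:
    def test_length_and_determinism(self):
        g1 = make_reference(1, 2_000_000, 0.5, 7, min_length=1_000_000)
        g2 = make_reference(1, 2_000_000, 0.5, 7, min_length=1_000_000)
        assert g1.names == ["chr1"]
        assert g1.length("chr1") == 2_000_000
        assert g1.chromosomes == g2.chromosomes

    def test_gc_fraction_binomial(self):
        # with n = 6e6 bases, the binomial standard error of the GC fraction
        # is ~2e-4, so +-0.01 is a ~50-sigma window
        g = make_reference(2, 3_000_000, 0.35, 1)
        seq = "".join(g.chromosomes.values())
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.35) < 0.01

    def test_rejects_unusable_scale(self):
        with pytest.raises(ValueError, match="too small"):
            make_reference(1, 100_000, 0.5, 0)


class TestGaps:
    def test_scaffold_join_run(self, small_genome):
        gaps = [GapRecord("chr1", 10_000, 11_000, "scaffold_join")]
        gapped = inject_gaps(small_genome, gaps)
        seq = gapped.chromosomes["chr1"]
        assert seq[10_000:11_000] == "N" * 1000
        assert seq[9_999] != "N" and seq[11_000] != "N"

    def test_unknown_size_run(self, small_genome):
        gapped = inject_gaps(small_genome, [GapRecord("chr1", 500, 600, "unknown_size")])
        assert gapped.chromosomes["chr1"][500:600] == "N" * 100

    def test_empty_track_identity(self, small_genome):
        assert inject_gaps(small_genome, []).chromosomes == small_genome.chromosomes

    def test_gap_class_run_length_coupling(self):
        with pytest.raises(ValueError):
            GapRecord("chr1", 0, 500, "scaffold_join")
        with pytest.raises(ValueError):
            GapRecord("chr1", 0, 1000, "sized")

    def test_overlapping_gaps_rejected(self, small_genome):
        gaps = [
            GapRecord("chr1", 1000, 2000, "scaffold_join"),
            GapRecord("chr1", 1500, 2500, "scaffold_join"),
        ]
        with pytest.raises(ValueError, match="overlap"):
            inject_gaps(small_genome, gaps)


class TestVariantGenome:
    def test_deletion_shortens_exactly(self, small_genome):
        ev = [SVEvent("d", "deletion", "chr1", 1_000_000, 100_000)]
        var, truth = derive_variant_genome(small_genome, ev, seed=3)
        assert var.length("chr1") == small_genome.length("chr1") - 100_000
        assert truth == ev

    def test_insertion_lengthens_exactly(self, small_genome):
        ev = [SVEvent("i", "insertion", "chr1", 1_000_000, 50_000)]
        var, _ = derive_variant_genome(small_genome, ev, seed=3)
        assert var.length("chr1") == small_genome.length("chr1") + 50_000

    def test_inversion_reverse_complements_interval(self, small_genome):
        s, size = 1_000_000, 80_000
        ev = [SVEvent("v", "inversion", "chr1", s, size)]
        var, _ = derive_variant_genome(small_genome, ev, seed=3)
        ref_seq = small_genome.chromosomes["chr1"]
        var_seq = var.chromosomes["chr1"]
        assert len(var_seq) == len(ref_seq)
        assert var_seq[s : s + size] == ref_seq[s : s + size].translate(REVCOMP)[::-1]
        assert var_seq[:s] == ref_seq[:s]
        # complementation swaps A<->T and C<->G, so GC content is conserved
        assert var_seq.count("G") + var_seq.count("C") == ref_seq.count("G") + ref_seq.count("C")

    def test_translocation_swaps_blocks(self):
        g = make_reference(2, 2_250_000, 0.4, 9)
        ev = [
            SVEvent(
                "t", "translocation", "chr1", 500_000, 60_000,
                partner_chrom="chr2", partner_start=1_200_000,
            )
        ]
        var, _ = derive_variant_genome(g, ev, seed=1)
        assert var.chromosomes["chr1"][500_000:560_000] == g.chromosomes["chr2"][1_200_000:1_260_000]
        assert var.chromosomes["chr2"][1_200_000:1_260_000] == g.chromosomes["chr1"][500_000:560_000]
        assert var.total_length == g.total_length

    def test_empty_event_list_identity(self, small_genome):
        var, truth = derive_variant_genome(small_genome, [], seed=0)
        assert var.chromosomes == small_genome.chromosomes
        assert truth == []

    def test_close_events_rejected(self, small_genome):
        ev = [
            SVEvent("a", "deletion", "chr1", 500_000, 100_000),
            SVEvent("b", "deletion", "chr1", 700_000, 100_000),
        ]
        with pytest.raises(ValueError, match="ambiguous"):
            derive_variant_genome(small_genome, ev, seed=0)


class TestDigestSites:
    def test_direct_scan(self):
        assert digest_sites("GAATTCAAGAATTC", "GAATTC") == [0, 8]

    def test_all_n(self):
        assert digest_sites("N" * 100, "GAATTC") == []

    @pytest.mark.parametrize("pattern", ["RGATCY", "AAGCTT", "GANTC"])
    def test_matches_brute_force_iupac_expansion(self, pattern):
        # oracle: expand the IUPAC pattern to all literal words, scan each
        iupac = {
            "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
            "N": "ACGT",
        }
        words = ["".join(w) for w in itertools.product(*(iupac[c] for c in pattern))]
        rng = np.random.default_rng(17)
        seq = "".join(rng.choice(list("ACGT"), size=4000))
        expected = sorted(
            {i for w in words for i in range(len(seq)) if seq.startswith(w, i)}
        )
        assert digest_sites(seq, pattern) == expected


class TestSampleClones:
    def test_insert_length_window(self, small_clones, sim_params):
        assert small_clones
        for c in small_clones:
            assert sim_params.insert_min <= c.insert_length <= sim_params.insert_max

    def test_zero_clones(self, small_genome, sim_params):
        assert sample_clones(small_genome, "L", "HindIII", 0, sim_params) == []

    def test_deterministic_per_seed(self, small_genome, sim_params):
        a = sample_clones(small_genome, "L", "EcoRI", 10, sim_params, seed=3)
        b = sample_clones(small_genome, "L", "EcoRI", 10, sim_params, seed=3)
        assert a == b

    def test_clone_length_law(self, small_genome, sim_params):
        """Sampled insert-length mean vs exhaustive fragment enumeration.

        The sampler draws a uniformly random left cut site, a geometric
        number of skipped sites, and a Gaussian size-selection accept; the
        acceptable-fragment-length mean under that law is computed by
        enumerating every boundary pair (i, j) with weight
        (1-p)^(j-i-1) * exp(-(L-mean)^2 / 2 sd^2) over in-window lengths.
        """
        from bacmap.simulate import _chromosome_boundaries

        clones = sample_clones(small_genome, "L", "HindIII", 300, sim_params, seed=9)
        observed = np.mean([c.insert_length for c in clones])

        bounds = _chromosome_boundaries(small_genome, "AAGCTT")["chr1"]
        spacing = bounds[-1] / (len(bounds) - 2)
        p = min(1.0, spacing / sim_params.insert_mean)
        total_w = 0.0
        total_wl = 0.0
        for i in range(len(bounds) - 1):
            for j in range(i + 1, len(bounds)):
                length = bounds[j] - bounds[i]
                if length > sim_params.insert_max:
                    break
                if length >= sim_params.insert_min:
                    w = (1 - p) ** (j - i - 1) * np.exp(
                        -0.5 * ((length - sim_params.insert_mean) / sim_params.insert_sd) ** 2
                    )
                    total_w += w
                    total_wl += w * length
        expected = total_wl / total_w
        assert abs(observed - expected) / expected < 0.05

    def test_lander_waterman_coverage(self, sim_params):
        """At 10x coverage, ~1 - e^-10 of the genome is covered by >= 1 clone.

        The chromosome is long relative to the insert so end effects (the
        terminal ~150 kb reachable by fewer clone placements) stay below the
        1% budget of the bound.
        """
        genome = make_reference(1, 4_500_000, 0.35, seed=2)
        L = genome.length("chr1")
        n = int(10 * L / sim_params.insert_mean)
        fractions = []
        for seed in range(20):
            clones = sample_clones(genome, "L", "HindIII", n, sim_params, seed=seed)
            covered = np.zeros(L // 1000 + 1, dtype=bool)  # 1 kb resolution
            for c in clones:
                covered[c.truth_start // 1000 : c.truth_end // 1000] = True
            fractions.append(covered.mean())
        assert np.mean(fractions) >= 0.99


class TestBESAndFingerprints:
    def test_always_paired_when_prob_zero(self, small_genome, small_clones):
        params = SimParams(bes_single_end_prob=0.0)
        rng = np.random.default_rng(0)
        for c in small_clones:
            assert len(extract_bes(c, small_genome, params, rng=rng)) == 2

    def test_always_single_when_prob_one(self, small_genome, small_clones):
        params = SimParams(bes_single_end_prob=1.0)
        rng = np.random.default_rng(0)
        for c in small_clones:
            assert len(extract_bes(c, small_genome, params, rng=rng)) == 1

    def test_read_orientation_construction(self, small_genome, small_clones, sim_params):
        c = small_clones[0]
        reads = {r.end_label: r for r in extract_bes(c, small_genome, SimParams())}
        f, r = reads["F"], reads["R"]
        chrom = small_genome.chromosomes[c.truth_chrom]
        assert f.sequence == chrom[c.truth_start : c.truth_start + 600]
        assert f.truth_strand == "+" and r.truth_strand == "-"
        right_end = chrom[c.truth_end - 600 : c.truth_end]
        assert r.sequence == right_end.translate(REVCOMP)[::-1]

    def test_noise_free_bands_are_exact_fragments(self, small_genome, small_clones):
        params = SimParams(sizing_cv=0.0)
        c = small_clones[0]
        fp = fingerprint_clone(c, small_genome, "HindIII", params)
        insert = small_genome.fetch(c.truth_chrom, c.truth_start, c.truth_end)
        cuts = digest_sites(insert, "AAGCTT")
        bounds = [0] + cuts + [len(insert)]
        frags = [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
        expected = sorted(f for f in frags if f >= params.band_detect_min)
        assert sorted(fp.bands) == expected
        # digestion conserves length: retained bands + dropped fragments
        assert sum(frags) == c.insert_length

    def test_identical_clones_identical_fingerprints(self, small_genome, small_clones):
        params = SimParams(sizing_cv=0.0)
        c = small_clones[0]
        fp1 = fingerprint_clone(c, small_genome, "BstYI", params)
        fp2 = fingerprint_clone(c, small_genome, "BstYI", params)
        assert sorted(fp1.bands) == sorted(fp2.bands)

    def test_zero_band_digest_rejected(self, small_genome, small_clones):
        params = SimParams(band_detect_min=300_000, sizing_cv=0.0)
        with pytest.raises(ZeroBandFingerprint):
            fingerprint_clone(small_clones[0], small_genome, "HindIII", params)


def test_acceptable_fragment_count_matches_enumeration(small_genome, sim_params):
    from bacmap.simulate import _chromosome_boundaries

    bounds = _chromosome_boundaries(small_genome, "GAATTC")["chr1"]
    brute = sum(
        1
        for i in range(len(bounds))
        for j in range(i + 1, len(bounds))
        if sim_params.insert_min <= bounds[j] - bounds[i] <= sim_params.insert_max
    )
    assert acceptable_fragment_count(bounds, sim_params) == brute
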