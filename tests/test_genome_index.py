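"""Target-site indexing and Hamming-neighborhood enumeration."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csc.genome_index import (
    NeighborCounts,
    TargetIndex,
    brute_force_site_scan,
    build_target_index,
    hamming_neighbors,
    neighbor_counts,
    reverse_complement,
    write_bed,
)

from conftest import make_genome_with, random_dna


class TestPlantedSites:
    def test_unique_planted_guide_found_at_distance_zero(self, planted_index,
                                                         planted_genome):
        sites = hamming_neighbors(planted_index, planted_genome["unique"], 3)
        exact = [s for s in sites if s.distance == 0]
        assert len(exact) == 1
        site = exact[0]
        assert (site.chrom, site.start, site.strand) == ("chr1", 10_000, "+")
        assert site.protospacer == planted_genome["unique"]
        assert site.pam == "AGG"

    def test_duplicate_protospacer_yields_two_occurrences(self, planted_index,
                                                          planted_genome):
        nc = neighbor_counts(planted_index, planted_genome["dup"])
        assert nc.H0 == 2

    def test_two_mismatch_relative_found_only_at_distance_two(
            self, planted_index, planted_genome):
        nc = neighbor_counts(planted_index, planted_genome["twomm"])
        assert nc.as_tuple() == (0, 0, 1, 0)

    def test_absent_guide_has_empty_neighborhood(self, planted_index,
                                                 planted_genome):
        nc = neighbor_counts(planted_index, planted_genome["absent"])
        assert nc.as_tuple() == (0, 0, 0, 0)
        assert nc.total == 0

    def test_minus_strand_site_reports_plus_strand_coordinates(self):
        # plant a site only on the minus strand: genome carries the reverse
        # complement of protospacer+PAM
        guide = "ATGCATGCATGCATGCATGC"
        rng = np.random.default_rng(11)
        payload = reverse_complement(guide + "TGG")
        genome = {"c": make_genome_with(rng, 5_000, [(2_000, payload)])}
        idx = build_target_index(genome, k=20)
        sites = [s for s in idx.query(guide, 0)]
        assert len(sites) == 1
        s = sites[0]
        assert s.strand == "-"
        assert s.protospacer == guide
        assert s.pam == "TGG"
        # protospacer occupies + strand [2003, 2023) (3-bp PAM sits left)
        assert s.start == 2_003

    def test_repeat_family_of_five_copies_gives_h0_five(self):
        rng = np.random.default_rng(5)
        unit = "GATTACAGATTACAGATTAC" + "CGG"
        positions = [1000, 5000, 9000, 13000, 17000]
        genome = {"c": make_genome_with(rng, 20_000,
                                        [(p, unit) for p in positions])}
        idx = build_target_index(genome, k=20)
        assert idx.neighbor_counts("GATTACAGATTACAGATTAC").H0 == 5


class TestPamHandling:
    def test_non_ngg_pam_site_is_not_reported(self):
        guide = "ACGTACGTACGTACGTACGT"
        rng = np.random.default_rng(3)
        genome = {"c": make_genome_with(rng, 5_000, [(1_000, guide + "TGA")])}
        sites = brute_force_site_scan(genome, guide, 3)
        assert all(s.start != 1_000 or s.strand != "+" for s in sites)
        idx = build_target_index(genome, k=20)
        assert all(s.start != 1_000 or s.strand != "+"
                   for s in idx.query(guide, 0))

    def test_custom_pam_patterns_extend_the_site_set(self):
        guide = "ACGTACGTACGTACGTACGT"
        rng = np.random.default_rng(3)
        genome = {"c": make_genome_with(rng, 5_000, [(1_000, guide + "TAG")])}
        ngg = build_target_index(genome, k=20)
        both = build_target_index(genome, k=20, pam_patterns=("NGG", "NAG"))
        assert ngg.neighbor_counts(guide).H0 == 0
        assert both.neighbor_counts(guide).H0 == 1

    def test_windows_with_ambiguous_bases_are_skipped(self):
        guide = "ACGTACGTACGTACGTACGT"
        seq = guide[:10] + "N" + guide[11:] + "AGG"
        idx = build_target_index({"c": "T" * 30 + seq + "T" * 30}, k=20)
        assert idx.neighbor_counts(guide).total == 0


class TestErrors:
    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError, match="empty genome"):
            build_target_index({}, k=20)

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError, match="19 or 20"):
            build_target_index({"c": "ACGT" * 100}, k=18)

    def test_guide_length_mismatch_rejected(self, planted_index):
        with pytest.raises(ValueError, match="length"):
            planted_index.query("ACGT", 3)

    def test_non_acgt_guide_rejected(self, planted_index):
        with pytest.raises(ValueError, match="non-ACGT"):
            planted_index.query("N" * 20, 3)

    def test_brute_force_refuses_oversized_genome(self):
        big = {"c": "A" * 50_000_001}
        with pytest.raises(ValueError, match="brute-force"):
            brute_force_site_scan(big, "A" * 20)

    def test_brute_force_on_empty_genome_returns_nothing(self):
        assert brute_force_site_scan({"c": ""}, "A" * 20) == []


class TestAltContigs:
    def test_alt_contigs_excluded_when_flagged(self):
        guide = "ACGTACGTACGTACGTACGT"
        rng = np.random.default_rng(9)
        main = make_genome_with(rng, 3_000, [(500, guide + "AGG")])
        alt = make_genome_with(rng, 3_000, [(700, guide + "AGG")])
        genome = {"chr1": main, "chr1_alt": alt}
        keep_all = build_target_index(genome, k=20)
        no_alt = build_target_index(genome, k=20, exclude_alt=True)
        assert keep_all.neighbor_counts(guide).H0 == 2
        assert no_alt.neighbor_counts(guide).H0 == 1


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_trie_matches_brute_force_on_random_genome(self, seed):
        rng = np.random.default_rng(seed)
        genome = {"chr1": random_dna(rng, 100_000)}
        idx = build_target_index(genome, k=20)
        # guides: random, genome-derived, and mutated genome-derived
        guides = [random_dna(rng, 20) for _ in range(10)]
        seq = genome["chr1"]
        for _ in range(10):
            p = int(rng.integers(0, len(seq) - 23))
            g = seq[p : p + 20]
            guides.append(g)
            mut = list(g)
            for pos in rng.choice(20, size=2, replace=False):
                mut[pos] = "ACGT"[(("ACGT".index(mut[pos])) + 1) % 4]
            guides.append("".join(mut))
        expected = brute_force_site_scan(genome, guides, 3)
        for g in guides:
            assert hamming_neighbors(idx, g, 3) == expected[g]

    def test_monotonicity_in_max_distance(self, planted_index,
                                          planted_genome):
        for guide in (planted_genome["unique"], planted_genome["twomm"]):
            prev: set = set()
            for d in range(4):
                cur = {(s.chrom, s.start, s.strand)
                       for s in planted_index.query(guide, d)}
                assert prev <= cur
                prev = cur

    def test_strand_symmetry_of_neighbor_counts(self):
        rng = np.random.default_rng(21)
        genome = {"chr1": random_dna(rng, 50_000)}
        flipped = {"chr1": reverse_complement(genome["chr1"])}
        idx_f = build_target_index(genome, k=20)
        idx_r = build_target_index(flipped, k=20)
        for _ in range(20):
            p = int(rng.integers(0, 50_000 - 23))
            g = genome["chr1"][p : p + 20]
            if "N" in g:
                continue
            assert idx_f.neighbor_counts(g).as_tuple() == \
                idx_r.neighbor_counts(g).as_tuple()

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_property_trie_equals_brute_force_on_tiny_genomes(self, data):
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        genome = {"g": random_dna(rng, 2_000)}
        idx = build_target_index(genome, k=20)
        guide = random_dna(rng, 20)
        assert idx.query(guide, 3) == brute_force_site_scan(genome, guide, 3)


class TestDeterminismAndIO:
    def test_repeated_queries_are_identical(self, planted_index,
                                            planted_genome):
        a = planted_index.query(planted_genome["dup"], 3)
        b = planted_index.query(planted_genome["dup"], 3)
        assert a == b

    def test_index_roundtrip_through_file(self, tmp_path, planted_genome,
                                          planted_index):
        path = tmp_path / "idx.npz"
        planted_index.save(path)
        loaded = TargetIndex.load(path)
        assert loaded.k == planted_index.k
        assert loaded.genome_id == planted_index.genome_id
        g = planted_genome["dup"]
        assert loaded.query(g, 3) == planted_index.query(g, 3)

    def test_bed_export_roundtrips_coordinates(self, tmp_path, planted_index,
                                               planted_genome):
        sites = planted_index.query(planted_genome["unique"], 0)
        path = tmp_path / "sites.bed"
        write_bed(sites, path, name="guide1")
        line = path.read_text().strip().split("\t")
        assert line == ["chr1", "10000", "10020", "guide1", "0", "+"]

    def test_k19_index_supports_19mer_guides(self):
        rng = np.random.default_rng(13)
        guide19 = "GATTACAGATTACAGATTA"
        genome = {"c": make_genome_with(rng, 10_000,
                                        [(4_000, guide19 + "CGG")])}
        idx = build_target_index(genome, k=19)
        nc = idx.neighbor_counts(guide19)
        assert nc.H0 >= 1


def test_neighbor_counts_tally_matches_site_list(planted_index,
                                                 planted_genome):
    for g in (planted_genome["unique"], planted_genome["dup"],
              planted_genome["twomm"]):
        sites = planted_index.query(g, 3)
        nc = planted_index.neighbor_counts(g)
        assert nc.total == len(sites)
        for d in range(4):
            assert getattr(nc, f"H{d}") == sum(
                1 for s in sites if s.distance == d)
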