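"""Nucleotide diversity, AMOVA Phi_ST and haplotype tallies."""

import numpy as np
import pytest

from radpop.diversity import (amova_phi_st, haplotype_census,
                              nucleotide_diversity_genotypes,
                              nucleotide_diversity_sequences, phi_st,
                              phi_st_sequences)
from radpop.simulate import StudyDesign, simulate_genotype_matrix
from tests.conftest import make_matrix


class TestPi:
    def test_two_sequences_one_difference(self):
        assert nucleotide_diversity_sequences(
            ["AAAAAAAAAA", "AAAAAAAAAT"]) == pytest.approx(0.1)

    def test_identical_sequences(self):
        assert nucleotide_diversity_sequences(["ACGT", "ACGT"]) == 0.0

    def test_genotype_site_at_half_frequency(self):
        # 4 diploids, p = 0.5, complete data: brute force over the 28
        # chromosome pairs gives 2p(1-p) * 2n/(2n-1) = 16/28
        gm = make_matrix([[(0, 0)], [(0, 1)], [(1, 1)], [(0, 1)]])
        alleles = [0, 0, 0, 1, 1, 1, 0, 1]
        brute = np.mean([
            alleles[i] != alleles[j]
            for i in range(8) for j in range(i + 1, 8)
        ])
        table = nucleotide_diversity_genotypes(gm)
        pi = table[table.locus == "chr1"].pi.iloc[0]
        assert pi == pytest.approx(brute, abs=1e-12)
        assert pi == pytest.approx(0.5714285714285714)

    def test_genotype_and_sequence_paths_agree(self):
        gm = make_matrix([
            [(0, 1), (0, 0), (1, 1)],
            [(0, 0), (0, 1), (0, 1)],
            [(1, 1), (0, 0), (0, 0)],
        ])
        # explicit haploid sequences: one per allele
        seqs = []
        for s in range(3):
            for a in range(2):
                seqs.append("".join(
                    "T" if gm.gt[s, j, a] else "A" for j in range(3)))
        by_seq = nucleotide_diversity_sequences(seqs)
        table = nucleotide_diversity_genotypes(gm)
        by_gt = table[table.locus == "chr1"].pi.iloc[0]
        # sequence path averages over pairs; genotype path averages the
        # per-site unbiased heterozygosity — identical with complete data
        assert by_gt == pytest.approx(by_seq * 3 / 3)

    def test_all_missing_reports_na(self):
        gm = make_matrix([[(-1, -1)], [(-1, -1)]])
        table = nucleotide_diversity_genotypes(gm)
        assert np.isnan(table[table.locus == "chr1"].pi.iloc[0])


def brute_force_amova(dist, labels):
    """Independent variance-component computation, written from the
    definitional sums of squares."""
    labels = np.asarray(labels)
    N = len(labels)
    pops = sorted(set(labels))
    P = len(pops)
    ss_total = sum(dist[i, j] for i in range(N) for j in range(N)) / (2 * N)
    ss_within = 0.0
    for p in pops:
        idx = [i for i in range(N) if labels[i] == p]
        ss_within += sum(dist[i, j] for i in idx for j in idx) / (2 * len(idx))
    ms_within = ss_within / (N - P)
    ms_among = (ss_total - ss_within) / (P - 1)
    sizes = [sum(labels == p) for p in pops]
    n_c = (N - sum(s * s for s in sizes) / N) / (P - 1)
    sigma_a = (ms_among - ms_within) / n_c
    return max(sigma_a, 0) / (max(sigma_a, 0) + ms_within)


class TestPhiSt:
    def test_matches_brute_force_to_machine_precision(self):
        rng = np.random.default_rng(12)
        seqs = rng.integers(0, 2, size=(8, 5))
        dist = np.array([
            [np.sum(seqs[i] != seqs[j]) for j in range(8)] for i in range(8)
        ], dtype=float)
        labels = np.array(["a"] * 4 + ["b"] * 4)
        phi, _ = amova_phi_st(dist, labels)
        assert phi == pytest.approx(brute_force_amova(dist, labels),
                                    abs=1e-12)

    def test_fixed_differences_give_one(self):
        seqs = ["AAAAA", "AAAAA", "TTTTT", "TTTTT"]
        phi, _ = phi_st_sequences(seqs, ["a", "a", "b", "b"])
        assert phi == 1.0

    def test_identical_frequency_distributions_give_zero(self):
        seqs = ["AAAAA", "TTTTT", "AAAAA", "TTTTT"]
        phi, _ = phi_st_sequences(seqs, ["a", "a", "b", "b"])
        assert phi == pytest.approx(0.0, abs=1e-12)

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(3)
        dist = rng.random((10, 10))
        dist = dist + dist.T
        np.fill_diagonal(dist, 0)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        swapped = np.where(labels == "a", "b", "a")
        assert amova_phi_st(dist, labels)[0] == pytest.approx(
            amova_phi_st(dist, swapped)[0])

    def test_panmictic_splits_average_zero(self):
        design = StudyDesign(n_samples_per_group=10, n_groups=2,
                             n_autosomal_sites=200, n_z_sites=1,
                             group_allele_freq_divergence=0.0, seed=9)
        gm, _ = simulate_genotype_matrix(design)
        rng = np.random.default_rng(77)
        vals = []
        for _ in range(200):
            perm = rng.permutation(gm.n_samples)
            pm = {gm.sample_ids[i]: ("a" if r < gm.n_samples // 2 else "b")
                  for r, i in enumerate(perm)}
            v, _, _ = phi_st(gm, pm, ("a", "b"), per_locus=False)
            vals.append(v)
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        # raw components can be slightly positive after clamping at zero;
        # the mean should sit within sampling error of zero
        assert abs(vals.mean()) < max(2 * se, 0.01)

    def test_fixed_difference_matrix_gives_composite_one(self):
        design = StudyDesign(n_samples_per_group=6, n_groups=2,
                             n_autosomal_sites=150, n_z_sites=1,
                             group_allele_freq_divergence=1.0, seed=13)
        gm, truth = simulate_genotype_matrix(design)
        from radpop.genotypes import extract_biallelic_snps

        auto = gm.take_sites(np.flatnonzero(gm.chrom == "chr1"))
        auto = extract_biallelic_snps(auto)
        pm = dict(zip(gm.sample_ids, truth.groups))
        phi, _, _ = phi_st(auto, pm, ("G0", "G1"), per_locus=False)
        assert phi == 1.0

    def test_insufficient_population_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            phi_st(toy_matrix, {"S0": "a", "S1": "b", "S2": "b"}, ("a", "c"))


class TestHaplotypeCensus:
    def test_identical_sequences_single_haplotype(self):
        census = haplotype_census(
            {f"s{i}": "ACGTACGT" for i in range(5)},
            {f"s{i}": "sp1" for i in range(5)},
        )
        assert census.per_species_counts == {"sp1": 1}

    def test_counts_and_single_mutation_distance(self):
        census = haplotype_census(
            {"a": "AAA", "b": "AAT", "c": "AAT"},
            {"a": "sp1", "b": "sp1", "c": "sp1"},
        )
        assert census.per_species_counts == {"sp1": 2}
        assert census.distances[0, 1] == 1
        assert census.frequency_table["count"].sum() == 3

    def test_disjoint_species_share_nothing(self):
        census = haplotype_census(
            {"a": "AAAA", "b": "AATA", "c": "TTTT", "d": "TTAT"},
            {"a": "sp1", "b": "sp1", "c": "sp2", "d": "sp2"},
        )
        assert census.shared_pairs == []
        assert census.per_species_counts == {"sp1": 2, "sp2": 2}

    def test_shared_haplotype_detected(self):
        census = haplotype_census(
            {"a": "AAAA", "b": "AAAA"},
            {"a": "sp1", "b": "sp2"},
        )
        assert len(census.shared_pairs) == 1

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            haplotype_census({"a": "AAA", "b": "AA"}, {"a": "x", "b": "x"})


class TestFastaLoading:
    def test_aligned_fasta_round_trip(self, tmp_path):
        from radpop.diversity import load_fasta_alignment

        p = tmp_path / "coi.fa"
        p.write_text(">h1\nACGTAC\n>h2\nACGTAT\n>h3\nACGTAT\n")
        seqs = load_fasta_alignment(p)
        census = haplotype_census(seqs, {k: "sp" for k in seqs})
        assert census.per_species_counts == {"sp": 2}
        assert nucleotide_diversity_sequences(list(seqs.values())) == \
            pytest.approx(2 / (3 * 6))

    def test_ragged_alignment_rejected(self, tmp_path):
        from radpop.diversity import load_fasta_alignment

        p = tmp_path / "bad.fa"
        p.write_text(">a\nACGT\n>b\nACG\n")
        with pytest.raises(ValueError):
            load_fasta_alignment(p)
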