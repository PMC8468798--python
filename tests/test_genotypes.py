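"""VCF I/O, site filters, the Hardy-Weinberg screen and biallelic extraction."""

import math
from fractions import Fraction

import numpy as np
import pytest

from radpop.genotypes import (MISSING, extract_biallelic_snps, filter_sites,
                              hwe_screen, read_vcf, write_vcf)
from radpop.hwe import hwe_chi2_p, hwe_exact_p
from tests.conftest import make_matrix

TOY_VCF = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
chr1\t100\t.\tA\tG\t45\tPASS\t.\tGT:AD\t0/1:3,2\t0/0:8,0\t1/1:0,9
chr1\t200\t.\tC\tT\t50\tPASS\t.\tGT:AD\t./.:.\t0/1:6,7\t0/0:11,0
"""


class TestReadVcf:
    def test_toy_vcf_shape_and_content(self, tmp_path):
        p = tmp_path / "toy.vcf"
        p.write_text(TOY_VCF)
        gm = read_vcf(p)
        assert gm.n_samples == 3 and gm.n_sites == 2
        assert gm.sample_ids == ["S1", "S2", "S3"]
        assert gm.pos.tolist() == [100, 200]
        # ./. is preserved as missing, not reference
        assert tuple(gm.gt[0, 1]) == (MISSING, MISSING)
        # AD stored per sample/site
        assert gm.ad[0, 0, :2].tolist() == [3, 2]
        assert gm.ad[0, 1, 0] == MISSING

    def test_vcf_without_gt_raises(self, tmp_path):
        p = tmp_path / "nogt.vcf"
        p.write_text(TOY_VCF.replace("GT:AD", "AD").replace(
            "0/1:3,2", "3,2").replace("0/0:8,0", "8,0").replace(
            "1/1:0,9", "0,9").replace("./.:.", ".").replace(
            "0/1:6,7", "6,7").replace("0/0:11,0", "11,0"))
        with pytest.raises(ValueError, match="GT"):
            read_vcf(p)

    def test_write_read_round_trip(self, tmp_path, sim_cohort):
        gm, _ = sim_cohort
        p = tmp_path / "rt.vcf"
        write_vcf(gm, p)
        back = read_vcf(p)
        assert back.sample_ids == gm.sample_ids
        assert np.array_equal(back.gt, gm.gt)
        assert np.array_equal(back.ad[:, :, :2], gm.ad)
        assert np.array_equal(back.qual, gm.qual)


class TestFilterSites:
    def test_clean_site_retained_unchanged(self):
        gm = make_matrix([[(0, 1)], [(0, 0)], [(1, 1)]])
        out, report = filter_sites(gm)
        assert out.n_sites == 1
        assert np.array_equal(out.gt, gm.gt)

    def test_low_presence_site_dropped(self):
        # 10 samples, 3 missing -> 70% of alleles present < 80%
        rows = [[(0, 1)]] * 7 + [[(-1, -1)]] * 3
        gm = make_matrix(rows)
        out, report = filter_sites(gm)
        assert out.n_sites == 0
        assert report.steps[-1]["removed"] == 1

    def test_heterozygote_with_one_low_allele_invalidated(self):
        ad = [[[4, 11]], [[20, 20]]]
        gm = make_matrix([[(0, 1)], [(0, 1)]], ad_rows=ad)
        out, _ = filter_sites(gm, min_presence=0.0)
        assert tuple(out.gt[0, 0]) == (MISSING, MISSING)
        assert tuple(out.gt[1, 0]) == (0, 1)

    def test_low_qual_site_fully_invalidated(self):
        gm = make_matrix([[(0, 1)], [(0, 1)]], qual=[20.0])
        out, _ = filter_sites(gm)
        assert out.n_sites == 0

    def test_homozygote_ignores_uncalled_allele_depth(self):
        ad = [[[20, 0]], [[0, 20]]]
        gm = make_matrix([[(0, 0)], [(1, 1)]], ad_rows=ad)
        out, _ = filter_sites(gm, min_presence=0.0)
        assert tuple(out.gt[0, 0]) == (0, 0)

    def test_idempotence(self, sim_cohort):
        gm, _ = sim_cohort
        once, _ = filter_sites(gm)
        twice, report = filter_sites(once)
        assert twice.n_sites == once.n_sites
        assert report.steps[-1]["removed"] == 0

    def test_report_arithmetic(self, sim_cohort):
        gm, _ = sim_cohort
        _, report = filter_sites(gm)
        site_steps = [s for s in report.steps if s["unit"] == "sites"]
        for s in site_steps:
            assert s["removed"] + s["retained"] == report.input_sites

    def test_threshold_validation(self, toy_matrix):
        with pytest.raises(ValueError):
            filter_sites(toy_matrix, min_presence=1.5)


def exact_hwe_oracle(n_het, n_hom1, n_hom2):
    """Exact-fraction enumeration of the conditional HWE test."""
    n = n_het + n_hom1 + n_hom2
    n_a = min(n_het + 2 * n_hom1, n_het + 2 * n_hom2)

    def prob(h):
        ha = (n_a - h) // 2
        hb = n - h - ha
        return Fraction(
            math.factorial(n) * 2**h
            * math.factorial(n_a) * math.factorial(2 * n - n_a),
            math.factorial(ha) * math.factorial(hb) * math.factorial(h)
            * math.factorial(2 * n),
        )

    obs = prob(n_het)
    total = sum(prob(h) for h in range(n_a % 2, n_a + 1, 2))
    p = sum(prob(h) for h in range(n_a % 2, n_a + 1, 2) if prob(h) <= obs)
    return float(p / total)


class TestHweScreen:
    def test_perfect_proportions_not_flagged(self):
        assert hwe_exact_p(50, 25, 25) > 0.5

    def test_total_heterozygote_deficit_flagged(self):
        assert hwe_exact_p(0, 50, 50) < 1e-6

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = int(rng.integers(2, 31))
            het = int(rng.integers(0, n + 1))
            hom1 = int(rng.integers(0, n - het + 1))
            hom2 = n - het - hom1
            assert hwe_exact_p(het, hom1, hom2) == pytest.approx(
                exact_hwe_oracle(het, hom1, hom2), rel=1e-9)

    def test_chi2_agrees_on_strong_deviation(self):
        assert hwe_chi2_p(0, 50, 50) < 1e-6

    def test_structure_aware_screen(self):
        # two populations each in HWE at very different frequencies;
        # pooling would create a Wahlund heterozygote deficit
        rng = np.random.default_rng(5)
        rows = []
        for _ in range(30):  # pop A: p = 0.9
            g = rng.random(2) < 0.9
            rows.append([(int(g[0]), int(g[1]))] * 40)
        for _ in range(30):  # pop B: p = 0.1
            g = rng.random(2) < 0.1
            rows.append([(int(g[0]), int(g[1]))] * 40)
        gm = make_matrix(rows)
        pops = {f"S{i}": ("A" if i < 30 else "B") for i in range(60)}
        flagged, table = hwe_screen(gm, pops, alpha=1e-6)
        assert flagged == []
        pooled = {f"S{i}": "all" for i in range(60)}
        flagged_pooled, _ = hwe_screen(gm, pooled, alpha=1e-6)
        assert len(flagged_pooled) > 0

    def test_empty_population_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            hwe_screen(toy_matrix, {"S0": "a"})


class TestBiallelicExtraction:
    def test_triallelic_and_monomorphic_removed(self):
        gm = make_matrix(
            [
                [(0, 1), (0, 0), (0, 2)],
                [(0, 1), (0, 0), (0, 1)],
            ],
            alt=[["G"], ["G"], ["G", "T"]],
        )
        out = extract_biallelic_snps(gm)
        assert out.n_sites == 1
        assert out.pos.tolist() == [10]

    def test_singleton_minor_allele_retained(self):
        gm = make_matrix([[(0, 1)], [(0, 0)], [(0, 0)]])
        assert extract_biallelic_snps(gm).n_sites == 1

    def test_monomorphic_after_invalidation_removed(self):
        ad = [[[4, 4], [20, 20]], [[20, 0], [20, 20]]]
        gm = make_matrix([[(0, 1), (0, 1)], [(0, 0), (0, 1)]], ad_rows=ad)
        filtered, _ = filter_sites(gm, min_presence=0.0)
        out = extract_biallelic_snps(filtered)
        assert out.n_sites == 1
        assert out.pos.tolist() == [20]
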