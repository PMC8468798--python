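import numpy as np
import pytest

from radpop.genotypes import MISSING, GenotypeMatrix


def make_matrix(gt_rows, ad_rows=None, qual=None, chrom=None, pos=None,
                alt=None):
    """Build a small GenotypeMatrix from per-sample genotype tuples.

    ``gt_rows[s][j]`` is a (a0, a1) pair with -1 for missing; depths default
    to 20 reads on each called allele.
    """
    n_samples = len(gt_rows)
    n_sites = len(gt_rows[0])
    gt = np.array(gt_rows, dtype=np.int8)
    n_alleles = 2 if alt is None else 1 + max(len(a) for a in alt)
    if ad_rows is None:
        ad = np.full((n_samples, n_sites, n_alleles), 0, dtype=np.int32)
        for s in range(n_samples):
            for j in range(n_sites):
                for a in gt[s, j]:
                    if a != MISSING:
                        ad[s, j, a] += 20
        ad[np.all(gt == MISSING, axis=2)] = MISSING
    else:
        ad = np.array(ad_rows, dtype=np.int32)
    return GenotypeMatrix(
        sample_ids=[f"S{i}" for i in range(n_samples)],
        chrom=np.array(chrom if chrom is not None else ["chr1"] * n_sites,
                       dtype=object),
        pos=np.array(pos if pos is not None
                     else np.arange(1, n_sites + 1) * 10, dtype=np.int64),
        ref=["A"] * n_sites,
        alt=alt if alt is not None else [["G"]] * n_sites,
        gt=gt,
        ad=ad,
        qual=np.array(qual if qual is not None else [50.0] * n_sites,
                      dtype=float),
    )


@pytest.fixture
def toy_matrix():
    """3 samples x 4 sites: het, hom-alt, missing and monomorphic cases."""
    return make_matrix(
        [
            [(0, 1), (1, 1), (0, 0), (0, 0)],
            [(0, 0), (0, 1), (-1, -1), (0, 0)],
            [(0, 1), (0, 0), (0, 1), (0, 0)],
        ]
    )


@pytest.fixture(scope="session")
def sim_cohort():
    """A moderately sized simulated two-group cohort with known truth."""
    from radpop.simulate import StudyDesign, simulate_genotype_matrix

    design = StudyDesign(
        n_samples_per_group=12, n_groups=2, n_autosomal_sites=600,
        n_z_sites=200, missing_rate=0.1, sex_ratio=0.5,
        group_allele_freq_divergence=0.15, seed=2024,
    )
    return simulate_genotype_matrix(design)
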