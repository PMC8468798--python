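"""Coalescent and ddRAD-like synthetic data with known ground truth.

Every downstream stage of the pipeline (filtering, sexing, diversity,
SFS building, demographic fitting) can be exercised against data whose
generating parameters are recorded, so recovery can be checked exactly.

The coalescent engine samples Hudson-style single-locus genealogies without
recombination (ddRAD loci are short enough that intralocus recombination is
negligible) under piecewise-constant population sizes; mutations follow the
infinite-sites model, so the expected mutation count per frequency class is
``theta / 2`` times the class's branch length.

The genotype emulator mimics the salient features of a ddRAD genotype
matrix: per-site per-sample read depths drawn around a configurable median
(negative-binomial, overdispersed), flat missingness, and sex-dependent
Z-chromosome signal — ZW females are hemizygous on Z, so their Z calls are
emitted as homozygous (as variant callers do on hemizygous data) at about
half the autosomal depth, while ZZ males look autosome-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import sim_branch_1d, sim_branch_2d
from .genotypes import MISSING, GenotypeMatrix
from .sfs import Sfs1D, Sfs2D
from .stepwise import EpochModel

__all__ = [
    "StudyDesign",
    "SimTruth",
    "PAIRWISE_MODELS",
    "simulate_sfs_1d",
    "simulate_sfs_2d",
    "nnd_expected_sfs_2d",
    "simulate_genotype_matrix",
]

# registered two-population models and their parameter names
PAIRWISE_MODELS: dict[str, list[str]] = {
    "neutral_no_divergence": [],
    "split_migration": ["nu1", "nu2", "T", "m"],
    "isolation_with_migration": ["nu1", "nu2", "T", "m12", "m21"],
}


def _derive_seed(seed: int, salt: str) -> int:
    ss = np.random.SeedSequence([seed, abs(hash(salt)) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31 - 1)) + 1


def simulate_sfs_1d(
    n: int,
    model: EpochModel,
    theta: float,
    reps: int,
    seed: int,
) -> Sfs1D:
    """Mean unfolded spectrum over ``reps`` simulated genealogies.

    Entry ``i`` is the expected count of sites whose derived allele is
    carried by ``i`` of the ``n`` sampled chromosomes; a per-entry
    Monte-Carlo standard error is attached as ``stderr``.
    """
    if n < 2:
        raise ValueError("need at least two sampled chromosomes")
    if theta <= 0:
        raise ValueError("theta must be positive")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    nus = np.array([v for v, _ in reversed(model.steps)], dtype=float)
    ts = np.array([t for _, t in reversed(model.steps)], dtype=float)
    total, totalsq = sim_branch_1d(n, nus, ts, model.v_anc, reps,
                                   seed % (2**31 - 1))
    mean = total / reps
    var = np.maximum(totalsq / reps - mean**2, 0.0)
    sfs = Sfs1D(theta / 2.0 * mean, n, folded=False)
    sfs.stderr = theta / 2.0 * np.sqrt(var / reps)
    return sfs


def _unpack_pairwise(model_name: str, params) -> tuple[float, ...]:
    if model_name not in PAIRWISE_MODELS:
        raise KeyError(
            f"unknown pairwise model {model_name!r}; registered: "
            f"{sorted(PAIRWISE_MODELS)}"
        )
    expected = PAIRWISE_MODELS[model_name]
    params = list(params)
    if len(params) != len(expected):
        raise ValueError(
            f"{model_name} takes {len(expected)} parameters {expected}, "
            f"got {len(params)}"
        )
    if model_name == "neutral_no_divergence":
        return 1.0, 1.0, 0.0, 0.0, 0.0
    if model_name == "split_migration":
        nu1, nu2, T, m = params
        return nu1, nu2, T, m, m
    nu1, nu2, T, m12, m21 = params
    return nu1, nu2, T, m12, m21


def simulate_sfs_2d(
    n1: int,
    n2: int,
    model_name: str,
    params,
    theta: float,
    reps: int,
    seed: int,
) -> Sfs2D:
    """Mean joint spectrum from structured-coalescent simulation."""
    if n1 < 1 or n2 < 1:
        raise ValueError("need at least one chromosome per population")
    if theta <= 0 or reps < 1:
        raise ValueError("theta must be positive and reps >= 1")
    nu1, nu2, T, m12, m21 = _unpack_pairwise(model_name, params)
    if nu1 <= 0 or nu2 <= 0 or T < 0 or m12 < 0 or m21 < 0:
        raise ValueError("invalid pairwise model parameters")
    total, totalsq = sim_branch_2d(
        n1, n2, nu1, nu2, T, m12, m21, 1.0, reps, seed % (2**31 - 1)
    )
    mean = total / reps
    var = np.maximum(totalsq / reps - mean**2, 0.0)
    sfs = Sfs2D(theta / 2.0 * mean, n1, n2, folded=False)
    sfs.stderr = theta / 2.0 * np.sqrt(var / reps)
    return sfs


def nnd_expected_sfs_2d(n1: int, n2: int, theta: float = 1.0) -> Sfs2D:
    """Exact expected joint spectrum for a single panmictic population whose
    sample is arbitrarily partitioned into two groups:
    ``E[xi_ij] = theta/(i+j) * C(n1,i) C(n2,j) / C(n1+n2, i+j)``."""
    from math import comb

    data = np.zeros((n1 + 1, n2 + 1))
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            c = i + j
            if 1 <= c <= n1 + n2 - 1:
                data[i, j] = (
                    theta / c * comb(n1, i) * comb(n2, j)
                    / comb(n1 + n2, c)
                )
    return Sfs2D(data, n1, n2, folded=False)


# ---------------------------------------------------------------------------
# ddRAD-like genotype matrices


@dataclass
class StudyDesign:
    """Parameters of a simulated ddRAD cohort.

    ``median_depth`` defaults to 119 reads, a typical per-sample median for
    a well-covered ddRAD library; ``group_allele_freq_divergence`` is a
    Balding-Nichols style F: 0 makes all groups share allele frequencies,
    1 fixes each group for one allele.  ``sex_ratio`` is the fraction of
    females (the ZW, hemizygous sex).
    """

    n_samples_per_group: int = 12
    n_groups: int = 2
    n_autosomal_sites: int = 1000
    n_z_sites: int = 100
    median_depth: float = 119.0
    depth_dispersion: float = 8.0
    missing_rate: float = 0.0
    sex_ratio: float = 0.5
    group_allele_freq_divergence: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples_per_group", "n_groups", "n_autosomal_sites",
                     "n_z_sites"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0 <= self.sex_ratio <= 1):
            raise ValueError("sex_ratio must be in [0, 1]")
        if not (0 <= self.group_allele_freq_divergence <= 1):
            raise ValueError("group_allele_freq_divergence must be in [0, 1]")
        if self.median_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")


@dataclass
class SimTruth:
    """Ground truth accompanying every simulated dataset."""

    design: StudyDesign
    sexes: list[str]
    groups: list[str]
    group_freqs: np.ndarray  # (n_groups, n_sites)
    is_z: np.ndarray

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"sample": [f"S{i:03d}" for i in range(len(self.sexes))],
             "sex": self.sexes, "group": self.groups}
        ).to_csv(path, sep="\t", index=False)


def _nbinom_depth(rng, mean, dispersion, size):
    # negative binomial parameterized by mean and overdispersion "size" r
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_genotype_matrix(design: StudyDesign):
    """Draw a (GenotypeMatrix, SimTruth) pair under the given design."""
    rng = np.random.default_rng(design.seed)
    n_samples = design.n_samples_per_group * design.n_groups
    n_sites = design.n_autosomal_sites + design.n_z_sites
    is_z = np.zeros(n_sites, dtype=bool)
    is_z[design.n_autosomal_sites:] = True

    # ancestral and per-group allele frequencies (Balding-Nichols)
    p_anc = rng.uniform(0.05, 0.95, size=n_sites)
    F = design.group_allele_freq_divergence
    if F == 0:
        freqs = np.tile(p_anc, (design.n_groups, 1))
    elif F == 1:
        freqs = (rng.random((design.n_groups, n_sites))
                 < p_anc[None, :]).astype(float)
    else:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        freqs = rng.beta(a[None, :], b[None, :],
                         size=(design.n_groups, n_sites))

    groups = [f"G{g}" for g in range(design.n_groups)
              for _ in range(design.n_samples_per_group)]
    sexes = ["F" if rng.random() < design.sex_ratio else "M"
             for _ in range(n_samples)]

    gt = np.full((n_samples, n_sites, 2), MISSING, dtype=np.int8)
    ad = np.full((n_samples, n_sites, 2), MISSING, dtype=np.int32)
    for s in range(n_samples):
        g = s // design.n_samples_per_group
        p = freqs[g]
        female = sexes[s] == "F"
        # genotypes
        auto = ~is_z
        gt[s, auto, 0] = rng.random(auto.sum()) < p[auto]
        gt[s, auto, 1] = rng.random(auto.sum()) < p[auto]
        hemi = (rng.random(is_z.sum()) < p[is_z]).astype(np.int8)
        if female:
            gt[s, is_z, 0] = hemi
            gt[s, is_z, 1] = hemi  # hemizygous call reported homozygous
        else:
            gt[s, is_z, 0] = hemi
            gt[s, is_z, 1] = rng.random(is_z.sum()) < p[is_z]
        # depths
        depth = _nbinom_depth(rng, design.median_depth,
                              design.depth_dispersion, n_sites)
        if female:
            depth[is_z] = _nbinom_depth(
                rng, design.median_depth / 2.0, design.depth_dispersion,
                is_z.sum())
        het = gt[s, :, 0] != gt[s, :, 1]
        d_alt = np.where(
            het,
            rng.binomial(depth, 0.5),
            depth * (gt[s, :, 0] == 1),
        )
        ad[s, :, 0] = depth - d_alt
        ad[s, :, 1] = d_alt
    # flat missingness
    miss = rng.random((n_samples, n_sites)) < design.missing_rate
    gt[miss] = MISSING
    ad[miss] = MISSING

    chrom = np.array(
        ["chr1"] * design.n_autosomal_sites + ["chrZ"] * design.n_z_sites,
        dtype=object,
    )
    pos = np.concatenate([
        np.arange(1, design.n_autosomal_sites + 1) * 100,
        np.arange(1, design.n_z_sites + 1) * 100,
    ]).astype(np.int64)
    gm = GenotypeMatrix(
        sample_ids=[f"S{i:03d}" for i in range(n_samples)],
        chrom=chrom,
        pos=pos,
        ref=["A"] * n_sites,
        alt=[["G"]] * n_sites,
        gt=gt,
        ad=ad,
        qual=np.full(n_sites, 60.0),
    )
    truth = SimTruth(design, sexes, groups, freqs, is_z)
    return gm, truth
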