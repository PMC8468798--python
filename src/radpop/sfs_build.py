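"""Build site-frequency spectra from genotype matrices."""

from __future__ import annotations

import numpy as np

from .genotypes import MISSING, GenotypeMatrix
from .sfs import Sfs1D, Sfs2D, projection_weights

__all__ = ["build_sfs_1d", "build_sfs_2d"]


def build_sfs_1d(
    gm: GenotypeMatrix,
    samples: list[int] | None = None,
    projection_n: int | None = None,
    allele: int = 1,
) -> Sfs1D:
    """Tally alternate-allele counts per site into an unfolded spectrum.

    Sites with missing alleles are hypergeometrically projected down to
    ``projection_n`` sampled chromosomes when given (their fractional
    contributions sum to one per site); without projection, incomplete sites
    are dropped.  ``L`` records the number of contributing sites.
    """
    sel = slice(None) if samples is None else samples
    gt = gm.gt[sel]
    n_full = gt.shape[0] * 2
    n = projection_n if projection_n is not None else n_full
    if n < 2:
        raise ValueError("need at least two haploid samples")
    if projection_n is not None and projection_n > n_full:
        raise ValueError("projection size exceeds the sampled alleles")
    hits = (gt == allele).sum(axis=(0, 2))
    called = (gt != MISSING).sum(axis=(0, 2))
    data = np.zeros(n + 1)
    L = 0
    for j in range(gm.n_sites):
        c, a = int(called[j]), int(hits[j])
        if projection_n is None:
            if c == n_full:
                data[a] += 1
                L += 1
        elif c >= projection_n:
            data += projection_weights(c, projection_n, a)
            L += 1
    if L == 0:
        raise ValueError(
            "no site has enough called alleles for the requested projection"
        )
    return Sfs1D(data, n, folded=False, L=L)


def build_sfs_2d(
    gm: GenotypeMatrix,
    samples1: list[int],
    samples2: list[int],
    allele: int = 1,
) -> Sfs2D:
    """Joint spectrum over two sample groups (complete-data sites only)."""
    g1, g2 = gm.gt[samples1], gm.gt[samples2]
    n1, n2 = g1.shape[0] * 2, g2.shape[0] * 2
    data = np.zeros((n1 + 1, n2 + 1))
    L = 0
    for j in range(gm.n_sites):
        a, b = g1[:, j], g2[:, j]
        if np.any(a == MISSING) or np.any(b == MISSING):
            continue
        data[(a == allele).sum(), (b == allele).sum()] += 1
        L += 1
    return Sfs2D(data, n1, n2, folded=False, L=L)
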