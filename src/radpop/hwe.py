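"""Exact (and chi-square) tests for Hardy-Weinberg genotype proportions.

The exact test conditions on the observed allele counts and sums the
probabilities of all heterozygote counts no more likely than the observed
one — the standard conditional exact test used by variant-filtering tools.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

__all__ = ["hwe_exact_p", "hwe_chi2_p"]


def _log_prob_het(n_het: int, n_a: int, n: int) -> float:
    """log P(het count | n diploids, n_a copies of allele a), conditional on
    the allele counts, under random union of gametes."""
    n_hom_a = (n_a - n_het) // 2
    n_hom_b = n - n_het - n_hom_a
    return (
        gammaln(n + 1)
        - gammaln(n_hom_a + 1)
        - gammaln(n_hom_b + 1)
        - gammaln(n_het + 1)
        + n_het * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(2 * n - n_a + 1)
        - gammaln(2 * n + 1)
    )


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value from genotype counts."""
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_a = min(n_het + 2 * n_hom1, n_het + 2 * n_hom2)  # rarer allele copies
    obs_lp = _log_prob_het(n_het, n_a, n)
    # heterozygote count shares parity with the rarer-allele count
    hets = range(n_a % 2, n_a + 1, 2)
    lps = np.array([_log_prob_het(h, n_a, n) for h in hets])
    lmax = lps.max()
    total = np.exp(lps - lmax).sum()
    p = np.exp(lps[lps <= obs_lp + 1e-12] - lmax).sum() / total
    return float(min(1.0, p))


def hwe_chi2_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """One-degree-of-freedom chi-square Hardy-Weinberg p-value."""
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    p = (2 * n_hom1 + n_het) / (2 * n)
    q = 1 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_hom1, n_het, n_hom2], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.nansum(
            np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0)
        )
    return float(chi2.sf(stat, df=1))
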