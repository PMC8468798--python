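"""Genetic sexing from Z-chromosome vs autosome coverage and heterozygosity.

In birds, males are ZZ and females ZW: loci mapping to the Z chromosome are
recovered in females at roughly half the male sequencing depth and appear
homozygous (a hemizygous locus has one allele).  Each sample's Z/autosome
depth ratio is normalized by the cohort's male mode, so absolute library
depth differences cancel; a female call additionally requires near-zero Z
heterozygosity relative to autosomal heterozygosity, while depth alone
suffices for a male call.  Samples between the two modes stay unassigned
with both evidence values reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = ["SexCall", "assign_sex"]


@dataclass
class SexCall:
    sample_id: str
    z_autosome_depth_ratio: float
    z_heterozygosity: float
    autosomal_heterozygosity: float
    call: str  # "female" | "male" | "unassigned"


def _mean_depth(ad: np.ndarray) -> float:
    d = ad.astype(float)
    d[d == MISSING] = np.nan
    site_depth = np.nansum(np.where(np.isnan(d), np.nan, d), axis=1)
    site_depth[np.all(np.isnan(d), axis=1)] = np.nan
    return float(np.nanmean(site_depth)) if np.any(~np.isnan(site_depth)) else np.nan


def _het_fraction(gt: np.ndarray) -> float:
    called = np.all(gt != MISSING, axis=1)
    if called.sum() == 0:
        return np.nan
    het = gt[called, 0] != gt[called, 1]
    return float(het.mean())


def assign_sex(
    gm: GenotypeMatrix,
    z_chromosomes: set[str],
    female_ratio_max: float = 0.65,
    male_ratio_min: float = 0.85,
    het_ratio_max_for_female: float = 0.1,
) -> list[SexCall]:
    """Assign genetic sex per sample.

    The raw per-sample ratio (mean Z depth / mean autosomal depth) is
    normalized by the cohort male mode, estimated as the median of the upper
    ratio cluster; a cohort therefore needs at least some males for the
    normalization to be meaningful.
    """
    z_sel = np.isin(gm.chrom, list(z_chromosomes))
    if not z_sel.any():
        raise ValueError("no sites on the given Z chromosome(s)")
    if z_sel.all():
        raise ValueError("no autosomal sites available")
    raw = np.empty(gm.n_samples)
    z_het = np.empty(gm.n_samples)
    a_het = np.empty(gm.n_samples)
    for s in range(gm.n_samples):
        dz = _mean_depth(gm.ad[s, z_sel])
        da = _mean_depth(gm.ad[s, ~z_sel])
        raw[s] = dz / da if da and da > 0 else np.nan
        z_het[s] = _het_fraction(gm.gt[s, z_sel])
        a_het[s] = _het_fraction(gm.gt[s, ~z_sel])
    finite = raw[np.isfinite(raw)]
    if finite.size == 0:
        raise ValueError("no sample has usable depth data")
    upper = finite[finite >= 0.75 * np.quantile(finite, 0.95)]
    male_mode = float(np.median(upper))
    calls = []
    for s in range(gm.n_samples):
        ratio = raw[s] / male_mode if np.isfinite(raw[s]) else np.nan
        if np.isfinite(a_het[s]) and a_het[s] > 0:
            het_ratio = z_het[s] / a_het[s]
        else:
            het_ratio = np.nan
        if not np.isfinite(ratio):
            call = "unassigned"
        elif ratio >= male_ratio_min:
            call = "male"
        elif ratio <= female_ratio_max and (
            np.isfinite(het_ratio) and het_ratio <= het_ratio_max_for_female
        ):
            call = "female"
        else:
            call = "unassigned"
        calls.append(
            SexCall(gm.sample_ids[s], float(ratio), float(z_het[s]),
                    float(a_het[s]), call)
        )
    return calls


def sex_calls_to_frame(calls: list[SexCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"sample": c.sample_id, "depth_ratio": c.z_autosome_depth_ratio,
             "z_het": c.z_heterozygosity, "auto_het": c.autosomal_heterozygosity,
             "call": c.call}
            for c in calls
        ]
    )
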