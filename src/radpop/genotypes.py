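"""Genotype matrix container, VCF I/O and ddRAD-style site filtering.

Filtering follows the retention rules typical for ddRAD genotype matrices:
a called allele needs a minimum per-allele read depth (default 5x, i.e. 10x
for a homozygous genotype), the site needs a minimum PHRED quality (default
30), and a site is kept only if at least a minimum fraction of alleles
(default 80%) remain callable across samples.  Depth/quality failures
invalidate individual genotype calls rather than deleting whole sites; the
presence filter then acts on the post-invalidation matrix.

Coordinates are 1-based inclusive as in VCF; internal arrays are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hwe import hwe_exact_p, hwe_chi2_p

__all__ = [
    "GenotypeMatrix",
    "FilterReport",
    "read_vcf",
    "write_vcf",
    "filter_sites",
    "hwe_screen",
    "extract_biallelic_snps",
]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Samples x sites diploid genotypes with per-allele read depths.

    ``gt`` has shape (n_samples, n_sites, 2) with allele indices (0 = ref)
    and -1 for missing; ``ad`` has shape (n_samples, n_sites, max_alleles)
    with -1 where depth is unavailable.
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: list[str]
    alt: list[list[str]]
    gt: np.ndarray
    ad: np.ndarray
    qual: np.ndarray

    def __post_init__(self) -> None:
        n_samples, n_sites = len(self.sample_ids), len(self.pos)
        if self.gt.shape != (n_samples, n_sites, 2):
            raise ValueError("gt shape mismatch")
        if self.ad.shape[:2] != (n_samples, n_sites):
            raise ValueError("ad shape mismatch")
        if len(self.qual) != n_sites or len(self.chrom) != n_sites:
            raise ValueError("per-site array length mismatch")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        for r, a in zip(self.ref, self.alt):
            if not r or any(not x for x in a):
                raise ValueError("empty allele string")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.sample_ids,
            self.chrom[idx],
            self.pos[idx],
            [self.ref[i] for i in idx],
            [self.alt[i] for i in idx],
            self.gt[:, idx].copy(),
            self.ad[:, idx].copy(),
            self.qual[idx].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return self.take_sites(np.arange(self.n_sites))

    def called_allele_fraction(self) -> np.ndarray:
        """Per-site fraction of non-missing alleles across samples."""
        return (self.gt != MISSING).mean(axis=(0, 2))

    def alt_allele_counts(self, allele: int = 1, samples=None):
        """(alt copies, called copies) per site over the given samples."""
        gt = self.gt if samples is None else self.gt[samples]
        called = (gt != MISSING).sum(axis=(0, 2))
        hits = (gt == allele).sum(axis=(0, 2))
        return hits, called


@dataclass
class FilterReport:
    """Sequential per-filter tally; site-level rows satisfy
    removed + retained = input for each step."""

    input_sites: int
    steps: list[dict] = field(default_factory=list)

    def add(self, name: str, removed: int, retained: int, unit: str = "sites",
            **info) -> None:
        self.steps.append(
            {"filter": name, "unit": unit, "removed": int(removed),
             "retained": int(retained), **info}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF I/O

def read_vcf(path) -> GenotypeMatrix:
    """Load a multi-sample VCF 4.x (GT required, AD optional)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns")
    chrom, pos, ref, alt, qual = [], [], [], [], []
    gts, ads = [], []
    max_alleles = 2
    for i, v in enumerate(vcf):
        try:
            genotypes = v.genotypes
        except Exception as err:
            raise ValueError(
                f"{path}: record {i + 1} ({v.CHROM}:{v.POS}) has no "
                f"parseable GT field"
            ) from err
        if genotypes is None:
            raise ValueError(f"{path}: record {i + 1} lacks GT")
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(list(v.ALT))
        max_alleles = max(max_alleles, 1 + len(v.ALT))
        qual.append(v.QUAL if v.QUAL is not None else np.nan)
        g = np.array([row[:2] for row in genotypes], dtype=np.int16)
        gts.append(g)
        ad = v.format("AD")
        if ad is None:
            ads.append(np.full((len(samples), max_alleles), MISSING,
                               dtype=np.int32))
        else:
            ad = np.asarray(ad, dtype=np.int64)
            ad[ad < 0] = MISSING  # cyvcf2 encodes '.' as a large negative
            ads.append(ad.astype(np.int32))
    if not pos:
        raise ValueError(f"{path}: VCF contains no variant records")
    n_sites = len(pos)
    gt = np.stack(gts, axis=1).astype(np.int8)
    ad_arr = np.full((len(samples), n_sites, max_alleles), MISSING,
                     dtype=np.int32)
    for j, ad in enumerate(ads):
        ad_arr[:, j, : ad.shape[1]] = ad
    return GenotypeMatrix(
        samples,
        np.array(chrom, dtype=object),
        np.array(pos, dtype=np.int64),
        ref,
        alt,
        gt,
        ad_arr,
        np.array(qual, dtype=float),
    )


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT and AD fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">\n')
        for c in dict.fromkeys(gm.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for j in range(gm.n_sites):
            n_alleles = 1 + len(gm.alt[j])
            cols = [
                str(gm.chrom[j]),
                str(gm.pos[j]),
                ".",
                gm.ref[j],
                ",".join(gm.alt[j]) if gm.alt[j] else ".",
                "." if np.isnan(gm.qual[j]) else f"{gm.qual[j]:g}",
                "PASS",
                ".",
                "GT:AD",
            ]
            for s in range(gm.n_samples):
                a0, a1 = gm.gt[s, j]
                gt_str = ("." if a0 == MISSING else str(a0)) + "/" + (
                    "." if a1 == MISSING else str(a1))
                ad = gm.ad[s, j, :n_alleles]
                ad_str = ",".join("." if d == MISSING else str(int(d))
                                  for d in ad)
                cols.append(f"{gt_str}:{ad_str}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Filters

def filter_sites(
    gm: GenotypeMatrix,
    min_allele_depth: int = 5,
    min_phred: float = 30.0,
    min_presence: float = 0.8,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply depth, quality and presence retention rules.

    A genotype call is set missing if any of its called alleles has read
    depth below ``min_allele_depth`` or the site quality is below
    ``min_phred``; a site is then dropped when fewer than ``min_presence`` of
    its alleles remain called.
    """
    if min_allele_depth < 0 or not (0 <= min_presence <= 1) or min_phred < 0:
        raise ValueError("filter thresholds outside valid ranges")
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    out = gm.copy()
    report = FilterReport(gm.n_sites)

    # per-allele depth rule (genotype-level invalidation)
    n_invalid_depth = 0
    called = out.gt != MISSING
    for a in range(out.ad.shape[2]):
        has_allele = np.any((out.gt == a) & called, axis=2)
        depth = out.ad[:, :, a]
        bad = has_allele & (depth != MISSING) & (depth < min_allele_depth)
        n_invalid_depth += int(np.sum(bad & np.any(called, axis=2)))
        out.gt[bad] = MISSING
    report.add("allele_depth", n_invalid_depth,
               int(np.any(out.gt != MISSING, axis=2).sum()),
               unit="genotypes", threshold=min_allele_depth)

    # site quality rule invalidates every genotype at the site
    low_qual = ~(gm.qual >= min_phred)  # nan counts as failing
    n_invalid_qual = int(np.sum((out.gt[:, low_qual, 0] != MISSING)))
    out.gt[:, low_qual, :] = MISSING
    report.add("site_phred", n_invalid_qual,
               int(np.any(out.gt != MISSING, axis=2).sum()),
               unit="genotypes", threshold=min_phred)

    # presence rule drops sites
    presence = out.called_allele_fraction()
    keep = presence >= min_presence
    report.add("presence", int((~keep).sum()), int(keep.sum()),
               unit="sites", threshold=min_presence)
    out = out.take_sites(np.flatnonzero(keep))
    return out, report


def hwe_screen(
    gm: GenotypeMatrix,
    populations: dict[str, str],
    alpha: float = 1e-6,
    method: str = "exact",
) -> tuple[list[int], pd.DataFrame]:
    """Flag sites deviating from Hardy-Weinberg within any one population.

    The test is run separately per population (never pooled, so allele
    frequency differences between structured populations do not create
    spurious signal).  Flagged sites are reported, not removed.  Returns the
    flagged site indices and a per-site table of minimum p-values.
    """
    pops: dict[str, list[int]] = {}
    for i, s in enumerate(gm.sample_ids):
        if s not in populations:
            raise ValueError(f"sample {s!r} missing from the population map")
        pops.setdefault(populations[s], []).append(i)
    for name, members in pops.items():
        if not members:
            raise ValueError(f"population {name!r} is empty")
    pfun = hwe_exact_p if method == "exact" else hwe_chi2_p
    rows = []
    flagged = []
    for j in range(gm.n_sites):
        min_p, min_pop = 1.0, None
        for name, members in pops.items():
            g = gm.gt[members, j]
            ok = np.all((g >= 0) & (g <= 1), axis=1)
            g = g[ok]
            if len(g) < 2:
                continue
            n_alt = g.sum(axis=1)
            n_het = int((n_alt == 1).sum())
            n_hom_ref = int((n_alt == 0).sum())
            n_hom_alt = int((n_alt == 2).sum())
            p = pfun(n_het, n_hom_ref, n_hom_alt)
            if p < min_p:
                min_p, min_pop = p, name
        rows.append({"site": j, "chrom": gm.chrom[j], "pos": gm.pos[j],
                     "min_p": min_p, "population": min_pop,
                     "flagged": min_p < alpha})
        if min_p < alpha:
            flagged.append(j)
    return flagged, pd.DataFrame(rows)


def extract_biallelic_snps(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep sites with exactly two alleles observed among called genotypes
    (drops monomorphic and multi-allelic sites)."""
    keep = []
    for j in range(gm.n_sites):
        g = gm.gt[:, j]
        alleles = np.unique(g[g != MISSING])
        if len(alleles) == 2:
            keep.append(j)
    return gm.take_sites(np.array(keep, dtype=int))
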