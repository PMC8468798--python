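"""Nucleotide diversity, AMOVA-based Phi_ST, and haplotype tallies.

Phi_ST follows the molecular analysis of variance of Excoffier, Smouse &
Quattro: with pairwise sequence differences as the (squared) distance,
``Phi_ST = sigma2_among / (sigma2_among + sigma2_within)``.  For diploid
unphased nuclear data each individual's two alleles are treated as
independent haploid draws — a documented approximation.  Composite values
are computed on concatenated data, not averaged over loci.  A negative
among-population component is floored at zero for the ratio; the raw
components are returned alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "load_fasta_alignment",
    "nucleotide_diversity_genotypes",
    "nucleotide_diversity_sequences",
    "amova_phi_st",
    "phi_st",
    "HaplotypeCensus",
    "haplotype_census",
]


def load_fasta_alignment(path) -> dict[str, str]:
    """Read an aligned FASTA (e.g. mtDNA COI haplotypes) as id -> sequence.

    All sequences must share one length; gaps/ambiguities are kept and
    excluded pairwise by the downstream statistics.
    """
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"{path}: no FASTA records")
    if len({len(s) for s in seqs.values()}) != 1:
        raise ValueError(f"{path}: sequences are not aligned to equal length")
    return seqs


# ---------------------------------------------------------------------------
# Nucleotide diversity

def _site_het(hits: np.ndarray, called: np.ndarray) -> np.ndarray:
    """Unbiased per-site mean pairwise difference 2a(c-a)/(c(c-1))."""
    with np.errstate(divide="ignore", invalid="ignore"):
        h = 2.0 * hits * (called - hits) / (called * (called - 1.0))
    h[called < 2] = np.nan
    return h


def nucleotide_diversity_genotypes(
    gm: GenotypeMatrix,
    samples=None,
    locus_lengths: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-chromosome and concatenated pi from a genotype matrix.

    ``locus_lengths`` maps chromosome id to the total callable length (bp);
    without it, the variant-site count itself is used as the denominator
    (pi over variable sites only).  Missing genotypes are handled with
    pairwise-complete allele counts per site.
    """
    hits, called = gm.alt_allele_counts(samples=samples)
    h = _site_het(hits.astype(float), called.astype(float))
    rows = []
    total_diff, total_len = 0.0, 0.0
    for c in dict.fromkeys(gm.chrom):
        sel = gm.chrom == c
        vals = h[sel]
        if np.all(np.isnan(vals)):
            rows.append({"locus": c, "pi": np.nan, "L": np.nan})
            continue
        diff = np.nansum(vals)
        L = (locus_lengths or {}).get(c, int(np.sum(~np.isnan(vals))))
        rows.append({"locus": c, "pi": diff / L, "L": L})
        total_diff += diff
        total_len += L
    rows.append({"locus": "concatenated",
                 "pi": total_diff / total_len if total_len else np.nan,
                 "L": total_len})
    return pd.DataFrame(rows)


def nucleotide_diversity_sequences(seqs: list[str], L: float | None = None) -> float:
    """Average pairwise difference per site among aligned sequences.

    Sites where either sequence of a pair carries a gap or ambiguity are
    excluded from that pair's comparison (pairwise-complete counting).
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned to equal length")
    valid = set("ACGTacgt")
    arr = [s.upper() for s in seqs]
    n = len(arr)
    total = 0.0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            comp = diff = 0
            for x, y in zip(arr[i], arr[j]):
                if x in valid and y in valid:
                    comp += 1
                    if x != y:
                        diff += 1
            if comp:
                denom = L if L is not None else comp
                total += diff / denom
                pairs += 1
    if pairs == 0:
        return np.nan
    return total / pairs


# ---------------------------------------------------------------------------
# AMOVA Phi_ST

def amova_phi_st(dist: np.ndarray, labels: np.ndarray) -> tuple[float, dict]:
    """Two-level AMOVA from a squared-distance matrix and population labels.

    Returns (phi_st, components); the ratio floors a negative
    among-population variance at zero, while ``components`` keeps the raw
    values.
    """
    labels = np.asarray(labels)
    pops = np.unique(labels)
    if len(pops) < 2:
        raise ValueError("need two populations")
    N = len(labels)
    sizes = np.array([(labels == p).sum() for p in pops])
    if np.any(sizes < 2):
        raise ValueError("each population needs at least 2 sequences")
    ssd_total = dist[np.triu_indices(N, k=1)].sum() / N
    ssd_within = 0.0
    for p in pops:
        idx = np.flatnonzero(labels == p)
        sub = dist[np.ix_(idx, idx)]
        ssd_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ssd_among = ssd_total - ssd_within
    df_among = len(pops) - 1
    df_within = N - len(pops)
    sigma_within = ssd_within / df_within if df_within else 0.0
    n_prime = (N - (sizes**2).sum() / N) / df_among
    sigma_among = (ssd_among / df_among - sigma_within) / n_prime
    num = max(sigma_among, 0.0)
    denom = num + sigma_within
    phi = num / denom if denom > 0 else 0.0
    raw_denom = sigma_among + sigma_within
    return phi, {
        "phi_raw": sigma_among / raw_denom if raw_denom != 0 else 0.0,
        "sigma2_among": sigma_among,
        "sigma2_within": sigma_within,
        "ssd_total": ssd_total,
        "ssd_within": ssd_within,
        "n_prime": n_prime,
    }


def _haploid_rows(gm: GenotypeMatrix, samples: list[int]) -> np.ndarray:
    """Each diploid sample contributes two haploid allele rows (int, -1
    missing) over the matrix's sites."""
    rows = []
    for s in samples:
        rows.append(gm.gt[s, :, 0])
        rows.append(gm.gt[s, :, 1])
    return np.array(rows, dtype=np.int16)


def _pairwise_diff_matrix(rows: np.ndarray) -> np.ndarray:
    """Pairwise difference counts with pairwise-complete sites, rescaled to
    the full site count when data are missing."""
    n, n_sites = rows.shape
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (rows[i] != MISSING) & (rows[j] != MISSING)
            comp = ok.sum()
            if comp == 0:
                continue
            diff = np.sum(rows[i][ok] != rows[j][ok])
            d[i, j] = d[j, i] = diff * n_sites / comp
    return d


def phi_st(
    gm: GenotypeMatrix,
    pop_map: dict[str, str],
    pops: tuple[str, str],
    per_locus: bool = True,
) -> tuple[float, dict, pd.DataFrame | None]:
    """Pairwise Phi_ST between two populations from a genotype matrix.

    Alleles are treated as haploid sequences over the matrix's sites.
    Returns (composite phi on the concatenated data, raw variance
    components, per-locus table or None).
    """
    idx = {p: [i for i, s in enumerate(gm.sample_ids) if pop_map.get(s) == p]
           for p in pops}
    for p, members in idx.items():
        if len(members) < 1:
            raise ValueError(f"population {p!r} has no samples")
    samples = idx[pops[0]] + idx[pops[1]]
    labels = np.array(
        [pops[0]] * (2 * len(idx[pops[0]])) + [pops[1]] * (2 * len(idx[pops[1]]))
    )
    rows = _haploid_rows(gm, samples)
    composite, comps = amova_phi_st(_pairwise_diff_matrix(rows), labels)
    table = None
    if per_locus:
        recs = []
        for c in dict.fromkeys(gm.chrom):
            sel = gm.chrom == c
            sub = rows[:, sel]
            try:
                val, _ = amova_phi_st(_pairwise_diff_matrix(sub), labels)
            except ValueError:
                val = np.nan
            recs.append({"locus": c, "phi_st": val,
                         "pos_lo": int(gm.pos[sel].min()),
                         "pos_hi": int(gm.pos[sel].max())})
        table = pd.DataFrame(recs)
    return composite, comps, table


def phi_st_sequences(seqs: list[str], labels) -> tuple[float, dict]:
    """Phi_ST from aligned haploid sequences (e.g. mtDNA haplotypes)."""
    labels = np.asarray(labels)
    n = len(seqs)
    d = np.zeros((n, n))
    valid = set("ACGTacgt")
    for i in range(n):
        for j in range(i + 1, n):
            diff = sum(
                1 for x, y in zip(seqs[i].upper(), seqs[j].upper())
                if x in valid and y in valid and x != y
            )
            d[i, j] = d[j, i] = diff
    return amova_phi_st(d, labels)


# ---------------------------------------------------------------------------
# Haplotype census

@dataclass
class HaplotypeCensus:
    per_species_counts: dict[str, int]
    frequency_table: pd.DataFrame
    distances: np.ndarray
    haplotypes: list[str]
    shared_pairs: list[tuple[str, str, str]]


def haplotype_census(seqs: dict[str, str], species: dict[str, str]) -> HaplotypeCensus:
    """Count unique haplotypes per species and mutation distances.

    ``seqs`` maps sequence id to an aligned sequence; ``species`` maps id to
    a species label.  Sites with ambiguity codes or gaps are excluded
    pairwise when counting mutation differences; haplotype identity uses the
    full sequence string.
    """
    ids = list(seqs)
    lengths = {len(seqs[i]) for i in ids}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned to equal length")
    hap_index: dict[str, int] = {}
    assignments = {}
    for i in ids:
        s = seqs[i].upper()
        if s not in hap_index:
            hap_index[s] = len(hap_index)
        assignments[i] = hap_index[s]
    haplotypes = list(hap_index)
    H = len(haplotypes)
    valid = set("ACGT")
    dist = np.zeros((H, H))
    for a in range(H):
        for b in range(a + 1, H):
            diff = sum(
                1 for x, y in zip(haplotypes[a], haplotypes[b])
                if x in valid and y in valid and x != y
            )
            dist[a, b] = dist[b, a] = diff
    recs = []
    for i in ids:
        recs.append({"id": i, "species": species[i],
                     "haplotype": assignments[i]})
    table = (
        pd.DataFrame(recs)
        .groupby(["species", "haplotype"])
        .size()
        .reset_index(name="count")
    )
    counts = {
        sp: int(table[table.species == sp].haplotype.nunique())
        for sp in sorted(set(species.values()))
    }
    shared = []
    by_hap = table.groupby("haplotype")["species"].apply(list)
    for hap, sps in by_hap.items():
        sps = sorted(set(sps))
        for a in range(len(sps)):
            for b in range(a + 1, len(sps)):
                shared.append((sps[a], sps[b], hap))
    return HaplotypeCensus(counts, table, dist, haplotypes, shared)
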