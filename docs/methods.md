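# Methods

This note documents the models, numerical choices and known limitations of
`radpop`, in the order a dataset flows through the package.

## Genotype filtering

A genotype call is invalidated (set missing) when any of its *called*
alleles has read depth below `min_allele_depth` (default 5×; a homozygote
therefore needs 10× on its single called allele, and an uncalled allele's
zero depth is ignored) or when the site's PHRED quality is below
`min_phred` (default 30). Only after genotype-level invalidation does the
presence rule act: a site is dropped when fewer than `min_presence`
(default 80%) of alleles — two per diploid sample — remain called. The
filter is idempotent, and the report's site-level rows always satisfy
removed + retained = input.

The presence threshold is interpreted per *allele* rather than per
genotype; for fully called or fully missing genotypes the two readings
coincide, and the allele reading is the stricter one in mixed cases.

The Hardy–Weinberg screen uses the exact conditional test (probability of
the heterozygote count given the allele counts; two-sided by summing all
configurations no more probable than the observed one, no mid-p). It runs
separately within each mapped population and never on the pooled sample,
so Wahlund-effect heterozygote deficits caused by population structure do
not trigger flags. Flagged sites (p < 1e-6 in at least one population) are
reported but retained by default; removal is the caller's decision. A
chi-square variant is available (`method="chi2"`), but the exact test is
the default since the flagging threshold sits deep in the tail where the
chi-square approximation is unreliable.

## Genetic sexing

For each sample the Z/autosome depth ratio is computed from summed allele
depths and normalized by the cohort's male mode, estimated as the median
of ratios at or above 75% of the 95th percentile. This makes calls
invariant to uniform depth rescaling between libraries, but it assumes the
cohort contains males (an all-female cohort would be normalized against
females and miscalled) — a documented limitation rather than a failure
mode the method can detect. A male call needs only the depth ratio
(≥ 0.85 of the male mode); a female call requires both lines of evidence:
ratio ≤ 0.65 and Z-to-autosome heterozygosity ratio ≤ 0.1. Samples between
the thresholds, or without usable depth, are reported `unassigned` with
their evidence values rather than forced into a class. The numeric
thresholds bisect the theoretical modes (0.5 for ZW females, 1.0 for ZZ
males) with margin and are configurable.

## Diversity and divergence

π is the average pairwise difference per site. On genotype matrices it is
computed per site as 2a(c−a)/(c(c−1)) from the alternate-allele count *a*
among the *c* called alleles (pairwise-complete handling of missingness;
this is the unbiased estimator, equal to the brute-force mean over all
chromosome pairs), then summed and divided by the locus length — the
variant-site count by default, or supplied callable lengths when
monomorphic sites are known.

Φ_ST follows the Excoffier–Smouse–Quattro analysis of molecular variance
with pairwise-difference distances. Unphased diploid genotypes contribute
their two alleles as independent haploid rows — an approximation that
ignores within-individual correlation and is documented as such. The
composite statistic is the AMOVA of the concatenated data, *not* the mean
of per-locus values. A negative among-population component is floored at
zero for the reported ratio; the raw component and the unclamped ratio are
preserved in the output, and the unclamped ratio is what should be
averaged when checking the null (the clamped mean is positively biased by
construction). With missing data, pairwise distances are rescaled from
pairwise-complete site counts to the full site count.

Haplotype censuses operate on exact sequence identity over the full
aligned string; mutation-count distances between haplotypes exclude
non-ACGT symbols pairwise.

## Site-frequency spectra

Spectra keep their full array length in every fold state: folding adds
entry n−i onto entry i and masks the redundant upper half, so index
arithmetic and the text round-trip (header with shape and fold state,
entries line, 0/1 mask line) are uniform and bit-exact for integer
counts. The `singletons_and_full` mask removes the monomorphic classes and
the minor-allele-count-1 classes — the classes most sensitive to
sequencing error in empirical data. "Variant present in only one sample"
is read as one sampled *chromosome* (minor allele count 1); the
one-diploid-individual reading (count ≤ 2) can be expressed by masking
entry 2 as well. Sites with missing alleles are hypergeometrically
projected to a smaller even sample size when a projection is requested,
otherwise dropped. Minor-allele (folded) orientation is the default
throughout, as no outgroup polarization is assumed.

## Single-population stepwise model

The history is an indefinitely long ancestral epoch of relative size 1
followed by ordered epochs (ν_k, T_k), earliest first, ending at the
present; rendering ~100 short steps approximates a continuous Ne(t)
trajectory. Sizes are relative to N_ANC, durations in 2·N_ANC
generations, and θ = 4·N_ANC·μ·L.

**Expectation engine.** Instead of a diffusion grid, the expected SFS is
computed exactly: within an epoch of constant ν the ancestral-lineage
death chain (rate k(k−1)/2 per unit coalescent time) is propagated by a
matrix exponential in rescaled time τ = t/ν, and the expected real time
spent with k lineages accumulates as ν·A⁻¹(e^{AΔτ}−I)P (A is triangular
and nonsingular once the absorbing single-lineage state is dropped). The
ancestral epoch is handled analytically: the chain visits every state
below its entry state exactly once, with mean holding time 2ν_Anc/(k(k−1)).
Branch lengths map to frequency classes via
P(k-lineage branch subtends i of n) = C(n−i−1,k−2)/C(n−1,k−1). For a
constant history this reproduces E[ξ_i] = θ/i to machine precision (the
suite checks < 1% for n up to 60; observed error is ~1e-12%). Cost is one
(n−1)×(n−1) `expm` per epoch, well under a millisecond at n = 40.

**Parameterization.** Up to 100 free (ν_k, T_k) pairs are not identifiable
from a single folded spectrum — experiments with even four free parameters
on a clean tenfold-expansion spectrum find histories with *better*
composite likelihood than the truth and arbitrary parameter values. The
fit therefore exposes K control points (default 10), each with a free size
and duration, rendered across `n_steps` steps either piecewise-constant or
geometrically interpolated from the previous control value (the segment's
last substep lands exactly on its control value, so one-substep segments
make the two modes agree). K is configurable down to 1 (a single size
change) and up to per-step freedom for users who want it.

**Fitting.** Poisson composite likelihood over unmasked entries; θ enters
linearly and is profiled analytically (θ̂ = Σk/Σm), never searched.
Optimization is bounded Nelder–Mead on log parameters (box [1e-3, 1e3] for
sizes, [1e-4, 5] for durations), multi-start with N(0,1) log-scale
perturbations around a neutral start; the first start is unperturbed.
Everything is deterministic given the seed. Invalid parameter regions
return a large finite penalty rather than infinity so the simplex stays
well-defined.

**Uncertainty.** Standard errors come from the observed information
(central-difference Hessian of the composite log-likelihood on log
parameters, θ included), CIs as estimate × exp(±z·SE). A singular
information matrix falls back to a pseudo-inverse and sets a `wide_ci`
flag instead of raising.

## Two-population models

Three registered models: `neutral_no_divergence` (no parameters — one
panmictic population arbitrarily split into two samples),
`split_migration` (ν1, ν2, T, symmetric m) and `isolation_with_migration`
(ν1, ν2, T, m12, m21); a split-*without*-migration fit is expressed by
fixing m = 0. The panmictic expectation is the closed form
E[ξ_ij] = θ/(i+j) · C(n1,i)C(n2,j)/C(n1+n2,i+j). The split models use
high-repetition structured-coalescent averaging with common random
numbers: a fixed engine seed makes the expected spectrum — and hence the
likelihood — a deterministic function of the parameters, at the price of
an O(1/√reps) systematic wiggle. Engine fidelity is configurable: ~600
replicates suffice for model selection (AIC margins are hundreds of log
units), ~4,000 for parameter recovery. Model choice is by AIC with the
profiled θ counted as a parameter; ties break toward fewer parameters.
Migrants per generation into population *i* are M = m·ν_i/2 under the
adopted convention (m per 2·N_ANC generations), printed with every output.

## The simulator and what passing tests show

The coalescent engine samples single-locus genealogies without
recombination, selection or sequencing-error base miscalls; mutations are
Poisson on branch lengths (infinite sites). Returned spectra are
branch-length expectations scaled by θ/2 — the mean over the mutation
process — with per-entry Monte-Carlo standard errors, so simulator-based
checks are variance-reduced. Epoch boundaries are honored exactly by
piecewise-exponential waiting times (no Euler stepping).

The ddRAD emulator draws group allele frequencies from a Balding–Nichols
model around uniform(0.05, 0.95) ancestral frequencies (divergence F = 0
shares frequencies; F = 1 fixes alleles per group), negative-binomial
total depths around a median of 119× (a typical well-covered ddRAD
library; overdispersion r = 8 by default), binomially split read depths
for heterozygotes, flat missingness, and the Z/W coverage signature
(females hemizygous on Z, reported homozygous, at half depth). It does
*not* emulate allele dropout at restriction sites, batch effects,
reference bias, or error-driven singletons — so passing the sexing and
Φ_ST tests shows the statistics are computed correctly, not that real
libraries are this clean. Genotype frequencies are *not* coalescent-derived,
so SFS-based demographic fitting should be validated against the
coalescent simulators, not the genotype emulator.

## Validation experiment design

The self-validation battery (`radpop.benchmarks`, asserted in the test
suite and re-measured by `scripts/acceptance.py`) fixes these problem
sizes as its study conditions: single-population recovery uses a tenfold
expansion starting 0.1 × 2·N_ANC generations ago, n = 40 chromosomes,
θ set for ~5,000 segregating sites, 20 replicates; model selection uses
n = 20+20 and ~10,000 sites, 25 replicates per generating model.

Two design choices matter for interpretation. First, recovery replicates
are generated through the Monte-Carlo simulator (a code path independent
of the deterministic engine being fitted), each replicate with its own
genealogies so generation noise is independent across replicates. Second,
the recovery spectra are folded but singletons are *not* masked:
singleton masking is an empirical-data hygiene rule aimed at sequencing
error, and with the singleton class removed the size of a recent
expansion is not identifiable to ±20% at this data size (the likelihood
develops a ridge toward arbitrarily large sizes with compensating times).
The recovered size is summarized by the geometric mean across replicates,
matching the log scale on which the parameter is estimated; the
arithmetic mean inherits the right skew of a log-scale MLE. Model
selection uses folded, masked spectra as in the empirical workflow.

## Pipeline

`run_pipeline` executes filter → HWE screen → sexing → π/Φ_ST → SFS →
stepwise fits → unit conversion, rejecting configs with unknown keys,
deriving per-stage seeds from the global seed by hashing the stage name,
and writing a manifest with a SHA-256 checksum of every artifact; reruns
with the same config reproduce the fit outputs bit-for-bit. A missing
calibration block skips conversion with an explicit notice instead of
failing. Generation time and per-species constants (α, survival, μ
anchors, locus lengths) are configuration inputs, never hardcoded; every
converted output echoes the constants used.

## Known limitations

- Composite (per-site independent Poisson) likelihoods ignore linkage;
  SEs and CIs are anti-conservative on strongly linked data. No
  locus-bootstrap is provided.
- The stepwise fit's identifiability depends on K; the default K = 10 with
  a 100-step render is a smoothness prior in disguise, not an inference of
  the true step count.
- The structured-coalescent expectation is stochastic-but-seeded; two
  different engine seeds give slightly different likelihood surfaces
  (within the O(1/√reps) band).
- Sexing requires males in the cohort and Z-linked sites that survive
  filtering.
- The strong-migration limit of the split models coalesces at the pooled
  size ν1 + ν2; convergence to the panmictic reference is O(1/m) and only
  holds with matched total size.
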