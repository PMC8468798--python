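"""Self-validation experiments: oracles, recovery harnesses, concordance.

Each function runs one end-to-end check of the package against an
independent expectation — closed forms, Monte-Carlo genealogies, simulated
ground truth, or hand-derivable fixtures — and returns plain numbers.  The
test suite asserts on them; the reproduction script reports them.

Problem sizes are chosen so the whole battery runs in minutes on one core:
single-population recovery uses 20 Poisson replicates of an S~5,000-site
spectrum at n=40; model selection uses 25 replicates of S~10,000-site joint
spectra at n=20+20.
"""

from __future__ import annotations

import numpy as np

from .diversity import amova_phi_st, phi_st
from .genotypes import (GenotypeMatrix, extract_biallelic_snps, filter_sites,
                        hwe_screen)
from .pairwise import PairwiseFitConfig, fit_pairwise, select_model
from .sexing import assign_sex
from .sfs import Sfs1D, Sfs2D, apply_mask, fold
from .simulate import (StudyDesign, simulate_genotype_matrix, simulate_sfs_1d,
                       simulate_sfs_2d)
from .stepwise import (EpochModel, StepwiseFitConfig, confidence_intervals,
                       expected_sfs_stepwise, fit_stepwise)
from .units import Calibration, calibrate_mu, n_anc_from_theta, scale_fit
from .fitting import FitResult

__all__ = [
    "constant_model_error",
    "engine_vs_simulation",
    "single_population_recovery",
    "pairwise_model_recovery",
    "phi_st_checks",
    "toy_filter_vcf_matrix",
    "filter_exactness",
    "sexing_concordance",
    "conversion_round_trip",
]


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0]
               % (2**31 - 1)) + 1


def constant_model_error(sizes=(10, 40, 60)) -> float:
    """Worst relative error (%) of the deterministic stepwise engine against
    the neutral closed form E[xi_i] = theta / i."""
    worst = 0.0
    for n in sizes:
        sfs = expected_sfs_stepwise(EpochModel.constant(), n)
        expected = 1.0 / np.arange(1, n)
        worst = max(worst, float(np.abs(sfs.data[1:n] / expected - 1).max()))
    return 100.0 * worst


def engine_vs_simulation(seed: int, n: int = 20, reps: int = 100_000) -> float:
    """Max |z| between the deterministic expectation and the mean of
    ``reps`` simulated genealogies for a two-epoch tenfold expansion,
    compared per unmasked folded entry."""
    model = EpochModel([(1.0, 0.4), (10.0, 0.1)])
    det = apply_mask(fold(expected_sfs_stepwise(model, n)))
    sim = simulate_sfs_1d(n, model, 1.0, reps, seed=_sub_seed(seed, 1))
    sim_f = fold(sim)
    # fold the Monte-Carlo errors in quadrature
    se = np.sqrt(fold(Sfs1D(sim.stderr**2, n)).data)
    sel = ~det.mask
    z = (sim_f.data[sel] - det.data[sel]) / se[sel]
    return float(np.abs(z).max())


def single_population_recovery(seed: int, n_reps: int = 20) -> dict:
    """Recover a recent tenfold expansion (onset at scaled time 0.1) from
    folded spectra of ~5,000 segregating sites at n=40.

    The generating expectation comes from the Monte-Carlo simulator (an
    independent route from the deterministic engine being fitted); each
    replicate draws Poisson entry counts.  Returns the mean recent-size
    estimate, its relative error, and 95% CI coverage.
    """
    truth_v = 10.0
    truth = EpochModel([(truth_v, 0.1)])
    n = 40
    ref = simulate_sfs_1d(n, truth, 1.0, 20_000, seed=_sub_seed(seed, 2))
    theta = 5000.0 / ref.data[1:n].sum()
    estimates, covered = [], 0
    for rep in range(n_reps):
        # each replicate simulates its own genealogies, so generation noise
        # is independent across replicates and averages out of the summary
        gen = simulate_sfs_1d(n, truth, 1.0, 30_000,
                              seed=_sub_seed(seed, 300 + rep))
        rng = np.random.default_rng(_sub_seed(seed, 100 + rep))
        obs = fold(Sfs1D(rng.poisson(theta * gen.data).astype(float), n))
        cfg = StepwiseFitConfig(
            n_free_sizes=1, n_steps=1, n_starts=3, interpolation="constant",
            seed=_sub_seed(seed, 200 + rep), maxfev=600,
        )
        fit = fit_stepwise(obs, cfg)
        cis = confidence_intervals(fit, obs)
        est, lo, hi = cis["v_0"]
        estimates.append(est)
        covered += lo <= truth_v <= hi
    estimates = np.array(estimates)
    # the size parameter is inferred on a log scale; the geometric mean is
    # the matching location summary (the arithmetic mean inherits the
    # right-skew of a log-scale MLE)
    geo = float(np.exp(np.log(estimates).mean()))
    return {
        "recent_size_estimate": geo,
        "rel_error_pct": 100.0 * abs(geo / truth_v - 1.0),
        "median_recent_size": float(np.median(estimates)),
        "ci_coverage_pct": 100.0 * covered / n_reps,
        "n_reps": n_reps,
    }


def pairwise_model_recovery(seed: int, n_reps: int = 25) -> dict:
    """AIC model selection accuracy on simulated joint spectra.

    Data are simulated under neutral-no-divergence and under
    split-migration (nu1=nu2=1, T=0.5, m=1) at n=20+20 with ~10,000 sites,
    folded and masked; both models are fitted to every replicate and the
    AIC winner recorded.
    """
    n1 = n2 = 20
    from .simulate import nnd_expected_sfs_2d

    gen_nnd = nnd_expected_sfs_2d(n1, n2)
    gen_sm = simulate_sfs_2d(n1, n2, "split_migration", [1.0, 1.0, 0.5, 1.0],
                             1.0, 100_000, seed=_sub_seed(seed, 3))

    def theta_for(mean_sfs):
        sel = mean_sfs.data.copy()
        sel[0, 0] = sel[-1, -1] = 0.0
        return 10_000.0 / sel.sum()

    def classify(mean_sfs, theta, rep, salt):
        rng = np.random.default_rng(_sub_seed(seed, salt + rep))
        obs = apply_mask(fold(Sfs2D(
            rng.poisson(theta * mean_sfs.data).astype(float), n1, n2)))
        cfg = PairwiseFitConfig(n_starts=3, engine_reps=600, maxfev=250,
                                seed=_sub_seed(seed, salt + 1000 + rep))
        fits = [fit_pairwise(obs, "neutral_no_divergence", cfg),
                fit_pairwise(obs, "split_migration", cfg)]
        return select_model(fits)[0]["model"]

    t_nnd, t_sm = theta_for(gen_nnd), theta_for(gen_sm)
    nnd_correct = sum(
        classify(gen_nnd, t_nnd, rep, 5000) == "neutral_no_divergence"
        for rep in range(n_reps))
    sm_correct = sum(
        classify(gen_sm, t_sm, rep, 7000) == "split_migration"
        for rep in range(n_reps))
    return {
        "nnd_correct_pct": 100.0 * nnd_correct / n_reps,
        "sm_correct_pct": 100.0 * sm_correct / n_reps,
        "n_reps": n_reps,
    }


def phi_st_checks(seed: int, n_splits: int = 200) -> dict:
    """Phi_ST against a brute-force variance decomposition and its two
    boundary behaviors (fixed differences; random splits of one panmictic
    sample)."""
    rng = np.random.default_rng(_sub_seed(seed, 4))

    def brute(dist, labels):
        labels = np.asarray(labels)
        N = len(labels)
        pops = sorted(set(labels))
        ss_total = dist.sum() / (2 * N)
        ss_within = 0.0
        for p in pops:
            idx = np.flatnonzero(labels == p)
            ss_within += dist[np.ix_(idx, idx)].sum() / (2 * len(idx))
        ms_w = ss_within / (N - len(pops))
        ms_a = (ss_total - ss_within) / (len(pops) - 1)
        sizes = [int((labels == p).sum()) for p in pops]
        n_c = (N - sum(s * s for s in sizes) / N) / (len(pops) - 1)
        s_a = (ms_a - ms_w) / n_c
        return max(s_a, 0) / (max(s_a, 0) + ms_w)

    max_diff = 0.0
    for _ in range(20):
        seqs = rng.integers(0, 2, size=(10, 6))
        dist = (seqs[:, None, :] != seqs[None, :, :]).sum(axis=2).astype(float)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        ours, _ = amova_phi_st(dist, labels)
        max_diff = max(max_diff, abs(ours - brute(dist, labels)))

    fixed_design = StudyDesign(
        n_samples_per_group=6, n_groups=2, n_autosomal_sites=150,
        n_z_sites=1, group_allele_freq_divergence=1.0,
        seed=_sub_seed(seed, 5))
    gm, truth = simulate_genotype_matrix(fixed_design)
    auto = extract_biallelic_snps(
        gm.take_sites(np.flatnonzero(gm.chrom == "chr1")))
    pm = dict(zip(gm.sample_ids, truth.groups))
    phi_fixed, _, _ = phi_st(auto, pm, ("G0", "G1"), per_locus=False)

    # each replicate simulates a fresh panmictic cohort and splits it at
    # random, so the 200 values are independent and their SE is honest
    vals = []
    for k in range(n_splits):
        pan_design = StudyDesign(
            n_samples_per_group=8, n_groups=2, n_autosomal_sites=600,
            n_z_sites=1, group_allele_freq_divergence=0.0,
            seed=_sub_seed(seed, 6000 + k))
        gm2, _ = simulate_genotype_matrix(pan_design)
        perm = rng.permutation(gm2.n_samples)
        pm2 = {gm2.sample_ids[i]: ("a" if r < gm2.n_samples // 2 else "b")
               for r, i in enumerate(perm)}
        _, comps, _ = phi_st(gm2, pm2, ("a", "b"), per_locus=False)
        vals.append(comps["phi_raw"])  # unclamped: mean should center on 0
    vals = np.array(vals)
    return {
        "brute_force_max_abs_diff": float(max_diff),
        "fixed_difference_phi": float(phi_fixed),
        "panmictic_mean_phi": float(vals.mean()),
        "panmictic_se": float(vals.std(ddof=1) / np.sqrt(len(vals))),
        "n_splits": n_splits,
    }


def toy_filter_vcf_matrix() -> tuple[GenotypeMatrix, dict]:
    """A crafted 50-site, 30-sample matrix with known filter violations.

    Layout (hand-derivable):

    * 30 clean biallelic sites — survive everything;
    * 1 site with a total heterozygote deficit (15 hom-ref / 15 hom-alt) —
      flagged by the exact HWE screen at alpha 1e-6, but retained;
    * 4 sites with PHRED 20 < 30 — every genotype invalidated, dropped by
      the presence rule;
    * 5 sites where 7/30 genotypes fail the 5x allele-depth rule —
      23/30 = 76.7% alleles present < 80%, dropped;
    * 4 sites where exactly one genotype fails the depth rule —
      29/30 present, retained;
    * 3 sites whose only alternate carrier fails the depth rule —
      monomorphic after invalidation, removed by biallelic extraction;
    * 3 tri-allelic sites — removed by biallelic extraction.

    Expected surviving biallelic sites: 30 + 1 + 4 = 35; HWE flags: 1.
    """
    n_samp = 30
    sites = []  # (gts, ads, qual, alt)

    def site(gts, ads, qual=45.0, alt=("G",)):
        sites.append((gts, ads, qual, list(alt)))

    clean_g = [(0, 1)] * 10 + [(0, 0)] * 20
    clean_a = [(10, 10, 0)] * 10 + [(20, 0, 0)] * 20
    for _ in range(30):
        site(clean_g, clean_a)
    site([(0, 0)] * 15 + [(1, 1)] * 15,
         [(20, 0, 0)] * 15 + [(0, 20, 0)] * 15)  # HWE deficit, retained
    for _ in range(4):
        site(clean_g, clean_a, qual=20.0)
    low7_g = [(0, 1)] * 10 + [(0, 0)] * 20
    low7_a = [(4, 12, 0)] * 7 + [(10, 10, 0)] * 3 + [(20, 0, 0)] * 20
    for _ in range(5):
        site(low7_g, low7_a)
    low1_a = [(3, 3, 0)] + [(10, 10, 0)] * 9 + [(20, 0, 0)] * 20
    for _ in range(4):
        site(low7_g, low1_a)
    mono_g = [(0, 1)] + [(0, 0)] * 29
    mono_a = [(4, 4, 0)] + [(20, 0, 0)] * 29
    for _ in range(3):
        site(mono_g, mono_a)
    tri_g = [(0, 1)] * 5 + [(0, 2)] * 5 + [(0, 0)] * 20
    tri_a = [(10, 10, 0)] * 5 + [(10, 0, 10)] * 5 + [(20, 0, 0)] * 20
    for _ in range(3):
        site(tri_g, tri_a, alt=("G", "T"))

    n_sites = len(sites)
    gt = np.zeros((n_samp, n_sites, 2), dtype=np.int8)
    ad = np.zeros((n_samp, n_sites, 3), dtype=np.int32)
    qual = np.zeros(n_sites)
    alt = []
    for j, (gts, ads, q, a) in enumerate(sites):
        for s in range(n_samp):
            gt[s, j] = gts[s]
            ad[s, j] = ads[s]
        qual[j] = q
        alt.append(a)
    gm = GenotypeMatrix(
        sample_ids=[f"S{i:02d}" for i in range(n_samp)],
        chrom=np.array(["chr1"] * n_sites, dtype=object),
        pos=np.arange(1, n_sites + 1, dtype=np.int64) * 10,
        ref=["A"] * n_sites,
        alt=alt,
        gt=gt,
        ad=ad,
        qual=qual,
    )
    expected = {"surviving_sites": 35, "hwe_flagged": 1, "input_sites": 50}
    return gm, expected


def filter_exactness(tmp_dir=None) -> dict:
    """Round-trip the crafted matrix through VCF text, filter, and count."""
    import tempfile
    from pathlib import Path

    from .genotypes import read_vcf, write_vcf

    gm, expected = toy_filter_vcf_matrix()
    with tempfile.TemporaryDirectory(dir=tmp_dir) as td:
        p = Path(td) / "toy.vcf"
        write_vcf(gm, p)
        loaded = read_vcf(p)
    filtered, report = filter_sites(loaded)
    final = extract_biallelic_snps(filtered)
    pops = {s: "one" for s in final.sample_ids}
    flagged, _ = hwe_screen(final, pops, alpha=1e-6)
    return {
        "surviving_sites": final.n_sites,
        "expected_surviving_sites": expected["surviving_sites"],
        "hwe_flagged": len(flagged),
        "expected_hwe_flagged": expected["hwe_flagged"],
        "input_sites": gm.n_sites,
    }


def sexing_concordance(seed: int) -> dict:
    """Genetic-sex calls against simulated truth (n=24, 300 Z sites,
    20% missingness)."""
    design = StudyDesign(
        n_samples_per_group=12, n_groups=2, n_autosomal_sites=400,
        n_z_sites=300, missing_rate=0.2, sex_ratio=0.5,
        seed=_sub_seed(seed, 7))
    gm, truth = simulate_genotype_matrix(design)
    calls = assign_sex(gm, {"chrZ"})
    want = {"F": "female", "M": "male"}
    correct = sum(c.call == want[s] for c, s in zip(calls, truth.sexes))
    return {"concordance_pct": 100.0 * correct / gm.n_samples,
            "n_samples": gm.n_samples}


def conversion_round_trip() -> dict:
    """Worst relative error of the theta / calibration round trips."""
    from .units import unscale_params

    errs = []
    # theta = 4 N mu L identity
    calib = Calibration(mu_site_year=2.3e-9, G=1.7, L=79_862.0)
    theta = 123.4
    n_anc = n_anc_from_theta(theta, calib)
    errs.append(abs(4 * n_anc * calib.mu_gen_site * calib.L / theta - 1))
    # scale / unscale
    model = EpochModel([(2.0, 0.3), (5.0, 0.1)])
    fit = FitResult(
        model_name="stepwise", param_names=["v_0", "v_1", "t_0", "t_1"],
        params=np.array([2.0, 5.0, 0.3, 0.1]), theta=theta, loglik=-1.0,
        n_starts=1, converged=True, seed=0, extra={"epoch_model": model})
    back = unscale_params(scale_fit(fit, calib), calib)
    for name, value in fit.params_dict().items():
        errs.append(abs(back[name] / value - 1))
    # calibration anchor self-consistency
    mu = calibrate_mu(3.3e6, 0.73, 42.0, 5000.0, 2.5)
    calib2 = Calibration(mu_site_year=mu, G=2.5, L=5000.0)
    errs.append(abs(0.73 * 2 * n_anc_from_theta(42.0, calib2) * 2.5 / 3.3e6
                    - 1))
    return {"max_rel_error": float(max(errs))}
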