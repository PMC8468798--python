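"""End-to-end orchestration: filter -> sex -> stats -> SFS -> fits -> units.

A single global seed is fanned out per stage through a stable derivation
(hash of the stage name), so each stage is independently reproducible.  The
run manifest records every artifact with a checksum, the parameters actually
used, and the package version; deterministic stages reproduce identical
manifests on rerun.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .diversity import nucleotide_diversity_genotypes, phi_st
from .genotypes import (extract_biallelic_snps, filter_sites, hwe_screen,
                        read_vcf, write_vcf)
from .sexing import assign_sex, sex_calls_to_frame
from .sfs import apply_mask, fold, write_sfs
from .sfs_build import build_sfs_1d
from .simulate import StudyDesign, simulate_genotype_matrix
from .stepwise import StepwiseFitConfig, confidence_intervals, fit_stepwise
from .units import Calibration, scale_fit

__all__ = ["PipelineConfig", "run_pipeline", "make_fixture"]

_KNOWN_KEYS = {
    "vcf", "pop_map", "z_chromosomes", "out_dir", "seed",
    "filters", "sfs", "fit_single", "calibration",
}
_FILTER_KEYS = {"min_allele_depth", "min_phred", "min_presence", "hwe_alpha"}
_SFS_KEYS = {"projection_fraction"}
_FIT_KEYS = {"n_free_sizes", "n_steps", "n_starts", "interpolation", "maxfev"}


@dataclass
class PipelineConfig:
    vcf: str
    pop_map: dict[str, str]
    out_dir: str
    z_chromosomes: list[str] = field(default_factory=lambda: ["chrZ"])
    seed: int = 0
    filters: dict = field(default_factory=dict)
    sfs: dict = field(default_factory=dict)
    fit_single: dict = field(default_factory=dict)
    calibration: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for block, allowed in [("filters", _FILTER_KEYS), ("sfs", _SFS_KEYS),
                               ("fit_single", _FIT_KEYS)]:
            extra = set(raw.get(block, {})) - allowed
            if extra:
                raise ValueError(f"unknown keys in {block!r}: {sorted(extra)}")
        return cls(**raw)


def stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the stages in order and return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}, "outputs": {}}

    def record(name: str, path: Path, params: dict) -> None:
        manifest["stages"].setdefault(name, {"params": params, "files": []})
        manifest["stages"][name]["files"].append(path.name)
        manifest["outputs"][path.name] = _checksum(path)

    # --- filter ------------------------------------------------------------
    gm = read_vcf(config.vcf)
    fparams = {"min_allele_depth": 5, "min_phred": 30.0, "min_presence": 0.8,
               "hwe_alpha": 1e-6}
    fparams.update(config.filters)
    hwe_alpha = fparams.pop("hwe_alpha")
    gm_f, report = filter_sites(gm, **fparams)
    flagged, hwe_table = hwe_screen(gm_f, config.pop_map, alpha=hwe_alpha)
    gm_snp = extract_biallelic_snps(gm_f)
    report.add("biallelic", gm_f.n_sites - gm_snp.n_sites, gm_snp.n_sites)
    p = out / "filter_report.tsv"
    report.to_tsv(p)
    record("filter", p, {**fparams, "hwe_alpha": hwe_alpha,
                         "hwe_flagged": len(flagged)})
    p = out / "filtered.vcf"
    write_vcf(gm_snp, p)
    record("filter", p, {})

    # --- sexing ------------------------------------------------------------
    has_z = any(np.isin(gm_snp.chrom, config.z_chromosomes))
    if has_z:
        calls = assign_sex(gm_snp, set(config.z_chromosomes))
        p = out / "sex_calls.tsv"
        sex_calls_to_frame(calls).to_csv(p, sep="\t", index=False)
        record("sex", p, {"z_chromosomes": config.z_chromosomes})
    else:
        manifest["stages"]["sex"] = {"skipped": "no Z-linked sites survived"}

    # --- diversity / divergence --------------------------------------------
    auto_sel = ~np.isin(gm_snp.chrom, config.z_chromosomes)
    gm_auto = gm_snp.take_sites(np.flatnonzero(auto_sel))
    pops = sorted(set(config.pop_map.values()))
    pi = nucleotide_diversity_genotypes(gm_auto)
    p = out / "pi.tsv"
    pi.to_csv(p, sep="\t", index=False)
    record("stats", p, {})
    phi_rows = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            try:
                composite, comps, _ = phi_st(
                    gm_auto, config.pop_map, (pops[i], pops[j]),
                    per_locus=False)
            except ValueError:
                continue
            phi_rows.append({"pop1": pops[i], "pop2": pops[j],
                             "phi_st": composite})
    p = out / "phi_st.tsv"
    import pandas as pd

    pd.DataFrame(phi_rows).to_csv(p, sep="\t", index=False)
    record("stats", p, {})

    # --- SFS + single-population fits --------------------------------------
    proj_frac = config.sfs.get("projection_fraction", 0.9)
    fit_params = {"n_free_sizes": 4, "n_steps": 20, "n_starts": 5,
                  "interpolation": "geometric", "maxfev": 600}
    fit_params.update(config.fit_single)
    fits = {}
    for pop in pops:
        members = [i for i, s in enumerate(gm_auto.sample_ids)
                   if config.pop_map[s] == pop]
        if len(members) < 3:
            continue
        proj = max(4, int(2 * len(members) * proj_frac))
        sfs = build_sfs_1d(gm_auto, members, projection_n=proj)
        sfs = apply_mask(fold(sfs))
        p = out / f"{pop}.fs"
        write_sfs(sfs, p)
        record("sfs", p, {"projection_n": proj})
        cfg = StepwiseFitConfig(
            seed=stage_seed(config.seed, f"fit:{pop}"), **fit_params)
        fit = fit_stepwise(sfs, cfg)
        confidence_intervals(fit, sfs)
        result = {
            "model": fit.model_name,
            "params": fit.params_dict(),
            "theta": fit.theta,
            "loglik": fit.loglik,
            "cis": fit.cis,
            "trajectory_scaled": fit.extra["epoch_model"].trajectory().tolist(),
            "units": ("sizes relative to N_ANC; durations in 2*N_ANC "
                      "generations; theta = 4*N_ANC*mu*L"),
        }
        fits[pop] = (fit, result)
        p = out / f"fit_{pop}.json"
        p.write_text(json.dumps(result, indent=2, default=float))
        record("fit_single", p, {**fit_params, "seed": cfg.seed})

    # --- unit conversion ----------------------------------------------------
    if config.calibration:
        calib = Calibration(**config.calibration)
        for pop, (fit, _) in fits.items():
            scaled = scale_fit(fit, calib)
            p = out / f"fit_{pop}_biological.json"
            p.write_text(json.dumps(scaled, indent=2, default=float))
            record("convert", p, {"calibration": calib.provenance()})
    else:
        manifest["stages"]["convert"] = {
            "skipped": "no calibration block in config"}

    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def make_fixture(out_dir, seed: int = 0):
    """Write a small simulated demo cohort (VCF + truth + pop map)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = StudyDesign(
        n_samples_per_group=12,
        n_groups=3,
        n_autosomal_sites=2000,
        n_z_sites=200,
        missing_rate=0.05,
        group_allele_freq_divergence=0.3,
        seed=seed,
    )
    gm, truth = simulate_genotype_matrix(design)
    write_vcf(gm, out / "fixture.vcf")
    truth.to_tsv(out / "truth.tsv")
    with open(out / "pops.tsv", "w") as fh:
        fh.write("sample\tpopulation\n")
        for s, g in zip(gm.sample_ids, truth.groups):
            fh.write(f"{s}\t{g}\n")
    return gm, truth
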