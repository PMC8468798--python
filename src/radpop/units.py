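"""Conversion of scaled inference parameters to biological units.

The bridge between diffusion-scaled parameters and individuals/years is
``theta = 4 * N_ANC * mu_gen * L`` (diploid autosomes), so
``N_ANC = theta / (4 mu_gen L)``; sizes scale as ``nu * N_ANC`` individuals
and durations as ``t * 2 * N_ANC * G`` years, with ``G`` the generation time
in years.  When no trustworthy per-site mutation rate exists, ``mu`` is
calibrated from an anchor: a divergence time known in years whose scaled
model time has been estimated, which closes the two scaling equations.

Generation time uses the mean-age-of-parents form ``G = alpha + s/(1 - s)``
(age at maturity plus mean adult life expectancy beyond it under constant
annual survival ``s``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import FitResult
from .stepwise import EpochModel

__all__ = [
    "Calibration",
    "generation_time",
    "calibrate_mu",
    "scale_fit",
    "unscale_params",
    "per_locus_rate",
]


@dataclass
class Calibration:
    """Constants used to convert scaled parameters.

    mu_site_year : substitutions/site/year
    G : generation time, years
    alpha : age at sexual maturity, years (provenance only if G given)
    survival : adult annual survival fraction
    L : total locus length, bp
    anchor_time_years, anchor_T_scaled : optional divergence-time anchor
    ploidy_factor : 4 for diploid autosomes, 2 for haploid maternal loci
    """

    mu_site_year: float
    G: float
    L: float
    alpha: float | None = None
    survival: float | None = None
    anchor_time_years: float | None = None
    anchor_T_scaled: float | None = None
    ploidy_factor: float = 4.0

    def __post_init__(self) -> None:
        for name in ("mu_site_year", "G", "L"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.survival is not None and not (0 < self.survival < 1):
            raise ValueError("survival must be in (0, 1)")

    @property
    def mu_gen_site(self) -> float:
        """Substitutions/site/generation."""
        return self.mu_site_year * self.G

    def provenance(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def generation_time(alpha: float, survival: float) -> float:
    """G = alpha + s / (1 - s) years."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if not (0 <= survival < 1):
        raise ValueError("survival must be in [0, 1)")
    return alpha + survival / (1.0 - survival)


def calibrate_mu(
    anchor_time_years: float,
    anchor_T_scaled: float,
    theta: float,
    L: float,
    G: float,
) -> float:
    """Per-site per-year mutation rate from a divergence-time anchor.

    Solves the coupled scaling ``N_ANC = theta / (4 mu_gen L)`` and
    ``anchor_time_years = anchor_T_scaled * 2 * N_ANC * G``:

        mu_gen = anchor_T_scaled * theta * G / (2 L anchor_time_years)

    returned per year (``mu_gen / G``).
    """
    for name, v in [("anchor_time_years", anchor_time_years),
                    ("anchor_T_scaled", anchor_T_scaled),
                    ("theta", theta), ("L", L), ("G", G)]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    mu_gen = anchor_T_scaled * theta * G / (2.0 * L * anchor_time_years)
    return mu_gen / G


def per_locus_rate(mu_site_year: float, L: float, G: float) -> float:
    """Substitutions per locus per generation: ``mu * G * L``."""
    if mu_site_year <= 0 or L <= 0 or G <= 0:
        raise ValueError("all rate inputs must be positive")
    return mu_site_year * G * L


def n_anc_from_theta(theta: float, calib: Calibration) -> float:
    return theta / (calib.ploidy_factor * calib.mu_gen_site * calib.L)


def scale_fit(fit: FitResult, calib: Calibration) -> dict:
    """Convert a FitResult's scaled parameters to individuals and years.

    Sizes ``nu`` become ``nu * N_ANC`` individuals, durations ``t`` become
    ``t * 2 * N_ANC * G`` years.  For stepwise fits the rendered trajectory
    is emitted as (years before present, Ne) by cumulative summation from
    the present backwards.  CIs, when present, are scaled multiplicatively.
    """
    if not fit.converged:
        raise ValueError("refusing to scale an unconverged fit")
    n_anc = n_anc_from_theta(fit.theta, calib)
    year_per_t = 2.0 * n_anc * calib.G
    out = {
        "N_ANC": n_anc,
        "theta": fit.theta,
        "provenance": calib.provenance(),
        "params_biological": {},
    }
    for name, value in fit.params_dict().items():
        if name.startswith(("nu", "v")):
            out["params_biological"][name + "_individuals"] = value * n_anc
        elif name.startswith(("T", "t")):
            out["params_biological"][name + "_years"] = value * year_per_t
        else:
            out["params_biological"][name] = value
    if fit.cis:
        scaled_cis = {}
        for name, (est, lo, hi) in fit.cis.items():
            if name.startswith(("nu", "v")):
                f = n_anc
            elif name.startswith(("T", "t")):
                f = year_per_t
            else:
                f = 1.0
            scaled_cis[name] = (est * f, lo * f, hi * f)
        out["cis_biological"] = scaled_cis
    model = fit.extra.get("epoch_model")
    if isinstance(model, EpochModel):
        rows = model.trajectory()
        out["trajectory"] = [
            {"years_bp_start": r[0] * year_per_t,
             "years_bp_end": (r[1] * year_per_t if np.isfinite(r[1])
                              else np.inf),
             "Ne": r[2] * n_anc}
            for r in rows
        ]
    return out


def unscale_params(scaled: dict, calib: Calibration) -> dict:
    """Invert :func:`scale_fit` for the parameter block (round-trip check)."""
    n_anc = scaled["N_ANC"]
    year_per_t = 2.0 * n_anc * calib.G
    out = {}
    for name, value in scaled["params_biological"].items():
        if name.endswith("_individuals"):
            out[name[: -len("_individuals")]] = value / n_anc
        elif name.endswith("_years"):
            out[name[: -len("_years")]] = value / year_per_t
        else:
            out[name] = value
    return out
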