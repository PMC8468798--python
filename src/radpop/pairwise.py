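"""Two-population demographic models: expectation, fitting, model choice.

Three registered models, in the conventions usual for joint-SFS inference
(sizes relative to the ancestral population, times in 2*N_ANC generations,
migration rates per 2*N_ANC generations):

* ``neutral_no_divergence`` — one panmictic population arbitrarily split
  into two samples; no free parameters.
* ``split_migration`` — split at time ``T`` into sizes ``nu1``/``nu2`` with
  symmetric migration ``m``.
* ``isolation_with_migration`` — as above with asymmetric ``m12``/``m21``.

The expected joint spectrum for the panmictic model is a closed form; for
the split models it is the average over structured-coalescent genealogies
with a fixed internal random stream (common random numbers), which makes the
composite likelihood a deterministic function of the parameters at any given
engine seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import (
    FitResult,
    fisher_information_cis,
    multistart_fit,
    poisson_loglik,
    profile_theta,
)
from .sfs import Sfs2D, apply_mask, fold
from .simulate import PAIRWISE_MODELS, nnd_expected_sfs_2d, simulate_sfs_2d

__all__ = [
    "PairwiseFitConfig",
    "expected_sfs_2d",
    "fit_pairwise",
    "select_model",
    "migrants_per_generation",
    "PAIRWISE_MODELS",
]

_DEFAULT_BOUNDS = {
    "nu1": (1e-2, 1e2),
    "nu2": (1e-2, 1e2),
    "T": (1e-3, 10.0),
    "m": (1e-3, 20.0),
    "m12": (1e-3, 20.0),
    "m21": (1e-3, 20.0),
}


def expected_sfs_2d(
    model_name: str,
    params,
    n1: int,
    n2: int,
    engine_reps: int = 20000,
    engine_seed: int = 987654321,
) -> Sfs2D:
    """Expected joint spectrum at unit mutation rate (theta = 1)."""
    if model_name not in PAIRWISE_MODELS:
        raise KeyError(f"unknown pairwise model {model_name!r}")
    want = PAIRWISE_MODELS[model_name]
    if len(list(params)) != len(want):
        raise ValueError(f"{model_name} takes parameters {want}")
    if model_name == "neutral_no_divergence":
        return nnd_expected_sfs_2d(n1, n2, theta=1.0)
    sfs = simulate_sfs_2d(n1, n2, model_name, params, 1.0, engine_reps,
                          engine_seed)
    return sfs


@dataclass
class PairwiseFitConfig:
    n_starts: int = 10
    seed: int = 0
    engine_reps: int = 600
    engine_seed: int = 987654321
    bounds: dict | None = None
    fixed: dict | None = None  # name -> value, e.g. {"m": 0.0}
    maxfev: int = 400
    perturb_scale: float = 1.0


def _prepare_expected(model_name, params, observed, engine_reps, engine_seed):
    exp_sfs = expected_sfs_2d(model_name, params, observed.n1, observed.n2,
                              engine_reps, engine_seed)
    if observed.folded:
        exp_sfs = fold(exp_sfs)
    exp_sfs.mask = observed.mask.copy()
    return exp_sfs


def fit_pairwise(
    observed: Sfs2D,
    model_name: str,
    config: PairwiseFitConfig | None = None,
) -> FitResult:
    """Multi-start composite-likelihood fit of a registered model.

    Parameters named in ``config.fixed`` are held at the given value (this
    is how a split-without-migration fit is expressed: ``fixed={"m": 0.0}``).
    Deterministic given ``config.seed`` and the engine seed.
    """
    config = config or PairwiseFitConfig()
    if model_name not in PAIRWISE_MODELS:
        raise KeyError(f"unknown pairwise model {model_name!r}")
    all_names = PAIRWISE_MODELS[model_name]
    fixed = dict(config.fixed or {})
    free_names = [p for p in all_names if p not in fixed]
    bounds = dict(_DEFAULT_BOUNDS)
    bounds.update(config.bounds or {})

    def assemble(free_values):
        vals = dict(zip(free_names, free_values))
        vals.update(fixed)
        return [vals[p] for p in all_names]

    def expected_from_logx(logx):
        return _prepare_expected(
            model_name, assemble(np.exp(logx)), observed,
            config.engine_reps, config.engine_seed,
        )

    if not free_names:
        exp_sfs = _prepare_expected(model_name, assemble([]), observed,
                                    config.engine_reps, config.engine_seed)
        theta = profile_theta(observed, exp_sfs)
        ll = poisson_loglik(observed, exp_sfs, theta)
        best_x = np.array([])
        starts_log = []
        converged = True
    else:
        def negll(logx):
            try:
                val = -poisson_loglik(observed, expected_from_logx(logx))
            except (ValueError, FloatingPointError):
                return 1e12
            return val if np.isfinite(val) else 1e12

        x0 = np.array(
            [np.log(np.sqrt(bounds[p][0] * bounds[p][1]))
             if p.startswith("m") else 0.0
             for p in free_names]
        )
        # neutral-ish start: sizes 1, moderate T, geometric-mid migration
        for i, p in enumerate(free_names):
            if p == "T":
                x0[i] = np.log(0.5)
        lower = np.array([np.log(bounds[p][0]) for p in free_names])
        upper = np.array([np.log(bounds[p][1]) for p in free_names])
        best_x, best_fun, starts_log, converged = multistart_fit(
            negll, x0, lower, upper, config.n_starts, config.seed,
            config.perturb_scale, config.maxfev,
        )
        exp_sfs = expected_from_logx(best_x)
        theta = profile_theta(observed, exp_sfs)
        ll = poisson_loglik(observed, exp_sfs, theta)

    full_params = assemble(np.exp(best_x)) if all_names else []
    fit = FitResult(
        model_name=model_name,
        param_names=list(all_names),
        params=np.array(full_params, dtype=float),
        theta=theta,
        loglik=ll,
        n_starts=config.n_starts,
        converged=converged,
        seed=config.seed,
        starts_log=starts_log,
        data_shape=observed.data.shape,
        data_total=observed.total(),
        extra={"config": config, "free_names": free_names,
               "fixed": fixed, "n_free": len(free_names)},
    )
    return fit


def pairwise_confidence_intervals(
    fit: FitResult, observed: Sfs2D, level: float = 0.95
) -> dict:
    """Observed-information CIs for the free parameters plus theta."""
    config: PairwiseFitConfig = fit.extra["config"]
    free_names = fit.extra["free_names"]
    fixed = fit.extra["fixed"]
    vals = fit.params_dict()

    def ll(log_full):
        free = np.exp(log_full[:-1])
        pd_ = dict(zip(free_names, free))
        pd_.update(fixed)
        params = [pd_[p] for p in fit.param_names]
        exp_sfs = _prepare_expected(fit.model_name, params, observed,
                                    config.engine_reps, config.engine_seed)
        return poisson_loglik(observed, exp_sfs, np.exp(log_full[-1]))

    log_full = np.log(
        np.array([vals[p] for p in free_names] + [fit.theta])
    )
    cis, se, wide = fisher_information_cis(
        ll, log_full, free_names + ["theta"], level
    )
    fit.cis = cis
    fit.se_log = se
    fit.wide_ci = wide
    return cis


def select_model(fits: list[FitResult]) -> list[dict]:
    """Rank fits of the same observed spectrum by AIC.

    AIC = 2k - 2 loglik with k the free-parameter count (profiled theta
    included).  Ties break toward fewer parameters.  Returns the ranking,
    best first, with delta-AIC values.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    shapes = {f.data_shape for f in fits}
    totals = {round(f.data_total, 6) for f in fits}
    if len(shapes) > 1 or len(totals) > 1:
        raise ValueError("fits were computed on different observed spectra")
    rows = []
    for f in fits:
        k = f.extra.get("n_free", len(f.params)) + 1
        rows.append({"model": f.model_name, "n_params": k,
                     "loglik": f.loglik, "aic": 2 * k - 2 * f.loglik,
                     "fit": f})
    rows.sort(key=lambda r: (r["aic"], r["n_params"]))
    best = rows[0]["aic"]
    for r in rows:
        r["delta_aic"] = r["aic"] - best
    return rows


def migrants_per_generation(fit: FitResult, receiving_pop: int) -> float:
    """Expected migrant lineages per generation into ``receiving_pop``
    (1 or 2): ``M = m_into * nu_receiving / 2`` with ``m`` per 2*N_ANC
    generations.  Models without migration give 0."""
    vals = fit.params_dict()
    if fit.model_name == "neutral_no_divergence":
        return 0.0
    if fit.model_name == "split_migration":
        m_into = vals["m"]
    elif fit.model_name == "isolation_with_migration":
        m_into = vals["m12"] if receiving_pop == 1 else vals["m21"]
    else:
        return 0.0
    nu = vals["nu1"] if receiving_pop == 1 else vals["nu2"]
    return float(m_into * nu / 2.0)


def migration_rate_from_migrants(M: float, nu_receiving: float) -> float:
    """Inverse of :func:`migrants_per_generation`."""
    return 2.0 * M / nu_receiving
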