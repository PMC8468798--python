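"""Shared machinery for composite-likelihood SFS fitting.

The observed spectrum entries are treated as independent Poisson counts with
means ``theta * m_i``, where ``m_i`` is the model expectation at unit mutation
rate.  theta enters the likelihood linearly, so it is profiled analytically
(``theta_hat = sum(k) / sum(m)`` over unmasked entries) rather than searched.
Uncertainty comes from the observed information (numerical Hessian of the
composite log-likelihood on log-parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import norm

__all__ = [
    "FitResult",
    "poisson_loglik",
    "profile_theta",
    "multistart_fit",
    "fisher_information_cis",
]


@dataclass
class FitResult:
    """Outcome of a multi-start composite-likelihood optimization."""

    model_name: str
    param_names: list[str]
    params: np.ndarray
    theta: float
    loglik: float
    n_starts: int
    converged: bool
    seed: int
    starts_log: list[dict] = field(default_factory=list)
    data_shape: tuple = ()
    data_total: float = 0.0
    se_log: np.ndarray | None = None
    cis: dict | None = None
    wide_ci: bool = False
    extra: dict = field(default_factory=dict)

    @property
    def n_free_params(self) -> int:
        # +1 counts the analytically profiled theta
        return len(self.params) + 1

    def params_dict(self) -> dict:
        return dict(zip(self.param_names, (float(p) for p in self.params)))


def _check_compatible(observed, expected) -> None:
    if observed.data.shape != expected.data.shape:
        raise ValueError("observed and expected spectra have different shapes")
    if observed.folded != expected.folded:
        raise ValueError("fold-state mismatch between observed and expected")
    if not np.array_equal(observed.mask, expected.mask):
        raise ValueError("mask mismatch between observed and expected spectra")


def _unmasked(observed, expected):
    sel = ~np.ravel(observed.mask)
    k = np.ravel(observed.data)[sel]
    m = np.ravel(expected.data)[sel]
    if k.size == 0:
        raise ValueError("all spectrum entries are masked; likelihood undefined")
    return k, m


def profile_theta(observed, expected) -> float:
    """Analytic maximum-likelihood theta for a unit-rate model spectrum."""
    k, m = _unmasked(observed, expected)
    tot = m.sum()
    if tot <= 0:
        raise ValueError("model spectrum has no unmasked mass")
    return float(k.sum() / tot)


def poisson_loglik(observed, expected, theta: float | None = None) -> float:
    """Poisson composite log-likelihood of ``observed`` given
    ``theta * expected``.  With ``theta=None`` the profiled value is used."""
    _check_compatible(observed, expected)
    if theta is None:
        theta = profile_theta(observed, expected)
    if theta <= 0:
        raise ValueError("theta must be positive")
    k, m = _unmasked(observed, expected)
    mu = theta * m
    ll = np.where(
        mu > 0,
        k * np.log(np.where(mu > 0, mu, 1.0)) - mu - gammaln(k + 1),
        np.where(k > 0, -np.inf, 0.0),
    )
    return float(ll.sum())


def multistart_fit(
    objective,
    x0: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    n_starts: int,
    seed: int,
    perturb_scale: float = 1.0,
    maxfev: int = 2000,
):
    """Minimize ``objective`` (negative log-likelihood on log-parameters)
    from ``n_starts`` perturbed starting points with a bounded simplex search.

    The first start uses ``x0`` unperturbed; the rest add N(0, scale) noise in
    log space, clipped to the box.  Returns (best_x, best_fun, starts_log,
    converged).
    """
    rng = np.random.default_rng(seed)
    bounds = list(zip(lower, upper))
    best_x, best_fun = None, np.inf
    starts_log = []
    converged = False
    for s in range(n_starts):
        if s == 0:
            start = x0.copy()
        else:
            start = x0 + rng.normal(0.0, perturb_scale, size=x0.shape)
        start = np.clip(start, lower, upper)
        res = minimize(
            objective,
            start,
            method="Nelder-Mead",
            bounds=bounds,
            options={"maxfev": maxfev, "xatol": 1e-5, "fatol": 1e-7},
        )
        starts_log.append(
            {"start": start.tolist(), "fun": float(res.fun), "nfev": int(res.nfev),
             "success": bool(res.success)}
        )
        if res.fun < best_fun:
            best_fun = float(res.fun)
            best_x = np.asarray(res.x, dtype=float)
    # converged = a finite optimum was reached (per-start simplex success is
    # logged; hitting maxfev with a finite value is still a usable fit)
    converged = best_x is not None and np.isfinite(best_fun) and best_fun < 1e11
    if best_x is None or not np.isfinite(best_fun):
        raise RuntimeError("no optimization start produced a finite objective")
    return best_x, best_fun, starts_log, converged


def fisher_information_cis(
    loglik_fn,
    log_params: np.ndarray,
    names: list[str],
    level: float = 0.95,
    step: float = 1e-3,
):
    """Observed-information standard errors and CIs on log-scale parameters.

    ``loglik_fn`` maps the log-parameter vector (including log-theta as the
    last entry, if desired) to the composite log-likelihood.  Returns
    ``(cis, se_log, wide_ci)`` where ``cis[name] = (estimate, lo, hi)`` are
    back-transformed to the natural scale.  A singular information matrix is
    reported via ``wide_ci=True`` with pseudo-inverse SEs, not an exception.
    """
    p = len(log_params)
    H = np.zeros((p, p))
    f0 = loglik_fn(log_params)
    for i in range(p):
        for j in range(i, p):
            x = log_params.copy()
            if i == j:
                x[i] += step
                fp = loglik_fn(x)
                x[i] -= 2 * step
                fm = loglik_fn(x)
                H[i, i] = (fp - 2 * f0 + fm) / step**2
            else:
                vals = []
                for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                    x = log_params.copy()
                    x[i] += si * step
                    x[j] += sj * step
                    vals.append(loglik_fn(x))
                H[i, j] = H[j, i] = (vals[0] - vals[1] - vals[2] + vals[3]) / (
                    4 * step**2
                )
    info = -H
    wide = False
    try:
        cov = np.linalg.inv(info)
        if not np.all(np.diag(cov) > 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
        wide = True
    se = np.sqrt(np.abs(np.diag(cov)))
    z = norm.ppf(0.5 + level / 2.0) if level > 0 else 0.0
    cis = {}
    for i, name in enumerate(names):
        est = float(np.exp(log_params[i]))
        lo = float(np.exp(log_params[i] - z * se[i]))
        hi = float(np.exp(log_params[i] + z * se[i]))
        cis[name] = (est, lo, hi)
    return cis, se, wide
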