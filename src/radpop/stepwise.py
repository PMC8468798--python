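"""Stepwise time-interval model of effective population size.

A single population's history is described as an ordered series of epochs of
constant relative size: an ancestral epoch of size ``v_anc`` (the reference,
``v_anc = 1``) extending indefinitely into the past, followed by ``n_steps``
intervals, each with its own relative size ``v_k`` and scaled duration
``t_k``.  Rendering many short steps approximates a continuous size
trajectory; the most recent step ends at the present.

Units follow the usual diffusion convention: sizes are relative to the
ancestral size ``N_ANC`` and durations are in units of ``2 * N_ANC``
generations.  The population-scaled mutation rate is
``theta = 4 * N_ANC * mu * L``.

The expected site-frequency spectrum is computed deterministically, without a
diffusion grid, from coalescent theory.  Writing ``A`` for the generator of
the ancestral-lineage death chain (state ``k`` = number of surviving
lineages, rate ``k(k-1)/2`` per unit coalescent time), a change of time
variable turns each constant-size epoch into a matrix-exponential update of
the state distribution, and the expected real time spent with ``k`` lineages
accumulates as ``nu_e * A^{-1} (e^{A dtau} - I) P``.  Branch lengths convert
to frequency classes through the classical subtending probability
``P(branch with k lineages subtends i of n leaves) =
C(n-i-1, k-2) / C(n-1, k-1)``, giving

    E[xi_i] = (theta / 2) * sum_k k * E[T_k] * C(n-i-1, k-2) / C(n-1, k-1).

For a constant-size history this reduces exactly to ``E[xi_i] = theta / i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm, solve_triangular

from .fitting import (
    FitResult,
    fisher_information_cis,
    multistart_fit,
    poisson_loglik,
    profile_theta,
)
from .sfs import Sfs1D, apply_mask, fold

__all__ = [
    "EpochModel",
    "StepwiseFitConfig",
    "expected_sfs_stepwise",
    "composite_loglik",
    "fit_stepwise",
    "confidence_intervals",
]


@dataclass
class EpochModel:
    """Ordered epochs (earliest first) after an indefinitely long ancestral
    epoch of relative size ``v_anc``.

    ``steps`` holds ``(v_k, t_k)`` pairs: size relative to the ancestral
    population and duration in ``2 * N_ANC`` generations.  The last step ends
    at the present.  ``t_anc`` is retained for bookkeeping; coalescence in the
    ancestral epoch is treated analytically (unbounded duration).
    """

    steps: list[tuple[float, float]] = field(default_factory=list)
    v_anc: float = 1.0
    t_anc: float = np.inf

    def __post_init__(self) -> None:
        if self.v_anc <= 0:
            raise ValueError("ancestral size must be positive")
        for v, t in self.steps:
            if v <= 0:
                raise ValueError("epoch sizes must be positive")
            if t < 0:
                raise ValueError("epoch durations must be non-negative")

    @property
    def total_step_time(self) -> float:
        return float(sum(t for _, t in self.steps))

    @classmethod
    def constant(cls, n_steps: int = 0, t_total: float = 1.0) -> "EpochModel":
        """A constant-size history rendered (optionally) as equal steps."""
        if n_steps == 0:
            return cls([])
        return cls([(1.0, t_total / n_steps)] * n_steps)

    def trajectory(self) -> np.ndarray:
        """(time_before_present_start, time_before_present_end, size) rows,
        most recent step first."""
        rows = []
        t = 0.0
        for v, dt in reversed(self.steps):
            rows.append((t, t + dt, v))
            t += dt
        rows.append((t, np.inf, self.v_anc))
        return np.array(rows)


def _death_generator(n: int) -> np.ndarray:
    """Generator of the block-counting chain on states k = 2..n (state 1 is
    absorbing and dropped, making the matrix invertible)."""
    k = np.arange(2, n + 1)
    rates = k * (k - 1) / 2.0
    A = np.diag(-rates)
    for idx in range(1, n - 1):
        A[idx - 1, idx] = rates[idx]
    return A


def expected_lineage_times(model: EpochModel, n: int) -> np.ndarray:
    """Expected real (scaled) time spent with k = 2..n ancestral lineages."""
    m = n - 1
    A = _death_generator(n)
    P = np.zeros(m)
    P[-1] = 1.0  # start with n lineages at the present
    ET = np.zeros(m)
    # walk backward in time: most recent step first
    for v, t in reversed(model.steps):
        if t == 0:
            continue
        dtau = t / v
        E = expm(A * dtau)
        # integral of P over the epoch (standard time), via A^{-1}(e^{At}-I)P
        rhs = E @ P - P
        integral = solve_triangular(A, rhs, lower=False)
        ET += v * integral
        P = E @ P
    # ancestral epoch: from state j the chain visits every k <= j exactly
    # once, with mean holding time v_anc * 2 / (k (k - 1))
    k = np.arange(2, n + 1)
    prob_reach = np.cumsum(P[::-1])[::-1]  # P(K_start >= k)
    ET += model.v_anc * 2.0 / (k * (k - 1)) * prob_reach
    return ET


def expected_sfs_stepwise(model: EpochModel, n: int) -> Sfs1D:
    """Expected unfolded spectrum at unit mutation rate (theta = 1).

    Multiplying the entries by theta gives expected site counts.
    """
    if n < 4:
        raise ValueError("need a haploid sample size of at least 4")
    ET = expected_lineage_times(model, n)
    k = np.arange(2, n + 1)
    # subtending probabilities via log-binomials for numerical range
    from scipy.special import gammaln

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    data = np.zeros(n + 1)
    for i in range(1, n):
        kk = k[k <= n - i + 1]
        logp = log_comb(n - i - 1, kk - 2) - log_comb(n - 1, kk - 1)
        data[i] = 0.5 * np.sum(kk * ET[kk - 2] * np.exp(logp))
    return Sfs1D(data, n, folded=False)


def composite_loglik(observed: Sfs1D, expected_relative: Sfs1D,
                     theta: float | None = None) -> float:
    """Poisson composite log-likelihood over unmasked entries; ``theta=None``
    substitutes the analytic profile estimate."""
    return poisson_loglik(observed, expected_relative, theta)


# ---------------------------------------------------------------------------
# Fitting

@dataclass
class StepwiseFitConfig:
    """Configuration for fitting the stepwise model.

    ``n_free_sizes`` control points carry the free parameters; each control
    segment also has a free duration.  The trajectory is rendered over
    ``n_steps`` short steps, with sizes either constant within a segment
    ("constant") or log-linearly interpolated from the previous control value
    ("geometric"), which renders a continuous size transformation.
    """

    n_free_sizes: int = 10
    n_steps: int = 100
    n_starts: int = 50
    interpolation: str = "geometric"
    size_bounds: tuple[float, float] = (1e-3, 1e3)
    time_bounds: tuple[float, float] = (1e-4, 5.0)
    seed: int = 0
    maxfev: int = 2000
    perturb_scale: float = 1.0
    init_total_time: float = 0.4

    def __post_init__(self) -> None:
        if self.interpolation not in ("geometric", "constant"):
            raise ValueError("interpolation must be 'geometric' or 'constant'")
        if self.n_starts < 1 or self.n_free_sizes < 1:
            raise ValueError("n_starts and n_free_sizes must be >= 1")
        if self.n_steps < self.n_free_sizes:
            raise ValueError("n_steps must be >= n_free_sizes")


def render_epoch_model(
    sizes: np.ndarray,
    durations: np.ndarray,
    n_steps: int,
    interpolation: str = "geometric",
) -> EpochModel:
    """Render K control segments (earliest first) as an ``n_steps``-step
    EpochModel.  In geometric mode segment k interpolates log-linearly from
    the previous control size (the ancestral size 1 for the first segment) to
    its own control size; the segment's final substep lands exactly on the
    control value, so with one substep per segment the two modes agree."""
    K = len(sizes)
    base = n_steps // K
    counts = [base + (1 if k < n_steps % K else 0) for k in range(K)]
    steps: list[tuple[float, float]] = []
    prev = 1.0
    for k in range(K):
        J = counts[k]
        dt = durations[k] / J
        for j in range(J):
            if interpolation == "geometric":
                frac = (j + 1) / J
                v = np.exp((1 - frac) * np.log(prev) + frac * np.log(sizes[k]))
            else:
                v = sizes[k]
            steps.append((float(v), float(dt)))
        prev = sizes[k]
    return EpochModel(steps)


def _stepwise_objective(observed, config):
    K = config.n_free_sizes
    n = observed.n

    def expected_from_logx(logx):
        sizes = np.exp(logx[:K])
        durations = np.exp(logx[K:])
        model = render_epoch_model(sizes, durations, config.n_steps,
                                   config.interpolation)
        exp_sfs = expected_sfs_stepwise(model, n)
        if observed.folded:
            exp_sfs = fold(exp_sfs)
        exp_sfs.mask = observed.mask.copy()
        return exp_sfs

    def negll(logx):
        try:
            exp_sfs = expected_from_logx(logx)
            val = -poisson_loglik(observed, exp_sfs)
        except (ValueError, np.linalg.LinAlgError):
            return 1e12
        return val if np.isfinite(val) else 1e12

    return expected_from_logx, negll


def fit_stepwise(observed: Sfs1D, config: StepwiseFitConfig) -> FitResult:
    """Multi-start fit of the stepwise model to a folded, masked spectrum.

    Starts differ only in their randomly perturbed initial log-parameters;
    the best composite log-likelihood wins.  Deterministic given
    ``config.seed``.
    """
    K = config.n_free_sizes
    expected_from_logx, negll = _stepwise_objective(observed, config)
    x0 = np.concatenate(
        [np.zeros(K), np.full(K, np.log(config.init_total_time / K))]
    )
    lower = np.concatenate(
        [np.full(K, np.log(config.size_bounds[0])),
         np.full(K, np.log(config.time_bounds[0]))]
    )
    upper = np.concatenate(
        [np.full(K, np.log(config.size_bounds[1])),
         np.full(K, np.log(config.time_bounds[1]))]
    )
    best_x, best_fun, starts_log, converged = multistart_fit(
        negll, x0, lower, upper, config.n_starts, config.seed,
        config.perturb_scale, config.maxfev,
    )
    exp_sfs = expected_from_logx(best_x)
    theta = profile_theta(observed, exp_sfs)
    names = [f"v_{k}" for k in range(K)] + [f"t_{k}" for k in range(K)]
    model = render_epoch_model(
        np.exp(best_x[:K]), np.exp(best_x[K:]), config.n_steps,
        config.interpolation,
    )
    return FitResult(
        model_name="stepwise",
        param_names=names,
        params=np.exp(best_x),
        theta=theta,
        loglik=-best_fun,
        n_starts=config.n_starts,
        converged=converged,
        seed=config.seed,
        starts_log=starts_log,
        data_shape=observed.data.shape,
        data_total=observed.total(),
        extra={"config": config, "epoch_model": model},
    )


def confidence_intervals(fit: FitResult, observed: Sfs1D,
                         level: float = 0.95) -> dict:
    """Per-parameter 95% (by default) CIs from the observed information of
    the composite likelihood, computed on log parameters (including theta)
    and back-transformed."""
    if fit.model_name != "stepwise":
        raise ValueError("expected a stepwise FitResult")
    config: StepwiseFitConfig = fit.extra["config"]
    expected_from_logx, _ = _stepwise_objective(observed, config)

    def ll(logx_full):
        exp_sfs = expected_from_logx(logx_full[:-1])
        return poisson_loglik(observed, exp_sfs, np.exp(logx_full[-1]))

    log_full = np.concatenate([np.log(fit.params), [np.log(fit.theta)]])
    names = fit.param_names + ["theta"]
    cis, se, wide = fisher_information_cis(ll, log_full, names, level)
    fit.cis = cis
    fit.se_log = se
    fit.wide_ci = wide
    return cis
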