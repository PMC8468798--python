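"""The stepwise time-interval Ne model: expectation engine, likelihood, fit."""

import math

import numpy as np
import pytest

from radpop.sfs import Sfs1D, apply_mask, fold
from radpop.simulate import simulate_sfs_1d
from radpop.stepwise import (EpochModel, StepwiseFitConfig, composite_loglik,
                             confidence_intervals, expected_sfs_stepwise,
                             fit_stepwise, render_epoch_model)
from radpop.fitting import profile_theta


class TestExpectationEngine:
    @pytest.mark.parametrize("n", [10, 40, 60])
    def test_constant_history_reduces_to_theta_over_i(self, n):
        sfs = expected_sfs_stepwise(EpochModel.constant(), n)
        expected = 1.0 / np.arange(1, n)
        assert np.abs(sfs.data[1:n] / expected - 1).max() < 0.01

    def test_constant_rendered_as_100_steps_still_exact(self):
        sfs = expected_sfs_stepwise(EpochModel.constant(100, 2.0), 40)
        expected = 1.0 / np.arange(1, 40)
        assert np.abs(sfs.data[1:40] / expected - 1).max() < 1e-10

    def test_recent_expansion_enriches_singletons(self):
        sfs = expected_sfs_stepwise(EpochModel([(10.0, 0.1)]), 20)
        assert sfs.data[1] / sfs.data[2] > 2.0

    def test_merging_equal_adjacent_steps_is_neutral(self):
        a = expected_sfs_stepwise(EpochModel([(3.0, 0.2), (3.0, 0.3)]), 15)
        b = expected_sfs_stepwise(EpochModel([(3.0, 0.5)]), 15)
        assert np.allclose(a.data, b.data)

    def test_time_reversed_bottleneck_is_not_expansion(self):
        bottleneck = expected_sfs_stepwise(
            EpochModel([(0.1, 0.2), (1.0, 0.2)]), 20)
        expansion = expected_sfs_stepwise(
            EpochModel([(1.0, 0.2), (0.1, 0.2)]), 20)
        assert not np.allclose(bottleneck.data[1:20], expansion.data[1:20],
                               rtol=0.05)

    def test_matches_simulated_genealogies(self):
        model = EpochModel([(1.0, 0.4), (10.0, 0.1)])
        n = 20
        det = expected_sfs_stepwise(model, n)
        sim = simulate_sfs_1d(n, model, 1.0, 30_000, seed=21)
        z = (sim.data[1:n] - det.data[1:n]) / sim.stderr[1:n]
        assert np.abs(z).max() < 4

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            expected_sfs_stepwise(EpochModel.constant(), 3)


class TestCompositeLoglik:
    def test_hand_computed_three_entry_case(self):
        k = np.array([0.0, 2.0, 1.0])
        m = np.array([0.0, 1.0, 0.5])
        theta = 2.0
        obs = Sfs1D(k, 2, mask=np.array([True, False, False]))
        exp = Sfs1D(m, 2, mask=np.array([True, False, False]))
        expected = sum(
            ki * math.log(theta * mi) - theta * mi - math.log(math.factorial(int(ki)))
            for ki, mi in [(2, 1.0), (1, 0.5)]
        )
        assert composite_loglik(obs, exp, theta) == pytest.approx(expected)

    def test_profiled_theta_recovers_scaling_exactly(self):
        exp = expected_sfs_stepwise(EpochModel.constant(), 12)
        theta = 37.5
        obs = Sfs1D(theta * exp.data, 12)
        assert profile_theta(obs, exp) == pytest.approx(theta, rel=1e-14)

    def test_all_masked_spectrum_is_an_error(self):
        obs = Sfs1D(np.ones(5), 4, mask=np.ones(5, bool))
        exp = Sfs1D(np.ones(5), 4, mask=np.ones(5, bool))
        with pytest.raises(ValueError):
            composite_loglik(obs, exp, 1.0)

    def test_fold_state_mismatch_rejected(self):
        obs = fold(Sfs1D(np.ones(5), 4))
        exp = Sfs1D(np.ones(5), 4)
        with pytest.raises(ValueError):
            composite_loglik(obs, exp, 1.0)


class TestRendering:
    def test_constant_mode_renders_plateaus(self):
        m = render_epoch_model(np.array([2.0, 5.0]), np.array([0.4, 0.2]),
                               4, "constant")
        assert [v for v, _ in m.steps] == [2.0, 2.0, 5.0, 5.0]
        assert sum(t for _, t in m.steps) == pytest.approx(0.6)

    def test_geometric_mode_is_monotone_and_hits_control_value(self):
        m = render_epoch_model(np.array([8.0]), np.array([0.5]), 10,
                               "geometric")
        sizes = [v for v, _ in m.steps]
        assert all(a < b for a, b in zip(sizes, sizes[1:]))
        assert sizes[0] > 1.0
        assert sizes[-1] == pytest.approx(8.0)

    def test_one_substep_geometric_equals_constant(self):
        g = render_epoch_model(np.array([4.0, 9.0]), np.array([0.2, 0.1]),
                               2, "geometric")
        c = render_epoch_model(np.array([4.0, 9.0]), np.array([0.2, 0.1]),
                               2, "constant")
        assert np.allclose(np.array(g.steps), np.array(c.steps))


class TestFit:
    def _observed(self, seed=0):
        truth = EpochModel([(10.0, 0.1)])
        det = expected_sfs_stepwise(truth, 20)
        theta = 2000 / det.data[1:20].sum()
        rng = np.random.default_rng(seed)
        return fold(Sfs1D(rng.poisson(theta * det.data).astype(float), 20))

    def test_fixed_seed_fit_is_bit_identical(self):
        obs = self._observed()
        cfg = StepwiseFitConfig(n_free_sizes=1, n_steps=1, n_starts=1,
                                interpolation="constant", seed=5, maxfev=300)
        f1 = fit_stepwise(obs, cfg)
        f2 = fit_stepwise(obs, cfg)
        assert np.array_equal(f1.params, f2.params)
        assert f1.loglik == f2.loglik and f1.theta == f2.theta

    def test_best_loglik_nondecreasing_in_starts(self):
        obs = self._observed()
        lls = []
        for n_starts in (1, 4):
            cfg = StepwiseFitConfig(n_free_sizes=1, n_steps=1,
                                    n_starts=n_starts,
                                    interpolation="constant", seed=2,
                                    maxfev=300)
            lls.append(fit_stepwise(obs, cfg).loglik)
        assert lls[1] >= lls[0] - 1e-9

    def test_constant_truth_yields_flat_trajectory(self):
        det = expected_sfs_stepwise(EpochModel.constant(), 20)
        theta = 3000 / det.data[1:20].sum()
        rng = np.random.default_rng(4)
        obs = fold(Sfs1D(rng.poisson(theta * det.data).astype(float), 20))
        cfg = StepwiseFitConfig(n_free_sizes=2, n_steps=4, n_starts=3,
                                interpolation="constant", seed=6, maxfev=500)
        fit = fit_stepwise(obs, cfg)
        sizes = [v for v, _ in fit.extra["epoch_model"].steps]
        assert max(sizes) / min(sizes) <= 1.5


class TestConfidenceIntervals:
    def _fit(self, obs, seed=1):
        cfg = StepwiseFitConfig(n_free_sizes=1, n_steps=1, n_starts=2,
                                interpolation="constant", seed=seed,
                                maxfev=400)
        return fit_stepwise(obs, cfg)

    def test_zero_level_collapses_to_estimate(self):
        truth = EpochModel([(5.0, 0.2)])
        det = expected_sfs_stepwise(truth, 16)
        obs = fold(Sfs1D(np.round(100 * det.data), 16))
        fit = self._fit(obs)
        cis = confidence_intervals(fit, obs, level=0.0)
        for est, lo, hi in cis.values():
            assert lo == pytest.approx(est) and hi == pytest.approx(est)

    def test_duplicated_data_shrinks_se_by_sqrt2(self):
        truth = EpochModel([(5.0, 0.2)])
        det = expected_sfs_stepwise(truth, 16)
        theta = 4000 / det.data[1:16].sum()
        rng = np.random.default_rng(8)
        counts = rng.poisson(theta * det.data).astype(float)
        obs1 = fold(Sfs1D(counts.copy(), 16))
        obs2 = fold(Sfs1D(2 * counts, 16))  # two concatenated copies
        f1 = self._fit(obs1)
        confidence_intervals(f1, obs1)
        f2 = self._fit(obs2)
        confidence_intervals(f2, obs2)
        ratio = f2.se_log / f1.se_log
        assert np.median(ratio) == pytest.approx(1 / np.sqrt(2), rel=0.15)
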