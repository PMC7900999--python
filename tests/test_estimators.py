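"""Monte Carlo estimators: allocation, rates, bias, MC/QMC/MLMC loops."""

import numpy as np
import pytest

from tracermc import estimators as est


def _synthetic_stats(levels, bias_fn, var_fn, n=400, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    out = []
    for level in levels:
        s = est.LevelStats(level=level)
        b, sd = bias_fn(level), np.sqrt(var_fn(level))
        for _ in range(n):
            y = b * (1 + noise * rng.standard_normal()) + sd * rng.standard_normal()
            s.update(np.array([y]), np.array([0.0]))
        out.append(s)
    return out


class TestOptimalAllocation:
    def test_worked_two_level_case(self):
        # V = [4, 1], C = [1, 4], theta = 0, eps = 1: N = [8, 2]
        N = est.optimal_allocation([4, 1], [1, 4], eps=1.0, theta=0.0, floor=1)
        assert list(N) == [8, 2]
        # and the variance budget identity sum V_l/N_l = eps^2 holds
        assert 4 / N[0] + 1 / N[1] == pytest.approx(1.0)

    def test_single_level_reduces_to_mc_count(self):
        N = est.optimal_allocation([2.0], [1.0], eps=0.1, theta=0.5, floor=1)
        assert N[0] == int(np.ceil(2.0 / (0.5 * 0.01)))

    def test_halving_eps_quadruples_counts(self):
        a = est.optimal_allocation([4, 1], [1, 4], eps=0.5, theta=0.0, floor=1)
        b = est.optimal_allocation([4, 1], [1, 4], eps=0.25, theta=0.0, floor=1)
        assert list(b) == [4 * x for x in a]

    def test_counts_decay_when_variance_falls_faster_than_cost_grows(self):
        V = [2.0 ** (-4 * l) for l in range(1, 5)]
        C = [2.0 ** (2 * l) for l in range(1, 5)]
        N = est.optimal_allocation(V, C, eps=1e-3, theta=0.5, floor=1)
        assert all(N[i] >= N[i + 1] for i in range(3))


class TestRateEstimation:
    def test_exact_geometric_variance_decay(self):
        stats = []
        for level in (2, 3, 4):
            s = est.LevelStats(level=level)
            s.n = 10
            s._sy = np.array([0.0])
            s._sy2 = np.array([9 * 2.0 ** (-4 * level)])
            s._sq = np.zeros(1)
            s._sq2 = np.zeros(1)
            s._sm2 = np.zeros(1)
            stats.append(s)
        r = est.estimate_rates(stats)
        assert r.beta == pytest.approx(4.0, abs=1e-9)

    def test_constant_variance_gives_zero_rate(self):
        stats = _synthetic_stats((2, 3, 4), lambda l: 0.0, lambda l: 1.0, seed=1)
        assert abs(est.estimate_rates(stats).beta) < 0.5

    def test_noisy_bias_regression_recovers_slope(self):
        stats = _synthetic_stats(
            (2, 3, 4, 5), lambda l: 5 * 2.0 ** (-2 * l), lambda l: 1e-12, noise=0.01
        )
        r = est.estimate_rates(stats)
        assert r.alpha == pytest.approx(2.0, abs=0.1)

    def test_requires_two_level_differences(self):
        stats = _synthetic_stats((2,), lambda l: 1.0, lambda l: 1.0, n=10)
        with pytest.raises(est.EstimatorError):
            est.estimate_rates(stats)


class TestBiasExtrapolation:
    def test_zero_mean_difference_gives_zero_bias(self):
        stats = _synthetic_stats((2, 3), lambda l: 0.0, lambda l: 1e-30, n=5)
        assert est.bias_estimate(stats, alpha=2.0) == pytest.approx(0.0, abs=1e-12)

    def test_exact_geometric_tail(self):
        # E[Y_l] = c 2^(-alpha l): the remainder sum_{l>L} equals
        # |E Y_L| / (2^alpha - 1) exactly
        c, alpha, L = 5.0, 2.0, 4
        stats = _synthetic_stats(
            (3, 4), lambda l: c * 2.0 ** (-alpha * l), lambda l: 1e-30, n=5
        )
        tail = sum(c * 2.0 ** (-alpha * l) for l in range(L + 1, 60))
        assert est.bias_estimate(stats, alpha) == pytest.approx(tail, rel=1e-9)

    def test_slower_decay_doubles_the_estimate(self):
        stats = _synthetic_stats((2, 3), lambda l: 2.0 ** (-l), lambda l: 1e-30, n=5)
        b1 = est.bias_estimate(stats, alpha=1.0)
        b2 = est.bias_estimate(stats, alpha=2.0)
        assert b1 == pytest.approx(3 * b2)

    def test_nonpositive_alpha_rejected(self):
        stats = _synthetic_stats((2, 3), lambda l: 1.0, lambda l: 1.0, n=5)
        with pytest.raises(est.EstimatorError):
            est.bias_estimate(stats, alpha=0.0)


class TestStandardMC:
    def test_degenerate_constant_sampler(self):
        cfg = est.EstimatorConfig(eps=0.1, n_initial=8, seed=0)
        res = est.mc_estimate(lambda rng: np.array([3.0]), cfg)
        assert res.estimate[0] == 3.0
        assert res.variance == 0.0
        assert res.allocation[1] == 8

    def test_gaussian_mean_within_clt_band(self):
        mu, sd = 1.0, 0.5
        cfg = est.EstimatorConfig(eps=0.03, theta=0.5, seed=3)
        res = est.mc_estimate(lambda rng: np.array([rng.normal(mu, sd)]), cfg)
        n = res.allocation[1]
        assert abs(res.estimate[0] - mu) < 3 * sd / np.sqrt(n)
        assert res.variance <= (1 - cfg.theta) * cfg.eps**2

    def test_cost_is_count_times_level_cost(self):
        cfg = est.EstimatorConfig(eps=0.5, seed=1, c3=2.0, gamma=3.0)
        res = est.mc_estimate(lambda rng: np.array([rng.normal()]), cfg, level=2)
        assert res.total_cost == res.allocation[2] * 2.0 * 2.0 ** (3.0 * 2)


class TestRandomizedQMC:
    def test_product_integrand_value_and_default_randomizations(self):
        s = 3
        cfg = est.EstimatorConfig(eps=0.002, seed=4)
        res = est.qmc_estimate(lambda u: np.array([np.prod(u[:s])]), s, cfg)
        assert cfg.qmc_randomizations == 32
        assert res.info["M"] == 32
        assert res.estimate[0] == pytest.approx(2.0**-s, abs=3 * res.std_error[0] + 1e-4)

    def test_constant_integrand_has_zero_variance(self):
        cfg = est.EstimatorConfig(eps=0.1, seed=5)
        res = est.qmc_estimate(lambda u: np.array([2.0]), 4, cfg)
        assert res.variance == 0.0
        assert res.info["n"] == 1

    def test_error_decays_near_first_order(self):
        # scrambled-net error on a smooth 4D integrand: fitted slope of the
        # per-randomization std vs N clearly steeper than the MC -1/2
        s, M = 4, 16
        rng_seeds = np.random.SeedSequence(6).spawn(M)
        from scipy.stats import qmc as sq

        engines = [sq.Sobol(s, scramble=True, seed=np.random.default_rng(c)) for c in rng_seeds]
        Ns = [8, 32, 128, 512]
        stds = []
        for N in Ns:
            means = []
            for eng in engines:
                eng.reset()
                pts = eng.random(N)
                means.append(np.prod(pts, axis=1).mean())
            stds.append(np.std(means, ddof=1))
        slope = np.polyfit(np.log2(Ns), np.log2(stds), 1)[0]
        assert slope < -0.8

    def test_dimension_limit_raises(self):
        cfg = est.EstimatorConfig(eps=0.1, seed=0)
        with pytest.raises(est.EstimatorError, match="dimension"):
            est.qmc_estimate(lambda u: np.array([0.0]), 30000, cfg)


class TestMLMC:
    @staticmethod
    def _coupled_toy(level, rng, rate=2.0, noise=0.3):
        z = rng.normal()
        e = rng.normal()
        ql = z + 2.0 ** (-rate * level) * (1 + noise * e)
        qc = 0.0 if level == 1 else z + 2.0 ** (-rate * (level - 1)) * (1 + noise * e)
        return np.array([ql]), np.array([qc])

    def test_telescoping_identity_with_shared_events(self):
        # when every level sees the same event list, the sum of level means
        # reproduces the finest-level sample mean exactly
        rng = np.random.default_rng(7)
        z = rng.standard_normal(50)
        q1 = 2 * z
        q2 = 2 * z + 0.3
        q3 = 2 * z + 0.35
        stats = [est.LevelStats(level=l) for l in (1, 2, 3)]
        for i in range(50):
            stats[0].update(np.array([q1[i]]), np.array([0.0]))
            stats[1].update(np.array([q2[i]]), np.array([q1[i]]))
            stats[2].update(np.array([q3[i]]), np.array([q2[i]]))
        total = sum(s.mean_y[0] for s in stats)
        assert total == pytest.approx(q3.mean(), rel=1e-12)

    def test_degenerate_identical_levels_match_single_level_mc(self):
        def pair(level, rng):
            q = np.array([rng.normal(2.0, 1.0)])
            return (q, np.zeros(1)) if level == 1 else (q, q)

        cfg = est.EstimatorConfig(eps=0.2, seed=8, gamma=1.0)
        res = est.mlmc_estimate(pair, 2, cfg)
        assert np.all(res.info["stats"][2].var_y == 0)
        assert res.estimate[0] == pytest.approx(res.info["stats"][1].mean_y[0])

    def test_unbiased_on_linear_gaussian_toy(self):
        cfg = est.EstimatorConfig(eps=0.04, seed=9, gamma=2.0)
        res = est.mlmc_estimate(self._coupled_toy, 6, cfg)
        # exact mean of Q_infinity is 0 + remainder of the 2^-2l ladder
        assert res.converged
        assert abs(res.estimate[0] - 2.0 ** (-2 * max(res.allocation))) < max(
            3 * np.sqrt(res.variance) + res.bias, 0.05
        )

    def test_variance_budget_respected_on_success(self):
        cfg = est.EstimatorConfig(eps=0.05, seed=10, gamma=2.0)
        res = est.mlmc_estimate(self._coupled_toy, 6, cfg)
        assert res.converged
        assert res.variance <= (1 - cfg.theta) * cfg.eps**2 + 1e-12

    def test_uncoupled_sampling_destroys_variance_reduction(self):
        rng = np.random.default_rng(11)
        coupled = est.LevelStats(level=2)
        uncoupled = est.LevelStats(level=2)
        for _ in range(3000):
            qf, qc = self._coupled_toy(2, rng)
            coupled.update(qf, qc)
            qf2, _ = self._coupled_toy(2, rng)
            _, qc2 = self._coupled_toy(2, rng)
            uncoupled.update(qf2, qc2)
        var_q = 1.0  # Var[z]
        assert uncoupled.var_y[0] > 0.8 * 2 * var_q
        assert coupled.var_y[0] < 0.1 * var_q

    def test_failed_convergence_reported_at_level_cap(self):
        def biased_pair(level, rng):
            # bias does not decay: no level can satisfy the bias share
            q = np.array([rng.normal(1.0, 0.1) + 1.0])
            qc = np.array([0.0]) if level == 1 else np.array([rng.normal(1.0, 0.1)])
            return q, qc

        cfg = est.EstimatorConfig(eps=0.01, seed=12, gamma=1.0, n_cap=200)
        res = est.mlmc_estimate(biased_pair, 3, cfg)
        assert not res.converged
        assert res.info["best_eps"] is None or res.info["best_eps"] > cfg.eps


class TestComparison:
    def test_costs_match_hand_computed_allocation(self):
        stats = _synthetic_stats(
            (1, 2, 3),
            lambda l: 2.0 ** (-2 * l),
            lambda l: 2.0 ** (-4 * l),
            n=2000,
            seed=13,
        )
        rates = est.estimate_rates(stats)
        cfg = est.EstimatorConfig(eps=1e-2, theta=0.5, gamma=4.0, c3=1.0)
        eps = 0.02
        table = est.compare_methods(stats, rates, cfg, [eps])
        V = np.array([s.max_var_y for s in stats])
        C = np.array([cfg.pseudo_cost(l) for l in (1, 2, 3)])
        L = int(table.loc[0, "mlmc_levels"])
        N = est.optimal_allocation(V[:L], C[:L], eps, 0.5, 2)
        assert table.loc[0, "mlmc_cost"] == pytest.approx(float(np.sum(N * C[:L])))
        n_mc = stats[-1].var_q.max() / (0.5 * eps**2)
        assert table.loc[0, "mc_cost"] == pytest.approx(n_mc * C[-1])

    def test_single_level_degenerate_hierarchy_matches_mc(self):
        # one level: the MLMC allocation collapses to the MC sample count
        s = _synthetic_stats((1,), lambda l: 1.0, lambda l: 4.0, n=5000, seed=14)[0]
        cfg = est.EstimatorConfig(eps=0.1, theta=0.5, gamma=2.0)
        N = est.optimal_allocation([s.max_var_y], [cfg.pseudo_cost(1)], 0.1, 0.5, 1)
        n_mc = int(np.ceil(s.max_var_y / (0.5 * 0.01)))
        assert abs(N[0] - n_mc) <= 1
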