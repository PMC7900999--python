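"""Standard, quasi and multilevel Monte Carlo estimators.

All estimators handle vector-valued output functionals; stopping and sample
allocation are driven by the worst (max-over-functionals) variance and bias,
while per-functional errors are also reported.  The mean-square error budget
eps^2 is split as bias^2 <= theta eps^2 and variance <= (1 - theta) eps^2.

MLMC uses the telescoping estimator over coupled level pairs
Y_l = Q_l - Q_(l-1) (Q_0 = 0), the optimal per-level allocation

    N_l = (1-theta)^-1 eps^-2 (sum_l sqrt(V_l C_l)) sqrt(V_l / C_l),

geometric-decay rate estimation by log2 least squares, and a geometric-tail
bias extrapolation |E Y_L| / (2^alpha - 1).  Randomized QMC uses M
independently scrambled Sobol sequences (default M = 32) with sample doubling
until the estimator variance meets its budget.

Costs default to a pseudo-cost model C_l = c3 * 2^(gamma l); wall-clock
costs can be recorded but the method comparisons use pseudo-costs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd
from scipy.stats import qmc as scipy_qmc


class EstimatorError(RuntimeError):
    pass


@dataclass
class EstimatorConfig:
    eps: float
    theta: float = 0.5
    max_level: int | None = None
    n_initial: int = 8
    qmc_randomizations: int = 32
    seed: int = 0
    cost_model: str = "pseudo"  # or "wallclock"
    c3: float = 1.0
    gamma: float = 4.0
    alpha_fallback: float = 2.0  # used before two level differences exist
    sample_floor: int = 2
    n_cap: int = 200_000  # safety cap on any single-level sample count

    def __post_init__(self):
        if self.eps <= 0:
            raise EstimatorError("eps must be positive")
        if not 0 < self.theta < 1:
            raise EstimatorError("theta must be in (0, 1)")
        if self.qmc_randomizations < 2:
            raise EstimatorError("need at least 2 QMC randomizations")

    def pseudo_cost(self, level: int) -> float:
        return self.c3 * 2.0 ** (self.gamma * level)


def _rng_for(seed: int, level: int, index: int) -> np.random.Generator:
    """Counter-based stream: reproducible under re-allocation."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(level, index)))


@dataclass
class LevelStats:
    """Streaming sample moments of Q_l and Y_l = Q_l - Q_(l-1) on one level."""

    level: int
    n: int = 0
    _sy: np.ndarray | None = None
    _sy2: np.ndarray | None = None
    _sq: np.ndarray | None = None
    _sq2: np.ndarray | None = None
    _sm2: np.ndarray | None = None  # sum of (Q_l^2 - Q_(l-1)^2), for SD telescoping
    cost: float = 0.0  # accumulated wall-clock (optional)

    def update(self, q_fine: np.ndarray, q_coarse: np.ndarray, cost: float = 0.0):
        qf = np.asarray(q_fine)
        qc = np.asarray(q_coarse)
        y = qf - qc
        if self._sy is None:
            k = y.size
            self._sy = np.zeros(k)
            self._sy2 = np.zeros(k)
            self._sq = np.zeros(k)
            self._sq2 = np.zeros(k)
            self._sm2 = np.zeros(k)
        self.n += 1
        self._sy += y
        self._sy2 += y**2
        self._sq += qf
        self._sq2 += qf**2
        self._sm2 += qf**2 - qc**2
        self.cost += cost

    @property
    def mean_y(self) -> np.ndarray:
        return self._sy / self.n

    @property
    def var_y(self) -> np.ndarray:
        if self.n < 2:
            return np.zeros_like(self._sy)
        return np.maximum(0.0, (self._sy2 - self._sy**2 / self.n) / (self.n - 1))

    @property
    def mean_q(self) -> np.ndarray:
        return self._sq / self.n

    @property
    def var_q(self) -> np.ndarray:
        if self.n < 2:
            return np.zeros_like(self._sq)
        return np.maximum(0.0, (self._sq2 - self._sq**2 / self.n) / (self.n - 1))

    @property
    def mean_m2(self) -> np.ndarray:
        """Mean of Q_l^2 - Q_(l-1)^2 (telescopes to E[Q_L^2])."""
        return self._sm2 / self.n

    @property
    def max_var_y(self) -> float:
        return float(self.var_y.max())

    @property
    def max_abs_mean_y(self) -> float:
        return float(np.abs(self.mean_y).max())


@dataclass
class RateEstimates:
    alpha: float
    beta: float
    gamma: float
    c1: float
    c2: float
    c3: float
    levels_used: list = dfield(default_factory=list)


def estimate_rates(
    stats: list[LevelStats], costs: list[float] | None = None
) -> RateEstimates:
    """Least-squares log2 decay/growth rates from level differences (l >= 2)."""
    diff = [s for s in stats if s.level >= 2 and s.n >= 2]
    if len(diff) < 2:
        raise EstimatorError("rate estimation needs at least two level differences")
    ls = np.array([s.level for s in diff], dtype=float)
    bias = np.array([max(s.max_abs_mean_y, 1e-300) for s in diff])
    var = np.array([max(s.max_var_y, 1e-300) for s in diff])
    a_slope, a_icpt = np.polyfit(ls, np.log2(bias), 1)
    b_slope, b_icpt = np.polyfit(ls, np.log2(var), 1)
    if costs is not None:
        lc = np.array([s.level for s in stats], dtype=float)
        g_slope, g_icpt = np.polyfit(lc, np.log2(np.maximum(costs, 1e-300)), 1)
    else:
        g_slope, g_icpt = 0.0, 0.0
    return RateEstimates(
        alpha=-a_slope,
        beta=-b_slope,
        gamma=g_slope,
        c1=2.0**a_icpt,
        c2=2.0**b_icpt,
        c3=2.0**g_icpt,
        levels_used=[s.level for s in diff],
    )


def bias_estimate(stats: list[LevelStats], alpha: float) -> float:
    """Geometric-tail extrapolation max_Q |E Y_L| / (2^alpha - 1)."""
    if alpha <= 0:
        raise EstimatorError("alpha must be positive for bias extrapolation")
    finest = max(stats, key=lambda s: s.level)
    return finest.max_abs_mean_y / (2.0**alpha - 1.0)


def optimal_allocation(
    variances: np.ndarray, costs: np.ndarray, eps: float, theta: float, floor: int = 2
) -> np.ndarray:
    """Per-level sample counts minimising cost at statistical error (1-theta)eps^2."""
    V = np.asarray(variances, dtype=float)
    C = np.asarray(costs, dtype=float)
    if np.any(C <= 0):
        raise EstimatorError("costs must be positive")
    budget = (1.0 - theta) * eps**2
    total = np.sum(np.sqrt(V * C))
    N = np.ceil(total / budget * np.sqrt(V / C))
    return np.maximum(N, floor).astype(int)


@dataclass
class EstimatorResult:
    estimate: np.ndarray
    std_error: np.ndarray  # per-functional statistical error (std of estimator)
    variance: float  # worst-functional estimator variance
    bias: float
    eps: float
    theta: float
    total_cost: float
    allocation: dict
    converged: bool
    method: str
    info: dict = dfield(default_factory=dict)

    @property
    def mse_ok(self) -> bool:
        return (
            self.variance <= (1 - self.theta) * self.eps**2 + 1e-15
            and self.bias**2 <= self.theta * self.eps**2 + 1e-15
        )


# ---------------------------------------------------------------------------
# standard MC
# ---------------------------------------------------------------------------


def mc_estimate(
    sample_fn,
    config: EstimatorConfig,
    cost_per_sample: float | None = None,
    level: int = 1,
) -> EstimatorResult:
    """Single-level Monte Carlo on a fixed discretization level.

    ``sample_fn(rng) -> array`` draws one functional vector.  The caller is
    responsible for choosing the level fine enough that the bias is within
    its sqrt(theta) eps share.  N grows until max_Q V[Q]/N <= (1-theta)eps^2.
    """
    if cost_per_sample is None:
        cost_per_sample = config.pseudo_cost(level)
    budget = (1 - config.theta) * config.eps**2
    stats = LevelStats(level=level)
    n_target = max(config.n_initial, config.sample_floor)
    converged = False
    while True:
        while stats.n < n_target:
            q = np.atleast_1d(np.asarray(sample_fn(_rng_for(config.seed, level, stats.n))))
            stats.update(q, np.zeros_like(q))
        vmax = stats.max_var_y  # Y = Q on a single level
        if vmax / stats.n <= budget:
            converged = True
            break
        needed = int(np.ceil(vmax / budget))
        if needed > config.n_cap:
            break
        n_target = max(needed, stats.n + 1)
    return EstimatorResult(
        estimate=stats.mean_y,
        std_error=np.sqrt(stats.var_y / stats.n),
        variance=stats.max_var_y / stats.n,
        bias=0.0,
        eps=config.eps,
        theta=config.theta,
        total_cost=stats.n * cost_per_sample,
        allocation={level: stats.n},
        converged=converged,
        method="mc",
    )


# ---------------------------------------------------------------------------
# randomized QMC
# ---------------------------------------------------------------------------


def qmc_estimate(
    sample_fn,
    dim: int,
    config: EstimatorConfig,
    cost_per_sample: float | None = None,
    level: int = 1,
    n_initial: int = 1,
    n_max: int = 2**14,
) -> EstimatorResult:
    """Randomized quasi Monte Carlo with M scrambled Sobol streams.

    ``sample_fn(u) -> array`` evaluates the integrand at one point of the
    unit cube (dimension ``dim``; scalar inputs first, then white-noise
    coordinates in coarse-to-fine order).  The estimator is the average of
    the M per-scramble means; its variance is their sample variance over M.
    N doubles until the variance budget (1-theta)eps^2 is met.
    """
    if dim > 21201:
        raise EstimatorError(
            "QMC dimension exceeds the Sobol generator limit; reduce the level "
            "or the field resolution"
        )
    if cost_per_sample is None:
        cost_per_sample = config.pseudo_cost(level)
    M = config.qmc_randomizations
    ss = np.random.SeedSequence(config.seed, spawn_key=(987, 0))
    engines = [
        scipy_qmc.Sobol(d=dim, scramble=True, seed=np.random.default_rng(child))
        for child in ss.spawn(M)
    ]
    sums = None
    n = 0
    n_next = max(1, n_initial)
    budget = (1 - config.theta) * config.eps**2
    converged = False
    history = []  # (N, worst estimator variance) after each doubling
    while True:
        draw = n_next - n
        for m, eng in enumerate(engines):
            pts = eng.random(draw)
            vals = np.array([np.atleast_1d(sample_fn(u)) for u in pts])
            s = vals.sum(axis=0)
            if sums is None:
                sums = np.zeros((M, s.size))
            sums[m] += s
        n = n_next
        means = sums / n  # (M, k)
        est_var = means.var(axis=0, ddof=1) / M
        history.append((n, float(est_var.max())))
        if float(est_var.max()) <= budget:
            converged = True
            break
        if 2 * n > n_max:
            break
        n_next = 2 * n
    estimate = means.mean(axis=0)
    return EstimatorResult(
        estimate=estimate,
        std_error=np.sqrt(est_var),
        variance=float(est_var.max()),
        bias=0.0,
        eps=config.eps,
        theta=config.theta,
        total_cost=n * M * cost_per_sample,
        allocation={level: (n, M)},
        converged=converged,
        method="qmc",
        info={"n": n, "M": M, "history": history},
    )


# ---------------------------------------------------------------------------
# MLMC
# ---------------------------------------------------------------------------


def mlmc_estimate(
    pair_fn,
    n_levels_available: int,
    config: EstimatorConfig,
    costs_fn=None,
    initial_levels: int = 2,
) -> EstimatorResult:
    """Adaptive MLMC loop: sample, re-allocate, test bias, extend levels.

    ``pair_fn(level, rng) -> (Q_l, Q_(l-1))`` returns one coupled pair of
    functional vectors sampled from the same event (level 1 returns
    (Q_1, 0)).  The loop takes scheduled samples, updates level variances,
    re-computes the optimal allocation (only ever adding samples), and stops
    when the extrapolated bias meets sqrt(theta) eps, extending the hierarchy
    while levels remain; otherwise it reports failed convergence with the
    best achievable tolerance.
    """
    L_max = config.max_level or n_levels_available
    L_max = min(L_max, n_levels_available)
    if costs_fn is None:
        costs_fn = config.pseudo_cost
    L = min(max(initial_levels, 2), L_max)
    stats = {l: LevelStats(level=l) for l in range(1, L + 1)}
    scheduled = {l: config.n_initial for l in range(1, L + 1)}
    converged = False
    best_eps = None
    while any(scheduled[l] > stats[l].n for l in stats):
        for l in sorted(stats):
            while stats[l].n < scheduled[l]:
                rng = _rng_for(config.seed, l, stats[l].n)
                qf, qc = pair_fn(l, rng)
                stats[l].update(np.atleast_1d(qf), np.atleast_1d(qc))
        V = np.array([stats[l].max_var_y for l in sorted(stats)])
        C = np.array([costs_fn(l) for l in sorted(stats)])
        N_opt = optimal_allocation(V, C, config.eps, config.theta, config.sample_floor)
        N_opt = np.minimum(N_opt, config.n_cap)
        extra = False
        for i, l in enumerate(sorted(stats)):
            if N_opt[i] > scheduled[l]:
                scheduled[l] = int(N_opt[i])
                extra = True
        if extra:
            continue
        # statistical budget met: check the bias
        try:
            rates = estimate_rates(list(stats.values()))
            alpha = rates.alpha if rates.alpha > 0.1 else config.alpha_fallback
        except EstimatorError:
            alpha = config.alpha_fallback
        bias = bias_estimate(list(stats.values()), alpha)
        best_eps = np.sqrt(
            bias**2 + float(np.sum([stats[l].max_var_y / stats[l].n for l in stats]))
        )
        if bias**2 <= config.theta * config.eps**2:
            converged = True
            break
        if L == L_max:
            break  # failed convergence: bias target unreachable on this hierarchy
        L += 1
        stats[L] = LevelStats(level=L)
        scheduled[L] = config.n_initial

    levels = sorted(stats)
    estimate = np.sum([stats[l].mean_y for l in levels], axis=0)
    var_per_fn = np.sum([stats[l].var_y / stats[l].n for l in levels], axis=0)
    try:
        rates = estimate_rates(list(stats.values()))
        alpha = rates.alpha if rates.alpha > 0.1 else config.alpha_fallback
    except EstimatorError:
        rates, alpha = None, config.alpha_fallback
    bias = bias_estimate(list(stats.values()), alpha)
    total_cost = float(np.sum([stats[l].n * costs_fn(l) for l in levels]))
    return EstimatorResult(
        estimate=estimate,
        std_error=np.sqrt(var_per_fn),
        variance=float(np.max(var_per_fn)),
        bias=bias,
        eps=config.eps,
        theta=config.theta,
        total_cost=total_cost,
        allocation={l: stats[l].n for l in levels},
        converged=converged,
        method="mlmc",
        info={"stats": stats, "rates": rates, "best_eps": best_eps},
    )


def telescoped_variance(stats: list[LevelStats]) -> np.ndarray:
    """Per-functional Var[Q] from moment telescoping: sum E[Q_l^2 - Q_(l-1)^2]
    minus the squared telescoped mean (clipped at zero)."""
    m1 = np.sum([s.mean_y for s in stats], axis=0)
    m2 = np.sum([s.mean_m2 for s in stats], axis=0)
    return np.maximum(0.0, m2 - m1**2)


def mlmc_pair_from_single(sample_fn):
    """Wrap a single-level sampler as a degenerate pair function (level 1)."""

    def pair(level, rng):
        q = np.atleast_1d(sample_fn(rng))
        return q, np.zeros_like(q)

    return pair


# ---------------------------------------------------------------------------
# method comparison
# ---------------------------------------------------------------------------


def compare_methods(
    stats: list[LevelStats],
    rates: RateEstimates,
    config: EstimatorConfig,
    eps_list,
    qmc_runner=None,
) -> pd.DataFrame:
    """Total-cost comparison of MC, QMC and MLMC at equal tolerances.

    MC cost is extrapolated from the finest-level variance via the central
    limit theorem (N = V[Q_L] / ((1-theta) eps^2), each sample at cost C_L).
    QMC cost is measured by ``qmc_runner(eps) -> EstimatorResult`` on the
    finest level (cost per sample C_L).  MLMC cost follows the optimal
    allocation over the measured level variances, with the number of levels
    L(eps) chosen from the fitted bias model c1 2^(-alpha L) <= sqrt(theta)
    eps, capped at the available hierarchy.  The normalized MLMC column is
    eps^2 (log eps)^-2 C_tot, expected near-constant when beta = gamma.
    """
    stats = sorted(stats, key=lambda s: s.level)
    L_avail = stats[-1].level
    V = np.array([s.max_var_y for s in stats])
    C = np.array([config.pseudo_cost(s.level) for s in stats])
    var_QL = float(stats[-1].var_q.max())
    rows = []
    for eps in eps_list:
        budget = (1 - config.theta) * eps**2
        n_mc = var_QL / budget
        mc_cost = n_mc * C[-1]
        # levels needed for the bias share
        L_eps = L_avail
        for L in range(2, L_avail + 1):
            if rates.c1 * 2.0 ** (-rates.alpha * L) <= np.sqrt(config.theta) * eps:
                L_eps = L
                break
        Vl, Cl = V[:L_eps], C[:L_eps]
        N_l = optimal_allocation(Vl, Cl, eps, config.theta, config.sample_floor)
        ml_cost = float(np.sum(N_l * Cl))
        row = {
            "eps": eps,
            "mc_cost": mc_cost,
            "mlmc_cost": ml_cost,
            "mlmc_levels": L_eps,
            "mlmc_normalized": eps**2 * np.log(eps) ** -2 * ml_cost,
            "mlmc_allocation": tuple(int(n) for n in N_l),
        }
        if qmc_runner is not None:
            res = qmc_runner(eps)
            row["qmc_cost"] = res.total_cost
            row["qmc_n"] = res.info.get("n")
        rows.append(row)
    return pd.DataFrame(rows)
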