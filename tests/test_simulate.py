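"""Stochastic simulators: conservation laws, equivalences, determinism."""

import numpy as np
import pytest
from scipy import stats

from spclone import (
    CellCycleModel,
    CloneSizeSample,
    SimulationConfig,
    SPParameters,
    TimeGrid,
    empirical_pmf,
    simulate_clones,
)
from spclone._kernels import simulate_markov, simulate_nonmarkov


@pytest.fixture(scope="module")
def tg():
    return TimeGrid([3, 21, 84, 365], unit="days")


class TestConservedProgenitorLimit:
    """With r = 0 every division is asymmetric, so the single progenitor
    is conserved and no clone can ever go extinct."""

    def test_markov_clones_never_extinct(self, tg):
        sizes = simulate_markov(2000, 2.9, 0.0, 2.9, tg.weeks, 123, 1, 0)
        assert sizes.min() >= 1

    def test_nonmarkov_clones_never_extinct(self, tg):
        sizes = simulate_nonmarkov(2000, 2.9, 0.0, 2.9, 8.0, tg.weeks, 123, 1, 0)
        assert sizes.min() >= 1

    def test_markov_mean_matches_b_cell_balance(self, tg):
        # E[n] = 1 + (lam/Gamma)(1 - exp(-Gamma t)) when n_A is conserved
        lam, gam = 2.9, 2.9
        n = 40_000
        sizes = simulate_markov(n, lam, 0.0, gam, tg.weeks, 5, 1, 0)
        for k, t in enumerate(tg.weeks):
            expected = 1.0 + (lam / gam) * (1.0 - np.exp(-gam * t))
            sem = sizes[:, k].std() / np.sqrt(n)
            assert abs(sizes[:, k].mean() - expected) < 4.0 * sem + 1e-3


class TestCriticality:
    """Symmetric fates are balanced, so E[n_A(t)] = n_A(0) = 1 and the
    unconditioned mean basal size is 1 + (lam/Gamma)(1 - exp(-Gamma t))."""

    def test_mean_basal_size_trajectory(self, benchmark_params, tg):
        p = benchmark_params
        cfg = SimulationConfig(parameters=p, timepoints=tg, n_clones=100_000,
                               rng_seed=99)
        sample = simulate_clones(cfg)
        gam = p.stratification_rate
        for k, t in enumerate(tg.weeks):
            expected = 1.0 + (p.division_rate / gam) * (1.0 - np.exp(-gam * t))
            col = sample.sizes[:, k]
            sem = col.std() / np.sqrt(col.size)
            assert abs(col.mean() - expected) < 4.0 * sem

    def test_late_time_mean_is_inverse_rho(self, benchmark_params):
        # balance of production and stratification: E[n] -> 1/rho
        tg = TimeGrid([52.0], unit="weeks")
        cfg = SimulationConfig(parameters=benchmark_params, timepoints=tg,
                               n_clones=100_000, rng_seed=7)
        col = simulate_clones(cfg).sizes[:, 0]
        target = 1.0 / benchmark_params.progenitor_fraction
        sem = col.std() / np.sqrt(col.size)
        assert abs(col.mean() - target) < 4.0 * sem


class TestExtinction:
    def test_extinction_is_absorbing(self, benchmark_params, tg):
        cfg = SimulationConfig(parameters=benchmark_params, timepoints=tg,
                               n_clones=20_000, rng_seed=11)
        sizes = simulate_clones(cfg).sizes
        dead = sizes == 0
        # once extinct, a clone stays extinct at all later timepoints
        assert np.all(dead[:, :-1] <= dead[:, 1:])

    def test_extinct_fraction_nondecreasing(self, benchmark_params, tg):
        cfg = SimulationConfig(parameters=benchmark_params, timepoints=tg,
                               n_clones=20_000, rng_seed=12)
        surv = simulate_clones(cfg).surviving_fraction()
        assert np.all(np.diff(surv) <= 1e-12)


class TestDeterminism:
    def test_identical_config_identical_sample(self, benchmark_params, tg):
        cfg = SimulationConfig(parameters=benchmark_params, timepoints=tg,
                               n_clones=500, rng_seed=321)
        a = simulate_clones(cfg).sizes
        b = simulate_clones(cfg).sizes
        assert np.array_equal(a, b)

    def test_gamma_engine_deterministic(self, benchmark_params, tg):
        cfg = SimulationConfig(
            parameters=benchmark_params, timepoints=tg, n_clones=500,
            rng_seed=321, cell_cycle=CellCycleModel(kind="gamma", gamma_shape=4.0),
        )
        assert np.array_equal(simulate_clones(cfg).sizes,
                              simulate_clones(cfg).sizes)


class TestEngineEquivalence:
    def test_gamma_shape_one_matches_markov(self, benchmark_params, tg):
        """Gamma(1) division times are exponential, so the two engines must
        be statistically indistinguishable at every timepoint."""
        p = benchmark_params
        n = 10_000
        mk = SimulationConfig(parameters=p, timepoints=tg, n_clones=n, rng_seed=1)
        gm = SimulationConfig(
            parameters=p, timepoints=tg, n_clones=n, rng_seed=2,
            cell_cycle=CellCycleModel(kind="gamma", gamma_shape=1.0),
        )
        a = simulate_clones(mk)
        b = simulate_clones(gm)
        for k in range(len(tg)):
            res = stats.ks_2samp(a.sizes[:, k], b.sizes[:, k])
            assert res.pvalue > 0.01

    def test_division_time_law_is_gamma(self):
        """With r=0 and Gamma ~ 0 the clone jumps from size 1 to 2 exactly at
        the founder's division time, so P(n >= 2 at t) is the Gamma CDF."""
        lam, shape = 2.0, 64.0
        ts = np.array([0.3, 0.5, 0.7])  # weeks, around the mean 1/lam
        n = 10_000
        sizes = simulate_nonmarkov(n, lam, 0.0, 1e-9, shape, ts, 77, 1, 0)
        for k, t in enumerate(ts):
            expected = stats.gamma.cdf(t, a=shape, scale=1.0 / (lam * shape))
            observed = np.mean(sizes[:, k] >= 2)
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) < 4.0 * se + 1e-4


class TestEmpiricalPMF:
    def test_point_mass(self):
        tg1 = TimeGrid([7.0], unit="days")
        sample = CloneSizeSample(timepoints=tg1,
                                 sizes=np.full((50, 1), 3, dtype=np.int64))
        pmf = empirical_pmf(sample, 0)
        assert pmf.probabilities[3] == pytest.approx(1.0)
        assert pmf.total_mass == pytest.approx(1.0)

    def test_conditioning_normalizes_over_survivors(self, benchmark_params, tg):
        cfg = SimulationConfig(parameters=benchmark_params, timepoints=tg,
                               n_clones=5000, rng_seed=4)
        sample = simulate_clones(cfg)
        un = empirical_pmf(sample, 3)
        co = empirical_pmf(sample, 3, condition_on_survival=True)
        assert un.total_mass == pytest.approx(1.0)
        assert co.total_mass == pytest.approx(1.0)
        assert co.probabilities[0] == 0.0
        # conditioned mass proportional to unconditioned over n >= 1
        ratio = co.probabilities[1:] * (1 - un.probabilities[0])
        assert np.allclose(ratio, un.probabilities[1:], atol=1e-12)

    def test_all_extinct_conditioning_error(self):
        tg1 = TimeGrid([7.0], unit="days")
        sample = CloneSizeSample(timepoints=tg1,
                                 sizes=np.zeros((10, 1), dtype=np.int64))
        with pytest.raises(ValueError, match="extinct"):
            empirical_pmf(sample, 0, condition_on_survival=True)


class TestInitialConditionOption:
    def test_basal_random_start_has_more_extinction(self, benchmark_params):
        """A B-founded clone dies after one stratification, so starting from
        a random basal cell (A w.p. rho) lowers survival vs an A start."""
        tg1 = TimeGrid([21.0], unit="days")
        base = dict(parameters=benchmark_params, timepoints=tg1, n_clones=20_000)
        a_start = simulate_clones(SimulationConfig(rng_seed=8, **base))
        mixed = simulate_clones(SimulationConfig(rng_seed=8,
                                                 random_initial_basal=True, **base))
        assert mixed.surviving_fraction()[0] < a_start.surviving_fraction()[0]
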