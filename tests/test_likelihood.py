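"""Log-likelihood arithmetic, grid surfaces and interval construction."""

import numpy as np
import pytest

from spclone import (
    CloneDataset,
    CloneSizePMF,
    GridSpec,
    LikelihoodSurface,
    interval_from_surface,
    log_likelihood,
    mle_grid_analytic,
    mle_grid_simulation,
    per_timepoint_surfaces,
)
from spclone.likelihood import ZERO_PROB_SENTINEL


def _pmf(t_days, probs):
    return CloneSizePMF(t_days / 7.0, np.asarray(probs, dtype=float),
                        conditioned=True)


class TestLogLikelihood:
    def test_direct_arithmetic(self):
        # counts {1: 2, 2: 1}, probabilities {1: 0.5, 2: 0.25}
        data = CloneDataset.from_records([("m", 3.0, 1), ("m", 3.0, 1),
                                          ("m", 3.0, 2)])
        pmfs = {3.0: _pmf(3.0, [0.0, 0.5, 0.25])}
        expected = 2 * np.log(0.5) + np.log(0.25)
        assert log_likelihood(data, pmfs) == pytest.approx(expected)
        assert expected == pytest.approx(-2.7726, abs=1e-4)

    def test_empty_dataset_scores_zero(self):
        assert log_likelihood(CloneDataset.empty(), {}) == 0.0

    def test_linearity_in_counts(self):
        recs = [("m", 3.0, 1), ("m", 3.0, 2), ("m", 10.0, 3)]
        data1 = CloneDataset.from_records(recs)
        data5 = CloneDataset.from_records(recs * 5)
        pmfs = {3.0: _pmf(3.0, [0.0, 0.5, 0.25, 0.25]),
                10.0: _pmf(10.0, [0.0, 0.3, 0.3, 0.4])}
        assert log_likelihood(data5, pmfs) == pytest.approx(
            5 * log_likelihood(data1, pmfs))

    def test_zero_probability_sentinel(self):
        data = CloneDataset.from_records([("m", 3.0, 2), ("m", 3.0, 2)])
        pmfs = {3.0: _pmf(3.0, [0.0, 1.0, 0.0])}
        assert log_likelihood(data, pmfs) == pytest.approx(2 * ZERO_PROB_SENTINEL)

    def test_missing_support_raises(self):
        data = CloneDataset.from_records([("m", 3.0, 7)])
        pmfs = {3.0: _pmf(3.0, [0.0, 0.5, 0.5])}
        with pytest.raises(ValueError, match="exceeds PMF support"):
            log_likelihood(data, pmfs)

    def test_missing_timepoint_raises(self):
        data = CloneDataset.from_records([("m", 3.0, 1)])
        with pytest.raises(KeyError, match="timepoint"):
            log_likelihood(data, {10.0: _pmf(10.0, [0.0, 1.0])})


class TestGridSpec:
    def test_default_grid_is_49_by_49_open_intervals(self):
        g = GridSpec()
        assert len(g.r_nodes) == 49 and len(g.rho_nodes) == 49
        assert g.r_nodes[0] > 0 and g.r_nodes[-1] == pytest.approx(0.5)
        assert g.rho_nodes[0] > 0 and g.rho_nodes[-1] < 1.0


@pytest.fixture(scope="module")
def small_surface(large_cohort):
    data = large_cohort.dataset.restrict_to([10.0, 84.0])
    return data, mle_grid_analytic(data, 2.9, grid=GridSpec(9, 9), n_max=256)


class TestAnalyticSurface:
    def test_additivity_over_independent_data(self, large_cohort):
        """Log-likelihood is additive over independent observations: a
        dataset split into two halves scores the sum of the halves at every
        grid point (all three fits share the same timepoints, hence the
        same PMFs)."""
        grid = GridSpec(5, 5)
        data = large_cohort.dataset.restrict_to([10.0, 84.0])
        d1 = CloneDataset(data.table.iloc[::2])
        d2 = CloneDataset(data.table.iloc[1::2])
        s1 = mle_grid_analytic(d1, 2.9, grid=grid)
        s2 = mle_grid_analytic(d2, 2.9, grid=grid)
        s12 = mle_grid_analytic(d1.concat(d2), 2.9, grid=grid)
        assert np.allclose(s12.loglik, s1.loglik + s2.loglik, rtol=1e-12)

    def test_per_timepoint_decomposition_is_exact(self, small_surface):
        data, full = small_surface
        parts = per_timepoint_surfaces(data, 2.9, grid=GridSpec(9, 9), n_max=256)
        total = sum(s.loglik for s in parts.values())
        assert np.allclose(full.loglik, total, rtol=1e-12)

    def test_single_timepoint_intervals_are_wider(self, small_surface):
        data, full = small_surface
        parts = per_timepoint_surfaces(data, 2.9, grid=GridSpec(9, 9), n_max=256)
        iv_full = full.intervals()
        for s in parts.values():
            iv = s.intervals()
            for par in ("r", "rho"):
                w_single = iv[par][1] - iv[par][0]
                w_full = iv_full[par][1] - iv_full[par][0]
                assert w_single >= w_full


class TestSimulationSurface:
    def test_matches_analytic_argmax_within_one_cell(self, large_cohort):
        """Cross-validation of the two MLE routes on the same data with
        exponential cycles (reduced sampling, all 7 timepoints).

        The observed table is subsampled so that simulations outnumber
        observations, as in the real fitting protocol; otherwise rare
        observed sizes fall into empirical-PMF sampling zeros and the
        sentinel dominates the simulation-route surface.
        """
        data = CloneDataset(
            large_cohort.dataset.table.iloc[::30].reset_index(drop=True)
        )
        grid = GridSpec(9, 9)
        sa = mle_grid_analytic(data, 2.9, grid=grid)
        ss = mle_grid_simulation(data, 2.9, grid=grid, n_clones=10_000,
                                 rng_seed=5)
        dr = abs(sa.argmax[0] - ss.argmax[0])
        drho = abs(sa.argmax[1] - ss.argmax[1])
        assert dr <= 0.5 / 9 + 1e-12
        assert drho <= 1.0 / 10 + 1e-12

    def test_small_sample_surfaces_are_noisy(self, large_cohort):
        """Tiny per-point sampling produces unstable surfaces: the argmax
        wanders across seeds far more than with heavy sampling."""
        data = large_cohort.dataset.restrict_to([10.0])
        grid = GridSpec(5, 5)

        def argmax_spread(n_clones):
            pts = [mle_grid_simulation(data, 2.9, grid=grid, n_clones=n_clones,
                                       rng_seed=s).argmax for s in range(4)]
            pts = np.array(pts)
            return pts.std(axis=0).sum()

        assert argmax_spread(10) > argmax_spread(5_000)


class TestIntervals:
    def _gaussian_surface(self):
        g = GridSpec(21, 21)
        r0, rho0 = 0.25, 0.5
        R, P = np.meshgrid(g.r_nodes, g.rho_nodes, indexing="ij")
        ll = -((R - r0) ** 2 / 0.002 + (P - rho0) ** 2 / 0.008)
        return LikelihoodSurface(g.r_nodes, g.rho_nodes, ll)

    def test_symmetric_surface_symmetric_interval(self):
        s = self._gaussian_surface()
        iv = s.intervals()
        r_lo, r_hi = iv["r"]
        mode = s.argmax[0]
        spacing = s.r_nodes[1] - s.r_nodes[0]
        assert abs((mode - r_lo) - (r_hi - mode)) <= spacing + 1e-12

    def test_full_level_covers_grid(self):
        s = self._gaussian_surface()
        iv = interval_from_surface(s, level=1.0)
        assert iv["r"] == (s.r_nodes[0], s.r_nodes[-1])
        assert iv["rho"] == (s.rho_nodes[0], s.rho_nodes[-1])

    def test_sharper_data_never_widens_intervals(self, large_cohort):
        data = large_cohort.dataset.restrict_to([21.0])
        sub = CloneDataset(data.table.iloc[:200])
        rep = CloneDataset(
            sub.table.loc[sub.table.index.repeat(10)].reset_index(drop=True)
        )
        grid = GridSpec(15, 15)
        iv_small = mle_grid_analytic(sub, 2.9, grid=grid).intervals()
        iv_big = mle_grid_analytic(rep, 2.9, grid=grid).intervals()
        for par in ("r", "rho"):
            assert (iv_big[par][1] - iv_big[par][0]) <= (
                iv_small[par][1] - iv_small[par][0]) + 1e-12

    def test_degenerate_surface_warns_zero_width(self):
        g = GridSpec(5, 5)
        ll = np.full((5, 5), -1e8)
        ll[2, 2] = 0.0
        s = LikelihoodSurface(g.r_nodes, g.rho_nodes, ll)
        with pytest.warns(UserWarning, match="degenerate"):
            iv = s.intervals()
        assert iv["r"][0] == iv["r"][1]
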