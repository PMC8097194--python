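"""Grid-search maximum-likelihood inference of (r, rho) at fixed lambda.

The log-likelihood of a parameter set theta given observed clone-size
frequencies x_n(t) is

    l(theta; x) = sum_t sum_n x_n(t) * log p_n(t, theta),

where p_n(t, theta) is the (survival-conditioned, by default) clone-size
probability.  p_n comes either from the exact generating-function engine
(exponential cell cycles only) or from empirical PMFs estimated by
simulation (any cell-cycle model).  lambda is fixed from an orthogonal
measurement (H2B-GFP dilution) and never fitted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .analytic import AnalyticEngineError, clone_size_pmfs
from .data import CloneDataset
from .params import CellCycleModel, SPParameters, TimeGrid
from .pmf import CloneSizePMF
from .simulate import SimulationConfig, empirical_pmf, simulate_clones

__all__ = [
    "GridSpec",
    "LikelihoodSurface",
    "log_likelihood",
    "mle_grid_analytic",
    "mle_grid_simulation",
    "per_timepoint_surfaces",
    "interval_from_surface",
]

logger = logging.getLogger(__name__)

#: Log-likelihood contribution per clone whose observed size has zero
#: estimated probability (simulation-estimated PMFs have sampling zeros).
#: Keeps the grid ranking total where -inf would not.
ZERO_PROB_SENTINEL = -1.0e3


@dataclass(frozen=True)
class GridSpec:
    """Uniform open-interval grid over (r, rho).

    Nodes are ``r_i = r_max * i / n_r`` for i = 1..n_r (0 excluded, the
    closed upper bound r = 0.5 included) and ``rho_j = j / (n_rho + 1)``
    for j = 1..n_rho (both endpoints excluded).  The 49x49 default matches
    the standard analytic grid; simulation-based fits typically use 19x19.
    """

    n_r: int = 49
    n_rho: int = 49
    r_max: float = 0.5

    def __post_init__(self) -> None:
        if self.n_r < 2 or self.n_rho < 2:
            raise ValueError("grid needs at least 2 nodes per axis")

    @property
    def r_nodes(self) -> np.ndarray:
        return self.r_max * np.arange(1, self.n_r + 1) / self.n_r

    @property
    def rho_nodes(self) -> np.ndarray:
        return np.arange(1, self.n_rho + 1) / (self.n_rho + 1.0)


@dataclass
class LikelihoodSurface:
    """Log-likelihood over an (r, rho) grid with derived summaries."""

    r_nodes: np.ndarray
    rho_nodes: np.ndarray
    loglik: np.ndarray  # shape (n_r, n_rho)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.loglik = np.asarray(self.loglik, dtype=float)
        if self.loglik.shape != (len(self.r_nodes), len(self.rho_nodes)):
            raise ValueError("loglik shape must be (n_r, n_rho)")

    @property
    def argmax(self) -> tuple[float, float]:
        """(r_hat, rho_hat) at the grid maximum."""
        i, j = np.unravel_index(np.nanargmax(self.loglik), self.loglik.shape)
        return float(self.r_nodes[i]), float(self.rho_nodes[j])

    @property
    def max_loglik(self) -> float:
        return float(np.nanmax(self.loglik))

    def normalized(self) -> np.ndarray:
        """exp(l - max l), normalized to sum to 1 over the grid."""
        with np.errstate(over="ignore"):
            w = np.exp(self.loglik - self.max_loglik)
        w[~np.isfinite(w)] = 0.0
        return w / w.sum()

    def marginal(self, param: str) -> np.ndarray:
        w = self.normalized()
        return w.sum(axis=1) if param == "r" else w.sum(axis=0)

    def intervals(self, level: float = 0.95) -> dict:
        return interval_from_surface(self, level)

    def __add__(self, other: "LikelihoodSurface") -> "LikelihoodSurface":
        if not (
            np.array_equal(self.r_nodes, other.r_nodes)
            and np.array_equal(self.rho_nodes, other.rho_nodes)
        ):
            raise ValueError("surfaces must share the same grid to be summed")
        return LikelihoodSurface(
            self.r_nodes, self.rho_nodes, self.loglik + other.loglik,
            metadata={"summed_from": [self.metadata, other.metadata]},
        )


def log_likelihood(
    data: CloneDataset,
    pmfs: dict[float, CloneSizePMF],
    sentinel: float = ZERO_PROB_SENTINEL,
) -> float:
    """l(theta; x) = sum_t sum_n x_n(t) log p_n(t, theta).

    ``pmfs`` maps each observed timepoint (days) to its clone-size PMF;
    conditioning of the PMFs must match the data (observed clone tables are
    survival-conditioned).  An observed size without a PMF entry (beyond
    n_max) raises; an observed size whose estimated probability is exactly
    zero contributes ``sentinel`` per clone.
    """
    total = 0.0
    for t in data.time_days:
        if float(t) not in pmfs:
            raise KeyError(f"no PMF supplied for observed timepoint {t} days")
        counts = data.counts_at(t)
        p = pmfs[float(t)].probabilities
        if len(counts) > len(p):
            n_bad = int(np.max(np.nonzero(counts)[0]))
            if n_bad >= len(p):
                raise ValueError(
                    f"observed clone size {n_bad} at t={t} d exceeds PMF "
                    f"support n_max={len(p) - 1}; increase n_max"
                )
            counts = counts[: len(p)]
        n = np.arange(len(counts))
        x = counts
        pn = p[: len(counts)]
        pos = (x > 0) & (pn > 0.0)
        zero = (x > 0) & (pn <= 0.0)
        total += float(np.dot(x[pos], np.log(pn[pos])))
        total += float(x[zero].sum()) * sentinel
    return total


def _surface_from_pmf_factory(data, grid, pmf_factory, metadata):
    """Shared grid loop: evaluate l(theta) for every (r, rho) node."""
    r_nodes = grid.r_nodes
    rho_nodes = grid.rho_nodes
    loglik = np.full((len(r_nodes), len(rho_nodes)), -np.inf)
    failures = 0
    for i, r in enumerate(r_nodes):
        for j, rho in enumerate(rho_nodes):
            try:
                pmfs = pmf_factory(float(r), float(rho))
                loglik[i, j] = log_likelihood(data, pmfs)
            except AnalyticEngineError as exc:  # mask, never abort the grid
                failures += 1
                logger.warning("grid point (r=%g, rho=%g) failed: %s", r, rho, exc)
    meta = dict(metadata)
    meta["failed_grid_points"] = failures
    return LikelihoodSurface(r_nodes, rho_nodes, loglik, metadata=meta)


def mle_grid_analytic(
    data: CloneDataset,
    lam: float,
    grid: GridSpec | None = None,
    n_max: int = 256,
    conditioned: bool = True,
) -> LikelihoodSurface:
    """Likelihood surface using exact (exponential-cycle) PMFs.

    Valid only under the exponential cell-cycle assumption; Gamma-cycle
    data must go through :func:`mle_grid_simulation` or SMC-ABC.
    """
    grid = grid or GridSpec()
    tg = data.time_grid()
    t_days = [float(t) for t in tg.days]

    def factory(r, rho):
        p = SPParameters(lam, r, rho)
        pmfs = clone_size_pmfs(p, tg, n_max=n_max, conditioned=conditioned)
        return dict(zip(t_days, pmfs))

    meta = {
        "engine": "analytic",
        "lambda_per_week": lam,
        "n_max": n_max,
        "conditioned": conditioned,
        "grid": {"n_r": grid.n_r, "n_rho": grid.n_rho, "r_max": grid.r_max},
    }
    return _surface_from_pmf_factory(data, grid, factory, meta)


def mle_grid_simulation(
    data: CloneDataset,
    lam: float,
    grid: GridSpec | None = None,
    n_clones: int = 100_000,
    cell_cycle: CellCycleModel | None = None,
    conditioned: bool = True,
    rng_seed: int = 0,
) -> LikelihoodSurface:
    """Likelihood surface from simulation-estimated PMFs.

    Per grid point, ``n_clones`` clones are simulated at the data's
    timepoints under the chosen cell-cycle model (this is the route that
    supports Gamma cycles) and the empirical PMFs are plugged into the
    log-likelihood.  Sampling zeros at observed sizes contribute the
    documented sentinel; affected cells are counted in the metadata.
    """
    grid = grid or GridSpec(n_r=19, n_rho=19)
    cell_cycle = cell_cycle or CellCycleModel()
    tg = data.time_grid()
    t_days = [float(t) for t in tg.days]
    n_obs_max = int(data.table["clone_size"].max()) if len(data) else 1
    seed_root = np.random.SeedSequence(rng_seed)
    seeds = iter(seed_root.generate_state(grid.n_r * grid.n_rho * 2))

    def factory(r, rho):
        p = SPParameters(lam, r, rho)
        cfg = SimulationConfig(
            parameters=p, timepoints=tg, n_clones=n_clones,
            rng_seed=int(next(seeds) % (2**31)), cell_cycle=cell_cycle,
        )
        sample = simulate_clones(cfg)
        pmfs = {}
        for k, t in enumerate(t_days):
            pmfs[t] = empirical_pmf(
                sample, k, condition_on_survival=conditioned, n_max=n_obs_max
            )
        return pmfs

    meta = {
        "engine": "simulation",
        "lambda_per_week": lam,
        "n_clones_per_point": n_clones,
        "cell_cycle": cell_cycle.kind.value,
        "gamma_shape": cell_cycle.gamma_shape,
        "conditioned": conditioned,
        "rng_seed": rng_seed,
        "grid": {"n_r": grid.n_r, "n_rho": grid.n_rho, "r_max": grid.r_max},
    }
    return _surface_from_pmf_factory(data, grid, factory, meta)


def per_timepoint_surfaces(
    data: CloneDataset,
    lam: float,
    grid: GridSpec | None = None,
    n_max: int = 256,
    conditioned: bool = True,
) -> dict[float, LikelihoodSurface]:
    """One analytic likelihood surface per observed timepoint.

    The full-data log-likelihood separates over timepoints, so the
    pointwise sum of these surfaces equals the all-timepoint surface
    exactly.  All surfaces are built in a single pass over the grid (the
    PMFs for the full time grid are computed once per node).
    """
    grid = grid or GridSpec()
    tg = data.time_grid()
    t_days = [float(t) for t in tg.days]
    r_nodes = grid.r_nodes
    rho_nodes = grid.rho_nodes
    logliks = {t: np.full((len(r_nodes), len(rho_nodes)), -np.inf) for t in t_days}
    failures = 0
    per_t_data = {t: data.restrict_to([t]) for t in t_days}
    for i, r in enumerate(r_nodes):
        for j, rho in enumerate(rho_nodes):
            try:
                p = SPParameters(lam, float(r), float(rho))
                pmfs = dict(zip(
                    t_days,
                    clone_size_pmfs(p, tg, n_max=n_max, conditioned=conditioned),
                ))
            except AnalyticEngineError as exc:
                failures += 1
                logger.warning("grid point (r=%g, rho=%g) failed: %s", r, rho, exc)
                continue
            for t in t_days:
                logliks[t][i, j] = log_likelihood(per_t_data[t], {t: pmfs[t]})
    out = {}
    for t in t_days:
        out[t] = LikelihoodSurface(
            r_nodes, rho_nodes, logliks[t],
            metadata={
                "engine": "analytic", "lambda_per_week": lam, "n_max": n_max,
                "conditioned": conditioned, "timepoint_days": t,
                "failed_grid_points": failures,
            },
        )
    return out


def _equal_tailed(nodes: np.ndarray, weights: np.ndarray, level: float):
    """Equal-tailed interval of a discrete distribution on ``nodes``."""
    alpha = (1.0 - level) / 2.0
    cdf = np.cumsum(weights)
    cdf /= cdf[-1]
    lo = int(np.searchsorted(cdf, alpha, side="left"))
    hi = int(np.searchsorted(cdf, 1.0 - alpha, side="left"))
    hi = min(hi, len(nodes) - 1)
    return float(nodes[lo]), float(nodes[hi])


def interval_from_surface(s: LikelihoodSurface, level: float = 0.95) -> dict:
    """Per-parameter equal-tailed intervals from the normalized surface.

    The surface is exponentiated relative to its maximum, normalized over
    the grid, marginalized per parameter, and equal-tailed quantile
    intervals are read off the discrete marginals.  The construction is
    recorded in the returned metadata.
    """
    if not (0.0 < level <= 1.0):
        raise ValueError("level must be in (0, 1]")
    w_r = s.marginal("r")
    w_rho = s.marginal("rho")
    if np.max(s.normalized()) > 1.0 - 1e-12:
        warnings.warn(
            "degenerate likelihood surface: all normalized mass in one cell; "
            "intervals have zero width", stacklevel=2,
        )
    r_int = _equal_tailed(s.r_nodes, w_r, level)
    rho_int = _equal_tailed(s.rho_nodes, w_rho, level)
    return {
        "level": level,
        "r": r_int,
        "rho": rho_int,
        "method": "normalize-and-marginalize grid posterior, equal-tailed quantiles",
    }
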