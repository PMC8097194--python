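"""Sequential Monte Carlo approximate Bayesian computation for (r, rho).

Likelihood-free inference: candidate (r, rho) pairs are drawn from uniform
priors, clones are simulated under the candidate (with either cell-cycle
model — this is what makes the approach robust to non-exponential division
times), and candidates are kept when the summed per-timepoint two-sample
Kolmogorov–Smirnov distance to the observed clone sizes falls below a
tolerance that shrinks from generation to generation.  Accepted particles
are importance-reweighted in the standard SMC fashion and perturbed with an
adaptive Gaussian kernel between generations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .data import CloneDataset
from .params import CellCycleKind, CellCycleModel, SPParameters, stratification_rate
from .simulate import CloneSizeSample

__all__ = [
    "ABCConfig",
    "ABCPosterior",
    "ks_statistic",
    "ks_distance",
    "smc_abc",
    "posterior_summaries",
]


def ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample KS statistic: sup-norm of the empirical CDF difference."""
    x = np.sort(np.asarray(x))
    y = np.sort(np.asarray(y))
    if x.size == 0 or y.size == 0:
        raise ValueError("KS statistic needs non-empty samples on both sides")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / x.size
    cdf_y = np.searchsorted(y, grid, side="right") / y.size
    return float(np.max(np.abs(cdf_x - cdf_y)))


def ks_distance(sim: CloneSizeSample, obs: CloneDataset,
                per_mouse: bool = False) -> float:
    """Summed per-timepoint KS distance between simulated and observed sizes.

    By default observed clones are pooled across mice within each
    timepoint; with ``per_mouse`` the KS statistic is computed against each
    mouse separately and averaged within the timepoint before summing.
    Both sides are conditioned on survival (n >= 1) to match what lineage
    tracing records.  Raises if either side is empty at some timepoint.
    """
    obs_days = obs.time_days
    sim_days = sim.timepoints.days
    if len(obs_days) != len(sim_days) or not np.allclose(obs_days, sim_days):
        raise ValueError(
            f"timepoint mismatch: simulated {sim_days} vs observed {obs_days}"
        )
    total = 0.0
    for k, t in enumerate(obs_days):
        o = obs.sizes_at(t)
        s = sim.at(k, survivors_only=True)
        if o.size == 0 or s.size == 0:
            raise ValueError(
                f"empty sample at timepoint {t} days "
                f"(observed n={o.size}, simulated survivors n={s.size})"
            )
        if per_mouse:
            tbl = obs.table[obs.table["time_days"] == t]
            ds = [
                ks_statistic(s, grp["clone_size"].to_numpy())
                for _, grp in tbl.groupby("mouse_id")
            ]
            total += float(np.mean(ds))
        else:
            total += ks_statistic(s, o)
    return total


@dataclass(frozen=True)
class ABCConfig:
    """SMC-ABC protocol settings.

    Defaults reproduce the full protocol: 10 populations of 500 particles,
    1000 simulated clones per candidate, adaptive (median-of-previous)
    tolerance, Gaussian perturbation kernel with twice the weighted
    particle covariance, and uniform priors r ~ U(0, 0.5), rho ~ U(0, 1).
    """

    n_populations: int = 10
    population_size: int = 500
    clones_per_particle: int = 1000
    tolerance_quantile: float = 0.5
    kernel_scale: float = 2.0
    r_bounds: tuple = (0.0, 0.5)
    rho_bounds: tuple = (0.0, 1.0)
    min_acceptance_rate: float = 1e-3
    rng_seed: int = 0


@dataclass
class ABCPosterior:
    """Weighted particle population over (r, rho) plus run history."""

    particles: np.ndarray  # shape (N, 2): columns r, rho
    weights: np.ndarray
    tolerances: list
    acceptance_rates: list
    mean_distances: list
    config: ABCConfig
    metadata: dict = field(default_factory=dict)
    generation_particles: list = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        self.weights = w / w.sum()

    @property
    def effective_sample_size(self) -> float:
        return float(1.0 / np.sum(self.weights**2))


def _weighted_quantile(values, weights, q):
    order = np.argsort(values)
    v = np.asarray(values)[order]
    w = np.asarray(weights)[order]
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    idx = np.searchsorted(cdf, np.atleast_1d(q), side="left")
    idx = np.clip(idx, 0, len(v) - 1)
    out = v[idx]
    return out if np.ndim(q) else float(out[0])


def _simulate_particle(r, rho, lam, cell_cycle, n_clones, t_weeks, seed):
    gam = stratification_rate(rho, lam)
    if cell_cycle.kind is CellCycleKind.EXPONENTIAL:
        return _kernels.simulate_markov(n_clones, lam, r, gam, t_weeks, seed, 1, 0)
    return _kernels.simulate_nonmarkov(
        n_clones, lam, r, gam, cell_cycle.gamma_shape, t_weeks, seed, 1, 0
    )


def _distance_to_obs(sizes, obs_sorted):
    """Summed KS distance; an all-extinct simulated timepoint scores 1."""
    total = 0.0
    for k, o in enumerate(obs_sorted):
        s = sizes[:, k]
        s = s[s > 0]
        if s.size == 0:
            total += 1.0
            continue
        s = np.sort(s)
        grid = np.concatenate([s, o])
        cdf_s = np.searchsorted(s, grid, side="right") / s.size
        cdf_o = np.searchsorted(o, grid, side="right") / o.size
        total += float(np.max(np.abs(cdf_s - cdf_o)))
    return total


def smc_abc(
    data: CloneDataset,
    lam: float,
    cell_cycle: CellCycleModel | None = None,
    config: ABCConfig | None = None,
) -> ABCPosterior:
    """Run the SMC-ABC loop and return the final weighted population.

    Generation 1 accepts ``population_size`` prior draws outright (infinite
    tolerance); each later generation resamples the previous population by
    weight, perturbs with the adaptive Gaussian kernel, rejects proposals
    outside the prior support, simulates ``clones_per_particle`` clones at
    the data's timepoints, and accepts when the summed KS distance is at or
    below the current tolerance (the ``tolerance_quantile`` of the previous
    generation's accepted distances, so tolerances strictly shrink).  If
    the acceptance rate falls below ``min_acceptance_rate`` the loop stops
    early with the population built so far — by then the tolerance is
    pushing into overfitting territory.
    """
    cell_cycle = cell_cycle or CellCycleModel()
    cfg = config or ABCConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    t_grid = data.time_grid()
    t_weeks = t_grid.weeks
    obs_sorted = [np.sort(data.sizes_at(t)) for t in data.time_days]
    if any(o.size == 0 for o in obs_sorted):
        raise ValueError("observed dataset has an empty timepoint")

    N = cfg.population_size
    r_lo, r_hi = cfg.r_bounds
    rho_lo, rho_hi = cfg.rho_bounds

    def sim_distance(r, rho):
        seed = int(rng.integers(2**32))
        sizes = _simulate_particle(
            r, rho, lam, cell_cycle, cfg.clones_per_particle, t_weeks, seed
        )
        return _distance_to_obs(sizes, obs_sorted)

    # generation 1: prior sample, uniform weights
    particles = np.column_stack([
        rng.uniform(r_lo, r_hi, N), rng.uniform(rho_lo, rho_hi, N)
    ])
    # open intervals: resample the (measure-zero) boundary draws
    for col, (lo, hi) in ((0, cfg.r_bounds), (1, cfg.rho_bounds)):
        bad = (particles[:, col] <= lo) | (particles[:, col] >= hi)
        while np.any(bad):
            particles[bad, col] = rng.uniform(lo, hi, int(bad.sum()))
            bad = (particles[:, col] <= lo) | (particles[:, col] >= hi)
    distances = np.array([sim_distance(r, rho) for r, rho in particles])
    weights = np.full(N, 1.0 / N)

    tolerances = [float("inf")]
    acceptance_rates = [1.0]
    mean_distances = [float(distances.mean())]
    history = [particles.copy()]
    stopped_early = False

    for gen in range(2, cfg.n_populations + 1):
        eps = float(_weighted_quantile(distances, weights, cfg.tolerance_quantile))
        cov = np.cov(particles.T, aweights=weights) * cfg.kernel_scale
        cov += np.eye(2) * 1e-12
        L = np.linalg.cholesky(cov)
        cov_inv = np.linalg.inv(cov)
        norm = 1.0 / (2.0 * np.pi * np.sqrt(np.linalg.det(cov)))

        new_particles = np.empty_like(particles)
        new_distances = np.empty(N)
        new_weights = np.empty(N)
        accepted = 0
        attempts = 0
        max_attempts = int(np.ceil(N / cfg.min_acceptance_rate))
        while accepted < N and attempts < max_attempts:
            attempts += 1
            idx = rng.choice(N, p=weights)
            theta = particles[idx] + L @ rng.standard_normal(2)
            r, rho = theta
            if not (r_lo < r < r_hi and rho_lo < rho < rho_hi):
                continue
            d = sim_distance(r, rho)
            if d > eps:
                continue
            diff = particles - theta
            kern = norm * np.exp(-0.5 * np.einsum("ij,jk,ik->i", diff, cov_inv, diff))
            denom = float(np.dot(weights, kern))
            new_particles[accepted] = theta
            new_distances[accepted] = d
            new_weights[accepted] = 1.0 / max(denom, 1e-300)  # flat prior numerator
            accepted += 1
        if accepted < N:
            warnings.warn(
                f"SMC-ABC stopped early in generation {gen}: acceptance rate "
                f"fell below {cfg.min_acceptance_rate:g} at tolerance {eps:.4g}; "
                f"returning the {accepted}-particle partial population",
                stacklevel=2,
            )
            stopped_early = True
            if accepted > 0:
                particles = new_particles[:accepted].copy()
                distances = new_distances[:accepted].copy()
                weights = new_weights[:accepted] / new_weights[:accepted].sum()
                tolerances.append(eps)
                acceptance_rates.append(accepted / attempts)
                mean_distances.append(float(distances.mean()))
                history.append(particles.copy())
            break
        particles = new_particles
        distances = new_distances
        weights = new_weights / new_weights.sum()
        tolerances.append(eps)
        acceptance_rates.append(accepted / attempts)
        mean_distances.append(float(distances.mean()))
        history.append(particles.copy())

    return ABCPosterior(
        particles=particles,
        weights=weights,
        tolerances=tolerances,
        acceptance_rates=acceptance_rates,
        mean_distances=mean_distances,
        config=cfg,
        metadata={
            "lambda_per_week": lam,
            "cell_cycle": cell_cycle.kind.value,
            "gamma_shape": cell_cycle.gamma_shape,
            "distance": "summed per-timepoint two-sample KS, mice pooled",
            "stopped_early": stopped_early,
            "n_generations_run": len(tolerances),
        },
        generation_particles=history,
    )


def posterior_summaries(post: ABCPosterior, level: float = 0.95,
                        kde_grid: int = 64) -> dict:
    """Weighted point estimates, credible intervals and a 2-D KDE grid."""
    w = post.weights
    ess = post.effective_sample_size
    if ess < 10:
        warnings.warn(
            f"effective sample size {ess:.1f} < 10; summaries are unreliable",
            stacklevel=2,
        )
    alpha = (1.0 - level) / 2.0
    out = {"level": level, "effective_sample_size": ess}
    for name, col in (("r", 0), ("rho", 1)):
        v = post.particles[:, col]
        lo, med, hi = _weighted_quantile(v, w, [alpha, 0.5, 1.0 - alpha])
        out[name] = {
            "median": float(med),
            "mean": float(np.dot(w, v)),
            "interval": (float(lo), float(hi)),
        }
    # weighted KDE for visualization; degenerate populations get no KDE
    from scipy.stats import gaussian_kde

    r = post.particles[:, 0]
    rho = post.particles[:, 1]
    if np.ptp(r) > 1e-12 and np.ptp(rho) > 1e-12 and ess > 2:
        try:
            kde = gaussian_kde(post.particles.T, weights=w)
            rg = np.linspace(r.min(), r.max(), kde_grid)
            pg = np.linspace(rho.min(), rho.max(), kde_grid)
            R, P = np.meshgrid(rg, pg, indexing="ij")
            out["kde"] = {
                "r_grid": rg,
                "rho_grid": pg,
                "density": kde(np.vstack([R.ravel(), P.ravel()])).reshape(R.shape),
            }
        except (np.linalg.LinAlgError, ValueError):
            pass  # near-degenerate population: no meaningful KDE
    return out
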