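"""Stochastic clone simulation under the SP model.

Wraps the compiled Gillespie (Markovian) and Gamma-cell-cycle
(non-Markovian) kernels in a configuration object, and turns samples of
basal clone sizes into empirical PMFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .params import CellCycleKind, CellCycleModel, CloneState, SPParameters, TimeGrid
from .pmf import CloneSizePMF

__all__ = [
    "SimulationConfig",
    "CloneSizeSample",
    "simulate_clones",
    "empirical_pmf",
]

_SEED_MOD = 2**32


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed for a reproducible clone-simulation run.

    ``initial_state`` defaults to a single progenitor (one A cell), the
    standard assumption that lineage-tracing induction labels a dividing
    cell.  Set ``random_initial_basal=True`` to instead start each clone
    from a basal cell drawn as A with probability rho and B otherwise.
    """

    parameters: SPParameters
    timepoints: TimeGrid
    n_clones: int
    rng_seed: int = 0
    cell_cycle: CellCycleModel = field(default_factory=CellCycleModel)
    initial_state: CloneState = field(default_factory=CloneState)
    random_initial_basal: bool = False

    def __post_init__(self) -> None:
        if self.n_clones <= 0:
            raise ValueError(f"n_clones must be positive, got {self.n_clones}")
        if self.initial_state.extinct:
            raise ValueError("initial state must contain at least one cell")


@dataclass(frozen=True)
class CloneSizeSample:
    """Basal clone sizes for each simulated clone at each timepoint.

    ``sizes[c, k]`` is the basal size of clone ``c`` at ``timepoints[k]``;
    clone identity is preserved across timepoints (rows are trajectories
    sampled at the grid, so extinction is permanent along a row).
    """

    timepoints: TimeGrid
    sizes: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sizes)
        if s.ndim != 2 or s.shape[1] != len(self.timepoints):
            raise ValueError("sizes must have shape (n_clones, n_timepoints)")
        object.__setattr__(self, "sizes", s)

    @property
    def n_clones(self) -> int:
        return self.sizes.shape[0]

    def at(self, k: int, survivors_only: bool = False) -> np.ndarray:
        col = self.sizes[:, k]
        return col[col > 0] if survivors_only else col

    def surviving_fraction(self) -> np.ndarray:
        return (self.sizes > 0).mean(axis=0)


def _initial_counts(cfg: SimulationConfig, rng: np.random.Generator):
    n = cfg.n_clones
    if not cfg.random_initial_basal:
        a = np.full(n, cfg.initial_state.n_A, dtype=np.int64)
        b = np.full(n, cfg.initial_state.n_B, dtype=np.int64)
        return a, b
    rho = cfg.parameters.progenitor_fraction
    is_a = rng.random(n) < rho
    return is_a.astype(np.int64), (~is_a).astype(np.int64)


def simulate_clones(cfg: SimulationConfig) -> CloneSizeSample:
    """Simulate ``cfg.n_clones`` independent clones; return their sizes.

    Dispatches on the cell-cycle model: exponential cycles run the exact
    Gillespie chain; Gamma cycles run the per-cell scheduled-event engine.
    Identical configuration (including seed) reproduces identical output.
    """
    p = cfg.parameters
    t_weeks = cfg.timepoints.weeks
    gam = p.stratification_rate
    rng = np.random.default_rng(cfg.rng_seed)
    kernel_seed = int(rng.integers(_SEED_MOD))
    init_a, init_b = _initial_counts(cfg, rng)

    homogeneous = not cfg.random_initial_basal
    if cfg.cell_cycle.kind is CellCycleKind.EXPONENTIAL:
        if homogeneous:
            sizes = _kernels.simulate_markov(
                cfg.n_clones, p.division_rate, p.symmetric_prob, gam,
                t_weeks, kernel_seed, int(init_a[0]), int(init_b[0]),
            )
        else:
            sizes = _mixed_start(
                _kernels.simulate_markov, cfg, init_a, init_b, rng, t_weeks, gam
            )
    else:
        shape = cfg.cell_cycle.gamma_shape
        if homogeneous:
            sizes = _kernels.simulate_nonmarkov(
                cfg.n_clones, p.division_rate, p.symmetric_prob, gam, shape,
                t_weeks, kernel_seed, int(init_a[0]), int(init_b[0]),
            )
        else:
            def kern(n, lam, r, g, tw, sd, ia, ib):
                return _kernels.simulate_nonmarkov(n, lam, r, g, shape, tw, sd, ia, ib)

            sizes = _mixed_start(kern, cfg, init_a, init_b, rng, t_weeks, gam)
    return CloneSizeSample(timepoints=cfg.timepoints, sizes=sizes)


def _mixed_start(kernel, cfg, init_a, init_b, rng, t_weeks, gam):
    """Run the kernel separately for A-founded and B-founded clones."""
    p = cfg.parameters
    n_a_start = int(init_a.sum())
    n_b_start = cfg.n_clones - n_a_start
    parts = []
    for n, (ia, ib) in ((n_a_start, (1, 0)), (n_b_start, (0, 1))):
        if n == 0:
            continue
        seed = int(rng.integers(_SEED_MOD))
        parts.append(
            kernel(n, p.division_rate, p.symmetric_prob, gam, t_weeks, seed, ia, ib)
        )
    return np.concatenate(parts, axis=0) if len(parts) > 1 else parts[0]


def empirical_pmf(
    sample: CloneSizeSample,
    timepoint_index: int,
    condition_on_survival: bool = False,
    n_max: int | None = None,
) -> CloneSizePMF:
    """Normalized histogram of basal sizes at one timepoint.

    With ``condition_on_survival`` the histogram is restricted to clones
    with n >= 1 and renormalized; an error is raised if every clone is
    extinct at that timepoint.
    """
    sizes = sample.at(timepoint_index, survivors_only=condition_on_survival)
    if sizes.size == 0:
        raise ValueError(
            "cannot condition on survival: every clone is extinct at timepoint "
            f"index {timepoint_index}"
        )
    top = int(sizes.max())
    length = (top if n_max is None else max(n_max, top)) + 1
    counts = np.bincount(sizes, minlength=length).astype(float)
    probs = counts / counts.sum()
    return CloneSizePMF(
        time_weeks=float(sample.timepoints.weeks[timepoint_index]),
        probabilities=probs,
        conditioned=condition_on_survival,
    )
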