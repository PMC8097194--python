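"""Synthetic lineage-tracing cohorts with biological variation.

Emulates the sacrifice design of a transgenic lineage-tracing experiment:
each synthetic mouse is assigned its own (lambda, r, rho) drawn from stated
normal distributions (inter-mouse variation), contributes exactly one
timepoint, and yields a table of surviving basal clone sizes.  The
ground-truth parameters of every mouse are kept in a separate ledger that
never leaks into the "observed" table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import CloneDataset
from .params import CellCycleModel, SPParameters, TimeGrid
from .simulate import SimulationConfig, simulate_clones

__all__ = [
    "ParameterDistribution",
    "CohortDesign",
    "SyntheticCohort",
    "draw_mouse_parameters",
    "generate_cohort",
    "subset_timepoints",
    "large_sample_design",
]

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31


@dataclass(frozen=True)
class ParameterDistribution:
    """Independent per-mouse normal distributions for (lambda, r, rho).

    Draws are rejection-resampled into the valid domain
    (lambda > 0, 0 < r <= 0.5, 0 < rho < 1).  Zero standard deviations give
    every mouse exactly the mean parameters.
    """

    lambda_mean: float = 2.9
    lambda_sd: float = 0.0
    r_mean: float = 0.09
    r_sd: float = 0.0
    rho_mean: float = 0.7
    rho_sd: float = 0.0

    def __post_init__(self) -> None:
        SPParameters(self.lambda_mean, self.r_mean, self.rho_mean)  # validates means
        if min(self.lambda_sd, self.r_sd, self.rho_sd) < 0:
            raise ValueError("standard deviations must be non-negative")


def draw_mouse_parameters(
    dist: ParameterDistribution, rng: np.random.Generator
) -> SPParameters:
    """One mouse's (lambda, r, rho), truncated-normal by rejection."""

    def draw(mean, sd, lo, hi, closed_hi=False):
        if sd == 0.0:
            return mean
        for _ in range(10_000):
            v = rng.normal(mean, sd)
            if lo < v < hi or (closed_hi and v == hi):
                return v
        raise ValueError(
            f"rejection sampling failed: N({mean}, {sd}) essentially never "
            f"lands in ({lo}, {hi})"
        )

    lam = draw(dist.lambda_mean, dist.lambda_sd, 0.0, np.inf)
    r = draw(dist.r_mean, dist.r_sd, 0.0, 0.5, closed_hi=True)
    rho = draw(dist.rho_mean, dist.rho_sd, 0.0, 1.0)
    return SPParameters(lam, r, rho)


@dataclass(frozen=True)
class CohortDesign:
    """Design of a synthetic sacrifice experiment.

    ``clones_per_mouse`` is the number of surviving clones recorded per
    mouse (subsampled without replacement); ``None`` keeps every surviving
    simulated clone.  Defaults follow the standard protocol: 7 timepoints,
    3 mice per timepoint, 10 000 simulated clones per mouse, 100 observed.
    """

    timepoints: TimeGrid = field(default_factory=TimeGrid.standard)
    mice_per_timepoint: int = 3
    clones_per_mouse: int | None = 100
    simulated_clones_per_mouse: int = 10_000
    parameters: ParameterDistribution = field(default_factory=ParameterDistribution)
    cell_cycle: CellCycleModel = field(default_factory=CellCycleModel)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mice_per_timepoint < 1:
            raise ValueError("mice_per_timepoint must be >= 1")
        if self.simulated_clones_per_mouse < 1:
            raise ValueError("simulated_clones_per_mouse must be >= 1")

    @property
    def n_mice(self) -> int:
        return self.mice_per_timepoint * len(self.timepoints)


def large_sample_design(
    parameters: SPParameters,
    n_total_clones: int = 100_000,
    timepoints: TimeGrid | None = None,
    cell_cycle: CellCycleModel | None = None,
    rng_seed: int = 0,
) -> CohortDesign:
    """Single-parameter large-sample design (no biological variation).

    ``n_total_clones`` simulated clones are spread evenly over the
    timepoints (one synthetic "mouse" per timepoint) and every surviving
    clone is retained — the high-sampling regime used to benchmark
    inference engines against a known ground truth.
    """
    timepoints = timepoints or TimeGrid.standard()
    per_tp = int(np.ceil(n_total_clones / len(timepoints)))
    dist = ParameterDistribution(
        lambda_mean=parameters.division_rate, lambda_sd=0.0,
        r_mean=parameters.symmetric_prob, r_sd=0.0,
        rho_mean=parameters.progenitor_fraction, rho_sd=0.0,
    )
    return CohortDesign(
        timepoints=timepoints,
        mice_per_timepoint=1,
        clones_per_mouse=None,
        simulated_clones_per_mouse=per_tp,
        parameters=dist,
        cell_cycle=cell_cycle or CellCycleModel(),
        rng_seed=rng_seed,
    )


@dataclass
class SyntheticCohort:
    """Observed-style clone table plus the hidden ground-truth ledger."""

    dataset: CloneDataset
    truth: pd.DataFrame  # mouse_id, time_days, lambda, r, rho, mouse_seed
    design: CohortDesign

    def true_means(self) -> dict:
        d = self.design.parameters
        return {"lambda": d.lambda_mean, "r": d.r_mean, "rho": d.rho_mean}


def _mice_schedule(design: CohortDesign, per_timepoint_counts=None):
    """(timepoint_days, mouse_slot) pairs in deterministic order."""
    days = design.timepoints.days
    if per_timepoint_counts is None:
        per_timepoint_counts = [design.mice_per_timepoint] * len(days)
    sched = []
    for t, count in zip(days, per_timepoint_counts):
        for m in range(count):
            sched.append((float(t), m))
    return sched


def generate_cohort(design: CohortDesign,
                    per_timepoint_counts=None) -> SyntheticCohort:
    """Simulate the full cohort defined by ``design``.

    For each (timepoint, mouse slot): draw that mouse's parameters,
    simulate ``simulated_clones_per_mouse`` clones to the mouse's sacrifice
    time, keep the surviving clones (n >= 1), and record
    ``clones_per_mouse`` of them (all, if ``None`` or fewer survive —
    with a logged warning when the target cannot be met).
    """
    rng = np.random.default_rng(design.rng_seed)
    rows = []
    truth_rows = []
    for t_days, slot in _mice_schedule(design, per_timepoint_counts):
        mouse_id = f"m{int(round(t_days)):03d}d_{slot}"
        p = draw_mouse_parameters(design.parameters, rng)
        mouse_seed = int(rng.integers(_SEED_MOD))
        cfg = SimulationConfig(
            parameters=p,
            timepoints=TimeGrid([t_days], unit="days"),
            n_clones=design.simulated_clones_per_mouse,
            rng_seed=mouse_seed,
            cell_cycle=design.cell_cycle,
        )
        sizes = simulate_clones(cfg).at(0, survivors_only=True)
        if design.clones_per_mouse is not None:
            if sizes.size < design.clones_per_mouse:
                logger.warning(
                    "mouse %s: only %d surviving clones (< %d requested); "
                    "keeping all", mouse_id, sizes.size, design.clones_per_mouse,
                )
            else:
                sizes = rng.choice(sizes, size=design.clones_per_mouse,
                                   replace=False)
        rows.extend((mouse_id, t_days, int(n)) for n in sizes)
        truth_rows.append(
            (mouse_id, t_days, p.division_rate, p.symmetric_prob,
             p.progenitor_fraction, mouse_seed)
        )
    dataset = CloneDataset(
        pd.DataFrame(rows, columns=["mouse_id", "time_days", "clone_size"]),
        metadata={
            "synthetic": True,
            "rng_seed": design.rng_seed,
            "cell_cycle": design.cell_cycle.kind.value,
            "gamma_shape": design.cell_cycle.gamma_shape,
            "clones_per_mouse": design.clones_per_mouse,
            "simulated_clones_per_mouse": design.simulated_clones_per_mouse,
        },
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["mouse_id", "time_days", "lambda", "r", "rho", "mouse_seed"],
    )
    return SyntheticCohort(dataset=dataset, truth=truth, design=design)


def subset_timepoints(
    cohort: SyntheticCohort, keep_days, rebalance: bool = False
) -> SyntheticCohort:
    """Restrict a cohort to ``keep_days`` timepoints.

    Without ``rebalance`` the existing records are filtered.  With
    ``rebalance`` the cohort's total mouse budget is redistributed evenly
    over the kept timepoints and the mice are regenerated from the stored
    design (same parameter distribution and protocol, fresh derived seed) —
    the "same animal budget, fewer timepoints" experimental design
    question.
    """
    keep = [float(t) for t in keep_days]
    if len(keep) == 0:
        raise ValueError("keep_days must name at least one timepoint")
    have = set(float(t) for t in cohort.design.timepoints.days)
    missing = [t for t in keep if t not in have]
    if missing:
        raise ValueError(f"timepoints {missing} not present in the cohort design")
    keep_sorted = sorted(keep)

    if not rebalance:
        dataset = cohort.dataset.restrict_to(keep_sorted)
        truth = cohort.truth[cohort.truth["time_days"].isin(keep_sorted)]
        design = replace(cohort.design,
                         timepoints=TimeGrid(keep_sorted, unit="days"))
        return SyntheticCohort(dataset=dataset, truth=truth.reset_index(drop=True),
                               design=design)

    total_mice = cohort.design.n_mice
    k = len(keep_sorted)
    base, extra = divmod(total_mice, k)
    counts = [base + (1 if i < extra else 0) for i in range(k)]
    derived_seed = (cohort.design.rng_seed * 1_000_003 + hash(tuple(keep_sorted))) % _SEED_MOD
    design = replace(
        cohort.design,
        timepoints=TimeGrid(keep_sorted, unit="days"),
        rng_seed=derived_seed,
    )
    return generate_cohort(design, per_timepoint_counts=counts)
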