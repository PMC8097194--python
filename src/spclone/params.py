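"""Core domain types for the single-progenitor (SP) model.

The SP model describes homeostasis of a squamous epithelium maintained by a
single equipotent progenitor population.  Progenitor (A) cells in the basal
layer divide at rate ``lambda`` (per week) and the fate of each division is
drawn independently::

    A -> A + A   with probability r        (symmetric duplication)
    A -> A + B   with probability 1 - 2r   (asymmetric)
    A -> B + B   with probability r        (symmetric differentiation)

Differentiating basal (B) cells exit the cell cycle and stratify into the
suprabasal compartment at rate ``Gamma``.  Balanced production and loss of
basal cells (homeostasis) ties the stratification rate to the progenitor
fraction ``rho`` of the basal layer:

    Gamma = rho * lambda / (1 - rho)

All rates are quoted per week internally; experimental timepoints arrive in
days and are converted once at ingest.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SPParameters",
    "CellCycleKind",
    "CellCycleModel",
    "CloneState",
    "TimeGrid",
    "stratification_rate",
    "validate_parameters",
    "DAYS_PER_WEEK",
    "STANDARD_TIMEPOINTS_DAYS",
]

DAYS_PER_WEEK = 7.0

#: The sacrifice timepoints of the standard lineage-tracing protocol (days).
STANDARD_TIMEPOINTS_DAYS = (3.0, 10.0, 21.0, 42.0, 84.0, 180.0, 365.0)


def stratification_rate(rho: float, lam: float) -> float:
    """Stratification rate ``Gamma = rho * lam / (1 - rho)`` (per week).

    Homeostasis requires that the loss of basal cells through stratification
    balance the production of differentiating daughters, which fixes Gamma
    given the progenitor fraction ``rho`` and division rate ``lam``.

    Raises
    ------
    ValueError
        If ``rho`` lies outside the open interval (0, 1) (the rate diverges
        as ``rho -> 1``) or ``lam`` is not positive.
    """
    if not (0.0 < rho < 1.0):
        raise ValueError(f"progenitor_fraction rho must lie in (0, 1), got {rho!r}")
    if not lam > 0.0:
        raise ValueError(f"division_rate lambda must be positive, got {lam!r}")
    return rho * lam / (1.0 - rho)


@dataclass(frozen=True)
class SPParameters:
    """Parameter set (lambda, r, rho) of the SP model with derived Gamma.

    Attributes
    ----------
    division_rate : float
        Progenitor division rate lambda, per week.
    symmetric_prob : float
        Probability r of a symmetric division outcome (AA and BB each occur
        with probability r); constrained to ``0 < r <= 0.5``.
    progenitor_fraction : float
        Fraction rho of basal-layer cells that are progenitors, in (0, 1).
    shedding_rate : float
        Suprabasal shedding rate mu, per week.  Carried for completeness;
        basal clone sizes do not depend on it and no computation uses it.
    """

    division_rate: float
    symmetric_prob: float
    progenitor_fraction: float
    shedding_rate: float = 0.0

    def __post_init__(self) -> None:
        errors = []
        if not self.division_rate > 0.0:
            errors.append(f"division_rate must be > 0, got {self.division_rate!r}")
        if not (0.0 < self.symmetric_prob <= 0.5):
            errors.append(
                f"symmetric_prob must lie in (0, 0.5], got {self.symmetric_prob!r}"
            )
        if not (0.0 < self.progenitor_fraction < 1.0):
            errors.append(
                "progenitor_fraction must lie in (0, 1), got "
                f"{self.progenitor_fraction!r}"
            )
        if self.shedding_rate < 0.0:
            errors.append(f"shedding_rate must be >= 0, got {self.shedding_rate!r}")
        if errors:
            raise ValueError("; ".join(errors))

    @property
    def stratification_rate(self) -> float:
        """Derived Gamma = rho*lambda/(1-rho), per week."""
        return stratification_rate(self.progenitor_fraction, self.division_rate)

    @property
    def gamma_ratio(self) -> float:
        """Dimensionless stratification ratio Gamma/lambda = rho/(1-rho)."""
        return self.progenitor_fraction / (1.0 - self.progenitor_fraction)

    def replace(self, **kwargs) -> "SPParameters":
        return replace(self, **kwargs)


def validate_parameters(p: SPParameters) -> SPParameters:
    """Return ``p`` unchanged after re-checking every bound.

    ``SPParameters`` validates on construction, so this is mainly useful for
    objects rebuilt from untrusted serialized state.
    """
    return SPParameters(
        division_rate=p.division_rate,
        symmetric_prob=p.symmetric_prob,
        progenitor_fraction=p.progenitor_fraction,
        shedding_rate=p.shedding_rate,
    )


class CellCycleKind(str, enum.Enum):
    EXPONENTIAL = "exponential"
    GAMMA = "gamma"


@dataclass(frozen=True)
class CellCycleModel:
    """Cell-cycle (division-time) law for progenitor cells.

    ``exponential`` gives the Markovian model; ``gamma`` draws each cell's
    time to division from a Gamma(shape, scale) law whose scale is always
    mean-matched so that the mean division time equals ``1/lambda``.  Shape
    values above 1 produce the refractory period seen in histone-dilution
    and live-imaging measurements of epithelial cell cycles.
    """

    kind: CellCycleKind = CellCycleKind.EXPONENTIAL
    gamma_shape: float | None = None

    def __post_init__(self) -> None:
        kind = CellCycleKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is CellCycleKind.GAMMA:
            if self.gamma_shape is None or not self.gamma_shape > 0.0:
                raise ValueError(
                    "gamma cell-cycle model requires a positive gamma_shape, got "
                    f"{self.gamma_shape!r}"
                )
        elif self.gamma_shape is not None:
            raise ValueError("gamma_shape is only meaningful for kind='gamma'")

    def scale_for(self, lam: float) -> float:
        """Gamma scale parameter so that the mean division time is 1/lam."""
        if self.kind is not CellCycleKind.GAMMA:
            raise ValueError("scale_for is defined for the gamma model only")
        return 1.0 / (lam * self.gamma_shape)


@dataclass(frozen=True)
class CloneState:
    """Counts of progenitor (A) and differentiating (B) basal cells.

    ``n_A = n_B = 0`` is the absorbing extinct state: an extinct clone never
    revives.
    """

    n_A: int = 1
    n_B: int = 0

    def __post_init__(self) -> None:
        if self.n_A < 0 or self.n_B < 0:
            raise ValueError(f"cell counts must be non-negative, got {self}")

    @property
    def basal_size(self) -> int:
        return self.n_A + self.n_B

    @property
    def extinct(self) -> bool:
        return self.n_A == 0 and self.n_B == 0


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing observation times with an explicit unit.

    External files quote timepoints in days (the lineage-tracing convention);
    every engine works in weeks.  Conversion happens exactly once, here.
    """

    times: tuple
    unit: str = "days"

    def __init__(self, times: Sequence[float], unit: str = "days") -> None:
        times = tuple(float(t) for t in times)
        if unit not in ("days", "weeks"):
            raise ValueError(f"unit must be 'days' or 'weeks', got {unit!r}")
        if len(times) == 0:
            raise ValueError("TimeGrid requires at least one timepoint")
        if any(t < 0 for t in times):
            raise ValueError("timepoints must be non-negative")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"timepoints must be strictly increasing, got {times}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "unit", unit)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def weeks(self) -> np.ndarray:
        if self.unit == "weeks":
            return np.asarray(self.times, dtype=float)
        return np.asarray(self.times, dtype=float) / DAYS_PER_WEEK

    @property
    def days(self) -> np.ndarray:
        if self.unit == "days":
            return np.asarray(self.times, dtype=float)
        return np.asarray(self.times, dtype=float) * DAYS_PER_WEEK

    @classmethod
    def standard(cls) -> "TimeGrid":
        """The 7 standard sacrifice timepoints: 3,10,21,42,84,180,365 days."""
        return cls(STANDARD_TIMEPOINTS_DAYS, unit="days")
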