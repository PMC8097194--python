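"""Clone-size probability mass functions and survival conditioning."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CloneSizePMF", "condition_on_survival"]


@dataclass(frozen=True)
class CloneSizePMF:
    """Probability mass over basal clone size n = 0..n_max at one timepoint.

    Attributes
    ----------
    time_weeks : float
        Timepoint, in weeks.
    probabilities : np.ndarray
        ``probabilities[n]`` is P(basal size = n); length ``n_max + 1``.
    conditioned : bool
        If True the mass is restricted to surviving clones (n >= 1) and
        renormalized, matching what lineage tracing observes.
    """

    time_weeks: float
    probabilities: np.ndarray
    conditioned: bool = False

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.ndim != 1 or p.size < 2:
            raise ValueError("probabilities must be a 1-D vector over n=0..n_max")
        if np.any(p < -1e-12):
            raise ValueError("probabilities must be non-negative")
        if self.conditioned and abs(p[0]) > 1e-12:
            raise ValueError("a survival-conditioned PMF must have no mass at n=0")

    @property
    def n_max(self) -> int:
        return self.probabilities.size - 1

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(self.probabilities.size)

    @property
    def total_mass(self) -> float:
        return float(self.probabilities.sum())

    @property
    def truncated_mass(self) -> float:
        """Probability mass beyond n_max (1 - sum for a proper PMF)."""
        return max(0.0, 1.0 - self.total_mass)

    def mean(self) -> float:
        p = self.probabilities
        return float(np.dot(np.arange(p.size), p) / p.sum())

    def extinction_probability(self) -> float:
        if self.conditioned:
            return 0.0
        return float(self.probabilities[0])


def condition_on_survival(pmf: CloneSizePMF) -> CloneSizePMF:
    """Restrict a PMF to surviving clones (n >= 1) and renormalize.

    The conditional probability of size n given survival is
    ``p_n / (1 - P_0)``.  Using ``1 - P_0`` (rather than the sum of the
    stored entries) keeps true tail mass beyond n_max out of the retained
    entries instead of silently redistributing it; for an empirical PMF the
    two denominators coincide.  Idempotent on already-conditioned input;
    raises if all mass sits at n = 0.
    """
    if pmf.conditioned:
        return pmf
    p = pmf.probabilities.copy()
    surviving = 1.0 - p[0]
    if surviving <= 1e-15 or p[1:].sum() <= 0.0:
        raise ValueError(
            "cannot condition on survival: all probability mass is at n=0"
        )
    p[0] = 0.0
    p /= surviving
    return CloneSizePMF(time_weeks=pmf.time_weeks, probabilities=p, conditioned=True)
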