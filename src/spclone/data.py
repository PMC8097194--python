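"""Observed / simulated clone-size datasets.

A :class:`CloneDataset` is the long-format table lineage tracing produces:
one row per surviving clone, with the mouse it came from, the sacrifice
timepoint (days) and its basal clone size (>= 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import TimeGrid

__all__ = ["CloneRecord", "CloneDataset"]

REQUIRED_COLUMNS = ("mouse_id", "time_days", "clone_size")


@dataclass(frozen=True)
class CloneRecord:
    mouse_id: str
    time_days: float
    clone_size: int


@dataclass
class CloneDataset:
    """Long-format clone table plus run metadata.

    All clone sizes are >= 1: lineage tracing scores persisting clones, so
    the dataset is implicitly conditioned on clone survival.
    """

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"clone table is missing required columns: {missing}")
        df = df.copy()
        sizes = df["clone_size"]
        if len(df):
            frac = np.asarray(sizes, dtype=float) % 1.0
            if np.any(frac != 0.0):
                bad = df.index[frac != 0.0][0]
                raise ValueError(
                    f"row {bad}: clone_size must be an integer, got {sizes[bad]!r}"
                )
            if (sizes < 1).any():
                bad = df.index[(sizes < 1).to_numpy()][0]
                raise ValueError(
                    f"row {bad}: clone_size must be >= 1 (observed clones are "
                    "conditioned on survival; size-0 clones are unobservable)"
                )
            if (df["time_days"] < 0).any():
                bad = df.index[(df["time_days"] < 0).to_numpy()][0]
                raise ValueError(f"row {bad}: time_days must be non-negative")
        df["clone_size"] = sizes.astype(np.int64)
        df["time_days"] = df["time_days"].astype(float)
        self.table = df.reset_index(drop=True)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_records(cls, records, metadata=None) -> "CloneDataset":
        rows = [
            (r.mouse_id, r.time_days, r.clone_size)
            if isinstance(r, CloneRecord)
            else tuple(r)
            for r in records
        ]
        df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
        return cls(df, metadata or {})

    @classmethod
    def empty(cls, metadata=None) -> "CloneDataset":
        df = pd.DataFrame({c: [] for c in REQUIRED_COLUMNS})
        return cls(df, metadata or {})

    # -- views -------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    @property
    def time_days(self) -> np.ndarray:
        """Sorted unique timepoints present, in days."""
        return np.sort(self.table["time_days"].unique())

    def time_grid(self) -> TimeGrid:
        return TimeGrid(self.time_days, unit="days")

    def sizes_at(self, t_days: float) -> np.ndarray:
        """Basal clone sizes pooled across mice at one timepoint."""
        mask = self.table["time_days"] == t_days
        return self.table.loc[mask, "clone_size"].to_numpy()

    def counts_at(self, t_days: float) -> np.ndarray:
        """Frequency x_n of each clone size n at one timepoint (index = n)."""
        sizes = self.sizes_at(t_days)
        if sizes.size == 0:
            return np.zeros(1)
        return np.bincount(sizes).astype(float)

    def restrict_to(self, keep_days) -> "CloneDataset":
        keep = set(float(t) for t in keep_days)
        mask = self.table["time_days"].isin(keep)
        return CloneDataset(self.table.loc[mask], dict(self.metadata))

    def concat(self, other: "CloneDataset") -> "CloneDataset":
        df = pd.concat([self.table, other.table], ignore_index=True)
        return CloneDataset(df, dict(self.metadata))
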