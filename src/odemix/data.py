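"""Snapshot dataset container.

A snapshot is the set of single-cell measurements taken at one (condition,
time) pair; destructive assays measure fresh cells at every snapshot, so
there is no tracking across time.  Cells are statistically independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SnapshotDataset"]


@dataclass
class SnapshotDataset:
    """Single-cell measurements indexed by (condition id, time).

    ``snapshots`` maps ``(condition, time)`` to a 1-D array of per-cell
    values; ``conditions`` maps condition ids to their stimulus records
    (e.g. ``{"stimulus": 1.0}`` or ``{"dose": 0.2}``).
    """

    snapshots: dict
    conditions: dict = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for (cond, t), values in self.snapshots.items():
            v = np.asarray(values, dtype=float).ravel()
            if v.size == 0:
                raise ValueError(f"empty snapshot ({cond}, {t})")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite measurements in snapshot ({cond}, {t})")
            clean[(str(cond), float(t))] = v
        self.snapshots = clean

    # -- basic queries -----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return int(sum(v.size for v in self.snapshots.values()))

    @property
    def n_snapshots(self) -> int:
        return len(self.snapshots)

    def counts(self) -> dict:
        return {k: int(v.size) for k, v in self.snapshots.items()}

    def values(self, condition, time) -> np.ndarray:
        return self.snapshots[(str(condition), float(time))]

    def all_values(self) -> np.ndarray:
        return np.concatenate([v for v in self.snapshots.values()])

    def check_positive(self):
        """Raise if any measurement is non-positive (log-normal analyses)."""
        for (cond, t), v in self.snapshots.items():
            bad = np.flatnonzero(v <= 0)
            if bad.size:
                raise ValueError(
                    f"snapshot ({cond}, t={t}) has non-positive measurements "
                    f"at cell indices {bad[:10].tolist()}"
                )

    def check_design(self, design):
        missing = [s for s in design.snapshots if s not in self.snapshots]
        if missing:
            raise ValueError(f"dataset lacks snapshots required by design: {missing}")

    # -- conversion --------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, value_col: str = "value",
                       stimulus_cols=("stimulus", "dose")) -> "SnapshotDataset":
        for col in ("condition", "time", value_col):
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        snapshots = {}
        conditions = {}
        for (cond, t), grp in df.groupby(["condition", "time"], sort=True):
            snapshots[(str(cond), float(t))] = grp[value_col].to_numpy(dtype=float)
            rec = {}
            for sc in stimulus_cols:
                if sc in df.columns:
                    levels = grp[sc].unique()
                    if len(levels) != 1:
                        raise ValueError(
                            f"snapshot ({cond}, {t}) mixes {sc} levels {levels}"
                        )
                    rec[sc] = float(levels[0])
            conditions.setdefault(str(cond), rec)
        return cls(snapshots=snapshots, conditions=conditions)

    def to_dataframe(self, value_col: str = "value") -> pd.DataFrame:
        rows = []
        for (cond, t) in sorted(self.snapshots):
            v = self.snapshots[(cond, t)]
            rec = self.conditions.get(cond, {})
            for x in v:
                row = {"condition": cond, "time": t, **rec, value_col: x}
                rows.append(row)
        return pd.DataFrame(rows)

    def subset(self, keys) -> "SnapshotDataset":
        return SnapshotDataset(
            snapshots={k: self.snapshots[k] for k in keys},
            conditions=dict(self.conditions),
        )
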