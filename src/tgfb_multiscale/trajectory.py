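"""Shared trajectory container and delimited-table writers.

A :class:`Trajectory` is a time grid plus one column per state variable,
with unit strings and free-form metadata (model id, parameter hash, seed).
Tables are written as plain delimited text, one header row with
``name [unit]`` column labels, numbers at 17 significant digits so that a
write/read/write cycle is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "write_trajectory", "read_trajectory"]


@dataclass
class Trajectory:
    """Time grid, state matrix and metadata of one simulation run."""

    t: np.ndarray
    y: np.ndarray  # shape (len(t), n_states)
    columns: list[str]
    units: list[str]
    time_unit: str = "s"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 2 or self.y.shape[0] != self.t.shape[0]:
            raise ValueError("state matrix must have one row per time point")
        if len(self.columns) != self.y.shape[1]:
            raise ValueError("one column name per state variable required")
        if len(self.units) != len(self.columns):
            raise ValueError("one unit string per state variable required")

    @property
    def n_times(self) -> int:
        return len(self.t)

    def column(self, name: str) -> np.ndarray:
        return self.y[:, self.columns.index(name)]

    def at(self, t: float) -> np.ndarray:
        """State linearly interpolated at time ``t`` (within the span)."""
        if not (self.t[0] <= t <= self.t[-1]):
            raise ValueError(
                f"time {t} outside trajectory span [{self.t[0]}, {self.t[-1]}]"
            )
        return np.array(
            [np.interp(t, self.t, self.y[:, j]) for j in range(self.y.shape[1])]
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=self.columns)
        df.insert(0, "time", self.t)
        return df


def _header(traj: Trajectory) -> list[str]:
    cols = [f"time [{traj.time_unit}]"]
    cols += [f"{n} [{u}]" for n, u in zip(traj.columns, traj.units)]
    return cols


def write_trajectory(traj: Trajectory, path: str | Path, delimiter: str = ",") -> Path:
    """Write a trajectory as a delimited table (header + one row per time).

    Floats are rendered with ``%.17g`` so the table round-trips losslessly.
    """
    path = Path(path)
    if traj.n_times == 0:
        raise ValueError("refusing to write an empty trajectory")
    lines = [delimiter.join(_header(traj))]
    data = np.column_stack([traj.t, traj.y])
    for row in data:
        lines.append(delimiter.join(f"{v:.17g}" for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_trajectory(path: str | Path, delimiter: str = ",") -> Trajectory:
    """Read a table written by :func:`write_trajectory`."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    header = lines[0].split(delimiter)
    names, units = [], []
    for col in header:
        name, _, unit = col.partition(" [")
        names.append(name)
        units.append(unit.rstrip("]"))
    data = np.array(
        [[float(v) for v in line.split(delimiter)] for line in lines[1:]]
    )
    return Trajectory(
        t=data[:, 0],
        y=data[:, 1:],
        columns=names[1:],
        units=units[1:],
        time_unit=units[0],
    )
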