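"""Trajectory container, delimited-text I/O, and delay embedding.

A :class:`Trajectory` is the phase-space object everything in this package
operates on: a uniformly sampled sequence of state vectors.  Row ``i``
corresponds to physical time ``t0 + i * dt``; all indexing is 0-based and
forecast horizons are handled internally as integer step counts ``L`` with
physical horizon ``eta = L * dt``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "load_trajectory", "write_table", "delay_embed"]


@dataclass(frozen=True)
class Trajectory:
    """A uniformly sampled multivariate time series in phase space.

    Parameters
    ----------
    states : ndarray, shape (N, D)
        One row per time step, one column per state variable. All entries
        must be finite; missing values are not supported.
    dt : float
        Physical time per step (model time units or days), > 0.
    labels : sequence of str, optional
        Variable names, length D.
    meta : str
        Free-form provenance text.
    """

    states: np.ndarray
    dt: float
    labels: Optional[tuple] = None
    meta: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.states, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.ndim != 2:
            raise ValueError(f"states must be 2-D (N, D); got ndim={arr.ndim}")
        n, d = arr.shape
        if n < 2:
            raise ValueError(f"need at least 2 time steps; got N={n}")
        if d < 1:
            raise ValueError("need at least one state variable")
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite entry at row {bad[0]}, column {bad[1]}"
            )
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0; got {self.dt}")
        object.__setattr__(self, "states", arr)
        if self.labels is not None:
            labels = tuple(str(x) for x in self.labels)
            if len(labels) != d:
                raise ValueError(
                    f"{len(labels)} labels for {d} columns"
                )
            object.__setattr__(self, "labels", labels)

    @property
    def n_steps(self) -> int:
        return self.states.shape[0]

    @property
    def n_vars(self) -> int:
        return self.states.shape[1]

    def times(self, t0: float = 0.0) -> np.ndarray:
        """Physical time axis ``t0 + i * dt``."""
        return t0 + self.dt * np.arange(self.n_steps)

    def reversed(self) -> "Trajectory":
        """Time-reversed copy (used for backward-horizon analysis)."""
        return Trajectory(self.states[::-1].copy(), self.dt, self.labels,
                          meta=self.meta + " [reversed]")

    def __len__(self) -> int:
        return self.n_steps


def load_trajectory(path, delimiter: str = ",", has_header: Optional[bool] = None,
                    dt: float = 1.0) -> Trajectory:
    """Read a trajectory from delimited text (one row per time step).

    ``has_header=None`` auto-detects a header by a non-numeric first row.
    Every cell must parse as a finite number; errors name the offending
    row and column.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"trajectory file not found: {path}")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: empty file")

    first = lines[0].split(delimiter)
    if has_header is None:
        has_header = not _all_numeric(first)
    labels = None
    data_lines = lines
    if has_header:
        labels = tuple(s.strip() for s in first)
        data_lines = lines[1:]

    ncol = None
    rows = []
    for k, ln in enumerate(data_lines):
        cells = ln.split(delimiter)
        if ncol is None:
            ncol = len(cells)
        elif len(cells) != ncol:
            raise ValueError(
                f"{path}: ragged row {k}: expected {ncol} columns, got {len(cells)}"
            )
        row = []
        for j, cell in enumerate(cells):
            try:
                row.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at row {k}, column {j}: {cell!r}"
                ) from None
        rows.append(row)
    if len(rows) < 2:
        raise ValueError(f"{path}: need at least 2 data rows, got {len(rows)}")
    return Trajectory(np.asarray(rows, dtype=float), dt=dt, labels=labels,
                      meta=f"loaded from {path}")


def _all_numeric(cells: Sequence[str]) -> bool:
    for c in cells:
        try:
            float(c)
        except ValueError:
            return False
    return True


def write_table(table, path, float_format: str = "%.12g") -> None:
    """Write columnar results as delimited text with a header row.

    Accepts a pandas DataFrame, a dict of equal-length columns, or a
    :class:`Trajectory` (written with its variable labels). Values
    round-trip through :func:`load_trajectory` / ``pandas.read_csv`` to
    12 significant digits.
    """
    if isinstance(table, Trajectory):
        cols = table.labels or [f"v{j}" for j in range(table.n_vars)]
        df = pd.DataFrame(table.states, columns=list(cols))
    elif isinstance(table, pd.DataFrame):
        df = table
    else:
        df = pd.DataFrame(table)
    df.to_csv(path, index=False, float_format=float_format)


def delay_embed(series, dim: int, lag: int, dt: float = 1.0) -> Trajectory:
    """Delay-coordinate embedding of a scalar series.

    Reconstructs a ``dim``-dimensional phase space from a single observable:
    row ``i`` of the output is ``(x[i], x[i+lag], ..., x[i+(dim-1)*lag])``.
    The output has ``N - (dim-1)*lag`` rows.

    Raises ``ValueError`` when the series is too short for ``(dim, lag)``.
    """
    x = np.asarray(series, dtype=float).ravel()
    if dim < 1:
        raise ValueError(f"dim must be >= 1; got {dim}")
    if lag < 1:
        raise ValueError(f"lag must be >= 1; got {lag}")
    n = x.size
    n_out = n - (dim - 1) * lag
    if n_out < 2:
        raise ValueError(
            f"series of length {n} too short for dim={dim}, lag={lag} "
            f"(would give {n_out} rows)"
        )
    cols = [x[j * lag: j * lag + n_out] for j in range(dim)]
    emb = np.column_stack(cols)
    return Trajectory(emb, dt=dt, meta=f"delay embedding dim={dim} lag={lag}")
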