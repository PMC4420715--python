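"""Long-format data handling: discretization onto the grid, validation, CSV I/O.

The grid convention is 1-based: raw measurement times are divided by the grid
resolution and rounded half-up to the nearest positive integer, so enrollment
(raw time 0) maps to index 1 and index g corresponds to raw time ~ g *
resolution.  Duplicate (subject, grid index) pairs created by rounding are
merged by averaging their outcomes, with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("pacfcov")

__all__ = ["LongitudinalDataset", "read_long_csv"]

DEFAULT_COLUMNS = {
    "id": "id",
    "time": "time",
    "y": "y",
    "dose": "dose",
    "dropout": "dropout",
}


def _grid_index(raw_times, resolution: float) -> np.ndarray:
    """Round-half-up discretization; clamps to the positive integers."""
    g = np.floor(np.asarray(raw_times, dtype=float) / resolution + 0.5).astype(int)
    return np.maximum(g, 1)


@dataclass
class LongitudinalDataset:
    """Irregular longitudinal data on a discrete grid 1..T.

    Per-subject arrays are aligned lists: ``times[i]`` holds the strictly
    increasing grid indices for subject ``ids[i]``, ``y[i]`` the outcomes.
    ``dose`` is a 0/1 indicator per subject and ``dropout`` the per-subject
    dropout time in raw units (e.g. weeks).
    """

    ids: list
    times: list
    y: list
    dose: np.ndarray
    dropout: np.ndarray
    T: int
    resolution: float = 1.0
    latent: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.dropout = np.asarray(self.dropout, dtype=float)
        self.times = [np.asarray(t, dtype=int) for t in self.times]
        self.y = [np.asarray(v, dtype=float) for v in self.y]
        n = len(self.ids)
        if not (len(self.times) == len(self.y) == len(self.dose) == len(self.dropout) == n):
            raise ValueError("per-subject arrays have inconsistent lengths")
        if n == 0 or all(len(t) == 0 for t in self.times):
            raise ValueError("dataset contains no observations")
        if not np.all(np.isin(self.dose, [0.0, 1.0])):
            raise ValueError("dose must be a 0/1 indicator")
        bad = []
        for i, (t, v) in enumerate(zip(self.times, self.y)):
            if len(t) != len(v):
                raise ValueError(f"subject {self.ids[i]}: times/outcomes length mismatch")
            if len(t) == 0:
                continue
            if t[0] < 1 or t[-1] > self.T or np.any(np.diff(t) <= 0):
                raise ValueError(
                    f"subject {self.ids[i]}: grid indices must be strictly "
                    f"increasing within 1..{self.T}"
                )
            # allow half-a-grid-step slack for round-half-up discretization
            if t[-1] * self.resolution > self.dropout[i] + 0.5 * self.resolution:
                bad.append(self.ids[i])
        if bad:
            raise ValueError(
                f"dropout earlier than an observed time for subjects: {bad}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    @property
    def n_obs(self) -> int:
        return int(sum(len(t) for t in self.times))

    def gap_times(self) -> np.ndarray:
        """All within-subject gaps between consecutive grid indices, pooled."""
        gaps = [np.diff(t) for t in self.times if len(t) > 1]
        if not gaps:
            return np.array([], dtype=int)
        return np.concatenate(gaps)

    def dropout_grid(self) -> np.ndarray:
        """Dropout times discretized to the grid (clamped to 1..T)."""
        return np.minimum(_grid_index(self.dropout, self.resolution), self.T)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, sid in enumerate(self.ids):
            for t, v in zip(self.times[i], self.y[i]):
                rows.append(
                    (sid, t * self.resolution, int(t), v, self.dose[i], self.dropout[i])
                )
        return pd.DataFrame(
            rows, columns=["id", "time", "grid_time", "y", "dose", "dropout"]
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def read_long_csv(
    path,
    column_map: dict | None = None,
    resolution: float = 1.0,
    T: int | None = None,
) -> LongitudinalDataset:
    """Read a long-format CSV (one row per measurement) onto the grid.

    Parameters
    ----------
    path : str or file-like
    column_map : dict, optional
        Overrides for the default column names
        ``{'id', 'time', 'y', 'dose', 'dropout'}``.
    resolution : float
        Raw time units per grid step (e.g. 4 for a 4-week grid).
    T : int, optional
        Grid length; defaults to the maximum observed grid index.

    Raises
    ------
    ValueError
        On missing columns, a non-numeric outcome, an empty file, or any
        subject observed after their dropout time.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError("input file contains no data rows")
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    y = pd.to_numeric(df[cols["y"]], errors="coerce")
    if y.isna().any():
        raise ValueError("non-numeric or missing outcome values present")

    work = pd.DataFrame(
        {
            "id": df[cols["id"]],
            "grid": _grid_index(df[cols["time"]].to_numpy(dtype=float), resolution),
            "y": y.to_numpy(dtype=float),
            "dose": df[cols["dose"]].to_numpy(dtype=float),
            "dropout": df[cols["dropout"]].to_numpy(dtype=float),
        }
    )
    n_before = len(work)
    merged = (
        work.groupby(["id", "grid"], sort=False, as_index=False)
        .agg(y=("y", "mean"), dose=("dose", "first"), dropout=("dropout", "first"))
    )
    if len(merged) < n_before:
        logger.warning(
            "merged %d duplicate (subject, grid index) pairs by averaging outcomes",
            n_before - len(merged),
        )
    merged = merged.sort_values(["id", "grid"], kind="mergesort")

    ids, times, ys, dose, dropout = [], [], [], [], []
    for sid, grp in merged.groupby("id", sort=False):
        ids.append(sid)
        times.append(grp["grid"].to_numpy())
        ys.append(grp["y"].to_numpy())
        dose.append(grp["dose"].iloc[0])
        dropout.append(grp["dropout"].iloc[0])
    T_eff = int(T) if T is not None else int(max(t.max() for t in times))
    return LongitudinalDataset(
        ids=ids,
        times=times,
        y=ys,
        dose=np.asarray(dose),
        dropout=np.asarray(dropout),
        T=T_eff,
        resolution=float(resolution),
    )
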