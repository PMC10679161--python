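"""Study-design rules: inclusion filtering, compliance descriptives, and
discretization of unequally spaced prompts onto an equally spaced time grid.

The lag-1 model needs observations on a common time step. Unequal prompt
spacing is handled with a discrete time filter: each person's observations
are assigned to the nearest cell of a one-hour grid anchored at their first
completed prompt, with unfilled cells (including nights) treated as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import EsmDataset

__all__ = [
    "PersonGrid",
    "GriddedSeries",
    "CompletionStats",
    "exclusion_filter",
    "completion_stats",
    "build_time_grid",
    "lag_pairs",
]

MINUTES_PER_DAY = 1440


# --------------------------------------------------------------------------
# inclusion rule
# --------------------------------------------------------------------------

def exclusion_filter(
    data: EsmDataset, min_fraction: float = 1.0 / 3.0
) -> tuple[EsmDataset, dict]:
    """Remove persons who completed less than ``min_fraction`` of their
    scheduled prompts.

    The comparison is strict: a person is excluded iff
    ``completed < min_fraction * scheduled``, so with 60 scheduled prompts
    the cutoff is 20 and a person with exactly 20 completed is retained.

    Returns the filtered dataset (rows of retained persons unmodified) and a
    report dict with the removed ids, their counts, and the threshold used.
    """
    if data.scheduled.empty:
        raise ValueError("scheduled prompt counts unknown; attach a schedule")
    completed = data.completed_counts()
    threshold = min_fraction * data.scheduled
    excluded_mask = completed < threshold
    excluded = completed[excluded_mask]
    retained = list(completed.index[~excluded_mask])
    report = {
        "min_fraction": float(min_fraction),
        "threshold_per_person": {str(k): float(v)
                                 for k, v in threshold[excluded_mask].items()},
        "excluded": {str(k): int(v) for k, v in excluded.items()},
        "n_excluded": int(excluded_mask.sum()),
        "n_retained": len(retained),
    }
    return data.subset_persons(retained), report


# --------------------------------------------------------------------------
# compliance descriptives
# --------------------------------------------------------------------------

@dataclass
class CompletionStats:
    """Per-person completion rates plus study-level aggregates."""

    per_person: pd.DataFrame  # person_id, scheduled, completed, rate
    total_entries: int
    mean_rate: float          # mean of per-person rates
    sd_rate: float
    min_rate: float
    max_rate: float
    overall_rate: float       # total completed / total scheduled
    mean_within_day_gap: float  # minutes between consecutive completed prompts
    sd_within_day_gap: float

    def as_dict(self) -> dict:
        return {
            "total_entries": self.total_entries,
            "mean_rate": self.mean_rate,
            "sd_rate": self.sd_rate,
            "min_rate": self.min_rate,
            "max_rate": self.max_rate,
            "overall_rate": self.overall_rate,
            "mean_within_day_gap": self.mean_within_day_gap,
            "sd_within_day_gap": self.sd_within_day_gap,
        }


def completion_stats(data: EsmDataset) -> CompletionStats:
    """Compliance descriptives: per-person rates and their aggregates.

    The within-day gap statistics are computed over consecutive completed
    prompts sharing a person and day, pooled across the sample.
    """
    completed = data.completed_counts()
    per = pd.DataFrame({
        "person_id": completed.index,
        "scheduled": data.scheduled.to_numpy(),
        "completed": completed.to_numpy(),
    })
    per["rate"] = np.where(per["scheduled"] > 0,
                           per["completed"] / per["scheduled"], np.nan)
    rates = per["rate"].dropna()
    gaps = (data.data.groupby(["person_id", "day"])["timestamp_minute"]
            .diff().dropna().to_numpy())
    return CompletionStats(
        per_person=per,
        total_entries=int(per["completed"].sum()),
        mean_rate=float(rates.mean()) if len(rates) else float("nan"),
        sd_rate=float(rates.std(ddof=1)) if len(rates) > 1 else 0.0,
        min_rate=float(rates.min()) if len(rates) else float("nan"),
        max_rate=float(rates.max()) if len(rates) else float("nan"),
        overall_rate=(float(per["completed"].sum() / per["scheduled"].sum())
                      if per["scheduled"].sum() else float("nan")),
        mean_within_day_gap=float(gaps.mean()) if len(gaps) else float("nan"),
        sd_within_day_gap=float(gaps.std(ddof=1)) if len(gaps) > 1 else 0.0,
    )


# --------------------------------------------------------------------------
# time grid
# --------------------------------------------------------------------------

@dataclass
class PersonGrid:
    """One person's equally spaced series with explicit missing cells."""

    person_id: object
    origin_minute: float           # timestamp of cell 0 (minutes since study start)
    values: np.ndarray             # (T, K), NaN where missing
    clock_hour: np.ndarray         # (T,) nominal clock hour of each cell

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def occupied(self) -> np.ndarray:
        return ~np.isnan(self.values[:, 0])


@dataclass
class GriddedSeries:
    """Per-person gridded series plus the collision log and hour centering.

    ``hour_center`` is the grand-mean clock hour over all occupied cells;
    the model's hour covariate is ``clock_hour - hour_center``.
    """

    grids: dict                     # person_id -> PersonGrid
    variables: tuple[str, ...]
    interval_minutes: float
    hour_center: float
    collisions: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def persons(self) -> list:
        return list(self.grids)

    @property
    def n_persons(self) -> int:
        return len(self.grids)

    def occupied_counts(self) -> pd.Series:
        return pd.Series({p: int(g.occupied.sum()) for p, g in self.grids.items()},
                         name="occupied")

    def to_wide_frame(self) -> pd.DataFrame:
        """Wide export: one row per person-cell with NaN sentinels."""
        rows = []
        for pid, g in self.grids.items():
            for t in range(g.n_cells):
                rows.append((pid, t, g.clock_hour[t], *g.values[t]))
        return pd.DataFrame(rows, columns=["person_id", "cell", "clock_hour",
                                           *self.variables])


def build_time_grid(
    data: EsmDataset, interval_minutes: float = 60.0
) -> GriddedSeries:
    """Assign each observation to the nearest cell of a per-person grid.

    The grid origin is the person's first completed observation; cell index
    = round(elapsed / interval), with the grid running continuously across
    days and nights. Cell collisions (two prompts mapping to one cell) keep
    the earlier observation; the later one is shifted to the next cell if
    that is empty, else dropped, and either way logged.
    """
    if interval_minutes <= 0:
        raise ValueError("interval_minutes must be > 0")
    grids: dict = {}
    collision_rows = []
    for pid, sub in data.data.groupby("person_id", sort=True):
        ts = sub["timestamp_minute"].to_numpy(float)
        if len(np.unique(ts)) != len(ts):
            raise ValueError(f"person {pid} has duplicated timestamps")
        vals = sub[list(data.variables)].to_numpy(float)
        origin = ts[0]
        target = np.rint((ts - origin) / interval_minutes).astype(int)
        # strict in-time-order pass: earlier observation keeps the cell
        placed: dict[int, int] = {}
        for j, c in enumerate(target):
            if c not in placed:
                placed[c] = j
            elif (c + 1) not in placed:
                placed[c + 1] = j
                collision_rows.append((pid, float(ts[j]), int(c), "shifted"))
            else:
                collision_rows.append((pid, float(ts[j]), int(c), "dropped"))
        n_cells = (max(placed) + 1) if placed else 0
        values = np.full((n_cells, len(data.variables)), np.nan)
        for c, j in placed.items():
            values[c] = vals[j]
        clock_hour = ((origin + np.arange(n_cells) * interval_minutes)
                      % MINUTES_PER_DAY) / 60.0
        grids[pid] = PersonGrid(person_id=pid, origin_minute=float(origin),
                                values=values, clock_hour=clock_hour)
    collisions = pd.DataFrame(collision_rows,
                              columns=["person_id", "timestamp_minute",
                                       "target_cell", "resolution"])
    occ_hours = np.concatenate(
        [g.clock_hour[g.occupied] for g in grids.values()]
    ) if grids else np.array([])
    hour_center = float(occ_hours.mean()) if len(occ_hours) else 0.0
    return GriddedSeries(grids=grids, variables=data.variables,
                         interval_minutes=float(interval_minutes),
                         hour_center=hour_center, collisions=collisions)


def lag_pairs(grid: GriddedSeries) -> pd.Series:
    """Usable lag-1 transitions per person: consecutive cells both occupied.

    Because all momentary items are answered within one questionnaire, the
    count is common to every variable pair; the Series sums to the total
    number of transitions informing the lag coefficients.
    """
    out = {}
    for pid, g in grid.grids.items():
        occ = g.occupied
        out[pid] = int(np.sum(occ[1:] & occ[:-1]))
    return pd.Series(out, name="lag_pairs", dtype=int)
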