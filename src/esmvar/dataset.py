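"""Long-format container for experience-sampling records.

An :class:`EsmDataset` wraps a pandas DataFrame of momentary records plus the
per-person number of scheduled prompts (needed by the compliance and
exclusion rules, since missed prompts leave no row).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EsmDataset"]

ID_COLUMNS = ["person_id", "day", "prompt_index", "scheduled_minute", "timestamp_minute"]


@dataclass
class EsmDataset:
    """Long-format momentary records with per-person scheduling metadata.

    Parameters
    ----------
    data
        One row per completed prompt with columns ``person_id``, ``day``,
        ``prompt_index``, ``scheduled_minute`` (minutes since that day's
        window opened), ``timestamp_minute`` (minutes since the study
        started, i.e. midnight of day 0), and one column per momentary
        variable (Likert units). Optional item-level columns may follow.
    variables
        Ordered names of the momentary composite columns.
    scheduled
        Prompts scheduled per person (Series indexed by person id). Persons
        with zero completed rows must still appear here.
    meta
        Free-form provenance (seeds, realized completion rates, ...).
    """

    data: pd.DataFrame
    variables: tuple[str, ...]
    scheduled: pd.Series
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.variables = tuple(self.variables)
        missing = [c for c in ID_COLUMNS + list(self.variables)
                   if c not in self.data.columns]
        if missing:
            raise ValueError(f"EsmDataset missing columns: {missing}")
        self.data = self.data.sort_values(
            ["person_id", "timestamp_minute"], kind="stable"
        ).reset_index(drop=True)
        self.scheduled = self.scheduled.astype(int)
        extra = set(self.data["person_id"].unique()) - set(self.scheduled.index)
        if extra:
            raise ValueError(
                f"persons present in data but not in the scheduled-count table: "
                f"{sorted(extra)[:5]}"
            )
        ts = self.data.groupby("person_id")["timestamp_minute"]
        if (ts.apply(lambda s: (np.diff(s.to_numpy()) < 0).any())).any():
            raise ValueError("timestamps must be non-decreasing within person")

    @property
    def persons(self) -> np.ndarray:
        """Person ids with scheduling metadata (completed rows or not)."""
        return np.asarray(self.scheduled.index)

    @property
    def n_persons(self) -> int:
        return len(self.scheduled)

    def completed_counts(self) -> pd.Series:
        """Completed prompts per scheduled person (zero-filled)."""
        counts = self.data.groupby("person_id").size()
        return counts.reindex(self.scheduled.index, fill_value=0).astype(int)

    def subset_persons(self, keep) -> "EsmDataset":
        keep = list(keep)
        return EsmDataset(
            data=self.data[self.data["person_id"].isin(keep)].copy(),
            variables=self.variables,
            scheduled=self.scheduled.loc[keep],
            meta=dict(self.meta),
        )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, variables, scheduled_per_person: int | pd.Series,
                 meta: dict | None = None) -> "EsmDataset":
        """Load records from CSV; ``scheduled_per_person`` may be a constant
        (applied to every person appearing in the file) or a full Series."""
        df = pd.read_csv(path)
        if isinstance(scheduled_per_person, pd.Series):
            sched = scheduled_per_person
        else:
            persons = pd.Index(sorted(df["person_id"].unique()), name="person_id")
            sched = pd.Series(int(scheduled_per_person), index=persons)
        return cls(data=df, variables=tuple(variables), scheduled=sched,
                   meta=meta or {})
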