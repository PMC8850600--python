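"""Time budgets and food-intake frequency from instant-level behavior labels.

A time budget expresses each behavior's share of the total observation
record (TOR) as a percentage.  Food intake is grazing + eating; its
frequency is reported in minutes per hour of window time (equivalently
hours per day), with each 6-s record contributing exactly its record
duration of behavior time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .behaviors import BEHAVIORS, INTAKE_BEHAVIORS, validate_behavior

DEFAULT_RECORD_DURATION_S = 6.0


@dataclass
class TimeBudget:
    """Per-behavior percentages of the total observation record."""

    scope: str  # "overall", a genetic group, or an animal id
    percentages: dict[str, float]
    n_labels: int


@dataclass
class IntakeFrequency:
    animal_id: str
    window: str
    minutes_per_hour: float
    hours_per_day: float


def time_budget(
    labels: pd.DataFrame,
    grouping: str = "overall",
) -> list[TimeBudget]:
    """Percent of labels per behavior, by scope.

    ``labels`` needs a ``behavior`` column plus ``genetic_group`` /
    ``animal_id`` when grouping by those.  Empty groups are omitted with a
    warning.  Percentages per scope sum to 100.
    """
    if grouping not in {"overall", "genetic_group", "animal_id"}:
        raise ValueError(f"unknown grouping {grouping!r}")
    frame = labels[labels["behavior"].notna()]
    for label in frame["behavior"].unique():
        validate_behavior(str(label))
    if grouping == "overall":
        scopes = {"overall": frame}
    else:
        scopes = {str(k): g for k, g in frame.groupby(grouping)}
    budgets = []
    for scope, group in scopes.items():
        if group.empty:
            warnings.warn(f"empty group {scope!r} omitted from time budget")
            continue
        counts = group["behavior"].value_counts()
        total = int(counts.sum())
        budgets.append(
            TimeBudget(
                scope=scope,
                percentages={
                    b: 100.0 * counts.get(b, 0) / total for b in BEHAVIORS
                },
                n_labels=total,
            )
        )
    return budgets


def intake_frequency(
    labeled_records: pd.DataFrame,
    record_duration_s: float = DEFAULT_RECORD_DURATION_S,
    window: tuple[pd.Timestamp, pd.Timestamp] | None = None,
    animal_id: str = "overall",
) -> IntakeFrequency:
    """Minutes per hour spent in grazing + eating within a time window.

    minutes/h = (intake-record count × record duration / 60) ÷ window hours.
    The window defaults to the records' own span (inclusive of the last
    record's duration).
    """
    rec = labeled_records
    if window is None:
        if rec.empty:
            raise ValueError("cannot infer a window from an empty record set")
        start = rec["timestamp"].min()
        end = rec["timestamp"].max() + pd.Timedelta(seconds=record_duration_s)
    else:
        start, end = window
        rec = rec[(rec["timestamp"] >= start) & (rec["timestamp"] < end)]
    hours = (end - start).total_seconds() / 3600.0
    if hours <= 0:
        raise ValueError("window length must be positive")
    n_intake = int(rec["behavior"].isin(INTAKE_BEHAVIORS).sum())
    mph = (n_intake * record_duration_s / 60.0) / hours
    return IntakeFrequency(
        animal_id=animal_id,
        window=f"{start.isoformat()}/{end.isoformat()}",
        minutes_per_hour=mph,
        hours_per_day=mph * 24.0 / 60.0,
    )


def min_per_hour_to_h_per_day(minutes_per_hour: float) -> float:
    """Convert an intake frequency to hours per day (display-rounded).

    20.35 min/h → 8.14 h/day; 15.19 min/h → 6.08 h/day.
    """
    if not 0 <= minutes_per_hour <= 60:
        raise ValueError("minutes per hour must lie in [0, 60]")
    return round(minutes_per_hour * 24.0 / 60.0, 2)
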