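"""Reading, converting, quality-controlling and label-aligning sensor streams.

Record streams are plain pandas DataFrames with columns ``sensor_id``,
``animal_id``, ``timestamp`` (tz-aware UTC), ``x_g``, ``y_g``, ``z_g``;
observation tables carry ``animal_id``, ``timestamp``, ``behavior``,
``source``.  CSV round-trips use ISO-8601 timestamps.

Quality control follows the 60-second rule: whenever the interval between
successive records of one animal is *strictly greater* than ``max_gap_s``, a
new contiguous segment is started; derived variables that look across
records (movement variation) never straddle a segment boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behaviors import validate_behavior

RECORD_COLUMNS = ["sensor_id", "animal_id", "timestamp", "x_g", "y_g", "z_g"]
OBS_COLUMNS = ["animal_id", "timestamp", "behavior", "source"]

DEFAULT_MAX_GAP_S = 60.0
DEFAULT_SCAN_INTERVAL_S = 600.0


@dataclass(frozen=True)
class ConversionScale:
    """Linear raw-count → g-unit map, per axis: out = (raw − offset) × gain."""

    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    gain: tuple[float, float, float] = (1.0, 1.0, 1.0)


def convert_raw_to_g(
    raw: tuple[float, float, float] | np.ndarray,
    scale: ConversionScale,
) -> tuple[float, float, float]:
    """Convert one raw integer triple to g units through an explicit scale.

    No hardware default is applied: the configured full-scale range of the
    accelerometer must be supplied by the caller as a :class:`ConversionScale`.
    """
    if scale is None:
        raise ValueError("a ConversionScale is required; no default is assumed")
    raw = np.asarray(raw, dtype=float)
    out = (raw - np.asarray(scale.offset)) * np.asarray(scale.gain)
    return (float(out[0]), float(out[1]), float(out[2]))


@dataclass
class Segment:
    """A gap-free run of one animal's records."""

    animal_id: str
    records: pd.DataFrame

    def __len__(self) -> int:
        return len(self.records)

    @property
    def start(self) -> pd.Timestamp:
        return self.records["timestamp"].iloc[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.records["timestamp"].iloc[-1]


def segment_records(
    records: pd.DataFrame, max_gap_s: float = DEFAULT_MAX_GAP_S
) -> list[Segment]:
    """Split one animal's ordered stream at gaps strictly greater than 60 s.

    A gap of exactly ``max_gap_s`` does NOT split (the rule is
    "higher than 60 s").  Raises on unsorted input.  The union of the
    returned segments is the input, in order.
    """
    if records.empty:
        return []
    animals = records["animal_id"].unique()
    if len(animals) != 1:
        raise ValueError("segment_records expects a single animal's stream")
    ts = records["timestamp"].to_numpy()
    diffs = np.diff(ts).astype("timedelta64[ns]").astype(np.int64) / 1e9
    if (diffs <= 0).any():
        raise ValueError("records must be sorted by strictly increasing timestamp")
    breaks = np.flatnonzero(diffs > max_gap_s) + 1
    pieces = np.split(np.arange(len(records)), breaks)
    return [
        Segment(animal_id=str(animals[0]), records=records.iloc[idx].reset_index(drop=True))
        for idx in pieces
    ]


def segment_all(
    records: pd.DataFrame, max_gap_s: float = DEFAULT_MAX_GAP_S
) -> list[Segment]:
    """Segment a multi-animal stream animal by animal."""
    out: list[Segment] = []
    for _, group in records.groupby("animal_id", sort=False):
        out.extend(segment_records(group.reset_index(drop=True), max_gap_s))
    return out


def align_labels(
    records: pd.DataFrame,
    observations: pd.DataFrame,
    policy: str = "forward_fill",
    scan_interval_s: float = DEFAULT_SCAN_INTERVAL_S,
) -> pd.DataFrame:
    """Attach scan-sampled behavior labels to 6-s records.

    Policies:

    * ``forward_fill`` (default): each observation labels the interval from
      its scan instant up to the next scan (at most one scan interval), the
      scan-sampling convention that a scan represents its interval.
    * ``nearest``: a record takes the label of the closest observation when
      that distance is at most half the scan interval; ties go to the
      earlier observation.

    Records outside coverage get a null behavior.  Duplicate observations of
    one animal at one instant raise.
    """
    if policy not in {"forward_fill", "nearest"}:
        raise ValueError(f"unknown alignment policy {policy!r}")
    for label in observations["behavior"].unique():
        validate_behavior(str(label))
    dup = observations.duplicated(subset=["animal_id", "timestamp"])
    if dup.any():
        raise ValueError("duplicate observations for one animal and instant")

    out = records.copy()
    out["behavior"] = pd.Series([None] * len(out), dtype=object)
    for animal_id, rec in records.groupby("animal_id", sort=False):
        obs = observations[observations["animal_id"] == animal_id].sort_values(
            "timestamp"
        )
        if obs.empty:
            continue
        rec_ts = rec["timestamp"].to_numpy()
        obs_ts = obs["timestamp"].to_numpy()
        obs_lab = obs["behavior"].to_numpy(dtype=object)
        if policy == "forward_fill":
            idx = np.searchsorted(obs_ts, rec_ts, side="right") - 1
            valid = idx >= 0
            dist = np.full(len(rec_ts), np.inf)
            dist[valid] = (
                (rec_ts[valid] - obs_ts[idx[valid]])
                .astype("timedelta64[ns]")
                .astype(np.int64)
                / 1e9
            )
            # coverage caps at one scan interval (exclusive of the next scan)
            within = valid & (dist < scan_interval_s)
            labels = np.where(within, obs_lab[np.clip(idx, 0, None)], None)
        else:  # nearest
            pos = np.searchsorted(obs_ts, rec_ts)
            left = np.clip(pos - 1, 0, len(obs_ts) - 1)
            right = np.clip(pos, 0, len(obs_ts) - 1)
            d_left = np.abs(rec_ts - obs_ts[left]).astype("timedelta64[ns]").astype(np.int64) / 1e9
            d_right = np.abs(obs_ts[right] - rec_ts).astype("timedelta64[ns]").astype(np.int64) / 1e9
            use_left = d_left <= d_right  # tie → earlier observation
            idx = np.where(use_left, left, right)
            dist = np.where(use_left, d_left, d_right)
            within = dist <= scan_interval_s / 2.0
            labels = np.where(within, obs_lab[idx], None)
        out.loc[rec.index, "behavior"] = labels
    return out


# --------------------------------------------------------------------------
# CSV dialects
# --------------------------------------------------------------------------

def read_records_csv(path) -> pd.DataFrame:
    """Read a records CSV (ISO-8601 UTC timestamps), sorted per animal."""
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records CSV missing columns: {', '.join(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    return df[RECORD_COLUMNS]


def write_records_csv(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out[RECORD_COLUMNS].to_csv(path, index=False)


def read_observations_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observations CSV missing columns: {', '.join(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    for label in df["behavior"].unique():
        validate_behavior(str(label))
    return df[OBS_COLUMNS]


def write_observations_csv(observations: pd.DataFrame, path) -> None:
    out = observations.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out[OBS_COLUMNS].to_csv(path, index=False)
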