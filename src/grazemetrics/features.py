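"""Per-record derived variables from the tri-axial signal.

Eight variables are computed from each record's axis values (X, Y, Z in g
units), following the standard accelerometry definitions used for ingestive
behavior classification:

======================  =====================================================
signal magnitude area   ``|X| + |Y| + |Z|``
signal vector magnitude ``sqrt(X² + Y² + Z²)``
movement variation      ``|X'−X| + |Y'−Y| + |Z'−Z|`` to the next record
energy                  ``(X² + Y² + Z²)²``  (= SVM⁴)
entropy                 ``(1 + (X+Y+Z))² · ln(1 + (X+Y+Z)²)``
pitch (deg)             ``atan(−X / sqrt(Y² + Z²)) · 180/π``
roll (deg)              ``atan2(Y, Z) · 180/π``
inclination (deg)       ``atan(sqrt(X² + Y²) / Z) · 180/π``
======================  =====================================================

"Entropy" is kept as the conventional name although the quantity is not an
information entropy.  Degenerate angles use the two-argument arctangent
convention: pitch at Y=Z=0 is ±90° by the sign of −X, inclination at Z=0 is
+90° when the numerator is positive, and atan2(0, 0) is 0.

Movement variation is attached to the earlier record of each consecutive
pair within a segment; the final record of a segment has no successor and
gets a null, and such rows are dropped from modeling tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sensor_io import Segment

STATIC_FEATURES = [
    "sma",
    "svm",
    "energy",
    "entropy",
    "pitch_deg",
    "roll_deg",
    "inclination_deg",
]
FEATURE_COLUMNS = STATIC_FEATURES[:2] + ["movement_variation"] + STATIC_FEATURES[2:]
TIME_COLUMNS = ["day", "month", "hour", "minute", "second"]


def static_features(x, y, z):
    """Compute the seven single-record variables; inputs in g units.

    Accepts scalars or aligned arrays; returns a dict of arrays (or floats).
    Raises on non-finite input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(z).all()):
        raise ValueError("axis values must be finite")
    sq = x * x + y * y + z * z
    s = x + y + z
    hyp_yz = np.hypot(y, z)
    hyp_xy = np.hypot(x, y)
    pitch = np.degrees(np.arctan2(-x, hyp_yz))
    roll = np.degrees(np.arctan2(y, z))
    # atan2(-0.0, z<0) returns -180 exactly; keep roll in (-180, 180]
    roll = np.where(roll <= -180.0, roll + 360.0, roll)
    with np.errstate(divide="ignore", invalid="ignore"):
        incl = np.where(
            z == 0.0,
            np.where(hyp_xy > 0.0, 90.0, 0.0),
            np.degrees(np.arctan(hyp_xy / np.where(z == 0.0, 1.0, z))),
        )
    out = {
        "sma": np.abs(x) + np.abs(y) + np.abs(z),
        "svm": np.sqrt(sq),
        "energy": sq * sq,
        "entropy": (1.0 + s) ** 2 * np.log1p(s * s),
        "pitch_deg": pitch,
        "roll_deg": roll,
        "inclination_deg": incl,
    }
    if x.ndim == 0:
        out = {k: float(v) for k, v in out.items()}
    return out


def movement_variation(prev: pd.Series, curr: pd.Series) -> float:
    """Sum of absolute per-axis differences between two consecutive records."""
    return float(
        abs(curr["x_g"] - prev["x_g"])
        + abs(curr["y_g"] - prev["y_g"])
        + abs(curr["z_g"] - prev["z_g"])
    )


def _segment_features(segment: Segment, segment_id: int) -> pd.DataFrame:
    rec = segment.records
    feats = static_features(
        rec["x_g"].to_numpy(), rec["y_g"].to_numpy(), rec["z_g"].to_numpy()
    )
    dx = rec[["x_g", "y_g", "z_g"]].diff(-1).abs()  # diff to the NEXT record
    mv = dx.sum(axis=1, skipna=False).to_numpy()  # NaN on the last row
    ts = rec["timestamp"].dt
    table = pd.DataFrame(
        {
            "segment_id": segment_id,
            "sensor_id": rec["sensor_id"].to_numpy(),
            "animal_id": rec["animal_id"].to_numpy(),
            "timestamp": rec["timestamp"].to_numpy(),
            "day": ts.day.to_numpy(),
            "month": ts.month.to_numpy(),
            "hour": ts.hour.to_numpy(),
            "minute": ts.minute.to_numpy(),
            "second": ts.second.to_numpy(),
            "sma": feats["sma"],
            "svm": feats["svm"],
            "movement_variation": mv,
            "energy": feats["energy"],
            "entropy": feats["entropy"],
            "pitch_deg": feats["pitch_deg"],
            "roll_deg": feats["roll_deg"],
            "inclination_deg": feats["inclination_deg"],
        }
    )
    if "behavior" in rec.columns:
        table["behavior"] = rec["behavior"].to_numpy(dtype=object)
    return table


def build_feature_table(
    segments: list[Segment],
    genetic_group_of: dict[str, str] | None = None,
    modeling: bool = True,
) -> pd.DataFrame:
    """One feature row per record across segments.

    With ``modeling=True`` (default) rows whose movement variation is null
    (each segment's last record) are dropped, and, when a ``behavior`` column
    is present, unlabeled rows are dropped as well — the documented filter
    for classifier tables.  The unfiltered table has Σ segment lengths rows;
    the movement-variation filter leaves Σ(lengths) − #segments.
    """
    if not segments:
        return pd.DataFrame()
    parts = [_segment_features(seg, i) for i, seg in enumerate(segments)]
    table = pd.concat(parts, ignore_index=True)
    if genetic_group_of is not None:
        table["genetic_group"] = table["animal_id"].map(genetic_group_of)
    if modeling:
        table = table[table["movement_variation"].notna()]
        if "behavior" in table.columns:
            table = table[table["behavior"].notna()]
        table = table.reset_index(drop=True)
    return table
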