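"""Synthetic herd generator: behavior timelines, sensor streams, performance.

This module fabricates complete desk-scale studies of beef cattle on tropical
pasture with known ground truth.  A study consists of

* a continuous per-animal behavior timeline drawn from a semi-Markov renewal
  process (lognormal bout durations, circadian entry-intensity modulation),
* a tri-axial accelerometer stream sampled every 6 s (one record per
  ``sampling_period_s``), each axis a per-behavior mean plus a sinusoidal
  oscillation plus Gaussian noise,
* scan-sampled visual observations (one instantaneous label per animal every
  10 min, 06:00-18:00),
* per-period forage covariates and body weights generating an observed
  intermediate average daily gain (iADG) through a known linear model.

Defaults emulate the study conditions the package targets: 22 animals in
three genetic groups (10 Nellore finished in the dry season on 2.0 % BW
supplement, 5 Nellore and 7 crossbred reared in the wet season on 0 and
0.3 % BW), an overall behavior composition of 28.9 % grazing, 9.8 %
ruminating, 51.0 % lying-standing, 1.4 % drinking, 6.0 % eating and 2.9 %
other, supplement eating concentrated near 10:00, 12:00 and 16:00, and a
resting (lying-standing) signal that is quieter than every other behavior on
all three axes.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behaviors import BEHAVIORS, GENETIC_GROUPS, INTAKE_BEHAVIORS, validate_behavior

SECONDS_PER_DAY = 86_400


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnimalMeta:
    """Identity and husbandry metadata for one monitored animal."""

    animal_id: str
    sensor_id: str
    genetic_group: str
    initial_weight_kg: float
    supplement_level_pct_bw: float

    def __post_init__(self) -> None:
        if self.genetic_group not in GENETIC_GROUPS:
            raise ValueError(f"unknown genetic group {self.genetic_group!r}")
        if self.initial_weight_kg <= 0:
            raise ValueError("initial weight must be positive")
        if self.supplement_level_pct_bw < 0:
            raise ValueError("supplement level must be >= 0")


@dataclass(frozen=True)
class CircadianProfile:
    """Clock-time modulation of a behavior's entry intensity.

    ``windows`` is a list of ``(start, end, multiplier)`` with clock times as
    "HH:MM" strings; outside every window the ``baseline`` multiplier applies.
    Profiles whose time-average multiplier is ~1 leave the long-run behavior
    composition unchanged while concentrating bouts inside their windows.
    """

    baseline: float = 1.0
    windows: tuple[tuple[str, str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValueError("circadian baseline must be >= 0")
        for start, end, mult in self.windows:
            if mult < 0:
                raise ValueError("circadian multipliers must be >= 0")
            _parse_clock(start), _parse_clock(end)

    def multiplier_at(self, second_of_day: float) -> float:
        for start, end, mult in self.windows:
            if _parse_clock(start) <= second_of_day < _parse_clock(end):
                return mult
        return self.baseline


def _parse_clock(text: str) -> int:
    """'HH:MM' → second of day."""
    hh, mm = text.split(":")
    sec = int(hh) * 3600 + int(mm) * 60
    if not 0 <= sec <= SECONDS_PER_DAY:
        raise ValueError(f"clock time out of range: {text!r}")
    return sec


#: overall behavior composition target (fractions of total time)
DEFAULT_PROPORTIONS: dict[str, float] = {
    "grazing": 0.289,
    "ruminating": 0.098,
    "lying_standing": 0.510,
    "drinking": 0.014,
    "eating": 0.060,
    "other": 0.029,
}

#: per-behavior lognormal bout durations: (median seconds, log-sd dispersion)
DEFAULT_BOUT_PARAMS: dict[str, tuple[float, float]] = {
    "grazing": (1500.0, 0.6),
    "ruminating": (1200.0, 0.5),
    "lying_standing": (2400.0, 0.6),
    "drinking": (60.0, 0.4),
    "eating": (420.0, 0.5),
    "other": (120.0, 0.6),
}

#: entry-intensity corrections compensating the normalization bias that
#: circadian gating introduces into long-run time shares (calibrated once so
#: the default schedule converges to DEFAULT_PROPORTIONS)
DEFAULT_ENTRY_CORRECTION: dict[str, float] = {
    "grazing": 1.0,
    "ruminating": 1.03,
    "lying_standing": 1.03,
    "drinking": 1.0,
    "eating": 2.23,
    "other": 1.0,
}

#: circadian defaults: supplement eating happens in three trough windows
#: (time-average multiplier of each profile is 1, preserving composition)
DEFAULT_CIRCADIAN: dict[str, CircadianProfile] = {
    "eating": CircadianProfile(
        baseline=0.0,
        windows=(
            ("09:30", "10:30", 8.0),
            ("11:30", "12:30", 8.0),
            ("15:30", "16:30", 8.0),
        ),
    ),
    "grazing": CircadianProfile(
        baseline=0.8,
        windows=(("06:00", "09:00", 1.6), ("15:00", "18:00", 1.6)),
    ),
    "lying_standing": CircadianProfile(
        baseline=0.6,
        windows=(("18:00", "24:00", 1.4), ("00:00", "06:00", 1.4)),
    ),
}


def default_animals() -> tuple[AnimalMeta, ...]:
    """The 22-head default herd: 10 Nellore-dry, 5 Nellore-wet, 7 crossbred-wet."""
    spec = [
        ("nellore_dry", 10, 343.0, 2.0),
        ("nellore_wet", 5, 310.0, 0.0),
        ("crossbred_wet", 7, 324.0, 0.3),
    ]
    animals: list[AnimalMeta] = []
    k = 0
    for group, n, weight, suppl in spec:
        for i in range(n):
            k += 1
            animals.append(
                AnimalMeta(
                    animal_id=f"A{k:02d}",
                    sensor_id=f"S{k:03d}",
                    genetic_group=group,
                    initial_weight_kg=weight,
                    supplement_level_pct_bw=suppl,
                )
            )
    return tuple(animals)


@dataclass(frozen=True)
class ScheduleConfig:
    """Parameters of the semi-Markov behavior schedule simulator."""

    target_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    bout_duration_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUT_PARAMS)
    )
    circadian: dict[str, CircadianProfile] = field(
        default_factory=lambda: dict(DEFAULT_CIRCADIAN)
    )
    entry_correction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENTRY_CORRECTION)
    )
    day_span: int = 1
    animals: tuple[AnimalMeta, ...] = field(default_factory=default_animals)

    def __post_init__(self) -> None:
        total = sum(self.target_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"target_proportions must sum to 1 (got {total!r})"
            )
        for label in self.target_proportions:
            validate_behavior(label)
        for label, (median, sigma) in self.bout_duration_params.items():
            validate_behavior(label)
            if median <= 0 or sigma < 0:
                raise ValueError(f"invalid bout duration params for {label}")
        if self.day_span < 1:
            raise ValueError("day_span must be >= 1")


@dataclass(frozen=True)
class BehaviorSignal:
    """Accelerometer signature of one behavior (all values in g units)."""

    mean: tuple[float, float, float]
    amplitude: float
    period_s: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.amplitude < 0 or self.period_s <= 0:
            raise ValueError("amplitude/noise must be >= 0 and period > 0")


#: head-mounted sensor signatures; resting is quietest on every axis, and its
#: mean vector has the smallest norm (head at rest carries less dynamic load)
DEFAULT_SIGNALS: dict[str, BehaviorSignal] = {
    "grazing": BehaviorSignal((0.30, 0.22, 0.92), amplitude=0.35, period_s=1.3, noise_sd=0.12),
    "ruminating": BehaviorSignal((0.10, 0.12, 0.96), amplitude=0.18, period_s=1.0, noise_sd=0.08),
    "lying_standing": BehaviorSignal((0.04, 0.05, 0.80), amplitude=0.02, period_s=4.0, noise_sd=0.02),
    "drinking": BehaviorSignal((0.20, 0.32, 0.88), amplitude=0.20, period_s=2.0, noise_sd=0.10),
    "eating": BehaviorSignal((0.26, 0.36, 0.84), amplitude=0.30, period_s=0.8, noise_sd=0.12),
    "other": BehaviorSignal((0.16, 0.15, 0.95), amplitude=0.26, period_s=3.0, noise_sd=0.15),
}


@dataclass(frozen=True)
class SignalConfig:
    """Per-behavior signal model plus the sampling cadence (default 6 s)."""

    behaviors: dict[str, BehaviorSignal] = field(
        default_factory=lambda: dict(DEFAULT_SIGNALS)
    )
    sampling_period_s: float = 6.0

    def __post_init__(self) -> None:
        if self.sampling_period_s <= 0:
            raise ValueError("sampling_period_s must be > 0")
        for label in self.behaviors:
            validate_behavior(label)
        rest = self.behaviors.get("lying_standing")
        if rest is not None:
            quiet = rest.amplitude + rest.noise_sd
            for label, sig in self.behaviors.items():
                if label == "lying_standing":
                    continue
                if quiet >= sig.amplitude + sig.noise_sd:
                    raise ValueError(
                        "lying_standing amplitude + noise must be strictly "
                        f"smaller than {label}'s on all axes"
                    )

    def zero_noise(self) -> "SignalConfig":
        """Copy with every behavior's Gaussian noise removed (sd scaled to ~0)."""
        quiet = {
            label: replace(sig, noise_sd=1e-9 if label != "lying_standing" else 0.0)
            for label, sig in self.behaviors.items()
        }
        return SignalConfig(behaviors=quiet, sampling_period_s=self.sampling_period_s)


#: coefficients of the iADG-generating linear model (kg/day per unit)
DEFAULT_PERF_COEFFICIENTS: dict[str, float] = {
    "intake_frequency": 0.030,   # per min/h of grazing+eating
    "supplement_level": 0.100,   # per % BW
    "cp_pct": 0.020,
    "ndf_pct": -0.010,
    "adf_pct": -0.005,
    "forage_mass_kg_ha": 0.00005,
    "leaf_pct": 0.010,
    "stem_pct": -0.005,
    "day": 0.001,                # cumulative day index at period end
}

DEFAULT_GROUP_OFFSETS: dict[str, float] = {
    "nellore_dry": 0.0,
    "nellore_wet": 0.05,
    "crossbred_wet": 0.12,
}


@dataclass(frozen=True)
class PerformanceGenConfig:
    """Generative linear model for observed iADG (kg/day)."""

    intercept: float = -0.20
    coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PERF_COEFFICIENTS)
    )
    group_offsets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_OFFSETS)
    )
    noise_sd: float = 0.05
    period_length_days: int = 28
    plausibility_band: tuple[float, float] = (0.0, 2.0)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        lo, hi = self.plausibility_band
        if not lo < hi:
            raise ValueError("plausibility band must be a nonempty interval")


#: season-level forage descriptors (forage mass kg/ha, % of DM for the rest)
SEASON_COVARIATES: dict[str, dict[str, float]] = {
    "dry": {
        "forage_mass_kg_ha": 5020.0,
        "cp_pct": 16.5,
        "ndf_pct": 51.5,
        "adf_pct": 24.9,
        "leaf_pct": 14.5,
        "stem_pct": 9.1,  # leaf:stem ratio 1.6
    },
    "wet": {
        "forage_mass_kg_ha": 7900.0,
        "cp_pct": 15.6,
        "ndf_pct": 61.3,
        "adf_pct": 30.2,
        "leaf_pct": 30.7,
        "stem_pct": 30.7,  # leaf:stem ratio 1.0
    },
}

GROUP_SEASON: dict[str, str] = {
    "nellore_dry": "dry",
    "nellore_wet": "wet",
    "crossbred_wet": "wet",
}

GROUP_START_DATE: dict[str, str] = {
    "nellore_dry": "2019-09-15",
    "nellore_wet": "2020-01-20",
    "crossbred_wet": "2020-01-20",
}


@dataclass(frozen=True)
class StudyScenario:
    """Everything needed to generate one synthetic study."""

    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    signal: SignalConfig = field(default_factory=SignalConfig)
    performance: PerformanceGenConfig = field(default_factory=PerformanceGenConfig)
    n_periods: int = 3
    dropout_rate: float = 0.0
    dropout_burst_mean: float = 5.0
    weight_sd_kg: float = 30.0
    covariate_jitter: float = 0.05
    paddock_jitter: float = 0.03  # per animal-period forage sampling spread
    intake_jitter_min_per_h: float = 1.5

    def __post_init__(self) -> None:
        if self.n_periods < 1:
            raise ValueError("n_periods must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


# --------------------------------------------------------------------------
# behavior timeline
# --------------------------------------------------------------------------

@dataclass
class BehaviorTimeline:
    """Piecewise-constant behavior path for one animal.

    ``bounds_s`` holds bout start offsets (seconds from study start, first 0)
    and ``labels`` the behavior of each bout; the last bout ends at ``span_s``.
    """

    animal_id: str
    start: pd.Timestamp
    bounds_s: np.ndarray
    labels: np.ndarray
    span_s: float

    def label_at(self, offsets_s: np.ndarray) -> np.ndarray:
        offsets_s = np.asarray(offsets_s, dtype=float)
        if offsets_s.size and (offsets_s.min() < 0 or offsets_s.max() >= self.span_s):
            raise ValueError("offsets outside the simulated span")
        idx = np.searchsorted(self.bounds_s, offsets_s, side="right") - 1
        return self.labels[idx]

    def time_in(self, labels: set[str], start_s: float = 0.0, end_s: float | None = None) -> float:
        """Seconds spent in *labels* within [start_s, end_s)."""
        end_s = self.span_s if end_s is None else end_s
        ends = np.append(self.bounds_s[1:], self.span_s)
        lo = np.clip(self.bounds_s, start_s, end_s)
        hi = np.clip(ends, start_s, end_s)
        mask = np.isin(self.labels, list(labels))
        return float(np.sum((hi - lo)[mask]))

    def proportions(self) -> dict[str, float]:
        """Empirical fraction of total time per behavior."""
        ends = np.append(self.bounds_s[1:], self.span_s)
        dur = ends - self.bounds_s
        out = {b: 0.0 for b in BEHAVIORS}
        for label, d in zip(self.labels, dur):
            out[label] += float(d)
        return {b: v / self.span_s for b, v in out.items()}


def _entry_weights(config: ScheduleConfig) -> dict[str, float]:
    """Renewal-reward weights: p_b / E[bout length] so time shares hit targets."""
    weights = {}
    for label, p in config.target_proportions.items():
        median, sigma = config.bout_duration_params[label]
        mean = median * math.exp(sigma**2 / 2.0)
        weights[label] = p / mean * config.entry_correction.get(label, 1.0)
    return weights


def simulate_schedule(
    config: ScheduleConfig, seed: int
) -> dict[str, BehaviorTimeline]:
    """Simulate a behavior timeline per animal.

    At each renewal the next behavior is drawn with probability proportional
    to (target share / mean bout length) x circadian multiplier at the clock
    time of entry, then held for a lognormal bout.  Self-transitions are
    allowed (the renewal-reward identity then makes long-run time shares
    converge to ``target_proportions`` when circadian profiles average to 1).
    """
    base_weights = _entry_weights(config)
    labels_order = [b for b in BEHAVIORS if config.target_proportions.get(b, 0) > 0]
    span = config.day_span * SECONDS_PER_DAY
    timelines: dict[str, BehaviorTimeline] = {}
    for idx, animal in enumerate(config.animals):
        rng = np.random.default_rng([seed % (2**31), idx])
        t = 0.0
        bounds: list[float] = []
        labels: list[str] = []
        while t < span:
            second_of_day = t % SECONDS_PER_DAY
            w = np.array(
                [
                    base_weights[b]
                    * config.circadian.get(b, CircadianProfile()).multiplier_at(
                        second_of_day
                    )
                    for b in labels_order
                ]
            )
            if w.sum() <= 0:  # every behavior gated off right now
                w = np.array([base_weights[b] for b in labels_order])
            behavior = rng.choice(labels_order, p=w / w.sum())
            median, sigma = config.bout_duration_params[behavior]
            duration = float(rng.lognormal(math.log(median), sigma))
            if labels and labels[-1] == behavior:
                pass  # merged bout: extend without a new breakpoint
            else:
                bounds.append(t)
                labels.append(behavior)
            t += duration
        start = pd.Timestamp(GROUP_START_DATE[animal.genetic_group], tz="UTC")
        timelines[animal.animal_id] = BehaviorTimeline(
            animal_id=animal.animal_id,
            start=start,
            bounds_s=np.asarray(bounds, dtype=float),
            labels=np.asarray(labels, dtype=object),
            span_s=float(span),
        )
    return timelines


# --------------------------------------------------------------------------
# sensor signal
# --------------------------------------------------------------------------

def simulate_signal(
    timeline: BehaviorTimeline,
    signal_config: SignalConfig,
    seed: int,
    sensor_id: str = "S000",
) -> pd.DataFrame:
    """Sample a tri-axial record stream along one animal's timeline.

    Each axis is behavior mean + amplitude x sin(2*pi*t/period + bout phase)
    + N(0, noise_sd).  One record per ``sampling_period_s``; the record count
    is floor(span / sampling_period_s).
    """
    rng = np.random.default_rng(
        [seed % (2**31), zlib.crc32(timeline.animal_id.encode())]
    )
    dt = signal_config.sampling_period_s
    n = int(timeline.span_s // dt)
    offsets = np.arange(n) * dt
    labels = timeline.label_at(offsets)
    bout_idx = np.searchsorted(timeline.bounds_s, offsets, side="right") - 1
    phases = rng.uniform(0, 2 * np.pi, size=(len(timeline.bounds_s), 3))

    xyz = np.empty((n, 3))
    for behavior, sig in signal_config.behaviors.items():
        mask = labels == behavior
        if not mask.any():
            continue
        t = offsets[mask, None]
        ph = phases[bout_idx[mask]]
        osc = sig.amplitude * np.sin(2 * np.pi * t / sig.period_s + ph)
        noise = rng.normal(0.0, sig.noise_sd, size=(int(mask.sum()), 3))
        xyz[mask] = np.asarray(sig.mean) + osc + noise
    unknown = ~np.isin(labels, list(signal_config.behaviors))
    if unknown.any():
        raise ValueError("timeline contains behaviors absent from SignalConfig")

    return pd.DataFrame(
        {
            "sensor_id": sensor_id,
            "animal_id": timeline.animal_id,
            "timestamp": timeline.start + pd.to_timedelta(offsets, unit="s"),
            "x_g": xyz[:, 0],
            "y_g": xyz[:, 1],
            "z_g": xyz[:, 2],
        }
    )


# --------------------------------------------------------------------------
# scan-sampled observation and record dropout
# --------------------------------------------------------------------------

def observe_scan_sampling(
    timelines: dict[str, BehaviorTimeline],
    scan_interval_min: float = 10.0,
    daily_window: tuple[str, str] = ("06:00", "18:00"),
) -> pd.DataFrame:
    """Instantaneous behavior labels on the scan grid, both endpoints included.

    The default 06:00-18:00 window at 10-min intervals yields 73 scans per
    animal-day.  Night behavior stays simulated but unobserved.
    """
    start_s, end_s = (_parse_clock(c) for c in daily_window)
    if not 0 <= start_s < end_s <= SECONDS_PER_DAY:
        raise ValueError("daily window must lie within one day, start < end")
    step = scan_interval_min * 60.0
    scan_offsets = np.arange(start_s, end_s + 1e-9, step)
    rows = []
    for animal_id, timeline in timelines.items():
        days = int(timeline.span_s // SECONDS_PER_DAY)
        if days < 1 or end_s > timeline.span_s:
            raise ValueError("observation window outside the simulated span")
        for day in range(days):
            offs = day * SECONDS_PER_DAY + scan_offsets
            labels = timeline.label_at(offs)
            rows.append(
                pd.DataFrame(
                    {
                        "animal_id": animal_id,
                        "timestamp": timeline.start + pd.to_timedelta(offs, unit="s"),
                        "behavior": labels,
                        "source": "synthetic",
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def inject_gaps(
    records: pd.DataFrame,
    dropout_rate: float,
    burst_length_mean: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Remove contiguous bursts of records (telemetry dropouts).

    A two-state Markov chain walks the stream: from "keep" it enters a burst
    with rate chosen so the stationary dropped fraction equals
    ``dropout_rate``; burst lengths are geometric with the given mean.
    """
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must be in [0, 1)")
    if dropout_rate == 0:
        return records.copy()
    leave = 1.0 / burst_length_mean
    enter = leave * dropout_rate / (1.0 - dropout_rate)
    rng = np.random.default_rng(seed % (2**31))
    keep_mask = np.ones(len(records), dtype=bool)
    pos = 0
    for _, group in records.groupby("animal_id", sort=False):
        n = len(group)
        u = rng.uniform(size=n)
        dropping = False
        for i in range(n):
            dropping = (u[i] >= leave) if dropping else (u[i] < enter)
            keep_mask[pos + i] = not dropping
        pos += n
    return records.loc[keep_mask].reset_index(drop=True)


# --------------------------------------------------------------------------
# performance generation
# --------------------------------------------------------------------------

def simulate_performance(
    design: pd.DataFrame,
    perf_config: PerformanceGenConfig,
    seed: int,
) -> pd.DataFrame:
    """Generate observed iADG (kg/day) and start/end weights per animal-period.

    ``design`` needs one row per animal-period with every covariate named in
    the config plus ``genetic_group`` and ``start_weight_kg``.  iADG is the
    linear predictor plus Gaussian noise, clipped to the plausibility band;
    end weight = start weight + iADG x period length.
    """
    required = set(perf_config.coefficients) | {"genetic_group", "start_weight_kg"}
    missing = sorted(required - set(design.columns))
    if missing:
        raise ValueError(f"design is missing covariates: {', '.join(missing)}")
    rng = np.random.default_rng(seed % (2**31))
    lp = np.full(len(design), perf_config.intercept, dtype=float)
    for name, coef in perf_config.coefficients.items():
        lp += coef * design[name].to_numpy(dtype=float)
    lp += design["genetic_group"].map(perf_config.group_offsets).to_numpy(dtype=float)
    noise = rng.normal(0.0, perf_config.noise_sd, size=len(design))
    lo, hi = perf_config.plausibility_band
    iadg = np.clip(lp + noise, lo, hi)
    out = design.copy()
    out["iadg_observed"] = iadg
    out["end_weight_kg"] = (
        out["start_weight_kg"] + iadg * perf_config.period_length_days
    )
    return out


def sample_performance_design(
    n: int,
    seed: int,
    perf_config: PerformanceGenConfig | None = None,
) -> pd.DataFrame:
    """Randomised animal-period design for parameter-recovery studies.

    Rows jitter around the two seasons' printed forage values so that no
    covariate is constant or collinear; intake frequency and supplement level
    vary per row.
    """
    rng = np.random.default_rng(seed % (2**31))
    groups = rng.choice(GENETIC_GROUPS, size=n)
    seasons = np.array([GROUP_SEASON[g] for g in groups])
    rows = {
        name: np.array([SEASON_COVARIATES[s][name] for s in seasons])
        * rng.uniform(0.85, 1.15, size=n)
        for name in (
            "forage_mass_kg_ha",
            "cp_pct",
            "ndf_pct",
            "adf_pct",
            "leaf_pct",
            "stem_pct",
        )
    }
    design = pd.DataFrame(rows)
    design["intake_frequency"] = rng.uniform(10.0, 30.0, size=n)
    design["supplement_level"] = np.where(
        groups == "nellore_dry", 2.0, np.where(groups == "nellore_wet", 0.0, 0.3)
    ) * rng.uniform(0.8, 1.2, size=n)
    design["day"] = rng.choice([28, 56, 84], size=n).astype(float)
    design["genetic_group"] = groups
    design["start_weight_kg"] = rng.normal(325.0, 30.0, size=n)
    design["animal_id"] = [f"A{i:03d}" for i in range(n)]
    design["period"] = (design["day"] // 28).astype(int)
    return design


# --------------------------------------------------------------------------
# full study
# --------------------------------------------------------------------------

@dataclass
class StudyBundle:
    """One complete synthetic study with its generating truth attached."""

    animals: tuple[AnimalMeta, ...]
    timelines: dict[str, BehaviorTimeline]
    records: pd.DataFrame
    observations: pd.DataFrame
    covariates: pd.DataFrame
    performance: pd.DataFrame
    scenario: StudyScenario
    seed: int

    def true_record_labels(self) -> pd.Series:
        """Ground-truth behavior for every sensor record (by timeline lookup)."""
        labels = np.empty(len(self.records), dtype=object)
        for animal_id, group in self.records.groupby("animal_id", sort=False):
            timeline = self.timelines[animal_id]
            offs = (
                (group["timestamp"] - timeline.start).dt.total_seconds().to_numpy()
            )
            labels[group.index.to_numpy()] = timeline.label_at(offs)
        return pd.Series(labels, index=self.records.index, name="behavior")


def _observed_intake_min_per_h(
    timeline: BehaviorTimeline, daily_window: tuple[str, str] = ("06:00", "18:00")
) -> float:
    start_s, end_s = (_parse_clock(c) for c in daily_window)
    days = int(timeline.span_s // SECONDS_PER_DAY)
    total = 0.0
    for day in range(days):
        total += timeline.time_in(
            set(INTAKE_BEHAVIORS),
            day * SECONDS_PER_DAY + start_s,
            day * SECONDS_PER_DAY + end_s,
        )
    window_h = days * (end_s - start_s) / 3600.0
    return (total / 60.0) / window_h


def generate_study(scenario: StudyScenario | None = None, seed: int = 0) -> StudyBundle:
    """Generate a full self-consistent study bundle.

    Deterministic: identical (scenario, seed) pairs reproduce identical
    bundles.  The per-period intake frequencies entering the performance
    model are each animal's simulated daytime intake plus a small per-period
    jitter (stored as ``intake_period_offset`` so downstream stages can
    substitute classifier-predicted intake coherently).
    """
    scenario = scenario or StudyScenario()
    timelines = simulate_schedule(scenario.schedule, seed)
    sensor_of = {a.animal_id: a.sensor_id for a in scenario.schedule.animals}
    records = pd.concat(
        [
            simulate_signal(timelines[a.animal_id], scenario.signal, seed, sensor_of[a.animal_id])
            for a in scenario.schedule.animals
        ],
        ignore_index=True,
    )
    if scenario.dropout_rate > 0:
        records = inject_gaps(
            records, scenario.dropout_rate, scenario.dropout_burst_mean, seed + 1
        )
    observations = observe_scan_sampling(timelines)

    rng = np.random.default_rng([seed % (2**31), 9101])
    cov_rows = []
    for group in GENETIC_GROUPS:
        season = GROUP_SEASON[group]
        for period in range(1, scenario.n_periods + 1):
            base = SEASON_COVARIATES[season]
            jitter = rng.uniform(
                1 - scenario.covariate_jitter, 1 + scenario.covariate_jitter, len(base)
            )
            cov_rows.append(
                {"genetic_group": group, "period": period, "season": season}
                | {k: v * j for (k, v), j in zip(base.items(), jitter)}
            )
    covariates = pd.DataFrame(cov_rows)

    perf_rows = []
    period_len = scenario.performance.period_length_days
    for animal in scenario.schedule.animals:
        base_intake = _observed_intake_min_per_h(timelines[animal.animal_id])
        start_w = float(
            rng.normal(animal.initial_weight_kg, scenario.weight_sd_kg / 3.0)
        )
        for period in range(1, scenario.n_periods + 1):
            offset = float(rng.normal(0.0, scenario.intake_jitter_min_per_h))
            cov = covariates[
                (covariates["genetic_group"] == animal.genetic_group)
                & (covariates["period"] == period)
            ].iloc[0]
            perf_rows.append(
                {
                    "animal_id": animal.animal_id,
                    "genetic_group": animal.genetic_group,
                    "period": period,
                    "day": float(period * period_len),
                    "intake_frequency": base_intake + offset,
                    "intake_period_offset": offset,
                    # supplement is offered as % of current BW, so the realised
                    # level drifts slightly from period to period
                    "supplement_level": animal.supplement_level_pct_bw
                    * float(rng.uniform(0.93, 1.07)),
                    "start_weight_kg": start_w,
                    # forage is sampled at the paddock level, so each
                    # animal-period sees its own draw around the group mean
                    **{
                        k: float(cov[k])
                        * float(
                            rng.uniform(
                                1 - scenario.paddock_jitter,
                                1 + scenario.paddock_jitter,
                            )
                        )
                        for k in SEASON_COVARIATES["dry"]
                    },
                }
            )
    perf_design = pd.DataFrame(perf_rows)
    performance = simulate_performance(perf_design, scenario.performance, seed + 2)
    # chain start weights across consecutive periods
    for animal_id, grp in performance.groupby("animal_id", sort=False):
        grp = grp.sort_values("period")
        w = grp["start_weight_kg"].iloc[0]
        for idx in grp.index:
            performance.loc[idx, "start_weight_kg"] = w
            w = w + performance.loc[idx, "iadg_observed"] * period_len
            performance.loc[idx, "end_weight_kg"] = w

    return StudyBundle(
        animals=scenario.schedule.animals,
        timelines=timelines,
        records=records,
        observations=observations,
        covariates=covariates,
        performance=performance,
        scenario=scenario,
        seed=seed,
    )
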