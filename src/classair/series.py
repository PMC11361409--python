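"""Core time-series containers for classroom air-quality data.

A :class:`ConcentrationSeries` holds one pollutant channel at one sampling
location (indoor, outdoor, or valve-switched "mixed") as a timestamped,
quality-flagged vector.  Downstream analysis works on 30-min
:class:`WindowedSeries` averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Recognised pollutant channels and their units.
CHANNELS = {
    "co2": "ppm",
    "total_ufp": "#/cc",
    "aircraft_ufp": "#/cc",
    "cpc_total": "#/cc",
    "bc": "ug/m3",
}

LOCATIONS = ("indoor", "outdoor", "mixed")

#: Per-sample quality flags.
QUALITY_OK = "ok"
QUALITY_ERROR = "error"
QUALITY_TRIMMED = "trimmed"
QUALITY_SUBSTITUTED = "substituted"
QUALITY_FLAGS = (QUALITY_OK, QUALITY_ERROR, QUALITY_TRIMMED, QUALITY_SUBSTITUTED)


@dataclass(frozen=True)
class ValveSchedule:
    """Alternating-inlet solenoid valve timing.

    The valve alternates the instrument inlet between indoor and outdoor
    every ``period`` (field default 5 min, switching on wall-clock multiples
    such as hh:00:00, hh:05:00).  The first ``trim_head`` of each interval is
    discarded to let the sampled air column flush after a switch.

    Parameters
    ----------
    period : pd.Timedelta
        Length of one single-location interval.
    phase_origin : pd.Timestamp
        Instant at which an interval of ``first_location`` begins.
    trim_head : pd.Timedelta
        Duration flagged ``trimmed`` at the start of every interval.
    first_location : str
        Which location the cycle starts with at ``phase_origin``.
    """

    period: pd.Timedelta = pd.Timedelta(minutes=5)
    phase_origin: pd.Timestamp = pd.Timestamp("2021-06-01 00:00:00")
    trim_head: pd.Timedelta = pd.Timedelta(minutes=2)
    first_location: str = "indoor"

    def __post_init__(self) -> None:
        if self.period <= pd.Timedelta(0):
            raise ValueError("valve period must be positive")
        if not pd.Timedelta(0) <= self.trim_head < self.period:
            raise ValueError("trim_head must lie in [0, period)")
        if self.first_location not in ("indoor", "outdoor"):
            raise ValueError("first_location must be 'indoor' or 'outdoor'")


@dataclass(frozen=True)
class SessionMetadata:
    """Context for one school visit.

    ``hepa_intervals`` is a list of ``(start, end, cadr_m3h)`` tuples marking
    when the portable HEPA unit ran and at what clean-air delivery rate.
    """

    school_id: str
    visit: int
    room_volume_m3: float
    hepa_intervals: tuple = ()
    channels_present: frozenset = frozenset()
    valve_schedule: ValveSchedule | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.room_volume_m3 <= 0:
            raise ValueError("room_volume_m3 must be positive")
        ivs = sorted(self.hepa_intervals, key=lambda iv: iv[0])
        for (s0, e0, c0), (s1, _, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError("hepa_intervals overlap")
        for s, e, cadr in ivs:
            if cadr < 0:
                raise ValueError("cadr must be nonnegative")
            if e <= s:
                raise ValueError("hepa interval end must follow start")
        object.__setattr__(self, "hepa_intervals", tuple(ivs))

    def hepa_state_at(self, when) -> bool:
        when = pd.Timestamp(when)
        return any(s <= when < e and c > 0 for s, e, c in self.hepa_intervals)


@dataclass
class ConcentrationSeries:
    """One pollutant channel at one location, quality-flagged per sample."""

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    channel: str
    location: str
    quality: np.ndarray = field(default=None)  # type: ignore[assignment]
    valve_schedule: ValveSchedule | None = None

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if self.quality is None:
            self.quality = np.where(
                np.isfinite(self.values) & (self.values >= 0),
                QUALITY_OK,
                QUALITY_ERROR,
            )
        self.quality = np.asarray(self.quality, dtype=object)
        if not (len(self.timestamps) == len(self.values) == len(self.quality)):
            raise ValueError("timestamps, values, quality must share length")
        if len(self.timestamps) > 1 and not self.timestamps.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")
        if len(self.timestamps) != len(self.timestamps.unique()):
            raise ValueError("timestamps must be strictly increasing (duplicates found)")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        if not set(self.quality) <= set(QUALITY_FLAGS):
            raise ValueError("unknown quality flag present")
        # negative or non-finite values must not carry an analysable flag
        usable = np.isin(self.quality, (QUALITY_OK, QUALITY_SUBSTITUTED))
        if np.any(usable & ~(np.isfinite(self.values) & (self.values >= 0))):
            raise ValueError("usable samples must be finite and nonnegative")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def units(self) -> str:
        return CHANNELS[self.channel]

    @property
    def ok_mask(self) -> np.ndarray:
        return self.quality == QUALITY_OK

    @property
    def usable_mask(self) -> np.ndarray:
        """Samples fit for analysis: ``ok`` or ``substituted``."""
        return np.isin(self.quality, (QUALITY_OK, QUALITY_SUBSTITUTED))

    def native_resolution(self) -> pd.Timedelta:
        """Median sampling interval (10 s for the field instruments)."""
        if len(self) < 2:
            raise ValueError("need at least two samples")
        return pd.Timedelta(np.median(np.diff(self.timestamps.asi8)), unit="ns")

    def slice(self, start, end) -> "ConcentrationSeries":
        """Samples with ``start <= t < end``."""
        m = (self.timestamps >= pd.Timestamp(start)) & (self.timestamps < pd.Timestamp(end))
        return replace(
            self,
            timestamps=self.timestamps[m],
            values=self.values[m],
            quality=self.quality[m],
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view (timestamp, channel, location, value, quality)."""
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "channel": self.channel,
                "location": self.location,
                "value": self.values,
                "quality": self.quality.astype(str),
            }
        )


@dataclass
class WindowedSeries:
    """Fixed-length window means of a concentration series.

    Windows are half-open ``[start, start + length)`` and aligned so that
    boundaries fall on whole multiples of ``length`` from midnight (hence on
    the hour for the default 30-min windows).
    """

    window_starts: pd.DatetimeIndex
    means: np.ndarray
    coverage: np.ndarray
    window_length: pd.Timedelta
    channel: str
    location: str

    def __post_init__(self) -> None:
        self.window_starts = pd.DatetimeIndex(self.window_starts)
        self.means = np.asarray(self.means, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=float)
        if not (len(self.window_starts) == len(self.means) == len(self.coverage)):
            raise ValueError("window_starts, means, coverage must share length")
        if np.any((self.coverage < 0) | (self.coverage > 1 + 1e-9)):
            raise ValueError("coverage must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.window_starts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_start": self.window_starts,
                "mean": self.means,
                "coverage": self.coverage,
                "channel": self.channel,
                "location": self.location,
            }
        )


def window_average(
    series: ConcentrationSeries,
    length: pd.Timedelta = pd.Timedelta(minutes=30),
    min_coverage: float = 0.5,
) -> WindowedSeries:
    """Average a series over half-open, midnight-aligned windows.

    Means use only usable (``ok``/``substituted``) samples.  ``coverage`` is
    the fraction of the window populated by usable samples at the series'
    native resolution; windows below ``min_coverage`` are dropped.

    Parameters
    ----------
    series : ConcentrationSeries
    length : pd.Timedelta
        Window length (30 min matches the infiltration analysis).
    min_coverage : float
        Minimum usable fraction for a window to be kept.
    """
    length = pd.Timedelta(length)
    if length <= pd.Timedelta(0):
        raise ValueError("window length must be positive")
    usable = series.usable_mask
    if not usable.any():
        return WindowedSeries(
            pd.DatetimeIndex([]), np.array([]), np.array([]),
            length, series.channel, series.location,
        )
    dt = series.native_resolution()
    ts = series.timestamps[usable]
    vals = series.values[usable]
    starts = ts.floor(length)
    df = pd.DataFrame({"start": starts, "value": vals})
    g = df.groupby("start", sort=True)["value"]
    means = g.mean()
    counts = g.size()
    expected = max(int(round(length / dt)), 1)
    coverage = (counts / expected).clip(upper=1.0)
    keep = coverage >= min_coverage
    return WindowedSeries(
        pd.DatetimeIndex(means.index[keep]),
        means.to_numpy()[keep],
        coverage.to_numpy()[keep],
        length,
        series.channel,
        series.location,
    )


def align_windows(a: WindowedSeries, b: WindowedSeries) -> pd.DataFrame:
    """Inner-join two windowed series on window start.

    Returns a frame with columns ``window_start``, ``a``, ``b``.
    """
    if a.window_length != b.window_length:
        raise ValueError("window lengths differ")
    fa = pd.Series(a.means, index=a.window_starts, name="a")
    fb = pd.Series(b.means, index=b.window_starts, name="b")
    joined = pd.concat([fa, fb], axis=1, join="inner")
    joined.index.name = "window_start"
    return joined.reset_index()
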