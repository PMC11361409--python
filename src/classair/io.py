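"""Reading, demultiplexing and cleaning instrument time series.

The field instruments log delimited text at ~10-s resolution.  Column names
differ per instrument dialect, so :func:`read_series` takes a small config
mapping.  When a solenoid valve alternated one instrument between indoor and
outdoor inlets, :func:`demux_valve` splits the mixed stream; the first two
minutes of each interval are flagged ``trimmed`` because the sampled air
column mixes across the switch.  NanoScan error gaps in the total-particle
channel are back-filled from the co-located CPC with :func:`substitute_cpc`.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .series import (
    QUALITY_ERROR,
    QUALITY_OK,
    QUALITY_SUBSTITUTED,
    QUALITY_TRIMMED,
    ConcentrationSeries,
    ValveSchedule,
)

DEFAULT_COLUMNS = {"time": "timestamp", "value": "value"}


def read_series(
    path,
    channel: str,
    location: str,
    columns: dict | None = None,
    tz: str | None = None,
    sep: str = ",",
) -> ConcentrationSeries:
    """Read one instrument channel from a delimited text file.

    Parameters
    ----------
    path : path-like
        Delimited text file with a header row.
    channel, location : str
        Channel and location labels for the resulting series.
    columns : dict, optional
        ``{"time": <timestamp column>, "value": <value column>}``; defaults
        to ``timestamp``/``value``.
    tz : str, optional
        Target timezone; naive timestamps are localised, aware ones
        converted, so mixed instrument clocks land on one axis.

    Samples that fail to parse or are negative are flagged ``error`` and
    retained (the cleaning steps may later substitute them).
    """
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - message wrapper
        raise ValueError(f"unreadable file {path}: {exc}") from exc
    for key in ("time", "value"):
        if cols[key] not in df.columns:
            raise ValueError(f"column {cols[key]!r} not found in {path}")
    ts = pd.to_datetime(df[cols["time"]], errors="coerce")
    if ts.isna().all():
        raise ValueError(f"no parsable timestamps in {path}")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna())[0])
        raise ValueError(f"unparsable timestamp at row {row} of {path}")
    if tz is not None:
        ts = ts.dt.tz_localize(tz) if ts.dt.tz is None else ts.dt.tz_convert(tz)
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        bad = int(np.flatnonzero(ts.diff().dt.total_seconds().fillna(1) <= 0)[0])
        raise ValueError(f"non-monotone timestamp at row {bad} of {path}")
    values = pd.to_numeric(df[cols["value"]], errors="coerce").to_numpy(dtype=float)
    quality = np.where(np.isfinite(values) & (values >= 0), QUALITY_OK, QUALITY_ERROR)
    if (quality == QUALITY_OK).sum() == 0:
        raise ValueError(f"no parsable rows in {path}")
    return ConcentrationSeries(
        timestamps=pd.DatetimeIndex(ts),
        values=values,
        channel=channel,
        location=location,
        quality=quality.astype(object),
    )


def write_series(series: ConcentrationSeries, path, columns: dict | None = None) -> None:
    """Write a series in the same delimited dialect :func:`read_series` expects."""
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    pd.DataFrame(
        {cols["time"]: series.timestamps, cols["value"]: series.values}
    ).to_csv(path, index=False)


def demux_valve(
    series: ConcentrationSeries, schedule: ValveSchedule | None = None
) -> tuple[ConcentrationSeries, ConcentrationSeries]:
    """Split a valve-switched ``mixed`` series into indoor and outdoor series.

    Each sample is assigned to exactly one location by its 5-min interval;
    samples within ``trim_head`` of an interval start keep their value but
    are flagged ``trimmed`` and ignored by the analysis.  The trim applies
    uniformly to every channel sampled through the valve, keeping channels
    time-aligned.

    Returns ``(indoor, outdoor)``.
    """
    if schedule is None:
        schedule = series.valve_schedule
    if schedule is None:
        raise ValueError("mixed series requires a ValveSchedule")
    if series.location != "mixed":
        raise ValueError("demux_valve expects a mixed-location series")
    cycle = 2 * schedule.period
    if len(series) == 0 or series.timestamps[-1] - series.timestamps[0] < cycle:
        raise ValueError("series shorter than one full valve cycle")

    offset_ns = (series.timestamps - schedule.phase_origin).asi8
    period_ns = schedule.period.value
    interval_idx = np.floor_divide(offset_ns, period_ns)
    within_ns = offset_ns - interval_idx * period_ns
    first_parity = 0 if schedule.first_location == "indoor" else 1
    is_indoor = (interval_idx % 2) == first_parity
    in_trim = within_ns < schedule.trim_head.value

    def build(mask: np.ndarray, location: str) -> ConcentrationSeries:
        q = series.quality[mask].copy()
        trim = in_trim[mask] & (q == QUALITY_OK)
        q[trim] = QUALITY_TRIMMED
        return ConcentrationSeries(
            timestamps=series.timestamps[mask],
            values=series.values[mask],
            channel=series.channel,
            location=location,
            quality=q,
        )

    return build(is_indoor, "indoor"), build(~is_indoor, "outdoor")


def substitute_cpc(
    nanoscan: ConcentrationSeries,
    cpc: ConcentrationSeries,
    tolerance: pd.Timedelta = pd.Timedelta(seconds=30),
) -> ConcentrationSeries:
    """Fill NanoScan total-particle error gaps with co-located CPC counts.

    For each ``error``-flagged NanoScan sample, the nearest usable CPC sample
    within ``tolerance`` supplies the value, flagged ``substituted``.  Gaps
    with no CPC coverage stay ``error``.  Applies to the total-concentration
    channel only — the CPC is not size-resolved, so the aircraft size-bin
    channel is never substituted.
    """
    if nanoscan.channel != "total_ufp":
        raise ValueError("substitution applies only to the total_ufp channel")
    if cpc.channel != "cpc_total":
        raise ValueError("substitute source must be the cpc_total channel")
    if len(cpc) and len(nanoscan):
        if (cpc.timestamps[-1] < nanoscan.timestamps[0]
                or nanoscan.timestamps[-1] < cpc.timestamps[0]):
            raise ValueError("nanoscan and cpc series do not overlap in time")
    err = nanoscan.quality == QUALITY_ERROR
    if not err.any() or not len(cpc):
        return replace(nanoscan)

    cpc_usable = cpc.usable_mask
    cpc_ts = cpc.timestamps[cpc_usable]
    cpc_vals = cpc.values[cpc_usable]
    values = nanoscan.values.copy()
    quality = nanoscan.quality.copy()
    if len(cpc_ts):
        target = pd.DataFrame({"t": nanoscan.timestamps[err]})
        source = pd.DataFrame({"t": cpc_ts, "v": cpc_vals})
        matched = pd.merge_asof(
            target, source, on="t", direction="nearest", tolerance=tolerance
        )
        hit = matched["v"].notna().to_numpy()
        idx = np.flatnonzero(err)[hit]
        values[idx] = matched["v"].to_numpy()[hit]
        quality[idx] = QUALITY_SUBSTITUTED
    return replace(nanoscan, values=values, quality=quality)


def tidy_table(series_list) -> pd.DataFrame:
    """Concatenate series into one tidy long-format table."""
    frames = [s.to_frame() for s in series_list]
    return pd.concat(frames, ignore_index=True)
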