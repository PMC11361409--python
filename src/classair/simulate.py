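"""Synthetic indoor/outdoor air-quality data with known ground truth.

The generator emulates the structure of a school monitoring session:

* an outdoor particle series built from a baseline, a sinusoidal diurnal
  traffic cycle, Poisson-arriving exponential aircraft plumes, and
  multiplicative lognormal instrument noise;
* an indoor series governed by the single-zone mass balance
  ``dC_in/dt = P*a*C_out - (a + k_dep + CADR/V) * C_in``
  with penetration ``P``, air-exchange rate ``a`` (1/h), surface deposition
  ``k_dep`` (1/h) and the portable cleaner's clean-air delivery rate CADR
  (m^3/h, zero when the unit is off);
* a dry-ice CO2 elevation-then-decay experiment for air-exchange estimation;
* straight-line synthetic flight tracks with per-flight geofence truth.

The indoor integrator holds the outdoor concentration constant within each
step and applies the exact exponential update, so the steady state is
unbiased by the step size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .series import ConcentrationSeries, QUALITY_OK
from .units import MILE_TO_M, EARTH_RADIUS_M

DEFAULT_START = pd.Timestamp("2021-06-01 00:00:00")


@dataclass(frozen=True)
class ZoneConfig:
    """Physical parameters of a single well-mixed classroom zone."""

    volume: float  # m^3
    aer: float  # outdoor air-exchange rate a, 1/h
    deposition: float = 0.0  # k_dep, 1/h
    penetration: float = 1.0  # P, dimensionless
    cadr: float = 0.0  # m^3/h when the HEPA unit runs

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if self.aer < 0 or self.deposition < 0 or self.cadr < 0:
            raise ValueError("rates must be nonnegative")
        if not 0 < self.penetration <= 1:
            raise ValueError("penetration must lie in (0, 1]")

    def loss_rate(self, cadr: float | None = None) -> float:
        """Total first-order indoor loss rate (1/h)."""
        c = self.cadr if cadr is None else cadr
        return self.aer + self.deposition + c / self.volume

    def steady_state_ratio(self, cadr: float | None = None) -> float:
        """Model-implied indoor/outdoor ratio P*a / (a + k_dep + CADR/V)."""
        loss = self.loss_rate(cadr)
        if loss == 0:
            return 1.0
        return self.penetration * self.aer / loss


@dataclass(frozen=True)
class OutdoorSourceConfig:
    """Outdoor concentration model: baseline + diurnal + plumes + noise.

    Defaults describe a school site under a busy flight path: a 5000 #/cc
    baseline (the study-area median outdoor level), a traffic diurnal cycle
    peaking mid-morning, about two aircraft plumes per hour decaying with a
    ~10-min time constant, and 15% multiplicative measurement scatter.
    """

    baseline: float = 5000.0
    diurnal_amplitude: float = 1500.0
    diurnal_peak_hour: float = 8.0
    plume_rate: float = 2.0  # events/h
    plume_peak: float = 8000.0
    plume_decay: float = 6.0  # 1/h
    noise_cv: float = 0.15
    drift_sd: float = 150.0  # additive slow instrument drift sd, same units
    drift_tau_h: float = 2.0  # drift correlation time

    def __post_init__(self) -> None:
        for name in ("baseline", "diurnal_amplitude", "plume_rate",
                     "plume_peak", "plume_decay", "noise_cv", "drift_sd",
                     "drift_tau_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.noise_cv >= 1:
            raise ValueError("noise_cv must be < 1")


@dataclass
class SimOutput:
    """A simulated indoor/outdoor session with its generating truth."""

    outdoor: ConcentrationSeries
    indoor: ConcentrationSeries
    truth: dict


def _time_grid(start, duration_h: float, dt_s: float) -> pd.DatetimeIndex:
    n = int(round(duration_h * 3600 / dt_s))
    return pd.Timestamp(start) + pd.to_timedelta(np.arange(n) * dt_s, unit="s")


def simulate_outdoor(
    config: OutdoorSourceConfig,
    duration_h: float,
    dt_s: float = 10.0,
    seed: int = 0,
    start=DEFAULT_START,
    channel: str = "total_ufp",
    return_events: bool = False,
):
    """Simulate an outdoor concentration series.

    With ``return_events=True`` also returns the plume arrival times (hours
    from start), which tests use as a counting oracle.
    """
    if duration_h <= 0 or dt_s <= 0:
        raise ValueError("duration and dt must be positive")
    rng = np.random.default_rng(seed)
    ts = _time_grid(start, duration_h, dt_s)
    t_h = np.arange(len(ts)) * dt_s / 3600.0
    hour_of_day = (ts - ts.normalize()).total_seconds().to_numpy() / 3600.0

    base = config.baseline + config.diurnal_amplitude * np.sin(
        2 * np.pi * (hour_of_day - config.diurnal_peak_hour + 6.0) / 24.0
    )
    n_events = rng.poisson(config.plume_rate * duration_h)
    event_times = np.sort(rng.uniform(0.0, duration_h, size=n_events))
    for t0 in event_times:
        m = t_h >= t0
        base[m] += config.plume_peak * np.exp(-config.plume_decay * (t_h[m] - t0))
    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        base = base * rng.lognormal(-0.5 * sigma**2, sigma, size=len(base))
    base = np.clip(base, 0.0, None)
    series = ConcentrationSeries(ts, base, channel, "outdoor",
                                 np.full(len(ts), QUALITY_OK, dtype=object))
    if return_events:
        return series, event_times
    return series


def simulate_indoor(
    outdoor: ConcentrationSeries,
    zone: ZoneConfig,
    hepa_intervals=(),
    dt_s: float | None = None,
    initial: float | None = None,
) -> ConcentrationSeries:
    """Integrate the single-zone mass balance driven by an outdoor series.

    Within each step the outdoor level is held constant and the exact
    exponential solution applied:

        C[n+1] = alpha * C[n] + (P*a/L) * (1 - alpha) * C_out[n],
        alpha = exp(-L*dt),  L = a + k_dep + CADR/V.

    ``hepa_intervals`` is a list of ``(start, end, cadr_m3h)``; outside them
    CADR is zero.  ``initial`` defaults to the steady state for the first
    step's CADR, so long simulations need no burn-in.
    """
    native = outdoor.native_resolution().total_seconds()
    if dt_s is None:
        dt_s = native
    if dt_s > native + 1e-9:
        raise ValueError("dt must not exceed the outdoor sampling interval")
    ts = outdoor.timestamps
    x = outdoor.values.astype(float)
    if dt_s < native - 1e-9:
        # refine the grid; outdoor held at its last observed value
        fine = pd.date_range(ts[0], ts[-1], freq=pd.Timedelta(seconds=dt_s))
        x = pd.Series(x, index=ts).reindex(fine, method="ffill").to_numpy()
        ts = fine

    cadr_per_step = np.zeros(len(ts))
    for s, e, cadr in hepa_intervals:
        m = (ts >= pd.Timestamp(s)) & (ts < pd.Timestamp(e))
        cadr_per_step[m] = cadr

    dt_h = dt_s / 3600.0
    if initial is None:
        initial = zone.steady_state_ratio(cadr_per_step[0]) * x[0]

    y = np.empty(len(ts))
    # piecewise-constant CADR -> run the linear recursion segment by segment
    boundaries = np.flatnonzero(np.diff(cadr_per_step) != 0) + 1
    segments = np.split(np.arange(len(ts)), boundaries)
    carry = float(initial)
    for seg in segments:
        if len(seg) == 0:
            continue
        loss = zone.loss_rate(cadr_per_step[seg[0]])  # 1/h
        alpha = np.exp(-loss * dt_h)
        if loss > 0:
            beta = zone.penetration * zone.aer / loss * (1.0 - alpha)
        else:
            beta = 0.0
        y_seg, zf = lfilter([0.0, beta], [1.0, -alpha], x[seg], zi=[carry])
        y[seg] = y_seg
        carry = float(zf[0])
    if dt_s < native - 1e-9:
        y = pd.Series(y, index=ts).reindex(outdoor.timestamps).to_numpy()
        ts = outdoor.timestamps
        if np.isnan(y).any():
            raise ValueError("refined dt must divide the outdoor sampling interval")
    quality = np.full(len(ts), QUALITY_OK, dtype=object)
    return ConcentrationSeries(ts, np.clip(y, 0.0, None), outdoor.channel,
                               "indoor", quality)


def simulate_session(
    zone: ZoneConfig,
    source: OutdoorSourceConfig | None = None,
    duration_h: float = 24.0,
    dt_s: float = 10.0,
    hepa_intervals=(),
    seed: int = 0,
    start=DEFAULT_START,
    channel: str = "total_ufp",
) -> SimOutput:
    """One monitoring session: outdoor driver plus its indoor response.

    The room responds to the *clean* outdoor signal; measurement noise is
    applied independently to the recorded indoor and outdoor channels:
    fast multiplicative scatter (``noise_cv``) plus a slow additive
    instrument drift (Ornstein-Uhlenbeck, sd ``drift_sd``, correlation time
    ``drift_tau_h``).  The drift does not shrink when the HEPA unit lowers
    the indoor signal, which is what erodes the indoor-outdoor correlation
    during the intervention.
    """
    import dataclasses

    source = source or OutdoorSourceConfig()
    clean_cfg = dataclasses.replace(source, noise_cv=0.0)
    clean_out = simulate_outdoor(clean_cfg, duration_h, dt_s, seed, start, channel)
    clean_in = simulate_indoor(clean_out, zone, hepa_intervals, dt_s)

    noise_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA1]))

    def record(series: ConcentrationSeries) -> ConcentrationSeries:
        n = len(series)
        vals = series.values.copy()
        if source.noise_cv > 0:
            sigma = np.sqrt(np.log1p(source.noise_cv**2))
            vals = vals * noise_rng.lognormal(-0.5 * sigma**2, sigma, n)
        if source.drift_sd > 0:
            phi = np.exp(-dt_s / (source.drift_tau_h * 3600.0))
            eps = noise_rng.normal(0.0, source.drift_sd * np.sqrt(1 - phi**2), n)
            x0 = noise_rng.normal(0.0, source.drift_sd)
            drift, _ = lfilter([1.0], [1.0, -phi], eps, zi=[phi * x0])
            vals = vals + drift
        vals = np.clip(vals, 0.0, None)
        return ConcentrationSeries(series.timestamps, vals, series.channel,
                                   series.location)

    outdoor = record(clean_out)
    indoor = record(clean_in)
    cadr = hepa_intervals[0][2] if hepa_intervals else 0.0
    truth = {
        "aer": zone.aer,
        "deposition": zone.deposition,
        "penetration": zone.penetration,
        "cadr": cadr,
        "steady_state_ratio": zone.steady_state_ratio(cadr),
    }
    return SimOutput(outdoor=outdoor, indoor=indoor, truth=truth)


def simulate_co2_experiment(
    zone: ZoneConfig,
    background: float = 420.0,
    peak_multiple: float = 4.5,
    noise_sd: float = 2.0,
    dt_s: float = 10.0,
    seed: int = 0,
    ramp_h: float = 0.5,
    decay_h: float = 2.0,
    monitor_bias: float = 0.02,
    start=DEFAULT_START,
):
    """Simulate a dry-ice CO2 elevation-then-decay experiment.

    CO2 is raised to ``peak_multiple`` times the ambient background, the
    source removed, and the room decays back toward background at the zone's
    air-exchange rate (a gas tracer sees no deposition and no HEPA removal).
    Two room monitors are emitted — room centre, and a wall inlet biased by
    ``monitor_bias`` relative — plus a constant-ambient outdoor series.

    Returns a :class:`classair.aer.DecayExperiment`.
    """
    from .aer import DecayExperiment  # local import avoids a cycle

    if peak_multiple < 4:
        warnings.warn(
            "protocol calls for elevating CO2 to at least 4x background",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    peak = peak_multiple * background
    pre_h = 5 / 60.0
    ts = _time_grid(start, pre_h + ramp_h + decay_h, dt_s)
    t_h = np.arange(len(ts)) * dt_s / 3600.0
    clean = np.empty(len(ts))
    m_pre = t_h < pre_h
    m_ramp = (t_h >= pre_h) & (t_h < pre_h + ramp_h)
    m_decay = t_h >= pre_h + ramp_h
    clean[m_pre] = background
    clean[m_ramp] = background + (peak - background) * (t_h[m_ramp] - pre_h) / ramp_h
    clean[m_decay] = background + (peak - background) * np.exp(
        -zone.aer * (t_h[m_decay] - pre_h - ramp_h)
    )

    def monitor(bias: float) -> ConcentrationSeries:
        noisy = clean * (1 + bias) + rng.normal(0.0, noise_sd, size=len(ts))
        return ConcentrationSeries(ts, np.clip(noisy, 0.0, None), "co2", "indoor")

    center = monitor(0.0)
    wall = monitor(monitor_bias)
    outdoor_vals = background + rng.normal(0.0, noise_sd, size=len(ts))
    outdoor = ConcentrationSeries(ts, np.clip(outdoor_vals, 0.0, None), "co2", "outdoor")
    decay_start = ts[0] + pd.Timedelta(hours=pre_h + ramp_h)
    decay_end = ts[-1]
    return DecayExperiment(
        room_monitors=[center, wall],
        outdoor=outdoor,
        decay_start=decay_start,
        decay_end=decay_end,
    )


# ---------------------------------------------------------------------------
# flight tracks


@dataclass(frozen=True)
class TrackGeometry:
    """Geometry for straight-line synthetic flight tracks.

    Tracks are constructed in a local tangent plane around the site and keep
    clear margins around the 1-mile / 750-m geofence thresholds, so the
    stored per-flight ground truth cannot flip under great-circle rounding.
    """

    n_points: int = 25
    track_length_m: float = 20_000.0
    p_near: float = 0.5  # probability a flight is made to qualify
    force_through: bool | None = None  # True/False overrides p_near

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("need at least 2 points per track")


def generate_flight_tracks(
    site: tuple[float, float],
    n_arrivals: int,
    n_departures: int,
    geometry: TrackGeometry = TrackGeometry(),
    seed: int = 0,
    airport: str = "SEA",
    start=DEFAULT_START,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate synthetic tracks with known geofence ground truth.

    Returns ``(tracks, truth)``: ``tracks`` has columns ``flight_id,
    airport, operation, time, lat, lon, alt_m``; ``truth`` has one row per
    flight with the constructed ``near_site`` boolean (any point below 750 m
    within one mile of ``site``, evaluated on the planar construction).
    """
    if n_arrivals < 0 or n_departures < 0:
        raise ValueError("counts must be nonnegative")
    rng = np.random.default_rng(seed)
    lat0, lon0 = site
    ops = ["arrival"] * n_arrivals + ["departure"] * n_departures
    rows, truth_rows = [], []
    mile = MILE_TO_M
    for i, op in enumerate(ops):
        fid = f"F{i:04d}"
        if geometry.force_through is not None:
            near = geometry.force_through
        else:
            near = rng.random() < geometry.p_near
        theta = rng.uniform(0, 2 * np.pi)  # track bearing
        if near:
            d = rng.uniform(0.10, 0.85) * mile  # closest approach
            alt_ca = rng.uniform(150.0, 650.0)
        else:
            if rng.random() < 0.5:  # laterally clear
                d = rng.uniform(1.15, 4.0) * mile
                alt_ca = rng.uniform(100.0, 2000.0)
            else:  # overhead but high
                d = rng.uniform(0.10, 0.85) * mile
                alt_ca = rng.uniform(850.0, 2000.0)
        # altitude changes slowly along-track; margins above keep truth stable
        slope = rng.uniform(0.01, 0.05) * (-1 if op == "arrival" else 1)
        s = np.linspace(-geometry.track_length_m / 2, geometry.track_length_m / 2,
                        geometry.n_points)
        ux, uy = np.cos(theta), np.sin(theta)
        px, py = -uy, ux
        x = d * px + s * ux
        y = d * py + s * uy
        inside = np.sqrt(x**2 + y**2) < mile
        alt = alt_ca + slope * s
        # clamp altitudes inside the fence to preserve the constructed truth
        if near:
            alt = np.where(inside, np.clip(alt, 100.0, 680.0), np.clip(alt, 50.0, None))
        else:
            alt = np.where(inside, np.clip(alt, 850.0, None), np.clip(alt, 50.0, None))
        qualifies = bool(np.any(inside & (alt < 750.0)))
        lat = lat0 + np.degrees(y / EARTH_RADIUS_M)
        lon = lon0 + np.degrees(x / (EARTH_RADIUS_M * np.cos(np.radians(lat0))))
        times = pd.Timestamp(start) + pd.to_timedelta(
            i * 600 + np.arange(geometry.n_points) * 10, unit="s"
        )
        for j in range(geometry.n_points):
            rows.append((fid, airport, op, times[j], lat[j], lon[j], alt[j]))
        truth_rows.append((fid, airport, op, qualifies))
    tracks = pd.DataFrame(
        rows, columns=["flight_id", "airport", "operation", "time", "lat", "lon", "alt_m"]
    )
    truth = pd.DataFrame(truth_rows, columns=["flight_id", "airport", "operation", "near_site"])
    return tracks, truth
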