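"""Outdoor air-exchange rate from a CO2 elevation-decay experiment.

With the room sealed and CO2 elevated well above ambient, the excess
concentration decays exponentially at the outdoor air-exchange rate::

    C(t) = C_bg + A0 * exp(-k * dt)

where ``C_bg`` is the ambient (outdoor) CO2 level, ``A0 = C_peak - C_bg``
the initial elevation and ``k`` (1/h) the air-exchange rate.  The model is
fitted by nonlinear least squares over the decay window with the background
held fixed at the measured ambient mean; a log-linear slope on
``ln(C - C_bg)`` is reported as a cross-check.

Protocol checks: the peak should reach at least four times background
(:func:`elevation_check`), the two room monitors should agree before being
averaged (:func:`check_uniformity`), and the series should decay to at most
one third of its initial elevation for the fit to be deemed adequate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .series import ConcentrationSeries

DEFAULT_BACKGROUND_PPM = 420.0


@dataclass
class DecayExperiment:
    """One CO2 decay experiment: room monitor(s), ambient reference, window."""

    room_monitors: list
    outdoor: ConcentrationSeries | float
    decay_start: pd.Timestamp
    decay_end: pd.Timestamp

    def __post_init__(self) -> None:
        if not self.room_monitors:
            raise ValueError("need at least one room monitor")
        self.decay_start = pd.Timestamp(self.decay_start)
        self.decay_end = pd.Timestamp(self.decay_end)
        if self.decay_start >= self.decay_end:
            raise ValueError("decay_start must precede decay_end")


def check_uniformity(
    monitors: list,
    window: pd.Timedelta = pd.Timedelta(minutes=5),
    tol: float = 0.10,
) -> tuple[bool, ConcentrationSeries]:
    """Check room monitors agree, and merge them by pointwise averaging.

    Uniform means the rolling-mean relative spread between monitors stays
    within ``tol`` throughout their overlap.  A single monitor passes
    trivially.  Returns ``(uniform, merged)``.
    """
    if len(monitors) == 1:
        return True, monitors[0]
    frames = [
        pd.Series(m.values, index=m.timestamps).where(pd.Series(m.usable_mask, index=m.timestamps))
        for m in monitors
    ]
    joined = pd.concat(frames, axis=1, join="inner").dropna()
    if joined.empty:
        raise ValueError("monitors do not overlap in time")
    dt = monitors[0].native_resolution()
    n_roll = max(int(round(window / dt)), 1)
    smooth = joined.rolling(n_roll, min_periods=1).mean()
    spread = (smooth.max(axis=1) - smooth.min(axis=1)) / smooth.mean(axis=1)
    uniform = bool((spread <= tol).all())
    merged_vals = joined.mean(axis=1)
    merged = ConcentrationSeries(
        pd.DatetimeIndex(joined.index),
        merged_vals.to_numpy(),
        monitors[0].channel,
        monitors[0].location,
    )
    return uniform, merged


def elevation_check(experiment: DecayExperiment) -> bool:
    """True iff the peak CO2 reached at least 4x the ambient background."""
    _, merged = check_uniformity(experiment.room_monitors)
    peak = float(np.max(merged.values[merged.usable_mask]))
    bg = _background(experiment)
    return peak >= 4.0 * bg


def _background(experiment: DecayExperiment) -> float:
    out = experiment.outdoor
    if out is None:
        return DEFAULT_BACKGROUND_PPM
    if isinstance(out, (int, float)):
        return float(out)
    win = out.slice(experiment.decay_start, experiment.decay_end)
    usable = win.usable_mask
    if not usable.any():
        usable = out.usable_mask
        return float(np.mean(out.values[usable]))
    return float(np.mean(win.values[usable]))


@dataclass
class CO2DecayResults:
    """Fitted air-exchange rate and diagnostics from a CO2 decay."""

    k: float  # air-exchange rate, 1/h
    k_stderr: float
    a0: float  # initial elevation C_peak - C_bg, ppm
    background: float  # ppm
    r_squared: float
    k_loglinear: float  # cross-check slope estimate, 1/h
    adequate: bool  # decayed to <= 1/3 of the initial elevation
    uniform: bool  # room monitors agreed
    n_obs: int

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return self.k - z * self.k_stderr, self.k + z * self.k_stderr

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "CO2 decay air-exchange fit",
            "--------------------------",
            f"k (air exchange rate)   {self.k:8.3f} 1/h  (95% CI {lo:.3f}-{hi:.3f})",
            f"log-linear cross-check  {self.k_loglinear:8.3f} 1/h",
            f"A0 (initial elevation)  {self.a0:8.1f} ppm",
            f"background              {self.background:8.1f} ppm",
            f"R^2                     {self.r_squared:8.4f}",
            f"n                       {self.n_obs:8d}",
            f"adequate decay (<=1/3)  {str(self.adequate):>8}",
            f"monitors uniform        {str(self.uniform):>8}",
        ]
        return "\n".join(lines)


class CO2DecayModel:
    """Exponential-decay model for a CO2 air-exchange experiment.

    Parameters
    ----------
    experiment : DecayExperiment
    uniformity_tol : float
        Relative tolerance for the monitor-agreement check.
    min_samples : int
        Minimum usable samples in the decay window.
    """

    def __init__(
        self,
        experiment: DecayExperiment,
        uniformity_tol: float = 0.10,
        min_samples: int = 10,
    ) -> None:
        self.experiment = experiment
        self.uniformity_tol = uniformity_tol
        self.min_samples = min_samples

    def fit(self) -> CO2DecayResults:
        exp_ = self.experiment
        uniform, merged = check_uniformity(exp_.room_monitors, tol=self.uniformity_tol)
        bg = _background(exp_)
        win = merged.slice(exp_.decay_start, exp_.decay_end)
        usable = win.usable_mask
        elev = win.values - bg
        keep = usable & (elev > 0)
        n_dropped = int((usable & ~keep).sum())
        if n_dropped:
            warnings.warn(
                f"excluded {n_dropped} samples at or below background", stacklevel=2
            )
        if keep.sum() < self.min_samples:
            raise ValueError(
                f"only {int(keep.sum())} usable samples above background; "
                f"need at least {self.min_samples}"
            )
        t_h = (
            (win.timestamps[keep] - exp_.decay_start).total_seconds().to_numpy() / 3600.0
        )
        c = win.values[keep]
        e = elev[keep]

        # log-linear slope: initial guess and cross-check
        slope, intercept = np.polyfit(t_h, np.log(e), 1)
        k0 = max(-slope, 1e-6)
        a0_0 = float(np.exp(intercept))

        def model(t, a0, k):
            return bg + a0 * np.exp(-k * t)

        popt, pcov = optimize.curve_fit(
            model, t_h, c, p0=[a0_0, k0], maxfev=10_000
        )
        a0_hat, k_hat = popt
        k_se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
        resid = c - model(t_h, *popt)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((c - c.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

        # adequacy: elevation must have fallen to <= 1/3 of its start
        head = e[: max(min(5, len(e) // 10), 1)].mean()
        tail = e[-max(min(5, len(e) // 10), 1):].mean()
        adequate = bool(tail <= head / 3.0)
        if not adequate:
            warnings.warn(
                "decay did not reach one-third of the initial elevation; "
                "k reported but flagged inadequate",
                stacklevel=2,
            )
        return CO2DecayResults(
            k=float(k_hat),
            k_stderr=k_se,
            a0=float(a0_hat),
            background=bg,
            r_squared=r2,
            k_loglinear=float(-slope),
            adequate=adequate,
            uniform=uniform,
            n_obs=int(keep.sum()),
        )
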