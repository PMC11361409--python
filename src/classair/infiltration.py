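"""Indoor/outdoor infiltration ratios and HEPA removal effectiveness.

Infiltration is the ratio of indoor to outdoor concentration computed on
aligned 30-min window means, assuming the indoor pollutant is of outdoor
origin.  HEPA removal effectiveness compares the infiltration measured with
the cleaner running against the no-cleaner baseline::

    effectiveness = 1 - infiltration_HEPA / infiltration_noHEPA

Inference is nonparametric: bootstrap CIs over windows, a one-sided
Wilcoxon rank-sum test for the before-vs-after contrast, and Pearson
correlation of aligned indoor/outdoor windows as a coupling diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .series import ConcentrationSeries, WindowedSeries, align_windows

#: Windows whose outdoor mean falls below this are excluded (near-zero
#: denominators): number concentrations in #/cc, BC in ug/m3.
DEFAULT_OUTDOOR_FLOOR = {"total_ufp": 50.0, "aircraft_ufp": 50.0,
                         "cpc_total": 50.0, "bc": 0.05, "co2": 50.0}


@dataclass
class InfiltrationResults:
    """Windowed infiltration estimate for one channel and HEPA state."""

    channel: str
    hepa_state: str  # "off" | "on"
    window_ratios: np.ndarray
    point: float  # mean of window ratios (primary aggregate)
    median: float
    ci_low: float
    ci_high: float
    n_windows: int

    def summary(self) -> str:
        return (
            f"Infiltration [{self.channel}, HEPA {self.hepa_state}]: "
            f"{self.point:.3f} (95% CI {self.ci_low:.3f}-{self.ci_high:.3f}, "
            f"median {self.median:.3f}, n={self.n_windows} windows)"
        )


@dataclass
class EffectivenessResult:
    """Fractional reduction in infiltration attributable to the HEPA unit."""

    channel: str
    effectiveness: float
    ci_low: float
    ci_high: float
    method: str  # "ratio" | "regression"

    @property
    def percent(self) -> float:
        """Effectiveness on the percentage scale (e.g. 83.3)."""
        return 100.0 * self.effectiveness

    def summary(self) -> str:
        return (
            f"HEPA removal effectiveness [{self.channel}, {self.method}]: "
            f"{self.percent:.0f}% (95% CI {100*self.ci_low:.0f}-{100*self.ci_high:.0f}%)"
        )


class InfiltrationModel:
    """Windowed indoor/outdoor ratio estimator.

    Parameters
    ----------
    indoor, outdoor : WindowedSeries
        Time-aligned window means for the same channel.
    hepa_state : str
        "off" or "on".
    outdoor_floor : float, optional
        Minimum outdoor window mean; defaults per channel.
    min_windows : int
        Fewer aligned usable windows than this is an error.
    """

    def __init__(
        self,
        indoor: WindowedSeries,
        outdoor: WindowedSeries,
        hepa_state: str,
        outdoor_floor: float | None = None,
        min_windows: int = 4,
    ) -> None:
        if indoor.channel != outdoor.channel:
            raise ValueError("indoor and outdoor channels differ")
        if hepa_state not in ("off", "on"):
            raise ValueError("hepa_state must be 'off' or 'on'")
        self.indoor = indoor
        self.outdoor = outdoor
        self.hepa_state = hepa_state
        self.outdoor_floor = (
            outdoor_floor
            if outdoor_floor is not None
            else DEFAULT_OUTDOOR_FLOOR.get(indoor.channel, 0.0)
        )
        self.min_windows = min_windows

    def window_ratios(self) -> np.ndarray:
        aligned = align_windows(self.indoor, self.outdoor)
        keep = aligned["b"] > self.outdoor_floor
        aligned = aligned[keep]
        if len(aligned) < self.min_windows:
            raise ValueError(
                f"only {len(aligned)} usable aligned windows; "
                f"need at least {self.min_windows}"
            )
        return (aligned["a"] / aligned["b"]).to_numpy()

    def fit(self, n_boot: int = 2000, seed: int = 0) -> InfiltrationResults:
        ratios = self.window_ratios()
        rng = np.random.default_rng(seed)
        boot = rng.choice(ratios, size=(n_boot, len(ratios)), replace=True).mean(axis=1)
        lo, hi = np.percentile(boot, [2.5, 97.5])
        return InfiltrationResults(
            channel=self.indoor.channel,
            hepa_state=self.hepa_state,
            window_ratios=ratios,
            point=float(ratios.mean()),
            median=float(np.median(ratios)),
            ci_low=float(lo),
            ci_high=float(hi),
            n_windows=len(ratios),
        )


def compute_infiltration(
    indoor: WindowedSeries,
    outdoor: WindowedSeries,
    hepa_state: str,
    **fit_kwargs,
) -> InfiltrationResults:
    """Convenience wrapper: build an :class:`InfiltrationModel` and fit it."""
    return InfiltrationModel(indoor, outdoor, hepa_state).fit(**fit_kwargs)


def removal_effectiveness(infiltration_off: float, infiltration_on: float) -> float:
    """Point effectiveness 1 - I_on/I_off (may be negative)."""
    if infiltration_off == 0:
        raise ValueError("effectiveness undefined when baseline infiltration is 0")
    return 1.0 - infiltration_on / infiltration_off


def compute_effectiveness(
    before: InfiltrationResults,
    after: InfiltrationResults,
    n_boot: int = 2000,
    seed: int = 0,
) -> EffectivenessResult:
    """HEPA removal effectiveness from before/after infiltration estimates.

    The CI resamples the two sets of window ratios jointly (one resample of
    each per bootstrap replicate) and takes percentile bounds.
    """
    if before.hepa_state != "off" or after.hepa_state != "on":
        raise ValueError("expected before.hepa_state='off' and after.hepa_state='on'")
    if before.channel != after.channel:
        raise ValueError("channels differ between before and after")
    eff = removal_effectiveness(before.point, after.point)
    rng = np.random.default_rng(seed)
    b = rng.choice(before.window_ratios,
                   size=(n_boot, len(before.window_ratios)), replace=True).mean(axis=1)
    a = rng.choice(after.window_ratios,
                   size=(n_boot, len(after.window_ratios)), replace=True).mean(axis=1)
    boot = 1.0 - a / b
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return EffectivenessResult(
        channel=before.channel,
        effectiveness=float(eff),
        ci_low=float(lo),
        ci_high=float(hi),
        method="ratio",
    )


def wilcoxon_compare(
    before_ratios,
    after_ratios,
    alternative: str = "greater",
) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum test: before stochastically greater.

    Uses the exact null distribution for combined n <= 20 (no ties),
    otherwise the tie-corrected normal approximation.
    """
    before = np.asarray(before_ratios, dtype=float)
    after = np.asarray(after_ratios, dtype=float)
    if len(before) < 4 or len(after) < 4:
        raise ValueError("need at least 4 values per group")
    pooled = np.concatenate([before, after])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across groups; p = 1", stacklevel=2)
        return 0.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(before, after, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def io_correlation(indoor: WindowedSeries, outdoor: WindowedSeries) -> float:
    """Pearson r between aligned indoor and outdoor window means.

    Returns NaN (with a warning) when either input has zero variance.
    """
    aligned = align_windows(indoor, outdoor)
    if len(aligned) < 4:
        raise ValueError("need at least 4 aligned windows")
    a = aligned["a"].to_numpy()
    b = aligned["b"].to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("zero variance; correlation undefined", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def lag_persistence(
    indoor: ConcentrationSeries,
    outdoor: ConcentrationSeries,
    hepa_off_time,
    horizon: pd.Timedelta = pd.Timedelta(minutes=120),
    window: pd.Timedelta = pd.Timedelta(minutes=30),
    step: pd.Timedelta = pd.Timedelta(minutes=5),
) -> pd.DataFrame:
    """Rolling indoor-outdoor correlation after the HEPA unit switches off.

    Tracks how quickly the indoor signal re-couples to the outdoor driver.
    Returns a frame of (elapsed_min, r, n_samples, truncated).
    """
    t0 = pd.Timestamp(hepa_off_time)
    end = min(indoor.timestamps[-1], outdoor.timestamps[-1])
    truncated = end < t0 + horizon
    if truncated:
        warnings.warn("series end before the requested horizon; table truncated",
                      stacklevel=2)
    rows = []
    elapsed = pd.Timedelta(0)
    while elapsed + window <= horizon:
        ws, we = t0 + elapsed, t0 + elapsed + window
        if we > end + indoor.native_resolution():
            break
        si = indoor.slice(ws, we)
        so = outdoor.slice(ws, we)
        fi = pd.Series(si.values[si.usable_mask], index=si.timestamps[si.usable_mask])
        fo = pd.Series(so.values[so.usable_mask], index=so.timestamps[so.usable_mask])
        joined = pd.concat([fi, fo], axis=1, join="inner").dropna()
        if len(joined) >= 4 and joined.iloc[:, 0].std() > 0 and joined.iloc[:, 1].std() > 0:
            r = float(stats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1]).statistic)
        else:
            r = float("nan")
        rows.append((elapsed.total_seconds() / 60.0, r, len(joined), truncated))
        elapsed += step
    return pd.DataFrame(rows, columns=["elapsed_min", "r", "n_samples", "truncated"])
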