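"""Lagged log-log regression of indoor on outdoor concentration.

The model regresses the natural log of the indoor 30-min window mean on the
log of the outdoor mean from the window 30 min earlier (outdoor peaks lead
indoor peaks by roughly one window), a HEPA on/off indicator, and a
school-specific intercept::

    log(C_indoor) ~ log(C_outdoor, lagged) + HEPA + School

``exp(beta_HEPA)`` is the multiplicative indoor reduction while the cleaner
runs, so the regression-based removal effectiveness is
``1 - exp(beta_HEPA)``.  Fitted with OLS (school as categorical fixed
effects); predictions at a fixed outdoor level propagate the coefficient
covariance through the linear predictor and exponentiate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .infiltration import EffectivenessResult
from .series import SessionMetadata, WindowedSeries, align_windows


@dataclass
class RegressionDesign:
    """Row data for the log-log model.

    ``frame`` columns: log_indoor, log_outdoor_lagged, hepa (0/1),
    school (str).  Rows with a nonpositive indoor or outdoor mean are
    dropped before the log transform and counted in ``dropped_zero_rows``.
    """

    frame: pd.DataFrame
    dropped_zero_rows: int = 0
    flagged_schools: tuple = ()

    def __post_init__(self) -> None:
        required = {"log_indoor", "log_outdoor_lagged", "hepa", "school"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"design frame missing columns {sorted(missing)}")
        vals = self.frame[["log_indoor", "log_outdoor_lagged"]].to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("design contains non-finite values")

    def __len__(self) -> int:
        return len(self.frame)

    @staticmethod
    def concat(designs: list["RegressionDesign"]) -> "RegressionDesign":
        return RegressionDesign(
            frame=pd.concat([d.frame for d in designs], ignore_index=True),
            dropped_zero_rows=sum(d.dropped_zero_rows for d in designs),
            flagged_schools=tuple(
                s for d in designs for s in d.flagged_schools
            ),
        )


def build_design(
    indoor: WindowedSeries,
    outdoor: WindowedSeries,
    hepa_intervals,
    school: str,
    lag: pd.Timedelta = pd.Timedelta(minutes=30),
    drop_flag_fraction: float = 0.20,
) -> RegressionDesign:
    """Pair indoor windows with lagged outdoor windows into model rows.

    ``hepa_intervals`` is a list of ``(start, end, cadr)``; a window is
    HEPA-on when its start falls inside an interval with positive CADR.
    A session where more than ``drop_flag_fraction`` of candidate rows drop
    for zero/negative means is flagged (such rooms can also be excluded
    wholesale by the caller).
    """
    lag = pd.Timedelta(lag)
    if lag % indoor.window_length != pd.Timedelta(0):
        raise ValueError("lag must be a multiple of the window length")
    fi = pd.Series(indoor.means, index=indoor.window_starts, name="indoor")
    fo = pd.Series(outdoor.means, index=outdoor.window_starts + lag, name="outdoor")
    joined = pd.concat([fi, fo], axis=1, join="inner").dropna()
    if joined.empty:
        raise ValueError("no alignable indoor/outdoor window pairs at this lag")
    positive = (joined["indoor"] > 0) & (joined["outdoor"] > 0)
    dropped = int((~positive).sum())
    kept = joined[positive]
    if kept.empty:
        raise ValueError(
            f"all {len(joined)} rows dropped: nonpositive indoor or outdoor means "
            f"(school {school})"
        )
    meta = SessionMetadata(school_id=school, visit=1, room_volume_m3=1.0,
                           hepa_intervals=tuple(hepa_intervals))
    hepa = np.array([int(meta.hepa_state_at(t)) for t in kept.index])
    frame = pd.DataFrame(
        {
            "log_indoor": np.log(kept["indoor"].to_numpy()),
            "log_outdoor_lagged": np.log(kept["outdoor"].to_numpy()),
            "hepa": hepa,
            "school": school,
        }
    )
    flagged = ()
    if dropped > drop_flag_fraction * len(joined):
        flagged = (school,)
        warnings.warn(
            f"school {school}: {dropped}/{len(joined)} rows dropped for "
            "nonpositive means",
            stacklevel=2,
        )
    return RegressionDesign(frame=frame, dropped_zero_rows=dropped,
                            flagged_schools=flagged)


@dataclass
class HepaLogLogResults:
    """Coefficients and covariance of the fitted log-log model."""

    params: pd.Series
    cov: pd.DataFrame
    bse: pd.Series
    n_obs: int
    dropped_zero_rows: int
    schools: tuple
    reference_school: str
    channel: str = "total_ufp"
    _sm_results: object = field(default=None, repr=False)

    @property
    def beta_outdoor(self) -> float:
        return float(self.params["log_outdoor_lagged"])

    @property
    def beta_hepa(self) -> float:
        return float(self.params["hepa"])

    @property
    def school_effects(self) -> pd.Series:
        """Per-school intercepts (reference school's effect is 0)."""
        effects = {self.reference_school: 0.0}
        for s in self.schools:
            key = f"C(school)[T.{s}]"
            if key in self.params.index:
                effects[s] = float(self.params[key])
        return pd.Series(effects).sort_index()

    def _linear_predictor_row(self, outdoor_level: float, school: str, hepa: int) -> np.ndarray:
        if school not in self.schools:
            raise ValueError(f"unknown school {school!r}")
        row = pd.Series(0.0, index=self.params.index)
        row["Intercept"] = 1.0
        row["log_outdoor_lagged"] = np.log(outdoor_level)
        row["hepa"] = float(hepa)
        key = f"C(school)[T.{school}]"
        if key in row.index:
            row[key] = 1.0
        return row.to_numpy()

    def predict_indoor(
        self,
        outdoor_level: float = 5000.0,
        school: str | None = None,
        hepa: int = 0,
        alpha: float = 0.05,
    ) -> tuple[float, float, float]:
        """Predict the indoor concentration at a fixed outdoor level.

        Returns ``(point, ci_low, ci_high)`` on the concentration scale.
        The CI propagates the coefficient covariance through the linear
        predictor (normal interval on the log scale, then exponentiated).
        """
        if outdoor_level <= 0:
            raise ValueError("outdoor_level must be positive")
        if school is None:
            school = self.reference_school
        x = self._linear_predictor_row(outdoor_level, school, hepa)
        eta = float(x @ self.params.to_numpy())
        se = float(np.sqrt(x @ self.cov.to_numpy() @ x))
        z = stats.norm.ppf(1 - alpha / 2)
        return float(np.exp(eta)), float(np.exp(eta - z * se)), float(np.exp(eta + z * se))

    def effectiveness(self, alpha: float = 0.05) -> EffectivenessResult:
        """Regression-based removal effectiveness 1 - exp(beta_HEPA).

        The CI transforms a normal interval for beta_HEPA through the
        monotone map ``b -> 1 - exp(b)``.
        """
        b = self.beta_hepa
        se = float(self.bse["hepa"])
        z = stats.norm.ppf(1 - alpha / 2)
        return EffectivenessResult(
            channel=self.channel,
            effectiveness=float(1.0 - np.exp(b)),
            ci_low=float(1.0 - np.exp(b + z * se)),
            ci_high=float(1.0 - np.exp(b - z * se)),
            method="regression",
        )

    def summary(self):
        if self._sm_results is not None:
            return self._sm_results.summary()
        return repr(self.params)


class HepaLogLogModel:
    """OLS log-log model of indoor on lagged outdoor concentration.

    Build from a :class:`RegressionDesign` (or several, via
    :meth:`from_designs`) and call :meth:`fit`.
    """

    MIN_EXTRA_ROWS = 5

    def __init__(self, design: RegressionDesign, channel: str = "total_ufp") -> None:
        self.design = design
        self.channel = channel

    @classmethod
    def from_designs(cls, designs: list, channel: str = "total_ufp") -> "HepaLogLogModel":
        return cls(RegressionDesign.concat(list(designs)), channel=channel)

    def fit(self) -> HepaLogLogResults:
        df = self.design.frame.copy()
        schools = tuple(sorted(df["school"].unique()))
        if df["hepa"].nunique() < 2:
            raise ValueError("hepa indicator is constant; beta_hepa inestimable")
        formula = "log_indoor ~ log_outdoor_lagged + hepa"
        if len(schools) > 1:
            formula += " + C(school)"
        import statsmodels.formula.api as smf

        model = smf.ols(formula, data=df)
        n_params = model.exog.shape[1]
        if len(df) < n_params + self.MIN_EXTRA_ROWS:
            raise ValueError(
                f"need at least {n_params + self.MIN_EXTRA_ROWS} rows, have {len(df)}"
            )
        rank = np.linalg.matrix_rank(model.exog)
        if rank < n_params:
            raise ValueError("rank-deficient design: collinear terms among "
                             f"{list(model.exog_names)}")
        res = model.fit()
        missing_states = [
            s for s in schools
            if df.loc[df["school"] == s, "hepa"].nunique() < 2
        ]
        if missing_states:
            warnings.warn(
                f"schools without both HEPA states: {missing_states}", stacklevel=2
            )
        return HepaLogLogResults(
            params=res.params,
            cov=pd.DataFrame(res.cov_params(), index=res.params.index,
                             columns=res.params.index),
            bse=res.bse,
            n_obs=int(res.nobs),
            dropped_zero_rows=self.design.dropped_zero_rows,
            schools=schools,
            reference_school=schools[0],
            channel=self.channel,
            _sm_results=res,
        )


def fit_loglog(design: RegressionDesign, channel: str = "total_ufp") -> HepaLogLogResults:
    """Convenience wrapper: ``HepaLogLogModel(design).fit()``."""
    return HepaLogLogModel(design, channel=channel).fit()


def regression_effectiveness(fit: HepaLogLogResults) -> EffectivenessResult:
    """Removal effectiveness from the fitted HEPA coefficient."""
    return fit.effectiveness()
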