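"""Build per-subject monthly airborne-lead exposures from monitor data.

Annual address-level exposure estimates (e.g. from a land-use model) carry the
spatial signal but no within-year temporal variation.  A central EPA monitor
carries the temporal signal.  This module combines the two: monthly scaling
factors (calendar-month mean of the monitor series divided by a multi-year
baseline mean) multiply the residence-time-weighted annual estimate for the
matching year of life, yielding 144 monthly exposure estimates per subject
from birth to the 12th birthday.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("leadlag.exposure")

#: number of monthly lags from birth to the 12th birthday
N_LAGS_DEFAULT = 144


def _ym(ts: pd.Timestamp) -> int:
    """Serial calendar-month index (year*12 + month-1)."""
    return ts.year * 12 + ts.month - 1


# ---------------------------------------------------------------------------
# Monitor series
# ---------------------------------------------------------------------------

@dataclass
class MonitorSeries:
    """Dated airborne-lead concentrations (ng/m3) from one monitor.

    Dates must be strictly increasing and concentrations non-negative.
    """

    observations: pd.DataFrame  # columns: date (datetime64), concentration
    monitor_id: str = ""

    def __post_init__(self) -> None:
        obs = self.observations
        if not {"date", "concentration"} <= set(obs.columns):
            raise ValueError("observations need 'date' and 'concentration' columns")
        obs = obs.copy()
        obs["date"] = pd.to_datetime(obs["date"])
        if len(obs) and not obs["date"].is_monotonic_increasing:
            raise ValueError("monitor dates must be increasing")
        if len(obs) and obs["date"].duplicated().any():
            raise ValueError("monitor dates must be strictly increasing (duplicates found)")
        if len(obs) and (obs["concentration"] < 0).any():
            raise ValueError("monitor concentrations must be non-negative")
        self.observations = obs.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.observations)

    @classmethod
    def from_csv(cls, path, monitor_id: str = "") -> "MonitorSeries":
        df = pd.read_csv(path, parse_dates=["date"]).sort_values("date")
        return cls(df[["date", "concentration"]], monitor_id=monitor_id)

    def to_csv(self, path) -> None:
        self.observations.to_csv(path, index=False, date_format="%Y-%m-%d",
                                 float_format="%.12g")


def merge_monitor_series(primary: MonitorSeries, secondary: MonitorSeries,
                         cutoff_date) -> MonitorSeries:
    """Substitute a nearby monitor before ``cutoff_date``.

    Observations strictly before the cutoff come from ``secondary``, those on
    or after the cutoff from ``primary`` (primary wins on overlapping dates).
    """
    cutoff = pd.Timestamp(cutoff_date)
    before = secondary.observations[secondary.observations["date"] < cutoff]
    after = primary.observations[primary.observations["date"] >= cutoff]
    merged = pd.concat([before, after], ignore_index=True).sort_values("date")
    if merged.empty:
        raise ValueError(
            f"merged series empty: no secondary data before {cutoff.date()} "
            f"and no primary data on/after it"
        )
    mid = f"{primary.monitor_id}|{secondary.monitor_id}<{cutoff.date()}"
    return MonitorSeries(merged.reset_index(drop=True), monitor_id=mid)


# ---------------------------------------------------------------------------
# Scaling factors
# ---------------------------------------------------------------------------

@dataclass
class ScalingFactorTable:
    """Per-calendar-month temporal adjustment ratios.

    ``factors`` maps (year, month) to the ratio of that calendar month's mean
    monitor concentration to the baseline-period mean.  Ratios are
    dimensionless and non-negative.
    """

    factors: dict  # (year, month) -> float
    baseline_mean: float
    baseline_window: tuple  # (start Timestamp, end Timestamp)
    interpolated_months: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.baseline_mean > 0:
            raise ValueError("baseline mean must be positive")
        if any(v < 0 for v in self.factors.values()):
            raise ValueError("scaling factors must be non-negative")
        # dense array keyed by serial month index, NaN outside coverage
        keys = sorted(self.factors)
        self._ym0 = keys[0][0] * 12 + keys[0][1] - 1
        ymax = keys[-1][0] * 12 + keys[-1][1] - 1
        arr = np.full(ymax - self._ym0 + 1, np.nan)
        for (y, m), v in self.factors.items():
            arr[y * 12 + m - 1 - self._ym0] = v
        self._arr = arr

    def factor(self, year: int, month: int) -> float:
        """Factor for a calendar month; NaN if outside coverage."""
        i = year * 12 + month - 1 - self._ym0
        if i < 0 or i >= len(self._arr):
            return float("nan")
        return float(self._arr[i])

    def factor_by_index(self, ym: np.ndarray) -> np.ndarray:
        """Vectorized lookup by serial month index year*12+month-1."""
        i = np.asarray(ym) - self._ym0
        out = np.full(i.shape, np.nan)
        ok = (i >= 0) & (i < len(self._arr))
        out[ok] = self._arr[i[ok]]
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [(y, m, v) for (y, m), v in sorted(self.factors.items())]
        return pd.DataFrame(rows, columns=["year", "month", "factor"])


def compute_scaling_factors(series: MonitorSeries, baseline_window,
                            baseline_method: str = "raw",
                            gap_policy: str = "interpolate") -> ScalingFactorTable:
    """Monthly means divided by the baseline-period mean.

    Parameters
    ----------
    baseline_window : (start, end)
        Inclusive date window defining the denominator, e.g.
        ("2001-01-01", "2005-12-31").
    baseline_method : "raw" | "monthly-means"
        Denominator is the mean of all raw observations in the window
        (default) or the mean of the window's monthly means.
    gap_policy : "interpolate" | "strict"
        Calendar months inside the series span with no observation are filled
        by linear interpolation of adjacent monthly means (logged), or raise.
    """
    obs = series.observations
    if obs.empty:
        raise ValueError("empty monitor series")
    start, end = (pd.Timestamp(baseline_window[0]), pd.Timestamp(baseline_window[1]))
    in_base = obs[(obs["date"] >= start) & (obs["date"] <= end)]
    if in_base.empty:
        raise ValueError("baseline window contains no observations")

    ymi = obs["date"].dt.year * 12 + obs["date"].dt.month - 1
    monthly = obs.groupby(ymi)["concentration"].mean()
    full_idx = np.arange(ymi.min(), ymi.max() + 1)
    monthly = monthly.reindex(full_idx)

    missing = monthly.index[monthly.isna()]
    interpolated = []
    if len(missing):
        names = [f"{i // 12:04d}-{i % 12 + 1:02d}" for i in missing]
        if gap_policy == "strict":
            raise ValueError(f"no monitor observations for month(s): {', '.join(names)}")
        monthly = monthly.interpolate(method="linear", limit_direction="both")
        interpolated = names
        logger.warning("interpolated monthly means for %d month(s): %s",
                       len(names), ", ".join(names))

    if baseline_method == "raw":
        base_mean = float(in_base["concentration"].mean())
    elif baseline_method == "monthly-means":
        bymi = in_base["date"].dt.year * 12 + in_base["date"].dt.month - 1
        base_mean = float(in_base.groupby(bymi)["concentration"].mean().mean())
    else:
        raise ValueError(f"unknown baseline_method {baseline_method!r}")
    if base_mean == 0:
        raise ValueError("baseline mean is zero; cannot form scaling factors")

    factors = {(int(i) // 12, int(i) % 12 + 1): float(v / base_mean)
               for i, v in monthly.items()}
    return ScalingFactorTable(factors, base_mean, (start, end),
                              interpolated_months=interpolated)


# ---------------------------------------------------------------------------
# Residence histories
# ---------------------------------------------------------------------------

@dataclass
class ResidenceHistory:
    """One subject's address intervals with annual exposure estimates.

    Intervals are (start_date, end_date, annual_estimate) with end exclusive;
    they must not overlap.  Gaps are permitted but produce missing annual
    estimates for uncovered years.
    """

    subject_id: str
    birth_date: pd.Timestamp
    intervals: list  # [(start: Timestamp, end: Timestamp, estimate: float)]

    def __post_init__(self) -> None:
        self.birth_date = pd.Timestamp(self.birth_date)
        iv = sorted(
            [(pd.Timestamp(s), pd.Timestamp(e), float(v)) for s, e, v in self.intervals]
        )
        for (s1, e1, _), (s2, _, _) in zip(iv, iv[1:]):
            if s2 < e1:
                raise ValueError(
                    f"subject {self.subject_id}: overlapping residence intervals "
                    f"at {s2.date()}"
                )
        for s, e, _ in iv:
            if e <= s:
                raise ValueError(f"subject {self.subject_id}: empty interval {s.date()}")
        self.intervals = iv


def annual_residence_estimate(history: ResidenceHistory, year_of_life: int) -> float:
    """Duration-weighted annual estimate for one year of life (1..12).

    Year ``y`` spans the interval [birth + (y-1) years, birth + y years);
    each residence overlapping it contributes its annual estimate weighted by
    actual calendar days of overlap.  Returns NaN (logged) if the year is
    entirely uncovered.
    """
    if not 1 <= year_of_life <= 12:
        raise ValueError("year_of_life must be in 1..12")
    b = history.birth_date
    ys = b + pd.DateOffset(years=year_of_life - 1)
    ye = b + pd.DateOffset(years=year_of_life)
    wsum = 0.0
    vsum = 0.0
    for s, e, v in history.intervals:
        days = (min(e, ye) - max(s, ys)).days
        if days > 0:
            wsum += days
            vsum += days * v
    if wsum == 0:
        logger.warning("subject %s: year of life %d has no residence coverage",
                       history.subject_id, year_of_life)
        return float("nan")
    span = (ye - ys).days
    if wsum < span:
        logger.warning("subject %s: year of life %d only %d/%d days covered",
                       history.subject_id, year_of_life, int(wsum), span)
    return vsum / wsum


def residences_from_csv(path) -> list:
    """Read residence histories from long CSV
    (subject_id, birth_date, start_date, end_date, annual_estimate)."""
    df = pd.read_csv(path, parse_dates=["birth_date", "start_date", "end_date"])
    out = []
    for sid, grp in df.groupby("subject_id", sort=True):
        out.append(ResidenceHistory(
            subject_id=str(sid),
            birth_date=grp["birth_date"].iloc[0],
            intervals=list(zip(grp["start_date"], grp["end_date"],
                               grp["annual_estimate"])),
        ))
    return out


def residences_to_csv(histories, path) -> None:
    rows = []
    for h in histories:
        for s, e, v in h.intervals:
            rows.append((h.subject_id, h.birth_date.date(), s.date(), e.date(), v))
    pd.DataFrame(rows, columns=["subject_id", "birth_date", "start_date",
                                "end_date", "annual_estimate"]
                 ).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Monthly exposure matrix
# ---------------------------------------------------------------------------

@dataclass
class MonthlyExposureMatrix:
    """n_subjects x 144 exposures (ng/m3); column j = month of life j.

    Month 1 is the birth month.  Missing cells are NaN, never silently zero;
    ``missing`` lists (subject_id, month_of_life, reason).
    """

    subjects: list
    values: np.ndarray
    missing: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.subjects):
            raise ValueError("values must be (n_subjects, n_lags)")
        with np.errstate(invalid="ignore"):
            if (self.values < 0).any():
                raise ValueError("exposures must be non-negative")

    @property
    def n_lags(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long format: subject_id, month_of_life, exposure."""
        n, L = self.values.shape
        return pd.DataFrame({
            "subject_id": np.repeat(self.subjects, L),
            "month_of_life": np.tile(np.arange(1, L + 1), n),
            "exposure": self.values.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "MonthlyExposureMatrix":
        df = pd.read_csv(path)
        wide = df.pivot(index="subject_id", columns="month_of_life",
                        values="exposure").sort_index()
        return cls(subjects=[str(s) for s in wide.index],
                   values=wide.to_numpy())


def build_monthly_exposures(histories, factors: ScalingFactorTable,
                            n_lags: int = N_LAGS_DEFAULT) -> MonthlyExposureMatrix:
    """x_ij = annual estimate for year ceil(j/12) x factor for the calendar
    month containing ``birth + (j-1) months``.

    Months of life run anniversary-to-anniversary and are attributed to the
    calendar month in which they begin.  A missing factor or missing annual
    estimate marks the cell NaN and is logged with subject and month.
    """
    n = len(histories)
    X = np.full((n, n_lags), np.nan)
    missing = []
    j = np.arange(n_lags)  # month_of_life - 1
    years = j // 12 + 1
    for i, h in enumerate(histories):
        ann = np.array([annual_residence_estimate(h, int(y))
                        for y in range(1, n_lags // 12 + 1)])
        ym = _ym(h.birth_date) + j  # month arithmetic: birth month + (j-1)
        f = factors.factor_by_index(ym)
        est = ann[years - 1]
        X[i] = est * f
        bad_f = np.isnan(f)
        bad_e = np.isnan(est) & ~bad_f
        for jj in np.flatnonzero(bad_f):
            missing.append((h.subject_id, int(jj) + 1, "missing scaling factor"))
        for jj in np.flatnonzero(bad_e):
            missing.append((h.subject_id, int(jj) + 1, "missing annual estimate"))
    if missing:
        logger.warning("monthly exposure matrix has %d missing cells over %d subjects",
                       len(missing), len({m[0] for m in missing}))
    return MonthlyExposureMatrix(subjects=[h.subject_id for h in histories],
                                 values=X, missing=missing)
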