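"""Synthetic study cohort with a known true lag-response curve.

The generator emulates the structure of a birth-cohort air-lead study: an
irregular (3-6 day) seasonal monitor series with a multi-year baseline,
per-subject residence histories carrying log-normal annual address-level
exposure estimates with AR(1) year-to-year correlation and 0-2 address
moves, confounding covariates, behavioral t-scores generated from the exact
linear distributed-lag equation

    y_i = alpha + sum_j beta_j x_ij + c_i' gamma + N(0, noise_sd),

and BASC-style validity indices.  Monthly exposures x_ij are produced by
routing the synthetic monitor series and residence histories through the
same scaling-factor machinery the analysis uses (`leadlag.exposure`), never
by a separate code path, so the generating equation and the fitted model
share one exposure definition.  The truth (curve, covariate coefficients,
intercept, realized covariate design) is carried alongside the data for
recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exposure import (MonitorSeries, MonthlyExposureMatrix, ResidenceHistory,
                       build_monthly_exposures, compute_scaling_factors,
                       residences_to_csv)

#: ages (years) of the six follow-up visits contributing covariate averages
VISIT_AGES = (1, 2, 3, 4, 7, 12)

_EDU_LEVELS = ("high school or less", "some college", "college or graduate school")
_EDU_PROBS = (0.19, 0.29, 0.52)


# ---------------------------------------------------------------------------
# True lag-response curves
# ---------------------------------------------------------------------------

@dataclass
class TrueLagCurve:
    """Effect (score points per 1 ng/m3) at each of L monthly lags."""

    values: np.ndarray
    shape_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.shape_name == "null" and np.any(self.values != 0):
            raise ValueError("null curve must be identically zero")

    @property
    def n_lags(self) -> int:
        return len(self.values)

    @classmethod
    def bump(cls, n_lags: int = 144, peak: float = 1.0, center: float = 60.0,
             width: float = 12.0) -> "TrueLagCurve":
        """Gaussian bump: a single sensitive window of ~4 sd months."""
        j = np.arange(1, n_lags + 1)
        return cls(peak * np.exp(-0.5 * ((j - center) / width) ** 2), "bump")

    @classmethod
    def step(cls, n_lags: int = 144, height: float = 1.0, start: int = 49,
             end: int = 72) -> "TrueLagCurve":
        j = np.arange(1, n_lags + 1)
        return cls(np.where((j >= start) & (j <= end), height, 0.0), "step")

    @classmethod
    def linear_decay(cls, n_lags: int = 144, start_value: float = 1.0
                     ) -> "TrueLagCurve":
        j = np.arange(1, n_lags + 1)
        return cls(start_value * (n_lags - j) / (n_lags - 1), "linear-decay")

    @classmethod
    def null(cls, n_lags: int = 144) -> "TrueLagCurve":
        return cls(np.zeros(n_lags), "null")

    @classmethod
    def wiggle(cls, n_lags: int = 144, amplitude: float = 1.0,
               period: float = 6.0) -> "TrueLagCurve":
        """High-frequency oscillation, adversarial for the smoothness prior."""
        j = np.arange(1, n_lags + 1)
        return cls(amplitude * np.sin(2 * np.pi * j / period), "wiggle")

    @classmethod
    def from_shape(cls, shape_name: str, n_lags: int = 144, **kw) -> "TrueLagCurve":
        factory = {"bump": cls.bump, "step": cls.step, "null": cls.null,
                   "linear-decay": cls.linear_decay, "wiggle": cls.wiggle}
        if shape_name not in factory:
            raise ValueError(f"unknown curve shape {shape_name!r}")
        return factory[shape_name](n_lags=n_lags, **kw)


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

def _default_strengths() -> dict:
    # score points per unit of each covariate (t-score scale)
    return {
        "blood_lead": 2.0,
        "deprivation": 6.0,
        "greenspace": -5.0,
        "ecat": 5.0,
        "maternal_education[some college]": -1.0,
        "maternal_education[college or graduate school]": -2.0,
    }


def _default_corr() -> dict:
    # correlation of each covariate with the subject's latent log-exposure level
    return {
        "blood_lead": 0.2,
        "deprivation": 0.3,
        "greenspace": -0.3,
        "ecat": 0.3,
        "maternal_education": -0.3,
    }


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults emulate the study setting."""

    n_subjects: int = 300
    n_lags: int = 144
    seed: int = 0
    scale_name: str = "anxiety"

    # monitor series (ng/m3)
    monitor_start: str = "2001-01-01"
    monitor_end: str = "2016-01-01"
    monitor_baseline: float = 1.5
    monitor_amplitude: float = 0.5
    monitor_month_sd: float = 0.6   # log-scale calendar-month source variability
    monitor_noise_sd: float = 0.5   # log-scale observation-level noise
    baseline_window: tuple = ("2001-01-01", "2005-12-31")

    # births and residences
    birth_start: str = "2001-10-01"
    birth_end: str = "2003-07-31"
    exposure_median: float = 0.51   # target subject-level median (ng/m3)
    subject_log_sd: float = 0.3     # between-subject spread of log exposure
    ar1_rho: float = 0.7            # year-to-year log-exposure correlation
    ar1_sd: float = 0.35            # stationary sd of yearly log deviations
    move_probs: tuple = (0.5, 0.35, 0.15)  # P(0, 1, 2 address moves)
    move_log_sd: float = 0.4        # log-scale shift at an address change

    # outcome (t-score scale)
    outcome_mean: float = 50.0
    outcome_sd: float = 10.0        # nominal marginal sd (descriptive)
    noise_sd: float = 10.0          # residual sd of the generating equation

    confounder_strengths: dict = field(default_factory=_default_strengths)
    confounder_exposure_corr: dict = field(default_factory=_default_corr)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("monitor_noise_sd", "monitor_month_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("noise_sd", "outcome_sd", "subject_log_sd", "ar1_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(sum(self.move_probs) - 1.0) > 1e-9:
            raise ValueError("move_probs must sum to 1")
        start, end = pd.Timestamp(self.monitor_start), pd.Timestamp(self.monitor_end)
        b0, b1 = pd.Timestamp(self.baseline_window[0]), pd.Timestamp(self.baseline_window[1])
        needed = pd.Timestamp(self.birth_end) + pd.DateOffset(years=12)
        if end < b1 or start > b0:
            raise ValueError("monitor span does not cover the baseline period")
        if end < needed:
            raise ValueError(
                f"monitor span ends {end.date()}, before the last subject's "
                f"12th birthday {needed.date()}"
            )


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Complete synthetic study inputs plus the generating truth."""

    config: SimulationConfig
    monitor_series: MonitorSeries
    factors: object                       # ScalingFactorTable
    residence_histories: list
    exposure: MonthlyExposureMatrix
    covariates: pd.DataFrame              # subject_id, maternal_education, blood_lead
    covariate_visits: pd.DataFrame        # subject_id, visit_age, deprivation, ...
    outcomes: pd.DataFrame                # subject_id, scale, score, f/c/r indices
    truth: dict

    @property
    def subjects(self) -> list:
        return self.exposure.subjects

    def write(self, out_dir) -> None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.monitor_series.to_csv(out / "monitor.csv")
        residences_to_csv(self.residence_histories, out / "residences.csv")
        self.exposure.to_csv(out / "exposures.csv")
        self.covariates.to_csv(out / "covariates.csv", index=False,
                               float_format="%.12g")
        self.covariate_visits.to_csv(out / "covariate_visits.csv", index=False,
                                     float_format="%.12g")
        self.outcomes.to_csv(out / "outcomes.csv", index=False,
                             float_format="%.12g")
        truth = {
            "shape_name": self.truth["curve"].shape_name,
            "curve": list(self.truth["curve"].values),
            "gamma": self.truth["gamma"],
            "intercept": self.truth["intercept"],
            "seed": self.config.seed,
            "invalid": {k: list(v) for k, v in self.truth.get("invalid", {}).items()},
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def simulate_monitor_series(config: SimulationConfig,
                            rng: np.random.Generator | None = None) -> MonitorSeries:
    """Seasonal monitor series sampled at irregular 3-6 day intervals.

    concentration(t) = (baseline + amplitude * sin(2*pi * fraction-of-year))
    times a log-normal calendar-month source effect (sd ``monitor_month_sd``)
    times log-normal observation noise (sd ``monitor_noise_sd``).  Airborne
    lead is spiky: month-to-month source variability dominates the smooth
    seasonal cycle.  With both noise terms zero the series is the exact
    sinusoid; concentrations stay non-negative by construction.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    start = pd.Timestamp(config.monitor_start)
    end = pd.Timestamp(config.monitor_end)
    total_days = (end - start).days
    steps = rng.integers(3, 7, size=total_days // 3 + 2)
    offsets = np.concatenate([[0], np.cumsum(steps)])
    offsets = offsets[offsets <= total_days]
    dates = start + pd.to_timedelta(offsets, unit="D")
    doy = dates.dayofyear.to_numpy()
    seasonal = config.monitor_amplitude * np.sin(2 * np.pi * doy / 365.25)
    ym = (dates.year * 12 + dates.month - 1).to_numpy()
    month_eff = config.monitor_month_sd * rng.standard_normal(ym.max() - ym.min() + 1)
    noise = config.monitor_noise_sd * rng.standard_normal(len(dates))
    conc = ((config.monitor_baseline + seasonal).clip(0.0)
            * np.exp(month_eff[ym - ym.min()] + noise))
    return MonitorSeries(pd.DataFrame({"date": dates, "concentration": conc}),
                         monitor_id="synthetic")


def _covariate_draws(config: SimulationConfig, u: np.ndarray,
                     rng: np.random.Generator):
    """Subject-level covariates correlated with the exposure latent ``u``."""
    n = len(u)
    corr = config.confounder_exposure_corr

    def mix(r, z):
        r = float(np.clip(r, -1, 1))
        return r * u + np.sqrt(1 - r * r) * z

    # maternal education: ordered probit on a latent normal
    e_lat = mix(corr.get("maternal_education", 0.0), rng.standard_normal(n))
    cuts = stats.norm.ppf(np.cumsum(_EDU_PROBS)[:-1])
    edu = np.array(_EDU_LEVELS, dtype=object)[np.searchsorted(cuts, e_lat)]

    # blood lead (ug/dL): log-normal matching mean 0.57, sd 0.37
    cv2 = (0.37 / 0.57) ** 2
    sig = np.sqrt(np.log1p(cv2))
    mu = np.log(0.57) - sig ** 2 / 2
    blood = np.exp(mu + sig * mix(corr.get("blood_lead", 0.0),
                                  rng.standard_normal(n)))

    dep = np.clip(0.41 + 0.15 * mix(corr.get("deprivation", 0.0),
                                    rng.standard_normal(n)), 0.0, 1.0)
    green = np.clip(0.54 + 0.08 * mix(corr.get("greenspace", 0.0),
                                      rng.standard_normal(n)), -1.0, 1.0)
    ecat = np.clip(0.37 + 0.10 * mix(corr.get("ecat", 0.0),
                                     rng.standard_normal(n)), 0.01, None)
    return edu, blood, dep, green, ecat


def simulate_cohort(config: SimulationConfig, curve: TrueLagCurve) -> SyntheticCohort:
    """Generate a full synthetic cohort driven by ``curve``.

    Outcomes satisfy the linear DLM generating equation exactly (before
    noise); monthly exposures are built through `leadlag.exposure`.
    """
    if curve.n_lags != config.n_lags:
        raise ValueError(
            f"curve has {curve.n_lags} lags, config expects {config.n_lags}")
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    ids = [f"S{i + 1:04d}" for i in range(n)]

    monitor = simulate_monitor_series(config, rng=rng)
    factors = compute_scaling_factors(monitor, config.baseline_window)

    b0 = pd.Timestamp(config.birth_start)
    span = (pd.Timestamp(config.birth_end) - b0).days
    births = b0 + pd.to_timedelta(rng.integers(0, span + 1, n), unit="D")

    u = rng.standard_normal(n)  # latent driving exposure level and confounders
    edu, blood, dep, green, ecat = _covariate_draws(config, u, rng)

    # residence histories: log-normal annual estimates, AR(1) over years of
    # life, 0-2 moves with an address-level log shift.  The subject log level
    # is centred against the realized median scaling factor so the median
    # monthly exposure hits the configured target whatever the monitor noise.
    fmed = float(np.median(list(factors.factors.values())))
    mu_i = (np.log(config.exposure_median) - np.log(fmed)
            + config.subject_log_sd * u)
    histories = []
    for i in range(n):
        birth = births[i]
        a = np.empty(12)
        a[0] = config.ar1_sd * rng.standard_normal()
        innov_sd = config.ar1_sd * np.sqrt(1 - config.ar1_rho ** 2)
        for y in range(1, 12):
            a[y] = config.ar1_rho * a[y - 1] + innov_sd * rng.standard_normal()
        n_moves = rng.choice(len(config.move_probs), p=config.move_probs)
        end12 = birth + pd.DateOffset(years=12)
        move_days = np.sort(rng.integers(30, (end12 - birth).days - 30,
                                         size=n_moves))
        bounds = ([birth] + [birth + pd.Timedelta(days=int(d)) for d in move_days]
                  + [end12])
        deltas = np.concatenate([[0.0],
                                 config.move_log_sd * rng.standard_normal(n_moves)])
        intervals = []
        for y in range(12):
            ys = birth + pd.DateOffset(years=y)
            ye = birth + pd.DateOffset(years=y + 1)
            for k in range(len(bounds) - 1):
                s, e = max(bounds[k], ys), min(bounds[k + 1], ye)
                if s < e:
                    intervals.append((s, e, float(np.exp(mu_i[i] + a[y] + deltas[k]))))
        histories.append(ResidenceHistory(subject_id=ids[i], birth_date=birth,
                                          intervals=intervals))

    exposure = build_monthly_exposures(histories, factors, n_lags=config.n_lags)
    if np.isnan(exposure.values).any():
        raise RuntimeError("synthetic exposures contain missing cells; "
                           "monitor span does not cover all subject months")

    # covariate design exactly as the analysis model codes it
    covariates = pd.DataFrame({"subject_id": ids, "maternal_education": edu,
                               "blood_lead": blood, "deprivation": dep,
                               "greenspace": green, "ecat": ecat})
    from .dlm import build_covariate_design
    C, labels = build_covariate_design(
        covariates, ("maternal_education", "blood_lead", "deprivation",
                     "greenspace", "ecat"))
    gamma = dict(config.confounder_strengths)
    unknown = set(gamma) - set(labels)
    if unknown:
        raise ValueError(f"confounder_strengths refer to unknown terms: {unknown}")
    gvec = np.array([gamma.get(lab, 0.0) for lab in labels])

    signal = exposure.values @ curve.values
    cov_terms = C @ gvec
    intercept = float(config.outcome_mean - np.mean(signal + cov_terms))
    scores = intercept + signal + cov_terms + config.noise_sd * rng.standard_normal(n)

    outcomes = pd.DataFrame({
        "subject_id": ids,
        "scale": config.scale_name,
        "score": scores,
        "f_index": rng.integers(0, 5, n),
        "c_index": rng.integers(0, 12, n),
        "r_index": rng.integers(80, 116, n),
    })

    # six-visit panel: subject-level mean plus small visit-to-visit noise
    visit_sd = {"deprivation": 0.03, "greenspace": 0.02, "ecat": 0.02}
    rows = []
    for age in VISIT_AGES:
        rows.append(pd.DataFrame({
            "subject_id": ids, "visit_age": age,
            "deprivation": np.clip(dep + visit_sd["deprivation"]
                                   * rng.standard_normal(n), 0, 1),
            "greenspace": np.clip(green + visit_sd["greenspace"]
                                  * rng.standard_normal(n), -1, 1),
            "ecat": np.clip(ecat + visit_sd["ecat"]
                            * rng.standard_normal(n), 0.0, None),
        }))
    visits = pd.concat(rows, ignore_index=True).sort_values(
        ["subject_id", "visit_age"]).reset_index(drop=True)

    truth = {"curve": curve, "gamma": {lab: float(g) for lab, g in zip(labels, gvec)},
             "intercept": intercept, "covariate_design": pd.DataFrame(C, columns=labels),
             "signal": signal, "invalid": {}}
    return SyntheticCohort(config=config, monitor_series=monitor, factors=factors,
                           residence_histories=histories, exposure=exposure,
                           covariates=covariates, covariate_visits=visits,
                           outcomes=outcomes, truth=truth)


def inject_invalid_records(cohort: SyntheticCohort, fractions: dict,
                           seed: int = 12345) -> SyntheticCohort:
    """Plant invalid validity indices in a known, recorded subject subset.

    ``fractions`` maps any of "f", "c", "r" to the fraction of subjects
    (rounded to a count) receiving F>6, C>17 or R outside [66, 125].
    """
    for k, v in fractions.items():
        if not 0 <= v <= 1:
            raise ValueError(f"fraction for {k!r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out = cohort.outcomes.copy()
    n = len(out)
    invalid = {}
    for key, col in (("f", "f_index"), ("c", "c_index"), ("r", "r_index")):
        frac = fractions.get(key, 0.0)
        k = int(round(frac * n))
        if k == 0:
            continue
        pick = np.sort(rng.choice(n, size=k, replace=False))
        if key == "f":
            out.loc[pick, col] = 7
        elif key == "c":
            out.loc[pick, col] = 18
        else:
            out.loc[pick, col] = np.where(np.arange(k) % 2 == 0, 130, 60)
        invalid[key] = [out.loc[i, "subject_id"] for i in pick]
    truth = dict(cohort.truth)
    truth["invalid"] = invalid
    return replace(cohort, outcomes=out, truth=truth)
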