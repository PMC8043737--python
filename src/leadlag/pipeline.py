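"""End-to-end orchestration: simulate -> exposures -> QC -> DLM -> windows.

A run is driven by a `RunConfig` (YAML-serializable).  Every stochastic
stage derives from the single run seed, each artifact is stamped with it,
and identical config + seed reproduce byte-identical outputs.  All analysis
thresholds (edf cap, CI level, validity cutoffs, baseline window) live in
the config rather than in code.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dlm, qc, synthetic, windows as win
from .exposure import MonthlyExposureMatrix

logger = logging.getLogger("leadlag.pipeline")

ANALYSIS_COVARIATES = ("maternal_education", "blood_lead", "deprivation",
                       "greenspace", "ecat")


def setup_logging(level: str = "INFO", logfile=None) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(level=getattr(logging, level.upper()),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s",
                        handlers=handlers, force=True)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

def _default_scales() -> list:
    return [{"name": "anxiety", "shape": "bump",
             "peak": 1.0, "center": 60.0, "width": 12.0}]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    n_subjects: int = 300
    n_lags: int = 144
    scales: list = field(default_factory=_default_scales)
    basis_dialect: str = "cr"
    smoothing: str = "reml"
    ci_level: float = 0.95
    edf_cap: float = 20.0
    f_max: int = qc.F_MAX
    c_max: int = qc.C_MAX
    r_min: int = qc.R_MIN
    r_max: int = qc.R_MAX
    invalid_fractions: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    log_level: str = "INFO"
    # optional pre-built inputs (file mode); when set, simulation is skipped
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.edf_cap < 4:
            raise ValueError("edf_cap must be >= 4")
        for s in self.scales:
            if "name" not in s or "shape" not in s:
                raise ValueError(f"scale entry needs 'name' and 'shape': {s}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _sim_config(config: RunConfig, scale: dict, seed: int) -> synthetic.SimulationConfig:
    kw = dict(config.simulation)
    kw.update(n_subjects=config.n_subjects, n_lags=config.n_lags,
              seed=seed, scale_name=scale["name"])
    return synthetic.SimulationConfig(**kw)


def _curve_for(scale: dict, n_lags: int) -> synthetic.TrueLagCurve:
    kw = {k: v for k, v in scale.items() if k not in ("name", "shape")}
    return synthetic.TrueLagCurve.from_shape(scale["shape"], n_lags=n_lags, **kw)


# ---------------------------------------------------------------------------
# Fit serialization
# ---------------------------------------------------------------------------

def fit_to_dict(fit: dlm.DLMFit) -> dict:
    return {
        "intercept": fit.intercept,
        "theta": [float(t) for t in fit.theta],
        "gamma": {k: float(v) for k, v in fit.gamma.items()},
        "lambda": fit.lam,
        "edf": fit.edf,
        "edf_total": fit.edf_total,
        "residual_sd": fit.residual_sd,
        "n_used": fit.n_used,
        "refit": fit.refit,
        "basis": {"kind": fit.basis.kind, "dialect": fit.basis.dialect,
                  "n_knots": int(fit.basis.n_coef)},
        "exclusions": {k: list(v) for k, v in fit.exclusions.items()},
        "theta_covariance": [[float(v) for v in row]
                             for row in fit.theta_covariance],
    }


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            logger.info("stage %s: done", name)
    return _Ctx()


def run_pipeline(config: RunConfig) -> Path:
    """Run the full synthetic reproduction; returns the run directory.

    For each configured scale: simulate a cohort driven by that scale's true
    curve, apply validity QC and covariate averaging, fit the penalized DLM
    (adjusted and unadjusted, with the edf refit rule), detect sensitive
    windows, and write fit JSON, curve CSV, window CSV, exclusion ledgers
    and a manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.inputs:
        for key, path in config.inputs.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"configured input '{key}' not found: {path}")

    all_windows = []
    manifest = {"seed": config.seed, "config": config.to_dict(), "scales": {}}
    for idx, scale in enumerate(config.scales):
        name = scale["name"]
        scale_seed = config.seed + idx  # one base seed threads every stage
        sdir = out / name
        sdir.mkdir(exist_ok=True)

        with _stage(f"simulate[{name}]"):
            sim_cfg = _sim_config(config, scale, scale_seed)
            curve_true = _curve_for(scale, config.n_lags)
            cohort = synthetic.simulate_cohort(sim_cfg, curve_true)
            if config.invalid_fractions:
                cohort = synthetic.inject_invalid_records(
                    cohort, config.invalid_fractions, seed=scale_seed + 500000)
            cohort.write(sdir / "data")

        with _stage(f"qc[{name}]"):
            kept, ledger = qc.filter_valid_basc(
                cohort.outcomes, f_max=config.f_max, c_max=config.c_max,
                r_min=config.r_min, r_max=config.r_max)
            ledger.to_csv(sdir / "validity_exclusions.csv", index=False)
            panel = qc.build_covariate_panel(cohort.covariates,
                                            cohort.covariate_visits)

        with _stage(f"fit[{name}]"):
            keep_mask = np.array([s in set(kept) for s in cohort.subjects])
            x = MonthlyExposureMatrix(
                subjects=[s for s, k in zip(cohort.subjects, keep_mask) if k],
                values=cohort.exposure.values[keep_mask])
            scores = (cohort.outcomes.set_index("subject_id")
                      .loc[x.subjects, "score"])
            covars = panel.values.loc[x.subjects].reset_index()
            results = {}
            for adjusted in (True, False):
                tag = "adjusted" if adjusted else "unadjusted"
                spec = dlm.ModelSpec(
                    outcome_name=name,
                    covariate_names=ANALYSIS_COVARIATES if adjusted else (),
                    n_lags=config.n_lags, dialect=config.basis_dialect,
                    smoothing=config.smoothing, adjusted=adjusted,
                    ci_level=config.ci_level, edf_cap=config.edf_cap)
                fit = dlm.fit_with_refit_rule(x, scores,
                                              covars if adjusted else None,
                                              spec=spec)
                curve = dlm.lag_effects(fit, level=config.ci_level)
                wins = win.detect_windows(curve)
                report = win.summarize_peaks(wins, curve, scale=name)
                report.insert(1, "model", tag)
                (sdir / f"fit_{tag}.json").write_text(
                    json.dumps(fit_to_dict(fit), indent=1, sort_keys=True))
                curve.to_csv(sdir / f"curve_{tag}.csv")
                report.to_csv(sdir / f"windows_{tag}.csv", index=False,
                              float_format="%.12g")
                excl = [(reason, sid) for reason, sids in fit.exclusions.items()
                        for sid in sids]
                pd.DataFrame(excl, columns=["reason", "subject_id"]).to_csv(
                    sdir / f"fit_exclusions_{tag}.csv", index=False)
                results[tag] = (fit, curve)
                all_windows.append(report)

        overlap = compare_adjusted_unadjusted(results["adjusted"][1],
                                              results["unadjusted"][1])
        manifest["scales"][name] = {
            "seed": scale_seed,
            "n_used_adjusted": results["adjusted"][0].n_used,
            "n_used_unadjusted": results["unadjusted"][0].n_used,
            "edf_adjusted": results["adjusted"][0].edf,
            "edf_unadjusted": results["unadjusted"][0].edf,
            "refit_adjusted": results["adjusted"][0].refit,
            "refit_unadjusted": results["unadjusted"][0].refit,
            "adjusted_unadjusted_overlap": overlap["overlap"],
        }

    if all_windows:
        pd.concat(all_windows, ignore_index=True).to_csv(
            out / "windows.csv", index=False, float_format="%.12g")
    from . import __version__
    manifest["version"] = __version__
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return out


def compare_adjusted_unadjusted(curve_a: dlm.LagEffectCurve,
                                curve_u: dlm.LagEffectCurve) -> dict:
    """Window overlap (Jaccard over window months) and peak differences
    between adjusted and unadjusted fits of the same scale."""
    if len(curve_a.lag) != len(curve_u.lag):
        raise ValueError("adjusted and unadjusted curves have different lag counts")
    wa = win.detect_windows(curve_a)
    wu = win.detect_windows(curve_u)
    ma = set().union(*[set(w.months) for w in wa]) if wa else set()
    mu = set().union(*[set(w.months) for w in wu]) if wu else set()
    union = ma | mu
    overlap = 1.0 if not union else len(ma & mu) / len(union)
    peaks_a = {w.peak_month: w.peak_effect for w in wa}
    peaks_u = {w.peak_month: w.peak_effect for w in wu}
    peak_diff = float(np.max(np.abs(curve_a.beta - curve_u.beta)))
    return {"overlap": overlap, "months_adjusted": sorted(ma),
            "months_unadjusted": sorted(mu), "peaks_adjusted": peaks_a,
            "peaks_unadjusted": peaks_u, "max_curve_difference": peak_diff}
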